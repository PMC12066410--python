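"""Alpha/beta diversity, ordination, clustering and PERMANOVA.

The PERMANOVA here partitions a distance matrix sequentially (Type-I,
factors in the order given), matching the convention of a single
ordered-factor table: Gower-center the squared distance matrix,

    G = -1/2 (I - 11'/n) D^2 (I - 11'/n),

then attribute SS via nested projection (hat) matrices H_0 ⊂ H_1 ⊂ ...
built by adding one factor's design columns at a time:

    SS_k = tr((H_k - H_{k-1}) G),   SS_res = tr((I - H_m) G).

Pseudo-F per factor is (SS_k/df_k) / (SS_res/df_res); significance comes
from free permutation of sample labels, p = (b + 1) / (m + 1).  R^2 is
SS_k over tr(G).  Numeric factor columns enter as single covariates
(1 df), categorical columns as dummy sets.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist, squareform

from .modeling import bh_adjust

RESIDUAL = "Residual"
TOTAL = "Total"


def shannon_index(profile: pd.DataFrame) -> pd.Series:
    """Shannon diversity H = -sum p_i ln p_i per sample (nats).

    ``profile`` is species x sample (counts or percents; proportions are
    recomputed per sample).  All-zero samples yield a missing value.
    """
    values = profile.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("abundances must be nonnegative")
    totals = values.sum(axis=0)
    out = np.full(values.shape[1], np.nan)
    for j, total in enumerate(totals):
        if total > 0:
            p = values[:, j][values[:, j] > 0] / total
            out[j] = float(-(p * np.log(p)).sum())
    return pd.Series(out, index=profile.columns, name="shannon")


def bray_curtis(profile: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between samples.

    d(A, B) = 1 - 2 sum_i min(A_i, B_i) / (sum A + sum B); entries lie in
    [0, 1].  A pair of all-zero samples has no defined dissimilarity and
    is flagged (NaN).
    """
    if profile.shape[1] < 2:
        raise ValueError("need at least two samples")
    X = profile.to_numpy(dtype=float).T
    zero = X.sum(axis=1) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        condensed = pdist(X, metric="braycurtis")
    dm = squareform(condensed)
    np.fill_diagonal(dm, 0.0)
    if zero.sum() >= 2:
        warnings.warn(
            "all-zero sample pair(s): Bray-Curtis undefined for those entries",
            stacklevel=2,
        )
    return pd.DataFrame(dm, index=profile.columns, columns=profile.columns)


@dataclass(frozen=True)
class PermanovaResult:
    """Sequential PERMANOVA table: one row per factor plus residual/total."""

    table: pd.DataFrame
    n_permutations: int

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PermanovaResult(n_permutations={self.n_permutations})\n{self.table}"


def _gower_center(distances: np.ndarray) -> np.ndarray:
    n = distances.shape[0]
    a = -0.5 * distances**2
    centerer = np.eye(n) - np.full((n, n), 1.0 / n)
    return centerer @ a @ centerer


def _factor_columns(values: pd.Series) -> np.ndarray:
    """Design columns for one factor: numeric -> one centered column,
    categorical -> full dummy set (rank handled by projections)."""
    if pd.api.types.is_numeric_dtype(values):
        col = values.to_numpy(dtype=float)
        return (col - col.mean())[:, None]
    return pd.get_dummies(values.astype(str)).to_numpy(dtype=float)


def _hat(X: np.ndarray) -> np.ndarray:
    return X @ np.linalg.pinv(X)


def permanova(
    distances: pd.DataFrame,
    factors: pd.DataFrame,
    n_permutations: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Sequential (Type-I) PERMANOVA on a distance matrix.

    ``factors`` columns are tested in the order given; its index must
    align with the distance matrix.  Collinear factors contributing no
    new design dimensions are reported with df = 0 and flagged.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if list(distances.index) != list(distances.columns):
        raise ValueError("distance matrix index/columns mismatch")
    factors = factors.loc[list(distances.index)]
    d = distances.to_numpy(dtype=float)
    if not np.allclose(d, d.T, equal_nan=True):
        raise ValueError("distance matrix is not symmetric")
    n = d.shape[0]
    G = _gower_center(d)
    ss_total = float(np.trace(G))

    X = np.ones((n, 1))
    H_prev = _hat(X)
    rank_prev = 1
    projectors, dfs, names = [], [], []
    for name in factors.columns:
        X = np.hstack([X, _factor_columns(factors[name])])
        rank = int(np.linalg.matrix_rank(X))
        H = _hat(X)
        projectors.append(H - H_prev)
        dfs.append(rank - rank_prev)
        names.append(str(name))
        if rank == rank_prev:
            warnings.warn(
                f"factor {name!r} is collinear with preceding factors (df = 0)",
                stacklevel=2,
            )
        H_prev, rank_prev = H, rank
    R = np.eye(n) - H_prev
    df_res = n - rank_prev

    def _partition(Gm: np.ndarray) -> tuple[np.ndarray, float]:
        ss = np.array([float(np.sum(P * Gm)) for P in projectors])
        return ss, float(np.sum(R * Gm))

    ss_factors, ss_res = _partition(G)
    ms_res = ss_res / df_res if df_res > 0 else np.nan
    F_obs = np.array(
        [
            (ss / df) / ms_res if df > 0 and ms_res > 0 else np.nan
            for ss, df in zip(ss_factors, dfs)
        ]
    )

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(names))
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        Gp = G[np.ix_(perm, perm)]
        ss_p, ss_res_p = _partition(Gp)
        ms_res_p = ss_res_p / df_res if df_res > 0 else np.nan
        for k, df in enumerate(dfs):
            if df > 0 and ms_res_p > 0:
                if (ss_p[k] / df) / ms_res_p >= F_obs[k]:
                    exceed[k] += 1
    pvals = np.where(
        np.isnan(F_obs), np.nan, (exceed + 1) / (n_permutations + 1)
    )

    rows = {
        name: {
            "df": df,
            "SumOfSqs": ss,
            "R2": ss / ss_total if ss_total > 0 else np.nan,
            "F": F,
            "P": p,
        }
        for name, df, ss, F, p in zip(names, dfs, ss_factors, F_obs, pvals)
    }
    rows[RESIDUAL] = {
        "df": df_res,
        "SumOfSqs": ss_res,
        "R2": ss_res / ss_total if ss_total > 0 else np.nan,
        "F": np.nan,
        "P": np.nan,
    }
    rows[TOTAL] = {
        "df": n - 1,
        "SumOfSqs": ss_total,
        "R2": 1.0,
        "F": np.nan,
        "P": np.nan,
    }
    table = pd.DataFrame(rows).T[["df", "SumOfSqs", "R2", "F", "P"]]
    table["df"] = table["df"].astype(int)
    return PermanovaResult(table, n_permutations)


def pairwise_permanova(
    distances: pd.DataFrame,
    grouping: pd.Series,
    n_permutations: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """One-factor PERMANOVA per group pair, BH-adjusted across pairs.

    Groups with fewer than two samples are skipped with a warning.
    Returns one row per pair: group_a, group_b, n_a, n_b, R2, F, p, q.
    """
    grouping = grouping.loc[list(distances.index)]
    sizes = grouping.value_counts()
    usable = sorted(sizes.index[sizes >= 2])
    skipped = sorted(sizes.index[sizes < 2])
    if skipped:
        warnings.warn(
            f"group(s) with a single sample skipped: {skipped}", stacklevel=2
        )
    rng = np.random.default_rng(seed)
    rows = []
    for a, b in itertools.combinations(usable, 2):
        members = grouping.index[grouping.isin([a, b])]
        sub = distances.loc[members, members]
        result = permanova(
            sub,
            grouping.loc[members].to_frame("group"),
            n_permutations=n_permutations,
            seed=int(rng.integers(2**31)),
        )
        row = result.table.loc["group"]
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "n_a": int(sizes[a]),
                "n_b": int(sizes[b]),
                "R2": row["R2"],
                "F": row["F"],
                "p": row["P"],
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q"] = bh_adjust(out["p"].to_numpy())
    return out


@dataclass(frozen=True)
class ClrPcaResult:
    """Principal components of CLR-transformed composition."""

    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # features x components
    explained_variance_ratio: pd.Series
    pseudocount: float


def clr_transform(profile: pd.DataFrame, pseudocount: float) -> pd.DataFrame:
    """Centered log-ratio per sample: ln(x + pc) minus the sample mean log."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    logged = np.log(profile.to_numpy(dtype=float) + pseudocount)
    clr = logged - logged.mean(axis=0, keepdims=True)
    return pd.DataFrame(clr, index=profile.index, columns=profile.columns)


def default_pseudocount(profile: pd.DataFrame) -> float:
    """Half the smallest nonzero value in the matrix."""
    values = profile.to_numpy(dtype=float)
    nonzero = values[values > 0]
    if nonzero.size == 0:
        raise ValueError("profile has no nonzero values")
    return float(nonzero.min() / 2.0)


def clr_pca(
    profile: pd.DataFrame, pseudocount: float | None = None
) -> ClrPcaResult:
    """PCA of the CLR-transformed species x sample profile.

    Samples are observations.  Components are deterministic up to the
    sign convention that each component's largest-magnitude loading is
    positive.
    """
    if pseudocount is None:
        pseudocount = default_pseudocount(profile)
    clr = clr_transform(profile, pseudocount)
    X = clr.to_numpy(dtype=float).T  # samples x features
    X = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    # Deterministic sign: largest |loading| per component is positive.
    for k in range(Vt.shape[0]):
        pivot = np.argmax(np.abs(Vt[k]))
        if Vt[k, pivot] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    scores = U * s
    var = s**2
    ratio = var / var.sum() if var.sum() > 0 else var
    comps = [f"PC{k + 1}" for k in range(len(s))]
    return ClrPcaResult(
        scores=pd.DataFrame(scores, index=profile.columns, columns=comps),
        loadings=pd.DataFrame(Vt.T, index=profile.index, columns=comps),
        explained_variance_ratio=pd.Series(ratio, index=comps),
        pseudocount=float(pseudocount),
    )


@dataclass(frozen=True)
class WardResult:
    """Ward.D2 dendrogram over the rows of a matrix."""

    linkage_matrix: np.ndarray
    labels: tuple[str, ...]
    newick: str


def _newick(node, labels: tuple[str, ...]) -> str:
    if node.is_leaf():
        return labels[node.id]
    left, right = node.get_left(), node.get_right()
    parts = []
    for child in (left, right):
        branch = node.dist - child.dist
        parts.append(f"{_newick(child, labels)}:{branch:.10g}")
    return f"({parts[0]},{parts[1]})"


def ward_cluster(
    matrix: pd.DataFrame,
    log_transform: bool = True,
    pseudocount: float | None = None,
) -> WardResult:
    """Agglomerative ward.D2 clustering of matrix rows (Euclidean).

    With ``log_transform`` the values are ln(x + pseudocount) first
    (pseudocount defaults to half the smallest nonzero value when zeros
    are present).  Merge heights are the ward.D2 criterion values;
    the Newick string carries branch lengths derived from them.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least two rows to cluster")
    X = matrix.to_numpy(dtype=float)
    if log_transform:
        if pseudocount is None:
            pseudocount = default_pseudocount(matrix) if (X == 0).any() else 0.0
        with np.errstate(divide="ignore", invalid="ignore"):
            X = np.log(X + pseudocount)
    if not np.isfinite(X).all():
        raise ValueError("non-finite values after transform")
    Z = linkage(X, method="ward")
    labels = tuple(str(i) for i in matrix.index)
    tree = to_tree(Z)
    return WardResult(Z, labels, f"{_newick(tree, labels)};")
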