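"""Per-feature inferential statistics.

Each feature (species percent, functional category NSAF%, ...) is
modeled with a linear mixed-effects model

    value ~ group * diet + (1 | mouse)

fit by REML, with sum-to-zero contrasts so the diet main effect is a
marginal (Type-III-style) test.  Diet significance is a Wald F on the
diet main-effect coefficients with residual denominator degrees of
freedom; per-diet marginal means average the fixed-effect predictions
over groups with equal weight and carry Wald 95% confidence intervals.
Two-condition comparisons use Welch's unequal-variance t-test with
log2 fold-changes, and multiple testing is controlled with
Benjamini-Hochberg q-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

Z_95 = 1.959963984540054


class WelchResult(NamedTuple):
    t: float
    p: float
    log2fc: float


def welch_test(
    group_a: np.ndarray, group_b: np.ndarray, floor: float | None = None
) -> WelchResult:
    """Welch's unequal-variance t-test plus log2 fold-change (a over b).

    Degenerate zero-variance inputs are resolved by the limit of the
    statistic: equal constant groups give t = 0, p = 1; unequal
    constants give |t| = inf, p = 0.  ``floor`` clips both means from
    below before the fold-change so features absent from one condition
    stay finite; without a floor a non-positive mean yields a flagged
    NaN fold-change.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2 or not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("each group needs >= 2 finite values")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t = np.inf if a.mean() > b.mean() else -np.inf
            p = 0.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=False)
        t, p = float(t), float(p)

    mean_a, mean_b = float(a.mean()), float(b.mean())
    if floor is not None:
        mean_a, mean_b = max(mean_a, floor), max(mean_b, floor)
    if mean_a <= 0 or mean_b <= 0:
        warnings.warn(
            "non-positive group mean with no abundance floor; log2fc undefined",
            stacklevel=2,
        )
        log2fc = np.nan
    else:
        log2fc = float(np.log2(mean_a / mean_b))
    return WelchResult(t, p, log2fc)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_features(
    nsaf_a: pd.DataFrame,
    nsaf_b: pd.DataFrame,
    q_threshold: float = 0.05,
    floor: float | None = None,
) -> pd.DataFrame:
    """Per-feature Welch tests between two conditions with BH control.

    ``nsaf_a``/``nsaf_b`` are feature x sample matrices from the two
    conditions; features are intersected.  The fold-change floor
    defaults to half the smallest nonzero value across both matrices.
    Returns one row per feature with t, p, q, log2fc (a over b) and a
    ``significant`` flag at q <= ``q_threshold``.
    """
    features = nsaf_a.index.intersection(nsaf_b.index)
    if len(features) == 0:
        warnings.warn("no shared features between conditions", stacklevel=2)
        return pd.DataFrame(
            columns=["mean_a", "mean_b", "t", "p", "q", "log2fc", "significant"]
        )
    if floor is None:
        combined = np.concatenate(
            [nsaf_a.loc[features].to_numpy().ravel(),
             nsaf_b.loc[features].to_numpy().ravel()]
        )
        nonzero = combined[combined > 0]
        floor = float(nonzero.min() / 2.0) if nonzero.size else None

    rows = []
    for feature in features:
        res = welch_test(
            nsaf_a.loc[feature].to_numpy(),
            nsaf_b.loc[feature].to_numpy(),
            floor=floor,
        )
        rows.append(
            {
                "feature": feature,
                "mean_a": float(nsaf_a.loc[feature].mean()),
                "mean_b": float(nsaf_b.loc[feature].mean()),
                "t": res.t,
                "p": res.p,
                "log2fc": res.log2fc,
            }
        )
    out = pd.DataFrame(rows).set_index("feature")
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["q"] <= q_threshold
    return out[["mean_a", "mean_b", "t", "p", "q", "log2fc", "significant"]]


# ---------------------------------------------------------------------------
# Mixed-effects models


@dataclass(frozen=True)
class FeatureLmmResult:
    """Fixed-effect inference for one feature."""

    feature: str
    diet_F: float
    diet_p: float
    flag: str  # "" | "zero_variance" | "singular"
    marginal_means: pd.DataFrame  # diet -> mean, ci_low, ci_high, se


def _fit_one_lmm(
    feature: str, data: pd.DataFrame, reml: bool = True
) -> FeatureLmmResult:
    diets = sorted(data["diet"].unique())
    groups = sorted(data["group"].unique())

    y = data["value"].to_numpy(dtype=float)
    if np.allclose(y, y[0]):
        constant = float(y[0])
        means = pd.DataFrame(
            {
                "mean": constant,
                "ci_low": constant,
                "ci_high": constant,
                "se": 0.0,
            },
            index=pd.Index(diets, name="diet"),
        )
        return FeatureLmmResult(feature, 0.0, 1.0, "zero_variance", means)

    crossed = data.groupby(["diet", "group"]).size().unstack(fill_value=0)
    singular = (crossed == 0).any(axis=None) and len(groups) > 1
    if not singular:
        try:
            return _fit_mixed(feature, data, diets, groups, reml)
        except (np.linalg.LinAlgError, ValueError):
            singular = True
    if singular:
        # A diet observed in one group only: the interaction is not
        # estimable.  Degrade to group-specific cell means.
        cell = data.groupby("diet")["value"].agg(["mean", "sem", "size"])
        means = pd.DataFrame(
            {
                "mean": cell["mean"],
                "ci_low": cell["mean"] - Z_95 * cell["sem"].fillna(0.0),
                "ci_high": cell["mean"] + Z_95 * cell["sem"].fillna(0.0),
                "se": cell["sem"].fillna(0.0),
            }
        )
        means.index.name = "diet"
        return FeatureLmmResult(feature, np.nan, np.nan, "singular", means)
    raise AssertionError("unreachable")


def _fit_mixed(
    feature: str, data: pd.DataFrame, diets, groups, reml: bool
) -> FeatureLmmResult:
    import statsmodels.formula.api as smf
    from patsy import build_design_matrices

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            "value ~ C(group, Sum) * C(diet, Sum)", data, groups=data["mouse"]
        )
        fit = model.fit(reml=reml)

    params = np.asarray(fit.fe_params)
    cov = np.asarray(fit.cov_params())[: len(params), : len(params)]
    names = list(fit.model.exog_names)
    diet_idx = [
        i
        for i, name in enumerate(names)
        if "C(diet, Sum)" in name and ":" not in name
    ]
    L = np.zeros((len(diet_idx), len(params)))
    for row, i in enumerate(diet_idx):
        L[row, i] = 1.0
    Lb = L @ params
    LVL = L @ cov @ L.T
    wald = float(Lb @ np.linalg.solve(LVL, Lb))
    q = len(diet_idx)
    n = len(data)
    rank = int(np.linalg.matrix_rank(fit.model.exog))
    ddf = max(n - rank, 1)
    F = wald / q
    p = float(stats.f.sf(F, q, ddf))

    design_info = fit.model.data.design_info
    rows = []
    for diet in diets:
        grid = pd.DataFrame({"group": groups, "diet": diet})
        (X,) = build_design_matrices([design_info], grid)
        x = np.asarray(X).mean(axis=0)  # equal weight over groups
        mean = float(x @ params)
        se = float(np.sqrt(x @ cov @ x))
        rows.append(
            {
                "diet": diet,
                "mean": mean,
                "ci_low": mean - Z_95 * se,
                "ci_high": mean + Z_95 * se,
                "se": se,
            }
        )
    means = pd.DataFrame(rows).set_index("diet")
    return FeatureLmmResult(feature, F, p, "", means)


def fit_feature_lmm(
    values: pd.DataFrame,
    metadata: pd.DataFrame,
    mouse_col: str = "mouse_id",
    group_col: str = "mouse_group",
    diet_col: str = "diet",
    reml: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit the group*diet mixed model to every feature.

    ``values`` is feature x sample; ``metadata`` is indexed by sample
    (or carries a ``sample_id`` column) with mouse, group and diet
    columns.  Returns ``(stats, marginal_means)``: per-feature diet F,
    p, BH q and a flag; and per-(feature, diet) marginal means with 95%
    confidence intervals.
    """
    meta = metadata.copy()
    if "sample_id" in meta.columns:
        meta = meta.set_index("sample_id")
    missing = [s for s in values.columns if s not in meta.index]
    if missing:
        raise ValueError(f"metadata missing sample {missing[0]!r}")
    meta = meta.loc[list(values.columns)]
    base = pd.DataFrame(
        {
            "mouse": meta[mouse_col].astype(str),
            "group": meta[group_col].astype(str),
            "diet": meta[diet_col].astype(str),
        },
        index=meta.index,
    )

    results, mean_frames = [], []
    for feature in values.index:
        data = base.copy()
        data["value"] = values.loc[feature].to_numpy(dtype=float)
        res = _fit_one_lmm(str(feature), data, reml=reml)
        results.append(
            {
                "feature": res.feature,
                "diet_F": res.diet_F,
                "diet_p": res.diet_p,
                "flag": res.flag,
            }
        )
        mm = res.marginal_means.reset_index()
        mm.insert(0, "feature", res.feature)
        mean_frames.append(mm)

    stats_df = pd.DataFrame(results).set_index("feature")
    testable = stats_df["diet_p"].notna()
    q = pd.Series(np.nan, index=stats_df.index)
    if testable.any():
        q.loc[testable] = bh_adjust(stats_df.loc[testable, "diet_p"].to_numpy())
    stats_df["diet_q"] = q
    means_df = pd.concat(mean_frames, ignore_index=True)
    return stats_df, means_df
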