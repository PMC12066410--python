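"""Diversity metrics, PERMANOVA vs independent oracles, clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from metaprot import diversity as dv


def euclidean_dm(points, ids):
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(points))
    return pd.DataFrame(d, index=ids, columns=ids)


def oracle_oneway_ss(dm: pd.DataFrame, groups: pd.Series):
    """Classical PERMANOVA sums of squares from within-group distances:
    SS_total = (1/n) sum_{i<j} d_ij^2, SS_within = sum_g (1/n_g) sum_{i<j in g} d_ij^2.
    """
    d2 = dm.to_numpy() ** 2
    n = len(dm)
    iu = np.triu_indices(n, 1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in groups.unique():
        idx = np.where(groups.to_numpy() == g)[0]
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return ss_total, ss_total - ss_within


def oracle_sequential_embedding(dm: pd.DataFrame, factors: pd.DataFrame):
    """Independent sequential partition: eigen-embed the Gower-centered
    matrix into coordinates Y (Y Y' = G) and run ordinary sequential
    multivariate regression on Y."""
    d = dm.to_numpy(dtype=float)
    n = d.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    G = -0.5 * J @ (d**2) @ J
    vals, vecs = np.linalg.eigh(G)
    vals = np.clip(vals, 0, None)
    Y = vecs * np.sqrt(vals)

    def design(cols):
        X = np.ones((n, 1))
        for c in cols:
            if pd.api.types.is_numeric_dtype(factors[c]):
                X = np.hstack([X, factors[c].to_numpy(float)[:, None]])
            else:
                X = np.hstack(
                    [X, pd.get_dummies(factors[c].astype(str)).to_numpy(float)]
                )
        return X

    names = list(factors.columns)
    ss = []
    prev_fit = np.zeros_like(Y)
    for k in range(1, len(names) + 1):
        X = design(names[:k])
        fit = X @ np.linalg.lstsq(X, Y, rcond=None)[0]
        ss.append(float(((fit - prev_fit) ** 2).sum()))
        prev_fit = fit
    ss_res = float(((Y - prev_fit) ** 2).sum())
    return np.array(ss), ss_res, float((Y - Y.mean(0)).ravel() @ (Y - Y.mean(0)).ravel())


class TestShannon:
    def test_single_species_zero(self):
        profile = pd.DataFrame({"s1": [10.0, 0.0]})
        assert dv.shannon_index(profile)["s1"] == 0.0

    def test_four_equal_species_ln4(self):
        profile = pd.DataFrame({"s1": [25.0] * 4})
        assert dv.shannon_index(profile)["s1"] == pytest.approx(np.log(4), abs=1e-9)

    def test_hand_computed_mixture(self):
        profile = pd.DataFrame({"s1": [0.5, 0.25, 0.25]})
        expected = -(0.5 * np.log(0.5) + 2 * 0.25 * np.log(0.25))
        assert dv.shannon_index(profile)["s1"] == pytest.approx(expected, abs=1e-9)

    def test_all_zero_sample_missing(self):
        profile = pd.DataFrame({"s1": [0.0, 0.0]})
        assert np.isnan(dv.shannon_index(profile)["s1"])

    @given(
        st.lists(st.integers(min_value=0, max_value=500), min_size=2, max_size=30).filter(
            lambda xs: sum(xs) > 0
        )
    )
    def test_bounded_by_log_richness(self, counts):
        profile = pd.DataFrame({"s1": [float(c) for c in counts]})
        h = dv.shannon_index(profile)["s1"]
        k = sum(c > 0 for c in counts)
        assert h <= np.log(k) + 1e-12
        if len(set(c for c in counts if c > 0)) == 1:
            assert h == pytest.approx(np.log(k), abs=1e-12)


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        profile = pd.DataFrame({"a": [3.0, 1.0], "b": [3.0, 1.0]})
        assert dv.bray_curtis(profile).loc["a", "b"] == 0.0

    def test_disjoint_supports_one(self):
        profile = pd.DataFrame({"a": [3.0, 0.0], "b": [0.0, 5.0]})
        assert dv.bray_curtis(profile).loc["a", "b"] == 1.0

    def test_worked_pair(self):
        profile = pd.DataFrame({"a": [2.0, 1.0], "b": [1.0, 3.0]})
        assert dv.bray_curtis(profile).loc["a", "b"] == pytest.approx(3 / 7, abs=1e-9)

    @given(st.integers(0, 2**31 - 1))
    def test_symmetric_bounded_zero_diagonal(self, seed):
        rng = np.random.default_rng(seed)
        profile = pd.DataFrame(
            rng.integers(1, 50, size=(5, 4)).astype(float),
            columns=list("abcd"),
        )
        dm = dv.bray_curtis(profile)
        arr = dm.to_numpy()
        assert np.allclose(arr, arr.T)
        assert np.all(np.diag(arr) == 0)
        assert ((arr >= 0) & (arr <= 1)).all()


class TestPermanova:
    def test_constant_factor_zero_ss(self):
        rng = np.random.default_rng(0)
        dm = euclidean_dm(rng.random((6, 3)), list("abcdef"))
        factors = pd.DataFrame({"g": ["x"] * 6}, index=list("abcdef"))
        with pytest.warns(UserWarning, match="collinear"):
            res = dv.permanova(dm, factors, n_permutations=9, seed=0)
        assert res.table.loc["g", "SumOfSqs"] == pytest.approx(0.0, abs=1e-12)
        assert res.table.loc["g", "df"] == 0

    def test_two_clear_groups_match_brute_force(self):
        d = np.ones((6, 6))
        d[:3, :3] = 0
        d[3:, 3:] = 0
        np.fill_diagonal(d, 0)
        dm = pd.DataFrame(d, index=list("abcdef"), columns=list("abcdef"))
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=list("abcdef"))
        res = dv.permanova(dm, groups.to_frame("g"), n_permutations=99, seed=1)
        ss_total, ss_between = oracle_oneway_ss(dm, groups)
        assert res.table.loc["Total", "SumOfSqs"] == pytest.approx(ss_total, abs=1e-9)
        assert res.table.loc["g", "SumOfSqs"] == pytest.approx(ss_between, abs=1e-9)
        assert res.table.loc["g", "R2"] == pytest.approx(ss_between / ss_total, abs=1e-9)

    def test_oneway_matches_formula_oracle_random(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            points = rng.normal(size=(8, 4))
            ids = [f"s{i}" for i in range(8)]
            dm = euclidean_dm(points, ids)
            groups = pd.Series(rng.choice(["A", "B", "C"], 8), index=ids)
            if groups.nunique() < 2:
                continue
            res = dv.permanova(dm, groups.to_frame("g"), n_permutations=19, seed=3)
            ss_total, ss_between = oracle_oneway_ss(dm, groups)
            assert res.table.loc["g", "SumOfSqs"] == pytest.approx(ss_between, abs=1e-9)
            assert res.table.loc["Total", "SumOfSqs"] == pytest.approx(ss_total, abs=1e-9)

    def test_sequential_matches_embedding_oracle(self):
        rng = np.random.default_rng(4)
        ids = [f"s{i}" for i in range(8)]
        points = rng.normal(size=(8, 5))
        dm = euclidean_dm(points, ids)
        factors = pd.DataFrame(
            {
                "f1": rng.choice(["a", "b"], 8),
                "f2": rng.choice(["x", "y", "z"], 8),
                "age": np.arange(8, dtype=float),
            },
            index=ids,
        )
        res = dv.permanova(dm, factors, n_permutations=19, seed=5)
        ss, ss_res, ss_total = oracle_sequential_embedding(dm, factors)
        for name, expected in zip(["f1", "f2", "age"], ss):
            assert res.table.loc[name, "SumOfSqs"] == pytest.approx(expected, abs=1e-9)
        assert res.table.loc["Residual", "SumOfSqs"] == pytest.approx(ss_res, abs=1e-9)

    def test_partition_sums_to_total(self):
        rng = np.random.default_rng(6)
        ids = [f"s{i}" for i in range(10)]
        dm = euclidean_dm(rng.normal(size=(10, 4)), ids)
        factors = pd.DataFrame(
            {"f1": rng.choice(["a", "b"], 10), "f2": rng.choice(["u", "v"], 10)},
            index=ids,
        )
        res = dv.permanova(dm, factors, n_permutations=9, seed=7)
        t = res.table
        parts = t.loc[["f1", "f2", "Residual"], "SumOfSqs"].sum()
        assert parts == pytest.approx(t.loc["Total", "SumOfSqs"], abs=1e-9)
        assert ((t["R2"].dropna() >= -1e-12) & (t["R2"].dropna() <= 1 + 1e-12)).all()

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(8)
        ids = [f"s{i}" for i in range(8)]
        dm = euclidean_dm(rng.normal(size=(8, 3)), ids)
        factors = pd.DataFrame({"g": rng.choice(["a", "b"], 8)}, index=ids)
        res1 = dv.permanova(dm, factors, n_permutations=49, seed=9)
        perm = rng.permutation(8)
        ids2 = [ids[i] for i in perm]
        dm2 = dm.loc[ids2, ids2]
        res2 = dv.permanova(dm2, factors.loc[ids2], n_permutations=49, seed=9)
        assert res1.table.loc["g", "R2"] == pytest.approx(res2.table.loc["g", "R2"], abs=1e-12)
        assert res1.table.loc["g", "F"] == pytest.approx(res2.table.loc["g", "F"], abs=1e-9)

    def test_oneway_pseudo_f_matches_skbio(self):
        skbio_dist = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(10)
        ids = [f"s{i}" for i in range(9)]
        dm = euclidean_dm(rng.normal(size=(9, 4)), ids)
        groups = pd.Series(rng.choice(["A", "B", "C"], 9), index=ids)
        res = dv.permanova(dm, groups.to_frame("g"), n_permutations=9, seed=11)
        ref = skbio_dist.permanova(
            skbio_dist.DistanceMatrix(dm.to_numpy(), ids), groups.to_numpy(), permutations=9
        )
        assert res.table.loc["g", "F"] == pytest.approx(ref["test statistic"], abs=1e-9)

    def test_invalid_permutation_count(self):
        dm = pd.DataFrame(np.zeros((2, 2)), index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError):
            dv.permanova(dm, pd.DataFrame({"g": ["a", "b"]}, index=["a", "b"]), 0)


class TestPairwisePermanova:
    def _dm_with_divergent_group(self, rng, divergent="g4", n_groups=5, per_group=4):
        labels, rows = [], []
        for g in range(n_groups):
            name = f"g{g}"
            center = np.zeros(3) if name != divergent else np.full(3, 4.0)
            for i in range(per_group):
                labels.append((f"{name}_{i}", name))
                rows.append(center + rng.normal(0, 0.5, 3))
        ids = [lab for lab, _ in labels]
        groups = pd.Series([g for _, g in labels], index=ids)
        return euclidean_dm(np.array(rows), ids), groups

    def test_divergent_group_pairs_rank_lowest_q(self):
        rng = np.random.default_rng(12)
        dm, groups = self._dm_with_divergent_group(rng)
        out = dv.pairwise_permanova(dm, groups, n_permutations=99, seed=13)
        out = out.sort_values("q")
        divergent_pairs = out[(out.group_a == "g4") | (out.group_b == "g4")]
        other_pairs = out[(out.group_a != "g4") & (out.group_b != "g4")]
        assert divergent_pairs["q"].max() <= other_pairs["q"].min()

    def test_q_monotone_in_p(self):
        rng = np.random.default_rng(14)
        dm, groups = self._dm_with_divergent_group(rng)
        out = dv.pairwise_permanova(dm, groups, n_permutations=49, seed=15)
        ordered = out.sort_values("p")
        assert (ordered["q"].diff().dropna() >= -1e-12).all()

    def test_singleton_group_skipped(self):
        rng = np.random.default_rng(16)
        ids = ["a1", "a2", "b1", "b2", "c1"]
        dm = euclidean_dm(rng.normal(size=(5, 2)), ids)
        groups = pd.Series(["A", "A", "B", "B", "C"], index=ids)
        with pytest.warns(UserWarning, match="single sample"):
            out = dv.pairwise_permanova(dm, groups, n_permutations=19, seed=17)
        assert set(map(tuple, out[["group_a", "group_b"]].to_numpy())) == {("A", "B")}


class TestClrPca:
    def test_clr_rows_sum_to_zero(self):
        rng = np.random.default_rng(18)
        profile = pd.DataFrame(rng.random((6, 5)) * 10, columns=[f"s{i}" for i in range(5)])
        clr = dv.clr_transform(profile, 0.01)
        assert np.allclose(clr.sum(axis=0), 0.0, atol=1e-9)

    def test_duplicate_samples_identical_scores(self):
        rng = np.random.default_rng(19)
        col = rng.random(6) * 10
        profile = pd.DataFrame({"a": col, "b": col, "c": rng.random(6) * 10})
        res = dv.clr_pca(profile)
        assert np.allclose(res.scores.loc["a"], res.scores.loc["b"], atol=1e-9)

    def test_two_cluster_profile_separates_on_pc1(self):
        rng = np.random.default_rng(20)
        # Samples 0-4 dominated by species 0, samples 5-9 by species 1.
        data = np.ones((6, 10))
        data[0, :5] = 50.0
        data[1, 5:] = 50.0
        data += rng.random((6, 10))
        profile = pd.DataFrame(data, columns=[f"s{i}" for i in range(10)])
        res = dv.clr_pca(profile)
        pc1 = res.scores["PC1"].to_numpy()
        side_a, side_b = pc1[:5], pc1[5:]
        assert (side_a.mean() - side_b.mean()) != 0
        assert (side_a > pc1.mean()).all() != (side_b > pc1.mean()).all()

    def test_scores_orthogonal(self):
        rng = np.random.default_rng(21)
        profile = pd.DataFrame(rng.random((7, 6)) * 5, columns=[f"s{i}" for i in range(6)])
        res = dv.clr_pca(profile)
        S = res.scores.to_numpy()
        gram = S.T @ S
        off = gram - np.diag(np.diag(gram))
        assert np.allclose(off, 0.0, atol=1e-8)


def oracle_ward_d2(points):
    """Exhaustive Lance-Williams ward.D2 agglomeration; returns merge
    heights and the partition (frozensets) merged at each step."""
    n = len(points)
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(points))
    clusters = {i: frozenset([i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    dist = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        (i, j), dij = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        merges.append((clusters[i] | clusters[j], dij))
        ni, nj = sizes[i], sizes[j]
        new = next_id
        next_id += 1
        for k in list(clusters):
            if k in (i, j):
                continue
            nk = sizes[k]
            dik = dist[tuple(sorted((i, k)))]
            djk = dist[tuple(sorted((j, k)))]
            dnew = np.sqrt(
                ((ni + nk) * dik**2 + (nj + nk) * djk**2 - nk * dij**2)
                / (ni + nj + nk)
            )
            dist[tuple(sorted((new, k)))] = dnew
        clusters[new] = clusters[i] | clusters[j]
        sizes[new] = ni + nj
        for k in (i, j):
            del clusters[k], sizes[k]
        dist = {
            pair: v for pair, v in dist.items() if i not in pair and j not in pair
        }
    return merges


class TestWardCluster:
    def test_identical_rows_merge_at_zero(self):
        matrix = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [5.0, 9.0]], index=list("ABC"))
        res = dv.ward_cluster(matrix, log_transform=False)
        assert res.linkage_matrix[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_line_points_nearest_pair_first(self):
        matrix = pd.DataFrame([[0.0], [1.0], [10.0]], index=list("ABC"))
        res = dv.ward_cluster(matrix, log_transform=False)
        first = sorted(res.linkage_matrix[0, :2].astype(int))
        assert first == [0, 1]  # A and B merge first
        assert res.newick.count("(") == 2

    def test_six_point_merge_order_matches_oracle(self):
        rng = np.random.default_rng(22)
        points = rng.normal(size=(6, 3))
        matrix = pd.DataFrame(points, index=[f"r{i}" for i in range(6)])
        res = dv.ward_cluster(matrix, log_transform=False)
        oracle = oracle_ward_d2(points)

        Z = res.linkage_matrix
        members = {i: frozenset([i]) for i in range(6)}
        for step, (left, right, height, _) in enumerate(Z):
            merged = members[int(left)] | members[int(right)]
            members[6 + step] = merged
            oracle_set, oracle_height = oracle[step]
            assert merged == oracle_set
            assert height == pytest.approx(oracle_height, abs=1e-9)

    def test_nonfinite_after_transform_rejected(self):
        matrix = pd.DataFrame([[0.0, 1.0], [2.0, 3.0]], index=list("AB"))
        with pytest.raises(ValueError):
            dv.ward_cluster(matrix, log_transform=True, pseudocount=0.0)
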