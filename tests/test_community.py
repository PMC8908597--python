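"""PERMANOVA and convergence-test checks with independent oracles.

The small-instance oracles recompute pseudo-F from the classic
within-group sum-of-squared-distances identity and enumerate label
assignments directly, sharing no code with the implementation.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from dietshift import community as comm

from conftest import paired_table


def points_dm(points, ids=None):
    ids = ids or [f"s{i}" for i in range(len(points))]
    return DistanceMatrix(squareform(pdist(np.asarray(points, float))), ids=ids)


def oracle_oneway_f(dmat: np.ndarray, labels) -> float:
    """Pseudo-F from SS_total - SS_within over squared distances."""
    labels = np.asarray(labels)
    n = len(labels)
    sst = (dmat**2).sum() / (2 * n)
    ssw = 0.0
    for g in set(labels):
        idx = np.flatnonzero(labels == g)
        ssw += (dmat[np.ix_(idx, idx)] ** 2).sum() / (2 * len(idx))
    ssa = sst - ssw
    k = len(set(labels))
    return (ssa / (k - 1)) / (ssw / (n - k))


class TestPermanova:
    def test_six_sample_exact_p_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(6, 2))
        pts[3:] += 1.5
        d = points_dm(pts)
        design = pd.DataFrame({"grp": ["A"] * 3 + ["B"] * 3}, index=list(d.ids))
        res = comm.permanova(d, design, ["grp"], n_perm="exact")

        labels = np.array(["A"] * 3 + ["B"] * 3)
        f0 = oracle_oneway_f(d.data, labels)
        count = total = 0
        for perm in itertools.permutations(labels):
            total += 1
            count += oracle_oneway_f(d.data, perm) >= f0 - 1e-12
        assert res.table.loc["grp", "F"] == pytest.approx(f0)
        assert res.p_value("grp") == pytest.approx(count / total)

    def test_r2_partition_sums_to_one(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(12, 3))
        d = points_dm(pts)
        design = pd.DataFrame(
            {"grp": ["A", "B", "C"] * 4, "x": rng.normal(size=12)}, index=list(d.ids)
        )
        res = comm.permanova(d, design, ["grp", "x"], n_perm=49, seed=0)
        assert res.table["R2"].drop("Total").sum() == pytest.approx(1.0, abs=1e-9)
        assert ((res.table["p"].dropna() >= 1 / 50) & (res.table["p"].dropna() <= 1)).all()

    def test_separated_groups_r2_near_one(self):
        rng = np.random.default_rng(2)
        pts = np.vstack([rng.normal(size=(6, 2)), rng.normal(size=(6, 2)) + 100.0])
        d = points_dm(pts)
        design = pd.DataFrame({"grp": ["A"] * 6 + ["B"] * 6}, index=list(d.ids))
        res = comm.permanova(d, design, ["grp"], n_perm=99, seed=0)
        assert res.r2("grp") > 0.98

    def test_mismatched_ids_error(self):
        d = points_dm(np.eye(3))
        design = pd.DataFrame({"grp": ["A", "B"]}, index=["s0", "s1"])
        with pytest.raises(ValueError, match="missing"):
            comm.permanova(d, design, ["grp"])


def interaction_setup(n_per_arm, delta_by_group, rng):
    """Change-space toy: subjects' two timepoints shift by a group delta."""
    groups, rows_t0, rows_t6 = [], [], []
    for g, delta in delta_by_group.items():
        for _ in range(n_per_arm):
            base = rng.dirichlet(np.ones(4))
            groups.append(g)
            rows_t0.append(base)
            shifted = base * np.exp([delta, -delta, 0, 0])
            rows_t6.append(shifted / shifted.sum())
    return paired_table(rows_t0, rows_t6, groups=groups)


class TestInteractionPermanova:
    def test_identical_timepoints_interaction_ss_zero(self):
        rng = np.random.default_rng(3)
        t = interaction_setup(4, {"A": 0.0, "B": 0.0, "C": 0.0}, rng)
        # make t6 exactly equal t0 so time explains nothing
        from dietshift.distances import euclidean_distances
        from dietshift.tables import log2_change

        ch = log2_change(t, pseudocount=1e-9)
        assert np.allclose(ch.values.to_numpy(), 0.0)

    def test_planted_interaction_detected(self):
        rng = np.random.default_rng(4)
        t = interaction_setup(8, {"A": 0.0, "B": 0.6, "C": 1.2}, rng)
        from dietshift.distances import weighted_unifrac
        from dietshift.simulate import generate_tree
        from dietshift.tables import to_relative

        tree = generate_tree(4, seed=1)
        dm = weighted_unifrac(to_relative(t), tree)
        res = comm.interaction_permanova(dm, t.meta, n_perm=199, seed=0)
        assert res.p_value("group:time") < 0.05

    def test_subject_missing_timepoint_rejected(self):
        rng = np.random.default_rng(5)
        t = interaction_setup(3, {"A": 0.0, "B": 0.0}, rng)
        t = t.select_samples([s for s in t.sample_ids if s != "subj0_t6"])
        from dietshift.distances import euclidean_distances
        from dietshift.tables import log2_change

        d = points_dm(np.random.default_rng(0).normal(size=(len(t.sample_ids), 2)),
                      ids=list(t.sample_ids))
        with pytest.raises(ValueError, match="lacking both"):
            comm.interaction_permanova(d, t.meta)


class TestPairwisePermanova:
    def test_three_pairs_with_bh(self):
        rng = np.random.default_rng(6)
        t = interaction_setup(6, {"A": 0.0, "B": 0.0, "C": 1.5}, rng)
        from dietshift.distances import weighted_unifrac
        from dietshift.simulate import generate_tree
        from dietshift.tables import to_relative

        dm = weighted_unifrac(to_relative(t), generate_tree(4, seed=2))
        out = comm.pairwise_permanova(dm, t.meta, n_perm=199, seed=0)
        assert len(out) == 3
        assert (out["q"] >= out["p"] - 1e-12).all()
        ab = out[(out.group_a == "A") & (out.group_b == "B")]["p"].iloc[0]
        with_c = out[(out.group_a == "C") | (out.group_b == "C")]["p"]
        assert (with_c < 0.05).all() and ab > 0.05

    def test_pair_sample_count_bookkeeping(self):
        rng = np.random.default_rng(7)
        t = interaction_setup(5, {"A": 0.0, "B": 0.0, "C": 0.0}, rng)
        from dietshift.distances import euclidean_distances
        from dietshift.tables import log2_change

        d = points_dm(rng.normal(size=(len(t.sample_ids), 2)), ids=list(t.sample_ids))
        out = comm.pairwise_permanova(d, t.meta, n_perm=19, seed=0)
        assert (out["n_samples"] == 20).all()  # 2 groups x 5 subjects x 2 timepoints


class TestVarianceExplained:
    def test_self_covariate_maximizes_r2(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(20, 3))
        d = points_dm(pts)
        from dietshift.distances import pcoa

        pc1 = pcoa(d, k=1).pc1
        r2_pc1 = comm.variance_explained(d, pc1, n_perm=49, seed=0).r2(pc1.name or "covariate")
        for _ in range(5):
            noise = pd.Series(rng.normal(size=20), index=list(d.ids), name="noise")
            r2_noise = comm.variance_explained(d, noise, n_perm=49, seed=0).r2("noise")
            assert r2_pc1 > r2_noise

    def test_constant_covariate_rejected(self):
        d = points_dm(np.random.default_rng(9).normal(size=(6, 2)))
        cov = pd.Series(np.ones(6), index=list(d.ids), name="c")
        with pytest.raises(ValueError, match="constant"):
            comm.variance_explained(d, cov, n_perm=9)

    def test_batch_applies_bh(self):
        rng = np.random.default_rng(10)
        d = points_dm(rng.normal(size=(15, 2)))
        covs = pd.DataFrame(rng.normal(size=(15, 3)), index=list(d.ids),
                            columns=["a", "b", "c"])
        out = comm.variance_explained_batch(d, covs, n_perm=49, seed=0)
        assert (out["q"] >= out["p"] - 1e-12).all()


class TestConvergence:
    def exhaustive_oracle(self, dmat, labels, group):
        """Exact p over all distinct label assignments (multiset perms)."""
        labels = np.asarray(labels)

        def delta(lab):
            lab = np.asarray(lab)
            idx = np.flatnonzero(lab == group)
            other = np.flatnonzero(lab != group)
            within = dmat[np.ix_(idx, idx)]
            w = within.sum() / (len(idx) * (len(idx) - 1))
            b = dmat[np.ix_(idx, other)].mean()
            return b - w

        obs = delta(labels)
        seen = set()
        count = total = 0
        for perm in itertools.permutations(labels):
            if perm in seen:
                continue
            seen.add(perm)
            total += 1
            count += delta(perm) >= obs - 1e-12
        return count / total

    def test_small_instance_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(8, 2))
        pts[:3] *= 0.2  # group A huddles together
        d = points_dm(pts)
        labels = ["A"] * 3 + ["B"] * 5
        groups = pd.Series(labels, index=list(d.ids))
        res = comm.convergence_test(d, groups, n_perm=20000, seed=0)
        p_oracle = self.exhaustive_oracle(d.data, labels, "A")
        se = np.sqrt(p_oracle * (1 - p_oracle) / 20000)
        assert abs(res.p_value("A") - p_oracle) < 4 * se + 1e-4

    def test_invariant_to_relabeling_and_order(self):
        rng = np.random.default_rng(12)
        pts = rng.normal(size=(9, 2))
        d = points_dm(pts)
        labels = pd.Series(["x"] * 3 + ["y"] * 3 + ["z"] * 3, index=list(d.ids))
        res1 = comm.convergence_test(d, labels, n_perm=99, seed=5)
        shuffled_ids = list(d.ids)[::-1]
        d2 = d.filter(shuffled_ids)
        res2 = comm.convergence_test(d2, labels.loc[shuffled_ids], n_perm=99, seed=5)
        for g in ["x", "y", "z"]:
            assert res1.delta(g) == pytest.approx(res2.delta(g))
        renamed = labels.map({"x": "u", "y": "v", "z": "w"})
        res3 = comm.convergence_test(d, renamed, n_perm=99, seed=5)
        assert res1.delta("x") == pytest.approx(res3.delta("u"))

    def test_tight_group_gets_minimal_p(self):
        rng = np.random.default_rng(13)
        pts = rng.normal(size=(12, 2)) * 5
        pts[:4] = rng.normal(size=(4, 2)) * 0.01  # near-identical quartet
        d = points_dm(pts)
        groups = pd.Series(["A"] * 4 + ["B"] * 4 + ["C"] * 4, index=list(d.ids))
        res = comm.convergence_test(d, groups, n_perm=999, seed=0)
        assert res.p_value("A") == pytest.approx(1 / 1000)
        assert res.table.loc["A", "within_mean"] < res.table.loc["A", "between_mean"]

    def test_singleton_group_rejected(self):
        d = points_dm(np.random.default_rng(14).normal(size=(4, 2)))
        groups = pd.Series(["A", "B", "B", "B"], index=list(d.ids))
        with pytest.raises(ValueError, match="size"):
            comm.convergence_test(d, groups, n_perm=9)
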