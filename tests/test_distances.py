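"""Distance and ordination checks, including independent oracles:

* a naive per-branch weighted UniFrac computed by explicit recursive
  traversal (no shared code with the implementation),
* scikit-bio's own beta_diversity as an external reference,
* PCA equivalence for PCoA on Euclidean distances.
"""

import io

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode
from skbio.diversity import beta_diversity
from skbio.stats.ordination import pcoa as skbio_pcoa

from dietshift import distances as dd
from dietshift import tables
from dietshift.simulate import generate_tree, taxon_labels

from conftest import make_table


def naive_weighted_unifrac(tree: TreeNode, rel_a: dict, rel_b: dict) -> float:
    """Brute-force oracle: walk every branch, sum l_b * |A_b - B_b|."""

    def leaves_below(node):
        return [t.name for t in node.tips()] if not node.is_tip() else [node.name]

    total = 0.0
    for node in tree.traverse(include_self=False):
        below = leaves_below(node)
        a = sum(rel_a.get(t, 0.0) for t in below)
        b = sum(rel_b.get(t, 0.0) for t in below)
        total += node.length * abs(a - b)
    return total


def relative_table(values, taxa):
    t = make_table(values, taxon_ids=list(taxa))
    return tables.to_relative(t)


class TestWeightedUnifrac:
    def test_identical_compositions_zero(self, cherry_tree):
        t = relative_table([[0.4, 0.6], [0.4, 0.6]], ["T0000", "T0001"])
        dm = dd.weighted_unifrac(t, cherry_tree)
        assert dm.data[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_cherry_hand_value(self, cherry_tree):
        # disjoint communities across two unit branches: 1*1 + 1*1 = 2
        t = relative_table([[1.0, 0.0], [0.0, 1.0]], ["T0000", "T0001"])
        dm = dd.weighted_unifrac(t, cherry_tree)
        assert dm.data[0, 1] == pytest.approx(2.0)

    @pytest.mark.parametrize("n_taxa", [4, 9, 16])
    def test_matches_naive_branch_oracle(self, n_taxa):
        rng = np.random.default_rng(n_taxa)
        tree = generate_tree(n_taxa, seed=n_taxa)
        taxa = taxon_labels(n_taxa)
        rel = rng.dirichlet(np.ones(n_taxa) * 0.5, size=5)
        t = relative_table(rel, taxa)
        dm = dd.weighted_unifrac(t, tree)
        for i in range(5):
            for j in range(i):
                expected = naive_weighted_unifrac(
                    tree, dict(zip(taxa, rel[i])), dict(zip(taxa, rel[j]))
                )
                assert dm.data[i, j] == pytest.approx(expected, rel=1e-9)

    def test_matches_scikit_bio(self):
        rng = np.random.default_rng(7)
        tree = generate_tree(12, seed=7)
        counts = rng.integers(0, 50, size=(6, 12))
        counts[:, 0] += 1
        rel = counts / counts.sum(axis=1, keepdims=True)
        t = relative_table(rel, taxon_labels(12))
        mine = dd.weighted_unifrac(t, tree)
        ref = beta_diversity(
            "weighted_unifrac",
            counts,
            ids=list(t.sample_ids),
            taxa=taxon_labels(12),
            tree=tree,
        )
        assert np.allclose(mine.data, ref.data, rtol=1e-9, atol=1e-12)

    def test_pseudometric_properties(self):
        rng = np.random.default_rng(3)
        tree = generate_tree(8, seed=3)
        rel = rng.dirichlet(np.ones(8), size=6)
        dm = dd.weighted_unifrac(relative_table(rel, taxon_labels(8)), tree).data
        assert np.allclose(dm, dm.T)
        assert np.allclose(np.diag(dm), 0.0)
        for i in range(6):
            for j in range(6):
                for k in range(6):
                    assert dm[i, j] <= dm[i, k] + dm[k, j] + 1e-12

    def test_normalized_bounded_in_unit_interval(self):
        rng = np.random.default_rng(5)
        tree = generate_tree(10, seed=5)
        rel = rng.dirichlet(np.ones(10) * 0.3, size=8)
        dm = dd.weighted_unifrac(
            relative_table(rel, taxon_labels(10)), tree, normalized=True
        ).data
        assert dm.min() >= 0.0 and dm.max() <= 1.0 + 1e-12

    def test_taxon_absent_from_tree_errors(self, cherry_tree):
        t = relative_table([[0.5, 0.5]], ["T0000", "TX"])
        with pytest.raises(ValueError, match="absent"):
            dd.weighted_unifrac(t, cherry_tree)

    def test_counts_input_rejected(self, cherry_tree):
        t = make_table([[3, 5]], taxon_ids=["T0000", "T0001"])
        with pytest.raises(ValueError, match="relative"):
            dd.weighted_unifrac(t, cherry_tree)


class TestEuclidean:
    def test_three_four_five(self):
        ch = tables.ChangeMatrix(
            pd.DataFrame([[0.0, 0.0], [3.0, 4.0]], index=["a", "b"]),
            pd.DataFrame({"group": ["A", "A"]}, index=["a", "b"]),
            1e-6,
        )
        dm = dd.euclidean_distances(ch)
        assert dm.data[0, 1] == pytest.approx(5.0)

    def test_triangle_inequality_random(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(6, 10))
        ch = tables.ChangeMatrix(
            pd.DataFrame(vals, index=[f"s{i}" for i in range(6)]),
            pd.DataFrame({"group": ["A"] * 6}, index=[f"s{i}" for i in range(6)]),
            1e-6,
        )
        dm = dd.euclidean_distances(ch).data
        for i in range(6):
            for j in range(6):
                for k in range(6):
                    assert dm[i, j] <= dm[i, k] + dm[k, j] + 1e-9


class TestPcoa:
    def test_recovers_planar_configuration(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(10, 2))
        from skbio import DistanceMatrix

        d = DistanceMatrix(squareform(pdist(pts)), ids=[f"s{i}" for i in range(10)])
        ordn = dd.pcoa(d, k=2)
        rebuilt = squareform(pdist(ordn.coordinates.to_numpy()))
        assert np.allclose(rebuilt, d.data, atol=1e-9)
        assert ordn.negative_eigenvalue_mass == pytest.approx(0.0, abs=1e-8)

    def test_pco1_equals_first_principal_component(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=(12, 6))
        ch = tables.ChangeMatrix(
            pd.DataFrame(vals, index=[f"s{i}" for i in range(12)]),
            pd.DataFrame({"group": ["A"] * 12}, index=[f"s{i}" for i in range(12)]),
            1e-6,
        )
        ordn = dd.pcoa(dd.euclidean_distances(ch), k=2)
        centered = vals - vals.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        pc1 = centered @ vt[0]
        got = ordn.pc1.to_numpy()
        agreement = max(
            abs(np.corrcoef(pc1, got)[0, 1]), abs(np.corrcoef(-pc1, got)[0, 1])
        )
        assert agreement == pytest.approx(1.0, abs=1e-9)

    def test_two_points(self):
        from skbio import DistanceMatrix

        d = DistanceMatrix([[0.0, 2.0], [2.0, 0.0]], ids=["a", "b"])
        ordn = dd.pcoa(d, k=1)
        assert np.allclose(np.abs(ordn.coordinates.to_numpy().ravel()), 1.0)

    def test_matches_scikit_bio_eigenvalues(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(8, 3))
        from skbio import DistanceMatrix

        d = DistanceMatrix(squareform(pdist(pts)), ids=[f"s{i}" for i in range(8)])
        mine = dd.pcoa(d, k=3)
        ref = skbio_pcoa(d, dimensions=3)
        assert np.allclose(mine.eigenvalues, ref.eigvals.to_numpy()[:3], atol=1e-8)

    def test_sign_canonicalization_stable(self):
        from skbio import DistanceMatrix

        rng = np.random.default_rng(8)
        pts = rng.normal(size=(7, 2))
        d = DistanceMatrix(squareform(pdist(pts)), ids=[f"s{i}" for i in range(7)])
        a = dd.pcoa(d, k=2).coordinates
        b = dd.pcoa(d, k=2).coordinates
        assert np.array_equal(a.to_numpy(), b.to_numpy())
        for col in a.columns:
            j = a[col].abs().idxmax()
            assert a.loc[j, col] > 0

    def test_excess_axes_truncated_with_warning(self):
        from skbio import DistanceMatrix

        d = DistanceMatrix([[0.0, 1.0], [1.0, 0.0]], ids=["a", "b"])
        with pytest.warns(UserWarning, match="truncating"):
            ordn = dd.pcoa(d, k=5)
        assert ordn.coordinates.shape[1] == 1
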