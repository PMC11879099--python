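"""Diversity, ordination and permutation-test oracles.

Hand-computed values for the alpha/beta indices; scikit-bio's PERMANOVA,
Mantel-free PCoA and Faith PD serve as independent cross-checks.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from skbio import DistanceMatrix

from rhizonet.diversity import (
    alpha_diversity,
    anova_tukey,
    bray_curtis,
    mrpp,
    pcoa,
    permanova,
    shared_unique_otus,
)
from rhizonet.errors import ValidationError
from rhizonet.types import CommunityTable


class TestAlpha:
    def test_uniform_community(self, small_table):
        rep = alpha_diversity(small_table)
        assert rep.loc["s1", "richness"] == 4
        assert rep.loc["s1", "shannon"] == pytest.approx(np.log(4))

    def test_two_taxa_even(self, small_table):
        # (5, 0, 5, 0, 0): -sum p ln p = ln 2
        assert alpha_diversity(small_table).loc["s2", "shannon"] == pytest.approx(np.log(2))

    def test_faith_pd_full_sample_is_total_branch_length(self, small_table, cherry_tree):
        rep = alpha_diversity(small_table, cherry_tree)
        total = sum(n.length for n in cherry_tree.traverse() if n.length is not None)
        assert rep.loc["s4", "faith_pd"] == pytest.approx(total)

    def test_empty_sample_warns_and_zeroes(self):
        table = CommunityTable(
            pd.DataFrame([[0, 0], [1, 1]], index=["e", "f"], columns=["t1", "t2"])
        )
        with pytest.warns(UserWarning):
            rep = alpha_diversity(table)
        assert rep.loc["e", "richness"] == 0
        assert rep.loc["e", "shannon"] == 0


class TestBrayCurtis:
    def test_hand_example(self):
        table = CommunityTable(
            pd.DataFrame([[1, 1], [1, 3]], index=["a", "b"], columns=["t1", "t2"])
        )
        d = bray_curtis(table)
        assert d["a", "b"] == pytest.approx(1 - 2 * 2 / 6)

    def test_identity_and_disjoint(self):
        table = CommunityTable(
            pd.DataFrame(
                [[2, 0], [2, 0], [0, 5]], index=["a", "b", "c"], columns=["t1", "t2"]
            )
        )
        d = bray_curtis(table)
        assert d["a", "b"] == 0
        assert d["a", "c"] == 1

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.lists(st.integers(0, 50), min_size=3, max_size=3),
            min_size=2,
            max_size=6,
        )
    )
    def test_bounded_and_symmetric(self, rows):
        if all(sum(r) == 0 for r in rows):
            return
        counts = pd.DataFrame(
            rows,
            index=[f"s{i}" for i in range(len(rows))],
            columns=["t1", "t2", "t3"],
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d = bray_curtis(CommunityTable(counts)).data
        assert (d >= 0).all() and (d <= 1 + 1e-12).all()
        assert np.allclose(d, d.T)


class TestPcoa:
    def test_line_configuration_recovered(self):
        x = np.array([0.0, 1.0, 3.0, 6.0])
        d = np.abs(x[:, None] - x[None, :])
        res = pcoa(DistanceMatrix(d, ids=list("abcd")))
        axis1 = res.coordinates["PCo1"].to_numpy()
        recon = np.abs(axis1[:, None] - axis1[None, :])
        assert np.allclose(recon, d, atol=1e-8)

    def test_planar_configuration_distances_reproduced(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(6, 2))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        res = pcoa(DistanceMatrix(d, ids=[str(i) for i in range(6)]))
        emb = res.coordinates.iloc[:, :2].to_numpy()
        recon = np.sqrt(((emb[:, None] - emb[None, :]) ** 2).sum(-1))
        assert np.allclose(recon, d, atol=1e-8)

    def test_equidistant_three_points_two_equal_eigenvalues(self):
        d = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        res = pcoa(DistanceMatrix(d, ids=list("abc")))
        pos = res.eigenvalues[res.eigenvalues > 1e-10]
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1])

    def test_matches_skbio_on_euclidean_input(self):
        from skbio.stats.ordination import pcoa as skbio_pcoa

        rng = np.random.default_rng(1)
        pts = rng.normal(size=(7, 3))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        dm = DistanceMatrix(d, ids=[str(i) for i in range(7)])
        ours = pcoa(dm)
        ref = skbio_pcoa(dm, number_of_dimensions=3)
        assert np.allclose(
            np.abs(ours.coordinates.iloc[:, :3].to_numpy()),
            np.abs(ref.samples.iloc[:, :3].to_numpy()),
            atol=1e-8,
        )


class TestPermanova:
    @pytest.fixture
    def separated(self):
        # 10 + 10 so the chance of a permutation reproducing the partition
        # (the only tie under complete separation) is negligible
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.normal(0, 0.1, (10, 2)), rng.normal(10, 0.1, (10, 2))])
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(20)]
        groups = pd.Series(["a"] * 10 + ["b"] * 10, index=ids)
        return DistanceMatrix(d, ids=ids), groups

    def test_complete_separation_minimal_p(self, separated):
        dm, groups = separated
        res = permanova(dm, groups, n_perm=999, seed=1)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_statistic_independent_of_seed(self, separated):
        dm, groups = separated
        a = permanova(dm, groups, n_perm=99, seed=1)
        b = permanova(dm, groups, n_perm=99, seed=2)
        assert a.statistic == b.statistic

    def test_matches_skbio_statistic(self, separated):
        from skbio.stats.distance import permanova as skbio_permanova

        dm, groups = separated
        ours = permanova(dm, groups, n_perm=99, seed=0)
        ref = skbio_permanova(dm, groups.to_numpy(), permutations=0)
        assert ours.statistic == pytest.approx(ref["test statistic"])

    def test_singleton_group_rejected(self, separated):
        dm, _ = separated
        groups = pd.Series(["a"] * 19 + ["b"], index=list(dm.ids))
        with pytest.raises(ValidationError):
            permanova(dm, groups, n_perm=99, seed=0)


class TestMrpp:
    def test_within_zero_between_positive(self):
        # 4 + 4 block design: within-group distances 0, between 1
        d = np.kron(np.array([[0.0, 1.0], [1.0, 0.0]]), np.ones((4, 4)))
        np.fill_diagonal(d, 0.0)
        ids = [f"s{i}" for i in range(8)]
        dm = DistanceMatrix(d, ids=ids)
        groups = pd.Series(["g1"] * 4 + ["g2"] * 4, index=ids)
        res = mrpp(dm, groups, n_perm=199, seed=0)
        assert res.statistic == 0.0
        assert res.effect > 0
        assert res.p_value < 0.05

    def test_null_effect_centered_near_zero(self):
        rng = np.random.default_rng(3)
        effects = []
        ids = [f"s{i}" for i in range(10)]
        for _ in range(50):
            pts = rng.normal(size=(10, 2))
            d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
            groups = pd.Series(rng.permutation(["a"] * 5 + ["b"] * 5), index=ids)
            res = mrpp(DistanceMatrix(d, ids=ids), groups, n_perm=49, seed=1)
            effects.append(res.effect)
        assert abs(np.mean(effects)) < 0.05


class TestSharedUnique:
    def test_identical_tables_all_shared(self):
        counts = pd.DataFrame(
            [[1, 2, 3], [1, 2, 3], [1, 2, 3], [1, 2, 3]],
            index=["a1", "a2", "b1", "b2"],
            columns=["t1", "t2", "t3"],
        )
        groups = pd.Series(["A", "A", "B", "B"], index=counts.index)
        part = shared_unique_otus(CommunityTable(counts), groups)
        assert part.unique("A") == 0 and part.unique("B") == 0
        assert part.shared_all() == 3

    def test_partial_overlap_counts(self):
        counts = pd.DataFrame(
            [[1, 1, 0], [0, 1, 1]], index=["a1", "b1"], columns=["t1", "t2", "t3"]
        )
        counts = pd.concat([counts, counts]).set_axis(["a1", "b1", "a2", "b2"])
        groups = pd.Series(["A", "B", "A", "B"], index=counts.index)
        part = shared_unique_otus(CommunityTable(counts), groups)
        assert part.unique("A") == 1
        assert part.unique("B") == 1
        assert part.shared_all() == 1
        # ternary proportions sum to 1 per taxon
        assert np.allclose(part.proportions.sum(axis=1), 1.0)

    def test_unknown_sample_labels_rejected(self, small_table):
        groups = pd.Series(["A", "B"], index=["s1", "s2"])  # missing s3, s4
        with pytest.raises(ValidationError):
            shared_unique_otus(small_table, groups)


def test_anova_tukey_separated_groups():
    values = pd.Series(
        [1.0, 1.1, 0.9, 5.0, 5.1, 4.9], index=[f"s{i}" for i in range(6)]
    )
    groups = pd.Series(["a"] * 3 + ["b"] * 3, index=values.index)
    res = anova_tukey(values, groups)
    assert res["p_value"] < 1e-4
    assert len(res["tukey"]) == 1
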