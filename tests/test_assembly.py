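"""Niche breadth, betaMNTD and pNST: closed forms and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from rhizonet.assembly import beta_mntd, levins_breadth, pnst, pnst_group_difference
from rhizonet.errors import InsufficientDataError, MissingTaxonError
from rhizonet.types import CommunityTable


def _table(rows, index, columns):
    return CommunityTable(pd.DataFrame(rows, index=index, columns=columns))


class TestLevins:
    def test_uniform_occupancy_b_equals_n(self):
        rows = [[10, 1]] * 6
        table = _table(rows, [f"s{i}" for i in range(6)], ["even", "other"])
        groups = pd.Series(["g"] * 6, index=table.sample_ids)
        rep = levins_breadth(table, groups)["g"]
        assert rep.b_values["even"] == pytest.approx(6.0)

    def test_single_sample_occupancy_b_equals_one(self):
        rows = [[5, 1], [0, 1], [0, 1]]
        table = _table(rows, ["s1", "s2", "s3"], ["lone", "other"])
        groups = pd.Series(["g"] * 3, index=table.sample_ids)
        rep = levins_breadth(table, groups)["g"]
        assert rep.b_values["lone"] == pytest.approx(1.0)

    def test_hand_computed_shares(self):
        # occupancy shares (0.5, 0.25, 0.25): B = 1/0.375
        rows = [[2, 1], [1, 1], [1, 1]]
        table = _table(rows, ["s1", "s2", "s3"], ["t", "other"])
        groups = pd.Series(["g"] * 3, index=table.sample_ids)
        rep = levins_breadth(table, groups)["g"]
        assert rep.b_values["t"] == pytest.approx(1 / 0.375)

    def test_bcom_is_mean_and_bounds_hold(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 20, size=(5, 8))
        counts[:, 0] = 1  # ensure at least one occupied taxon
        table = _table(counts, [f"s{i}" for i in range(5)], [f"t{j}" for j in range(8)])
        groups = pd.Series(["g"] * 5, index=table.sample_ids)
        rep = levins_breadth(table, groups)["g"]
        assert rep.bcom == pytest.approx(rep.b_values.mean())
        assert ((rep.b_values >= 1 - 1e-12) & (rep.b_values <= 5 + 1e-12)).all()

    def test_absent_taxon_excluded(self):
        rows = [[1, 0], [1, 0]]
        table = _table(rows, ["s1", "s2"], ["t", "absent"])
        groups = pd.Series(["g"] * 2, index=table.sample_ids)
        rep = levins_breadth(table, groups)["g"]
        assert "absent" not in rep.b_values.index


class TestBetaMntd:
    def test_identical_samples_zero(self, small_table, cherry_tree):
        counts = pd.concat([small_table.counts.iloc[[0]]] * 2)
        counts.index = ["a", "b"]
        d = beta_mntd(CommunityTable(counts), cherry_tree)
        assert d["a", "b"] == pytest.approx(0.0)

    def test_two_singleton_samples_patristic_distance(self, cherry_tree):
        table = _table([[3, 0], [0, 7]], ["a", "b"], ["t1", "t3"])
        d = beta_mntd(table, cherry_tree)
        ref = cherry_tree.tip_tip_distances()["t1", "t3"]
        assert d["a", "b"] == pytest.approx(ref)

    def test_shared_taxon_cannot_increase(self, cherry_tree):
        before = beta_mntd(_table([[3, 0], [0, 7]], ["a", "b"], ["t1", "t3"]), cherry_tree)
        after = beta_mntd(
            _table([[3, 0, 1], [0, 7, 1]], ["a", "b"], ["t1", "t3", "t5"]), cherry_tree
        )
        assert after["a", "b"] <= before["a", "b"] + 1e-12

    def test_matches_brute_force(self, cherry_tree):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 5, size=(4, 5))
        counts[counts.sum(axis=1) == 0, 0] = 1
        ids = [f"s{i}" for i in range(4)]
        taxa = ["t1", "t2", "t3", "t4", "t5"]
        table = _table(counts, ids, taxa)
        got = beta_mntd(table, cherry_tree, abundance_weighted=True)
        dm = cherry_tree.tip_tip_distances()
        for i in range(4):
            for j in range(i + 1, 4):
                # brute force: weighted nearest-taxon distance both ways
                def one_way(src, dst):
                    total, wsum = 0.0, 0.0
                    for a, ca in zip(taxa, counts[src]):
                        if ca == 0:
                            continue
                        near = min(dm[a, b] for b, cb in zip(taxa, counts[dst]) if cb > 0)
                        total += ca * near
                        wsum += ca
                    return total / wsum

                expected = 0.5 * (one_way(i, j) + one_way(j, i))
                assert got[ids[i], ids[j]] == pytest.approx(expected)

    def test_missing_tip_rejected(self, cherry_tree):
        table = _table([[1, 1], [1, 1]], ["a", "b"], ["t1", "t99"])
        with pytest.raises(MissingTaxonError):
            beta_mntd(table, cherry_tree)


class TestPnst:
    @pytest.fixture
    def random_setting(self):
        from rhizonet.synthetic import simulate_phylogeny

        rng = np.random.default_rng(5)
        taxa = [f"t{i + 1}" for i in range(30)]
        tree = simulate_phylogeny(taxa, seed=5)
        counts = rng.integers(0, 10, size=(6, 30))
        counts[counts.sum(axis=1) == 0, 0] = 1
        table = _table(counts, [f"s{i}" for i in range(6)], taxa)
        groups = pd.Series(["g"] * 6, index=table.sample_ids)
        return table, tree, groups

    def test_identical_samples_degenerate_null_dropped(self):
        # identical samples share every taxon, so observed AND null betaMNTD
        # are zero on every pair: the pairs are degenerate and dropped
        from rhizonet.synthetic import simulate_phylogeny

        taxa = [f"t{i + 1}" for i in range(12)]
        tree = simulate_phylogeny(taxa, seed=2)
        row = [1, 1, 1, 0, 0, 0, 2, 0, 0, 0, 0, 0]
        table = _table([row] * 4, [f"s{i}" for i in range(4)], taxa)
        groups = pd.Series(["g"] * 4, index=table.sample_ids)
        with pytest.warns(UserWarning):
            res = pnst(table, tree, groups, n_nulls=30, seed=0)["g"]
        assert len(res.pairs) == 0
        assert np.isnan(res.pnst)

    def test_sister_taxon_turnover_is_deterministic(self):
        # samples alternate between two phylogenetic sisters: observed
        # turnover distance is tiny relative to the tip-shuffled null, so
        # the similarity branch drives NST (and hence pNST) toward 0
        tree = TreeNode.read(["((t1:0.01,t2:0.01):5,((t3:1,t4:1):1,(t5:1,t6:1):1):4);"])
        taxa = [f"t{i + 1}" for i in range(6)]
        rows = [
            [5, 0, 0, 0, 0, 0],
            [0, 5, 0, 0, 0, 0],
            [5, 0, 0, 0, 0, 0],
            [0, 5, 0, 0, 0, 0],
        ]
        table = _table(rows, [f"s{i}" for i in range(4)], taxa)
        groups = pd.Series(["g"] * 4, index=table.sample_ids)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # identical pairs are degenerate
            res = pnst(table, tree, groups, n_nulls=50, seed=0)["g"]
        assert res.pnst < 0.1

    def test_bounds_and_seeded_reproducibility(self, random_setting):
        table, tree, groups = random_setting
        a = pnst(table, tree, groups, n_nulls=50, seed=3)["g"]
        b = pnst(table, tree, groups, n_nulls=50, seed=3)["g"]
        assert ((a.pairs["NST"] >= 0) & (a.pairs["NST"] <= 1)).all()
        assert 0.0 <= a.pnst <= 1.0
        pd.testing.assert_frame_equal(a.pairs, b.pairs)
        assert a.pnst_percent == pytest.approx(100 * a.pnst)

    def test_invariant_to_taxon_renaming(self, random_setting):
        # renaming taxa consistently in table and tree changes nothing
        table, tree, groups = random_setting
        res_a = pnst(table, tree, groups, n_nulls=40, seed=1)["g"]
        mapping = {t: f"renamed_{t}" for t in table.taxon_ids}
        renamed = CommunityTable(table.counts.rename(columns=mapping))
        tree_r = tree.copy()
        for tip in tree_r.tips():
            tip.name = mapping[tip.name]
        res_b = pnst(renamed, tree_r, groups, n_nulls=40, seed=1)["g"]
        assert res_a.pnst == pytest.approx(res_b.pnst)

    def test_observed_betamntd_invariant_to_column_order(self, random_setting):
        table, tree, groups = random_setting
        perm = np.random.default_rng(0).permutation(table.n_taxa)
        reordered = CommunityTable(table.counts[[table.taxon_ids[i] for i in perm]])
        a = beta_mntd(table, tree)
        b = beta_mntd(reordered, tree)
        assert np.allclose(a.data, b.data)

    def test_small_group_rejected(self, random_setting):
        table, tree, _ = random_setting
        groups = pd.Series(["g", "g", "h", "h", "h", "h"], index=table.sample_ids)
        with pytest.raises(InsufficientDataError):
            pnst(table, tree, groups, n_nulls=10, seed=0)

    def test_group_difference_bootstrap_seeded(self, random_setting):
        table, tree, _ = random_setting
        groups = pd.Series(["g"] * 3 + ["h"] * 3, index=table.sample_ids)
        res = pnst(table, tree, groups, n_nulls=30, seed=0)
        d1 = pnst_group_difference(res["g"], res["h"], n_boot=200, seed=4)
        d2 = pnst_group_difference(res["g"], res["h"], n_boot=200, seed=4)
        assert d1 == d2
        assert 0 < d1["p_value"] <= 1
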