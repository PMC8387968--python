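import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given
from hypothesis import strategies as st

import florastat as fs
from florastat.contingency import (
    cell_randomization_test,
    enumerate_tables,
    enumeration_bound,
    fisher_exact_enum,
    fisher_exact_mc,
    fisher_pvalue,
    grouped_class_analysis,
    integerize_margins,
    sample_fixed_margin_table,
    sample_fixed_margin_tables,
    table_log_prob,
)
from florastat.data_model import IdentificationClass
from florastat.errors import ValidationError
from florastat.resampling import iterate_subsample


class TestPatefieldSampler:
    def test_one_by_one_forced(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            assert sample_fixed_margin_table([5], [5], rng) == [[5]]

    def test_zero_row_forced(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            t = sample_fixed_margin_table([2, 0], [1, 1], rng)
            assert (t == [[1, 1], [0, 0]]).all()

    @given(st.lists(st.integers(0, 6), min_size=2, max_size=4),
           st.integers(2, 4), st.integers(0, 2 ** 31 - 1))
    def test_margins_always_satisfied(self, rows, c, seed):
        total = sum(rows)
        rng = np.random.default_rng(seed)
        cols = rng.multinomial(total, np.ones(c) / c)
        draws = sample_fixed_margin_tables(rows, cols, 50, rng)
        assert (draws.sum(axis=2) == np.asarray(rows)).all()
        assert (draws.sum(axis=1) == cols).all()

    def test_cell_means_match_independence(self):
        rows, cols = [12, 8, 5], [10, 9, 6]
        n = sum(rows)
        rng = np.random.default_rng(1)
        draws = sample_fixed_margin_tables(rows, cols, 20_000, rng)
        expected = np.outer(rows, cols) / n
        sd = draws.std(axis=0, ddof=1) / np.sqrt(draws.shape[0])
        assert (np.abs(draws.mean(axis=0) - expected) < 3 * sd + 1e-12).all()

    def test_unequal_totals_rejected(self):
        with pytest.raises(ValidationError):
            sample_fixed_margin_table([3], [2], np.random.default_rng(0))


class TestFisher:
    def test_antidiagonal_pair(self):
        # both feasible tables have probability 0.5
        assert fisher_exact_enum([[1, 0], [0, 1]]) == 1.0

    def test_diagonal_extreme(self):
        p = fisher_exact_enum([[10, 0], [0, 10]])
        assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-12)

    @pytest.mark.parametrize("table", [
        [[8, 2], [1, 5]], [[3, 7], [6, 4]], [[12, 0], [2, 9]],
        [[1, 1], [1, 1]],
    ])
    def test_enum_matches_scipy_two_by_two(self, table):
        ours = fisher_exact_enum(table)
        ref = scipy.stats.fisher_exact(table).pvalue
        assert ours == pytest.approx(ref, abs=1e-10)

    @pytest.mark.parametrize("table", [
        [[4, 1, 3], [2, 5, 0]], [[6, 0, 0], [0, 6, 6]], [[2, 2, 2], [2, 2, 2]],
    ])
    def test_mc_close_to_enum(self, table):
        rng = np.random.default_rng(7)
        exact = fisher_exact_enum(table)
        mc = fisher_exact_mc(table, B=20_000, rng=rng)
        assert abs(mc - exact) < 0.02

    def test_enumeration_is_complete(self):
        rows, cols = [3, 2], [2, 3]
        tables = list(enumerate_tables(rows, cols))
        # probabilities of all feasible tables sum to one
        lps = np.array([table_log_prob(t, rows, cols) for t in tables])
        assert np.exp(lps).sum() == pytest.approx(1.0, abs=1e-12)
        assert len({t.tobytes() for t in tables}) == len(tables)

    def test_dispatch_uses_enumeration_for_small_tables(self):
        table = [[2, 1], [1, 2]]
        assert enumeration_bound([3, 3], 2) <= 500
        assert fisher_pvalue(table, B=10, rng=np.random.default_rng(0)) == \
            fisher_exact_enum(table)

    def test_degenerate_table_p_one(self):
        assert fisher_pvalue([[0, 0], [0, 0]]) == 1.0


class TestIntegerize:
    @given(st.lists(st.lists(st.floats(0.0, 30.0), min_size=2, max_size=5),
                    min_size=2, max_size=5).filter(
        lambda m: len({len(r) for r in m}) == 1))
    def test_margins_share_total_and_stay_close(self, matrix):
        m = np.asarray(matrix)
        rows, cols = integerize_margins(m)
        assert rows.sum() == cols.sum() == int(round(m.sum()))
        assert (np.abs(rows - m.sum(axis=1)) <= 1.0 + 1e-9).all()
        assert (np.abs(cols - m.sum(axis=0)) <= 1.0 + 1e-9).all()


class TestCellRandomization:
    def test_centered_cell_unflagged(self):
        # a constant table: every random table equals the observed one
        obs = np.array([[2.0, 2.0], [2.0, 2.0]])
        res = cell_randomization_test(obs, n_rand=200,
                                      rng=np.random.default_rng(0))
        # sd may be zero or tiny; either way nothing should be flagged
        assert (res.flag == "none").all()
        assert (np.abs(res.z) < 2).all()

    def test_zero_spread_convention(self):
        # 1x2 margins force the table entirely: sd == 0 everywhere
        obs = np.array([[3.0, 2.0]])
        res = cell_randomization_test(obs, n_rand=100,
                                      rng=np.random.default_rng(0))
        assert (res.sd_random == 0).all()
        assert (res.z == 0).all()
        assert (res.prob == 0.5).all()
        assert (res.flag == "none").all()

    def test_planted_excess_flagged_higher(self):
        # observed diagonal far above the independence expectation
        obs = np.array([[40.0, 10.0], [10.0, 40.0]])
        res = cell_randomization_test(obs, n_rand=1000,
                                      rng=np.random.default_rng(0))
        assert res.flag[0, 0] == "higher" and res.flag[1, 1] == "higher"
        assert res.flag[0, 1] == "lower" and res.flag[1, 0] == "lower"
        assert res.prob[0, 0] > 0.95 and res.prob[0, 1] < 0.05

    def test_row_permutation_equivariance(self):
        obs = np.array([[30.0, 5.0, 10.0], [8.0, 20.0, 12.0],
                        [5.0, 5.0, 25.0]])
        res = cell_randomization_test(obs, n_rand=2000,
                                      rng=np.random.default_rng(3))
        perm = [2, 0, 1]
        res_p = cell_randomization_test(obs[perm], n_rand=2000,
                                        rng=np.random.default_rng(3))
        # same flags up to the row relabeling (z noise is Monte-Carlo small)
        assert (res.flag[perm] == res_p.flag).all()


class TestGroupedAnalysis:
    def _stream(self, classes_by_species, n_iter=100):
        rows = []
        for i, (grp, cls) in enumerate(classes_by_species):
            rows.append({"obs_id": f"O{i}", "setting": "database",
                         "verified_name": f"Genus{i:03d} sp",
                         "suggested_name": "", "organs": "both",
                         "focus": "single", "background": "vegetation",
                         "class_code": int(cls), "id_class": cls.label,
                         "_group": grp})
        obs = pd.DataFrame(rows)
        _, stream = iterate_subsample(obs, n_iter=n_iter, seed=0)
        species = pd.DataFrame({
            "accepted_name": obs["verified_name"],
            "genus": "Genus", "family": obs["_group"],
            "growth_form": obs["_group"], "life_form": obs["_group"],
            "habitat": obs["_group"], "frequency": 100,
            "n_training_images": 100})
        return stream, species

    def test_extreme_separation(self):
        S, N = IdentificationClass.SPECIES, IdentificationClass.NONE
        data = [("FamA", S)] * 50 + [("FamB", N)] * 50
        stream, species = self._stream(data, n_iter=60)
        res = grouped_class_analysis(stream, species, "family",
                                     min_group_size=10, fisher_B=2000,
                                     n_rand=500, seed=1)
        assert res.fisher.median_p < 0.001
        ia, ib = res.groups.index("FamA"), res.groups.index("FamB")
        assert res.cells.flag[ia, 0] == "higher"      # FamA x species
        assert res.cells.flag[ib, 3] == "higher"      # FamB x none
        assert res.percentages.loc["FamA", "species"] == 100.0

    def test_min_group_size_filter(self):
        S = IdentificationClass.SPECIES
        data = [("Big1", S)] * 12 + [("Big2", S)] * 11 + [("Tiny", S)] * 9
        stream, species = self._stream(data, n_iter=10)
        res = grouped_class_analysis(stream, species, "family",
                                     min_group_size=10, fisher_B=100,
                                     n_rand=100, seed=0)
        assert "Tiny" not in res.groups
        assert res.group_sizes == {"Big1": 12, "Big2": 11}

    def test_single_group_rejected(self):
        S = IdentificationClass.SPECIES
        data = [("Only", S)] * 20
        stream, species = self._stream(data, n_iter=10)
        with pytest.raises(ValidationError):
            grouped_class_analysis(stream, species, "family",
                                   min_group_size=10, seed=0)

    def test_unknown_grouping_rejected(self, small_dataset):
        obs, species, _ = small_dataset
        _, stream = iterate_subsample(obs, n_iter=10, seed=0)
        with pytest.raises(ValidationError):
            grouped_class_analysis(stream, species, "color", seed=0)
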