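"""Interchromosomal landscape operations against hand-computed oracles."""

import numpy as np
import pytest
from scipy.stats import chi2

from translocscape import landscape as L
from translocscape.core import BinnedMatrix, make_bins
from translocscape.synthgen import simulate_contacts

from conftest import make_pair_table, random_symmetric_matrix


def matrix_from_rows(rows, chrom_bins):
    bins = make_bins({c: n * 1_000_000 for c, n in chrom_bins.items()}, 1_000_000)
    return BinnedMatrix(bins, np.asarray(rows, dtype=float), 1_000_000)


class TestMasking:
    def test_hand_computed_row_totals(self):
        """Row totals [50, 150, 200, 90] at threshold 100 mask bins 0, 3."""
        counts = np.array(
            [
                [10.0, 10.0, 10.0, 20.0],
                [10.0, 60.0, 40.0, 40.0],
                [10.0, 40.0, 140.0, 10.0],
                [20.0, 40.0, 10.0, 20.0],
            ]
        )
        assert counts.sum(axis=1).tolist() == [50.0, 150.0, 200.0, 90.0]
        m = matrix_from_rows(counts, {"c1": 4})
        masked = L.mask_low_coverage_bins(m, 100)
        assert masked.mask.tolist() == [True, False, False, True]

    def test_all_above_threshold_unchanged(self, small_matrix):
        out = L.mask_low_coverage_bins(small_matrix, 0)
        assert not out.mask.any()
        assert np.array_equal(out.counts, small_matrix.counts)

    def test_idempotent(self, small_matrix):
        once = L.mask_low_coverage_bins(small_matrix, 12)
        twice = L.mask_low_coverage_bins(once, 12)
        assert np.array_equal(once.mask, twice.mask)

    def test_default_threshold_is_60k(self):
        import inspect

        sig = inspect.signature(L.mask_low_coverage_bins)
        assert sig.parameters["min_total"].default == 60_000


class TestNormalization:
    def test_total_already_at_target(self, small_matrix):
        iu = np.triu_indices(small_matrix.n_bins)
        total = small_matrix.counts[iu].sum()
        out = L.normalize_total(small_matrix, total)
        assert np.allclose(out.counts, small_matrix.counts)

    def test_double_target_halves(self, small_matrix):
        iu = np.triu_indices(small_matrix.n_bins)
        total = small_matrix.counts[iu].sum()
        out = L.normalize_total(small_matrix, total / 2)
        assert np.allclose(out.counts, small_matrix.counts / 2)

    def test_default_target_150m(self):
        assert L.DEFAULT_TARGET == 150_000_000

    def test_zero_total_rejected(self):
        m = matrix_from_rows(np.zeros((2, 2)), {"c1": 2})
        with pytest.raises(ValueError):
            L.normalize_total(m, 100)


class TestMerging:
    def test_identical_matrices_unchanged(self, small_matrix):
        out = L.merge_samples([small_matrix] * 3)
        assert np.allclose(out.counts, small_matrix.counts)

    @pytest.mark.parametrize(
        "values,expected", [((1.0, 2.0, 9.0), 2.0), ((1.0, 3.0), 2.0)]
    )
    def test_median_policy(self, values, expected):
        ms = []
        for v in values:
            ms.append(matrix_from_rows(np.full((2, 2), v), {"c1": 2}))
        out = L.merge_samples(ms)
        assert out.counts[0, 1] == expected

    def test_na_in_any_input_propagates(self):
        a = matrix_from_rows(np.full((2, 2), 5.0), {"c1": 2})
        b = matrix_from_rows(np.full((2, 2), 5.0), {"c1": 2})
        b.mask[0] = True
        out = L.merge_samples([a, b])
        assert np.isnan(out.effective()[0, 1])
        assert out.mask[0]

    def test_bin_mismatch_rejected(self):
        a = matrix_from_rows(np.zeros((2, 2)), {"c1": 2})
        b = matrix_from_rows(np.zeros((2, 2)), {"c2": 2})
        with pytest.raises(ValueError):
            L.merge_samples([a, b])


class TestPairFrequency:
    def test_hand_summed_frequency(self):
        """2x3-bin chromosomes with trans counts summing 12 give 12/6 = 2."""
        counts = np.zeros((5, 5))
        counts[0, 2:5] = [1.0, 2.0, 3.0]
        counts[1, 2:5] = [2.0, 3.0, 1.0]
        counts += counts.T
        m = matrix_from_rows(counts, {"c1": 2, "c2": 3})
        freq = L.pair_frequency(m)
        assert freq.value("c1", "c2") == pytest.approx(2.0)
        assert freq.value("c2", "c1") == pytest.approx(2.0)

    def test_zero_matrix_all_zero(self):
        m = matrix_from_rows(np.zeros((5, 5)), {"c1": 2, "c2": 3})
        assert L.pair_frequency(m).value("c1", "c2") == 0.0

    def test_excluded_pair_is_na(self, small_matrix):
        freq = L.pair_frequency(small_matrix, exclude_pairs={("c1", "c2")})
        assert np.isnan(freq.value("c1", "c2"))

    def test_symmetry_property(self):
        rng = np.random.default_rng(0)
        m = random_symmetric_matrix(rng, {"c1": 3, "c2": 4, "c3": 2})
        table = L.pair_frequency(m).table
        assert table.equals(table.T)

    def test_depth_invariance_after_normalization(self):
        """pair_frequency of depth-normalised matrices does not depend on
        the original sequencing depth."""
        rng = np.random.default_rng(1)
        m = random_symmetric_matrix(rng, {"c1": 3, "c2": 4})
        deep = m.copy()
        deep.counts = m.counts * 7.0
        f1 = L.pair_frequency(L.normalize_total(m, 1e6)).table
        f2 = L.pair_frequency(L.normalize_total(deep, 1e6)).table
        assert np.allclose(f1.to_numpy(), f2.to_numpy(), equal_nan=True)


class TestLog2FC:
    chroms = ["c1", "c2", "c3"]

    def test_equal_tables_zero(self):
        t = make_pair_table({("c1", "c2"): 4.0, ("c1", "c3"): 2.0}, self.chroms)
        fc = L.log2fc_pairs(L.ChromPairFreq(t), L.ChromPairFreq(t.copy()))
        assert fc.loc["c1", "c2"] == 0.0

    def test_doubling_gives_one(self):
        a = make_pair_table({("c1", "c2"): 8.0}, self.chroms)
        b = make_pair_table({("c1", "c2"): 4.0}, self.chroms)
        fc = L.log2fc_pairs(L.ChromPairFreq(a), L.ChromPairFreq(b))
        assert fc.loc["c1", "c2"] == 1.0

    def test_zero_denominator_is_na(self):
        a = make_pair_table({("c1", "c2"): 8.0}, self.chroms)
        b = make_pair_table({("c1", "c2"): 0.0}, self.chroms)
        fc = L.log2fc_pairs(L.ChromPairFreq(a), L.ChromPairFreq(b))
        assert np.isnan(fc.loc["c1", "c2"])


class TestCommonExtremes:
    def test_rank_enumeration_top_and_bottom(self):
        """20 strictly increasing pairs at q=0.10 select top 2 / bottom 2."""
        chroms = [f"c{i}" for i in range(6)]
        pairs = [
            (a, b) for i, a in enumerate(chroms) for b in chroms[i + 1:]
        ][:20]
        values = {p: float(k + 1) for k, p in enumerate(pairs)}
        t = make_pair_table(values, chroms)
        inc, dec = L.common_extreme_pairs(t, t.copy(), q=0.10)
        assert inc == set(pairs[-2:])
        assert dec == set(pairs[:2])

    def test_all_equal_selects_nothing(self):
        chroms = ["c1", "c2", "c3"]
        t = make_pair_table(
            {("c1", "c2"): 1.0, ("c1", "c3"): 1.0, ("c2", "c3"): 1.0}, chroms
        )
        inc, dec = L.common_extreme_pairs(t, t.copy(), q=0.10)
        assert inc == set() and dec == set()

    def test_invalid_q_rejected(self):
        t = make_pair_table({("c1", "c2"): 1.0}, ["c1", "c2"])
        with pytest.raises(ValueError):
            L.common_extreme_pairs(t, t, q=1.5)


class TestEnrichment:
    def test_hand_arithmetic_fold_and_chi2(self):
        """10/20 focal among selected vs 50/200 in universe: fold 2; the
        chi-square statistic is checked against the textbook formula."""
        universe = {(f"F1", f"x{k}") for k in range(50)} | {
            (f"y{k}", f"z{k}") for k in range(150)
        }
        selected = {(f"F1", f"x{k}") for k in range(10)} | {
            (f"y{k}", f"z{k}") for k in range(10)
        }
        fold, p = L.enrichment_test(selected, universe, {"F1", "F2"})
        assert fold == pytest.approx(2.0)
        # oracle: chi-square statistic from the 2x2 table by hand
        obs = np.array([[10, 10], [40, 140]], dtype=float)
        expect = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        stat = ((obs - expect) ** 2 / expect).sum()
        assert p == pytest.approx(chi2.sf(stat, 1))

    def test_equal_fraction_fold_one(self):
        universe = {("F1", f"x{k}") for k in range(10)} | {
            (f"y{k}", f"z{k}") for k in range(10)
        }
        selected = {("F1", "x0"), ("y0", "z0")}
        fold, _ = L.enrichment_test(selected, universe, {"F1"})
        assert fold == pytest.approx(1.0)

    def test_no_focal_pairs_rejected(self):
        universe = {("a", "b"), ("c", "d")}
        with pytest.raises(ValueError, match="focal"):
            L.enrichment_test({("a", "b")}, universe, {"chr11"})

    def test_brute_force_equivalence_small_universes(self):
        """Fold equals a direct 2x2 tabulation on random universes."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(10, 50))
            universe = set()
            for k in range(n):
                a = f"F" if rng.random() < 0.3 else f"a{k}"
                universe.add((a, f"b{k}"))
            sel = set(
                p for p in universe if rng.random() < 0.4
            )
            if not sel or not any("F" in pr for pr in universe):
                continue
            fold, _ = L.enrichment_test(sel, universe, {"F"})
            sf = sum(1 for p in sel if "F" in p)
            uf = sum(1 for p in universe if "F" in p)
            assert fold == pytest.approx(
                (sf / len(sel)) / (uf / len(universe))
            )


class TestPartnerRecovery:
    def test_translocation_partner_is_top_log2fc_pair(self, tx_config):
        """The configured partner pair tops the tumor/normal log2FC table."""
        normal, tumor, truth = simulate_contacts(tx_config)
        fn = L.pair_frequency(L.normalize_total(normal, 1e6))
        ft = L.pair_frequency(L.normalize_total(tumor, 1e6))
        fc = L.log2fc_pairs(ft, fn)
        assert set(L.top_partner_pair(fc)) == set(truth.partner_pair)
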