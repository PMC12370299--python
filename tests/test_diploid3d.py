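"""Deconvolution arithmetic, bead geometry and compartment aggregation."""

import numpy as np
import pandas as pd
import pytest

from translocscape import diploid3d as D3
from translocscape.core import BinnedMatrix, SegmentMap, make_bins
from translocscape.synthgen import BeadModel

from conftest import random_symmetric_matrix


def beads(coords, label="c_a"):
    return BeadModel(
        beads=pd.DataFrame(
            [(label, k, *xyz) for k, xyz in enumerate(coords)],
            columns=["chrom", "bin", "x", "y", "z"],
        )
    )


SM = SegmentMap({"c1": (1_500_000, 1_501_000)})


def two_chrom_matrix(counts):
    bins = make_bins({"c1": 3_000_000, "c2": 2_000_000}, 1_000_000)
    return BinnedMatrix(bins, np.asarray(counts, float), 1_000_000)


class TestDeconvoluteNormal:
    def test_cis_halved_trans_quartered(self):
        counts = np.zeros((5, 5))
        counts[0, 1] = counts[1, 0] = 10.0  # cis c1
        counts[0, 3] = counts[3, 0] = 8.0  # trans c1-c2
        m = two_chrom_matrix(counts)
        dip = D3.deconvolute(m, "normal")
        for allele in ("c1_a", "c1_b"):
            s = dip.chrom_slice(allele)
            assert dip.counts[s, s][0, 1] == 5.0
        for a in ("c1_a", "c1_b"):
            for b in ("c2_a", "c2_b"):
                block = dip.counts[dip.chrom_slice(a), dip.chrom_slice(b)]
                assert block[0, 0] == 2.0

    def test_conserves_totals_exactly(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            m = random_symmetric_matrix(rng, {"c1": 3, "c2": 4, "c3": 2})
            dip = D3.deconvolute(m, "normal")
            for chrom in m.chromosomes:
                s = m.chrom_slice(chrom)
                cis_in = m.counts[s, s].sum()
                cis_out = sum(
                    np.nansum(dip.counts[dip.chrom_slice(f"{chrom}_{x}"),
                                         dip.chrom_slice(f"{chrom}_{x}")])
                    for x in "ab"
                )
                assert cis_out == pytest.approx(cis_in, abs=1e-9)
            for i, ca in enumerate(m.chromosomes):
                for cb in m.chromosomes[i + 1:]:
                    t_in = m.counts[m.chrom_slice(ca), m.chrom_slice(cb)].sum()
                    t_out = sum(
                        np.nansum(dip.counts[dip.chrom_slice(f"{ca}_{x}"),
                                             dip.chrom_slice(f"{cb}_{y}")])
                        for x in "ab" for y in "ab"
                    )
                    assert t_out == pytest.approx(t_in, abs=1e-9)


class TestDeconvoluteTumor:
    def test_subtraction_rule(self):
        """Sample cis 12 with reference 8: wild-type 8, derivative 4."""
        sample = np.zeros((5, 5))
        sample[0, 1] = sample[1, 0] = 12.0
        ref = np.zeros((5, 5))
        ref[0, 1] = ref[1, 0] = 8.0
        dip = D3.deconvolute(
            two_chrom_matrix(sample), "tumor",
            normal_ref=two_chrom_matrix(ref), sm=SM,
        )
        wt = dip.counts[dip.chrom_slice("c1_wt"), dip.chrom_slice("c1_wt")]
        der = dip.counts[dip.chrom_slice("c1_der"), dip.chrom_slice("c1_der")]
        assert wt[0, 1] == 8.0
        assert der[0, 1] == 4.0

    def test_clamping_property(self):
        """wildtype + derivative = max(sample, reference) entrywise."""
        rng = np.random.default_rng(3)
        sample = random_symmetric_matrix(rng, {"c1": 3, "c2": 2})
        ref = random_symmetric_matrix(rng, {"c1": 3, "c2": 2})
        dip = D3.deconvolute(sample, "tumor", normal_ref=ref, sm=SM)
        s = sample.chrom_slice("c1")
        wt = dip.counts[dip.chrom_slice("c1_wt"), dip.chrom_slice("c1_wt")]
        der = dip.counts[dip.chrom_slice("c1_der"), dip.chrom_slice("c1_der")]
        assert np.allclose(wt + der, np.maximum(sample.counts[s, s], ref.counts[s, s]))

    def test_partner_trans_is_na(self):
        rng = np.random.default_rng(4)
        sample = random_symmetric_matrix(rng, {"c1": 2, "c2": 2, "c3": 2})
        ref = random_symmetric_matrix(rng, {"c1": 2, "c2": 2, "c3": 2})
        sm = SegmentMap({"c1": (1_000_000, 1_001_000), "c2": (1_000_000, 1_001_000)})
        dip = D3.deconvolute(sample, "tumor", normal_ref=ref, sm=sm)
        for a in ("c1_wt", "c1_der"):
            for b in ("c2_wt", "c2_der"):
                block = dip.counts[dip.chrom_slice(a), dip.chrom_slice(b)]
                assert np.isnan(block).all()
        # non-partner trans remains defined
        block = dip.counts[dip.chrom_slice("c1_wt"), dip.chrom_slice("c3_a")]
        assert np.isfinite(block).all()

    def test_requires_reference_and_matching_bins(self):
        rng = np.random.default_rng(5)
        m = random_symmetric_matrix(rng, {"c1": 3, "c2": 2})
        with pytest.raises(ValueError, match="normal_ref"):
            D3.deconvolute(m, "tumor", sm=SM)
        other = random_symmetric_matrix(rng, {"c1": 2, "c2": 2})
        with pytest.raises(ValueError, match="bin tables"):
            D3.deconvolute(m, "tumor", normal_ref=other, sm=SM)


class TestRadialPosition:
    def test_hand_center_of_mass(self):
        model = beads([(1, 0, 0), (3, 0, 0)])
        assert D3.radial_position(model, "c_a") == pytest.approx(2.0)

    def test_symmetric_beads_zero(self):
        model = beads([(1, 2, 3), (-1, -2, -3)])
        assert D3.radial_position(model, "c_a") == pytest.approx(0.0)

    def test_single_bead_distance(self):
        model = beads([(0, 3, 4)])
        assert D3.radial_position(model, "c_a") == pytest.approx(5.0)

    def test_rotation_invariance_and_linear_scaling(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(10, 3)) + [2.0, 0.5, -1.0]
        r = D3.radial_position(beads(coords), "c_a")
        # random rotation via QR
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        assert D3.radial_position(beads(coords @ q), "c_a") == pytest.approx(r)
        assert D3.radial_position(beads(coords * 3.0), "c_a") == pytest.approx(3 * r)


class TestPairwiseDistances:
    def test_three_four_five(self):
        model = BeadModel(
            beads=pd.DataFrame(
                [("a", 0, 0.0, 0.0, 0.0), ("b", 0, 3.0, 4.0, 0.0)],
                columns=["chrom", "bin", "x", "y", "z"],
            )
        )
        d = D3.pairwise_bin_distances(model, "a", "b")
        assert d[0, 0] == pytest.approx(5.0)

    def test_self_distance_zero_and_log1p(self):
        model = beads([(1, 1, 1), (1, 1, 1)])
        d = D3.pairwise_bin_distances(model, "c_a", "c_a")
        assert d[0, 1] == 0.0
        dl = D3.pairwise_bin_distances(model, "c_a", "c_a", log1p=True)
        assert dl[0, 1] == 0.0


class TestBreakpointProfile:
    def test_collinear_beads_distances(self):
        """Unit-spaced collinear beads give |bin - breakpoint| distances."""
        model = beads([(float(k), 0, 0) for k in range(6)])
        prof = D3.distance_to_breakpoint_profile([model], "c_a", 2)
        assert prof["median"].tolist() == [2.0, 1.0, 0.0, 1.0, 2.0, 3.0]

    def test_breakpoint_bin_itself_zero(self):
        model = beads([(0.0, 0, 0), (5.0, 0, 0)])
        prof = D3.distance_to_breakpoint_profile([model], "c_a", 0)
        assert prof.loc[prof["bin"] == 0, "median"].iloc[0] == 0.0

    def test_compartment_grouping_column(self):
        model = beads([(0.0, 0, 0), (1.0, 0, 0)])
        prof = D3.distance_to_breakpoint_profile(
            [model], "c_a", 0, compartments=pd.Series({0: "A", 1: "B"})
        )
        assert prof["compartment"].tolist() == ["A", "B"]


class TestCompartments:
    def sample(self, scores, chrom="c1"):
        n = len(scores)
        return pd.DataFrame(
            {"chrom": chrom, "start": np.arange(n) * 100_000, "score": scores}
        )

    def test_constant_scores(self):
        out = D3.aggregate_compartments([self.sample([0.4] * 10)])
        assert out["score"].iloc[0] == pytest.approx(0.4)
        assert out["label"].iloc[0] == "A"

    def test_zero_median_undetermined(self):
        scores = [-1.0] * 5 + [1.0] * 5
        out = D3.aggregate_compartments([self.sample(scores)])
        assert out["score"].iloc[0] == 0.0
        assert out["label"].iloc[0] == "undetermined"

    def test_per_type_median_across_samples(self):
        samples = [self.sample([v] * 10) for v in (0.2, -0.1, 0.3)]
        out = D3.aggregate_compartments(samples)
        assert out["score"].iloc[0] == pytest.approx(0.2)
        assert out["label"].iloc[0] == "A"

    def test_negative_label_b(self):
        out = D3.aggregate_compartments([self.sample([-0.3] * 10)])
        assert out["label"].iloc[0] == "B"


class TestEigenSelection:
    def make_gc(self, n=50, seed=0):
        return np.random.default_rng(seed).uniform(0.3, 0.6, n)

    def test_clear_winner_selected_as_is(self):
        gc = self.make_gc()
        v1 = gc + np.random.default_rng(1).normal(0, 0.05, len(gc))
        v2 = np.random.default_rng(2).normal(size=len(gc))
        sel = D3.select_eigenvector([(v1, 0.5), (v2, 0.3)], gc)
        assert not sel.manual
        assert sel.index == 0
        assert np.corrcoef(sel.vector, gc)[0, 1] > 0

    def test_negative_correlation_flipped(self):
        gc = self.make_gc()
        v = -(gc - gc.mean())
        sel = D3.select_eigenvector([(v, 0.5)], gc)
        assert not sel.manual
        assert np.corrcoef(sel.vector, gc)[0, 1] > 0

    def test_ambiguous_candidates_flagged_manual(self):
        gc = self.make_gc()
        noise = np.random.default_rng(3).normal(0, 0.12, len(gc))
        v1 = gc + noise
        v2 = gc + noise * 1.05
        sel = D3.select_eigenvector([(v1, 0.5), (v2, 0.45)], gc)
        assert sel.manual

    def test_weak_correlation_flagged_manual(self):
        gc = self.make_gc()
        v = np.random.default_rng(4).normal(size=len(gc))
        sel = D3.select_eigenvector([(v, 0.5)], gc)
        assert sel.manual


def test_radial_shift_percent_arithmetic():
    assert D3.radial_shift_percent(0.86, 5.0) == 17.2
    assert D3.radial_shift_percent(0.71, 5.0) == 14.2
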