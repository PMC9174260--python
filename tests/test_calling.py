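"""Dyad caller against a brute-force kernel-density oracle, plus QC ops."""

import numpy as np
import pandas as pd
import pytest

from nucleostates import (NucleosomeCaller, assign_region, call_dyads,
                          dyad_centered_profile, replicate_correlation,
                          saturation_curve, spacing_stats)
from conftest import make_genes, midpoint_frame


def brute_force_dyads(positions, bandwidth=30.0, merge=120):
    """Independent oracle: explicit Gaussian kernel sum on a 1-bp grid."""
    positions = np.asarray(positions, float)
    lo = int(positions.min()) - 150
    hi = int(positions.max()) + 150
    grid = np.arange(lo, hi + 1, dtype=float)
    dens = np.exp(-((grid[:, None] - positions[None, :]) ** 2)
                  / (2 * bandwidth ** 2)).sum(axis=1)
    peaks = [i for i in range(1, len(dens) - 1)
             if dens[i] > dens[i - 1] and dens[i] >= dens[i + 1]]
    out = []
    for pk in peaks:
        if out and pk - out[-1] < merge:
            if dens[pk] > dens[out[-1]]:
                out[-1] = pk
        else:
            out.append(pk)
    return np.array(out) + lo


class TestCallDyads:
    def test_no_midpoints_no_nucleosomes(self):
        out = call_dyads(pd.DataFrame(columns=["chrom", "pos"]))
        assert out.empty

    def test_point_mass_gives_one_perfect_dyad(self):
        mids = midpoint_frame([5000] * 200)
        out = call_dyads(mids)
        assert len(out) == 1
        assert out.loc[0, "dyad"] == 5000
        assert out.loc[0, "dop"] == 1.0

    def test_two_gaussian_clusters_recovered(self):
        rng = np.random.default_rng(42)
        pos = np.concatenate([rng.normal(1000, 20, 500),
                              rng.normal(1200, 20, 500)]).round().astype(int)
        out = call_dyads(midpoint_frame(pos))
        assert len(out) == 2
        assert abs(out.loc[0, "dyad"] - 1000) <= 5
        assert abs(out.loc[1, "dyad"] - 1200) <= 5

    def test_unsorted_input_rejected(self):
        mids = pd.DataFrame({"chrom": "chr1", "pos": [500, 100, 900]})
        with pytest.raises(ValueError, match="sorted"):
            call_dyads(mids)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        centers = np.cumsum(rng.integers(160, 260, 12)) + 1000
        pos = np.concatenate([
            rng.normal(c, 25, rng.integers(60, 160)) for c in centers])
        pos = np.sort(pos.round().astype(int))
        called = call_dyads(midpoint_frame(pos))["dyad"].to_numpy()
        oracle = brute_force_dyads(pos)
        assert len(called) == len(oracle)
        assert np.abs(called - oracle).max() <= 1

    def test_merge_keeps_higher_peak(self):
        # two modes 80 bp apart must merge into one dyad at the taller mode
        rng = np.random.default_rng(7)
        pos = np.concatenate([rng.normal(1000, 12, 500),
                              rng.normal(1080, 12, 120)])
        out = call_dyads(midpoint_frame(pos.round().astype(int)))
        assert len(out) == 1
        assert abs(out.loc[0, "dyad"] - 1000) <= 5

    def test_footprints_bounded_and_ordered(self, small_map):
        out = call_dyads(small_map.midpoints)
        assert ((out["start"] <= out["dyad"]) & (out["dyad"] < out["end"])).all()
        assert (out["end"] - out["dyad"] <= 101).all()
        assert (out["dyad"] - out["start"] <= 100).all()
        for _, sub in out.groupby("chrom"):
            assert (np.diff(sub["dyad"].to_numpy()) > 0).all()

    def test_zero_noise_recall(self):
        from nucleostates import SyntheticConfig, generate_nucleosome_map
        cfg = SyntheticConfig(positioning_noise_sd=0.0)
        m = generate_nucleosome_map(cfg, "Veh", n_regions=60, seed=13,
                                    emit_marks=False)
        called = call_dyads(m.midpoints)
        true = np.sort(m.nucleosomes["dyad"].to_numpy())
        got = np.sort(called["dyad"].to_numpy())
        idx = np.searchsorted(got, true)
        idx = np.clip(idx, 0, got.size - 1)
        near = np.minimum(np.abs(got[idx] - true),
                          np.abs(got[np.maximum(idx - 1, 0)] - true))
        assert (near <= 5).mean() >= 0.99


class TestSpacing:
    def test_constant_spacing(self):
        nucs = pd.DataFrame({"chrom": "chr1", "dyad": [0, 187, 374, 561]})
        st = spacing_stats(nucs)
        assert st.mode == 187
        assert st.histogram[187] == 3

    def test_out_of_range_excluded(self):
        nucs = pd.DataFrame({"chrom": "chr1", "dyad": [0, 100, 400]})
        st = spacing_stats(nucs)
        assert st.histogram.sum() == 1
        assert st.mode == 300

    def test_no_spacing_raises(self):
        nucs = pd.DataFrame({"chrom": ["chr1"], "dyad": [10]})
        with pytest.raises(ValueError, match="no spacing"):
            spacing_stats(nucs)

    def test_mode_invariant_under_shift(self, small_map):
        nucs = small_map.nucleosomes
        shifted = nucs.assign(dyad=nucs["dyad"] + 12_345)
        assert spacing_stats(nucs).mode == spacing_stats(shifted).mode


class TestAssignRegion:
    GENES = make_genes([("gA", "chr1", "+", 10_000, 12_000)])
    GENES_MINUS = make_genes([("gB", "chr1", "-", 10_000, 8_000)])

    @pytest.mark.parametrize("pos,expect", [
        (10_500, "Promoter"),
        (9_100, "Promoter"),
        (6_000, "Proximal"),
        (5_000, "Proximal"),      # boundary: [TSS-5000, TSS-1000) half-open
        (4_999, "Distal"),
        (10_900, "Promoter"),
        (12_500, None),           # downstream, outside the promoter window
        (100, "Distal"),          # 9.9 kb upstream
    ])
    def test_plus_strand(self, pos, expect):
        res = assign_region([("chr1", pos)], self.GENES)
        assert res.loc[0, "region"] == expect

    def test_minus_strand_upstream_reflected(self):
        res = assign_region([("chr1", 12_500)], self.GENES_MINUS)
        assert res.loc[0, "region"] == "Proximal"

    def test_nearest_tss_wins(self):
        genes = make_genes([("gA", "chr1", "+", 10_000, 12_000),
                            ("gC", "chr1", "+", 30_000, 32_000)])
        res = assign_region([("chr1", 26_500)], genes)
        assert res.loc[0, "gene"] == "gC"   # 3.5 kb vs 16.5 kb
        assert res.loc[0, "region"] == "Proximal"

    def test_unknown_chromosome(self):
        res = assign_region([("chrX", 10_000)], self.GENES)
        assert res.loc[0, "region"] is None

    def test_labels_partition_upstream_span(self):
        # every upstream position gets exactly one label; windows are disjoint
        positions = [("chr1", p) for p in range(-40_001, 11_000, 13)]
        res = assign_region(positions, self.GENES)
        pos = np.array([p for _, p in positions])
        expect = np.where(pos >= 9_000, "Promoter",
                          np.where(pos >= 5_000, "Proximal",
                                   np.where(pos >= -40_000, "Distal",
                                            None)))
        assert (res["region"].to_numpy() == expect).all()


class TestReplicateCorrelation:
    def test_identical_tracks(self):
        t = midpoint_frame(np.arange(0, 100_000, 37))
        assert replicate_correlation(t, t) == pytest.approx(1.0)

    def test_anticorrelated_tracks(self):
        # per-bin counts b = 10 - a
        a = np.repeat(np.arange(50), np.tile([1, 9], 25))
        b = np.repeat(np.arange(50), 10 - np.tile([1, 9], 25))
        ta = midpoint_frame(a * 200 + 5)
        tb = midpoint_frame(b * 200 + 5)
        assert replicate_correlation(ta, tb) == pytest.approx(-1.0)

    def test_poisson_thinned_replicates_correlate(self, small_map):
        rng = np.random.default_rng(0)
        pos = small_map.midpoints["pos"].to_numpy()
        keep_a = rng.random(pos.size) < 0.5
        keep_b = rng.random(pos.size) < 0.5
        ta = midpoint_frame(pos[keep_a])
        tb = midpoint_frame(pos[keep_b])
        assert replicate_correlation(ta, tb) > 0.9

    def test_zero_variance_rejected(self):
        t = midpoint_frame([100] * 5)
        with pytest.raises(ValueError, match="variance"):
            replicate_correlation(t, t)


class TestSaturation:
    def test_full_fraction_reproduces_count(self, small_map):
        full = len(call_dyads(small_map.midpoints))
        tab = saturation_curve(small_map.midpoints, [1.0], seed=0)
        assert tab.loc[0, "n_dyads"] == full

    def test_zero_fraction_rejected(self, small_map):
        with pytest.raises(ValueError):
            saturation_curve(small_map.midpoints, [0.0], seed=0)

    def test_saturated_at_half_depth(self, small_map):
        tab = saturation_curve(small_map.midpoints, [0.5, 1.0], seed=0)
        n_half, n_full = tab["n_dyads"]
        assert abs(n_full - n_half) / n_full < 0.05


class TestDyadProfile:
    def test_spike_at_zero(self):
        dyads = pd.DataFrame({"chrom": "chr1", "dyad": [1000, 2000]})
        mids = midpoint_frame([1000] * 5 + [2000] * 5)
        prof = dyad_centered_profile(dyads, mids)
        assert prof[600] == 5.0
        assert prof.sum() == 5.0

    def test_regular_array_side_peaks(self):
        dyads_pos = np.arange(10_000, 12_000, 187)
        dyads = pd.DataFrame({"chrom": "chr1", "dyad": dyads_pos})
        mids = midpoint_frame(np.repeat(dyads_pos, 20))
        prof = dyad_centered_profile(dyads, mids)
        assert prof[600 + 187] > 0 and prof[600 - 187] > 0
        assert prof[600 + 100] == 0

    def test_empty_midpoints_zero_vector(self):
        dyads = pd.DataFrame({"chrom": "chr1", "dyad": [1000]})
        prof = dyad_centered_profile(dyads, midpoint_frame([]))
        assert prof.shape == (1201,)
        assert not prof.any()

    def test_no_dyads_raises(self):
        with pytest.raises(ValueError, match="dyads"):
            dyad_centered_profile(pd.DataFrame(columns=["chrom", "dyad"]),
                                  midpoint_frame([1]))
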