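"""ChIP quantification: delta-CT enrichment, occupancy ratio, profiles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import median_sort, paired_t

from meioquant.chip import (
    AggregateResult,
    ChipSeqCounts,
    CoverageTrack,
    QpcrMeasurement,
    aggregate_replicates,
    calibrate_track,
    composite_median_profile,
    occupancy_ratio,
    profile_difference,
    qpcr_enrichment,
    read_bed_midpoints,
    read_bedgraph,
    write_bed,
    write_bedgraph,
)


def meas(role, ct, e=2.0, dilution=1.0, primer="p1"):
    return QpcrMeasurement(
        sample="s", primer=primer, role=role, ct_values=np.atleast_1d(ct),
        efficiency=e, dilution=dilution,
    )


class TestQpcrEnrichment:
    def test_equal_cts_give_unity(self):
        assert qpcr_enrichment(meas("ChIP", 20.0), meas("Input", 20.0)) == pytest.approx(1.0)

    def test_closed_form_power_of_two(self):
        e = qpcr_enrichment(meas("ChIP", 25.0), meas("Input", 20.0))
        assert e == pytest.approx(2.0**-5, abs=1e-15)

    def test_dilution_corrected_arithmetic_oracle(self):
        # E=1.9, dilution=5, CT_ChIP=25, CT_Input=20
        got = qpcr_enrichment(
            meas("ChIP", 25.0, e=1.9, dilution=5.0),
            meas("Input", 20.0, e=1.9, dilution=5.0),
        )
        dct = 25.0 - (20.0 - math.log(5.0, 1.9))
        assert got == pytest.approx(1.9**-dct, rel=1e-12)

    def test_geometric_mean_of_technical_replicates(self):
        chip = meas("ChIP", [24.0, 25.0, 26.0])
        gm = (24.0 * 25.0 * 26.0) ** (1.0 / 3.0)
        assert qpcr_enrichment(chip, meas("Input", 20.0)) == pytest.approx(
            2.0 ** -(gm - 20.0), rel=1e-12
        )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            meas("ChIP", 20.0, e=1.0)  # efficiency must exceed 1
        with pytest.raises(ValueError):
            qpcr_enrichment(meas("ChIP", 20.0, primer="a"), meas("Input", 20.0, primer="b"))

    @given(st.floats(min_value=15.0, max_value=30.0),
           st.floats(min_value=0.1, max_value=5.0))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_ct_values(self, ct_chip, delta):
        base = qpcr_enrichment(meas("ChIP", ct_chip), meas("Input", 20.0))
        higher_chip = qpcr_enrichment(meas("ChIP", ct_chip + delta), meas("Input", 20.0))
        higher_input = qpcr_enrichment(meas("ChIP", ct_chip), meas("Input", 20.0 + delta))
        assert higher_chip < base < higher_input


class TestAggregateReplicates:
    def test_identical_pairs_degenerate(self):
        res = aggregate_replicates([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])
        assert res.degenerate and res.p is None
        assert res.mean_a == 1.0 and res.mean_b == 2.0

    def test_paired_t_matches_formula_oracle(self):
        a = [1.0, 1.5, 0.9]
        b = [2.0, 2.4, 2.1]
        res = aggregate_replicates(a, b)
        t_exp, p_exp = paired_t(a, b)
        assert res.t == pytest.approx(t_exp, rel=1e-12)
        assert res.p == pytest.approx(p_exp, rel=1e-12)
        assert res.sem_a == pytest.approx(np.std(a, ddof=1) / np.sqrt(3), rel=1e-12)

    def test_unpaired_data_rejected(self):
        with pytest.raises(ValueError):
            aggregate_replicates([1.0, 2.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            aggregate_replicates([1.0, np.nan, 2.0], [1.0, 2.0, 3.0])


class TestOccupancyRatio:
    def test_equal_counts_unity(self):
        assert occupancy_ratio(ChipSeqCounts(10, 10, 10, 10)) == 1.0

    def test_arithmetic_oracle(self):
        assert occupancy_ratio(
            ChipSeqCounts(wx=100, ipx=150, wc=200, ipc=300)
        ) == pytest.approx((200 * 150) / (100 * 300))

    def test_scaling_identities(self):
        base = ChipSeqCounts(wx=100, ipx=150, wc=200, ipc=300)
        assert occupancy_ratio(
            ChipSeqCounts(wx=100, ipx=300, wc=200, ipc=300)
        ) == pytest.approx(2 * occupancy_ratio(base))
        assert occupancy_ratio(
            ChipSeqCounts(wx=200, ipx=150, wc=200, ipc=300)
        ) == pytest.approx(occupancy_ratio(base) / 2)

    @given(st.floats(min_value=0.1, max_value=100.0))
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_uniform_scaling(self, k):
        a = ChipSeqCounts(wx=120, ipx=80, wc=33, ipc=47)
        b = ChipSeqCounts(wx=120 * k, ipx=80 * k, wc=33 * k, ipc=47 * k)
        assert occupancy_ratio(a) == pytest.approx(occupancy_ratio(b), rel=1e-9)

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError):
            ChipSeqCounts(wx=0, ipx=1, wc=1, ipc=1)


class TestCalibrateTrack:
    def test_unit_ratio_identity(self, rng):
        t = CoverageTrack("chrI", rng.uniform(0, 5, 100))
        np.testing.assert_array_equal(calibrate_track(t, 1.0).values, t.values)

    def test_constant_track_scaled(self):
        t = CoverageTrack("chrI", np.full(10, 3.0))
        np.testing.assert_allclose(calibrate_track(t, 2.0).values, 6.0)

    def test_elementwise_oracle(self, rng):
        values = rng.uniform(0, 5, 200)
        out = calibrate_track(CoverageTrack("chrI", values), 0.37).values
        for i in range(len(values)):
            assert out[i] == values[i] * 0.37

    def test_preserves_position_ratios(self, rng):
        values = rng.uniform(0.1, 5, 50)
        out = calibrate_track(CoverageTrack("chrI", values), 0.73).values
        np.testing.assert_allclose(out[1:] / out[:-1], values[1:] / values[:-1])


class TestCompositeProfile:
    def _tracks(self, n_chrom, length, rng=None, peak=None):
        tracks, mids = {}, {}
        for i in range(n_chrom):
            chrom = f"chr{i}"
            v = np.zeros(length) if rng is None else rng.uniform(0, 1, length)
            if peak is not None:
                mid = length // 2
                half = (len(peak) - 1) // 2
                v[mid - half : mid + half + 1] += peak
            tracks[chrom] = CoverageTrack(chrom, v)
            mids[chrom] = length // 2
        return tracks, mids

    def test_identical_tracks_reproduce_single_window(self, rng):
        peak = np.bartlett(201) * 7.0
        tracks, mids = self._tracks(5, 2000, peak=peak)
        prof = composite_median_profile(tracks, mids, half_window=300)
        single = composite_median_profile(
            {"chr0": tracks["chr0"]}, {"chr0": mids["chr0"]}, half_window=300
        )
        np.testing.assert_array_equal(prof.median, single.median)

    def test_odd_count_median(self):
        tracks = {
            f"chr{i}": CoverageTrack(f"chr{i}", np.full(100, v))
            for i, v in enumerate([1.0, 2.0, 9.0])
        }
        mids = {c: 50 for c in tracks}
        prof = composite_median_profile(tracks, mids, half_window=10)
        np.testing.assert_array_equal(prof.median, 2.0)

    def test_matches_sort_based_median_oracle(self, rng):
        tracks, mids = self._tracks(7, 500, rng=rng)
        prof = composite_median_profile(tracks, mids, half_window=100)
        for j, off in enumerate([-100, -37, 0, 12, 100]):
            vals = [t.values[250 + off] for t in tracks.values()]
            idx = off + 100
            assert prof.median[idx] == pytest.approx(median_sort(vals))

    def test_chromosome_end_exclusion_counts(self):
        tracks = {"chrA": CoverageTrack("chrA", np.ones(10000)),
                  "chrB": CoverageTrack("chrB", np.ones(10000))}
        mids = {"chrA": 5000, "chrB": 100}  # chrB window truncated on the left
        prof = composite_median_profile(tracks, mids, half_window=3000)
        assert prof.n_contributing[0] == 1  # offset -3000 only chrA
        assert prof.n_contributing[3000] == 2  # offset 0
        assert np.isnan(prof.median).sum() == 0

    def test_commutes_with_calibration(self, rng):
        tracks, mids = self._tracks(4, 400, rng=rng)
        ratio = 0.42
        prof_then_scale = composite_median_profile(tracks, mids, half_window=50)
        scaled = {c: calibrate_track(t, ratio) for c, t in tracks.items()}
        scale_then_prof = composite_median_profile(scaled, mids, half_window=50)
        np.testing.assert_allclose(
            scale_then_prof.median, prof_then_scale.median * ratio, rtol=1e-12
        )

    def test_no_centromeres_rejected(self):
        with pytest.raises(ValueError):
            composite_median_profile({}, {})


class TestProfileDifference:
    def _profile(self, values, rng=None):
        tracks = {"c": CoverageTrack("c", np.asarray(values, dtype=float))}
        return composite_median_profile(tracks, {"c": len(values) // 2},
                                        half_window=min(50, len(values) // 4))

    def test_self_difference_is_zero(self, rng):
        p = self._profile(rng.uniform(0, 5, 400))
        diff = profile_difference(p, p)
        np.testing.assert_allclose(diff.median, 0.0)

    def test_elementwise_oracle(self, rng):
        a = self._profile(rng.uniform(0, 5, 400))
        b = self._profile(rng.uniform(0, 5, 400))
        diff = profile_difference(a, b)
        np.testing.assert_allclose(diff.median, a.median - b.median)

    def test_offset_mismatch_rejected(self, rng):
        from meioquant.chip import CompositeProfile

        a = CompositeProfile(np.arange(-5, 6), np.zeros(11), np.ones(11, dtype=int))
        b = CompositeProfile(np.arange(-4, 7), np.zeros(11), np.ones(11, dtype=int))
        with pytest.raises(ValueError):
            profile_difference(a, b)


class TestGenomeTrackIO:
    def test_bedgraph_round_trip(self, tmp_path, rng):
        values = np.round(rng.uniform(0, 5, 300), 3)
        tracks = {"chrI": CoverageTrack("chrI", values)}
        path = tmp_path / "t.bedgraph"
        write_bedgraph(tracks, path)
        back = read_bedgraph(path)
        np.testing.assert_allclose(back["chrI"].values, values)

    def test_bed_midpoints(self, tmp_path):
        path = tmp_path / "cen.bed"
        write_bed([("chrI", 100, 220, "CEN_chrI")], path)
        assert read_bed_midpoints(path) == {"chrI": 160}
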