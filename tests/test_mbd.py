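"""Binned coverage, RPKM, internal re-calibration, CGI analysis, peaks."""

import numpy as np
import pandas as pd
import pytest

from methyledit import mbd
from methyledit.errors import (
    CoordinateError,
    DegenerateInputError,
    NormalizationError,
    ParameterError,
)
from methyledit.intervals import IntervalSet


def _track(values, bin_size=10, state=mbd.RPKM, total=1000, chrom="chr1"):
    return mbd.CoverageTrack(
        bin_size, {chrom: np.asarray(values, dtype=float)}, state=state, total_fragments=total
    )


# ---------------------------------------------------------------------------
# bin_coverage / rpkm / quantify
# ---------------------------------------------------------------------------

class TestBinCoverage:
    def test_aligned_150bp_fragment_hits_15_bins(self):
        frags = IntervalSet.from_records([("chr1", 100, 250)])
        track = mbd.bin_coverage(frags, {"chr1": 1000}, bin_size=10)
        assert track.data["chr1"].sum() == 15
        assert (track.data["chr1"][10:25] == 1).all()

    def test_empty_fragments_give_zero_track(self):
        track = mbd.bin_coverage(IntervalSet(), {"chr1": 500}, bin_size=10)
        assert (track.data["chr1"] == 0).all()
        assert track.data["chr1"].size == 50

    def test_fragment_outside_genome_rejected(self):
        frags = IntervalSet.from_records([("chr1", 400, 600)])
        with pytest.raises(CoordinateError):
            mbd.bin_coverage(frags, {"chr1": 500})

    def test_matches_per_base_pileup_oracle(self, rng):
        n, L, bs = 1000, 2000, 10
        starts = rng.integers(0, L - 200, size=n)
        lengths = rng.integers(1, 200, size=n)
        frags = IntervalSet.from_arrays("chr1", starts, starts + lengths)
        track = mbd.bin_coverage(frags, {"chr1": L}, bin_size=bs)
        # oracle: per (bin, fragment) overlap test
        nb = L // bs
        oracle = np.zeros(nb)
        for b in range(nb):
            b0, b1 = b * bs, (b + 1) * bs
            oracle[b] = np.sum((starts < b1) & (starts + lengths > b0))
        assert np.array_equal(track.data["chr1"], oracle)


class TestRpkm:
    def test_known_value(self):
        raw = _track([1.0], state=mbd.RAW, total=10**6)
        assert mbd.rpkm_normalize(raw).data["chr1"][0] == pytest.approx(100.0)

    def test_scale_invariance(self, rng):
        vals = rng.integers(0, 50, size=100).astype(float)
        a = mbd.rpkm_normalize(_track(vals, state=mbd.RAW, total=5000))
        b = mbd.rpkm_normalize(_track(2 * vals, state=mbd.RAW, total=10000))
        assert np.allclose(a.data["chr1"], b.data["chr1"])

    def test_matches_formula_bin_by_bin(self, rng):
        vals = rng.integers(0, 50, size=64).astype(float)
        total, bs = 7777, 25
        out = mbd.rpkm_normalize(
            mbd.CoverageTrack(bs, {"chr1": vals.copy()}, state=mbd.RAW, total_fragments=total)
        )
        assert np.allclose(out.data["chr1"], vals * 1e9 / (total * bs))

    def test_zero_fragments_error(self):
        with pytest.raises(NormalizationError):
            mbd.rpkm_normalize(_track([1.0], state=mbd.RAW, total=0))

    def test_state_transition_enforced(self):
        with pytest.raises(NormalizationError):
            mbd.rpkm_normalize(_track([1.0], state=mbd.RPKM))


class TestQuantify:
    def test_constant_track(self):
        track = _track(np.full(100, 3.5))
        ivs = IntervalSet.from_records([("chr1", 5, 105), ("chr1", 200, 333)])
        assert np.allclose(mbd.quantify_intervals(track, ivs), 3.5)

    def test_mean_over_covered_bins(self):
        track = _track([0, 0, 2, 4, 6, 0])
        ivs = IntervalSet.from_records([("chr1", 20, 50)])  # bins 2,3,4
        assert mbd.quantify_intervals(track, ivs)[0] == pytest.approx(4.0)

    def test_zero_length_interval_rejected(self):
        with pytest.raises(CoordinateError):
            mbd.quantify_intervals(_track([1.0] * 10), IntervalSet.from_records([("chr1", 5, 5)]))

    def test_matches_brute_force_bin_average(self, rng):
        vals = rng.random(500)
        track = _track(vals)
        starts = rng.integers(0, 4000, size=50)
        ivs = IntervalSet.from_arrays("chr1", starts, starts + rng.integers(10, 900, size=50))
        means = mbd.quantify_intervals(track, ivs)
        for i, iv in enumerate(ivs):
            bins = [b for b in range(500) if b * 10 < iv.end and (b + 1) * 10 > iv.start]
            assert means[i] == pytest.approx(np.mean(vals[bins]))


# ---------------------------------------------------------------------------
# re-calibration
# ---------------------------------------------------------------------------

def _cgi_set(n, width=100, gap=100):
    starts = np.arange(n) * (width + gap) + gap
    return IntervalSet.from_arrays("chr1", starts, starts + width)


class TestRecalibrate:
    def _tracks(self, rng, n_bins=2000):
        vals = rng.random(n_bins) * 10
        unt = _track(vals)
        return unt, vals

    def test_identical_sample_gets_unit_factor(self, rng):
        unt, vals = self._tracks(rng)
        same = _track(vals.copy())
        cgis = _cgi_set(20)
        out, factors = mbd.recalibrate({"untreated": unt, "s": same}, cgis, mbd.RecalibrationConfig(k=10))
        assert factors == {"untreated": 1.0, "s": 1.0}
        assert np.allclose(out["s"].data["chr1"], vals)

    def test_doubled_sample_halved_back(self, rng):
        unt, vals = self._tracks(rng)
        doubled = _track(2 * vals)
        cgis = _cgi_set(20)
        out, factors = mbd.recalibrate(
            {"untreated": unt, "d": doubled}, cgis, mbd.RecalibrationConfig(k=10)
        )
        assert factors["d"] == pytest.approx(0.5)
        assert np.allclose(out["d"].data["chr1"], vals)

    def test_reference_mean_equal_across_samples_after_recal(self, rng):
        unt, vals = self._tracks(rng)
        other = _track(vals * rng.uniform(0.2, 5.0))
        cgis = _cgi_set(20)
        cfg = mbd.RecalibrationConfig(k=10)
        out, _ = mbd.recalibrate({"untreated": unt, "o": other}, cgis, cfg)
        ref_idx = mbd.select_reference_cgis(mbd.quantify_intervals(unt, cgis), 10)
        m_u = mbd.quantify_intervals(out["untreated"], cgis)[ref_idx].mean()
        m_o = mbd.quantify_intervals(out["o"], cgis)[ref_idx].mean()
        assert m_o == pytest.approx(m_u, rel=1e-12)

    def test_idempotent_on_recalibrated_tracks(self, rng):
        unt, vals = self._tracks(rng)
        other = _track(vals * 3.0)
        cgis = _cgi_set(20)
        cfg = mbd.RecalibrationConfig(k=10)
        once, _ = mbd.recalibrate({"untreated": unt, "o": other}, cgis, cfg)
        twice, factors = mbd.recalibrate(once, cgis, cfg)
        assert all(f == pytest.approx(1.0) for f in factors.values())
        assert np.allclose(twice["o"].data["chr1"], once["o"].data["chr1"])

    def test_zero_reference_signal_is_error(self, rng):
        unt, _ = self._tracks(rng)
        zero = _track(np.zeros(2000))
        with pytest.raises(NormalizationError):
            mbd.recalibrate({"untreated": unt, "z": zero}, _cgi_set(20), mbd.RecalibrationConfig(k=10))

    def test_k_larger_than_cgi_count_rejected(self, rng):
        unt, vals = self._tracks(rng)
        with pytest.raises(ParameterError):
            mbd.recalibrate({"untreated": unt}, _cgi_set(5), mbd.RecalibrationConfig(k=10))

    def test_removes_spurious_depletion_from_new_peaks(self, rng):
        """The motivating scenario: treatment creates many new high-signal
        regions; RPKM alone then depresses unchanged regions, re-calibration
        restores them."""
        n_bins = 4000
        cgis = _cgi_set(40)  # CGIs at bins [10k..] -> use bin coords below
        stable_bins = np.zeros(n_bins, dtype=bool)
        new_bins = np.zeros(n_bins, dtype=bool)
        for i, iv in enumerate(cgis):
            sl = slice(iv.start // 10, iv.end // 10)
            (stable_bins if i < 20 else new_bins)[sl] = True
        raw_unt = np.where(stable_bins, 100.0, 0.0) + 1.0
        raw_trt = np.where(stable_bins | new_bins, 100.0, 0.0) + 1.0
        unt = mbd.rpkm_normalize(
            mbd.CoverageTrack(10, {"chr1": raw_unt}, state=mbd.RAW, total_fragments=int(raw_unt.sum()))
        )
        trt = mbd.rpkm_normalize(
            mbd.CoverageTrack(10, {"chr1": raw_trt}, state=mbd.RAW, total_fragments=int(raw_trt.sum()))
        )
        stable_cgis = cgis.subset(np.arange(40) < 20)
        rpkm_ratio = (
            mbd.quantify_intervals(trt, stable_cgis).mean()
            / mbd.quantify_intervals(unt, stable_cgis).mean()
        )
        assert abs(rpkm_ratio - 1) > 0.3  # spurious depletion under RPKM alone
        out, _ = mbd.recalibrate(
            {"untreated": unt, "treated": trt}, cgis, mbd.RecalibrationConfig(k=20)
        )
        recal_ratio = (
            mbd.quantify_intervals(out["treated"], stable_cgis).mean()
            / mbd.quantify_intervals(out["untreated"], stable_cgis).mean()
        )
        assert abs(recal_ratio - 1) <= 0.05


# ---------------------------------------------------------------------------
# CGI classification
# ---------------------------------------------------------------------------

class TestClassifyCgis:
    def test_two_obvious_groups(self):
        track = _track([0, 0, 0, 0, 10, 10, 10, 10], bin_size=10)
        cgis = IntervalSet.from_arrays("chr1", np.arange(8) * 10, np.arange(8) * 10 + 10)
        labels = mbd.classify_cgis(track, cgis)
        assert list(labels) == ["unmethylated"] * 4 + ["methylated"] * 4

    def test_recovers_planted_split(self, rng):
        n = 200
        planted = rng.random(n) < 0.4
        signal = np.where(planted, rng.normal(50, 5, n), rng.normal(1, 0.3, n)).clip(0)
        track = _track(signal, bin_size=10)
        cgis = IntervalSet.from_arrays("chr1", np.arange(n) * 10, np.arange(n) * 10 + 10)
        labels = mbd.classify_cgis(track, cgis)
        assert ((labels == "methylated") == planted).all()

    def test_single_outlier_isolated(self):
        track = _track([2, 2, 2, 2, 40], bin_size=10)
        cgis = IntervalSet.from_arrays("chr1", np.arange(5) * 10, np.arange(5) * 10 + 10)
        labels = mbd.classify_cgis(track, cgis)
        assert list(labels) == ["unmethylated"] * 4 + ["methylated"]

    def test_identical_signals_degenerate(self):
        track = _track([5, 5, 5, 5], bin_size=10)
        cgis = IntervalSet.from_arrays("chr1", np.arange(4) * 10, np.arange(4) * 10 + 10)
        with pytest.raises(DegenerateInputError):
            mbd.classify_cgis(track, cgis)


# ---------------------------------------------------------------------------
# peak calling
# ---------------------------------------------------------------------------

def _recal(values, bin_size=10):
    return _track(values, bin_size=bin_size, state=mbd.RECALIBRATED)


class TestCallNewPeaks:
    def test_no_difference_no_peaks(self, rng):
        vals = rng.random(5000)
        peaks = mbd.call_new_peaks(_recal(vals), _recal(vals.copy()))
        assert len(peaks) == 0

    def test_flat_background_no_false_peaks(self):
        vals = np.ones(5000)
        assert len(mbd.call_new_peaks(_recal(vals), _recal(vals.copy()))) == 0

    def test_single_planted_gain_recovered(self):
        unt = np.ones(5000)
        trt = unt.copy()
        trt[1000:1050] += 10.0  # 500 bp gain
        peaks = mbd.call_new_peaks(_recal(trt), _recal(unt))
        assert len(peaks) == 1
        iv = next(iter(peaks))
        assert iv.start < 10500 and iv.end > 10000  # overlaps the planted interval

    def test_nearby_gains_fused_across_small_gap(self):
        unt = np.ones(3000)
        trt = unt.copy()
        trt[100:120] += 10.0
        trt[123:143] += 10.0  # 30 bp gap < merge_gap 50
        peaks = mbd.call_new_peaks(_recal(trt), _recal(unt))
        assert len(peaks) == 1
        iv = next(iter(peaks))
        assert iv.start == 1000 and iv.end == 1430

    def test_output_sorted_disjoint_min_width(self, rng):
        unt = rng.random(10000)
        trt = unt + (rng.random(10000) < 0.02) * 20.0
        peaks = mbd.call_new_peaks(_recal(trt), _recal(unt), cfg=mbd.PeakCallConfig(min_width=20))
        assert peaks.is_sorted() and peaks.is_disjoint()
        assert (peaks.widths() >= 20).all()

    def test_requires_recalibrated_tracks(self):
        with pytest.raises(NormalizationError):
            mbd.call_new_peaks(_track([1.0]), _track([1.0]))


# ---------------------------------------------------------------------------
# intersections / fold / matrix
# ---------------------------------------------------------------------------

class TestIntersectCounts:
    def test_disjoint_sets(self):
        peaks = IntervalSet.from_records([("chr1", 0, 10)])
        cgis = IntervalSet.from_records([("chr1", 50, 60)])
        counts = mbd.intersect_counts(peaks, cgis, cgis)
        assert counts["n_in_cgis"] == 0

    def test_exactly_coincident_counted_once(self):
        peaks = IntervalSet.from_records([("chr1", 50, 60)])
        cgis = IntervalSet.from_records([("chr1", 50, 60)])
        assert mbd.intersect_counts(peaks, cgis, cgis)["n_in_cgis"] == 1

    def test_matches_quadratic_oracle(self, rng):
        def random_disjoint(n):
            starts = np.sort(rng.choice(np.arange(0, 10000, 20), size=n, replace=False))
            return IntervalSet.from_arrays("chr1", starts, starts + rng.integers(5, 19, size=n))

        peaks = random_disjoint(80)
        cgis = random_disjoint(60)
        got = mbd.intersect_counts(peaks, cgis, cgis)
        oracle_pairs = set()
        for i, p in enumerate(peaks):
            for j, c in enumerate(cgis):
                if p.start < c.end and c.start < p.end:
                    oracle_pairs.add((i, j))
        assert set(got["pairs_cgis"]) == oracle_pairs
        assert got["n_in_cgis"] == len({i for i, _ in oracle_pairs})


class TestFoldReduction:
    def test_equal_gains_give_unity(self):
        r = mbd.fold_reduction(np.array([5.0]), np.array([5.0]), np.array([1.0]))
        assert r.fold == pytest.approx(1.0) and not r.censored

    def test_known_arithmetic(self):
        r = mbd.fold_reduction(np.array([8.8]), np.array([2.0]), np.array([1.0]))
        assert r.fold == pytest.approx(7.8)

    def test_non_positive_mutant_gain_censored(self):
        r = mbd.fold_reduction(np.array([5.0]), np.array([0.5]), np.array([1.0]))
        assert r.censored and r.fold >= 1000

    def test_non_positive_wt_gain_rejected(self):
        with pytest.raises(ParameterError):
            mbd.fold_reduction(np.array([1.0]), np.array([2.0]), np.array([1.0]))


class TestCgiMatrix:
    def test_constant_track_constant_matrix(self):
        track = _track(np.full(400, 2.0))
        cgis = IntervalSet.from_records([("chr1", 1200, 1500), ("chr1", 2000, 2600)])
        mat = mbd.cgi_matrix(track, cgis, flank=100, body_columns=20)
        assert np.allclose(mat, 2.0)

    def test_single_bin_body_repeats(self):
        vals = np.zeros(100)
        vals[50] = 7.0
        track = _track(vals)
        cgis = IntervalSet.from_records([("chr1", 500, 510)])
        mat = mbd.cgi_matrix(track, cgis, flank=0, body_columns=8)
        assert mat.shape == (1, 8) and np.allclose(mat, 7.0)

    def test_out_of_chromosome_flank_is_nan(self):
        track = _track(np.ones(100))
        cgis = IntervalSet.from_records([("chr1", 0, 50)])
        mat = mbd.cgi_matrix(track, cgis, flank=100, body_columns=5)
        assert np.isnan(mat[0, :10]).all()
        assert np.allclose(mat[0, 10:], 1.0)

    def test_matches_naive_row_extraction(self, rng):
        vals = rng.random(1000)
        track = _track(vals)
        cgis = IntervalSet.from_records([("chr1", 3000, 3500), ("chr1", 7000, 7100)])
        mat = mbd.cgi_matrix(track, cgis, flank=200, body_columns=10)
        for i, iv in enumerate(cgis):
            left = vals[iv.start // 10 - 20 : iv.start // 10]
            body = vals[iv.start // 10 : (iv.end - 1) // 10 + 1]
            right = vals[(iv.end - 1) // 10 + 1 : (iv.end - 1) // 10 + 21]
            assert np.allclose(mat[i, :20], left)
            assert np.allclose(
                mat[i, 20:30],
                np.interp(np.linspace(0, 1, 10), np.linspace(0, 1, body.size), body),
            )
            assert np.allclose(mat[i, 30:], right)

    def test_flank_must_align_to_bins(self):
        with pytest.raises(ParameterError):
            mbd.cgi_matrix(_track(np.ones(10)), IntervalSet.from_records([("chr1", 10, 20)]), flank=15)
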