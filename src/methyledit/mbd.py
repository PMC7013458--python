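"""Genome-wide MBD-seq style methylation signal analysis.

Coverage is binned at 10 bp, normalized to RPKM, and then re-calibrated
against an internal reference: the K CGIs with the highest signal in the
untreated sample.  Those regions are already fully methylated before any
treatment, so their pulldown signal cannot legitimately increase — any
apparent change there is a library-size artifact.  RPKM alone mis-scales
samples in which treatment creates many new methylated regions (the total
captured mass grows, so unchanged regions appear depleted); dividing each
sample by its mean over the reference set removes exactly that distortion.

Downstream operations: CGI quantification and two-class methylated /
unmethylated splitting, differential peak calling against the untreated
track, peak-CGI intersections, fold-reduction of off-target gain between
effector variants, and CGI-centered signal matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import (
    CoordinateError,
    DegenerateInputError,
    NormalizationError,
    ParameterError,
)
from .intervals import IntervalSet

RAW, RPKM, RECALIBRATED = "raw", "rpkm", "recalibrated"


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class CoverageTrack:
    """Binned per-chromosome signal with explicit normalization state."""

    bin_size: int
    data: dict[str, np.ndarray]
    state: str = RAW
    scale_factor: float = 1.0
    total_fragments: int = 0

    def copy(self) -> "CoverageTrack":
        return CoverageTrack(
            self.bin_size,
            {c: v.copy() for c, v in self.data.items()},
            self.state,
            self.scale_factor,
            self.total_fragments,
        )

    def to_bedgraph(self) -> pd.DataFrame:
        rows = []
        for chrom, vals in self.data.items():
            edges = np.arange(vals.size + 1) * self.bin_size
            rows.append(
                pd.DataFrame(
                    {"chrom": chrom, "start": edges[:-1], "end": edges[1:], "value": vals}
                )
            )
        return pd.concat(rows, ignore_index=True)


@dataclass(frozen=True)
class RecalibrationConfig:
    """Internal re-calibration settings: top-``k`` untreated CGIs as reference."""

    k: int = 1000
    reference_sample: str = "untreated"

    def __post_init__(self):
        if self.k < 1:
            raise ParameterError("k must be >= 1")


@dataclass(frozen=True)
class PeakCallConfig:
    """Differential peak-calling knobs (threshold, differential, width, gap)."""

    background_quantile: float = 0.99
    min_differential: float = 0.0
    min_width: int = 100
    merge_gap: int = 50

    def __post_init__(self):
        if not (0.0 < self.background_quantile < 1.0):
            raise ParameterError("background_quantile must be in (0, 1)")
        if self.min_width <= 0 or self.merge_gap < 0:
            raise ParameterError("min_width must be positive and merge_gap non-negative")


@dataclass
class FoldReductionResult:
    fold: float
    censored: bool = False          # True when the mutant gain was non-positive
    note: str = ""


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------

def bin_coverage(
    fragments: IntervalSet, chrom_sizes: Mapping[str, int], bin_size: int = 10
) -> CoverageTrack:
    """Raw binned coverage: each bin counts the fragments overlapping it."""
    if bin_size < 1:
        raise ParameterError("bin_size must be >= 1")
    fragments.validate_within(chrom_sizes)
    data = {
        chrom: np.zeros(-(-size // bin_size), dtype=np.float64)
        for chrom, size in chrom_sizes.items()
    }
    for chrom, grp in fragments.df.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        if (ends <= starts).any():
            raise CoordinateError("zero-length fragment")
        nb = data[chrom].size
        first = starts // bin_size
        last = (ends - 1) // bin_size
        diff = np.zeros(nb + 1, dtype=np.float64)
        np.add.at(diff, first, 1.0)
        np.add.at(diff, last + 1, -1.0)
        data[chrom] = np.cumsum(diff)[:-1]
    return CoverageTrack(bin_size, data, state=RAW, total_fragments=len(fragments))


def rpkm_normalize(track: CoverageTrack) -> CoverageTrack:
    """RPKM scaling: signal * 1e9 / (total_fragments * bin_size)."""
    if track.state != RAW:
        raise NormalizationError(f"expected a raw track, got state {track.state!r}")
    if track.total_fragments <= 0:
        raise NormalizationError("cannot RPKM-normalize a track with zero fragments")
    factor = 1e9 / (track.total_fragments * track.bin_size)
    out = track.copy()
    out.data = {c: v * factor for c, v in out.data.items()}
    out.state = RPKM
    return out


def quantify_intervals(track: CoverageTrack, intervals: IntervalSet) -> np.ndarray:
    """Mean bin signal per interval (bins overlapping the interval, equal weight)."""
    bs = track.bin_size
    out = np.empty(len(intervals), dtype=np.float64)
    for i, iv in enumerate(intervals):
        if iv.end <= iv.start:
            raise CoordinateError(f"zero-length interval {iv.chrom}:{iv.start}-{iv.end}")
        if iv.chrom not in track.data:
            raise CoordinateError(f"unknown chromosome {iv.chrom!r}")
        vals = track.data[iv.chrom]
        first = iv.start // bs
        last = (iv.end - 1) // bs
        if last >= vals.size:
            raise CoordinateError(f"interval beyond track end on {iv.chrom}")
        out[i] = vals[first : last + 1].mean()
    return out


# ---------------------------------------------------------------------------
# Internal re-calibration
# ---------------------------------------------------------------------------

def select_reference_cgis(
    untreated_means: np.ndarray, k: int
) -> np.ndarray:
    """Indices of the top-k CGIs by untreated mean signal.

    Ties are broken by genomic (input) order — stable and reproducible, and
    logged by callers when they occur.
    """
    n = untreated_means.size
    if k > n:
        raise ParameterError(f"k = {k} exceeds number of CGIs ({n})")
    order = np.lexsort((np.arange(n), -np.asarray(untreated_means, dtype=float)))
    return np.sort(order[:k])


def recalibrate(
    tracks: Mapping[str, CoverageTrack],
    cgis: IntervalSet,
    cfg: RecalibrationConfig = RecalibrationConfig(),
) -> tuple[dict[str, CoverageTrack], dict[str, float]]:
    """Anchor all samples to the untreated scale via top-K reference CGIs.

    For each sample i, ``f_i = mean_R(reference) / mean_R(sample_i)`` where R
    is the reference CGI set and mean_R averages the per-CGI mean signals;
    the whole track is multiplied by ``f_i``.  The reference sample keeps
    factor 1 exactly.  Requires all tracks in RPKM state on a shared binning.
    """
    if cfg.reference_sample not in tracks:
        raise NormalizationError(f"reference sample {cfg.reference_sample!r} missing")
    bin_sizes = {t.bin_size for t in tracks.values()}
    if len(bin_sizes) != 1:
        raise NormalizationError("tracks differ in bin size")
    for name, t in tracks.items():
        # re-running on already-recalibrated tracks is a no-op (factors 1)
        if t.state not in (RPKM, RECALIBRATED):
            raise NormalizationError(f"track {name!r} must be RPKM-normalized first")

    ref_track = tracks[cfg.reference_sample]
    ref_means = quantify_intervals(ref_track, cgis)
    ref_idx = select_reference_cgis(ref_means, cfg.k)
    ref_level = float(ref_means[ref_idx].mean())

    out_tracks: dict[str, CoverageTrack] = {}
    factors: dict[str, float] = {}
    for name, t in tracks.items():
        if name == cfg.reference_sample:
            f = 1.0
        else:
            level = float(quantify_intervals(t, cgis)[ref_idx].mean())
            if level <= 0:
                raise NormalizationError(f"sample {name!r} has zero signal over reference CGIs")
            f = ref_level / level
        new = t.copy()
        new.data = {c: v * f for c, v in new.data.items()}
        new.state = RECALIBRATED
        new.scale_factor = f
        out_tracks[name] = new
        factors[name] = f
    return out_tracks, factors


# ---------------------------------------------------------------------------
# CGI classification
# ---------------------------------------------------------------------------

def classify_cgis(track: CoverageTrack, cgis: IntervalSet) -> np.ndarray:
    """Two-class split of CGIs into 'methylated' / 'unmethylated'.

    One-dimensional two-means on log1p per-CGI mean signal, deterministically
    initialized at the 25th/75th percentiles; the class boundary is the
    midpoint of the final cluster centers.
    """
    if len(cgis) < 2:
        raise DegenerateInputError("need at least two CGIs to classify")
    x = np.log1p(quantify_intervals(track, cgis))
    if np.ptp(x) == 0:
        raise DegenerateInputError("all CGI signals identical: two-class split undefined")
    lo, hi = np.percentile(x, [25.0, 75.0])
    if lo == hi:
        lo, hi = float(x.min()), float(x.max())
    for _ in range(200):
        assign_hi = np.abs(x - hi) < np.abs(x - lo)
        new_lo = x[~assign_hi].mean() if (~assign_hi).any() else lo
        new_hi = x[assign_hi].mean() if assign_hi.any() else hi
        if new_lo == lo and new_hi == hi:
            break
        lo, hi = float(new_lo), float(new_hi)
    labels = np.where(assign_hi, "methylated", "unmethylated")
    return labels


# ---------------------------------------------------------------------------
# Peak calling and intersections
# ---------------------------------------------------------------------------

def call_new_peaks(
    treated: CoverageTrack,
    untreated: CoverageTrack,
    cgis: IntervalSet | None = None,
    cfg: PeakCallConfig = PeakCallConfig(),
) -> IntervalSet:
    """Peaks of newly gained signal in the treated sample.

    A bin belongs to a peak when treated signal strictly exceeds the
    background threshold (the configured quantile of untreated non-CGI bins)
    and the differential treated - untreated strictly exceeds
    ``min_differential``.  Runs are fused across gaps <= ``merge_gap`` and
    runs narrower than ``min_width`` are dropped.  Peak score = mean
    differential over the peak's bins.
    """
    for t in (treated, untreated):
        if t.state != RECALIBRATED:
            raise NormalizationError("peak calling expects re-calibrated tracks")
    if treated.bin_size != untreated.bin_size:
        raise NormalizationError("tracks differ in bin size")
    bs = treated.bin_size

    bg_values = []
    for chrom, vals in untreated.data.items():
        mask = np.ones(vals.size, dtype=bool)
        if cgis is not None:
            for iv in cgis:
                if iv.chrom == chrom:
                    mask[iv.start // bs : (iv.end - 1) // bs + 1] = False
        bg_values.append(vals[mask])
    bg = np.concatenate(bg_values) if bg_values else np.empty(0)
    threshold = float(np.quantile(bg, cfg.background_quantile)) if bg.size else 0.0

    min_bins = -(-cfg.min_width // bs)
    gap_bins = cfg.merge_gap // bs

    rows = []
    for chrom in treated.data:
        tv = treated.data[chrom]
        uv = untreated.data.get(chrom, np.zeros_like(tv))
        diff = tv - uv
        mask = (tv > threshold) & (diff > cfg.min_differential)
        runs = _mask_to_runs(mask)
        runs = _merge_runs(runs, gap_bins)
        for b0, b1 in runs:
            if b1 - b0 < min_bins:
                continue
            rows.append(
                (
                    chrom,
                    int(b0 * bs),
                    int(b1 * bs),
                    f"peak_{len(rows)}",
                    float(diff[b0:b1].mean()),
                    ".",
                )
            )
    return IntervalSet.from_records(rows).sort()


def _mask_to_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    return list(zip(edges[0::2], edges[1::2]))


def _merge_runs(runs: list[tuple[int, int]], gap_bins: int) -> list[tuple[int, int]]:
    if not runs:
        return []
    merged = [list(runs[0])]
    for s, e in runs[1:]:
        if s - merged[-1][1] <= gap_bins:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(int(s), int(e)) for s, e in merged]


def intersect_counts(
    peaks: IntervalSet, cgis: IntervalSet, subset: IntervalSet
) -> dict:
    """Counts of peaks overlapping (>= 1 bp) any CGI / any subset CGI."""
    in_cgis = peaks.overlaps_any(cgis)
    in_subset = peaks.overlaps_any(subset)
    return {
        "n_peaks": len(peaks),
        "n_in_cgis": int(in_cgis.sum()),
        "n_in_subset": int(in_subset.sum()),
        "pairs_cgis": peaks.overlap_pairs(cgis),
        "pairs_subset": peaks.overlap_pairs(subset),
    }


# ---------------------------------------------------------------------------
# Fold reduction and CGI matrices
# ---------------------------------------------------------------------------

def fold_reduction(
    wt_means: np.ndarray,
    mut_means: np.ndarray,
    untreated_means: np.ndarray,
    fold_ceiling: float = 1000.0,
) -> FoldReductionResult:
    """Fold-reduction of background-subtracted off-target gain, WT over mutant.

    All three inputs are per-CGI mean signals over the same (unmethylated)
    CGI set; the untreated mean is subtracted from both treated samples
    before taking the ratio.  A non-positive mutant gain cannot be divided
    through and is reported as censored at ``fold_ceiling``.
    """
    wt_gain = float(np.mean(wt_means) - np.mean(untreated_means))
    mut_gain = float(np.mean(mut_means) - np.mean(untreated_means))
    if wt_gain <= 0:
        raise ParameterError("non-positive wild-type gain: fold reduction undefined")
    if mut_gain <= 0:
        return FoldReductionResult(
            fold=fold_ceiling, censored=True, note=f">= {fold_ceiling} (mutant gain <= 0)"
        )
    return FoldReductionResult(fold=wt_gain / mut_gain)


def cgi_matrix(
    track: CoverageTrack,
    cgis: IntervalSet,
    flank: int = 1000,
    body_columns: int = 50,
) -> np.ndarray:
    """CGI-centered signal matrix: real-coordinate flanks, length-normalized body.

    Each row covers [start - flank, end + flank): ``flank / bin_size`` columns
    per flank in genomic bins, and the CGI body resampled to
    ``body_columns`` columns by linear interpolation.  Bins outside the
    chromosome are NaN.  Row order equals input order.
    """
    bs = track.bin_size
    if flank % bs:
        raise ParameterError("flank must be a multiple of bin_size")
    fcols = flank // bs
    ncols = 2 * fcols + body_columns
    out = np.full((len(cgis), ncols), np.nan)
    for i, iv in enumerate(cgis):
        vals = track.data[iv.chrom]
        # flanks in real coordinates
        left_bins = np.arange(iv.start // bs - fcols, iv.start // bs)
        right_first = (iv.end - 1) // bs + 1
        right_bins = np.arange(right_first, right_first + fcols)
        for dest, bins in ((0, left_bins), (fcols + body_columns, right_bins)):
            ok = (bins >= 0) & (bins < vals.size)
            out[i, dest : dest + fcols][ok] = vals[bins[ok]]
        # body resampled to fixed width
        b0 = iv.start // bs
        b1 = (iv.end - 1) // bs + 1
        body = vals[b0:b1]
        if body.size == 1:
            out[i, fcols : fcols + body_columns] = body[0]
        else:
            xp = np.linspace(0.0, 1.0, body.size)
            xq = np.linspace(0.0, 1.0, body_columns)
            out[i, fcols : fcols + body_columns] = np.interp(xq, xp, body)
    return out
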