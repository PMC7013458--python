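"""Targeted bisulfite-amplicon analysis.

The stages mirror a standard amplicon bis-seq workflow: 3' quality trimming,
overlap merging of read pairs, bisulfite-aware (reduced-alphabet) alignment
against the amplicon reference, per-CpG methylation calling, and conversion
QC from non-CpG cytosines.

Alignment is ungapped on a C->T collapsed alphabet.  Amplicon reads are
indel-free by construction (single locus, no structural variation), so a
full aligner would only add an external dependency without changing the
quantity extracted: the C/T state of each read base over a reference CpG.
This is the one intentional methodological simplification in the module and
it is exercised end-to-end by the simulator-backed recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from ._utils import revcomp_array, round_half_away, seq_to_array
from .errors import (
    DegenerateInputError,
    FormatError,
    MissingDataError,
    QCNotComputableError,
)

PHRED_OFFSET = 33
_C, _T = ord("C"), ord("T")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AmpliconSpec:
    """Amplicon reference with indexed CpG sites.

    CpG sites are numbered 1..n in reference order.  ``blocked_indices`` are
    sites under the dCas9-sgRNA footprint (sterically shielded from the
    methyltransferase, hence excluded from on-target averages);
    ``analysis_indices`` are the sites entering the region mean.
    """

    name: str
    sequence: str
    cpg_offsets: tuple[int, ...]            # 0-based offset of the C of each CG
    blocked_indices: frozenset[int] = frozenset()
    analysis_indices: tuple[int, ...] = ()

    def __post_init__(self):
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        offs = tuple(int(o) for o in self.cpg_offsets)
        object.__setattr__(self, "cpg_offsets", offs)
        if any(b >= a for a, b in zip(offs[1:], offs[:-1])):
            raise FormatError("CpG offsets must be strictly increasing")
        for o in offs:
            if seq[o : o + 2] != "CG":
                raise FormatError(f"offset {o} does not point at CG in {self.name}")
        idx = set(range(1, len(offs) + 1))
        if not set(self.blocked_indices) <= idx:
            raise FormatError("blocked index outside CpG range")
        if not set(self.analysis_indices) <= idx:
            raise FormatError("analysis index outside CpG range")
        if set(self.blocked_indices) & set(self.analysis_indices):
            raise FormatError("blocked and analysis CpG sets must be disjoint")

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_offsets)

    def non_cpg_c_offsets(self) -> np.ndarray:
        """Reference cytosines outside CpG context (conversion-QC positions)."""
        arr = seq_to_array(self.sequence)
        is_c = arr == _C
        is_c[list(self.cpg_offsets)] = False
        return np.flatnonzero(is_c)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "sequence": self.sequence,
            "cpg_offsets": list(self.cpg_offsets),
            "blocked_indices": sorted(self.blocked_indices),
            "analysis_indices": list(self.analysis_indices),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AmpliconSpec":
        return cls(
            name=d["name"],
            sequence=d["sequence"],
            cpg_offsets=tuple(d["cpg_offsets"]),
            blocked_indices=frozenset(d.get("blocked_indices", ())),
            analysis_indices=tuple(d.get("analysis_indices", ())),
        )


@dataclass
class MethylationProfile:
    """Per-CpG methylated/unmethylated call counts for one amplicon."""

    amplicon: str
    meth: np.ndarray          # int counts, one per CpG index
    unmeth: np.ndarray
    n_reads_used: int = 0
    conversion_rate_pct: float | None = None

    @property
    def coverage(self) -> np.ndarray:
        return self.meth + self.unmeth

    @property
    def levels(self) -> np.ndarray:
        """Methylation fraction per site; NaN where coverage is zero."""
        cov = self.coverage
        with np.errstate(invalid="ignore", divide="ignore"):
            lv = np.where(cov > 0, self.meth / np.maximum(cov, 1), np.nan)
        return lv


class Alignment(NamedTuple):
    offset: int       # 0-based placement of the read on the reference
    seq: str
    qual: str


# ---------------------------------------------------------------------------
# Read-level operations
# ---------------------------------------------------------------------------

def _decode_quals(qual: str) -> np.ndarray:
    q = seq_to_array(qual).astype(np.int16) - PHRED_OFFSET
    if q.size and (q < 0).any():
        raise FormatError("quality character below Phred+33 '!'")
    return q


def quality_trim(seq: str, qual: str, q_threshold: int = 20) -> tuple[str, str]:
    """Strip the 3' run of bases whose quality is below ``q_threshold``.

    Only the contiguous low-quality tail is removed; interior low-quality
    bases are left for the base-quality filter at calling time.  The result
    may be empty.
    """
    if len(seq) != len(qual):
        raise FormatError("sequence/quality length mismatch")
    q = _decode_quals(qual)
    keep = len(seq)
    while keep > 0 and q[keep - 1] < q_threshold:
        keep -= 1
    return seq[:keep], qual[:keep]


def merge_pairs(
    r1: str,
    q1: str,
    r2: str,
    q2: str,
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.1,
) -> tuple[str, str] | None:
    """Merge a read pair into a single fragment-spanning consensus.

    ``r2`` arrives in sequencer orientation and is reverse-complemented
    internally.  All overlap lengths >= ``min_overlap`` are scored; the
    accepted overlap maximizes matched bases subject to a mismatch fraction
    cap, with ties going to the longest overlap.  At a disagreeing position
    the higher-quality base wins (tie -> mate 1); the consensus quality is
    the maximum of the two.  Returns None when no overlap qualifies.
    """
    a1, a2 = seq_to_array(r1), revcomp_array(seq_to_array(r2))
    qa1, qa2 = _decode_quals(q1), _decode_quals(q2)[::-1].copy()
    l1, l2 = a1.size, a2.size
    max_l = min(l1, l2)
    if min_overlap < 1 or max_l < min_overlap:
        return None

    best: tuple[int, int] | None = None  # (matches, overlap_len)
    for ov in range(min_overlap, max_l + 1):
        matches = int(np.count_nonzero(a1[l1 - ov :] == a2[:ov]))
        if (ov - matches) / ov > max_mismatch_frac:
            continue
        if best is None or (matches, ov) > best:
            best = (matches, ov)
    if best is None:
        return None
    _, ov = best

    left = a1[: l1 - ov]
    lq = qa1[: l1 - ov]
    o1, o2 = a1[l1 - ov :], a2[:ov]
    oq1, oq2 = qa1[l1 - ov :], qa2[:ov]
    take2 = oq2 > oq1
    cons = np.where(take2, o2, o1)
    consq = np.maximum(oq1, oq2)
    right = a2[ov:]
    rq = qa2[ov:]

    seq = np.concatenate([left, cons, right])
    qual = np.concatenate([lq, consq, rq]) + PHRED_OFFSET
    return seq.tobytes().decode(), qual.astype(np.uint8).tobytes().decode()


def merge_pairs_batch(
    r1s: Sequence[str],
    q1s: Sequence[str],
    r2s: Sequence[str],
    q2s: Sequence[str],
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.1,
) -> tuple[list[tuple[str, str] | None], int]:
    """Vectorized :func:`merge_pairs` over many pairs of uniform length.

    Groups pairs by (len1, len2) and evaluates each candidate overlap across
    the whole group at once; pairs in singleton groups fall back to the
    scalar routine.  Semantics are identical to merge_pairs (asserted by a
    cross-check test).  Returns (results, n_rejected).
    """
    n = len(r1s)
    results: list[tuple[str, str] | None] = [None] * n
    groups: dict[tuple[int, int], list[int]] = {}
    for i in range(n):
        groups.setdefault((len(r1s[i]), len(r2s[i])), []).append(i)

    rejected = 0
    for (l1, l2), idx in groups.items():
        max_l = min(l1, l2)
        if max_l < min_overlap or min(l1, l2) == 0 or len(idx) < 8:
            for i in idx:
                res = merge_pairs(r1s[i], q1s[i], r2s[i], q2s[i], min_overlap, max_mismatch_frac)
                results[i] = res
                rejected += res is None
            continue
        m = len(idx)
        A1 = np.empty((m, l1), dtype=np.uint8)
        Q1 = np.empty((m, l1), dtype=np.int16)
        A2 = np.empty((m, l2), dtype=np.uint8)
        Q2 = np.empty((m, l2), dtype=np.int16)
        for k, i in enumerate(idx):
            A1[k] = seq_to_array(r1s[i])
            Q1[k] = _decode_quals(q1s[i])
            A2[k] = revcomp_array(seq_to_array(r2s[i]))
            Q2[k] = _decode_quals(q2s[i])[::-1]

        best_matches = np.full(m, -1, dtype=np.int64)
        best_ov = np.zeros(m, dtype=np.int64)
        for ov in range(min_overlap, max_l + 1):
            matches = np.count_nonzero(A1[:, l1 - ov :] == A2[:, :ov], axis=1)
            ok = (ov - matches) / ov <= max_mismatch_frac
            # lexicographic (matches, ov) improvement; ov increases monotonically
            better = ok & (matches >= best_matches)
            best_ov[better] = ov
            best_matches[better] = matches[better]

        for k, i in enumerate(idx):
            if best_matches[k] < 0:
                rejected += 1
                continue
            ov = int(best_ov[k])
            o1, o2 = A1[k, l1 - ov :], A2[k, :ov]
            oq1, oq2 = Q1[k, l1 - ov :], Q2[k, :ov]
            take2 = oq2 > oq1
            cons = np.where(take2, o2, o1)
            consq = np.maximum(oq1, oq2)
            seq = np.concatenate([A1[k, : l1 - ov], cons, A2[k, ov:]])
            qual = np.concatenate([Q1[k, : l1 - ov], consq, Q2[k, ov:]]) + PHRED_OFFSET
            results[i] = (seq.tobytes().decode(), qual.astype(np.uint8).tobytes().decode())
    return results, rejected


def align_bisulfite(
    seq: str, qual: str, amplicon: AmpliconSpec, min_identity: float = 0.9
) -> Alignment | None:
    """Ungapped placement of a (possibly bisulfite-converted) read.

    Both read and reference are collapsed C->T before scoring, so full or
    partial conversion is invisible to the aligner.  The best offset by match
    count wins (leftmost on ties); reads under ``min_identity`` in the
    reduced alphabet are rejected (returned as None).
    """
    if not seq:
        raise DegenerateInputError("empty read")
    ref = seq_to_array(amplicon.sequence)
    read = seq_to_array(seq)
    if read.size > ref.size:
        return None
    ref_red = np.where(ref == _C, _T, ref)
    read_red = np.where(read == _C, _T, read)
    n_off = ref.size - read.size + 1
    scores = np.empty(n_off, dtype=np.int64)
    for off in range(n_off):
        scores[off] = np.count_nonzero(read_red == ref_red[off : off + read.size])
    best = int(np.argmax(scores))  # argmax returns the leftmost maximum
    if scores[best] / read.size < min_identity:
        return None
    return Alignment(best, seq, qual)


# ---------------------------------------------------------------------------
# Calling and QC
# ---------------------------------------------------------------------------

def _grouped_base_counts(
    alignments: Iterable[Alignment],
    positions: np.ndarray,
    min_base_quality: int,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Count C and T calls at each reference position over all alignments.

    Bases other than C/T and bases below ``min_base_quality`` are ignored.
    Returns (c_counts, t_counts, n_reads).
    """
    positions = np.asarray(positions, dtype=np.int64)
    c_counts = np.zeros(positions.size, dtype=np.int64)
    t_counts = np.zeros(positions.size, dtype=np.int64)

    groups: dict[tuple[int, int], list[Alignment]] = {}
    n_reads = 0
    for aln in alignments:
        n_reads += 1
        groups.setdefault((aln.offset, len(aln.seq)), []).append(aln)

    for (offset, length), alns in groups.items():
        local = positions - offset
        in_read = (local >= 0) & (local < length)
        if not in_read.any():
            continue
        cols = local[in_read]
        mat = np.empty((len(alns), length), dtype=np.uint8)
        qmat = np.empty((len(alns), length), dtype=np.int16)
        for k, aln in enumerate(alns):
            mat[k] = seq_to_array(aln.seq)
            qmat[k] = _decode_quals(aln.qual)
        sub = mat[:, cols]
        ok = qmat[:, cols] >= min_base_quality
        c_counts[in_read] += np.count_nonzero((sub == _C) & ok, axis=0)
        t_counts[in_read] += np.count_nonzero((sub == _T) & ok, axis=0)
    return c_counts, t_counts, n_reads


def call_methylation(
    alignments: Iterable[Alignment],
    amplicon: AmpliconSpec,
    min_base_quality: int = 20,
) -> MethylationProfile:
    """Per-CpG methylation calls: C at a reference CpG cytosine is methylated,
    T unmethylated; other bases or low-quality calls are ignored.
    """
    alignments = list(alignments)
    positions = np.asarray(amplicon.cpg_offsets, dtype=np.int64)
    meth, unmeth, n_reads = _grouped_base_counts(alignments, positions, min_base_quality)
    return MethylationProfile(amplicon.name, meth, unmeth, n_reads_used=n_reads)


def conversion_qc(
    alignments: Iterable[Alignment],
    amplicon: AmpliconSpec,
    min_base_quality: int = 20,
) -> float:
    """Bisulfite conversion-rate estimate in percent.

    Non-CpG cytosines are expected to be unmethylated, so the fraction of
    T calls over C+T calls at those positions estimates the conversion rate.
    Independent of the methylation state of the CpG sites.
    """
    positions = amplicon.non_cpg_c_offsets()
    if positions.size == 0:
        raise QCNotComputableError(f"{amplicon.name}: no non-CpG cytosine in reference")
    c_counts, t_counts, _ = _grouped_base_counts(list(alignments), positions, min_base_quality)
    total = int(c_counts.sum() + t_counts.sum())
    if total == 0:
        raise QCNotComputableError("no usable base calls at non-CpG cytosines")
    return 100.0 * float(t_counts.sum()) / total


def region_mean(
    profile: MethylationProfile,
    amplicon: AmpliconSpec,
    min_reads: int = 100,
) -> float:
    """Unweighted mean methylation (percent) over the amplicon's analysis CpGs.

    Every analysis site must be covered and the profile must rest on at least
    ``min_reads`` merged reads (config-exposed floor; deep amplicon data is
    the norm, desk-scale simulations may lower it).
    """
    if not amplicon.analysis_indices:
        raise MissingDataError(f"{amplicon.name}: no analysis CpGs configured")
    if profile.n_reads_used < min_reads:
        raise MissingDataError(
            f"{amplicon.name}: {profile.n_reads_used} reads < floor of {min_reads}"
        )
    idx = np.asarray(amplicon.analysis_indices, dtype=np.int64) - 1
    cov = profile.coverage[idx]
    if (cov == 0).any():
        bad = [int(i + 1) for i in idx[cov == 0]]
        raise MissingDataError(f"{amplicon.name}: uncovered analysis CpG(s) {bad}")
    return float(np.mean(profile.levels[idx]) * 100.0)


# ---------------------------------------------------------------------------
# End-to-end amplicon pipeline
# ---------------------------------------------------------------------------

def run_bisseq(
    pairs1,
    pairs2,
    amplicon: AmpliconSpec,
    q_trim: int = 20,
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.1,
    min_identity: float = 0.9,
    min_base_quality: int = 20,
) -> tuple[MethylationProfile, dict]:
    """Trim, merge, align and call one amplicon; returns (profile, QC counters).

    ``pairs1``/``pairs2`` are sequences of FASTQ-like records with
    ``.name``/``.seq``/``.qual`` attributes, mate 2 in sequencer orientation.
    """
    if len(pairs1) != len(pairs2):
        raise FormatError("mate files differ in read count")
    t1s, t1q, t2s, t2q = [], [], [], []
    for rec1, rec2 in zip(pairs1, pairs2):
        s1, q1 = quality_trim(rec1.seq, rec1.qual, q_trim)
        s2, q2 = quality_trim(rec2.seq, rec2.qual, q_trim)
        t1s.append(s1)
        t1q.append(q1)
        t2s.append(s2)
        t2q.append(q2)

    merged, n_merge_rejected = merge_pairs_batch(
        t1s, t1q, t2s, t2q, min_overlap=min_overlap, max_mismatch_frac=max_mismatch_frac
    )
    alignments: list[Alignment] = []
    n_align_rejected = 0
    for res in merged:
        if res is None:
            continue
        aln = align_bisulfite(res[0], res[1], amplicon, min_identity=min_identity)
        if aln is None:
            n_align_rejected += 1
        else:
            alignments.append(aln)

    profile = call_methylation(alignments, amplicon, min_base_quality=min_base_quality)
    try:
        profile.conversion_rate_pct = conversion_qc(
            alignments, amplicon, min_base_quality=min_base_quality
        )
    except QCNotComputableError:
        profile.conversion_rate_pct = None
    qc = {
        "n_pairs": len(pairs1),
        "n_merged": len(pairs1) - n_merge_rejected,
        "n_merge_rejected": n_merge_rejected,
        "n_aligned": len(alignments),
        "n_align_rejected": n_align_rejected,
        "conversion_rate_pct": (
            None
            if profile.conversion_rate_pct is None
            else round_half_away(profile.conversion_rate_pct, 2)
        ),
    }
    return profile, qc
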