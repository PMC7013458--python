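"""sgRNA off-target enumeration: protospacer matches with mismatches, NGG PAM.

SpCas9 convention: the 20-nt protospacer sits immediately 5' of an NGG PAM
on the hit strand.  Mismatches are counted over the 20-mer only; the PAM
must match exactly except at its N position.  Both strands are scanned and
reverse-strand hits are reported in forward coordinates.  Bulges (indels)
are not modeled.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._utils import array_to_seq, revcomp_array, seq_to_array
from .errors import ParameterError
from .intervals import IntervalSet

HIT_COLUMNS = ["chrom", "start", "strand", "mismatches", "site", "pam"]


def _strand_scan(
    arr: np.ndarray, guide: np.ndarray, max_mismatches: int, pam: str
) -> tuple[np.ndarray, np.ndarray]:
    """(starts, mismatch counts) of hits on one strand of one sequence."""
    glen = guide.size
    wlen = glen + len(pam)
    n = arr.size - wlen + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    mm = np.zeros(n, dtype=np.int16)
    for j in range(glen):
        mm += arr[j : j + n] != guide[j]
    valid = np.ones(n, dtype=bool)
    for j, ch in enumerate(pam):
        if ch != "N":
            valid &= arr[glen + j : glen + j + n] == ord(ch)
    hits = np.flatnonzero(valid & (mm <= max_mismatches))
    return hits.astype(np.int64), mm[hits].astype(np.int64)


def scan(
    genome,
    protospacer: str,
    max_mismatches: int = 4,
    pam: str = "NGG",
) -> pd.DataFrame:
    """All genomic matches of ``protospacer`` with <= ``max_mismatches``.

    ``genome`` is a mapping chrom -> uppercase sequence (a
    :class:`~methyledit.synth.SyntheticGenome` also works).  Ambiguity codes
    are rejected in the protospacer; genome Ns never match a guide base (an
    N in the protospacer window counts as a mismatch, an N at the PAM's N
    position is allowed).  Returns a DataFrame sorted by
    (chrom, start, strand) with the 0-based start of the 20-mer in forward
    coordinates, the hit-strand site sequence and the PAM trinucleotide.
    """
    sequences = getattr(genome, "sequences", genome)
    protospacer = protospacer.upper()
    if len(protospacer) != 20 or set(protospacer) - set("ACGT"):
        raise ParameterError("protospacer must be a 20-mer over A/C/G/T")
    if max_mismatches < 0:
        raise ParameterError("max_mismatches must be non-negative")
    guide = seq_to_array(protospacer)
    glen = guide.size
    wlen = glen + len(pam)

    rows = []
    for chrom in sequences:
        arr = seq_to_array(sequences[chrom].upper())
        L = arr.size
        fstarts, fmm = _strand_scan(arr, guide, max_mismatches, pam)
        for s, m in zip(fstarts, fmm):
            site = array_to_seq(arr[s : s + glen])
            pam_seq = array_to_seq(arr[s + glen : s + wlen])
            rows.append((chrom, int(s), "+", int(m), site, pam_seq))
        rc = revcomp_array(arr)
        rstarts, rmm = _strand_scan(rc, guide, max_mismatches, pam)
        for s, m in zip(rstarts, rmm):
            site = array_to_seq(rc[s : s + glen])
            pam_seq = array_to_seq(rc[s + glen : s + wlen])
            rows.append((chrom, int(L - s - glen), "-", int(m), site, pam_seq))

    df = pd.DataFrame(rows, columns=HIT_COLUMNS)
    return df.sort_values(["chrom", "start", "strand"], kind="stable").reset_index(drop=True)


def hits_to_bed(hits: pd.DataFrame) -> IntervalSet:
    """Hits as BED6 intervals over the 20-mer; score = mismatch count."""
    return IntervalSet.from_arrays(
        hits["chrom"].tolist(),
        hits["start"].to_numpy(),
        hits["start"].to_numpy() + 20,
        name=[f"mm{m}" for m in hits["mismatches"]],
        score=hits["mismatches"].to_numpy().astype(float),
        strand=hits["strand"].tolist(),
    )
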