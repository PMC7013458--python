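"""Small shared helpers: rounding, seed derivation, DNA byte codecs."""

from __future__ import annotations

import hashlib
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

# DNA as uint8 ASCII codes; complement is a 256-entry lookup table.
_COMPLEMENT = np.arange(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMPLEMENT[_a] = _b
    _COMPLEMENT[_a + 32] = _b + 32  # lowercase


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round ties away from zero (so 1.585 -> 1.59 at 2 digits, -0.5 -> -1).

    Applied to reported ratios/percentages; ordinary banker's rounding would
    turn 10.05 into 10.0 instead of 10.1.
    """
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))


def derive_seed(master_seed: int, stage: str) -> int:
    """Expand one global seed into an independent, stable per-stage seed (< 2**31).

    Hash-based so adding a stage never perturbs the streams of existing ones.
    """
    digest = hashlib.sha256(f"{int(master_seed)}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(master_seed, stage))


def seq_to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()


def array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def revcomp_array(arr: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[arr[::-1]]


def revcomp(seq: str) -> str:
    return array_to_seq(revcomp_array(seq_to_array(seq)))


def find_cpg_sites(seq: str) -> np.ndarray:
    """0-based offsets of the C of every CG dinucleotide on the given strand."""
    arr = seq_to_array(seq)
    if arr.size < 2:
        return np.empty(0, dtype=np.int64)
    hits = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
    return np.flatnonzero(hits).astype(np.int64)
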