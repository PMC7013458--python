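"""Sorted genomic interval sets in BED convention (0-based, half-open).

The container backs CpG islands, MBD fragments and peak calls.  It is a thin
wrapper over numpy arrays held in a pandas DataFrame with BED6 columns; all
overlap logic assumes half-open coordinates and is tested against brute-force
oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import CoordinateError

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


class Interval(NamedTuple):
    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."


@dataclass
class IntervalSet:
    """An ordered collection of genomic intervals (BED6 semantics)."""

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=BED_COLUMNS))

    def __post_init__(self):
        missing = [c for c in BED_COLUMNS if c not in self.df.columns]
        for c in missing:
            self.df[c] = {"name": ".", "score": 0.0, "strand": "."}.get(c)
        self.df = self.df[BED_COLUMNS].reset_index(drop=True)
        if len(self.df):
            starts = self.df["start"].to_numpy()
            ends = self.df["end"].to_numpy()
            if (starts < 0).any():
                raise CoordinateError("negative interval start")
            if (ends < starts).any():
                raise CoordinateError("interval end precedes start")

    # -- construction -----------------------------------------------------
    @classmethod
    def from_records(cls, records: Sequence[tuple]) -> "IntervalSet":
        rows = [Interval(*r) for r in records]
        return cls(pd.DataFrame(rows, columns=BED_COLUMNS))

    @classmethod
    def from_arrays(cls, chrom, start, end, name=None, score=None, strand=None) -> "IntervalSet":
        n = len(start)
        df = pd.DataFrame(
            {
                "chrom": chrom if not isinstance(chrom, str) else [chrom] * n,
                "start": np.asarray(start, dtype=np.int64),
                "end": np.asarray(end, dtype=np.int64),
                "name": name if name is not None else ["."] * n,
                "score": score if score is not None else np.zeros(n),
                "strand": strand if strand is not None else ["."] * n,
            }
        )
        return cls(df)

    # -- basics ------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[Interval]:
        for row in self.df.itertuples(index=False):
            yield Interval(*row)

    @property
    def chroms(self) -> np.ndarray:
        return self.df["chrom"].to_numpy()

    @property
    def starts(self) -> np.ndarray:
        return self.df["start"].to_numpy()

    @property
    def ends(self) -> np.ndarray:
        return self.df["end"].to_numpy()

    @property
    def names(self) -> np.ndarray:
        return self.df["name"].to_numpy()

    def widths(self) -> np.ndarray:
        return self.ends - self.starts

    def sort(self) -> "IntervalSet":
        out = self.df.sort_values(["chrom", "start", "end"], kind="stable")
        return IntervalSet(out.reset_index(drop=True))

    def is_sorted(self) -> bool:
        df = self.df
        if len(df) < 2:
            return True
        key = list(zip(df["chrom"], df["start"], df["end"]))
        return all(a <= b for a, b in zip(key, key[1:]))

    def is_disjoint(self) -> bool:
        """True when no two intervals on the same chromosome overlap."""
        s = self.sort().df
        for _, grp in s.groupby("chrom", sort=False):
            ends = grp["end"].to_numpy()
            starts = grp["start"].to_numpy()
            if len(grp) > 1 and (starts[1:] < ends[:-1]).any():
                return False
        return True

    def validate_within(self, chrom_sizes: Mapping[str, int]) -> None:
        for chrom, grp in self.df.groupby("chrom", sort=False):
            if chrom not in chrom_sizes:
                raise CoordinateError(f"unknown chromosome {chrom!r}")
            if (grp["end"].to_numpy() > chrom_sizes[chrom]).any():
                raise CoordinateError(f"interval beyond end of {chrom}")

    def subset(self, mask) -> "IntervalSet":
        return IntervalSet(self.df.loc[np.asarray(mask)].reset_index(drop=True))

    # -- overlap algebra ----------------------------------------------------
    def overlap_pairs(self, other: "IntervalSet") -> list[tuple[int, int]]:
        """All (i, j) index pairs with >= 1 bp overlap between self[i] and other[j].

        ``other`` must be disjoint per chromosome (the CGI/peak case); within a
        chromosome the overlapping candidates then form a contiguous window in
        start order, located with two binary searches per query.
        """
        pairs: list[tuple[int, int]] = []
        # group `other` per chromosome with original indices
        by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, grp in other.df.groupby("chrom", sort=False):
            grp = grp.sort_values("start", kind="stable")
            by_chrom[chrom] = (
                grp["start"].to_numpy(),
                grp["end"].to_numpy(),
                grp.index.to_numpy(),
            )
        for i, iv in enumerate(self):
            entry = by_chrom.get(iv.chrom)
            if entry is None:
                continue
            starts, ends, idx = entry
            lo = np.searchsorted(ends, iv.start, side="right")
            hi = np.searchsorted(starts, iv.end, side="left")
            for j in range(lo, hi):
                if ends[j] > iv.start and starts[j] < iv.end:
                    pairs.append((i, int(idx[j])))
        return pairs

    def overlaps_any(self, other: "IntervalSet") -> np.ndarray:
        """Boolean per interval of self: does it overlap >= 1 bp of other?"""
        hit = np.zeros(len(self), dtype=bool)
        for i, _ in self.overlap_pairs(other):
            hit[i] = True
        return hit
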