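"""Genomic intervals, genome binning, and labeled region sets.

Coordinates are 0-based, half-open (BED convention) throughout the package.
A :class:`RegionSet` is the central currency between the region-selection
step and feature extraction: a labeled collection of intervals — recurrently
gained bins (``eGCR``), recurrently lost bins (``eLCR``), or hypermethylated
windows expected in tumor (``eHRT``) or in plasma cell types (``eHRP``) —
for one cancer type.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np

REGION_LABELS = ("eGCR", "eLCR", "eHRT", "eHRP")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class RegionSet:
    """A labeled set of genomic intervals for one cancer type.

    ``label`` is one of eGCR / eLCR (copy-number contrast bins) or
    eHRT / eHRP (hypermethylated region windows). eGCR/eLCR intervals must
    be non-overlapping; eHRT/eHRP windows are kept as ranked, possibly
    overlapping probe windows and counted independently downstream.
    """

    label: str
    intervals: list[GenomicInterval]
    cancer_type: str = "NA"
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.label not in REGION_LABELS:
            raise ValueError(f"label must be one of {REGION_LABELS}, got {self.label!r}")
        if self.label in ("eGCR", "eLCR"):
            _check_non_overlapping(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def total_length(self) -> int:
        return sum(len(iv) for iv in self.intervals)


def _check_non_overlapping(intervals: Sequence[GenomicInterval]) -> None:
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom, ivs in by_chrom.items():
        ivs = sorted(ivs, key=lambda x: x.start)
        for a, b in zip(ivs, ivs[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping intervals on {chrom}: "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )


def bin_genome(chrom_sizes: Mapping[str, int], bin_size: int) -> list[GenomicInterval]:
    """Tile each chromosome with consecutive ``bin_size`` bins.

    Bins never cross chromosome boundaries; the last bin per chromosome may
    be shorter. Chromosomes are emitted in the order of ``chrom_sizes``.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if not chrom_sizes:
        raise ValueError("no genome: chrom_sizes is empty")
    bins: list[GenomicInterval] = []
    for chrom, size in chrom_sizes.items():
        if size <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive length {size}")
        for start in range(0, size, bin_size):
            bins.append(GenomicInterval(chrom, start, min(start + bin_size, size)))
    return bins


class IntervalIndex:
    """Vectorized point-in-interval lookup over non-overlapping intervals.

    Maps genomic positions to the index of the containing interval, or -1.
    """

    def __init__(self, intervals: Sequence[GenomicInterval]):
        _check_non_overlapping(intervals)
        self.intervals = list(intervals)
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        per_chrom: dict[str, list[tuple[int, int, int]]] = {}
        for idx, iv in enumerate(intervals):
            per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, idx))
        for chrom, rows in per_chrom.items():
            rows.sort()
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            idxs = np.array([r[2] for r in rows], dtype=np.int64)
            self._by_chrom[chrom] = (starts, ends, idxs)

    def locate(self, chroms: np.ndarray, positions: np.ndarray) -> np.ndarray:
        """Interval index for each (chrom, position), -1 when uncovered."""
        positions = np.asarray(positions, dtype=np.int64)
        out = np.full(positions.shape, -1, dtype=np.int64)
        chroms = np.asarray(chroms)
        for chrom in np.unique(chroms):
            entry = self._by_chrom.get(str(chrom))
            if entry is None:
                continue
            starts, ends, idxs = entry
            mask = chroms == chrom
            pos = positions[mask]
            k = np.searchsorted(starts, pos, side="right") - 1
            hit = (k >= 0) & (pos < ends[np.clip(k, 0, len(ends) - 1)])
            sub = np.full(pos.shape, -1, dtype=np.int64)
            sub[hit] = idxs[k[hit]]
            out[mask] = sub
        return out


# --- BED I/O ---------------------------------------------------------------

def write_region_bed(regions: RegionSet, path: str | Path) -> None:
    """Write a RegionSet as BED3 with a header comment carrying metadata."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(
            f"# label={regions.label}\tcancer_type={regions.cancer_type}"
            f"\tprovenance={regions.provenance}\n"
        )
        for iv in regions.intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_region_bed(path: str | Path, label: str | None = None) -> RegionSet:
    """Read a RegionSet from BED3 written by :func:`write_region_bed`.

    Plain BED3 without the metadata header is accepted if ``label`` is given.
    """
    path = Path(path)
    meta = {"label": label, "cancer_type": "NA", "provenance": ""}
    intervals: list[GenomicInterval] = []
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                for tok in line.lstrip("# ").split("\t"):
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        if k in meta:
                            meta[k] = v
                continue
            fields = line.split("\t")
            intervals.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
    if meta["label"] is None:
        raise ValueError(f"{path}: BED has no label header; pass label explicitly")
    return RegionSet(
        label=str(meta["label"]),
        intervals=intervals,
        cancer_type=str(meta["cancer_type"]),
        provenance=str(meta["provenance"]),
    )
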