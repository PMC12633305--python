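"""cfDNA fragment containers and I/O.

A fragment is the genomic interval spanned by a sequenced cfDNA molecule
(template start to template end of a proper read pair). Fragment length is
the unit of fragmentomic signal: mono-nucleosomal cfDNA from healthy plasma
clusters near 167/197 bp (core + linker, chromatosome) while tumor-derived
fragments are shifted toward the ~145 bp nucleosome core.

Fragments carry an optional nonnegative weight (default 1) as a hook for
externally computed per-fragment bias corrections (e.g. GC weights); all
distribution-based features are invariant to a common rescaling of weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .intervals import GenomicInterval, IntervalIndex

logger = logging.getLogger(__name__)

DEFAULT_LENGTH_MIN = 90
DEFAULT_LENGTH_MAX = 500


@dataclass(frozen=True)
class FragmentRecord:
    """One cfDNA fragment as a half-open genomic interval with a weight."""

    chrom: str
    start: int
    end: int
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: {self.chrom}:{self.start}-{self.end}")
        if self.weight < 0:
            raise ValueError("weight must be nonnegative")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class FragmentSet:
    """Column-oriented container for one sample's fragments.

    Stores chrom/start/end/weight as numpy arrays so per-sample feature
    extraction stays vectorized; iteration yields FragmentRecord views.
    """

    def __init__(
        self,
        chrom: np.ndarray | Sequence[str],
        start: np.ndarray | Sequence[int],
        end: np.ndarray | Sequence[int],
        weight: np.ndarray | Sequence[float] | None = None,
    ):
        self.chrom = np.asarray(chrom, dtype=object)
        self.start = np.asarray(start, dtype=np.int64)
        self.end = np.asarray(end, dtype=np.int64)
        if weight is None:
            weight = np.ones(len(self.start))
        self.weight = np.asarray(weight, dtype=float)
        n = len(self.start)
        if not (len(self.chrom) == len(self.end) == len(self.weight) == n):
            raise ValueError("column lengths differ")
        if n and (self.end <= self.start).any():
            bad = int(np.argmax(self.end <= self.start))
            raise ValueError(
                f"malformed fragment at row {bad}: "
                f"{self.chrom[bad]}:{self.start[bad]}-{self.end[bad]}"
            )
        if n and (self.weight < 0).any():
            raise ValueError("weights must be nonnegative")

    def __len__(self) -> int:
        return len(self.start)

    def __iter__(self) -> Iterator[FragmentRecord]:
        for c, s, e, w in zip(self.chrom, self.start, self.end, self.weight):
            yield FragmentRecord(str(c), int(s), int(e), float(w))

    @property
    def length(self) -> np.ndarray:
        return self.end - self.start

    @property
    def midpoint(self) -> np.ndarray:
        return (self.start + self.end) // 2

    def subset(self, mask: np.ndarray) -> "FragmentSet":
        return FragmentSet(self.chrom[mask], self.start[mask], self.end[mask], self.weight[mask])

    def sorted(self) -> "FragmentSet":
        order = np.lexsort((self.start, self.chrom.astype(str)))
        return self.subset(order)

    @classmethod
    def from_records(cls, records: Sequence[FragmentRecord]) -> "FragmentSet":
        return cls(
            [r.chrom for r in records],
            [r.start for r in records],
            [r.end for r in records],
            [r.weight for r in records],
        )

    @classmethod
    def concat(cls, parts: Sequence["FragmentSet"]) -> "FragmentSet":
        return cls(
            np.concatenate([p.chrom for p in parts]) if parts else [],
            np.concatenate([p.start for p in parts]) if parts else [],
            np.concatenate([p.end for p in parts]) if parts else [],
            np.concatenate([p.weight for p in parts]) if parts else [],
        )


def load_fragments(
    source: str | Path,
    length_min: int = DEFAULT_LENGTH_MIN,
    length_max: int = DEFAULT_LENGTH_MAX,
) -> FragmentSet:
    """Load fragments from a BED file or a SAM/BAM alignment file.

    BED input: 3 columns (chrom, start, end) with an optional 4th weight
    column. SAM/BAM input: each proper pair contributes one fragment from
    the leftmost template start across the template length (taken from the
    forward-strand mate so each pair is counted once).

    Fragments with length outside [length_min, length_max] are dropped and
    the drop count logged. Output is sorted by (chrom, start).
    """
    source = Path(source)
    if not source.exists():
        raise FileNotFoundError(source)
    suffix = source.suffix.lower()
    if suffix in (".bam", ".sam", ".cram"):
        frags = _load_bam(source)
    else:
        frags = _load_bed(source)
    n_total = len(frags)
    if n_total == 0:
        raise ValueError(f"empty sample: no fragments parsed from {source}")
    keep = (frags.length >= length_min) & (frags.length <= length_max)
    dropped = n_total - int(keep.sum())
    if dropped:
        logger.info(
            "%s: dropped %d/%d fragments outside length [%d, %d]",
            source.name, dropped, n_total, length_min, length_max,
        )
    frags = frags.subset(keep)
    if len(frags) == 0:
        raise ValueError(
            f"empty sample: no fragments within length [{length_min}, {length_max}]"
        )
    return frags.sorted()


def _load_bed(path: Path) -> FragmentSet:
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    weights: list[float] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected ≥3 tab-separated fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end ({end}) must exceed start ({start})")
            chroms.append(fields[0])
            starts.append(start)
            ends.append(end)
            weights.append(float(fields[3]) if len(fields) > 3 else 1.0)
    return FragmentSet(chroms, starts, ends, weights)


def _load_bam(path: Path) -> FragmentSet:
    import pysam

    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    mode = "r" if path.suffix.lower() == ".sam" else "rb"
    with pysam.AlignmentFile(str(path), mode) as bam:
        for read in bam:
            if (
                read.is_unmapped
                or not read.is_paired
                or not read.is_proper_pair
                or read.is_secondary
                or read.is_supplementary
                or read.is_reverse  # count each pair once, from the forward mate
                or read.template_length <= 0
            ):
                continue
            chroms.append(read.reference_name)
            starts.append(read.reference_start)
            ends.append(read.reference_start + read.template_length)
    return FragmentSet(chroms, starts, ends)


def write_fragments_bed(
    frags: FragmentSet, path: str | Path, provenance: Sequence[str] | None = None
) -> None:
    """Write fragments as BED (4th column weight; optional 5th provenance tag)."""
    with Path(path).open("w") as fh:
        for i in range(len(frags)):
            row = (
                f"{frags.chrom[i]}\t{frags.start[i]}\t{frags.end[i]}\t"
                f"{frags.weight[i]:g}"
            )
            if provenance is not None:
                row += f"\t{provenance[i]}"
            fh.write(row + "\n")


def assign_to_bins(
    frags: FragmentSet, bins: Sequence[GenomicInterval]
) -> dict[int, np.ndarray]:
    """Assign each fragment to the unique bin containing its midpoint.

    Returns a map from bin index (into ``bins``) to the integer indices of
    the fragments assigned there. Fragments whose midpoint falls in no bin
    are dropped. Midpoint assignment avoids double counting fragments that
    straddle a bin edge.
    """
    index = IntervalIndex(bins)
    hits = index.locate(frags.chrom, frags.midpoint)
    out: dict[int, np.ndarray] = {}
    for b in range(len(bins)):
        idx = np.nonzero(hits == b)[0]
        if len(idx):
            out[b] = idx
    return out
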