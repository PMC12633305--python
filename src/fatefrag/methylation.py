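"""cfMeDIP-seq region-count features over hypermethylated region sets.

cfMeDIP-seq enriches methylated cfDNA fragments, so read counts over
regions expected hypermethylated in tumor tissue (eHRT) rise with the
circulating tumor fraction, while counts over regions hypermethylated in
plasma-resident cell types (eHRP) track the non-tumor background. Three
features summarize one sample's profile:

* ``s_ehrt`` — fraction of eHRT regions with at least ``min_reads`` reads
  (default 3), S_eHRT = |{r ∈ eHRT : c(r) ≥ 3}| / |eHRT|;
* ``s_ehrp`` — the same detection fraction over eHRP;
* ``r_tp``  — the ratio of total eHRT coverage to total eHRP coverage
  (with a pseudocount), the tumor-vs-plasma coverage contrast.

Counts are used as-is: the ≥3-read detection rule is absolute, so the
features are sensitive to library size (a per-million scaling option
exists but is off by default; document depth when comparing cohorts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import RegionSet


@dataclass
class MethylationConfig:
    """Tunables for methylation feature extraction."""

    min_reads: int = 3
    pseudocount: float = 1.0
    per_million: bool = False  # scale counts to reads-per-million before thresholding


@dataclass
class RegionCounts:
    """Per-region read counts for one sample over one region set."""

    region_set_label: str  # "eHRT" | "eHRP"
    counts: np.ndarray  # aligned with the RegionSet's interval order
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.region_set_label not in ("eHRT", "eHRP"):
            raise ValueError(
                f"region_set_label must be eHRT|eHRP, got {self.region_set_label!r}"
            )
        if len(self.counts) and (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class MethFeatures:
    """The three cfMeDIP features for one sample."""

    s_ehrt: float
    s_ehrp: float
    r_tp: float

    @staticmethod
    def feature_names() -> list[str]:
        return ["s_ehrt", "s_ehrp", "r_tp"]

    def as_dict(self) -> dict[str, float]:
        return {"s_ehrt": self.s_ehrt, "s_ehrp": self.s_ehrp, "r_tp": self.r_tp}


def count_reads(
    read_chroms: np.ndarray | Sequence[str],
    read_midpoints: np.ndarray | Sequence[int],
    regions: RegionSet,
    sample_id: str = "sample",
) -> RegionCounts:
    """Count reads per region by read midpoint, half-open [start, end).

    Overlapping regions are counted independently: a read midpoint inside
    two windows increments both. Region sets here are probe windows that
    may legitimately overlap, so no uniqueness of assignment is imposed.
    """
    if len(regions) == 0:
        raise ValueError("regions must be nonempty")
    chroms = np.asarray(read_chroms, dtype=object)
    mids = np.asarray(read_midpoints, dtype=np.int64)
    counts = np.zeros(len(regions), dtype=np.int64)
    # sort midpoints per chromosome once; each region then costs O(log n)
    per_chrom: dict[str, np.ndarray] = {}
    for chrom in np.unique(chroms):
        per_chrom[str(chrom)] = np.sort(mids[chroms == chrom])
    for i, iv in enumerate(regions.intervals):
        pos = per_chrom.get(iv.chrom)
        if pos is None:
            continue
        counts[i] = np.searchsorted(pos, iv.end - 1, side="right") - np.searchsorted(
            pos, iv.start, side="left"
        )
    return RegionCounts(
        region_set_label=regions.label if regions.label in ("eHRT", "eHRP") else "eHRT",
        counts=counts,
        sample_id=sample_id,
    )


def detection_fraction(rc: RegionCounts, min_reads: int = 3) -> float:
    """Fraction of regions with at least ``min_reads`` reads."""
    if len(rc.counts) == 0:
        raise ValueError("region set must be nonempty")
    return float((rc.counts >= min_reads).mean())


def coverage_ratio(
    rc_ehrt: RegionCounts, rc_ehrp: RegionCounts, pseudocount: float = 1.0
) -> float:
    """Total eHRT coverage over total eHRP coverage, pseudocounted."""
    if len(rc_ehrt.counts) == 0 or len(rc_ehrp.counts) == 0:
        raise ValueError("both region sets must be nonempty")
    return (rc_ehrt.total + pseudocount) / (rc_ehrp.total + pseudocount)


def extract_methylation(
    rc_ehrt: RegionCounts,
    rc_ehrp: RegionCounts,
    config: MethylationConfig | None = None,
) -> MethFeatures:
    """Compose the three cfMeDIP features for one sample."""
    config = config or MethylationConfig()
    ehrt, ehrp = rc_ehrt, rc_ehrp
    if config.per_million:
        lib = ehrt.total + ehrp.total
        scale = 1e6 / lib if lib > 0 else 1.0
        ehrt = RegionCounts(ehrt.region_set_label, ehrt.counts * scale, ehrt.sample_id)
        ehrp = RegionCounts(ehrp.region_set_label, ehrp.counts * scale, ehrp.sample_id)
    return MethFeatures(
        s_ehrt=detection_fraction(ehrt, config.min_reads),
        s_ehrp=detection_fraction(ehrp, config.min_reads),
        r_tp=coverage_ratio(ehrt, ehrp, config.pseudocount),
    )


# --- TSV I/O ---------------------------------------------------------------

def read_region_counts(
    path: str | Path, label: str, sample_id: str = "sample"
) -> RegionCounts:
    """Read a counts TSV with columns chrom, start, end, count."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"counts TSV missing columns: {sorted(missing)}")
    return RegionCounts(label, df["count"].to_numpy(), sample_id=sample_id)


def write_region_counts(
    rc: RegionCounts, regions: RegionSet, path: str | Path
) -> None:
    if len(rc.counts) != len(regions):
        raise ValueError("counts and regions lengths differ")
    df = pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in regions.intervals],
            "start": [iv.start for iv in regions.intervals],
            "end": [iv.end for iv in regions.intervals],
            "count": rc.counts,
        }
    )
    df.to_csv(path, sep="\t", index=False)
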