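"""Knowledge-informed selection of contrast regions.

Two families of region sets drive the downstream contrasts:

* **eGCR / eLCR** — genome bins recurrently gained / lost in a cancer type,
  derived from a cohort-scale copy-number call matrix. In plasma, amplified
  regions are expected enriched for ctDNA-derived fragments and deleted
  regions depleted, so contrasting fragmentomic distributions between the
  two sets concentrates tumor signal while cancelling sample-wide batch
  effects.
* **eHRT / eHRP** — 300 bp windows around CpG probes hypermethylated in
  tumor tissue vs. in plasma-resident cell types, selected from a
  precomputed differential-methylation table (fold-change and BH-adjusted
  p-value per probe).

Selection is deterministic and pure: rerunning with identical inputs gives
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, RegionSet


@dataclass
class CnaCohortMatrix:
    """Bin × sample binary gain/loss call matrix for one cancer type."""

    bins: list[GenomicInterval]
    samples: list[str]
    gain: np.ndarray  # shape (n_bins, n_samples), entries in {0,1}
    loss: np.ndarray
    cancer_type: str = "NA"

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain)
        self.loss = np.asarray(self.loss)
        expected = (len(self.bins), len(self.samples))
        for name, mat in (("gain", self.gain), ("loss", self.loss)):
            if mat.shape != expected:
                raise ValueError(f"{name} matrix shape {mat.shape} != bins×samples {expected}")
            if not np.isin(mat, (0, 1)).all():
                raise ValueError(f"{name} matrix entries must be 0/1")

    @property
    def gain_freq(self) -> np.ndarray:
        """Per-bin fraction of cohort samples with a gain call."""
        return self.gain.mean(axis=1)

    @property
    def loss_freq(self) -> np.ndarray:
        return self.loss.mean(axis=1)


@dataclass(frozen=True)
class DmrStat:
    """One probe's differential-methylation summary (tumor or plasma screen)."""

    probe_position: GenomicInterval
    fold_change: float
    adj_p: float
    direction: str  # "hyper" | "hypo"

    def __post_init__(self) -> None:
        if not (0.0 <= self.adj_p <= 1.0):
            raise ValueError(f"adj_p must be in [0,1], got {self.adj_p}")
        if self.fold_change <= 0:
            raise ValueError(f"fold_change must be positive, got {self.fold_change}")
        if self.direction not in ("hyper", "hypo"):
            raise ValueError(f"direction must be hyper|hypo, got {self.direction!r}")


def select_cna_regions(
    cohort: CnaCohortMatrix, recurrence_threshold: float = 0.25
) -> tuple[RegionSet, RegionSet]:
    """Select recurrently gained (eGCR) and lost (eLCR) bins.

    A bin enters eGCR when the fraction of cohort samples with a gain call
    in it is at least ``recurrence_threshold`` (likewise eLCR for losses).
    Bins recurrent in BOTH directions are excluded from both sets: the
    downstream distribution contrast assumes opposite ctDNA enrichment, and
    ambiguous bins would dilute both sides. The default threshold of 0.25 is
    the point at which most cancer types have at least 90% of cases carrying
    an alteration in the selected regions.
    """
    if not (0.0 < recurrence_threshold < 1.0):
        raise ValueError("recurrence_threshold must be in (0,1)")
    gain_hit = cohort.gain_freq >= recurrence_threshold
    loss_hit = cohort.loss_freq >= recurrence_threshold
    both = gain_hit & loss_hit
    gain_only = gain_hit & ~both
    loss_only = loss_hit & ~both
    if not gain_only.any() or not loss_only.any():
        raise ValueError(
            "empty contrast set: need at least one gain-recurrent and one "
            f"loss-recurrent bin at threshold {recurrence_threshold}"
        )
    prov = f"recurrence_threshold={recurrence_threshold}"
    egcr = RegionSet(
        "eGCR",
        [b for b, keep in zip(cohort.bins, gain_only) if keep],
        cancer_type=cohort.cancer_type,
        provenance=prov,
    )
    elcr = RegionSet(
        "eLCR",
        [b for b, keep in zip(cohort.bins, loss_only) if keep],
        cancer_type=cohort.cancer_type,
        provenance=prov,
    )
    return egcr, elcr


def recurrence_coverage_curve(
    cohort: CnaCohortMatrix, thresholds: Sequence[float]
) -> pd.DataFrame:
    """Genome fraction selected and sample fraction covered vs. threshold.

    For each threshold, bins recurrent in either direction are selected
    (without the both-directions exclusion — the curve asks how much of the
    cohort carries at least one alteration in the selected territory, so an
    ambiguous bin still covers its samples). An empty selection yields zero
    percentages rather than an error, keeping the curve continuous.
    """
    thresholds = list(thresholds)
    if not thresholds:
        raise ValueError("thresholds must be nonempty")
    if any(not (0.0 < t < 1.0) for t in thresholds):
        raise ValueError("each threshold must be in (0,1)")
    genome_len = sum(len(b) for b in cohort.bins)
    lengths = np.array([len(b) for b in cohort.bins], dtype=float)
    any_call = (cohort.gain + cohort.loss) > 0  # bins × samples
    rows = []
    for t in thresholds:
        selected = (cohort.gain_freq >= t) | (cohort.loss_freq >= t)
        pct_genome = float(lengths[selected].sum() / genome_len) if genome_len else 0.0
        if selected.any():
            covered = any_call[selected].any(axis=0)
            pct_samples = float(covered.mean())
        else:
            pct_samples = 0.0
        rows.append((t, pct_genome, pct_samples))
    return pd.DataFrame(
        rows, columns=["threshold", "pct_genome_selected", "pct_samples_covered"]
    )


def select_dmrs(
    stats: Sequence[DmrStat],
    fc_min: float = 1.5,
    p_max: float = 0.01,
    max_n: int = 3000,
    width: int = 300,
    label: str = "eHRT",
    cancer_type: str = "NA",
) -> RegionSet:
    """Select hypermethylated probe windows for eHRT or eHRP.

    Keeps hypermethylated probes with fold change above ``fc_min`` and
    adjusted p below ``p_max`` (strict inequalities, as the screen defines
    them), ranks by adjusted p ascending with ties broken by fold change
    descending then genomic coordinate, truncates to ``max_n``, and emits
    ``width``-bp windows centered on each probe, clipped at position 0.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    if not stats:
        raise ValueError("stats must be nonempty")
    survivors = [
        s
        for s in stats
        if s.direction == "hyper" and s.fold_change > fc_min and s.adj_p < p_max
    ]
    if not survivors:
        raise ValueError("no DMRs pass filters")
    survivors.sort(
        key=lambda s: (
            s.adj_p,
            -s.fold_change,
            s.probe_position.chrom,
            s.probe_position.start,
        )
    )
    survivors = survivors[:max_n]
    half = width // 2
    intervals = []
    for s in survivors:
        center = s.probe_position.midpoint
        start = max(0, center - half)
        intervals.append(GenomicInterval(s.probe_position.chrom, start, center + (width - half)))
    return RegionSet(
        label,
        intervals,
        cancer_type=cancer_type,
        provenance=f"fc_min={fc_min} p_max={p_max} max_n={max_n} width={width}",
    )


# --- TSV I/O ---------------------------------------------------------------

def read_cna_matrix(
    gain_path: str | Path, loss_path: str | Path, cancer_type: str = "NA"
) -> CnaCohortMatrix:
    """Read paired gain/loss TSVs: chrom, start, end, then one 0/1 column per sample."""
    gain_df = pd.read_csv(gain_path, sep="\t")
    loss_df = pd.read_csv(loss_path, sep="\t")
    coord_cols = ["chrom", "start", "end"]
    for name, df in (("gain", gain_df), ("loss", loss_df)):
        if list(df.columns[:3]) != coord_cols:
            raise ValueError(f"{name} TSV must start with columns {coord_cols}")
    if not gain_df[coord_cols].equals(loss_df[coord_cols]):
        raise ValueError("gain and loss TSVs disagree on bin coordinates")
    samples = list(gain_df.columns[3:])
    if list(loss_df.columns[3:]) != samples:
        raise ValueError("gain and loss TSVs disagree on sample columns")
    bins = [
        GenomicInterval(str(r.chrom), int(r.start), int(r.end))
        for r in gain_df[coord_cols].itertuples()
    ]
    return CnaCohortMatrix(
        bins=bins,
        samples=samples,
        gain=gain_df[samples].to_numpy(dtype=np.int8),
        loss=loss_df[samples].to_numpy(dtype=np.int8),
        cancer_type=cancer_type,
    )


def write_cna_matrix(cohort: CnaCohortMatrix, gain_path: str | Path, loss_path: str | Path) -> None:
    coords = pd.DataFrame(
        {
            "chrom": [b.chrom for b in cohort.bins],
            "start": [b.start for b in cohort.bins],
            "end": [b.end for b in cohort.bins],
        }
    )
    for path, mat in ((gain_path, cohort.gain), (loss_path, cohort.loss)):
        df = pd.concat(
            [coords, pd.DataFrame(mat, columns=cohort.samples)], axis=1
        )
        df.to_csv(path, sep="\t", index=False)


def read_dmr_stats(path: str | Path) -> list[DmrStat]:
    """Read a probe-level DMR table: chrom, pos, fold_change, adj_p, direction."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "pos", "fold_change", "adj_p", "direction"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"DMR TSV missing columns: {sorted(missing)}")
    return [
        DmrStat(
            probe_position=GenomicInterval(str(r.chrom), int(r.pos), int(r.pos) + 1),
            fold_change=float(r.fold_change),
            adj_p=float(r.adj_p),
            direction=str(r.direction),
        )
        for r in df.itertuples()
    ]


def write_dmr_stats(stats: Sequence[DmrStat], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "chrom": [s.probe_position.chrom for s in stats],
            "pos": [s.probe_position.start for s in stats],
            "fold_change": [s.fold_change for s in stats],
            "adj_p": [s.adj_p for s in stats],
            "direction": [s.direction for s in stats],
        }
    )
    df.to_csv(path, sep="\t", index=False)
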