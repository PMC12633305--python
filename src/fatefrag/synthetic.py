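"""Seeded synthetic cohorts with the statistical structure cfDNA analyses assume.

Generates every input the pipeline consumes — fragment sets, cohort CNA
call matrices, differential-methylation tables, cfMeDIP region counts,
and clinical timelines — with truth labels retained, so the full method
can be exercised and validated end-to-end without sequencing data.

The fragment model: a sample is a mixture of tumor- and normal-derived
fragments at tumor fraction TF. Normal cfDNA fragment lengths follow a
truncated Gaussian mixture with modes at 167 bp (nucleosome core +
linker), 197 bp (chromatosome) and a di-nucleosome shoulder near 330 bp;
tumor-derived fragments shift mass toward the 145 bp nucleosome core.
Copy number drives regional abundance: within a bin of copy number CN,
the chance a fragment is tumor-derived is TF·(CN/2) against (1 − TF) for
normal origin, so gained bins (CN 3–4) are enriched for ctDNA and lost
bins (CN 1) depleted — the contrast the FDD features read out.

cfMeDIP counts are Poisson: eHRT-truth regions at rate · (1 + k·TF),
eHRP regions at the base rate. Every generator is a pure function of
(design, seed): bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Sequence

import numpy as np
from scipy import stats as sp_stats
from statsmodels.stats.multitest import multipletests

from .clinical import ClinicalEvent, SampleTimepoint
from .fragments import FragmentSet
from .intervals import GenomicInterval, RegionSet, bin_genome
from .regions import CnaCohortMatrix, DmrStat

#: (mode bp, sd bp) of the truncated-Gaussian length components: nucleosome
#: core (~140), nuclease-trimmed mono-nucleosome shoulder (~152), core +
#: partial linker (~167), chromatosome + linker (~197), di-nucleosome (~330).
LENGTH_MODES = ((140.0, 5.0), (152.0, 7.0), (167.0, 8.0), (197.0, 12.0), (330.0, 30.0))
#: Mixture weights per origin: tumor mass concentrates on the core mode,
#: healthy mass on the trimmed/mono-nucleosome modes — reproducing the
#: observed contrast (tumor-enriched near 145 bp vs. healthy near 197 bp)
#: and a differential-CDF crossing below 150 bp.
HEALTHY_WEIGHTS = (0.04, 0.30, 0.36, 0.20, 0.10)
TUMOR_WEIGHTS = (0.54, 0.03, 0.07, 0.24, 0.12)


@dataclass
class CohortDesign:
    """Study-condition knobs for one synthetic cohort.

    The default genome is deliberately small (2 chromosomes × 30 Mb, 3 Mb
    bins → 20 bins, 5 gain-truth and 5 loss-truth) so full pipelines run
    in seconds; scale is a knob, not a constant.
    """

    n_healthy: int = 20
    n_tumor: int = 20
    tf_per_tumor: tuple[float, ...] = ()  # defaults to 0.1 for every tumor
    genome: dict[str, int] = field(
        default_factory=lambda: {"chr1": 30_000_000, "chr2": 30_000_000}
    )
    bin_size: int = 3_000_000
    gain_bins: tuple[int, ...] = (0, 1, 2, 3, 4)  # indices into bin_genome order
    loss_bins: tuple[int, ...] = (10, 11, 12, 13, 14)
    gain_cn: tuple[int, ...] = (3, 4, 3, 4, 3)
    loss_cn: int = 1
    n_fragments: int = 200_000
    length_min: int = 90
    length_max: int = 500
    healthy_weights: tuple[float, ...] = HEALTHY_WEIGHTS
    tumor_weights: tuple[float, ...] = TUMOR_WEIGHTS
    n_ehrt: int = 300
    n_ehrp: int = 300
    meth_rate: float = 2.0  # Poisson mean reads per region in a healthy sample
    meth_k: float = 10.0  # eHRT rate scales by (1 + k·TF)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.tf_per_tumor:
            self.tf_per_tumor = tuple([0.1] * self.n_tumor)
        if len(self.tf_per_tumor) != self.n_tumor:
            raise ValueError("tf_per_tumor length must equal n_tumor")
        if any(not (0.0 <= tf < 1.0) for tf in self.tf_per_tumor):
            raise ValueError("tumor fractions must be in [0,1)")
        if self.meth_rate <= 0 or self.meth_k < 0:
            raise ValueError("methylation rates must be positive")

    @property
    def bins(self) -> list[GenomicInterval]:
        return bin_genome(self.genome, self.bin_size)

    @property
    def copy_number(self) -> np.ndarray:
        cn = np.full(len(self.bins), 2.0)
        for i, b in enumerate(self.gain_bins):
            cn[b] = self.gain_cn[i % len(self.gain_cn)]
        cn[list(self.loss_bins)] = self.loss_cn
        return cn

    def truth_regions(self) -> tuple[RegionSet, RegionSet]:
        """The ground-truth eGCR/eLCR bin sets the generator enriches."""
        bins = self.bins
        egcr = RegionSet("eGCR", [bins[i] for i in self.gain_bins], provenance="truth")
        elcr = RegionSet("eLCR", [bins[i] for i in self.loss_bins], provenance="truth")
        return egcr, elcr

    def sample_tf(self, sample_idx: int) -> float:
        """Tumor fraction of sample ``sample_idx`` (healthy first, then tumors)."""
        if sample_idx < self.n_healthy:
            return 0.0
        return self.tf_per_tumor[sample_idx - self.n_healthy]


def _rng(design_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(design_seed), *map(int, key)]))


def _draw_lengths(
    rng: np.random.Generator,
    n: int,
    weights: Sequence[float],
    length_min: int,
    length_max: int,
) -> np.ndarray:
    """Truncated Gaussian mixture lengths: redraw out-of-range values, then
    clip the stragglers (a few per million at the default bounds)."""
    comp = rng.choice(len(LENGTH_MODES), size=n, p=np.asarray(weights) / np.sum(weights))
    mu = np.array([LENGTH_MODES[c][0] for c in comp])
    sd = np.array([LENGTH_MODES[c][1] for c in comp])
    lengths = rng.normal(mu, sd)
    for _ in range(6):
        bad = (lengths < length_min) | (lengths > length_max)
        if not bad.any():
            break
        lengths[bad] = rng.normal(mu[bad], sd[bad])
    return np.clip(np.round(lengths), length_min, length_max).astype(np.int64)


def simulate_fragments(
    design: CohortDesign, sample_idx: int
) -> tuple[FragmentSet, np.ndarray]:
    """One sample's fragment set plus per-fragment origin truth.

    Per fragment: a bin is drawn with weight ∝ bin length · (TF·CN/2 +
    (1 − TF)); origin is tumor with probability TF·(CN/2) / (TF·CN/2 +
    (1 − TF)) given the bin; position uniform within the bin; length from
    the origin's mixture. Returns (fragments, origins) with origins in
    {"tumor", "normal"}.
    """
    rng = _rng(design.seed, 1, sample_idx)
    tf = design.sample_tf(sample_idx)
    bins = design.bins
    cn = design.copy_number
    lengths_bp = np.array([len(b) for b in bins], dtype=float)
    tumor_mass = tf * cn / 2.0
    normal_mass = 1.0 - tf
    bin_weight = lengths_bp * (tumor_mass + normal_mass)
    bin_prob = bin_weight / bin_weight.sum()

    n = design.n_fragments
    bin_idx = rng.choice(len(bins), size=n, p=bin_prob)
    p_tumor = tumor_mass[bin_idx] / (tumor_mass[bin_idx] + normal_mass)
    is_tumor = rng.random(n) < p_tumor
    lengths = np.empty(n, dtype=np.int64)
    if is_tumor.any():
        lengths[is_tumor] = _draw_lengths(
            rng, int(is_tumor.sum()), design.tumor_weights,
            design.length_min, design.length_max,
        )
    if (~is_tumor).any():
        lengths[~is_tumor] = _draw_lengths(
            rng, int((~is_tumor).sum()), design.healthy_weights,
            design.length_min, design.length_max,
        )
    starts_bp = np.array([b.start for b in bins], dtype=np.int64)
    spans = np.array([len(b) for b in bins], dtype=np.int64)
    offset = rng.integers(0, spans[bin_idx] - 1, endpoint=False)
    start = starts_bp[bin_idx] + offset
    chrom = np.array([bins[i].chrom for i in bin_idx], dtype=object)
    frags = FragmentSet(chrom, start, start + lengths)
    origins = np.where(is_tumor, "tumor", "normal").astype(object)
    order = np.lexsort((frags.start, frags.chrom.astype(str)))
    return frags.subset(order), origins[order]


def simulate_meth_counts(
    design: CohortDesign, sample_idx: int
) -> tuple[np.ndarray, np.ndarray]:
    """Poisson cfMeDIP counts for (eHRT regions, eHRP regions).

    eHRT-truth rates scale by (1 + k·TF); eHRP regions stay at the base
    rate, emulating the tumor-vs-plasma hypermethylation contrast.
    """
    rng = _rng(design.seed, 2, sample_idx)
    tf = design.sample_tf(sample_idx)
    ehrt = rng.poisson(design.meth_rate * (1.0 + design.meth_k * tf), size=design.n_ehrt)
    ehrp = rng.poisson(design.meth_rate, size=design.n_ehrp)
    return ehrt, ehrp


def meth_truth_regions(design: CohortDesign) -> tuple[RegionSet, RegionSet]:
    """Non-overlapping 300 bp windows standing in for probe-derived eHRT/eHRP."""
    chrom = next(iter(design.genome))
    ehrt = RegionSet(
        "eHRT",
        [GenomicInterval(chrom, 1000 * i, 1000 * i + 300) for i in range(design.n_ehrt)],
        provenance="truth",
    )
    ehrp = RegionSet(
        "eHRP",
        [
            GenomicInterval(chrom, 1_000_000 + 1000 * i, 1_000_000 + 1000 * i + 300)
            for i in range(design.n_ehrp)
        ],
        provenance="truth",
    )
    return ehrt, ehrp


def simulate_cna_cohort(
    design: CohortDesign,
    n_samples: int,
    gain_freqs: Sequence[float],
    loss_freqs: Sequence[float],
    cancer_type: str = "synthetic",
) -> CnaCohortMatrix:
    """Bernoulli bin × sample call matrix at the given per-bin frequencies."""
    gain_freqs = np.asarray(gain_freqs, dtype=float)
    loss_freqs = np.asarray(loss_freqs, dtype=float)
    bins = design.bins
    if len(gain_freqs) != len(bins) or len(loss_freqs) != len(bins):
        raise ValueError("frequency vectors must match the bin count")
    if ((gain_freqs < 0) | (gain_freqs > 1)).any() or ((loss_freqs < 0) | (loss_freqs > 1)).any():
        raise ValueError("frequencies must be in [0,1]")
    rng = _rng(design.seed, 3)
    gain = (rng.random((len(bins), n_samples)) < gain_freqs[:, None]).astype(np.int8)
    loss = (rng.random((len(bins), n_samples)) < loss_freqs[:, None]).astype(np.int8)
    samples = [f"s{i:04d}" for i in range(n_samples)]
    return CnaCohortMatrix(bins, samples, gain, loss, cancer_type=cancer_type)


def simulate_clinical_timeline(
    n_patients: int,
    relapse_fraction: float,
    design: CohortDesign,
) -> tuple[list[ClinicalEvent], list[SampleTimepoint], dict]:
    """Synthetic treatment timelines with per-timepoint tumor-fraction truth.

    Every patient starts treatment (surgery at day 0, chemo at day 14) and
    is assessed roughly every 8 weeks. Relapsing patients (the first
    ``round(relapse_fraction · n)`` of the cohort) progress: their
    assessments flip to PD near relapse and their per-timepoint TF rises,
    while non-relapsing patients stay in response at TF ≈ 0. Sample scores
    are a monotone readout of TF (score = TF / (TF + 0.05)), standing in
    for a trained scorer. Returns (events, timepoints, truth) where truth
    maps patient → expected label per sample date, relapse date, and TF
    series.
    """
    if not (0.0 <= relapse_fraction <= 1.0):
        raise ValueError("relapse_fraction must be in [0,1]")
    rng = _rng(design.seed, 4)
    t0 = date(2024, 1, 1)
    n_relapse = round(relapse_fraction * n_patients)
    events: list[ClinicalEvent] = []
    samples: list[SampleTimepoint] = []
    truth: dict[str, dict] = {}
    for p in range(n_patients):
        pid = f"P{p:03d}"
        relapsing = p < n_relapse
        start = t0 + timedelta(days=int(rng.integers(0, 60)))
        events.append(ClinicalEvent(pid, start, "treatment", "surgery"))
        events.append(ClinicalEvent(pid, start + timedelta(days=14), "treatment", "chemo_start"))
        relapse_day = int(rng.integers(200, 360)) if relapsing else None
        assess_days = [56 + 56 * k + int(rng.integers(-7, 8)) for k in range(5)]
        tfs, expected = [], {}
        for k, d in enumerate(assess_days):
            if relapsing and relapse_day is not None and d >= relapse_day - 60:
                cat, tf = "PD", 0.05 * (1 + k)
            else:
                cat, tf = ("PR" if k < 2 else "SD"), 0.0 if not relapsing else 0.002 * k
            events.append(ClinicalEvent(pid, start + timedelta(days=d), "assessment", cat))
            sample_day = d + int(rng.integers(-10, 11))
            score = tf / (tf + 0.05)
            samples.append(
                SampleTimepoint(pid, start + timedelta(days=sample_day), score)
            )
            tfs.append(tf)
            expected[(start + timedelta(days=sample_day)).isoformat()] = (
                "NR" if cat == "PD" else "R"
            )
        if relapsing and relapse_day is not None:
            events.append(
                ClinicalEvent(pid, start + timedelta(days=relapse_day), "outcome", "relapse")
            )
        truth[pid] = {
            "relapsing": relapsing,
            "relapse_date": (
                (start + timedelta(days=relapse_day)).isoformat() if relapse_day else None
            ),
            "tf_series": tfs,
            "expected_labels": expected,
        }
    return events, samples, truth


def reference_dmr_screen(
    probe_positions: Sequence[GenomicInterval],
    tumor_profiles: np.ndarray,
    normal_profiles: np.ndarray,
) -> list[DmrStat]:
    """Fixture-grade differential-methylation screen over probe profiles.

    Per probe: fold change of group means, two-sided Wilcoxon rank-sum p,
    Benjamini–Hochberg adjustment across probes. ``tumor_profiles`` and
    ``normal_profiles`` are probes × samples matrices of methylation
    levels (≥3 samples per group). A probe constant across both groups
    records p = 1 rather than erroring.
    """
    tumor = np.asarray(tumor_profiles, dtype=float)
    normal = np.asarray(normal_profiles, dtype=float)
    if tumor.shape[1] < 3 or normal.shape[1] < 3:
        raise ValueError("need at least 3 profiles per group")
    if tumor.shape[0] != len(probe_positions) or normal.shape[0] != len(probe_positions):
        raise ValueError("profile rows must match probe_positions")
    pvals = np.ones(len(probe_positions))
    fcs = np.empty(len(probe_positions))
    eps = 1e-12
    for i in range(len(probe_positions)):
        t, n = tumor[i], normal[i]
        fcs[i] = (t.mean() + eps) / (n.mean() + eps)
        if np.ptp(np.concatenate([t, n])) == 0:
            pvals[i] = 1.0
        else:
            pvals[i] = sp_stats.mannwhitneyu(t, n, alternative="two-sided").pvalue
    adj = multipletests(pvals, method="fdr_bh")[1]
    return [
        DmrStat(
            probe_position=probe_positions[i],
            fold_change=float(fcs[i]),
            adj_p=float(adj[i]),
            direction="hyper" if fcs[i] >= 1.0 else "hypo",
        )
        for i in range(len(probe_positions))
    ]
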