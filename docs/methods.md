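# Methods

## Contrast-region selection

**Copy-number regions.** The genome is tiled into non-overlapping 3 Mb
bins (0-based, half-open coordinates everywhere; a trailing shorter bin
per chromosome). Given a cohort's binary gain/loss call matrix, a bin is
gain-recurrent when the fraction of samples with a gain call in it
reaches the recurrence threshold, and likewise for losses. The default
threshold is 0.25 — for most cancer types that leaves at least ~90% of
cases carrying an alteration inside the selected territory — and is a
per-cancer-type configuration value. A bin recurrent in *both* directions
is excluded from both sets: the downstream distribution contrast assumes
opposite ctDNA enrichment, and an ambiguous bin would dilute both sides.
The recurrence-coverage curve (genome fraction selected and cohort
fraction covered vs. threshold) uses either-direction selection without
that exclusion, since coverage asks only whether a sample is altered in
the selected territory; an empty selection yields zero percentages rather
than an error so threshold sweeps stay continuous.

**Methylation regions.** From a probe-level differential-methylation
table, hypermethylated probes with fold change > 1.5 and BH-adjusted
p < 0.01 (strict inequalities) are ranked by adjusted p ascending, ties
by fold change descending then genomic coordinate, truncated to 3,000,
and emitted as 300 bp windows centered on the probe, clipped at position
0. Windows are kept as ranked, possibly overlapping intervals and counted
independently — merging would change the detection-fraction denominator
in a way no external definition pins down.

## Fragmentomics features

Fragments are paired-end template intervals; lengths outside [90, 500] bp
are dropped. Each fragment is assigned to at most one bin by its midpoint
(avoiding double counting across edges). Per bin, seven metrics are
computed: weighted mean length, coverage (weight sum), window counts with
inclusive bounds 140–159 (nucleosome core), 160–170 (chromatosome),
171–240 (nucleosome), and two pseudocounted ratios, core/nucleosome and
(core+chromatosome)/nucleosome, with pseudocount 0.5. Bins with coverage
below 50 fragments are excluded from bin-level ECDFs (sparse-bin metric
values are dominated by shot noise); at least 3 usable bins per side are
required.

For each metric the FDD is the difference of empirical CDFs over eGCR
bins minus eLCR bins, evaluated on the sorted union of observed values;
for global fragment length, the ECDFs are over raw lengths of fragments
assigned to either family, on the integer grid 90..500. Summaries per
curve: TV = Σ|FDD| and the standard deviation of the FDD values, both
with uniform weight per grid point. σ is the square root of the variance
(the variance expression without the root is reported in some
transcriptions; the root makes the feature scale with the signal). The KL
divergence uses integer-length histograms with pseudocount 1 per cell,
natural log, direction KL(eGCR ‖ eLCR); a symmetrized variant exists
behind a config flag, off by default. The feature vector is fixed-order:
(tv, sd) per metric plus tv/sd/KL for global length — 17 fragmentomics
features, 20 with methylation.

Fragment weights (default 1) are a hook for externally computed
per-fragment bias corrections (e.g. GC weights); all ECDF- and
histogram-based features are invariant to a common rescaling. "Coverage"
is weighted fragment count, not base-level depth — with equal-size bins
the two are proportional.

## Methylation features

c(r) is the number of reads whose midpoint lies in region r (half-open;
overlapping windows each count). Features: S_eHRT = |{r ∈ eHRT : c(r) ≥
3}| / |eHRT|, the same over eHRP, and R_tp = (Σ_eHRT c + 1)/(Σ_eHRP c + 1).
The printed form of R_tp in the source material repeats eHRT in numerator
and denominator — an evident typo; the implementation follows the prose
("the ratio between the overall coverage of these two sets of regions").
Counts are used raw: the ≥3-read rule is absolute, so S_* is sensitive to
library size; a reads-per-million option exists but is off by default,
and cross-cohort comparisons should hold depth constant.

## Detection model

Elastic-net logistic regression, α = 0.5, glmnet-style λ on the grid
0, 0.01, …, 0.05, mapped to scikit-learn's `C = 1/(n·λ)` (λ = 0 is an
unpenalized fit). Features are standardized with training-set mean/sd
(stored on the scorer so scoring is self-contained); constant features
are dropped with a warning. λ is chosen by 10-fold stratified CV on mean
held-out binomial (or multinomial) deviance, ties toward stronger
regularization. Repeated CV selects λ once on the full training matrix,
then runs `n_repeats` repetitions of stratified 10-fold assignment seeded
`seed + repetition`, scoring each sample exactly once per repetition
while held out, with per-fold standardization; per-sample scores are
averaged across repetitions, AUC is computed on the averages, and
sensitivity/specificity are reported at the Youden-optimal threshold
(max sensitivity + specificity − 1). Classes with a single sample fall
back to leave-one-out, logged. Class weights are uniform; stratification
is by label only.

Cross-cohort training can first drop uncertainly labeled samples: tumors
kept only with TF > 0.03, healthy only with TF < 0.01, both strict.
Tissue-of-origin uses the same machinery multinomially over a feature
matrix that concatenates, per sample, the feature block computed against
every cancer type's region sets (an absent block surfaces as a
missing-value error at assembly); evaluation is one-vs-rest AUC on
repeated-CV averaged class probabilities. The Delta Score is the mean
tumor score minus mean control score. Stage correlation is Pearson on
ordinal codes H=0, I–IV=1–4.

## In silico dilution

The fraction of mixture reads drawn from the cancer sample is
R = TF_T·(TF_I·PL + (1−TF_I)·2)/(TF_I·PL): tumor cells contribute PL
genome copies per cell against 2 for normal cells, so the cancer sample's
tumor read fraction is f_I = TF_I·PL/(TF_I·PL + (1−TF_I)·2) and R·f_I
= TF_T exactly — the mixture's tumor-derived read fraction equals the
target for every ploidy, and R collapses to TF_T/TF_I at PL = 2.
Converting that read fraction back to a cell-level tumor fraction carries
a small-TF_T approximation of relative order O(TF_T). Depth is normalized
via CancerRatio = R·covT/covC and HealthyRatio = (1−R)·covT/covH, both
required ≤ 1. Fragments are kept by independent Bernoulli thinning (the
per-read semantics of standard subsampling tools), with one RNG stream
per (target TF, replicate) derived from the master seed so each replicate
is individually reproducible; healthy-only replicates subsample 90% of
reads. Provenance tags are retained so realized tumor-read fractions can
be validated against R.

## Clinical evaluation

Each plasma timepoint is labeled by the disease-status assessment nearest
in time, within ±50 days: SD, PR, CR, and remission map to responder, PD
to non-responder, anything farther to unlabeled. Distance ties go to the
later assessment — disease state evolves forward — and the rule is
order-independent in the input events. Trajectories anchor t = 0 at the
first treatment event (first sample as a flagged fallback). Group
comparisons use the two-sided Wilcoxon rank-sum test: exact enumeration
of all group assignments when both groups have ≤ 10 samples (correct
under ties, where the classical exact U distribution is not), otherwise
the tie-corrected normal approximation. Time-to-relapse binning uses
fixed 30.44-day months for determinism; bin ranges are half-open toward
relapse, edge samples go to the later bin, gap samples are reported as
unbinned rather than silently merged.

## Synthetic cohorts

The generator produces every pipeline input as a pure function of
(design, seed). Fragments: a bin is drawn with weight ∝ bin length ·
(TF·CN/2 + (1−TF)); the fragment is tumor-derived with probability
TF·(CN/2)/(TF·CN/2 + 1−TF) given the bin; position is uniform in the
bin; length comes from the origin's truncated Gaussian mixture. The
default genome is small (2 × 30 Mb, 3 Mb bins → 20 bins, 5 gain-truth
bins at CN 3–4 and 5 loss-truth at CN 1) so full pipelines run in
seconds.

The length model uses five components — nucleosome core (140 ± 5),
nuclease-trimmed mono-nucleosome shoulder (152 ± 7), core + partial
linker (167 ± 8), chromatosome + linker (197 ± 12), di-nucleosome
(330 ± 30) — with healthy weights (0.04, 0.30, 0.36, 0.20, 0.10) and
tumor weights (0.54, 0.03, 0.07, 0.24, 0.12). The trimmed shoulder is
deliberate: with only two well-separated symmetric modes at ~145 and
~167 bp, the differential-CDF crossing (the FDD peak) necessarily lands
near their midpoint (~155 bp) and the tumor distribution stochastically
dominates, leaving no negative lobe — neither matches the observed FDD
geometry of real cfDNA, whose healthy length density has a heavy sub-167
flank. With the shoulder, the pure-contrast FDD peaks at ~147 bp with its
minimum at ~186 bp. Truncation to [90, 500] redraws out-of-range values
up to six rounds, then clips the stragglers (a few per million).
Default depth is 200,000 fragments per sample: resolving a TF = 0.01
contrast requires per-grid-point ECDF noise √(2F(1−F)/n_side) below the
~1% CDF shift, which ~50,000 fragments per contrast side provides; it is
also a realistic desk-scale subsample of LPWGS depth.

cfMeDIP counts are Poisson with eHRT-truth rates scaled by (1 + k·TF),
k = 10, base rate 2 reads/region over 300 + 300 regions. CNA cohort
matrices are independent Bernoulli draws at specified per-bin
frequencies. Clinical timelines give every patient surgery + chemo and
~8-weekly assessments; relapsing patients flip to PD with rising TF near
a relapse date, and timepoint scores are a monotone readout of TF
standing in for a trained scorer. The fixture-grade DMR screen applies a
two-sided rank-sum test per probe with BH correction, recording p = 1
for constant probes.

**What passing tests show — and don't.** The generator reproduces the
structural assumptions the method relies on (regional ctDNA enrichment
proportional to copy number, origin-shifted length mixtures, TF-scaled
methylation rates) but none of the nuisances of real cohorts: GC and
mappability bias, batch-dependent length shifts, subclonal copy-number
heterogeneity, inter-patient baseline variation, duplicate and alignment
artifacts. Passing therefore validates the statistical machinery and its
implementation, not clinical performance; headline cohort metrics (AUCs
of 0.84–1.0 and sensitivity at very low TF) require the original
cohort-scale sequencing data and are out of scope here.

## Numerical and design choices

- ECDFs are right-continuous step functions via sorted search; FDD values
  are exact rationals of counts, so oracle agreement is bit-exact.
- Pseudocounts: 0.5 in bin-metric ratios, 1 per KL histogram cell, 1 in
  R_tp — all keep degenerate inputs finite without masking signal.
- Elastic-net fits use the saga solver with pinned `random_state`,
  `tol = 1e-7`, so identical inputs reproduce scores bit-exactly; model
  artifacts serialize to JSON (coefficients, scales, λ, metadata).
- Seeds: all generator streams derive from `SeedSequence([seed, *key])`
  with small integer keys, keeping streams independent and below 2³¹.
- Scale choices (20-bin genome, 200k fragments/sample, 60k for the
  40+40 detection cohort, 20 CV repetitions in the end-to-end checks vs.
  the 100 default) keep the full validation suite around a minute on one
  CPU while leaving every asserted contrast comfortably above its noise
  floor.

## Known limitations

- No internal GC/mappability correction; the per-fragment weight hook
  expects upstream tools.
- The ≥3-read methylation rule is depth-sensitive by construction.
- Recurrence is computed at fixed 3 Mb bin boundaries; cohort resources
  with different native binning are re-binned by overlap upstream.
- The dilution model controls tumor-read fraction, not cell-level tumor
  fraction, for PL ≠ 2 (exact conversion documented above).
- Multinomial tissue-of-origin requires every sample to carry every
  cancer type's feature block; partial panels are rejected rather than
  imputed.
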