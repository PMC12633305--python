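"""Select contrast regions from a cohort CNA matrix and a DMR table.

Builds a synthetic cohort of binary gain/loss calls with five recurrently
gained and five recurrently lost bins, selects eGCR/eLCR at the default
25% recurrence threshold, sweeps the threshold for the genome-vs-samples
coverage trade-off, and picks hypermethylated probe windows from a
simulated differential-methylation screen.
"""

import numpy as np

from fatefrag import CohortDesign, simulate_cna_cohort, reference_dmr_screen
from fatefrag.intervals import GenomicInterval
from fatefrag.regions import recurrence_coverage_curve, select_cna_regions, select_dmrs

design = CohortDesign(seed=1)
n_bins = len(design.bins)

# five gain-recurrent bins (40%), five loss-recurrent (40%), background 5%
gain_freqs = [0.40] * 5 + [0.05] * (n_bins - 5)
loss_freqs = [0.05] * (n_bins - 5) + [0.40] * 5
cohort = simulate_cna_cohort(design, n_samples=500, gain_freqs=gain_freqs, loss_freqs=loss_freqs)

egcr, elcr = select_cna_regions(cohort, recurrence_threshold=0.25)
print(f"eGCR: {len(egcr)} bins, eLCR: {len(elcr)} bins (truth: 5 each)")

curve = recurrence_coverage_curve(cohort, thresholds=[0.1, 0.25, 0.5])
print("\nthreshold  %genome  %samples-covered")
for row in curve.itertuples():
    print(f"{row.threshold:9.2f}  {row.pct_genome_selected:7.2f}  {row.pct_samples_covered:.3f}")
# lowering the threshold admits more genome and covers more of the cohort

# DMR selection: 200 probes, the first 30 truly doubled in tumor
rng = np.random.default_rng(1)
probes = [GenomicInterval("chr1", 2000 * i + 900, 2000 * i + 901) for i in range(200)]
normal = rng.normal(1.0, 0.1, size=(200, 10)).clip(0.01)
tumor = rng.normal(1.0, 0.1, size=(200, 10)).clip(0.01)
tumor[:30] *= 2.0
stats = reference_dmr_screen(probes, tumor, normal)
ehrt = select_dmrs(stats, fc_min=1.5, p_max=0.01, max_n=3000, width=300)
print(f"\nselected {len(ehrt)} eHRT windows of ≤300 bp (30 probes carry true signal)")
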