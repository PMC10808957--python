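# chromshift

Integrative downstream analysis of how a chromatin perturbation shifts
accessibility, transcription-factor occupancy, and the dynamic range of
gene expression between two conditions (wild-type vs knockout).

The package is aimed at computational biologists who already have peak
calls (BED/narrowPeak), a counts matrix, and gene models, and need the
*downstream* statistics reproducibly: peak-set Venn decomposition by
genomic overlap, nearest-TSS feature annotation and TSS/TES signal
profiles, log2 coverage-density comparison with a global fold-change
estimate, known-PWM motif containment shifts, expression decile/quintile
dynamic-range statistics, and replication-fork-rate rank tests.  Every
stage is validated against seeded synthetic data with planted parameters
the stage must recover.

## Core statistics

For peak sets $A$, $B$, the Venn decomposition classifies members by
≥ `min_bp` genomic overlap and counts shared connected components of the
bipartite overlap graph.  The global accessibility change between paired
per-peak densities $x_i$ (WT) and $y_i$ (KO) is

$$\Delta\% = 100\,(2^{m} - 1),\qquad
  m = \tfrac1n \sum_i \log_2 \frac{y_i + pc}{x_i + pc},$$

the mean of per-peak log ratios.  Motif containment scans both strands
with a log-odds PWM, $\mathrm{lo}_{bj} = \log_2\frac{(c_{bj} + pc\,\pi_b)/(N_j
+ pc)}{\pi_b}$, at a threshold of 0.8 of the min–max score range, and
reports the fraction of peaks with ≥ 1 hit per condition.  Differential
expression uses Welch's $t$ on $\log_2(\mathrm{CPM}+1)$ with
Benjamini–Hochberg adjustment and classifies at $p < 0.05$,
$|\log_2 FC| > 1$; dynamic-range compression is quantified by re-binning
each sample against reference-decile boundaries and by a two-sided $F$
test on within-sample variances.  Fork rates convert fiber lengths at
1 μm = 2.59 kb over the pulse time and are compared by the Mann–Whitney
$U$ test (exact enumeration for small samples, tie-corrected normal
approximation otherwise).

## Worked example

```python
from chromshift import (IntervalSet, PeakSpec, SimSpec, make_peak_sets,
                        venn_stats, make_density, global_fold_change)
from chromshift.simulate import chrom_sizes

spec = SimSpec(seed=0, peaks=PeakSpec(a_total=17_134, b_total=34_263, shared=16_550))
wt, ko = make_peak_sets(spec, sizes=chrom_sizes(spec))
v = venn_stats(IntervalSet(wt.records), IntervalSet(ko.records))
print(v.a_only, v.b_only, v.shared_clusters)

table = make_density(SimSpec(seed=0))   # 20,000 peaks, planted 1.25x ratio
print(round(global_fold_change("WT", "KO", table), 1))
```

prints

```
584 17713 16550
25.3
```

The first line is the Venn decomposition of two peak sets built with the
planted structure: 584 peaks unique to WT (3.4% of its 17,134), 17,713
unique to KO (51.7% of its 34,263), and 16,550 shared — the pattern of a
perturbation that creates new binding/accessible sites while preserving
existing ones.  The second line recovers the planted 25% global
accessibility increase from 20,000 noisy per-peak density pairs.

The `examples/` directory has one short narrative script per capability
(`peak_venn.py`, `annotate_and_profile.py`, `accessibility_shift.py`,
`motif_shift.py`, `expression_dynamics.py`, `fork_rates.py`); each
generates its inputs, runs the stage and explains the printed numbers.
A thin CLI wraps the same functions for file-based use:

```bash
chromshift venn --a wt_peaks.bed --b ko_peaks.bed --out venn.tsv
chromshift motif --peaks-a wt.bed --peaks-b ko.bed --genome genome.fa \
    --pfm motifs.pfm --out shift.tsv
```

## Documentation

`docs/methods.md` describes the models, defaults, numerical choices, what
the synthetic generators emulate (and deliberately do not), and known
limitations.
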