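"""Motif containment shift between two peak conditions.

Plants a CTCF-like consensus in 8.49% of WT peaks and 31.31% of KO peaks
(2,000 peaks each), scans both sets with the log-odds PWM on both strands,
and tabulates the per-condition containment fractions.  A hypergeometric
upper-tail test then asks whether the KO set is enriched for
motif-positive peaks against the pooled background.
"""

from chromshift import (
    GeneSpec,
    GenomeSpec,
    MotifSpec,
    PeakSpec,
    SimSpec,
    builtin_motifs,
    make_genome,
    make_peak_sets,
    motif_enrichment_test,
    motif_proportion_shift,
    pwm_from_pfm,
)
from chromshift.simulate import plant_motifs

spec = SimSpec(
    seed=0,
    genome=GenomeSpec(n_chroms=4, chrom_length=2_000_000),
    genes=GeneSpec(n_genes=0),
    peaks=PeakSpec(a_total=2_000, b_total=2_000, shared=0),
    motifs=MotifSpec(plant_fraction_a=0.0849, plant_fraction_b=0.3131),
)
genome = make_genome(spec)
wt, ko = make_peak_sets(spec, sizes=genome.sizes)
pfm = builtin_motifs()[0]  # synthetic CTCF-like model
planted = plant_motifs(spec, genome.sequences, wt, ko, pfm)

table = motif_proportion_shift(wt.records, ko.records, planted.genome, [pwm_from_pfm(pfm)])
fa, fb = table.loc[pfm.motif_id, ["fraction_a", "fraction_b"]]
print(f"{pfm.motif_id}: WT {100 * fa:.2f}%  ->  KO {100 * fb:.2f}%  "
      f"(planted 8.49% -> 31.31%)")

n_wt, n_ko = round(fa * 2000), round(fb * 2000)
p = motif_enrichment_test(n_ko, 2000, n_wt + n_ko, 4000)
print(f"KO enrichment vs pooled background: hypergeometric p = {p:.3g}")
print("(a large containment gain in KO means previously inaccessible motif")
print(" instances became scannable peaks after the perturbation)")
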