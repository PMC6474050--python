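"""Paired statistic vs unpaired group-mean baseline on a heterogeneous cohort.

Simulates a paired secretome where between-patient variability (3 log2 units)
exceeds the disease effect (1.5 log2 units on 10% of proteins), then compares
how many spiked proteins each approach recovers.  This is the scenario the
paired design exists for: group means overlap, within-pair ratios do not.
"""

import pairprot as pp

cfg = pp.preset("heterogeneous", seed=17)
dataset, truth = pp.simulate(cfg)
dataset = pp.filter_proteotypic(pp.filter_sequential_points(pp.normalize_tic(dataset)))
spiked = set(truth.loc[truth["affected"], "accession"])

paired = pp.analyze_dataset(dataset)
called = set(paired.proteins.loc[paired.proteins["direction"] == "case_up", "accession"])

baseline = pp.baseline_unpaired(dataset, fold_cutoff=1.5, alpha=0.05)
flagged = set(baseline.loc[baseline["flagged"], "accession"])

print(f"spiked proteins:                {len(spiked)} of {cfg.n_proteins}")
print(f"paired method true positives:   {len(called & spiked)} (false positives: {len(called - spiked)})")
print(f"unpaired baseline true positives: {len(flagged & spiked)}")
print()
print(
    "The unpaired Welch t-test with BH correction finds (essentially) nothing because\n"
    "patient-to-patient spread dwarfs the effect, while the paired sign statistic\n"
    "cancels each patient's own scale and recovers the spiked set."
)
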