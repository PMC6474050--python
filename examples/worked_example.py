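"""Paired analysis of the bundled three-peptide demonstration table.

Loads the ten-subject paired quant table shipped with the package, runs the
standard pipeline (TIC normalization, quality filters, per-subject coding,
exact binomial peptide p-values, Stouffer protein roll-up) and prints both
report levels.
"""

import pairprot as pp

dataset = pp.load_worked_example()
out = pp.run_pipeline(dataset)

print("Peptide report:")
print(out.result.peptides[["peptide", "accession", "x", "n", "p_value", "avg_log2_fold"]].to_string(index=False))
print()
print("Protein report:")
print(out.result.proteins[["accession", "p_value", "z", "k", "direction"]].to_string(index=False))
print()
print(
    "x/n are case-favoured successes over informative subjects; the p-value is the\n"
    "exact binomial upper tail P(X >= x) at 1/2 — small p (< 0.025) links the\n"
    "peptide/protein to the case condition, large p (> 0.975) to the control side;\n"
    "avg_log2_fold averages log2(case:control) over subjects quantified in both breasts."
)
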