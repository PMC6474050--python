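"""Replicate-CV filtering and paired re-analysis of targeted transition areas.

Builds a small SRM-style table (two proteins, three transitions, six paired
subjects, duplicate injections, one spiked global standard per run),
normalizes to the global standards, drops irreproducible transitions
(CV >= 15% across replicates in any sample), and runs the same paired
binomial/Stouffer statistic with transitions acting as peptides.
"""

import numpy as np
import pandas as pd

import pairprot as pp

rng = np.random.default_rng(7)
rows = []
transitions = {
    # transition -> (protein, true case:control fold, replicate jitter CV)
    "T1_y7": ("PKM", 2.0, 0.05),
    "T2_y5": ("PKM", 2.2, 0.05),
    "T3_y6": ("ALDOA", 1.0, 0.30),  # irreproducible: should fail the CV filter
}
for subj in [f"S{i}" for i in range(1, 7)]:
    base = rng.uniform(0.8, 1.2)
    for cond in ("case", "control"):
        for rep in (1, 2):
            for tid, (prot, fold, cv) in transitions.items():
                level = base * (fold if cond == "case" else 1.0)
                area = 100 * level * (1 + rng.normal(0, cv))
                rows.append(
                    dict(peptide=f"PEP_{tid}", protein=prot, transition=tid, subject=subj,
                         condition=cond, replicate=rep, area=max(area, 1.0),
                         is_global_standard=False)
                )
            rows.append(
                dict(peptide="STD", protein="GS", transition="G1", subject=subj,
                     condition=cond, replicate=rep, area=50 * (1 + rng.normal(0, 0.02)),
                     is_global_standard=True)
            )
records = pd.DataFrame(rows)

normalized = pp.normalize_to_global_standards(records)
kept, summary = pp.cv_filter(normalized, max_cv=0.15)
print("CV filter summary (worst per-sample replicate CV):")
print(summary.to_string(index=False))

result = pp.srm_paired_analysis(kept)
print("\nProtein report on retained transitions:")
print(result.proteins[["accession", "p_value", "k", "direction"]].to_string(index=False))
print(
    "\nTransitions reproducible across duplicate injections survive the 15% CV cap;\n"
    "a protein p-value < 0.05 confirms higher abundance on the case side."
)
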