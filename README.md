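# pairprot

Paired, peptide-centric differential abundance for label-free shotgun
proteomics.

## The problem

Biofluid proteomes — the motivating case is nipple aspirate fluid (NAF)
collected from both breasts of patients with unilateral breast cancer —
show inter-individual variability that is often larger than the disease
effect itself. Conventional group-mean comparisons (t-test + fold-change +
FDR) then find nothing: the between-patient spread swamps the signal. When
each patient contributes a matched pair of samples (diseased and
contralateral healthy breast), the pairing can cancel the patient-specific
scale, and a simple sign statistic becomes remarkably powerful.

`pairprot` is for proteomics researchers with paired label-free XIC
quantitations (long-format TSV export) who want a peptide-centric paired
analysis, plus the machinery around it: TIC normalization, quality filters,
a control-cohort false-positive exclusion, NIAF abundance ranking,
replicate-CV filtering for targeted (SRM) verification data, an unpaired
baseline for contrast, and a synthetic paired-cohort generator for
benchmarking.

## The statistic

For each proteotypic peptide and each subject *i*, the pair of
TIC-normalized XIC areas is coded as one of four states: a case:control
ratio when quantified in both samples, `+` (case only), `-` (control
only), or `0` (absent). Every non-absent subject is a Bernoulli trial;
"success" means higher abundance on the case side (ratio > 1 or `+`).
Under the null of no disease association each trial succeeds with
probability ½, so the peptide p-value is the exact binomial upper tail

$$p = P(X \ge x) = \sum_{j=x}^{n} \binom{n}{j} \left(\tfrac12\right)^n$$

with *n* trials and *x* successes. Small *p* (e.g. < 0.025) links the
peptide to the case condition; large *p* (> 0.975) to the control side.
Peptide p-values of a protein are combined by weighted Stouffer Z,

$$Z = \frac{\sum_{i=1}^{k} w_i Z_i}{\sqrt{\sum_{i=1}^{k} w_i^2}},
\qquad Z_i = \Phi^{-1}(1 - p_i), \qquad w_i = \sqrt{n_i},$$

and mapped to the one-sided protein p-value $p = 1 - \Phi(Z)$.

## Worked example

```
python examples/worked_example.py
```

runs the pipeline on the bundled ten-subject, three-peptide demonstration
table and prints:

```
Peptide report:
   peptide accession  x  n  p_value  avg_log2_fold
   YLYEIAR    P00002  2 10 0.989258      -1.508798
LVNEVTEFAK    P00001  3  5 0.500000      -0.363618
  AEFAEVSK    P00003  6  6 0.015625       1.667617

Protein report:
accession  p_value         z  k       direction
   P00003 0.015625  2.153875  1         case_up
   P00001 0.500000  0.000000  1 not_significant
   P00002 0.989258 -2.299362  1      control_up
```

`LVNEVTEFAK` was informative in 5 of 10 subjects with 3 successes —
P(X ≥ 3) = 0.5, no evidence either way. `AEFAEVSK` succeeded in all 6
informative subjects — P(X ≥ 6) = 1/64 ≈ 0.016 < 0.025, a case-linked
peptide with a mean 2^1.67 ≈ 3.2-fold elevation. `YLYEIAR` succeeded in
only 2 of 10 — p = 0.989 > 0.975, control-linked. With one peptide per
protein, the Stouffer roll-up passes these p-values through unchanged.

Other narrative scripts in `examples/`: `simulate_and_recover.py` (paired
statistic vs unpaired baseline on a heterogeneous cohort),
`srm_validation.py` (global-standard normalization, replicate-CV filter,
paired re-analysis of transition areas), `niaf_ranking.py` (protein
abundance ranking).

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch through the full pipeline on the bundled
demonstration table, the exact binomial p-value of the peptide whose
per-subject coded row is (0, +, 0, 0, 0, 0.19, 0.86, 1.37, 1.63, 0), and
writes it as JSON.

See `docs/methods.md` for the model, its assumptions, the synthetic-data
generator, numerical choices, and known limitations (including the
anti-conservative control-side tail of the discrete statistic).
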