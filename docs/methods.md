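# Methods

## Model and procedure

`pairprot` tests, peptide by peptide, whether a protein is more abundant in
the case member of paired samples than in its matched control. The
procedure, in pipeline order:

1. **TIC normalization.** Each XIC area is divided by its run's total ion
   current (the sum of all areas in that run), correcting loading and
   response differences between injections. Normalized areas of one run sum
   to 1; the operation is idempotent.
2. **Quality filters.** Records need (a) at least 6 sequential MS1
   precursor measurements in the XIC (a minimally sampled chromatographic
   peak; inclusive bound), (b) optionally an allowed precursor charge
   (typically +2/+3), and (c) a proteotypic peptide — one mapping to exactly
   one protein accession. Filters commute; records missing the optional
   annotations pass through with a warning.
3. **Per-subject coding.** For each peptide, each subject's pair of
   normalized areas becomes one of four states: `Ratio(case/control)` when
   quantified in both samples, `CaseOnly` (+) / `ControlOnly` (−) when
   quantified in one, `Absent` (0) otherwise. A zero area is "not
   obtained". Multiple charge states / repeat runs per subject are merged
   before coding (sum of areas by default; best charge optionally).
4. **Exact binomial peptide p-value.** Non-absent subjects are Bernoulli
   trials; success = ratio > 1 or `+` (a ratio of exactly 1 is a failure).
   Under the null each trial succeeds with probability ½ and
   p = P(X ≥ x) = Σ_{j=x}^{n} C(n,j)/2ⁿ, computed as an exact integer sum
   (no normal approximation). The *inclusive* upper tail is used: it is the
   convention that reproduces the published worked numbers for this
   method, and it makes the low tail conservative (see Limitations for the
   flip side).
5. **Average log2 fold.** Mean of log2(ratio) over ratio codes only;
   one-sided and absent codes carry no fold information. Undefined (NaN)
   when no subject had the peptide in both samples.
6. **Stouffer protein roll-up.** Z_i = Φ⁻¹(1 − p_i), w_i = √n_i,
   Z = Σw_iZ_i / √(Σw_i²), protein p = 1 − Φ(Z). Weights reflect how many
   subjects informed each peptide; the combination is invariant to common
   rescaling of the weights.
7. **Classification.** p < α_low ⇒ case-abundant; p > α_high ⇒
   control-abundant; defaults α_low = 0.025, α_high = 0.975 (targeted SRM
   verification conventionally relaxes to 0.05/0.95).
8. **Control-cohort exclusion.** Proteins significant in a
   control-vs-control comparison (paired healthy samples, where no true
   differences should exist) are removed from the case-significant set —
   a pragmatic false-positive guard.

Assumptions: peptides of a protein are treated as independent evidence
(they share the protein's true effect but their measurement errors are
assumed independent); subjects are independent; the coding discards
magnitude information by design, buying robustness to per-patient scaling
at the cost of efficiency when magnitudes are trustworthy.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `min_points` | 6 | minimum sequential MS1 measurements per XIC (count) |
| `allowed_charges` | off | precursor charges retained when annotated |
| `fold_gate_mode` / `min_fold` | off / 1.5 | optionally re-code ratios inside (1/1.5, 1.5) as absent |
| `alpha_low` / `alpha_high` | 0.025 / 0.975 | symmetric one-sided call thresholds |
| `charge_merge` | sum | merge rule for charge states/runs per subject (sum or best) |
| SRM `max_cv` | 0.15 | replicate CV cap, sample sd (n−1), per transition per sample |

The fold-change gate defaults **off** because the published worked coding
counts ratios of 1.06 and 1.15 as successes — the 1.5-fold requirement in
the upstream acquisition pipeline is evidently an XIC-extraction quality
rule, not part of the statistic. It is provided for users who want it; the
per-peptide and per-extraction interpretations are both reachable
(`fold_gate_mode="neutralize"` vs pre-filtering), neither asserted.
Whether the replicate-CV rule should hold in every sample or pooled across
samples is likewise not settled; per-sample-all is the default, pooled a
flag.

## Synthetic cohorts

The generator produces paired datasets from a log-normal intensity model:
log2 area = protein base (N(20, 2)) + peptide ionization offset (N(0, 1)) +
subject-protein heterogeneity (N(0, `subject_scale_sd`), shared by both
samples of a subject) + disease effect (`effect_log2fold` on the case
sample of affected proteins) + measurement noise (N(0,
`peptide_noise_sd`)). Areas are scaled per run by a lognormal TIC factor
and left-censored below `detection_threshold` (2¹⁶ against the 2²⁰ base,
censoring roughly the bottom 5%), which is what generates `+`/`−`/absent
codes mechanistically. Defaults: 10 subjects, 100 proteins with 3–8
peptides, 10% affected at +1.5 log2, heterogeneity SD 1.0, noise SD 0.5.
Presets: `homogeneous` (heterogeneity 0.3), `heterogeneous` (3.0 — patient
spread exceeding the effect, the regime that defeats group-mean testing),
`null` (no effect anywhere).

Heterogeneity is a per-(subject, protein) offset, not a per-subject
scalar: a global per-subject scale would be removed exactly by TIC
normalization and could not reproduce the between-patient protein
variability that motivates the paired design.

What the generator does **not** emulate: correlated peptide errors within
a protein, retention-time or identification artifacts, interference,
intensity-dependent noise, and real secretome abundance distributions. A
green simulation test therefore establishes the statistic's behaviour
under its own model assumptions, not performance on real data.

## Numerical choices

- Binomial tails are exact integer sums (`math.comb`), cached per (x, n).
- Peptide p-values are clamped to [1e−15, 1−1e−15] before Φ⁻¹, bounding
  Z_i at ±7.94; this guards overflow for all-success / all-failure
  peptides without changing any ranking.
- Ties at ratio exactly 1 (possible after floating normalization) count as
  failures, matching the strict "greater than 1" success rule.
- Report rows are sorted ascending by protein p-value with a stable sort;
  reports are byte-deterministic for identical inputs.
- No multiple-testing correction is applied to the Stouffer p-values (the
  method is used as published); a Benjamini–Hochberg column is emitted for
  information, and the unpaired baseline *does* use BH, as is conventional
  for it.
- Zero-variance groups in the unpaired baseline (degenerate constant data)
  get p = 1 when means coincide, p = 0 otherwise, instead of NaN.
- The NIAF rank-plot transform uses log base 10: −1e7·log10(mean NIAF).

## Known limitations

- **Anti-conservative control side.** The inclusive tail P(X ≥ x) makes
  p < 0.025 conservative but p > 0.975 liberal: at n = 10 the
  control-abundant call fires for x ≤ 2, which has null probability
  0.0547. Propagated through Φ⁻¹ and Stouffer (Var(Z_i) ≈ 1.2 at n = 10,
  and all-failure peptides clamp to Z = −7.94), the two-sided type-I error
  of the protein calls on effect-free simulated cohorts is ≈ 12–15%, not
  5%. The corresponding acceptance test documents this honestly and fails;
  users should treat control-abundant calls at 0.975 as a screen, not a
  calibrated test, or widen α_high.
- **Compositional closure.** TIC normalization maps each run onto shares
  summing to 1. Strong differential proteins (or, in simulations,
  heavy-tailed abundance with few proteins) shift every other protein's
  ratio in the opposite direction and correlate all peptides of a subject
  pair, further inflating false calls. Real runs, whose total current is
  dominated by stable bulk signal, are less exposed than small synthetic
  cohorts.
- Peptides of one protein are combined as independent; shared
  subject-level censoring and closure violate this mildly.
- The label-swap mirror of the statistic is exact on p-values
  (p′ = 1 − p + P(X = x)) but not on calls: a case call always mirrors to
  a control call, the converse fails for small n.
- The unpaired baseline is a plain Welch-t/BH/fold-cutoff contrast, not a
  reimplementation of any specific tool's adaptive fold criterion.
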