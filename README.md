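# wntpipe

Statistical pipeline for linking a high-throughput RNAi viability screen to
tumour-cohort outcome through an upstream-regulator gene signature, as used
in neuroblastoma Wnt/β-catenin studies. The package covers four analysis
stages, each usable on its own:

1. **Screen statistics** — 384-well plate normalization and hit calling.
   Raw luminescence is log2-transformed, a smooth spatial surface fitted on
   sample wells only (control columns excluded) is removed, and robust
   z-scores are computed against the library-wide per-condition
   distribution. A well is a hit when it lies at least 3 robust SD from the
   library median (the three-sigma rule), with the SD estimated by Huber's
   Proposal 2: the simultaneous location/scale M-estimate in which the data
   are winsorized at μ ± kσ (k = 1.5) inside a fixed-point iteration,

   σ² = Σᵢ min(|xᵢ − μ|, kσ)² / (n·β(k)),  β(k) = E[min(|Z|, k)²].

2. **Inferred transcriptional regulators (ITR)** — each candidate regulator
   in a user-supplied signed, weighted regulator→target network is scored
   against a differential-expression table by (a) the right-tail
   hypergeometric p of the overlap between its targets and the DE genes and
   (b) the activation z-score z = Σwᵢxᵢ/√Σwᵢ², where xᵢ = ±1 records
   whether the target's observed fold-change direction is concordant with
   the edge's predicted sign; |z| ≥ 2 labels the regulator activated or
   inhibited. A direction-less variant ranks regulators against bound-gene
   lists (e.g. ChIP targets).

3. **Signature construction and MYCN correction** — the genes contributing
   to a regulator's ITR calls in ≥ 2 contrasts form a signature with
   majority-vote expected directions. Tumour expression is corrected for
   MYCN by per-probe OLS (y = b0 + b1·MYCN_expr + b2·amplified), removing
   only the expression-level term b1·(m − m̄) in the manner of limma-style
   batch-effect removal; samples are then split into Signature(+)/(−) by
   Ward clustering of the standardized signature probes, and MNA separation
   is tested by one-way ANOVA on the per-sample signature score plus
   per-probe tests with Benjamini–Hochberg control.

4. **Survival statistics** — Kaplan–Meier curves, the log-rank test,
   median-split or best-cutoff-scan expression stratification (the scan
   always reports a Bonferroni-adjusted p over the cutoffs tried), and
   Spearman's ρ with the Student-t approximation for its p-value.

A synthetic-data module generates every input with planted ground truth —
plates with smooth spatial artifacts and spiked gene effects, DE tables
driven by planted regulator activity states, and a 478-sample cohort with a
minority MYCN-amplified subgroup and proportional-hazards survival — so the
whole pipeline is testable without any external download.

## Worked example

The numbered scripts under `analysis/` run the full story on synthetic
inputs (`python analysis/01_simulate_inputs.py --seed 1`, then 02–05).
With the default seed the run prints:

```
induced condition: 27 hits (22 anti-proliferative) of 2000 sample wells
planted spike recall: 100% (20/20 at -6 sigma)
...
planted regulator REG001 per contrast:
           overlap             p         z         state  rank
cellline1       19  5.854563e-22 -4.210520     inhibited     1
...
signature: 20 genes with >= 2-contrast support (20 planted targets)
clustering: Signature(+) n = 125, Signature(-) n = 353, ARI vs planted activity = 1.00
MNA separation: ANOVA F = 1159.7, p = 1.12e-129; 35/35 signature probes DE at p-adj < 0.05
signature groups: log-rank chi2 = 110.9 (df = 1), p = 6.08e-26
Spearman worked example: rho = -0.90, t-approximation p = 0.03739
```

Reading the numbers: all 20 genes spiked six robust SD below baseline are
recalled as anti-proliferative hits while the null wells produce the ~0.27%
two-sided tail expected under the three-sigma rule; the planted regulator
is ranked first and called "inhibited" in every contrast where its activity
was planted; the rebuilt signature splits the cohort into groups that
coincide with the planted high-activity samples (adjusted Rand index 1.0),
separate MYCN-amplified from non-amplified tumours even after MYCN
correction, and stratify survival (hazard ratio 3 was planted). The final
line is the classic five-point Spearman example: ρ = −0.9 at n = 5 gives a
two-sided t-approximation p of 0.0374.

Library functions are also exposed as a CLI (`wntpipe normalize-screen`,
`call-hits`, `itr`, `build-signature`, `correct-mycn`, `cluster-signature`,
`stratify`, `correlate`, `simulate`, `run`); `wntpipe run` executes the full
synthetic pipeline from one YAML config and writes a provenance record.

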