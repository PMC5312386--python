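# Methods

This note records the models, defaults and design decisions behind each
pipeline stage, what the synthetic generators do and do not emulate, and
the numerical choices that matter for reproducing results.

## Plate normalization

A 384-well plate is modelled as a 16 × 24 grid (rows A–P ↔ 1–16, columns
1–24). The outermost columns 1, 2, 23 and 24 are treated as control lines
and excluded from every fit, scale estimate and hit distribution; controls
still receive normalized values. The "rows 1–2 and 23–24" of screen
protocols are interpreted as *columns* of the standard orientation, since
indices up to 24 can only address columns; the excluded set is
configurable.

Normalization works on log2 signal. Per plate and per induction condition
a smooth surface f(row, col) is fitted to the sample wells and the
centred surface is subtracted:

    normalized = log2(raw) − (f − median(f over fitted wells)),

which preserves the plate median exactly. Two surface models are
available:

- **`polynomial` (default)** — OLS on the tensor-quadratic basis
  {1, r, c, r², c², rc} in centred coordinates, with one outlier-trimming
  pass: wells whose initial residual exceeds 3.5 robust SD are dropped and
  the surface refitted, so genuine biological effects (hits) do not steer
  the artifact estimate. Because an OLS fit is an orthogonal projection,
  normalization is idempotent to machine precision — renormalizing a
  normalized plate changes nothing — and a quadratic captures the
  low-order gradients and bowl/dome shapes that dominate real dispensing
  and evaporation artifacts.
- **`loess`** — classic tricube-weighted local linear regression over the
  grid with neighbourhood fraction `span` (default 0.7). More flexible,
  but a local smoother is not a projection, so repeated application keeps
  shrinking structure; it is offered for plates with artifacts a global
  quadratic cannot express.

Degenerate layouts (fewer than 10 usable sample wells) are an error rather
than a silent bad fit.

## Robust z-scores and Huber's Proposal 2

Library z-scores use the median and the normal-consistent MAD
(× 1.4826) of all normalized sample wells per condition, pooled across
plates ("the median of all samples"); a per-plate scope is available
behind a flag. Hit calling uses the same distribution: hit ⇔
|x − median| ≥ 3σ̂, boundary inclusive, with direction by sign
(anti-proliferative below the median).

σ̂ is Huber's Proposal 2: fixed-point iteration of μ ← mean of the data
winsorized at μ ± kσ and σ² ← Σ(win − μ)²/(n·β(k)), with k = 1.5 and
β(k) = 2Φ(k) − 1 − 2kφ(k) + 2k²(1 − Φ(k)) evaluated in closed form from
the standard normal so the estimate is consistent for the Gaussian SD.
Iteration starts at (median, 1.4826·MAD), stops when both parameters move
by < 1e-8, and raises after 200 iterations carrying the last iterate. At
k → ∞ the estimate reduces to the classical mean and (ddof = 0) SD; the
test suite verifies agreement with an independent root-solve of the two
estimating equations to 1e-8.

Fewer than 50 sample wells triggers an unstable-scale warning, not an
error.

## ITR scoring

The regulator network is an input (TSV of signed, weighted edges); no
proprietary knowledge base is reproduced or required. The DE set is
`padj ≤ 0.05` by default; the background is the measured universe (all
genes in the DE table), not the network's gene space. The overlap p is
the right-tail hypergeometric probability; the activation z is the
uncorrected concordance score Σwx/√Σw² — the bias-correction terms of
commercial implementations are not published and are deliberately not
imitated. Genes below the DE threshold contribute to neither concordance
nor discordance; edges with unknown sign count toward the overlap but not
the z. A regulator with no usable edge is "undetermined" (z undefined,
not 0). Ties in the overlap p are broken by |z| (descending, undefined
last) then by regulator id, making ranks deterministic.

## Signature construction and MYCN correction

A signature keeps the regulator's contributing genes supported by
≥ 2 contrasts (`min_contrasts`); the expected direction is the majority
observed DE direction, with ties mapped to "unknown". Unknown-direction
genes enter the clustering (unsigned) but not the per-sample score.

MYCN correction fits, per expression row, OLS of y on MYCN log2
expression and amplification status, then subtracts only the
expression-level effect b1·(m − m̄); the amplification effect is retained
by construction, and the partial R² of the MYCN-expression term (RSS
reduction against the amplification-only model) is reported per row.
Centring on m̄ keeps row means unchanged and makes correction idempotent:
refitting on a corrected matrix returns b1 ≈ 0. Near-collinearity of the
two covariates (condition number > 1e8) triggers a warning; constant rows
get zero coefficients.

The Signature(+)/(−) split uses Ward linkage on Euclidean distances over
per-probe standardized values, cut at the top merge. Polarity is assigned
by the direction-aligned mean score — the group scoring higher is
Signature(+) — so labels are reproducible regardless of cluster
enumeration order. The MNA separation "F-test" is implemented as one-way
ANOVA of the composite signature score by amplification status (df 1,
n − 2), the construction consistent with a single printed p-value;
per-probe two-sample t tests with Benjamini–Hochberg adjustment flag
individually separating probes.

## Survival

Kaplan–Meier estimation and the log-rank test are delegated to lifelines
(product-limit estimator; hypergeometric variance with ties pooled at
each event time); the six-subject hand-computed oracle in the test suite
pins the exact statistic (χ² = 121/99). Expression stratification
defaults to the median split. The best-cutoff scan — the approach of
interactive genomics platforms — evaluates every cutoff leaving ≥ 10% of
samples per side and always reports the Bonferroni-adjusted p next to the
minimal raw p, because the minimal p alone is strongly anti-conservative.
Spearman's ρ uses midranks and the two-sided p from
t = ρ√((n−2)/(1−ρ²)) on n − 2 df; ρ = ±1 returns the limiting p = 0.

## Synthetic data

Generators are pure functions of their parameters and a seed, and emit
exactly the formats the analysis reads.

- **Screen**: log2 signal = baseline (10, i.e. ~1000 luminescence counts)
  + planted surface + spike + N(0, noise_sd). The surface is a random
  quadratic with coefficients ~ U(−1, 1) scaled by `gradient_amplitude`
  and *centred to zero median* per plate — artifacts are spatial, plate
  offsets are not planted. Genes are scattered over sample wells by a
  seeded permutation (an arrayed library does not confound gene identity
  with position); spikes are specified in units of the noise SD; control
  wells sit at the constant baseline. Defaults: 2,000 genes, amplitude
  1.0, noise 0.3, two conditions.
- **Contrasts**: targets of an active regulator shift by
  state·sign·effect_mu (default 2.0), everything else is N(0, 0.5).
  Adjusted p-values are assigned rank-consistently with |log2FC| so that
  ~5% of non-targets pass 0.05 — the consuming statistic needs only DE
  membership and direction, so no full testing pipeline is simulated.
- **Cohort**: n = 478 with 20% MYCN-amplified, echoing the shape of
  published neuroblastoma microarray cohorts. MYCN expression is
  N(11, 1) in amplified vs N(8, 1) in non-amplified samples. The latent
  activity is binary: 1 in every amplified sample plus a 5% fraction of
  non-amplified ones (the signature should capture MNA tumours plus an
  extra high-activity group), 0 elsewhere. Signature probes follow
  direction·activity·effect + b1·MYCN + N(0, 0.5) with per-gene
  b1 ~ U(0.5, 1.5); about half the genes get a second probe (many-to-one
  probe→gene maps are the microarray norm). Survival is
  proportional-hazards exponential (Weibull shape exposed) with baseline
  median 1,500 days and a default hazard ratio of 3 per activity unit;
  uniform censoring is calibrated by bisection to the requested censored
  fraction (default 30%).

What the generators do **not** emulate: probe-level microarray noise
models, copy-number structure, batch effects, siRNA off-target effects,
or correlated gene-gene noise. Passing tests therefore demonstrate the
statistics recover planted structure under clean additive-Gaussian
conditions, not performance on raw platform data.

## Problem sizes and determinism

Every source of randomness is an explicit seed argument; identical seeds
give byte-identical outputs. The test suite and the acceptance script use
the study-scale defaults where they are cheap (478-sample cohorts,
2,000–10,000-well screens) and replicate counts of 50–200 seeds for the
Monte Carlo calibration checks; these sizes keep a full run in the
low minutes on one CPU while leaving the Monte Carlo error well below the
asserted margins.

## Known limitations

- The quadratic default cannot remove high-frequency spatial artifacts
  (e.g. single-row dispenser failures); use `surface="loess"` or inspect
  the per-plate QC output for those.
- The activation z-score is the plain concordance statistic; published
  commercial scores additionally apply unpublished bias corrections, so
  numeric values are comparable only in calibration, not one-to-one.
- The scan stratification adjusts by Bonferroni over the tried cutoffs,
  which is conservative under the strong dependence of neighbouring
  cutoffs; a permutation-calibrated minimum-p is a possible refinement.
- Survival handles one endpoint; competing risks and multivariable (Cox)
  modelling are out of scope.
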