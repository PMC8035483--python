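# Methods

This package implements a graph-theoretical analysis of resting-state
functional connectomes for a three-group clinical design (end-stage renal
disease with cognitive impairment, CI; without, NCI; healthy controls, HC),
together with a synthetic-cohort generator that makes every stage testable
against known ground truth.

## Analysis model

Each subject contributes a T x N matrix of region-averaged BOLD signals
(defaults: T = 240 volumes at TR = 2 s, N = 90 atlas regions; 230 volumes
after discarding the first 10).  The pipeline is:

1. **Signal cleaning** — discard, linear detrend, nuisance regression
   (Friston-24 motion expansion: 6 rigid-body parameters, their one-volume
   lags, and both sets squared), zero-phase order-4 Butterworth band-pass to
   0.01–0.08 Hz, and a closing detrend that guarantees exactly trend-free
   output.  Volumes whose framewise displacement
   FD(t) = Σ|Δtranslation| + 50 mm · Σ|Δrotation (rad)| exceeds 0.5 mm are
   flagged and dropped before covariance estimation (no neighbour
   augmentation; threshold and head radius configurable).  Subjects moving
   more than 1.0 mm or 1.0° anywhere in the scan are excluded outright.
   Regression precedes filtering so that nuisance fit does not reintroduce
   out-of-band variance.

2. **Connectivity** — the N x N partial-correlation matrix
   pcorr(i,j) = −Ω̂ᵢⱼ/√(Ω̂ᵢᵢΩ̂ⱼⱼ), where Ω̂ is the inverse of the
   shrinkage-regularized sample covariance (1−a)·S + a·diag(S).  Binary
   networks retain the E = round_half_up(S·N(N−1)/2) edges of largest
   |pcorr| at sparsity S, ties broken by ascending (row, column) index, so
   edge sets are nested across thresholds.

3. **Topology** — clustering coefficient Cp, characteristic path length Lp
   (mean over connected ordered pairs; unreachable pairs are excluded from
   Lp but contribute 0 to efficiencies, and the component count is always
   reported), global and local efficiency, nodal degree, nodal efficiency,
   and betweenness normalized by (N−1)(N−2)/2.  Small-world normalizations
   γ = Cp/⟨Cp_null⟩, λ = Lp/⟨Lp_null⟩, σ = γ/λ use degree-preserving
   Maslov–Sneppen double-edge-swap nulls (defaults: 100 nulls, 10 swaps per
   edge, attempt cap 10× the swap target; the cohort pipeline uses 20 nulls
   per grid point — see *Problem sizes*).  σ is estimable when the null
   means of Cp and Lp are finite and positive and λ > 0.

4. **Sparsity sweep** — the analysis range is the largest contiguous run of
   candidate grid points (default 0.05–0.50, step 0.01) on which σ is
   estimable and exceeds 1.0 for **every** subject.  Each metric's curve
   over the selected range is reduced to a trapezoidal area-under-curve
   scalar, giving one threshold-independent number per subject per metric
   (nodal metrics included).

5. **Statistics** — three-group comparison of each AUC by ANCOVA (linear
   model y ~ intercept + covariates + group; extra-sum-of-squares F on the
   group dummies; Bonferroni-corrected pairwise contrasts on adjusted
   means).  Default covariates are age and sex.  Exploratory partial
   correlations (residualizing on age, sex, education) relate the
   significant regions' nodal AUCs to cognition scores within the CI group,
   with Benjamini–Hochberg FDR across the family.  Demographic tables use
   the chi-square test (no continuity correction), one-way ANOVA, and
   two-sample t tests; the t variant (pooled or Welch) is always an explicit
   per-call parameter because published tables rarely state which was used.

### Why eGFR is not a default covariate

The estimated glomerular filtration rate separates dialysis patients
(~8 mL/min/1.73 m²) from healthy controls (~105) almost perfectly, so it is
near-collinear with the patient-vs-control dummies; adjusting for it
absorbs the very contrast under test (measured on the default cohort, the
σ-AUC group F collapses from p < 10⁻⁴ to p ≈ 0.08).  A covariate that codes
group membership is not a confounder, so the default adjustment set is age
and sex; eGFR can be re-enabled in the run configuration for designs where
it varies within groups.

### Shrinkage default (0.8)

With a 0.01–0.08 Hz band-pass at TR = 2 s, ~230 volumes carry only about
2·T·TR·bandwidth ≈ 64 effective temporal degrees of freedom — fewer than
the 90 regions being conditioned on.  At light shrinkage the precision
estimate is noise-dominated, and the noise is not node-uniform: a node
whose true edges are weak has more unexplained variance, inflating its
estimated partial correlations, so under global edge ranking its lost true
edges are replenished ~1:1 by spurious ones and nodal degree carries no
signal.  At heavy shrinkage the estimator approaches a regularized
marginal-correlation ranking with node-uniform noise, where weakened nodes
genuinely lose rank.  The default a = 0.8 was chosen by parameter recovery
against the generator's ground truth: it maximizes seeded-region recovery
(6/7 at 0.8, 0/7 at ≤ 0.65) while keeping diffuse secondary effects in
check (non-seeded significant regions triple at 0.9).  Ledoit–Wolf-style
shrinkage (~0.15 here) minimizes covariance Frobenius loss, which is not
the edge-ranking objective, and was rejected as the criterion.  The value
is recorded in every connectivity matrix and is configurable.

## Synthetic cohort

The generator defines the study conditions: 36 CI / 30 NCI / 48 HC
subjects, 240 volumes, TR 2 s, 90 regions with AAL-style labels (78
cortical + 12 subcortical; packaged label table).

**Ground truth.**  Each group has a Gaussian graphical model built from one
shared wiring seed: six 15-region modules wired as graded rings (strong
links to the two nearest module neighbours, base magnitude 0.28 in the
precision; 0.8× links two steps away closing triangles; two random chords
per module) plus sparse between-module shortcuts (0.25×, ~1.5 per node).
The diagonal is loaded to 0.1 above each row's unattenuated absolute sum,
guaranteeing strict diagonal dominance (verified by Cholesky, never
repaired).  Implied partial correlations of the backbone are ≈ 0.19–0.27 —
comfortably above the ≈ 0.08 sampling noise of a 230-volume scan — and the
grading matters: spreading the same total weight over six equal partners
caps every implied partial correlation near 1/k and nothing survives
estimation.

The seven seeded default-mode regions (SFGmed.L/R, PCG.L, ANG.L, PCUN.R,
AMYG.R, HIP.R) are built as connector hubs, as their anatomical
counterparts are: their incident weights are boosted ×1.8 and each receives
six extra between-module links at 0.5× base.  The hub baseline is what
makes an attenuation of these nodes visible as *decreased* nodal centrality
throughout the analysis range — without it the contrast exists only at the
sparsest thresholds and is diluted away by the AUC integration over the
selected range.

**Group differences.**  Precision entries incident to the seeded regions
are multiplied by (1 − attenuation): 0 for HC, 0.3 for NCI, 0.6 for CI,
with per-subject jitter (s.d. 0.15, clipped to [0, 0.9]).  Because the
diagonal uses the unattenuated row sums, implied partial correlations of
seeded edges scale exactly by (1 − attenuation) while all others are
untouched.

**Signals.**  AR(1) series (coefficient 0.3, BOLD-like smoothness) whose
innovations have covariance Ω⁻¹, scaled so the stationary spatial
covariance equals Ω⁻¹ exactly.  Motion traces are clipped random walks well
under the QC limits, with planted 0.6 mm step "spikes" (Poisson mean 1 per
subject) that each trip the 0.5 mm FD threshold at exactly one volume —
recorded per subject so scrubbing can be tested against ground truth.

**Phenotypes.**  Ages ~ N(31.5, 7.5²) truncated to 18–45, education
~ N(11.3, 2.7²), sex ~ Bernoulli(0.64 male) — all group-common, matching a
demographically matched design.  eGFR ~ N(8, 3²) truncated > 2 for patient
groups and N(105, 12²) for controls (the source design reports no GFR
values, so these ranges are generator decisions).  MoCA is drawn per group
(CI clipped ≤ 25, others ≥ 26, enforcing the MoCA < 26 classification rule
exactly).  Timed tests (TMT-A/B) and SDMT are linear in the subject's
standardized true DMN nodal strength — the row sum of |implied pcorr| at
the seeded nodes — with coupling ±0.5 and group means/s.d.s from the
published cohort table, targeting within-CI correlations of |r| ≈ 0.4–0.5
between scores and *true* DMN strength.  MoCA is deliberately uncoupled.
Note that correlations between scores and the *estimated* nodal AUCs are
substantially weaker (ceiling ≈ 0.2–0.3): with 230 band-limited volumes the
estimation noise dominates the within-group spread of the true strengths.
This is a property of the study conditions, not a bug — the exploratory
correlation stage therefore reports mostly sub-threshold q values on
synthetic cohorts.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: no volumetric images or hemodynamic forward
model; no physiological (cardiac/respiratory) noise, scanner drift beyond a
linear trend, or spatially correlated motion artefacts; Gaussian signals
(no BOLD non-linearity); a single fixed wiring shared by all subjects apart
from the seeded attenuation; and cognition scores generated directly from
the latent network truth rather than through any cognitive model.

## Numerical choices

- Round-half-up edge counts (0.10 × 4005 = 400.5 → 401) — documented
  because the half-integral case actually occurs at N = 90.
- Deterministic seeding throughout: every stochastic element derives its
  seed from SHA-256 of (master seed, stage label, subject id, grid point),
  so any single cell of the sweep is reproducible in isolation and results
  are independent of evaluation order; re-running a configuration
  reproduces every output byte-identically.
- Cp is accumulated over sorted per-node values so node relabeling changes
  nothing, not even the last bit.
- Rewiring that finds no legal swap (e.g. a complete graph) returns the
  input with a warning recording the swap deficit rather than failing.
- ANCOVA rank deficiency and collinear nuisance regressors raise errors
  naming the offending columns; constant (zero-variance) nuisance columns
  are silently dropped since the intercept spans them.

## Problem sizes

The cohort-scale runs (the pipeline defaults, the acceptance script, and
the end-to-end tests) use 20 null networks per (subject, grid point) and a
0.05–0.50 candidate grid at step 0.01; one full run of the 114-subject
pipeline takes roughly 6–8 minutes on one core.  Single-network analyses
default to 100 nulls.  The null count enters only the Monte-Carlo error of
γ and λ (a few percent at 20 nulls), not any systematic term.

## Known limitations

- With 230 band-limited volumes and 90 regions the connectivity estimates
  are heavily regularized; nodal degree contrasts are only interpretable
  because the estimator was chosen for ranking stability (see above), and
  group comparisons of single-region metrics remain noisy (expect false
  positives at the nominal α across 270 region × metric tests — the run
  report makes no multiplicity correction at the region-selection step, as
  region selection feeds an exploratory correlation analysis).
- The σ > 1 selection rule typically returns a low-sparsity range
  (~0.05–0.15) for these synthetic cohorts; denser networks lose their
  small-world margin to estimation noise.  All AUCs are therefore
  integrals over a narrower range than the 0.1–0.34 often seen with real
  cohorts, and their absolute scale is not comparable across ranges.
- Local efficiency and betweenness are computed exactly, not approximated;
  runtime grows quickly beyond a few hundred regions.
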