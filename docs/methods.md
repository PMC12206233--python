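# Methods

This note documents the models, conventions and design choices behind
`natpipe`, in the spirit of the methods documentation of packages like
statsmodels or msprime: what is computed, under which assumptions, which
knobs matter, and what the synthetic validation does and does not show.

## Graph construction

**Connectivity.** ROI-to-ROI connectivity is the Fisher transform
`z = arctanh(r)` of the Pearson correlation between ROI time series.
Correlations are clamped to ±(1 − 1e−7) before the transform so duplicated
series produce a large finite value instead of infinity; the diagonal is
forced to zero and the matrix symmetrized against floating-point drift. A
zero-variance ROI series is rejected with the ROI named — silently
propagating NaNs through a 300×300 matrix is the failure mode this guards
against.

**Proportional thresholding.** At density `d`, exactly
`round_half_up(d · N(N−1)/2)` upper-triangular entries are kept and set to
1. Edges are ranked by *signed* weight by default — the convention of the
standard connectome toolboxes, where a strongly negative correlation is
not a "strong" connection; ranking by magnitude is available via
`rank="abs"`. Ties at the cut are broken by ascending (row, column) index,
which makes the graph a pure function of the matrix. Round-half-up is
computed with a relative epsilon of 1e−9 because binary floats place
products like 0.35 × 44850 just below the half-way point. Density is
controlled **per network**: each subnetwork's own submatrix is thresholded,
rather than inducing the subnetwork from the thresholded whole-brain
graph. The two differ (a test demonstrates it), and per-network control is
what makes density a meaningful covariate in the models.

**Global efficiency and attack.** GE uses unweighted BFS distances;
disconnected pairs contribute zero, and `GE = 0` when `N ≤ 1` (the
efficiency of nothing is nothing, and it avoids 0/0). The attack removes
the highest-degree node of the *surviving* subgraph at every step
(adaptive targeting, the standard in the robustness literature), ties to
the lowest index; a `mode="static"` variant ranks once on the intact graph
for sensitivity analyses. GE of a surviving subgraph uses the surviving
node count as `N`. NAT is the mean of the `N` curve values (intact graph
plus `N−1` removals); with this normalization a graph that held GE = 1
through every attack scores exactly 1, making "fraction of maximum
possible efficiency retained" literal. The all-pairs BFS inner loop is
numba-compiled; an attack on a 300-node, 50%-density graph costs ~2 s, and
the whole-cohort attack stage a few minutes.

**tSNR.** Per ROI, temporal mean over temporal SD (unbiased SD); the scan
summary is the mean over ROIs, with zero-SD ROIs reported as undefined and
excluded with a warning. Used to check that scan quality is even across
the three acquisition sequences.

## Behavior scores

WEE (see README for the formula) is evaluated exactly; the 12–19 period
(recall bias) and the 50+ period (post-diagnosis activity) are parsed and
validated but never scored. Composites are **sums** of per-test z-scores
(a mean mode exists): the observed spread of the motor composite across a
~5-test battery is consistent with a sum, and sums keep per-test
contributions legible. Duration-type tests are negated **before**
z-standardization, which is algebraically identical to negating the
z-score and is the easiest variant to audit. The healthy-control reference
uses the unbiased (n−1) SD, appropriate for a 39-person reference sample;
a test with zero HC variance is excluded with a warning rather than
dividing by zero. Education enters all models as raw years.

## Statistical models

**Beta GLMM.** NAT is a fraction strictly inside (0, 1) measured nine
times per participant, so the first-stage model is

    y_ij | u_i ~ Beta(μ_ij φ, (1 − μ_ij) φ),   logit(μ_ij) = x_ij'β + u_i,
    u_i ~ N(0, σ_u²)

fitted by marginal maximum likelihood with 21-point Gauss–Hermite
quadrature (the integrand is one-dimensional and smooth; 21 points are
ample for σ_u well below 1). Slope columns are standardized internally for
optimization — covariates span four orders of magnitude — and estimates
and covariance mapped back exactly. Standard errors come from the inverse
numerical Hessian at the optimum; inference is Wald. Responses touching
0/1 are nudged into (ε, 1−ε), ε = 1e−6, with a warning. The reported
explained-variance slot is the explained deviance
`1 − D_model / D_null` at the fitted precision, with an intercept-only
fixed-effects null (no random intercept), so participant-level structure
counts as explained — the convention of the R packages usually used for
this model family. Known property, verified by simulation in the test
suite: the Wald SEs of *between-participant* covariates (age, sex, DaT,
PA, education, sequence) run anticonservative with only 22 clusters,
while the within-participant density slope is well calibrated (94–97% CI
coverage over 100 replicates). Conclusions about between-participant
effects at this sample size deserve the same caution the original pilot
setting does.

**Moderation and Johnson–Neyman.** Second-stage models are OLS with an
interaction (`outcome ~ NAT * moderator + controls`), complete cases only,
female and sequence-1 reference levels, and an explicit rank check that
names collinear columns (a constant moderator being the canonical way to
hit it). The JN region solves `|b₁ + b₃w| / SE(w) = t_crit` with
`SE(w)² = V₁₁ + 2w V₁₃ + w² V₃₃` — a quadratic in `w` — using the
residual degrees of freedom of the moderation model, and reports
significance intervals clipped to the observed moderator range, with
"everywhere"/"nowhere" stated explicitly when no interior boundary exists.
Boundaries agree with a 10⁵-point grid-search oracle to 4 decimals, and
the recomputed p-value at each boundary equals α to machine precision. No
multiple-testing correction is applied across the five network models
(α = 0.05 per test, matching the analysis convention this pipeline
implements).

## The synthetic cohort generator

The generator emulates the study conditions the pipeline assumes: 22 PD
(age 62.1 ± 8.0, education 15.8 ± 2.7 y, putaminal DaT z −3.6 ± 0.7,
15/22 male) and 39 HC (63.5 ± 6.5, 16.7 ± 2.8, 26/39 male); lifetime PA
log-normal with location log 58.3 and scale 0.85 (matching the reported
ratio of spread to centre — PA is nonnegative and strongly right-skewed);
fMRI sequences allocated 4/17/1 by largest-remainder apportionment (so the
study split is reproduced exactly at n = 22) with 740/500/740 volumes.
One PD participant's cognitive battery is marked missing, so the GCP
models run on n = 21.

**Time series.** Multivariate normal draws on a baseline level of 100,
with a correlation matrix built from a global factor (r = 0.05 between
blocks), one factor per subnetwork and a core factor: each subnetwork has
a tightly coupled core (half its ROIs, r = 0.35) and a periphery
(r = 0.25 at covariate reference). This two-tier structure exists for a
specific reason: proportional thresholding is invariant to shifting a
whole submatrix by a constant, so a planted covariate effect on the
*level* of within-block correlation would never reach the binarized
graphs. Effects therefore act on the **periphery** coupling — putaminal
DaT raises within-SMN periphery coupling by 0.08 per z-unit, education
raises within-ATN periphery coupling by 0.02 per year, clipped to
[0.05, core level]. Mean within-block correlation still rises with the
covariate, and the graph simultaneously homogenizes: with no dominant
core, degree-targeted attack has no high-value targets and NAT rises
(verified directly: mean SMN NAT climbs from ≈0.20 to ≈0.26 as periphery
coupling approaches the core level). The factor construction keeps the
matrix positive semi-definite by design, so Cholesky sampling never
fails.

**Behavior.** Latent motor ability is
`intercept + s_NAT · NAT + s_mod · NAT · min(PA, knot)` plus noise, with
`s_NAT = 250`, `s_mod = −0.15`, knot = 45 WEE. The slopes look large
because the between-participant spread of mean NAT is small (~0.01) —
which is also why empirical NAT-behavior regressions report coefficients
in the hundreds. The negative moderation slope makes the conditional NAT
effect strongest in sedentary participants and frozen above the knot,
so the Johnson–Neyman region is a lower interval of the PA range; the
knot is a deliberate simplification, since only threshold-type evidence
exists for the moderation's shape. Motor tests load 0.5 SD per ability
unit (durations with flipped sign); cognitive tests are driven by an
independent latent, so the cognitive-composite models are true nulls. All
noise scales with a single `noise_sd`, making zero-noise contracts exact.
Activity diaries are constructed to reproduce each profile's PA through
the WEE formula (one MET-4 year-round activity per scored period), plus
decorative entries in the unscored periods that the scorer must ignore.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: hemodynamics and autocorrelated BOLD noise,
head motion and scrubbing, spatial structure of the parcellation,
negative-correlation networks, covariate collinearity patterns of real
cohorts, and any claim that the planted effect sizes estimate the real
ones (they are free parameters chosen for detectability at pilot scale).
One honest consequence visible in the shipped study-scale run (seed 1):
with a faithful heavy-tailed PA distribution and n = 22, the moderation
fit is leverage-dominated — a single very-high-PA participant can flip
the interaction sign — so the pipeline's narrative results for the
moderation stage are reported with that caveat, exactly as a pilot study
should.

## Problem sizes and runtime

The test suite runs the full 300-ROI atlas only where cardinalities
demand it (the 22 × 9 somatomotor long table) and otherwise uses a
30-ROI scaled atlas with proportional subnetworks; simulation-based
calibration uses 100 GLMM replicates, 500 null moderation replicates and
200 small-graph attack oracles. The suite completes in about half a
minute, the acceptance script likewise; the full-scale analysis scripts
(whole-brain 300-node attacks for 22 participants at 9 densities) take a
few minutes and write their large intermediates under `scratch/`.

## Known limitations

* Estimation of the beta GLMM is bespoke (no installed Python package
  fits this family with random intercepts); it is validated by parameter
  recovery, coverage and order-invariance tests, not against a reference
  implementation.
* Wald inference with 22 clusters is anticonservative for
  between-participant effects (documented above).
* Negative-edge handling is a convention choice (signed ranking by
  default); at high densities negative Fisher-z edges can enter the
  graphs, and the `abs` mode changes which ones.
* The random-failure baseline (random node removal) and weighted-graph
  efficiency are deliberately out of scope: the analysis binarizes before
  attack and targets hubs.
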