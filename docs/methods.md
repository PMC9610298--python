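# Methods

This note records the models, numerical conventions and design choices
behind `chesar`, and what the synthetic generators do and do not emulate.

## Inhibition kinetics

A reversible competitive inhibitor obeys, at substrate concentration S,

    Ki,app = vi [I] / (v0 − vi) = K_I + (K_I / K_S) · S,

so the apparent inhibition constant is linear in S; the intercept of an
ordinary least-squares line of Ki,app on S is the enzyme–inhibitor
dissociation constant K_I, and K_S = intercept/slope recovers the
enzyme–substrate dissociation constant (equal to Km for the classical
competitive rate law).  Choices:

- **Unweighted per-point OLS.**  All (S, Ki,app) points enter the regression
  individually, with no per-S averaging and no weights.  The linearization is
  a single linear relation and no weighting scheme is prescribed for it;
  pre-averaging would also hide replicate scatter from the intercept's
  standard error.  Fits use `scipy.stats.linregress`; SEs are the standard
  OLS formulas.
- **Units fixed by convention** — S in mM, I and Ki in µM — and never
  auto-converted; CSV readers validate the unit-bearing header names.
- **20–80 % inhibition window.**  Records outside the informative inhibition
  range are excluded before fitting (inclusive boundaries).  Filtering is on
  by default and can be disabled for raw re-analysis; the exclusion count is
  logged and carried on the fit result.
- Non-positive intercepts flag the fit `nonphysical`; a slope below 1e-12
  suppresses K_S rather than reporting a wild ratio.

On the simulated assay design (9 substrate levels spanning 0.05–0.50 mM,
three inhibitor levels, triplicates, 5 % multiplicative noise), the median
relative error of the recovered Ki over 200 assays is below 10 % and the
empirical coverage of ki ± 2·SE is at or above nominal-ish 85 %; both are
asserted by the test suite.

## Selectivity tables

The selectivity index SI = Ki(AChE)/Ki(BChE) and pseudo-enantiomer
stereoselectivity ratios (CN-type over CD-type Ki for one enzyme) are plain
ratios; the interesting conventions are typographic:

- **Printed rounding**: ratios ≥ 10 to the nearest integer, ratios < 10 to
  two significant figures, matching the mixed precision of published SAR
  tables (533, 81, 0.063, …).  Raw values are always carried alongside.
- **Comparisons against printed values** use half a unit in the last printed
  digit.  The packaged reference table keeps the published figures verbatim;
  for nine of its 48 selectivity indices (listed in
  `chesar.datasets.SI_FROM_UNROUNDED`) and one stereoselectivity cell the
  printed index was evidently computed from unrounded constants and cannot
  be re-derived from the printed Ki at that tolerance.  Those exceptions are
  frozen and asserted as such, so a silent fixture edit cannot pass unnoticed.

## Drug-likeness and BBB levels

Rule bounds are kept exactly as stated for the oral-activity profile
(180 ≤ MW ≤ 500 g/mol, −0.4 ≤ logP ≤ 5.6, HBD < 5, HBA < 10, RB ≤ 10,
PSA < 140 Å²; at most one violation), with a tighter "recommended" set
(MW 500, logP 5, HBD 3, HBA 7, RB 8, PSA 70 Å²) as a named alternative.
logBBB (log10 brain/blood concentration ratio at steady state) is an input,
classified into four penetration levels with the boundary conventions
level 0: ≥ 0.7, level 1: [0, 0.7), level 2: (−0.52, 0), level 3: ≤ −0.52 —
a total partition of the finite reals, monotone in logBBB.

Property tables are sometimes printed with MW/100 and PSA/10.  Readers take
an explicit `scaled` flag; autodetection is deliberately refused because a
wrong guess silently perturbs MW by a factor of 100.

## NIPALS PCA

Components are extracted one at a time by the NIPALS power iteration with
deflation, on the mean-centered matrix (covariance PCA — no scaling to unit
variance).  Numerical choices:

- **Convergence**: relative change of the full score vector below 1e-10, or
  1000 iterations (non-converged components are returned but flagged).  The
  change of the score *norm* alone is not a usable criterion: the norm
  estimates the eigenvalue, which converges quadratically in the angular
  error, so a norm-based stop of 1e-10 leaves loadings wrong at the 1e-5
  level and would fail the package's own 1e-7 oracle-agreement bound.
- **Initialisation** from the residual column of largest variance;
  **sign convention**: the largest-magnitude element of each loading is made
  positive.  Both make results deterministic.
- Explained fractions are var(tᵢ) over the total variance of the centered
  input; zero-variance columns simply receive zero loading.

Activity PCA uses raw Ki in µM by default (a log10 option exists).  On the
packaged 48-compound panel the first component of the (Ki_BChE, Ki_AChE)
matrix carries 99.13 % of the variance, dominated by the AChE column's much
larger dynamic range.

## MD sampling and energy fingerprints

The sampler is a velocity Verlet integrator (one force evaluation per step,
previous forces cached) with Maxwell velocity initialisation and a
velocity-scaling thermostat (all velocities multiplied by √(T_target/T) —
applied every step by default, since only "temperature control" is assumed,
not a specific coupling interval).  The instantaneous temperature uses
N_dof = 3N − 3: center-of-mass momentum is removed at initialisation and is
conserved by internal forces.  Two unit systems exist: reduced (k_B = 1, the
default for toy fields) and physical (amu, Å, fs, kcal/mol) whose defaults —
0.5 fs step, 773.15 K initialisation, same thermostat target — are the
conventional deliberately-hot settings for phase-space coverage in PES
sampling.  No periodic boundaries, constraints or barostats.

Force evaluation is a pluggable contract (coordinates → energy, gradient),
so an external semiempirical or ab initio engine can be adapted in; the
shipped fields (harmonic well, Lennard-Jones dimer/cluster, 2-D double well)
are analytic, exactly differentiable, and verified against central
differences, which is what validating the integrator requires.

**Fingerprint construction.**  How a sampled PES becomes one fixed-length
regression row is genuinely open design space; the choice here is q equally
spaced quantiles (0…1 inclusive, default q = 64) of the potential-energy
sample with the sample minimum subtracted.  This is invariant to constant
energy offsets of the force field (gauge freedom a descriptor must not see),
insensitive to frame ordering, and fixed-length regardless of trajectory
length.  It deliberately discards coordinate-space information; the
operation is isolated so a coordinate-PCA variant can be swapped in.

## Exhaustive polynomial model search

Candidate predictors are all monomials of total degree 1..p in d variables
(C(d+p, p) − 1 of them; the intercept is always present and never counted).
Every term subset is fitted by SVD least squares (singular values below
1e-10 of the largest are truncated; models needing truncation are excluded
as rank-deficient rather than silently kept) and validated by hat-matrix
leave-one-out CV: PRESS = Σ (eᵢ/(1−hᵢᵢ))², predicted R² = 1 − PRESS/SST.
Leverages above 1 − 1e-8 (saturated points) invalidate a model.  The
shortcut is verified against explicit n-refit cross-validation to 1e-9.

**Selection rule.**  Four criteria matter: adjusted R², predicted R²,
LOO-CV MSE, and the number of variables.  Maximising predicted R² alone
systematically selects supersets of the true support — on planted-model
simulations the superset's cross-validated advantage is ~1e-6 in predicted
R², far inside CV noise, yet decisive under a strict maximum.  The default
ranking therefore applies the one-standard-error rule: among models whose
total PRESS is within one standard error of the minimum (plus a 1e-12·SST
floor so the band stays meaningful for noise-free data), the fewest-terms
model wins, with ties broken by lower PRESS and then lower subset bitmask.
Under this rule the search recovers planted supports exactly (20/20 seeds at
σ = 0.01 in the test suite).  The strict predicted-R² ranking remains
selectable (`SearchConfig(ranking="predicted_r2")`).

The full 3-variable 4th-order space holds 2^34 ≈ 1.7 × 10¹⁰ subsets —
cluster scale.  The implementation enforces an explicit enumeration budget
(default 2^20) with an always-available exact count-only mode; desk-scale
analyses use quadratic bases and/or term-count caps.

## Pipeline

Per compound family (CD-type vs CN-type, dihydro analogues included with
their parents by default; the split is configurable), the first principal
component of the (Ki_BChE, Ki_AChE) matrix — computed once on the full
table so all families share one activity scale, then subset — is regressed
on the leading principal components (default 3) of the compound ×
fingerprint matrix via the exhaustive search.  The report embeds the full
configuration, per-series best models and fitted-vs-observed scores, and is
byte-identical across reruns with the same inputs and seed.  A best model
with predicted R² below 0.5 is flagged `low_signal` rather than silently
reported.

## Synthetic data

- **Assays**: classical competitive-inhibition rates with multiplicative
  log-normal noise (mean 1, CV configurable; positivity preserved, as for
  plate-reader rates).  Default design: 9 substrate levels 0.05–0.50 mM,
  triplicates, three inhibitor levels placed so every noise-free record over
  the whole grid falls inside the 20–80 % window (the level solver inverts
  the rate law; its geometry is described at `default_inhibitor_levels`).
  At zero noise the generated records satisfy the linearization identity
  exactly.
- **Activity tables**: log-uniform Ki over the dynamic ranges of the
  packaged panel (0.075–19 µM BChE, 3.9–206 µM AChE — three orders of
  magnitude for BChE), arranged as paired CN/CD rows.
- **Fingerprint datasets**: latent scores Z (n × 3 standard normal) mapped
  through a fixed orthonormal q × 3 matrix, plus a planted low-order
  polynomial response with additive Gaussian noise.  Every generator is a
  pure function of its spec, seed included.

What the generators do **not** emulate: real conformational ensembles or
quantum-chemical energy surfaces, enzyme-assay systematics (substrate
depletion, optical artefacts, pipetting correlation), inter-compound
correlation of measurement error, and model misspecification (the planted
link is exactly polynomial).  Passing tests therefore demonstrate that the
machinery is correct and well-calibrated under its stated assumptions, not
that real cholinesterase data will yield models of comparable quality.

## Problem sizes

Tests and the validation suite run at desk scale by design: MD properties
use a 1-particle oscillator and a 3-particle trimer for 10⁴ steps; searches
enumerate the 32-model (2,2) and 512-model (3,2) spaces; the end-to-end
pipeline uses 24 compounds per series; kinetics calibration uses 200
simulated assays.  These sizes make every result reproducible in seconds
while exercising the same code paths as production-scale runs.

## Known limitations

- The Hunter-Downs intercept SE assumes homoscedastic residuals; with
  multiplicative rate noise the transformed Ki,app noise is heteroscedastic,
  which is why coverage is asserted at ≥ 0.85 rather than the nominal 0.95.
- NIPALS deflation accumulates rounding across many components; for
  near-full-rank extractions of ill-conditioned matrices a direct
  eigendecomposition is preferable (the package uses one as a test oracle
  only).
- The fingerprint discards all coordinate information from the trajectory;
  systems distinguishable only by geometry, not energy distribution, map to
  similar fingerprints.
- The velocity-scaling thermostat does not generate a canonical ensemble;
  it is used here for temperature control during sampling, not for
  computing thermodynamic observables.
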