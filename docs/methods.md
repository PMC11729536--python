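# Methods

## The model

`stormsurv` estimates apparent overwinter survival of marked adults from live
resightings at a breeding colony with Cormack-Jolly-Seber (CJS) models,
conditioning on first release. Apparent survival φ_t for interval *t*
(breeding season *t* → *t+1*) confounds mortality with permanent emigration;
resighting probability p_k is the probability that a marked, alive, present
individual is seen at occasion *k*.

Colour-ringed seabirds are typically easier to resight in the season after
they were last seen (observers re-check known birds, and site fidelity within
sub-colonies concentrates effort), so the package models **immediate
(one-occasion) trap-dependence**: at occasion *k*, an individual detected at
*k−1* is resighted with p_seen(k), one not detected with p_unseen(k). The
sufficient statistic is the **split-history m-array**: each detection before
the final occasion opens a release, so every m-array row conditions on "just
seen", and the cell probabilities are

    Pr(next at j | released at i) = Π_{k=i}^{j−1} φ_k ×
        { p_seen(i+1)                                          j = i+1
        { (1−p_seen(i+1)) Π_{k=i+2}^{j−1}(1−p_unseen(k)) p_unseen(j)   j > i+1

with the never-seen-again cell as the complement. Because an individual's
full history factorises at each detection, the product of segment
probabilities equals the individual-history likelihood summed over latent
death times; the test suite verifies this against an exhaustive enumeration
oracle to 1e-10 relative on all 3–5 occasion datasets tried, and verifies
that equal group probabilities reproduce the classic CJS likelihood exactly.

Both φ and p use logit links. Survival may be constant (`.`), fully
time-dependent (`t`), or logit-linear in per-winter covariates
(`PC1 + sSST`, `PC1 * population`, ...). Interactions are products of
standardised main effects (standardise-then-multiply); the two-level
oil-spill factor enters unstandardised as 0/1. Resighting structures follow
the field's table notation: `a/b` gives separate models for the seen/unseen
groups (each `.` or `t`), and `t + m` shares per-occasion effects with a
single additive trap offset *m* on the seen group's logit.

## Goodness of fit and overdispersion

Three U-CARE-style contingency tests on the raw histories:

* **2.CT** (trap-dependence): per interior occasion *i*, individuals detected
  at or before *i* and detected again later, cross-classified by (detected at
  *i*) × (next detection at *i+1* vs later). The pooled Mantel-Haenszel-style
  z is positive under trap-happiness.
* **3.SR** (transience): individuals detected at *i*, (newly vs previously
  marked) × (ever detected after *i*); positive z = new marks return less.
  Valid under immediate trap-dependence because both groups are in the
  "seen" state at *i*.
* **3.SM**: among individuals detected at *i* and again later, (new vs old) ×
  (next detection at *i+1* vs later). U-CARE's native 3.SM keeps multi-column
  tables (hence larger df); we use the 2×2 collapse, which changes component
  df but not the test's purpose.

Each 2×2 table contributes a raw Pearson χ² with 1 df — no continuity
correction, for transparency and testability. A table is informative only if
all margins are positive **and** every expected count is ≥ 2; otherwise it is
pooled out (df 0). This is a documented surrogate for U-CARE's (unpublished
in detail) pooling rules; on sparse data it is deliberately conservative.

The variance inflation factor is ĉ = Σχ²/Σdf over a configurable set of
tests, **excluding 2.CT by default** because the trap-dependence it detects
is modelled structurally rather than treated as noise. ĉ is reported raw (no
floor); the pipeline clamps to 1 before use, a separate and visible policy
decision. Under the null generator the empirical size of all three tests sits
within three binomial standard errors of the nominal 5% (500 replicates), and
the mean ĉ is 1 within ±0.1.

## Model selection and ANODEV

Models are ranked by QAICc = −2lnL/ĉ + 2K + 2K(K+1)/(ESS − K − 1).

* **Effective sample size**: Σ R_i, the total number of split-history
  releases (configurable; program conventions differ and are not derivable
  from the likelihood).
* **Parameter count K**: the structural count minus the rank deficiency of
  the observed curvature (eigenvalues below 1e-8 × the largest). Fully
  time-dependent structures lose the confounded final φ·p product this way
  automatically. Exact agreement with other programs' counting heuristics is
  not guaranteed and only shifts QAICc by a constant within a structure
  family; ΔQAICc orderings are robust to it.
* Akaike weights are exp(−Δ/2) normalised; ties break by smaller K then
  label.

ANODEV partitions temporal deviance with quasi-deviances D = −2lnL/ĉ:
R² = (D_cst − D_cov)/(D_cst − D_t) and
F = [(D_cst − D_cov)/J] / [(D_cov − D_t)/(T − J − 1)] on (J, T − J − 1)
degrees of freedom, J = number of covariate slopes, T = survival intervals.
Under a null covariate its empirical size is ≈ 5% (150 replicates in the
acceptance run).

The pipeline follows the standard two-step procedure: the resighting
structure is selected under φ(t) and frozen; one ĉ per dataset is applied to
every model in the run.

## Fitting and uncertainty

The negative log-likelihood is evaluated in log space over m-array cells, and
its **analytic gradient** is derived by the chain rule through the logit
links (each cell's log-probability is a sum of log φ, log p and log(1−p)
terms, so per-interval usage weights assemble the gradient exactly). BFGS
starts from all logits at zero — a deterministic, scale-appropriate start —
with a fixed-seed five-point jittered multi-start fallback. Convergence is
declared at gradient ∞-norm < 1e-5; with exact gradients this is routinely
attained, which is why the package carries the gradient code rather than
relying on finite differences.

The covariance is the pseudo-inverse of the finite-difference Hessian of the
(analytic) gradient, scaled by ĉ. Confidence intervals are Wald on the logit
scale, back-transformed; profile intervals are deliberately out of scope.
Estimates with |logit| > 15 are flagged as boundary ("inestimable" CI years),
as are intervals whose logit SE exceeds 10 or is undefined — under φ(t)p(t)
structures the final interval is confounded and typically flagged.

## Winter covariates

* **Storminess (PC1)**: PCA on the **correlation** matrix of the per-winter
  storm characteristics (the variables mix counts, hPa and hours, so the
  covariance matrix would be meaningless). Computed by SVD of the
  standardised matrix, valid when winters < variables. PC1 is oriented so it
  correlates positively with the storm count — high PC1 = stormy winter; any
  variable that moves opposite the storm count (e.g. mean gap) then loads
  negatively.
* **SST terms**: summer and winter box means, plus one-winter lags. The first
  winter's lag is missing; it is retained in the table and models using lags
  receive it as the (standardised) mean with a logged note. Box means are
  simple means over the user-supplied box series.
* **Population counts**: missing years take the mean of the nearest preceding
  and following counts; trailing (and leading) gaps carry the nearest
  observed value, flagged.
* **Oil spills**: a spill dated November–March flags the winter spanning that
  November–March (a March 1978 spill belongs to winter 1977/78). Spills
  outside those months or the study span are ignored with a warning.
* Continuous covariates are standardised (mean 0, SD 1) before modelling;
  standardisation is idempotent and the oil factor is never standardised.
  A correlation screen reports pairs with |r| > 0.7 (population and SSTs are
  expected to be collinear through shared trends and are not combined).

## Storm statistics

Tracks (6-hourly points with minimum sea-level pressure) are screened to
lifetimes strictly over 48 h and great-circle path lengths strictly over
1000 km. Per winter (1 Dec 00:00 UTC – 1 Mar 00:00 UTC, disjoint windows so a
storm belongs to exactly one winter) and closed lon/lat box:

* a storm counts if any point falls in the box during the window;
* duration sums first-to-last spans of consecutive in-box points (no
  sub-timestep interpolation; a single-point crossing contributes 0 h);
* intensity is the minimum SLP among **in-box** points (not the whole track);
* gaps run from one storm's last in-box time to the next storm's first
  (exit-to-entry; overlapping occupancies count as 0 h).
* exceedance days count daily maxima **≥** threshold ("exceeding" is read
  inclusively; the tie rule is explicit in the code and tested).

Shrinking the box or raising a threshold can never increase a count
(property-tested).

## Space use

A deliberately simple, projection-free utilisation distribution: the caller
supplies positions in equal-area coordinates; a fixed-bandwidth Gaussian
kernel density is evaluated at grid-cell centres and normalised to unit mass;
the 90% isopleth accumulates cells by descending density until ≥ 0.90.
Overlap is the directional fraction of one year's isopleth cells inside
another's (area-based, both directions reported, asymmetric by construction).
The bandwidth is user-supplied — no reference rule is imposed.

## The synthetic generator

The generator produces the statistical structure the analysis assumes, at the
study's scale: decades of occasions (T ≈ 36–51), ~30 new marks per season
(~800–1300 marked adults), survival near 0.93 (optionally logit-linear in
covariates), strong trap-happiness (p_seen ≈ 0.9, p_unseen ≈ 0.5), AR(1)
winter covariates with configurable cross-correlation (to reproduce the
population–SST collinearity), Poisson storm arrivals crossing the wintering
box with lognormal in-box durations and Normal minimum pressures, and daily
wind/wave maxima lifted on storm days. Identical seeds give byte-identical
outputs. The core anti-bug property ties the generator to the likelihood:
observed m-array cell frequencies match the likelihood's own cell
probabilities within three binomial SEs at large n.

What it does **not** emulate — and what passing tests therefore cannot show
about real data: heterogeneous individual detectability and effort trends,
transience, mark loss, senescence and sex structure, non-linear or threshold
storm effects, mass-mortality wrecks beyond what a low-φ winter induces, and
spatially explicit movement. Storm tracks are straight-line box crossings,
adequate for exercising occupancy/gap/exceedance logic but not for studying
track geometry.

## Problem sizes in tests and the acceptance run

Calibration and recovery use sizes chosen to make Monte-Carlo error small
relative to the tolerances they check: 400–500 replicates for test size
(binomial SE ≈ 0.01), 200 replicates for slope recovery at the study scale
(T = 36, 30 releases/occasion, β_PC1 = −0.2), 150 for ANODEV size, 50 for
selection consistency at a strong effect (β = −0.6). The end-to-end synthetic
study mirrors the longest-running colony series: 36 winters, ~1080 marked
adults, β_PC1 = −0.21 and β_sSST = −0.30 on logit survival.

## Known limitations

* The pooling rule (expected ≥ 2) can pool out most 2.CT tables in small,
  strongly trap-happy datasets where the unseen margin is thin; at the
  multidecadal scale the tests are well-populated.
* 3.SM uses 2×2 collapses, so its component df is smaller than U-CARE's
  multi-column version.
* K counting by curvature rank may differ from other programs' heuristics by
  a small constant within a structure family.
* ANODEV's F reference is approximate for quasi-deviances; its empirical size
  is monitored rather than assumed.
* Only immediate (one-occasion) trap-dependence is modelled; higher-order
  memory, multistate structure, individual covariates and dead recoveries are
  out of scope.
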