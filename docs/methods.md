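# Methods

## Data model and conventions

The response variable throughout is the **Burst Duration**: for each animal
and each second, the fraction of video frames in which the animal was
detected moving, a unitless value in [0, 1].  With `fps` frames per second,
second `s` (1-based) summarizes the frames in the half-open interval
`[s−1, s)` seconds, i.e. 0-based frame indices `(s−1)·fps … s·fps−1`.  A
trailing second with fewer than `fps` recorded frames is dropped rather than
rescaled, so every retained value is a fraction of a full second.

Analyses operate on **stimulus-aligned windows**: for a light change at
absolute second `E`, the pre-change vector covers seconds `E−29 … E`
(relative −29 … 0, second 0 being the last second of the old stimulus) and
the post-change vector covers `E+1 … E+30` (relative 1 … 30).  Light
transitions are abrupt and constrained to integer second boundaries;
non-integer event times are rejected rather than interpolated.  Missing data
are handled per (animal, event) window: an animal missing any second of a
window is excluded from that event only, and the exclusion count is
reported.  This is deliberately less destructive than excluding an animal
from the whole experiment.

A frame-level *burst-threshold* filter (discarding movement bouts shorter
than a given number of consecutive frames) is available but off by default:
small movements carry information and the default analyses keep them.

Files are plain CSV, UTF-8, comma-delimited, '.' decimal, header required —
one dialect, no sniffing.  Floats are written with 17 significant digits and
read with round-trip parsing so write → read reproduces float64 values
bit-exactly.

## Hotelling's T² on profiles

Two groups of profile vectors (dimension p = number of seconds in the
window) are compared with

    T² = n₁n₂/(n₁+n₂) · (x̄⁽¹⁾ − x̄⁽²⁾)′ S⁻¹ (x̄⁽¹⁾ − x̄⁽²⁾),

where `S` is the pooled sample covariance
`((n₁−1)S₁ + (n₂−1)S₂)/(n₁+n₂−2)`; no Behrens–Fisher (per-group covariance)
variant is offered.  Under the null,
`F = (n₁+n₂−p−1)/(p(n₁+n₂−2)) · T² ~ F(p, n₁+n₂−p−1)`, and the p-value is
the upper tail of that central F.  For p = 1 the statistic is exactly the
squared pooled-variance two-sample t.

**Singular covariance.** A singular `S` (zero-variance or collinear seconds)
is a hard error naming the offending columns; an explicit ridge
(`S + εI`) can be opted into.  Silent pseudo-inversion is not performed
because it changes the statistic's null distribution.

**Multiple testing.** Batteries of pairwise tests are adjusted with the
Benjamini–Hochberg step-up.  The adjustment family is *all tests of one
battery invocation* — the most conservative reproducible choice when the
family is otherwise underspecified — and raw p-values are always reported
alongside.

**Observation unit.** An observation is one (animal, event) profile.
Pooling the consecutive trials of one animal therefore treats repeated
measurements of the same animal as independent samples (pseudoreplication);
the command-line battery warns when trials are pooled, and `trial_index`
filters restrict to single trials.

## Power and sample size

Under a fixed alternative the F-transformed T² follows a noncentral F with
noncentrality

    τ² = n₁n₂/(n₁+n₂) · (μ⁽¹⁾ − μ⁽²⁾)′ Σ⁻¹ (μ⁽¹⁾ − μ⁽²⁾),

and power = P(F_{p, n₁+n₂−p−1, τ²} ≥ F_{p, n₁+n₂−p−1, α}).  The noncentral
tail is evaluated with scipy's `ncf` distribution; `ncp = 0` is routed
through the central F (the two coincide exactly), so null calibration
power(0) = α holds to machine precision.

**Effect-size parametrization.**  Planning functions accept a scalar effect
size Δ with equal group sizes n.  Two readings are supported:

- `"distance"` (default): Δ is the Mahalanobis distance
  `√(δ′Σ⁻¹δ)`, so τ² = (n/2)·Δ²;
- `"quadratic"`: Δ is the quadratic form `δ′Σ⁻¹δ` itself, so τ² = (n/2)·Δ.

The distance reading is the default because it is the one under which the
planning integers for a 2-second window at α = 0.05 and power 0.8 form the
internally consistent grid 32 / 41 / 56 / 79 for Δ = 0.8 / 0.7 / 0.6 / 0.5;
the quadratic reading yields 26 / 30 / 34 / 41.  The test suite pins this
distinction with an independent evaluation of the noncentral-F tail (the
Poisson mixture of central-F tails), kept separate from the scipy-based
implementation path.

**Minimal n** is found by scanning integers upward from `p + 2` (the
smallest n with positive error degrees of freedom) — powers are cheap and an
exact scan cannot skip the minimum, unlike bisection on a discretized
non-linear function.

**Scenario tabulation** draws group mean vectors elementwise from
user-specified uniform bands and computes analytic power against a supplied
Σ.  A default AR(1) covariance (`Σ_ij = σ²ρ^{|i−j|}`, ρ = 0.5) is shipped
for self-contained runs; it mimics the temporal correlation of per-second
activity but is *not* estimated from any experiment, and should be replaced
with a data-derived Σ for real planning.

## Sequential MANOVA and the Pillai–Bartlett trace

The MANOVA response is the window profile: either the 60-dimensional
concatenated (pre ‖ post) vector, or the 30-dimensional pre and post
vectors fitted separately (`response full|pre|post`).  Predictors are
categorical factors with treatment (first-level-reference) dummy coding;
well location enters as a 96-level factor.  By convention, well location
and biological repeat enter as main effects only — plate-position effects
are assumed invariant across strains, stages, trials and stimuli — though
the term list is fully user-configurable.

Sums of squares are **sequential (Type I)**: term k's hypothesis SSCP `H_k`
is the increment in fitted SSCP when k enters after terms 1 … k−1.  Term
order is therefore part of the model and is echoed in all outputs.  The
choice makes `Σ_k H_k + E` equal the total centered SSCP exactly, which is
what lets the Pillai trace

    V = tr(H(H+E)⁻¹),   0 ≤ V ≤ min(p, q)

be read as a share of explained variance, and the per-second η² values
below as a true variance partition.  The approximate F uses Pillai's
mapping: with `s = min(p,q)`, `m = (|p−q|−1)/2`, `n' = (v−p−1)/2`,
`F = ((2n'+s+1)/(2m+s+1)) · (V/s)/(1−V/s)` on `s(2m+s+1)` and `s(2n'+s+1)`
degrees of freedom.

**Numerical strategy.**  Fitting is by incremental block orthogonalization
(SVD-based Gram–Schmidt), not normal equations, so SSCP increments stay
stable with the 96-level location factor.  Rank decisions use a cutoff
relative to the raw block norm: columns of a term that are collinear within
the term are dropped silently; columns absorbed by *earlier* terms (e.g.
empty interaction cells in unbalanced data) reduce the term's hypothesis df
with a logged warning, matching R's model-fitting behaviour; a term with no
remaining column space is an error.  Unbalanced data are accepted —
sequential SS is well defined without balance.  The error df must be at
least p so that H+E is invertible; otherwise the fit aborts with advice to
shorten the window or reduce the term set.

Development cross-check: on frozen balanced and unbalanced fixtures the
per-term Pillai traces, approximate F values and p-values agree with R's
`summary(manova(...), test="Pillai")` (R 4.3.3) to 9+ digits; the frozen
values live in the test suite, so the agreement is re-verified on every run
without an R dependency.

## Per-second effect-size dynamics

For each relative second (−29 … 30) a univariate sequential ANOVA with the
same term order is fitted to that second's activity, and each term's

    η² = SS_term / SS_total

is recorded (SS_total = centered total SS).  Because the SS are sequential,
the per-second η² values of all terms plus the residual share sum to exactly
one, so stacked time courses read as variance shares.  Light-On and
Light-Off events are never mixed in one fit.  A constant response (zero
total SS up to rounding) yields η² = 0 for every term, with a warning.

## Synthetic plate experiments

The generator emulates the canonical assay — a 96-well (8×12) plate per
strain and biological repeat, 3.5 h dark adaptation with recording starting
0.5 h before the first light onset, three consecutive 30-min Light-On /
Light-Off trials, 30 frames/s — with the latent per-second movement rate

    r(a,t) = clamp₀₁( baseline(strain)·stage_mult(stage) + location(well)
                      + bio_rep + tech_rep + u_a
                      + kernel(t)·resp_mod(strain)·resp_mod(stage) + ε(a,t) )

- **Stimulus kernel**: `A·e^{−k(τ−1)} + s_level` at relative second τ ≥ 1
  after a light change, holding the plateau until the next change, with
  separate (A, k, s_level) for On and Off.  The exponential-decay-to-plateau
  shape is this package's modeling choice; every constant is in the config.
- **Location effect**: a radial gradient, brightest at the plate center
  (offset `location_coef·(1 − d/d_max)`), reflecting uneven bottom-panel
  illumination; its magnitude defaults to 0.
- **Noise**: an animal-level Gaussian random intercept `u_a` (SD 0.02 by
  default) and stationary AR(1) noise `ε` (ρ = 0.5, innovation SD 0.02).
  Default baselines (0.060–0.070 by strain), stage multipliers (0.6 → 1.1
  from 3 to 9 dpf) and On-response amplitude 0.35 place the latent rates in
  the range of real Burst-Duration traces, with response magnitudes growing
  over development.
- **Modes**: `second` emits the latent rate (plus optional clamped Gaussian
  observation noise), so group means and covariances are known exactly;
  `frame` draws fps independent Bernoulli(r) movement flags per second, so
  Burst Duration is Binomial(fps, r)/fps and the summarization code is
  exercised end to end.  Rates falling outside [0, 1] before clamping are
  counted and reported; clamping is what power-validation studies must
  avoid, which is why those use direct Gaussian draws with exact (μ, Σ).
- **Reproducibility**: one root seed; each animal's stream is keyed by its
  (plate, stage, well) counter, so enlarging the design never perturbs
  existing animals.  Output is bitwise reproducible for a fixed seed.

What the generator does **not** emulate: pixel-level detection, circadian
drift, habituation beyond the kernel plateau, non-Gaussian movement burst
distributions, and spatial correlation between neighbouring wells.  Passing
tests on synthetic data therefore establish the statistical machinery
(calibration, power, partitions), not the biological fidelity of any
particular dataset.

## Problem sizes used in validation

The test suite validates on reduced designs chosen to keep the full run in
the low minutes while preserving the statistical structure: type-I-error
calibration uses 2000 replicates of a null plate with 100 animals, a single
trial and the 30-second post-onset window (p = 30, 50 animals per group,
AR(1) ρ = 0.5), and accepts the empirical rate within 3 binomial standard
errors of α = 0.05; Monte-Carlo power checks use 1000 replicates per setting
across p ∈ {2, 10, 30}.  The demo workflow simulates a 4×6 plate section
with 3 strains × 2 stages × 2 biological repeats × 3 trials and 70-second
phases.

## Known limitations

- The T² test assumes multivariate normality and a common covariance across
  groups; Burst-Duration values are bounded fractions, so heavy clamping
  (very low or very high activity) distorts both assumptions.  No
  nonparametric profile test is provided.
- Sequential SS makes every reported effect conditional on the preceding
  terms; reordering terms changes the table on unbalanced data, which is
  why the order is echoed in outputs.
- The FDR family is per battery invocation; combining tables across
  invocations requires re-adjusting the pooled raw p-values.
- Power planning with the shipped AR(1) Σ is qualitative; quantitative
  planning needs a covariance estimated from pilot data.
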