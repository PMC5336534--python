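# Methods

## Structural erosion model

HPMC release is the erosion surrogate. The default structural model
is Michaelis–Menten depletion of the remaining polymer amount
`H(t)` (mg), `dH/dt = −V_MAX·H/(K_M + H)`, chosen because the
release rate of hydrophilic matrices starts near-constant and
declines as the matrix depletes. A mechanism-based surface-area law
`dH/dt = −R·(dose/W)·(W·H/dose)^γ` (tablet weight `W` in mg) is
implemented literally, as printed in its source, for structural
comparison; for `γ ≠ 1` the dimensional bookkeeping of the base is
absorbed into the scale of `R`. Release begins after a lag `t_lag`
(h) attributed to initial hydration; the lag is a pure delay measured
from dose time and is not re-applied per GI segment.

Both laws admit closed forms over constant-parameter intervals: the
Michaelis–Menten solution via the principal Lambert W branch (with a
log-scale Halley iteration once the argument would overflow, i.e.
`log x > 650`), the power law by separation of variables. A
piecewise-constant parameter timeline carries time-varying
environments; the state is propagated continuously across
breakpoints (no re-initialization). The default solver is the
chained closed form; an adaptive Runge–Kutta (DOP853, atol
1e−10 mg) route is retained as an independent numerical oracle, and
the two are required to agree within 1e−6 × dose in the test suite.

## Covariate model

Covariate effects multiply the typical values and are centered at
the reference condition — the pure low-molecular-weight-HPMC
formulation (40 %w/w K100LV, 57.6 %w/w DCP), pH 6.8, 50 rpm:

* linear `1 + S·(cov − ref)` (default for every covariate),
* power `(cov/ref)^PWR` and saturable `1 + E_MAX·cov/(cov₅₀ + cov)`
  forms for covariates observed over a wide range,
* the selected model: linear rpm/pH/DCP effects on `V_MAX`, linear
  pH/DCP effects on `K_M`, and a saturable inhibition of `V_MAX` by
  the high-MW HPMC share with `E_MAX` fixed at −1 (full inhibition),
  so `E_MK4M = 1 − MK4M/(MK4M₅₀ + MK4M)`.

Linear multipliers can go non-positive at extreme covariates; they
are floored at 1e−6 (with a warning in the public API) because rates
must stay positive. Ionic strength is carried in the data model and
the covariate-selection candidate set but has no effect in the
selected model.

Package defaults for all population parameters are the selected
in vitro model estimates (`V_MAX` 22.0 mg/h, `K_M` 34.2 mg, lag
0.179 h, MK4M₅₀ 18.7 %w/w, slopes per covariate unit, between-tablet
SD 0.0596 on log-`V_MAX`, additive error SD 1.95 mg) and, for the in
vivo layer, segment stresses 39.5/93.3/31.1/9.99 rpm, lag 0.410 h,
between-subject/between-occasion SDs 0.148/0.154 and combined error
(14.2% CV + 1.86 mg). These defaults double as the generating truth
of the synthetic-data module, making simulate-then-fit recovery the
package's core validation loop.

## GI environment construction

Tablet-location records give stomach, small-intestine and colon
entry times. The small intestine is segmented into proximal and
distal parts by one of three rules: fractional transit (transfer at
SI entry + 45% of the individual small-intestinal transit time), an
estimated population offset after gastric emptying, or a fixed 1-h
offset (the default, which performed best in the source analysis).
Each segment receives one pH per subject-occasion — a truncated
normal draw (bounds pH 0.5–9.0) from literature priors; only the
stomach prior depends on prandial status (fasting 1.73 ± 0.52,
postprandial 4.90 ± 0.81) — and a mechanical stress expressed as a
USP2 rotation-speed equivalent. Sampling pH once per
subject-occasion-segment (rather than per observation) was a design
choice; the truncation bounds likewise. When a dataset records the
pH values actually used (as the synthetic generator does), the
estimator conditions on them; otherwise it falls back to prior
means. Deterministic (prior-mean) pH defines the "typical"
prediction used for prediction correction.

## Estimation

The marginal likelihood is approximated by the Laplace method with
interaction: per grouping unit, the random-effect vector is
optimized (empirical Bayes mode) by a damped Newton scheme and the
Gaussian integral corrected by the log-determinant of the joint
curvature. Residual variance may depend on the prediction
(additive, proportional or combined error), so the interaction term
is retained. This targets the same integral as FOCE-I; exact
agreement with any particular linearization scheme is not attempted,
and the test suite instead requires agreement with adaptive
numerical quadrature within 0.1 OFV units on small instances (up to
three random-effect dimensions).

Random-effect layouts: independent tablets with a scalar log-normal
effect on `V_MAX` (between-tablet variability), or subjects with
nested occasions where occasion `j` sees `η_subject + η_occasion,j`
(between-subject plus between-occasion variability, one shared
variance per level). The nested inner problem has an
arrow-structured Hessian (occasions are conditionally independent
given the subject effect); the Newton solve and the Laplace
determinant exploit this via a Schur complement. Both layouts are
evaluated in fully vectorized form across units (padded arrays, one
Lambert-W call per segment per iteration); a scalar reference
implementation of each layout is kept and cross-checked against the
vectorized path to 1e−6.

Outer estimation minimizes the summed −2 log marginal likelihood
(OFV, constants included) by L-BFGS-B with finite-difference
gradients (step 1e−5 on the internal scale). Positivity is enforced
by log-parameterization of rates, amounts, lags, stresses and SDs;
covariate slopes are estimated on an internal scale of 0.01 so the
optimizer sees O(1) quantities. Inner Newton iterations stop when
the residual step would change the OFV by less than ~1e−9; a stall
detector prevents cycling at the floating-point floor. `AIC = OFV +
2p` with `p` the number of estimated parameters. Standard errors use
the sandwich estimator (per-unit score outer products between
inverse halves of the OFV Hessian, finite differences), falling back
to the Hessian alone with a warning if the sandwich is singular.
Variabilities are reported as CV% = 100·√(exp(ω²)−1); at these
magnitudes the alternative 100·ω convention differs by far less than
the estimation uncertainty.

Starting values default to the package's published-estimate defaults
(the natural choice when re-fitting data of this kind); stepwise
covariate modeling warm-starts each candidate fit from the incumbent
model's estimates. Missing observations are simply absent rows — no
imputation.

## Stepwise covariate modeling

Forward inclusion tests every remaining (covariate, parameter,
linear) candidate, includes the largest ΔOFV with p < 0.05 (χ², df =
number of new parameters: 1 for linear, 1 extra for a saturable or
power upgrade of an included linear relation), and iterates; upgrades
are only offered for covariates spanning a wide design range
(default: mechanical stress, MK4M). Backward deletion then removes,
one at a time, any relation whose deletion costs less than the
p ≥ 0.01 threshold, least significant first. Ties resolve to the
lower candidate index. The procedure is deterministic given the
dataset.

## Diagnostics

VPCs compare observed 5th/50th/95th percentiles per time bin against
95% confidence intervals of the same percentiles over simulated
replicates (default 1000; numpy's default linear-interpolation
quantile estimator for both observed and simulated data).
Prediction correction rescales observed and simulated values alike
by `typical(bin median)/typical(t_obs)` with the typical prediction
at η = 0 and prior-mean pH; pre-lag observations with zero typical
prediction are excluded with a warning. Censored VPCs re-apply the
study stopping rule — retain observations through the first crossing
of 60% released fraction, drop the rest — to every simulated
profile, mimicking a protocol that stops measuring once the tablet's
magnetic moment has decayed (~60% released); the
magnetization-to-release conversion itself is out of scope, the
threshold acts directly on released fraction. Default binning: one
bin per scheduled time in vitro, 1-h bins in vivo (binning was a
design choice; the source does not state one). The per-bin reference
times of the prediction correction are fixed from the observed
(censored) data and shared by every simulated replicate, so the
correction is one common rescaling per bin; typical predictions are
cached across replicates.

## Synthetic data

The in vitro generator reproduces the 23-cell design exactly
(triplicates; 8 cells flagged as previously published, giving the
24/45 profile split) over gastric (pH 1.2, 232 mOsm/kg) and
intestinal (pH 6.8, 98 or 232 mOsm/kg) media at 25–150 rpm. The
sampling schedule is an assumption: every 0.5 h to 16 h for the
slow-eroding high-MK4M formulations (F1, F2) and to 10 h for F3/F4,
spanning the release range. Noise is additive (σ 1.95 mg) on top of
log-normal between-tablet variability; a configurable
missing-at-random fraction emulates sample-quality dropout.

The in vivo generator emulates the magnetic-marker-monitoring (MMM)
crossover: 5 subjects × 6 occasions (F1/F2 fasting; F3/F4 both
prandial states), observations every 30 min to 14 h minus meal-break
windows (0.5 h at +4, +6, +10 h — window width is an assumption),
combined-error noise, and censoring at 60% released applied to the
noisy measurements, as a magnetometer-based stopping rule would be.
The 10-min MMM measurement duration is collapsed to point
observations. GI transit is a configurable stand-in for a
compartmental transit model: fasting gastric residence ~ exponential
(mean 0.7 h), postprandial ~ log-normal (median 3.5 h, log-SD 0.35),
small-intestinal transit ~ log-normal (median 3.5 h, log-SD 0.35),
truncated at the 14-h horizon. These distributions are package
assumptions chosen for physiological plausibility, not fitted
values; transition times are exact (not rounded to the 30-min grid).
Occasions of the low-polymer formulation F4 under fasting status are
excluded from in vivo estimation by default (they were systematically
mispredicted in the source analysis) but retained for diagnostics
and simulation.

What passing recovery tests shows — and does not. The generator
inverts the same model family the estimator fits, with pH draws
recorded and conditioned on, so recovery tests validate the
estimation machinery and identifiability under the study design.
They cannot detect structural misspecification against real tablets
(e.g. percolation-threshold behavior of low-HPMC formulations,
postprandial gastric pH drift, viscosity effects), and the transit
stand-in reproduces only the gross features of real GI transit.

Sequential stopping and finite-sample bias. The measurement-stop
rule (no observations after ~60% released) depends only on already
observed values, so it is ignorable for the likelihood: the fitted
objective is the exact marginal density of the retained data, and
the estimator is consistent. It is not unbiased at the study's
scale: with ~10–25 observations per occasion and stopping tied to
the erosion rate itself, maximum likelihood recovers the segment
mechanical stresses a few to ~15% low (stomach and distal small
intestine most affected; the bias largely disappears when the stop
rule is disabled). This was verified to be a property of the exact
likelihood — adaptive Gauss–Hermite quadrature over the nested
random-effect integrals prefers the same estimates as the Laplace
objective — not an artifact of the approximation or the optimizer.
An analysis of real data collected under the same protocol carries
the same property. Likelihood-ratio calibration has an analogous
caveat: covariates observed at only two design levels (pH) give
anticonservative chi-square tests on reduced designs, because the
between-tablet contrast has too few effective units; operating
characteristics are therefore checked on a covariate spanning four
levels (mechanical stress).

## Problem sizes and numerical choices

The test suite runs the full recovery experiments at the study's own
scale: the 69-profile in vitro design across 10 seeds, and the
clinical design replicated ×4 (20 subjects) once; the
covariate-selection operating characteristics use a reduced
single-formulation design (8 cells × 3, 1-h grid) with 20 power and
100 null replicates, and the VPC self-consistency check uses 50
seeds at 200 simulations each. Acceptance reporting repeats each
recovery experiment three times and reports medians. Degenerate
inputs: zero random-effect variance collapses the Laplace term to
the conditional likelihood at η = 0; an empty distal-SI interval is
simply omitted from the timeline; depletion drives the closed form
to exactly `dose` released without sign errors.

## Known limitations

* The Laplace scheme differs from specific FOCE-I linearizations by
  small OFV offsets; comparisons should stay within one engine.
* Finite-difference Hessians make standard errors approximate;
  they are cross-checked only through parameter-recovery behavior.
* The GI transit stand-in is not a validated transit model; its
  parameters are exposed in `TransitConfig` for calibration.
* Stomach mechanical stress is mostly informed by postprandial
  occasions (short fasting gastric residence), and the colon stress
  carries large uncertainty — mirrored in wide recovery tolerances.
* No pharmacokinetic (drug absorption) layer; erosion only.
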