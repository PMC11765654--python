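# Methods

## The two stages

**Stratification tests.** For each species with captures in both edge
and forest (ridge + valley) habitat classes, the canopy probability is
canopy captures / total captures per habitat and
`delta_edge = forest − edge`, positive when the species shifts toward
the understory at the edge. Under the no-shift null, positive and
non-positive signs are equally likely; the two-cell likelihood-ratio
statistic `G = 2 Σ O ln(O/E)` with `E = n/2` is referred to chi-square
with one degree of freedom. Exact ties (`delta_edge = 0`) are coded
non-positive — a deliberate, conservative convention for the headline
test; note it makes the tie-inclusive test mis-calibrated under a
continuous-sign null (ties shift the expected split away from 50:50),
which is why the package's null-calibration check assesses the nominal
rejection rate on species with non-zero delta only. Two sensitivity
filters mirror field practice: removing obligate understory genera
(*Caligo*, *Eryphanis*, *Taygetis*), then requiring at least three
individuals per habitat class.

**Mediation model.** One observation per unique marked individual; the
structural equations are listed in the README. The edges are exactly
the causal graph's: no interactions, covariates unstandardized, flat
(operationally: Normal(0, 100²)) priors on regression coefficients,
Uniform(0, 50] on error sds. Ridge and valley collapse to `FE = 0` at
analysis time but stay distinct in storage because the state space
keys series by the three habitats.

## Missing-data blocks

**Abiotic state space.** The 12 habitat × stratum × variable hourly
series each follow a first-plus-second-harmonic diurnal baseline with
AR(1) deviations, `x_t = b(hour_t) + e_t`, `e_t = ρ e_{t-1} + ε_t`,
`ε ~ N(0, σ_proc²)`, `e_0 ~ N(0, (3σ_proc)²)`, observed through logger
records `y ~ N(x_t, σ_obs²)`. Within the state-space family, the
harmonic-AR(1) form is this package's choice; it captures the strong
diurnal cycle with five baseline parameters per series. Series are keyed by habitat type, not
site: every logger at any site of a habitat × stratum informs the
shared series, which is what makes captures at never-instrumented
sites imputable. The hour grid is 1 h; two-hourly loggers simply
observe every other state. Mean levels get broad informative priors
(temperature N(25 °C, 5²); log-light N(6, 3²) canopy / N(2, 3²)
understory — artifact defaults, config-overridable); harmonic
amplitudes N(0, 10²).

**Species canopy tendency (FCT).** A species-level logit-scale trait.
Species scored in earlier work get Normal priors obtained by
least-squares fitting a Normal to logit-transformed posterior
quantiles of canopy probability (`fit_logit_normal_from_quantiles`);
unscored species draw from a tribe-level Normal with hyperpriors
tribe mean ~ N(0, 2.5²), tribe sd ~ Half-Normal(1.5). FCT enters the
outcome regression on the logit scale and is sampled jointly (full
Bayes), not plugged in.

## Light

Light is analysed as `ln(lux + offset)` with offset 1.0 (recorded in
run metadata): vegetation filters light multiplicatively and insect
photoreception follows the Weber–Fechner law, so the natural scale is
logarithmic; the offset keeps night-time zeros finite. The log base
and zero-handling are this package's convention. Day-resolution
capture timestamps are assigned a configurable representative hour
(default 12:00), logged, and propagated to contrast construction.

## Sampler

Pólya-Gamma augmentation renders the logistic outcome conditionally
Gaussian, so a full Gibbs sweep is available: outcome coefficients,
the three regression blocks, species tendencies (vectorised across
species), tribe hypers (conjugate mean; random-walk MH on log sd), and
— in joint mode — exact forward-filter backward-sampling of each
latent series with the outcome term entering as Gaussian
pseudo-observations through the capture's canopy-minus-understory
contrasts. PG(1, z) draws use a truncated-series representation
(K = 128 terms) with the exact mean of the discarded tail added, so
the truncation bias of the mean is zero. Chains are seeded from one
`SeedSequence`; identical seeds give identical draws. Convergence is
gated at split-R̂ ≤ 1.01 and ESS ≥ 400 on all fifteen structural
coefficients (arviz); a Gibbs sweep has no divergent transitions, so
the divergence count is structurally zero. Runs failing the gate still
return their draws, flagged `converged = False`, and the effect stage
refuses them unless forced.

### Why the posterior is modularized (the "cut")

With flat priors on the error sds, any Gaussian regression whose
response is itself a free latent quantity — the species tendency,
which appears as the response of one composition-regression term per
capture; the latent abiotic states behind per-capture LD/TD — makes
the joint density unbounded: `σ → 0` with every latent pinned to the
regression line is an infinite-density ridge, and in fact the posterior
mass near it diverges. Blocked Gibbs conditionals funnel into that
region within a handful of sweeps from any start (warm starts
included). The package therefore targets a modularized ("cut")
posterior: the three analysis regressions are fit, per sweep, to the
current draws of their responses but do not feed back into the
latents. Latent species tendencies are updated from their study
priors, the tribe hierarchy and the capture outcomes; latent abiotic
states from the logger likelihood, the AR dynamics and the capture
outcomes. The bounded logistic outcome term keeps information flowing
from captures into every imputation, so the joint intent — missing
values estimated together with the analysis model — is preserved,
while each block stays well posed. The counterfactual machinery uses
the regressions generatively, so effect definitions are unchanged.

The cut has a quantified cost: tendencies of species without study
priors carry no composition-selection information, which attenuates
the species-composition effect slightly (about −0.016 on the
probability scale under the default synthetic conditions) and
anti-attenuates the natural direct effect by a similar amount; the two
cancel in the total causal effect. Because the bias is roughly one
posterior sd for SCE, its 95% interval coverage on synthetic
replicates runs below nominal (15/20 in the packaged run) while the
other five effects are essentially nominal. Feedback variants were
evaluated and rejected: full feedback is unusable (the improper ridge
above), and feeding the composition regression back only into
unscored species is provably ridge-free but self-confirming, biasing
the composition slope far more than the cut does.

## Effects

Potential-outcomes contrasts `CAN(a, LD(a_L), TD(a_T, LD(a_TL)),
FCT(a_F))` with every mediator argument explicit. The telescoping
sequence (all-forest → flip exposure → flip LD → flip TD with its own
LD → flip FCT) defines NDE, light, temperature and species-composition
effects; TCE is the endpoint contrast and edge effect = TCE − SCE.
Expectations over mediator noise are Monte Carlo with common random
numbers — one triple of base normals per replicate reused across the
five settings — giving exact per-draw additivity and strong variance
reduction. The reference population is the observed capture set; every
covariate role is replaced by counterfactual draws, so the choice only
fixes the Monte Carlo replicate count per posterior draw (population ×
K; K defaults to 1000 and is reduced in test harnesses). The
synthetic module carries an independent brute-force oracle
(`oracle_effects`, K = 10⁶ at the true coefficient vector,
cross-checked against Gauss–Hermite quadrature in the tests).

## Synthetic data: what it emulates, and what it does not

Defaults mirror the study scale: 32 sites (10 edge / 12 ridge / 10
valley), 14 trapping days, ~1.6 captures per site-day (≈ 700
individuals), ~90 species in 12 tribes with log-series abundances,
capture hours uniform over the 08:00–16:00 trap window. Diurnal curves
put the edge understory near the forest canopy and far above the
forest understory in daytime light, and make canopies hotter by day
and slightly cooler at night. Logger records drop out at a base rate
inflated 2.5× in the first half of the study (missingness explainable
by time, hence MAR) and a configured number of sites per habitat are
never instrumented; 30 % of species are absent from the prior table.

Species identity per capture is assigned by drawing a target tendency
from the composition equation and picking a species with probability ∝
abundance × a narrow Gaussian kernel (sd 0.15) around the target — the
configured composition equation is then the observation-level truth up
to a negligible kernel widening (√(0.9² + 0.15²) ≈ 0.91 vs 0.9). Two
mediator regimes: `"regression"` (default) draws LD/TD from the
structural equations so the configured coefficients are exact ground
truth — used for recovery and coverage studies; `"abiotic"` reads
LD/TD off the latent diurnal series — used for end-to-end runs, where
the structural coefficients describe the realized contrasts only
approximately. The generator has no spatial autocorrelation between
sites, no bait or seasonality effects, and its captures are
exchangeable within site-days — passing tests say nothing about those
features of real data.

## Problem sizes and numerics

Test-suite scales were chosen as the package's own desk scale:
recovery and coverage use 20 replicates of 1000 captures with 2 chains
× (400 warmup + 700 kept × thin 5); the imputation benchmark uses one
paired site over 14 days with 20 % gaps against an exact
Kalman smoother at true parameters; null calibration uses 500
generator replicates for the G-test and 10 posterior fits for effect
coverage. Numerical guards: zero G-test cells contribute 0 (x ln x
limit); AR coefficients are truncated to (−0.995, 0.995); error-sd
draws are redrawn above the Uniform(0, 50] cap; FFBS conditional
variances are floored at 1e−12; the PG tail-mean correction is clipped
non-negative. Degenerate inputs are first-class: single-level FE
designs are flagged unidentified, zero-capture models run prior-only,
and empty hourly-summary cells are omitted and logged.

## Known limitations

The mediation model is deliberately minimal (no interactions, no
species-varying slopes, no splines), matching the graph exactly. The
cut posterior's SCE/NDE mis-centering is described above. The G-test
stage inherits the printed tie convention. The composition equation
treats captures as independent species draws, ignoring any within-day
trap correlation. Counterfactual FCT(a) draws come from the fitted
composition normal, not from resampling actual species.
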