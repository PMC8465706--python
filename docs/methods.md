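# Methods

## Model

The whole-body kinetics of ¹²⁴I/¹³¹I-CLR1404 are described by a
constant-coefficient linear compartmental system. With yᵢ(t) the percent
of injected activity in pool i,

    dyᵢ/dt = Σⱼ k_{j,i} yⱼ − Σⱼ k_{i,j} yᵢ − λ yᵢ,

where k_{i,j} [h⁻¹] is the first-order transfer constant from pool i to
pool j and λ [h⁻¹] the physical decay constant of the radiolabel. In
matrix form dy/dt = M y with column sums of M equal to −λ exactly: mass
leaves the system only by decay. The measured activity of organ s is a
sum of its *dry tissue* pools plus a blood fraction,
A_s(t) = Σ_{i∈s} yᵢ(t) + f_s·y_blood(t).

The reference structure has 17 compartments: blood; fast/slow pairs for
heart wall, kidneys, lungs, liver, bone marrow, the remaining tissues
(RT) and the tumor; a single spleen pool; and the urinary-bladder
contents. Most organs exchange blood→fast, fast→blood and fast→slow
(slow pools are sinks emptied only by decay); the tumor additionally
returns slow→fast; the spleen is a pure sink fed from blood; excretion
drains the kidney fast pool into the bladder contents. That gives 24
rate constants and 6 blood fractions (tumor and bladder blood content is
treated as negligible).

**Assumptions.** First-order (linear, time-invariant) kinetics; the
¹²⁴I- and ¹³¹I-labelled compounds are kinetically identical up to decay;
organ masses are constant; all fitted activities include physical decay
(a decay-corrected mode exists but is off by default).

## Numerics

Because M is constant the trajectory is computed exactly as matrix
exponentials over time increments (better conditioned than e^{M t_p} for
wide grids), and the cumulated activity over [0, ∞) of any observable
w·y is the closed form w·(−M⁻¹y₀) whenever the system is strictly stable
(λ > 0 or an open system). A singular M (closed system, λ=0) raises a
divergence error. Adaptive quadrature of the solved trajectory is used
as an independent cross-check in the test suite (agreement ≤ 1e−6
relative).

Decay constants are not hard-coded into the model class:
T½(¹³¹I) = 8.0252 d (λ = 3.5988e−3 h⁻¹) and T½(¹²⁴I) = 4.176 d are
standard nuclide data, exposed as configurable constants.

## Data processing

Per-mass concentrations [%/g] are scaled to whole-organ activities with
reference organ masses (human female reference values; 30 g phantom
masses for murine data). Tumor series arrive on separate PET (≤120 h)
and SPECT (>120 h) calibrations; the SPECT branch is fit to a single
exponential by weighted least squares on log-activities (positivity,
stability) and rescaled to match the PET value at the 120 h junction;
the overlapping SPECT point is discarded. Measurement uncertainties are
5% of the value (10% for tumor SPECT); series that carry their own
cohort dispersions (blood, urine) keep them. A σ floor of 1e−6 % guards
zero activities so inverse-variance weights stay finite. Default
exclusions: the 120 h urine point and the whole spinal-cord series.

## Fitting

The objective is WRSS = Σ(A_obs−A_model)²/σ². Two stages:

1. **Decoupling.** The blood curve is fit to a biexponential forcing
   function h(t) = A₁e^{−α₁t} + A₂e^{−α₂t} with A₁+A₂ = 100%. Each organ
   subsystem is then fitted with blood locked to h(t): the forcing enters
   as two pseudo-compartments that decay at α₁, α₂ and feed the tissue
   through the blood→tissue edges without being depleted. Physical decay
   applies to the tissue states; the forcing rates already contain decay
   because h was fitted to decay-included blood data (both decay modes
   are available; decay-included is the default so the decoupled and
   joint stages are consistent).
2. **Joint fit.** The forcing restriction is lifted; blood becomes a
   state with a 100% bolus initial condition, and all rates plus blood
   fractions are fitted simultaneously, initialized from the decoupled
   estimates.

The optimizer is simulated annealing with geometric cooling
(T_{k+1} = 0.95 T_k; 150 temperatures × 40 steps by default), initial
temperature from the interquartile spread of the objective over a random
probe of the box, log-space Gaussian proposals for rate constants
(linear for blood fractions), reflection at the bounds, restart from the
incumbent best at each temperature, and a proposal scale annealed with
√(T/T₀). Runs are bit-reproducible for a fixed seed. The annealing
optimum is then refined by a derivative-free Powell polish or (default)
a finite-difference trust-region least-squares polish on the weighted
residual vector in log-rate coordinates. The least-squares refinement
was adopted after the derivative-free options proved unable to track the
curved, nearly flat valleys created by fast blood↔tissue exchange pairs
(which equilibrate long before the first sample, leaving only their
ratio strongly identified): annealing plus Powell plateaus around
WRSS ~1e−3 on noise-free recovery problems, while the trust-region
polish reaches the generating truth to machine precision in seconds.
Annealing remains the global stage; the polish is a local refinement of
its optimum.

Rate constants are bounded to [1e−8, 1e2] h⁻¹ (two decades beyond the
fitted range on either side). Blood fractions are constrained to a
window of ±30% around their physiological reference values. Note a known
inconsistency in the reference configuration: the published best-fit
kidney blood fraction (2.7%) lies outside the ±30% window around its
2.0% reference, so recovery experiments that use the published values as
ground truth run with a ±50% window (otherwise the truth is infeasible
and noise-free WRSS stalls near 2e−2); the production default remains
±30% and is configurable.

Goodness-of-fit is reported as WRSS/(N−K) with K the number of free
rates plus blood fractions. Model ranking uses
AICc = N ln(WRSS/N) + 2K + 2K(K+1)/(N−K−1) with the natural logarithm
(standard AIC convention; the base is configurable); candidates are
comparable only on identical datasets, enforced by a dataset
fingerprint. Ties break toward smaller K, then lexicographic tag.

Candidate inventories: per organ, one dry-tissue pool (bidirectional or
sink) or a fast/slow pair (four rates, or slow sink); for excretion, the
kidney-fast route with every combination of the optional blood→bladder
and slow→fast edges, plus a urinary-path scheme (blood→transit
tissue→bladder, with or without transit→blood return) in which the
kidneys remain a regular two-pool organ so all excretion candidates fit
the same kidneys-plus-urine data and their AICc values are comparable.

Joint multi-subject fitting ties all parameters across subjects except a
named free group (default: every rate touching a tumor compartment),
summing the per-subject WRSS.

## Sensitivity analysis

Sobol first-order (Sᵢ) and total-order (S_Ti) indices of a scalar output
— by default the WRSS of the model against the reference dataset — under
independent truncated-normal perturbations of the parameters (10%
relative SD, truncated at zero to preserve rate positivity; the
truncation matters only in principle at 10% RSD). Estimators: Saltelli
two-block sampling with the Jansen formulas, cost M(K+2) evaluations;
Monte Carlo standard errors by bootstrap over sample rows. Full-scale
runs use M = 5×10⁴; the test suite uses M ≤ 2 000.

Pruning removes parameters whose S_Ti **plus** its MC standard error is
below the threshold (default 1e−4): a parameter that truly does not
influence the output yields an exactly zero Jansen estimate, whereas
weakly-but-genuinely identified rates sit orders of magnitude higher;
demanding confidence below threshold means small sample sizes prune
nothing rather than pruning essential paths.

## Monte Carlo uncertainty

Each run resamples every observation from Normal(value, σ) truncated at
zero and refits the model; parameter means and SDs are reported over the
completed runs (default 100; failures are logged and excluded, never
fatal). Data-perturbation and optimizer seeds are derived independently
per run from a master seed, making the full run table reproducible.

## Simplified dosimetric estimators

1. **Reduced model (SM):** slow pools removed except for RT and tumor;
   refit jointly.
2. **Biexponential (BE1/BE2):** per-organ weighted fit of
   c₁e^{−μ₁t}+c₂e^{−μ₂t} with Ã = c₁/μ₁ + c₂/μ₂; BE2 uses only the four
   points at [2, 24, 120, 505] h (an exhaustive subset search over the
   time grid is available and reports the best subset). Rates are
   unconstrained in sign so rising (bladder-like) series are detected: a
   non-positive fitted rate makes the integral undefined, reported as a
   flagged cell rather than an error.
3. **Monoexponential (E t\*):** a single measurement (A\*, t\*) is
   back-extrapolated to t=0 assuming pure physical decay and integrated
   over [0, ∞): Ã = A\*·e^{λt\*}/λ. Back-extrapolation is the only
   decay-consistent reading of a one-point fit; integrating from t\*
   instead is available as an option.

The comparison table reports 100·(Ã_simpl − Ã_full)/Ã_full per organ,
with undefined entries carried as blanks.

## Synthetic data

The clinical series the model derives from were digitized from published
figures and never deposited, so the generator stands in for them: it
solves the model from a 100% bolus, samples organ observables at
PET-like times [2, 5, 24, 48, 72, 120] h and SPECT-like times
[170, 330, 505] h (a plausible reading of the reported acquisition
ranges; fully configurable), applies multiplicative truncated-normal
noise at 5% relative SD (10% for tumor SPECT; a lognormal law is
available), and attaches matching σ. It produces nine organ series
(six merged organs, tumor PET and tumor SPECT kept separate so the
merge-and-rescale step is exercised, and a low-uptake spinal-cord series
at 0.4% of the blood curve that the default filters discard), plus blood
and urine. The murine template expresses five organs in %/g with the
30 g phantom masses and omits blood/urine series, mirroring the
xenograft data situation.

What the generator does **not** emulate: image-reconstruction artifacts,
partial-volume effects, inter-patient variability, or any PET/SPECT
calibration physics beyond a single tumor scale factor. Passing tests on
synthetic data therefore demonstrate correctness of the estimation
machinery under the model's own assumptions, not clinical validity.

## Problem sizes used in the shipped tests and pipeline defaults

Tests and the demonstration pipeline use reduced problem sizes chosen to
exercise every stage at desk scale: Sobol M between 24 and 2 000,
Monte Carlo 3–25 runs, annealing schedules of 4–20 temperatures with
8–20 steps, and 50 seeds for the structure-recovery experiment. The
full-scale settings (M = 5×10⁴, 100 MC runs, 150×40 annealing) are the
package defaults for production runs.

## Known limitations

* The published parameter values are printed to ~2 significant figures;
  forward-computed cumulated activities therefore reproduce the reported
  per-organ values only to a few percent, and the heart-wall
  blood-contribution share is pinned by those rounded values at 15.8%,
  below the reported ≈21% (the spleen share, 74.5%, matches its reported
  ≈77%). The two reported shares in fact imply mutually inconsistent
  blood integrals, so at least one cannot be reproduced exactly from any
  single parameter set.
* Fast exchange pairs (heart, tumor) equilibrate before the first
  sampling time; only their ratios are strongly identified by data on
  the clinical schedule. Recovery guarantees are therefore stated for
  parameters with total Sobol index above 0.05.
* Structural identifiability is asserted only numerically (recovery
  experiments), not symbolically.
* No absorbed-dose conversion: the package stops at cumulated activity.
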