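# Methods

`chemocal` implements a complete multivariate calibration workflow for the
simultaneous UV-spectrophotometric quantitation of two strongly overlapping
analytes in binary mixture: experimental design, validation-set sampling,
spectral preprocessing, five calibration models, and the figures of merit
used to compare them. Because no instrument spectra ship with the package,
every part of the workflow is exercised on synthetic Beer–Lambert mixture
spectra produced by `chemocal.simulate`.

## The study system

All models see the same two blocks: a spectral matrix `X` (n samples × 301
absorbances on the 200–260 nm grid at 0.2 nm) and a concentration matrix
`Y` (n × 2, µg mL⁻¹). The calibration set is the full 5-level × 2-factor
multilevel design — 25 mixtures with each component at 5.0, 10.0, 15.0,
20.0 or 25.0 µg mL⁻¹, every level appearing exactly five times per factor.
For two factors at five levels the cyclic multilevel construction and the
full factorial coincide (same run count, same level balance), so the full
factorial is generated. The validation set holds 13 mixtures drawn by
Latin hypercube sampling (LHS): each axis of the 5–25 µg mL⁻¹ square is
split into 13 equal-width intervals ("equal probability" under the uniform
marginal), one point lands uniformly inside each interval, and the
interval order is permuted independently per axis. The 25 + 13 = 38-sample
split is the conventional ≈2:1 calibration:validation ratio. A matched
Monte Carlo sampler (i.i.d. uniform) exists solely as the comparison
baseline.

## Synthetic spectra

Pure-component spectra are sums of Gaussian bands: component A has bands
at 210 nm (σ 8 nm) and 240 nm (σ 12 nm); component B at 205 nm (σ 6) and
225 nm (σ 10). Band positions are synthetic stand-ins chosen to reproduce
the heavily overlapped regime that motivates multivariate calibration
(cosine similarity of the normalised spectra > 0.7 over 200–260 nm); they
are not measurements of any real drug, and the generated manifest flags
this. Each component's molar scale is normalised so 15 µg mL⁻¹ gives a
0.4 AU peak, which keeps the strongest 25 + 25 µg mL⁻¹ mixture below
~1.3 AU — inside the linear Beer–Lambert range of a bench instrument.
(A 0.5 AU normalisation would push the overlapping sum to 1.6 AU, so the
linear-range constraint won.)

Mixtures follow `A = (C Sᵀ)(1 + scatter) + baseline + noise` with defaults
typical of bench UV work: additive detector noise SD 0.002 AU, per-sample
multiplicative scatter SD 0.01, per-sample linear baseline-slope SD
10⁻⁴ AU nm⁻¹. The plasma surrogate adds one broad band near 208 nm at a
random small amplitude plus raised additive noise, emulating residual
matrix absorption after protein precipitation; no extraction chemistry is
modelled. With all noise terms zero the map is exactly bilinear, which is
the regime the recovery guarantees are stated in.

Raw-stage spectra are validated as non-negative with a −0.05 AU
tolerance: near-zero absorbance plus additive noise and baseline drift
legitimately dips below zero on real spectrometers, and clipping would
distort the noise distribution the generator promises.

What the generator does **not** emulate: wavelength-dependent
(heteroscedastic) noise, stray light and detector nonlinearity at high
absorbance, band shifts with solvent or temperature, and real excipient
or plasma chemistry. Passing tests therefore demonstrate correctness of
the algorithms under a linear-mixture model with well-behaved noise, not
performance on any particular instrument's data.

## Preprocessing

Savitzky–Golay smoothing defaults to a third-order polynomial over an
eleven-point window; derivatives (first by default — the second is
markedly more noise-sensitive) are scaled by `step_nm⁻ᵈ` so their units
(AU nm⁻ᵈ) do not depend on the grid. Output keeps the full 301-point
grid; edge points are evaluated from the polynomial fitted to the nearest
complete window. SNV centers and scales each spectrum to unit SD (n−1
denominator). When both SNV and mean-centering are requested, SNV runs
first (a documented ordering choice; the alternative is equally
defensible). PCA diagnostics come from the SVD of the mean-centered
matrix, with variance percentages `100·σᵢ²/Σσ²`.

One empirical caveat, measured on this generator: under additive white
noise, Savitzky–Golay smoothing does *not* systematically lower the
RMSEC/RMSEP of a full-spectrum PLS model (the latent projection already
averages across ~301 channels); smoothing does, as expected, bring the
spectra themselves much closer to the noise-free signal. The test suite
asserts the latter property.

## PLS

Classical NIPALS with deflation of both blocks, modelling the two
components jointly (PLS2); a single-response call gives PLS1. The LV
count is the leave-one-out RMSECV minimum, ties broken toward fewer LVs;
RMSECV at k LVs pools both responses, `√(Σe²/(n·q))`. LOO is computed
with one NIPALS run per held-out sample, extracting the prediction for
every candidate LV count from that run's deflation sequence; the tests
verify equality (1e-10) with a naive per-(sample, LV) refit loop and, at
full rank, with ordinary least squares. RMSEC divides by n. A rank
deficiency below the requested LV count is an error in `fit_pls`; inside
cross-validation the extraction truncates at the achieved rank and the
last coefficients carry forward (noise-free data are exactly rank 2, and
a hard error there would make CV curves impossible).

## GA wavelength selection

Both flavours share one GA engine: binary chromosomes over wavelengths
(or contiguous windows when `window_size > 1`), size-2 tournament
selection, uniform crossover, per-bit mutation (default 1%), elitism of
one, all-zero children repaired by setting one random bit. The initial
population is random 50%-density masks plus one all-ones chromosome, so
the full-spectrum model is always in the search space and the returned
solution can never be worse than it. Best-so-far fitness is therefore
monotone non-increasing, and runs are exactly reproducible from the seed.

* **GA-PLS** minimises `RMSECV + λ·k/p` with λ = 0.05. The normalised
  count `k/p` keeps λ scale-free; the functional form is a documented
  choice (only λ's value is fixed by the study design). Defaults: 100
  generations, multi-restart with the lowest cross-validated fitness
  retained.
* **GA-ICOMP-PLS** minimises `ICOMP = −2 log L + 2 C(Σ̂)` where
  `Σ̂ = EᵀE/n` is the covariance of the *leave-one-out* residuals of the
  masked PLS model (so the criterion scores generalisation, not fit), the
  log-likelihood is the profiled Gaussian, and `C` is Bozdogan's C1
  covariance complexity `(q/2)·ln(tr Σ̂/q) − ½·ln det Σ̂` — zero exactly
  when Σ̂ is spherical, positive otherwise. Both analytes are modelled
  jointly (q = 2) because C1 vanishes identically at q = 1. Defaults: 50
  generations, population 30. A singular Σ̂ receives a one-time 1e-12
  ridge and the score is flagged.

The LV count is held fixed during the search: the GA selects wavelengths,
not model order.

## ANN

A 301-6-2 feed-forward net, tanh hidden layer, linear output. Inputs and
outputs are min-max scaled to [−1, 1] on the training partition only.
Samples are split 70/15/15 (round-half-up: 18/4/3 at n = 25) into
training, monitoring-validation and test; early stopping is off by
default (validation MSE is recorded).

Training is Levenberg–Marquardt: `(JᵀJ + μI)δ = −Jᵀe` with μ ×10 on a
rejected step and ÷10 on an accepted one, so accepted-step MSE strictly
decreases. Two numerical choices matter:

* the damped step is computed from the economy SVD of the Jacobian
  rather than the normal equations (squaring the condition number stalls
  a naive solve on this badly scaled two-layer problem), and
* before each LM step the output layer — linear in its own weights — is
  refreshed by its closed-form least-squares optimum, accepted only when
  it lowers the MSE. This hybrid step preserves the monotone guarantee
  and reaches interpolation in tens of epochs where plain LM needed
  thousands.

Initialisation for spectral calibration uses small hidden weights
(uniform ±0.004) and larger output weights (±4). The reason is
generalisation, not convergence: the absorbance→concentration map is
linear, and any *linear* interpolant of the rank-2 training data is exact
on the whole mixture manifold. Starting the tanh layer in its linear
regime makes the trained net embed that linear map; a generic ±0.5 init
saturates hidden units and leaves percent-level random wiggle between
calibration points. The generic initialiser (±0.5, as used for the small
test networks) remains available through `init_ann`'s scale parameters.

On noisy data the default configuration trains to interpolation and
therefore overfits the noise somewhat (visible as a higher ANN RMSEP in
the bundled study); a larger `goal` or the epoch budget are the
practitioner's levers.

## MCR-ALS

`D ≈ C Sᵀ` with non-negativity on both factors, solved by alternating
true non-negative least squares (active-set NNLS per column — not
zero-clipping, which would break monotonicity). Lack of fit
`100·√(Σe²/Σd²)` is non-increasing over iterations; convergence is a
relative lof change below 1% by default (configurable; "absolute vs
relative" was unspecified in the source procedure — relative is
implemented). Reported alongside: `r² = 100·(1 − (lof/100)²)` and the
residual SD `√(Σe²/(np))`. Initial spectral profiles are data rows chosen
by maximum dissimilarity (largest norm first, then largest residual off
the span of those chosen).

A bilinear factorisation under non-negativity alone is identified only up
to an invertible mixing of the factors. On exact rank-2 data, ALS can
legitimately stop at zero lack-of-fit in a rotated basis, so quantifying
each analyte by a univariate line on "its" resolved profile is not exact
in general. `quantify_from_mcr` therefore defaults to a **joint** linear
calibration map — OLS of the known calibration concentrations on all
resolved profiles plus intercept — which inverts whatever mixing ALS
settled on and is exact in the noise-free limit. The univariate rule
(assignment by best spectral/profile correlation, error on ambiguity) is
retained as `method="univariate"` for the rotation-free case.

## Figures of merit and method comparison

RMSEC/RMSECV/RMSEP all use `√(Σ(ŷ−y)²/n)` on their respective sample
sets. Recoveries are `100·ŷ/y` with n−1 SD, `%RSD = 100·SD/mean(%R)` and
`%RE = 100·mean(|ŷ−y|/y)` (mean absolute relative error; a signed-mean
variant is a one-line change). The predicted-vs-actual line is ordinary
least squares of ŷ on y with Pearson r (reported as missing, never 0,
when undefined). Method comparison uses the pooled-variance two-sample t
(a paired option exists) and `F = larger/smaller variance ≥ 1`; critical
values are computed from the t and F quantiles at runtime (e.g. 2.306 and
6.39 for two groups of five at α = 0.05), never from hard-coded tables.

## The sampling-comparison experiment

Two claims are tested. First, coverage: a 13-point Monte Carlo set leaves
at least one of 13 equal strata empty with probability `1 − 13!/13¹³`
(≈ 1 − 2.06·10⁻⁵) per axis — essentially always — while LHS never does,
by construction. Second, stability of the RMSEP estimate. Under a
well-specified 2-LV model with additive noise, prediction error is
essentially position-independent and measured RMSEP SDs for LHS and MC
coincide to within ~1% — there is nothing for stratification to
stabilise. The stabilising mechanism operates when prediction error
varies over the concentration space, so the experiment that isolates it
uses a single fixed calibration model with spatially structured bias (one
latent variable, i.e. deliberately underfit), re-draws only the
validation sets (`compare_sampling(fixed_calibration=True)`), and pools
the SD of RMSEP over five calibration blocks × 400 redraws. In that
regime the stratified sets give a consistently smaller SD (pooled ratio
≈ 1.1). Single blocks at small repeat counts remain noisy; the pooling
is part of the experiment's design, not a tolerance.

## Problem sizes and determinism

The bundled study runs at the design's natural sizes (25 + 13 + 13
samples, 301 wavelengths). Test and demonstration GA runs use reduced
populations/generations (e.g. 10–20 × 6–18) since their assertions are
structural (monotonicity, reproducibility, planted-signal recovery)
rather than exhaustive-search results; the library defaults keep the full
50 × 30 (ICOMP flavour) and 100-generation (penalized flavour) settings.
Every stochastic component — design jitter, noise draws, GA, ANN init,
partitions — takes an explicit integer seed; there is no global random
state, and equal seeds reproduce byte-identical artifacts.

## Known limitations

* The Gaussian-band spectra and noise model are deliberately simple;
  none of the recovery guarantees transfer to matrix effects or
  instrument nonlinearity that the generator does not model.
* MCR-ALS is run without closure, unimodality or known-spectra equality
  constraints; rotational ambiguity is handled at quantification time
  only.
* The ANN training path is tuned for small calibration-sized problems
  (tens of samples); the dense Jacobian would not scale to large nets.
* GA results are seeds-and-budget dependent as in any metaheuristic; the
  package guarantees reproducibility and monotone incumbent fitness, not
  global optimality.
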