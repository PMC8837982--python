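# Methods

This note documents the models behind `teagrow`, the defaults and why
they were chosen, what the synthetic generator does and does not
emulate, and the numerical choices that affect results.

## NDVI reconstruction

Cloud contamination depresses satellite NDVI abruptly; true canopy
vigor changes slowly. The reconstruction is a Savitzky–Golay filter —
per-window polynomial least squares expressed as a fixed convolution —
followed by maximum-value selection: each output is
`max(smoothed, observed)`, so the reconstruction is an upper envelope
of the smooth fit and the raw series. Defaults: window 5, polynomial
order 2. Edges use mirror padding (reflection without repeating the
edge sample), which preserves constants exactly; non-constant trends
are slightly bent within half a window of each end.

Two biases are worth knowing about, both characterized by the test
suite rather than hidden:

* the envelope retains positive noise excursions, so on *drop-free*
  data it biases the series upward by roughly the noise amplitude
  (about a 4% perturbation of the recovered cubic coefficient at noise
  sd 0.001). The envelope is a repair for cloud drops; when a series
  is known to be cloud-free, filter with `envelope=False` or fit the
  raw column;
* the mirror-padded edge values are biased by O(local slope), which
  matters for coefficient-recovery experiments but is negligible for
  the correlation and model-selection analyses.

An iterated-envelope variant is deliberately not implemented: one
filtering pass is the procedure being modelled.

## Soil features

Probe readings (10-minute cadence) are averaged per calendar day
(naive local time, no DST handling), then:

* **instantaneous features** — the mean of all readings in the
  half-open window `[epoch − 5 d, epoch)`, i.e. the five days leading
  up to each satellite revisit;
* **cumulative features (SST/SSMC/SSEC)** — running sums, from the
  first day of the series, of daily means exceeding 0, evaluated at
  each epoch (days at or below zero contribute nothing). This is the
  growing-degree-day construction applied in each variable's native
  unit; by instrument range the positivity threshold only ever binds
  for temperature. Units are °C·day, %·day and μs/cm·day.

Normalization is min–max to [0, 1] with the scaling parameters
retained for inversion; cumulation is applied before any
normalization (cumulate-then-normalize), since the sums are physically
meaningful in native units.

## Growth-response models

Five families per feature, named Y1–Y5: polynomials of degree 1, 2, 3
and power laws `a·x^b` (one term) and `a·x^b + c` (two terms).
Ternary ("fusion") fits use all monomials of total degree ≤ d in the
three features for polynomials; the ternary power family is the
additive per-feature law `Σⱼ aⱼ xⱼ^bⱼ`. Power laws require strictly
positive features.

Polynomials are solved by linear least squares on the design matrix.
Power laws use multi-start nonlinear least squares: a fixed grid of
exponents in [−3, 3] (amplitudes initialized by linear least squares
given the exponent), tolerances 1e-10, at most 20 starts, best SSE
wins. The start grid is fixed, so fits are deterministic.

Two RMSE conventions coexist and are exposed under separate names:

* construction tables: `RMSE = sqrt(SSE/(n−p−1))` — a residual
  standard error penalizing the p fitted features;
* validation tables: `RMSE = sqrt(MSE) = sqrt(SSE/n)`.

Adjusted R² is `1 − (1−R²)(n−1)/(n−p−1)` with p the number of
non-intercept basis terms (degree for univariate polynomials, 1 or 2
for the power laws, 3 for the ternary power law, 19 for the ternary
cubic). On a 12-epoch validation split the ternary cubic has
n ≤ p + 1, so its validation AR is reported as NaN rather than by an
undefined formula.

The split is chronological — first 60 epochs fit, last 12 validate —
with no shuffling. Note that chronological validation of
*instantaneous*-feature models is intrinsically hard: late-season soil
states alias early-season ones while NDVI does not (hysteresis), so
their held-out R² can be strongly negative even when construction R²
is decent. The cumulative features exist precisely because they are
monotone in time and carry the season's history.

## Bald Eagle Search

A population metaheuristic over a box-bounded continuous space. Each
iteration applies three moves to every individual, in narrative order:

1. select: `P_best + α·γ·(P_mean − P_i)`, γ ~ U(0,1) per individual,
   α ∈ [1.5, 2];
2. search: `P_i + x_i·(P_i − P_mean) + y_i·(P_i − P_{i+1})` with
   max-normalized Archimedean-spiral coordinates
   (θ = a·π·rand, r = θ + R·rand), circular neighbour indexing;
3. swoop: `rand·P_best + x1_i·(P_i − c1·P_mean) + y1_i·(P_i − c2·P_best)`
   with hyperbolic-spiral coordinates (r = θ, sinh/cosh).

Defaults: population 30, 100 iterations, α = 2, a = 10, R = 1.5,
c1 = c2 = 2. Design choices where the procedure is underdetermined:
greedy acceptance (a candidate replaces an individual only if strictly
better), matching the original BES publication and guaranteeing a
monotone best-so-far history; boundary handling by clipping; the
population mean recomputed per candidate; the spiral radius in the
swoop phase is `r = θ` exactly as that phase's equations state (no
`R·rand` term, unlike the search phase). On the 2-D sphere benchmark
the optimizer reaches ≤ 1e-2 from every tested seed well within 100
iterations.

## LSTM forecaster

A single-layer cell with gates acting on the concatenation
`[x_t, h_{t−1}]` and a sigmoid scalar readout `σ(W′h_L + b′)`; the
sigmoid readout is kept (rather than an identity head) because targets
are min–max normalized into (0, 1). "Hidden size" means the number of
units of this one layer.

Inputs are windows of `lookback` consecutive epochs of the three
normalized instantaneous soil features; the target is NDVI at the
window's final epoch. Default lookback 2 turns 72 epochs into 71
windows, split 50 train / 21 test chronologically. Normalization
parameters come from training rows only.

Training: full-batch backpropagation through time with Adam
(β₁ = 0.9, β₂ = 0.999), default 500 epochs, weights initialized
uniform ±0.1 under the seed. No mini-batching — the dataset is at most
a few dozen windows. Analytic gradients match central finite
differences to ≤ 1e-5 relative on randomized small instances.

## BES–LSTM tuning

BES searches (log₁₀ learning rate, hidden size) — log scale because
rates span decades, hidden size as a continuous coordinate rounded on
decoding — minimizing the RMSE of the trained network on the held-out
split. Every fitness evaluation trains under the same inner seed, so
fitness is a deterministic function of the candidate; otherwise greedy
acceptance would compare training noise. Defaults: lr ∈ [1e-4, 1e-1],
hidden ∈ [2, 64].

The tuning fitness is evaluated on the same split used for the final
comparison, mirroring the single train/test protocol of this study
design; this leaks the test split into model selection, so the
comparison measures *tuning effectiveness on that split*, not
generalization of the tuned configuration. The benchmark suite uses a
reduced search (population 6, 8 iterations, 150 training epochs per
evaluation) over 20 seed pairs and compares medians, which keeps the
whole experiment around three minutes on one CPU.

## Synthetic data

The generator emulates one instrumented site-year:

* ST: annual sinusoid (mean 20.5 °C, amplitude 7.5 °C, coldest around
  day 15 — winter ≈ 13 °C, summer ≈ 28 °C), 1 °C diurnal ripple,
  Gaussian sensor noise sd 0.2 °C;
* SMC and SEC: annual sinusoids in anti-phase with temperature (wet,
  salt-rich topsoil in the cool season) with their own phase days
  (45 and 5) so the three signals are correlated but not collinear;
  noise sd 0.5 % and 3 μs/cm. All readings are clipped to instrument
  ranges (ST −40…80 °C, SMC 0…100 %, SEC 0…5000 μs/cm);
* NDVI: a cubic response `0.15 + 1.9s − 1.6s² + 0.4s³` in the scaled
  cumulative feature `s = SST/7500` (rises through the season, dips
  slightly at the end, stays within [−1, 1]), plus observation noise
  (default sd 0.02) and, with probability 0.08 per epoch, an
  additive cloud shock of depth 0.3. Cloud distortion is additive
  rather than missingness because that is how contamination presents
  in real NDVI series. Several probe nodes can be simulated and
  averaged; the default is one pooled series, which is what the
  analysis consumes.

The generator computes its cumulative features through the same code
path the pipeline uses, so with all noise off the
generate → aggregate → cumulate → fit loop recovers the generating
cubic to machine precision — an end-to-end identity the tests assert.
For noisy recovery experiments the "low noise" condition is sd 5e-5:
the cubic coefficient's sampling error is about ten times the noise sd
at n = 60, so this makes 1% relative recovery a ≥ 8σ claim instead of
a per-seed coin flip.

What the generator does **not** emulate — and hence what passing tests
cannot show about real plantations: rainfall events and irrigation
(soil moisture is smooth here), multi-year trends, spatial
heterogeneity across probes, sensor drift and dropout, true
atmospheric/BRDF effects on NDVI beyond additive shocks, and any
management intervention. Absolute metric values on generated data are
properties of these modelling choices, not of any real plantation;
only structural claims (sign patterns, model-family ordering,
cumulative-vs-instantaneous contrast, tuning dominance) transfer.

## Degenerate inputs and tie-breaks

Constant sequences cannot be min–max normalized and raise; zero-
variance columns make correlations undefined and raise naming the
column; a constant target makes R² undefined and raises; MAPE with a
zero target is reported as NaN with a warning while the other four
metrics are returned. Non-finite objective values in BES reject the
candidate (logged) rather than poisoning the population; a fully
non-finite initialization fails loudly. A zero-width tuning dimension
is widened by 1e-9 internally and collapsed back on decoding, so a
degenerate search space returns its single candidate.
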