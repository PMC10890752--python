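# Methods

## The learning problem

A sensory neuron receives N parallel inputs x = (x₁ … x_N) through synaptic
weights w and responds with the rectified linear rate y = (wᵀx)₊.  Latent
features worth learning are assumed *sparse*: their amplitude distributions
are long-tailed (all-or-none events, oriented edges), i.e. they live in the
higher-order statistics of the input.  Second-order correlations — shared
Gaussian fluctuations, overlapping tuning curves, neighboring-pixel
correlations — are treated as uninformative.  Classical Hebbian mechanisms
follow exactly those second-order correlations (a linear Hebbian rule is a
principal-component analyzer), so the package centers on the rule family
that does not:

    Δw ∝ x·y^(p−1) − h_y·x·y,        h_y = ⟨y^r⟩,   p > 2,  r > p − 2.

Nonlinear Hebbian LTP (x·y^(p−1)) provides sensitivity to higher-order
structure; *linear* Hebbian LTD (−h_y·x·y) subtracts, at the homeostatic
equilibrium, exactly the covariance-driven part of the LTP drive.  The rule
ascends the normalized objective ⟨(y/σ_y)^p⟩ with σ_y = √⟨y²⟩, which is
invariant to any invertible linear transformation of the input — hence
"correlation-invariant".  p = 3, r = 2 is the BCM-like default
(Δw = η(xy² − h_y·xy), h_y = ⟨y²⟩); p = 4, r = 3 is the kurtosis variant.

Two controls deliberately lack this invariance and are implemented for
contrast: heterosynaptic LTD (Δw = η(xy² − w·y²), Oja-style weight scaling,
stabilizes the norm but leaves selectivity second-order driven) and the
linear Oja rule (Δw = η(xy − w·y²), a pure PCA learner on a linear neuron).

### Stability and the weight norm

The balancing factor h* = ⟨y³⟩/⟨y²⟩ makes ⟨wᵀΔw⟩ = 0 — indifferent
stability, the norm drifts freely.  Any supralinear running average
h_y = ⟨y^r⟩ (r > p − 2) instead stabilizes the norm at the value where the
two factors coincide; for p = 3, r = 2 that is |w| = ⟨x_w³⟩/⟨x_w²⟩² with
x_w the rectified projection of x on the converged unit direction
(`predicted_weight_norm`).  The norm therefore carries information about the
input statistics; this prediction is verified to 5% by the tests using the
time-averaged |w(t)| over the trailing third of training (the Adam iterate
jitters around the equilibrium by several percent at any single step).

## Homeostatic estimator

h_y is an exponential moving average of y^r with a window of τ_h = 200
*samples*.  The per-sample recursion is compounded over a mini-batch of K
samples (retention (1 − 1/τ_h)^K), keeping the adaptation timescale
independent of batch size.  This matters: the derivation assumes h_y
equilibrates much faster than w (η_h ≫ η), and applying one EMA step per
100-sample batch makes h lag the Adam-driven weights enough to destabilize
the rule.  h is initialized to the first batch's moment rather than 0 to
avoid an initial LTP-dominated transient.

## Training protocol (single neurons and population)

Mini-batches of 100 samples drawn i.i.d. with replacement from a
pre-generated dataset; Adam (lr 0.003, standard moment defaults) applied to
the batch-averaged plasticity update as an ascent direction; weights
initialized N(0, 1) per coordinate (population: N(0, 1/√N)).  Convergence is
declared by a fixed sample budget, not a tolerance.  Selectivity runs use
3×10⁶ draws: locking onto the sparse feature takes ~6×10⁵ draws (the
objective gradient toward the feature is quadratic in the current overlap,
so escaping the zero-overlap plateau is the slow phase), and washing the
initialization remnants out of low-variance directions — which is what
normalized projections measure — takes 2–3× longer still.

## Synthetic inputs

All inputs are generated internally at 1 sample = 1 ms and mean-subtracted
per channel.

**Grouped time series** (selectivity and decoding experiments). Three groups
of 20 channels: a *sparse* group sharing a binary ON/OFF renewal signal (ON
100 ms, ISI ~ Exp(1000 ms), amplitude set so the mean-subtracted common
component has sd 1.0), a *network* group sharing an Ornstein–Uhlenbeck
signal (τ = 200 ms, sd 1.2), and white background channels (sd 2.2).  The
independent per-channel noise on the first two groups is not separately
specified by the protocol; it is set to sd 1.0, the same order as the graded
noise levels (0.7–1.5) of the decoding experiments.  This choice has a
dynamical consequence worth knowing: with near-noiseless within-group
directions there is no restoring force on weight components in them, so
initialization remnants persist indefinitely and normalized projections
cannot approach 1 even though the feature component itself converges.  For
the decoding experiments the 20 sparse channels are subdivided 7/7/6 with
signal sds (1.5, 1.0, 0.7) and either matched noise (equal SNR) or fixed
signal and graded noise (1.5, 1.0, 0.7).

**Tuned population** (dictionary-learning experiment). A circular latent
θ(t) ∈ [0,1) follows a Gaussian random walk (increment sd 2.2e-3) smoothed
by a 100-ms exponential filter and wrapped modulo 1 — the smoothed walk
circles the domain ~100 times per 10⁶ samples.  100 inputs carry evenly
spaced wrapped-Gaussian tuning curves (width 0.05, amplitude 1, additive
noise sd 0.01).  Heterogeneous populations multiply width, amplitude and
noise of each input by independent log-normal(0, 0.2) factors.  Tuning
curves of trained networks are measured on probe stimuli with θ drawn
uniformly — statistically identical to the stationary walk but with
guaranteed bin occupancy.

**Correlated image patches** (spiking experiment). A 1/f²-power Gaussian
random field (unit sd) plus a Poisson(0.5) number of oriented line segments
per patch with amplitude 5; the stack is normalized to unit pixel variance.
The two ingredients are calibrated to the statistics the experiment
exercises: adjacent-pixel correlation ≈ 0.57 (second order) and
oriented-filter response excess kurtosis ≈ 4, inside the range reported for
natural images (higher order).  Patches are mean-subtracted and split into
ON/OFF channels (rate = 50 Hz × rectified ± pixel value), Poisson-encoded
for 100 ms per patch.  What this generator does *not* emulate: scale
invariance across octaves, phase structure of natural scenes, and occlusion
statistics — results here certify the mechanism (localized receptive fields
from correlated, sparse-featured input), not natural-image fidelity.
An optional loader samples patches from user-supplied grayscale images.

## Population network

16 output neurons; activities iterate y ← (Wx + W_rec·y)₊ for 10 steps per
sample from y = 0 (a damped mode is available but off by default).
Feedforward weights follow the configured rule with additive decay
λ_ff = 0.001; recurrent inhibitory weights follow

    ΔW_rec[i,j] = −η_rec·( y_i(y_j − θ) + λ_rec·W_rec[i,j] ),

η_rec = 0.03, θ = 1, λ_rec = 1, clipped to ≤ 0 with zero diagonal, applied
concurrently with the feedforward update each mini-batch.  The decay term's
sign is chosen so silence decays inhibition toward zero (the equilibrium
under sustained drive is W* = −y_i(y_j − θ)/λ_rec); the opposite reading
makes |W_rec| diverge, since rectification floors activity at zero and
removes any stabilizing feedback.

After training, the code reports: per-neuron tuning FWHM (baseline at the
curve minimum, half level halfway to the peak, circular crossings linearly
interpolated between 64 bins), preferred angles and their maximal circular
gap (tiling), linear Fisher information J(θ) = f′ᵀΣ⁻¹f′ (central-difference
derivatives, per-bin response covariance regularized by 1e-3 of its mean
diagonal, averaged over bins), and for heterogeneous inputs the Pearson
correlation ρ_σw between input tuning width and mean |feedforward weight|.

A caution on Fisher information: its magnitude is dominated by the output
noise floor and the estimator's covariance treatment, and varies by orders
of magnitude across defensible estimator choices (full covariance vs
diagonal vs Poisson-variance); comparisons should be made only within one
estimator, which is how the package reports it.

## Spiking network

Leaky integrate-and-fire outputs (v_rest = v_reset = −65 mV, threshold
−50 mV, τ_mem = 15 ms, dt = 1 ms) driven by Poisson ON/OFF input spikes
weighted by non-negative excitatory weights (synaptic gain 5 mV per unit
weight), minus a mean-cancellation current that tracks each channel's firing
rate (EMA, τ = 200 s), and optionally lateral inhibition with a 1-ms delay.

Triplet STDP with linear LTD:

    dW[j,i] = η⁺·y_j(t)·ȳ₊_j·x̄₊_i  −  η⁻·g·h_j·x_i(t)·ȳ₋_j  −  λ·W[j,i]

with traces x̄₊, ȳ₊, ȳ₋ (jump 1 at a spike, τ = 30 ms, read *before* the
current step's spikes so an isolated pre–post pair triggers neither term),
and h_j = (output-rate EMA)².  η⁺ = η⁻ = 1e-4 per spike event.  Because the
LTP term carries two trace factors (each ~ rate × τ) and the LTD term one,
the printed constants are not dimensionally balanced for δ-train inputs; the
normalization g = τ_trace/ν₀ is folded into LTD so the drifts balance
exactly at the target rate ν₀ (the BCM-like rate fixed point).  The
heterosynaptic variant replaces LTD by −η⁻·g_het·W·h with g_het = 800,
calibrated (like ν₀ = 3 Hz, the weight bound w_max = 3, and λ = 3e-4/s) to
hold output rates in 5–20 Hz and equilibrium weights near half the bound.
Desk-scale runs (8 neurons, 8×8 patches, 2×10⁴ patches ≈ 2000 s simulated)
shorten the homeostatic window to τ_h = 10 s, preserving its proportion of
the simulated duration.  Spiking inhibitory plasticity is the symmetric
pair-based rule with target rate θ = 3 Hz and decay toward zero, clipped
non-positive.

The rate-reduction consistency of the triplet rule — mean drift
η⁺ν_xν_y²τ² − η⁻g·h·ν_xν_yτ in a frozen-weight Poisson regime, the spiking
counterpart of Δw = η(xy² − h·xy) — is verified to 20% in the tests.

## Numerical choices and degenerate inputs

- Rectifier at exactly 0 contributes nothing to LTP or LTD.
- Updates are batch-averaged, so η is batch-size independent.
- Divergence guards: |w| > 1e6 (rate neurons, signals misuse of r ≤ p − 2),
  non-finite activities (recurrent net), non-finite weights (spiking).
- Wrapped Gaussians are truncated at 3 periods (error < 1e-8 for σ ≤ 0.2;
  a single period is used when σ ≤ 0.11, same error bound).
- FWHM on a flat curve raises; multiple super-half regions return the width
  of the peak-containing region.
- Whitening refuses rank-deficient covariances unless a pseudo-inverse mode
  is requested.
- The OU generator uses the exact AR(1) discretization with stationary
  initialization; the sparse ON/OFF amplitude uses the analytic duty cycle
  q = 100/(100 + τ_ISI).

## Problem sizes

Experiments run at two scales.  "paper": 10⁶-sample datasets, 10⁶ optimizer
draws, 64 spiking neurons on 16×16 patches with 10⁶ presentations.  "desk"
(the default, used by the tests and the acceptance script): 2–3×10⁵-sample
datasets (the optimizer still consumes the full draw budget by resampling),
16-neuron population networks, and 8 spiking neurons on 8×8 patches for
2×10⁴ presentations.  A full desk reproduction of every experiment completes
in minutes on one CPU.

## Known limitations

- The heterosynaptic control is bistable on the grouped dataset: both the
  high-variance network direction and the sparse direction (whose large ON
  events also feed x·y² LTP) are stable; about a third of seeds converge to
  the sparse one.  Statements about "the" heterosynaptic outcome are
  per-basin.
- Fisher-information magnitudes are estimator-dependent (see above); only
  within-estimator comparisons are meaningful.
- The p = 3 and p = 4 family members converge to the same sparse feature
  (output correlation > 0.98) but not to identical weight vectors when
  channel noise is substantial — the SNR-sparseness tradeoff is
  exponent-dependent.
- The spiking model omits conductances, refractoriness beyond reset,
  transmission delays (except the 1-ms inhibitory loop) and event-driven
  integration.
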