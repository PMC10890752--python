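"""Spiking implementation: Poisson ON/OFF encoding, LIF output population,
triplet STDP with linear LTD (plus a heterosynaptic-LTD variant), spiking
inhibitory plasticity, and an input-mean-cancellation current.

Conventions
-----------
* dt = 1 ms; spike indicators are per-step Bernoulli draws.
* synaptic traces jump by 1 at a spike and decay exponentially (tau = 30 ms
  for the plasticity traces), so a trace's mean is rate x tau.
* rate estimates (input mean cancellation, homeostatic factor) are EMAs of
  the spike indicator with tau_4 = tau_h = 200 s, in spikes/ms.
* weight updates use the trace values *before* the current step's spikes are
  added, so an isolated pre-post pair triggers neither the triplet LTP term
  (no prior post spike) nor LTD at the post spike (no pre spike there).

The printed triplet constants (eta+ = eta- = 1e-4) are not dimensionally
balanced once spike trains are delta functions: the LTP term carries two
trace factors (each ~ rate x tau) and the LTD term one.  A rate normalization
``ltd_gain = trace_tau / target_rate`` is therefore folded into the LTD term,
chosen so that LTP and LTD drifts balance exactly at the target output rate
(the BCM-like rate fixed point); an analogous ``het_gain`` holds the
heterosynaptic variant's equilibrium weights in the initial-weight range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signals import PatchSpec, gen_image_patches

__all__ = [
    "LIFParams",
    "TripletParams",
    "InhibParams",
    "SpikingConfig",
    "SpikingState",
    "poisson_encode",
    "lif_step",
    "triplet_update",
    "inhibitory_stdp_update",
    "run_development",
]


@dataclass(frozen=True)
class LIFParams:
    v_rest: float = -65.0  # mV
    v_threshold: float = -50.0
    v_reset: float = -65.0
    tau_mem: float = 15.0  # ms
    dt: float = 1.0

    def __post_init__(self) -> None:
        if not (self.v_reset <= self.v_rest < self.v_threshold):
            raise ValueError("need v_reset <= v_rest < v_threshold")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")


@dataclass(frozen=True)
class TripletParams:
    eta_plus: float = 1e-4
    eta_minus: float = 1e-4
    # weight decay per second. The decay time constant is chosen so that the
    # LTP/decay equilibrium sits near half the weight bound under target-rate
    # operation (the per-spike eta's fix the learning drift at ~2e-4/s, which
    # pins the usable decay scale).
    lambda_decay: float = 3e-4
    trace_tau: float = 30.0  # ms, for xbar+, ybar+, ybar-
    tau_h: float = 200_000.0  # ms (200 s) for the output-rate EMA
    variant: str = "linear_ltd"  # or "heterosyn_ltd"
    target_rate_hz: float = 10.0  # rate at which LTP and LTD balance
    het_gain: float = 18.0  # heterosynaptic LTD normalization (see module doc)

    def __post_init__(self) -> None:
        if self.variant not in ("linear_ltd", "heterosyn_ltd"):
            raise ValueError(f"unknown variant {self.variant!r}")
        for name in ("trace_tau", "tau_h"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def ltd_gain(self) -> float:
        """Rate normalization of the linear-LTD term: trace_tau / target rate
        (in 1/ms), making <dw> = 0 at the target output rate."""
        return self.trace_tau / (self.target_rate_hz / 1000.0)


@dataclass(frozen=True)
class InhibParams:
    """Symmetric spiking inhibitory plasticity with weight decay.

    Joint pre/post activity above the target rate ``theta`` (in spikes/ms)
    strengthens inhibition (weights grow more negative); silence decays the
    weights toward zero.
    """

    eta: float = 1e-3
    theta: float = 0.003  # spikes/ms (3 Hz target)
    lambda_decay: float = 3.0  # per second
    trace_tau: float = 20.0  # ms


@dataclass
class SpikingConfig:
    n_neurons: int = 64
    lif: LIFParams = field(default_factory=LIFParams)
    triplet: TripletParams = field(default_factory=TripletParams)
    inhib: InhibParams = field(default_factory=InhibParams)
    syn_gain: float = 3.0  # mV of EPSP per unit weight
    w_init_max: float = 1.0  # initial weights ~ U(0, w_init_max)
    w_max: float = 3.0  # hard upper bound on excitatory weights
    tau_input_rate: float = 200_000.0  # ms; EMA for mean cancellation


@dataclass
class SpikingState:
    W_exc: np.ndarray  # (M, N) >= 0
    W_inh: np.ndarray  # (M, M) <= 0, zero diagonal
    v: np.ndarray  # (M,) membrane potentials, mV
    xbar_plus: np.ndarray  # (N,) presynaptic LTP trace
    ybar_plus: np.ndarray  # (M,) postsynaptic triplet trace
    ybar_minus: np.ndarray  # (M,) postsynaptic LTD trace
    ybar_inh: np.ndarray  # (M,) symmetric trace of the inhibitory rule
    x_rate: np.ndarray  # (N,) input-rate EMA, spikes/ms (mean cancellation)
    y_rate: np.ndarray  # (M,) output-rate EMA, spikes/ms (homeostasis)


def poisson_encode(
    rates_hz: np.ndarray, duration_ms: float, dt: float, seed: int
) -> np.ndarray:
    """Bernoulli(rate*dt) spike raster of shape (n_steps, n_channels)."""
    rates_hz = np.asarray(rates_hz, dtype=float)
    if np.any(rates_hz < 0):
        raise ValueError("rates must be >= 0")
    p = rates_hz * dt / 1000.0
    if np.any(p > 1.0):
        raise ValueError("rate*dt exceeds 1 spike per step; decrease dt")
    rng = np.random.default_rng(seed)
    n_steps = int(round(duration_ms / dt))
    return (rng.random((n_steps, rates_hz.size)) < p[None, :]).astype(np.uint8)


def lif_step(v: np.ndarray, input_mv: np.ndarray, p: LIFParams) -> tuple[np.ndarray, np.ndarray]:
    """One leaky integrate-and-fire step; returns (v_new, spike indicator).

    v <- v + dt/tau_mem (v_rest - v) + input; spike when v >= threshold,
    then v <- v_reset.
    """
    if not np.all(np.isfinite(v)):
        raise FloatingPointError("non-finite membrane potential")
    v = v + (p.dt / p.tau_mem) * (p.v_rest - v) + input_mv
    spikes = v >= p.v_threshold
    v = np.where(spikes, p.v_reset, v)
    return v, spikes.astype(np.uint8)


def triplet_update(
    state: SpikingState,
    pre_spikes: np.ndarray,
    post_spikes: np.ndarray,
    params: TripletParams,
    dt: float = 1.0,
) -> np.ndarray:
    """Apply one time step of the triplet rule to W_exc (in place).

    linear_ltd:    dW[j,i] = eta+ y_j ybar+_j xbar+_i
                             - eta- ltd_gain h_j x_i ybar-_j
    heterosyn_ltd: dW[j,i] = eta+ y_j ybar+_j xbar+_i
                             - eta- het_gain W[j,i] h_j dt
    with h_j = (output-rate EMA)^2 and traces evaluated before this step's
    spikes are added.  Weights are clipped to [0, inf) here (the upper bound
    is enforced by the simulation loop).
    """
    W = state.W_exc
    h = state.y_rate**2
    post_idx = np.nonzero(post_spikes)[0]
    if post_idx.size:
        W[post_idx, :] += params.eta_plus * state.ybar_plus[post_idx, None] * state.xbar_plus[None, :]
    if params.variant == "linear_ltd":
        pre_idx = np.nonzero(pre_spikes)[0]
        if pre_idx.size:
            # fancy indexing returns a copy; assign back explicitly
            W[:, pre_idx] = np.maximum(
                W[:, pre_idx]
                - params.eta_minus * params.ltd_gain * (h * state.ybar_minus)[:, None],
                0.0,
            )
    else:
        W *= np.maximum(1.0 - params.eta_minus * params.het_gain * h * dt, 0.0)[:, None]
    return W


def inhibitory_stdp_update(
    state: SpikingState,
    pre_spikes: np.ndarray,
    post_spikes: np.ndarray,
    params: InhibParams,
    dt: float = 1.0,
) -> np.ndarray:
    """One step of the symmetric inhibitory rule on W_inh (in place).

    dW[i,j] = -eta ( xbar_j (y_i - theta dt) + x_j (ybar_i - theta) )
              - lambda W[i,j] dt
    clipped to <= 0, zero diagonal.  x and y are both output-population spike
    trains (pre = source neuron j, post = target neuron i).
    """
    W = state.W_inh
    tr = state.ybar_inh
    lam = params.lambda_decay * dt / 1000.0
    # continuous part: -eta * xbar_j * (-theta*dt)  and decay
    W += params.eta * params.theta * dt * tr[None, :] / params.trace_tau
    W -= lam * W
    post_idx = np.nonzero(post_spikes)[0]
    if post_idx.size:
        W[post_idx, :] -= params.eta * tr[None, :] / params.trace_tau
    pre_idx = np.nonzero(pre_spikes)[0]
    if pre_idx.size:
        W[:, pre_idx] -= params.eta * (tr[:, None] / params.trace_tau - params.theta)
    np.fill_diagonal(W, 0.0)
    np.minimum(W, 0.0, out=W)
    return W


def init_state(cfg: SpikingConfig, n_inputs: int, rng: np.random.Generator) -> SpikingState:
    M = cfg.n_neurons
    return SpikingState(
        W_exc=rng.uniform(0.0, cfg.w_init_max, size=(M, n_inputs)),
        W_inh=np.zeros((M, M)),
        v=np.full(M, cfg.lif.v_rest),
        xbar_plus=np.zeros(n_inputs),
        ybar_plus=np.zeros(M),
        ybar_minus=np.zeros(M),
        ybar_inh=np.zeros(M),
        x_rate=np.zeros(n_inputs),
        y_rate=np.full(M, cfg.triplet.target_rate_hz / 1000.0),
    )


def run_development(
    patches: PatchSpec,
    n_patches: int,
    cfg: SpikingConfig,
    seed: int,
    lateral_inhibition: bool = False,
    chunk: int = 2000,
) -> tuple[SpikingState, np.ndarray]:
    """Develop receptive fields from Poisson-encoded correlated patches.

    Each patch is presented for ``sample_duration_ms``; every millisecond the
    LIF population integrates the weighted excitatory spikes minus the
    mean-cancellation current (and inhibitory spikes when enabled), and the
    plasticity rules are applied.  Returns the final state and the ON-OFF
    receptive-field maps, shape (n_neurons, patch_size, patch_size).
    """
    rng = np.random.default_rng(seed)
    ps = patches.patch_size
    n_px = ps * ps
    n_inputs = 2 * n_px
    state = init_state(cfg, n_inputs, rng)
    lif, tp = cfg.lif, cfg.triplet
    dt = lif.dt
    T = int(round(patches.sample_duration_ms / dt))
    trace_decay = float(np.exp(-dt / tp.trace_tau))
    inh_decay = float(np.exp(-dt / cfg.inhib.trace_tau))
    a_in = dt / cfg.tau_input_rate
    a_h = dt / tp.tau_h
    # weight decay (linear_ltd variant) folded to one multiply per patch
    w_decay_patch = float(np.exp(-tp.lambda_decay * T * dt / 1000.0))
    # init x_rate to the generator's long-run mean so cancellation starts hot
    warm, on_w, off_w = gen_image_patches(patches, 500, seed=int(rng.integers(2**31)))
    state.x_rate[:] = np.concatenate([on_w.mean(0), off_w.mean(0)]) * dt / 1000.0

    done = 0
    while done < n_patches:
        n = min(chunk, n_patches - done)
        _, on, off = gen_image_patches(patches, n, seed=int(rng.integers(2**31)))
        rates = np.concatenate([on, off], axis=1)  # (n, 2*n_px), Hz
        p_spike = rates * dt / 1000.0
        if np.any(p_spike > 1.0):
            raise ValueError("rate*dt exceeds 1; lower rate_scale or dt")
        y_prev = np.zeros(cfg.n_neurons, dtype=np.uint8)
        for k in range(n):
            raster = rng.random((T, n_inputs)) < p_spike[k][None, :]
            cancel = cfg.syn_gain * (state.W_exc @ state.x_rate)  # (M,) per-ms
            for t in range(T):
                x_t = raster[t]
                pre_idx = np.nonzero(x_t)[0]
                I = cfg.syn_gain * state.W_exc[:, pre_idx].sum(axis=1) - cancel
                if lateral_inhibition:
                    # inhibitory spikes from the previous step (1 ms delay)
                    I = I + cfg.syn_gain * (state.W_inh @ y_prev)
                state.v, y_t = lif_step(state.v, I, lif)
                triplet_update(state, x_t, y_t, tp, dt)
                if lateral_inhibition:
                    inhibitory_stdp_update(state, y_t, y_t, cfg.inhib, dt)
                # trace updates (after plasticity: updates see pre-step traces)
                state.xbar_plus *= trace_decay
                state.xbar_plus[pre_idx] += 1.0
                state.ybar_plus *= trace_decay
                state.ybar_minus *= trace_decay
                state.ybar_inh *= inh_decay
                yi = np.nonzero(y_t)[0]
                if yi.size:
                    state.ybar_plus[yi] += 1.0
                    state.ybar_minus[yi] += 1.0
                    state.ybar_inh[yi] += 1.0
                state.x_rate += a_in * (x_t - state.x_rate)
                state.y_rate += a_h * (y_t - state.y_rate)
                y_prev = y_t
            if tp.variant == "linear_ltd":
                state.W_exc *= w_decay_patch
            np.clip(state.W_exc, 0.0, cfg.w_max, out=state.W_exc)
            if not np.all(np.isfinite(state.W_exc)):
                raise FloatingPointError("excitatory weights diverged")
        done += n
    rf = (state.W_exc[:, :n_px] - state.W_exc[:, n_px:]).reshape(cfg.n_neurons, ps, ps)
    return state, rf
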