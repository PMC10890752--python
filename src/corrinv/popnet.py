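"""Rate-based population network: feedforward plasticity with weight decay,
recurrent inhibitory plasticity, and rectified-linear recurrent dynamics.

A population of M output neurons receives the tuned input population through
signed feedforward weights W (M x N) and inhibits itself through recurrent
weights W_rec (M x M, zero diagonal, entries <= 0).  Activities are the fixed
point of y <- (W x + W_rec y)_+, approximated by a fixed number of iterations
per sample.  Feedforward synapses follow the configured plasticity rule
(correlation-invariant by default) with additive decay -lambda_ff * w;
recurrent synapses follow the covariance-style inhibitory rule

    dW_rec[i, j] = -eta_rec * ( y_i (y_j - theta) + lambda_rec * W_rec[i, j] )

clipped to non-positive values.  Silence therefore decays inhibition toward
zero, and sustained joint activity above the target theta strengthens it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rules import RuleConfig
from .signals import InputBatch
from .training import Adam, SGD

__all__ = ["PopNetConfig", "PopulationState", "recurrent_forward", "inhibitory_update", "train_population", "population_response"]


@dataclass
class PopNetConfig:
    n_outputs: int = 16
    rec_steps: int = 10
    eta_rec: float = 0.03
    theta_rec: float = 1.0
    lambda_rec: float = 1.0
    lambda_ff: float = 0.001
    rule: RuleConfig = field(default_factory=lambda: RuleConfig(variant="corr_invariant"))
    n_samples: int = 300_000
    batch_size: int = 100
    optimizer: str = "adam"
    lr: float = 0.003
    damped: bool = False

    def __post_init__(self) -> None:
        for name in ("eta_rec", "theta_rec", "lambda_rec", "lambda_ff", "lr"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class PopulationState:
    W: np.ndarray  # (M, N) signed feedforward weights
    W_rec: np.ndarray  # (M, M) <= 0, zero diagonal
    h: np.ndarray  # (M,) homeostatic estimates
    h_initialized: bool = False
    step: int = 0


def recurrent_forward(
    x: np.ndarray, state: PopulationState, rec_steps: int = 10, damped: bool = False
) -> np.ndarray:
    """Iterate y <- (W x + W_rec y)_+ from y = 0 for ``rec_steps`` iterations.

    ``x`` may be one sample (N,) or a batch (K, N); the fixed-point iteration
    runs independently per sample. With ``damped``, iterates are averaged with
    the previous value (useful if the plain iteration oscillates).
    """
    if rec_steps < 1:
        raise ValueError("rec_steps must be >= 1")
    single = x.ndim == 1
    X = x[None, :] if single else x
    drive = X @ state.W.T  # (K, M)
    Y = np.zeros_like(drive)
    for _ in range(rec_steps):
        Y_new = np.maximum(drive + Y @ state.W_rec.T, 0.0)
        Y = 0.5 * (Y + Y_new) if damped else Y_new
    if not np.all(np.isfinite(Y)):
        raise FloatingPointError("non-finite activities in recurrent dynamics")
    return Y[0] if single else Y


def inhibitory_update(state: PopulationState, y: np.ndarray, cfg: PopNetConfig) -> np.ndarray:
    """Apply the batch-averaged inhibitory plasticity step; returns W_rec.

    Off-diagonal entries move by -eta_rec*(mean_k y_i (y_j - theta) +
    lambda_rec * w_ij), then are clipped to <= 0; the diagonal stays 0.
    """
    Y = y[None, :] if y.ndim == 1 else y
    K = len(Y)
    hebb = Y.T @ (Y - cfg.theta_rec) / K  # (M, M): mean y_i (y_j - theta)
    W_rec = state.W_rec - cfg.eta_rec * (hebb + cfg.lambda_rec * state.W_rec)
    np.fill_diagonal(W_rec, 0.0)
    state.W_rec = np.minimum(W_rec, 0.0)
    return state.W_rec


def _feedforward_delta(state: PopulationState, X: np.ndarray, Y: np.ndarray, cfg: PopNetConfig) -> np.ndarray:
    """Per-neuron plasticity update, vectorized over the population.

    Matches rules.delta_w row-by-row for the supported variants (the LTP/LTD
    drive uses the network activity Y from the recurrent dynamics).
    """
    K = len(X)
    rule = cfg.rule
    v = rule.variant
    if v in ("corr_invariant", "kurtosis_bcm"):
        drive = (Y ** (rule.p - 1.0)).T @ X / K - state.h[:, None] * (Y.T @ X / K)
        return drive - cfg.lambda_ff * state.W
    if v == "oja_heterosyn":
        y2 = Y**2
        return y2.T @ X / K - y2.mean(axis=0)[:, None] * state.W - cfg.lambda_ff * state.W
    raise ValueError(f"variant {v!r} not supported in the population network")


def train_population(
    batch: InputBatch, cfg: PopNetConfig, seed: int
) -> tuple[PopulationState, dict]:
    """Train the population network on a tuned-input batch.

    Per mini-batch: recurrent forward pass, homeostatic update, concurrent
    feedforward (optimizer-scaled) and recurrent inhibitory updates.
    Initial W ~ N(0, 1/sqrt(N)), W_rec = 0. Deterministic given seed.
    """
    X_all = batch.data
    n, N = X_all.shape
    M = cfg.n_outputs
    rng = np.random.default_rng(seed)
    state = PopulationState(
        W=rng.normal(0.0, 1.0 / np.sqrt(N), size=(M, N)),
        W_rec=np.zeros((M, M)),
        h=np.zeros(M),
    )
    opt = Adam(cfg.lr) if cfg.optimizer == "adam" else SGD(cfg.lr)
    steps = cfg.n_samples // cfg.batch_size
    rule = cfg.rule
    diag = {"w_norm": [], "mean_rate": [], "rec_mean": []}
    for t in range(steps):
        idx = rng.integers(0, n, size=cfg.batch_size)
        X = X_all[idx]
        Y = recurrent_forward(X, state, cfg.rec_steps, cfg.damped)
        m = (Y**rule.r).mean(axis=0)
        if not state.h_initialized:
            state.h = m
            state.h_initialized = True
        else:
            state.h = state.h * (1.0 - 1.0 / rule.tau_h) + m / rule.tau_h
        if cfg.lr > 0:
            dW = _feedforward_delta(state, X, Y, cfg)
            state.W = state.W + opt.step(dW)
        if cfg.eta_rec > 0:
            inhibitory_update(state, Y, cfg)
        state.step += 1
        if np.linalg.norm(state.W) > 1e6:
            raise FloatingPointError("feedforward weights diverged")
        if t % 200 == 0:
            diag["w_norm"].append(float(np.linalg.norm(state.W, axis=1).mean()))
            diag["mean_rate"].append(float(Y.mean()))
            diag["rec_mean"].append(float(state.W_rec.mean()))
    return state, diag


def population_response(
    state: PopulationState, X: np.ndarray, cfg: PopNetConfig, chunk: int = 20_000
) -> np.ndarray:
    """Frozen-weight network responses for evaluation (chunked over samples)."""
    outs = []
    for i in range(0, len(X), chunk):
        outs.append(recurrent_forward(X[i : i + chunk], state, cfg.rec_steps, cfg.damped))
    return np.concatenate(outs, axis=0)
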