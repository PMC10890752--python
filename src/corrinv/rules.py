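"""Rate-based synaptic plasticity rules.

The central object is the correlation-invariant family

    dw  ∝  x y^(p-1)  -  h_y x y        (LTP nonlinear in y, LTD linear)

for a rectified-linear neuron y = (w^T x)_+, with a homeostatic factor
h_y = <y^r> tracked as an exponential moving average.  For p > 2 and
r > p - 2 the rule is stable and converges to a maximum of the normalized
sparsity objective <(y/sigma_y)^p>, which is invariant to invertible linear
transformations of the input.  p=3, r=2 is the BCM special case
dw = eta (x y^2 - h_y x y); p=4, r=3 is the kurtosis variant.

For comparison the module also implements heterosynaptic-LTD (Oja-style
weight scaling) rules, which stabilize the norm but are *not* invariant to
second-order input correlations, and the classic norm-constrained rule
dw = eta x f(y) followed by renormalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RuleConfig",
    "NeuronState",
    "forward",
    "delta_w",
    "update_h",
    "balancing_h_star",
    "predicted_weight_norm",
]

VARIANTS = ("corr_invariant", "kurtosis_bcm", "oja_linear", "oja_heterosyn", "norm_constrained")

#: divergence guard: abort when |w| exceeds this (signals e.g. r <= p-2 misuse)
W_MAX_NORM = 1e6


@dataclass
class RuleConfig:
    """Rule variant and its exponents/rates.

    p is the LTP exponent (LTP term x y^(p-1)), r the homeostatic exponent
    (h_y tracks <y^r>); stability of the invariant family requires p > 2 and
    r > p - 2.  ``balancing_h`` replaces the running average by the per-batch
    balancing factor h* = <y^p>/<y^2>, which leaves the weight norm at an
    indifferent equilibrium (<w^T dw> = 0).
    """

    variant: str = "corr_invariant"
    p: float | None = None
    r: float | None = None
    eta: float = 0.003
    tau_h: float = 200.0
    weight_decay: float = 0.0
    balancing_h: bool = False

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.p is None:
            self.p = 4.0 if self.variant == "kurtosis_bcm" else 3.0
        if self.r is None:
            self.r = 3.0 if self.variant == "kurtosis_bcm" else 2.0
        if self.variant in ("corr_invariant", "kurtosis_bcm"):
            if not self.p > 2:
                raise ValueError("invariant family requires p > 2")
            if not self.r > self.p - 2:
                raise ValueError("stability requires r > p - 2")
        if self.eta <= 0:
            raise ValueError("eta must be > 0")
        if self.tau_h < 1:
            raise ValueError("tau_h must be >= 1")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be >= 0")

    @property
    def rectified(self) -> bool:
        """oja_linear uses a pure linear neuron; all others rectify."""
        return self.variant != "oja_linear"

    def to_dict(self) -> dict:
        return {
            "rule.variant": self.variant,
            "rule.p": self.p,
            "rule.r": self.r,
            "rule.eta": self.eta,
            "rule.tau_h": self.tau_h,
            "rule.weight_decay": self.weight_decay,
            "rule.balancing_h": self.balancing_h,
        }


@dataclass
class NeuronState:
    """Weights and homeostatic estimate of a single rate neuron."""

    w: np.ndarray
    h_y: float = 0.0
    step: int = 0
    h_initialized: bool = False


def forward(w: np.ndarray, x: np.ndarray, rectified: bool = True) -> np.ndarray:
    """Activity y = (w^T x)_+ per sample (or w^T x if not rectified).

    ``x`` may be a single vector (N,) or a batch (K, N).
    """
    w = np.asarray(w)
    x = np.asarray(x)
    if x.shape[-1] != w.shape[0]:
        raise ValueError(f"dimension mismatch: x has {x.shape[-1]} channels, w has {w.shape[0]}")
    y = x @ w
    return np.maximum(y, 0.0) if rectified else y


def update_h(state: NeuronState, y_batch: np.ndarray, cfg: RuleConfig) -> float:
    """Exponential moving average of y^r with a window of tau_h *samples*.

    The per-sample recursion h <- h (1 - 1/tau_h) + y^r / tau_h is compounded
    over the K samples of the batch:

        h <- h (1 - 1/tau_h)^K + (1 - (1 - 1/tau_h)^K) * mean(y^r)

    so the homeostatic estimate adapts on the tau_h-sample timescale
    regardless of mini-batch size (the separation eta_h >> eta requires h to
    settle much faster than the weights move).  On the very first batch h is
    initialized directly to mean(y^r) to avoid a transient LTP-dominated
    blow-up from h = 0.
    """
    y = np.atleast_1d(np.asarray(y_batch, dtype=float))
    m = float(np.mean(y**cfg.r))
    if not state.h_initialized:
        state.h_y = m
        state.h_initialized = True
    else:
        keep = (1.0 - 1.0 / cfg.tau_h) ** y.size
        state.h_y = state.h_y * keep + (1.0 - keep) * m
    return state.h_y


def balancing_h_star(w: np.ndarray, x_batch: np.ndarray, p: float = 3.0) -> float:
    """Balancing homeostatic factor h* = <y^p>/<y^2> on the batch.

    At h = h*, the expected update has zero component along w
    (<w^T dw> ∝ <y^p> - h <y^2> = 0): indifferent stability.
    """
    y = forward(w, x_batch)
    m2 = float(np.mean(y**2))
    if m2 <= 0.0:
        raise ValueError("all-zero activity: balancing factor undefined")
    return float(np.mean(y**p)) / m2


def delta_w(state: NeuronState, x_batch: np.ndarray, cfg: RuleConfig) -> np.ndarray:
    """Batch-averaged weight update for the configured rule variant.

    corr_invariant / kurtosis_bcm:
        dw = eta * mean(x y^(p-1) - h_y x y) - eta * lambda * w
    oja_heterosyn:  dw = eta * mean(x y^2 - w y^2)
    oja_linear:     dw = eta * mean(x y - w y^2)   (linear neuron)
    norm_constrained: dw = eta * mean(x y^2), caller renormalizes |w| = 1.

    ``state.h_y`` must have been updated for this batch (or use balancing_h).
    """
    x = np.asarray(x_batch, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in input batch")
    w = state.w
    if np.linalg.norm(w) > W_MAX_NORM:
        raise FloatingPointError(
            "weight norm exceeded divergence guard (check p, r: stability needs r > p - 2)"
        )
    y = forward(w, x, rectified=cfg.rectified)
    v = cfg.variant
    if v in ("corr_invariant", "kurtosis_bcm"):
        if cfg.balancing_h:
            h = balancing_h_star(w, x, cfg.p)
        else:
            h = state.h_y
        drive = x.T @ (y ** (cfg.p - 1.0) - h * y) / len(x)
        return cfg.eta * drive - cfg.eta * cfg.weight_decay * w
    if v == "oja_heterosyn":
        y2 = y**2
        return cfg.eta * (x.T @ y2 / len(x) - w * float(np.mean(y2))) - cfg.eta * cfg.weight_decay * w
    if v == "oja_linear":
        return cfg.eta * (x.T @ y / len(x) - w * float(np.mean(y**2)))
    if v == "norm_constrained":
        return cfg.eta * (x.T @ (y**2) / len(x))
    raise ValueError(f"unknown variant {v!r}")


def apply_update(state: NeuronState, dw: np.ndarray, cfg: RuleConfig) -> None:
    """w <- w + dw, with renormalization for the norm-constrained baseline."""
    state.w = state.w + dw
    if cfg.variant == "norm_constrained":
        n = np.linalg.norm(state.w)
        if n > 0:
            state.w = state.w / n
    state.step += 1


def predicted_weight_norm(
    w_direction: np.ndarray, x_batch: np.ndarray, p: float = 3.0, r: float = 2.0
) -> float:
    """Analytic converged weight norm of the stable invariant family.

    |w| = ( <x_w^p> / (<x_w^r> <x_w^2>) )^(1/(r-p+2)),  x_w = (u^T x)_+ for the
    unit direction u.  For p=3, r=2 this reduces to <x_w^3>/<x_w^2>^2.
    """
    if abs(r - p + 2.0) < 1e-12:
        raise ValueError("exponent 1/(r-p+2) undefined for r = p - 2")
    u = np.asarray(w_direction, dtype=float)
    u = u / np.linalg.norm(u)
    xw = forward(u, x_batch)
    m2 = float(np.mean(xw**2))
    mr = float(np.mean(xw**r))
    mp = float(np.mean(xw**p))
    if m2 <= 0 or mr <= 0:
        raise ValueError("batch has no activity in the given direction")
    return (mp / (mr * m2)) ** (1.0 / (r - p + 2.0))
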