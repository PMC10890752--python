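"""Seeded stochastic-optimization training loop for single rate neurons.

Samples are drawn i.i.d. with replacement from a pre-generated dataset into
mini-batches (default 100); the homeostatic estimate is refreshed before each
weight update; the plasticity update dw is fed to the optimizer as an ascent
direction (Adam with standard moment defaults, or plain SGD).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rules import NeuronState, RuleConfig, apply_update, delta_w, forward, update_h
from .signals import InputBatch

__all__ = ["TrainConfig", "TrainResult", "Adam", "train_neuron", "group_projection"]


@dataclass
class TrainConfig:
    n_samples: int = 1_000_000  # total samples consumed (steps = n_samples/batch_size)
    batch_size: int = 100
    optimizer: str = "adam"
    lr: float = 0.003
    init_sd: float = 1.0
    seed: int = 0
    record_every: int = 50  # in optimizer steps

    def __post_init__(self) -> None:
        if not self.n_samples >= self.batch_size >= 1:
            raise ValueError("need n_samples >= batch_size >= 1")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class TrainResult:
    final_state: NeuronState
    w_trajectory: np.ndarray  # (snapshots, N)
    h_trajectory: np.ndarray  # (snapshots,)
    group_projections: np.ndarray | None  # (snapshots, n_groups)
    group_names: list[str] | None
    steps: int = 0


class Adam:
    """Minimal Adam optimizer treating the supplied dw as the ascent gradient."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = None
        self.v = None
        self.t = 0

    def step(self, grad: np.ndarray) -> np.ndarray:
        if self.m is None:
            self.m = np.zeros_like(grad)
            self.v = np.zeros_like(grad)
        self.t += 1
        self.m = self.b1 * self.m + (1 - self.b1) * grad
        self.v = self.b2 * self.v + (1 - self.b2) * grad**2
        mh = self.m / (1 - self.b1**self.t)
        vh = self.v / (1 - self.b2**self.t)
        return self.lr * mh / (np.sqrt(vh) + self.eps)


class SGD:
    def __init__(self, lr: float):
        self.lr = lr

    def step(self, grad: np.ndarray) -> np.ndarray:
        return self.lr * grad


def make_optimizer(cfg: TrainConfig):
    return Adam(cfg.lr) if cfg.optimizer == "adam" else SGD(cfg.lr)


def group_projection(w: np.ndarray, batch: InputBatch) -> np.ndarray:
    """Normalized projection of w onto each group's common-signal direction.

    For group g with unit loading u_g over its channels, returns
    (w_g . u_g) / |w| — the coordinates used to visualize learning
    trajectories in the (sparse, network) plane.
    """
    if batch.mixed:
        raise ValueError("group projections are undefined for linearly mixed batches")
    norm = np.linalg.norm(w)
    if norm == 0:
        return np.zeros(len(batch.groups))
    return np.array([float(w[g.channels] @ g.loading) / norm for g in batch.groups])


def train_neuron(batch: InputBatch, rule: RuleConfig, cfg: TrainConfig) -> TrainResult:
    """Train one rate neuron on the batch; deterministic given cfg.seed.

    The plasticity update (an ascent direction on the sparsity objective) is
    scaled by the optimizer; eta inside the rule is overridden by the
    optimizer learning rate (rule.eta is used directly only for sgd when
    cfg.lr is None-like conventions do not apply here: cfg.lr governs).
    """
    x = batch.data
    n, n_ch = x.shape
    rng = np.random.default_rng(cfg.seed)
    state = NeuronState(w=rng.normal(0.0, cfg.init_sd, size=n_ch))
    opt = make_optimizer(cfg)
    # the optimizer owns the step size; use a unit-eta copy of the rule
    unit_rule = RuleConfig(
        variant=rule.variant, p=rule.p, r=rule.r, eta=1.0, tau_h=rule.tau_h,
        weight_decay=rule.weight_decay, balancing_h=rule.balancing_h,
    )
    steps = cfg.n_samples // cfg.batch_size
    snaps_w, snaps_h, snaps_proj = [], [], []
    record_proj = not batch.mixed

    def record() -> None:
        snaps_w.append(state.w.copy())
        snaps_h.append(state.h_y)
        if record_proj:
            snaps_proj.append(group_projection(state.w, batch))

    record()
    for _ in range(steps):
        idx = rng.integers(0, n, size=cfg.batch_size)
        xb = x[idx]
        y = forward(state.w, xb, rectified=unit_rule.rectified)
        if not unit_rule.balancing_h:
            update_h(state, np.maximum(y, 0.0), unit_rule)
        dw = delta_w(state, xb, unit_rule)
        apply_update(state, opt.step(dw), unit_rule)
        if state.step % cfg.record_every == 0:
            record()

    return TrainResult(
        final_state=state,
        w_trajectory=np.array(snaps_w),
        h_trajectory=np.array(snaps_h),
        group_projections=np.array(snaps_proj) if record_proj else None,
        group_names=[g.spec.name for g in batch.groups],
        steps=steps,
    )
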