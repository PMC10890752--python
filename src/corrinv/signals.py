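"""Synthetic input processes for the rate-based plasticity experiments.

All generators follow the same conventions:

* 1 sample = 1 ms, so "time constants in ms" and "per-sample updates" are
  commensurable.
* every generator is a pure function of ``(spec, n_samples, seed)`` —
  identical arguments give bit-identical output;
* dataset assemblers (``gen_fig1_dataset`` & co.) subtract the empirical
  per-channel mean, so downstream plasticity rules see zero-mean inputs.

The three elementary processes are a sparse ON/OFF renewal signal (ON states
of fixed 100 ms duration separated by exponentially distributed intervals),
an Ornstein-Uhlenbeck process (Gaussian, temporally correlated), and white
Gaussian noise.  A group of channels shares one realization of the common
process plus independent per-channel noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GroupSpec",
    "GroupChannels",
    "InputBatch",
    "TuningPopulationSpec",
    "PatchSpec",
    "gen_sparse_on_off",
    "gen_ou",
    "gen_white_noise",
    "gen_fig1_dataset",
    "gen_fig2_dataset",
    "gen_population_dataset",
    "gen_image_patches",
    "apply_linear_mixing",
]

#: duration of one sparse ON state, in samples (= ms)
ON_DURATION = 100


@dataclass(frozen=True)
class GroupSpec:
    """Parameters of one input group sharing a common signal."""

    name: str
    n_inputs: int
    process: str  # sparse_on_off | ou | white_noise
    signal_sd: float
    noise_sd: float
    timescale_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.n_inputs < 1:
            raise ValueError("n_inputs must be >= 1")
        if self.signal_sd < 0 or self.noise_sd < 0:
            raise ValueError("signal_sd and noise_sd must be >= 0")
        if self.process not in ("sparse_on_off", "ou", "white_noise"):
            raise ValueError(f"unknown process {self.process!r}")
        if self.process in ("sparse_on_off", "ou") and self.timescale_ms <= 0:
            raise ValueError("timescale_ms must be > 0 for sparse_on_off/ou")


@dataclass(frozen=True)
class GroupChannels:
    """A group's location inside an assembled batch.

    ``loading`` is the unit vector describing how the group's common signal
    enters its channels; for uniform groups it is ``1/sqrt(n)`` per channel.
    """

    spec: GroupSpec
    start: int
    stop: int
    loading: np.ndarray

    @property
    def channels(self) -> slice:
        return slice(self.start, self.stop)


@dataclass
class InputBatch:
    """Zero-mean multichannel time series (samples x N) with group metadata."""

    data: np.ndarray
    groups: list[GroupChannels]
    latent: np.ndarray | None
    seed: int
    mixed: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def group_slice(self, name: str) -> GroupChannels:
        for g in self.groups:
            if g.spec.name == name:
                return g
        raise KeyError(name)

    def save(self, path) -> None:
        """Write to a .npz container (one array per field)."""
        np.savez(
            path,
            data=self.data,
            latent=self.latent if self.latent is not None else np.empty(0),
            seed=self.seed,
            mixed=self.mixed,
        )


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def _sparse_latent(n_samples: int, tau_isi: float, rng: np.random.Generator) -> np.ndarray:
    """Binary {0,1} renewal signal: ON for ON_DURATION, OFF ~ Exp(tau_isi)."""
    if n_samples == 0:
        return np.zeros(0)
    s = np.zeros(n_samples)
    # expected cycle length ON + tau; oversample the interval draws
    n_cyc = max(8, int(2 * n_samples / (ON_DURATION + tau_isi)) + 8)
    t = 0.0
    pos = 0
    while pos < n_samples:
        isis = rng.exponential(tau_isi, size=n_cyc)
        for isi in isis:
            t += isi
            start = int(t)
            if start >= n_samples:
                pos = n_samples
                break
            stop = min(start + ON_DURATION, n_samples)
            s[start:stop] = 1.0
            t += ON_DURATION
            pos = stop
        else:
            continue
        break
    return s


def gen_sparse_on_off(
    n_samples: int, spec: GroupSpec, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Sparse common ON/OFF signal broadcast to ``spec.n_inputs`` channels.

    The shared latent takes values {0, a} with ``a`` fixed so that the
    mean-subtracted common component has standard deviation ``signal_sd``
    (using the renewal duty cycle q = ON/(ON + tau_isi), variance q(1-q)a^2).
    Independent Gaussian noise of sd ``noise_sd`` is added per channel.

    Returns (matrix, latent); the matrix is *not* mean-subtracted here.
    """
    if n_samples < 0:
        raise ValueError("n_samples must be >= 0")
    rng = _rng(seed)
    tau = float(spec.timescale_ms)
    if spec.signal_sd > 0:
        q = ON_DURATION / (ON_DURATION + tau)
        a = spec.signal_sd / np.sqrt(q * (1.0 - q))
        latent = a * _sparse_latent(n_samples, tau, rng)
    else:
        latent = np.zeros(n_samples)
    x = latent[:, None] + rng.normal(0.0, spec.noise_sd, size=(n_samples, spec.n_inputs))
    return x, latent


def gen_ou(n_samples: int, spec: GroupSpec, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Common Ornstein-Uhlenbeck signal plus independent channel noise.

    Exact discretization with stationary initialization: the common component
    is Gaussian with sd ``signal_sd`` and autocorrelation exp(-dt/tau).
    """
    if n_samples < 0:
        raise ValueError("n_samples must be >= 0")
    rng = _rng(seed)
    tau = float(spec.timescale_ms)
    rho = np.exp(-1.0 / tau)
    innov_sd = spec.signal_sd * np.sqrt(1.0 - rho**2)
    z = rng.normal(0.0, 1.0, size=n_samples)
    if n_samples:
        from scipy.signal import lfilter

        # AR(1) with stationary start: x_0 ~ N(0, signal_sd^2)
        x0 = spec.signal_sd * z[0]
        latent, _ = lfilter([1.0], [1.0, -rho], innov_sd * z[1:], zi=[rho * x0])
        latent = np.concatenate([[x0], latent])
    else:
        latent = np.zeros(0)
    x = latent[:, None] + rng.normal(0.0, spec.noise_sd, size=(n_samples, spec.n_inputs))
    return x, latent


def gen_white_noise(n_samples: int, spec: GroupSpec, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Independent Gaussian channels (no common component)."""
    rng = _rng(seed)
    x = rng.normal(0.0, spec.signal_sd, size=(n_samples, spec.n_inputs))
    return x, np.zeros(n_samples)


_GEN = {"sparse_on_off": gen_sparse_on_off, "ou": gen_ou, "white_noise": gen_white_noise}


def _assemble(
    specs: list[GroupSpec],
    n_samples: int,
    seed: int,
    latent_from: str | None = None,
) -> InputBatch:
    """Generate each group with a derived child seed and mean-subtract."""
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(specs))]
    blocks, groups, latent = [], [], None
    start = 0
    for spec_g, child in zip(specs, child_seeds):
        x, lat = _GEN[spec_g.process](n_samples, spec_g, child)
        blocks.append(x)
        loading = np.full(spec_g.n_inputs, 1.0 / np.sqrt(spec_g.n_inputs))
        groups.append(GroupChannels(spec_g, start, start + spec_g.n_inputs, loading))
        if latent_from is not None and spec_g.name == latent_from:
            latent = lat
        start += spec_g.n_inputs
    data = np.concatenate(blocks, axis=1) if blocks else np.zeros((n_samples, 0))
    if n_samples > 0:
        data = data - data.mean(axis=0, keepdims=True)
    return InputBatch(data=data, groups=groups, latent=latent, seed=seed)


def gen_fig1_dataset(n_samples: int, seed: int) -> InputBatch:
    """Three groups of 20 channels: sparse (signal sd 1.0), OU "network"
    (signal sd 1.2), white background (sd 2.2); all channels mean-subtracted.

    The per-channel independent noise on the sparse and network groups is
    unit sd (same order as the common signals, matching the noisy-decoding
    setting of the amplitude/noise experiments).
    """
    specs = [
        GroupSpec("sparse", 20, "sparse_on_off", 1.0, 1.0, timescale_ms=1000.0),
        GroupSpec("network", 20, "ou", 1.2, 1.0, timescale_ms=200.0),
        GroupSpec("background", 20, "white_noise", 2.2, 0.0),
    ]
    return _assemble(specs, n_samples, seed, latent_from="sparse")


def gen_fig2_dataset(variant: str, n_samples: int, seed: int) -> InputBatch:
    """The 20 sparse inputs subdivided into three subgroups (7/7/6 channels)
    with graded amplitudes or graded noise, plus the two Gaussian distractor
    groups of the selectivity experiment.

    ``variant='amplitude'``: subgroup signal sds (1.5, 1.0, 0.7) with noise
    scaled identically, so all subgroups have the same signal-to-noise ratio.
    ``variant='noise'``: fixed signal sd 1.0, noise sds (1.5, 1.0, 0.7).

    All three sparse subgroups share *one* ON/OFF latent realization.
    """
    if variant not in ("amplitude", "noise"):
        raise ValueError(f"unknown variant {variant!r}")
    if variant == "amplitude":
        signal_sds = (1.5, 1.0, 0.7)
        noise_sds = signal_sds  # unit SNR in every subgroup
    else:
        signal_sds = (1.0, 1.0, 1.0)
        noise_sds = (1.5, 1.0, 0.7)

    ss = np.random.SeedSequence(seed)
    kids = ss.spawn(3)
    seeds = [int(k.generate_state(1)[0] % (2**31)) for k in kids]
    rng = _rng(seeds[0])

    # one shared unit-sd sparse latent
    tau = 1000.0
    q = ON_DURATION / (ON_DURATION + tau)
    a = 1.0 / np.sqrt(q * (1.0 - q))
    latent = a * _sparse_latent(n_samples, tau, rng)

    blocks, groups = [], []
    start = 0
    for i, (sig, noi, n_sub) in enumerate(zip(signal_sds, noise_sds, (7, 7, 6))):
        spec_g = GroupSpec(f"sparse{i + 1}", n_sub, "sparse_on_off", sig, noi, timescale_ms=tau)
        x = sig * latent[:, None] + rng.normal(0.0, noi, size=(n_samples, n_sub))
        blocks.append(x)
        groups.append(GroupChannels(spec_g, start, start + n_sub, np.full(n_sub, 1 / np.sqrt(n_sub))))
        start += n_sub
    for spec_g, child in zip(
        [
            GroupSpec("network", 20, "ou", 1.2, 1.0, timescale_ms=200.0),
            GroupSpec("background", 20, "white_noise", 2.2, 0.0),
        ],
        seeds[1:],
    ):
        x, _ = _GEN[spec_g.process](n_samples, spec_g, child)
        blocks.append(x)
        groups.append(
            GroupChannels(spec_g, start, start + spec_g.n_inputs, np.full(spec_g.n_inputs, 1 / np.sqrt(spec_g.n_inputs)))
        )
        start += spec_g.n_inputs
    data = np.concatenate(blocks, axis=1)
    if n_samples > 0:
        data = data - data.mean(axis=0, keepdims=True)
    return InputBatch(data=data, groups=groups, latent=latent, seed=seed, meta={"variant": variant})


# ---------------------------------------------------------------------------
# population-coding inputs: circular latent + Gaussian tuning curves


@dataclass(frozen=True)
class TuningPopulationSpec:
    n_inputs: int = 100
    tuning_sd: float = 0.05
    amplitude: float = 1.0
    noise_sd: float = 0.01
    latent_timescale_ms: float = 100.0
    walk_increment_sd: float = 2.2e-3
    heterogeneity_sd: float = 0.0


def circ_gauss(theta: np.ndarray, center, sd) -> np.ndarray:
    """Wrapped Gaussian on the unit circle, truncated at 3 periods
    (error < 1e-8 for sd <= 0.2)."""
    d = np.mod(theta - center + 0.5, 1.0) - 0.5  # wrapped to [-0.5, 0.5)
    if sd <= 0.15:
        # neighboring periods are < exp(-0.5*(0.35/0.15)^2) ~ 1e-2... use the
        # exact 3-term sum only when tails matter; here they are < 1e-8 for
        # sd <= 0.11 and < 2e-3 for sd = 0.15
        if sd <= 0.11:
            return np.exp(-0.5 * (d / sd) ** 2)
    out = 0.0
    for k in (-1.0, 0.0, 1.0):
        out = out + np.exp(-0.5 * ((d + k) / sd) ** 2)
    return out


def latent_walk(n_samples: int, spec: TuningPopulationSpec, rng: np.random.Generator) -> np.ndarray:
    """Random walk smoothed by an exponential filter (tau_3), wrapped to [0,1).

    The increment sd default is set so the smoothed trajectory travels around
    the circle about 100 times per 1e6 samples.
    """
    steps = rng.normal(0.0, spec.walk_increment_sd, size=n_samples)
    walk = np.cumsum(steps)
    from scipy.signal import lfilter

    alpha = 1.0 / spec.latent_timescale_ms
    smoothed = lfilter([alpha], [1.0, -(1.0 - alpha)], walk)
    start = rng.uniform(0.0, 1.0)
    return np.mod(start + smoothed, 1.0)


def gen_population_dataset(
    spec: TuningPopulationSpec, n_samples: int, seed: int
) -> InputBatch:
    """Circular latent encoded by evenly spaced Gaussian tuning curves.

    x_i(t) = A_i * circ_gauss(theta(t); c_i, sd_i) + noise_i, mean-subtracted.
    With ``heterogeneity_sd`` > 0, per-input width/amplitude/noise are jittered
    by independent log-normal multipliers exp(N(0, heterogeneity_sd)).
    """
    if spec.n_inputs < 2:
        raise ValueError("n_inputs must be >= 2")
    rng = _rng(seed)
    theta = latent_walk(n_samples, spec, rng)
    n = spec.n_inputs
    centers = np.arange(n) / n
    if spec.heterogeneity_sd > 0:
        mult = rng.lognormal(0.0, spec.heterogeneity_sd, size=(3, n))
    else:
        mult = np.ones((3, n))
    widths = spec.tuning_sd * mult[0]
    amps = spec.amplitude * mult[1]
    noise_sds = spec.noise_sd * mult[2]

    data = np.empty((n_samples, n))
    for i in range(n):
        data[:, i] = amps[i] * circ_gauss(theta, centers[i], widths[i])
    data += rng.normal(0.0, 1.0, size=(n_samples, n)) * noise_sds[None, :]
    means = data.mean(axis=0) if n_samples > 0 else np.zeros(n)
    data = data - means[None, :]
    g = GroupChannels(
        GroupSpec("population", n, "white_noise", spec.amplitude, spec.noise_sd),
        0,
        n,
        np.full(n, 1 / np.sqrt(n)),
    )
    return InputBatch(
        data=data,
        groups=[g],
        latent=theta,
        seed=seed,
        meta={
            "centers": centers,
            "widths": widths,
            "amplitudes": amps,
            "noise_sds": noise_sds,
            "channel_means": means,
            "spec": spec,
        },
    )


def population_probe(
    batch: InputBatch, n_samples: int = 20_000, seed: int = 0, mode: str = "uniform"
) -> tuple[np.ndarray, np.ndarray]:
    """Probe stimuli for tuning-curve measurement.

    Draws latent values theta (``mode='uniform'``: i.i.d. uniform on [0,1),
    statistically equivalent to the stationary latent walk but with guaranteed
    bin coverage; ``mode='grid'``: evenly spaced) and generates the noisy
    input population at each, using the same tuning parameters and
    channel-mean offsets as the training batch.  Inputs are memoryless given
    theta, so probing is equivalent to reading tuning curves off the
    time series.  Returns (X, theta).
    """
    m = batch.meta
    centers, widths = m["centers"], m["widths"]
    amps, noise_sds, means = m["amplitudes"], m["noise_sds"], m["channel_means"]
    rng = _rng(seed)
    if mode == "uniform":
        theta = rng.uniform(0.0, 1.0, size=n_samples)
    elif mode == "grid":
        theta = np.arange(n_samples) / n_samples
    else:
        raise ValueError(f"unknown probe mode {mode!r}")
    n = len(centers)
    X = np.empty((len(theta), n))
    for i in range(n):
        X[:, i] = amps[i] * circ_gauss(theta, centers[i], widths[i])
    X += rng.normal(0.0, 1.0, size=X.shape) * noise_sds[None, :]
    X -= means[None, :]
    return X, theta


# ---------------------------------------------------------------------------
# correlated image patches -> ON/OFF rates


@dataclass(frozen=True)
class PatchSpec:
    """Synthetic correlated-image patches split into ON/OFF rate channels.

    The generator superimposes a 1/f^2-power Gaussian random field (spatial
    low-pass, giving the positive neighbor-pixel correlations) and a Poisson
    number of oriented line segments (sparse higher-order structure), then
    normalizes the stack to unit pixel variance.
    """

    patch_size: int = 16
    spectral_exponent: float = 2.0
    edge_density: float = 0.5  # mean number of line segments per patch
    edge_amp: float = 5.0  # segment amplitude in units of the field sd
    rate_scale: float = 50.0  # Hz per unit pixel amplitude
    sample_duration_ms: float = 100.0

    def __post_init__(self) -> None:
        if self.patch_size < 4:
            raise ValueError("patch_size must be >= 4")


def _pink_field(n: int, ps: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    fx = np.fft.fftfreq(ps)
    f = np.sqrt(fx[:, None] ** 2 + fx[None, :] ** 2)
    f[0, 0] = 1.0
    amp = f ** (-exponent / 2.0)
    amp[0, 0] = 0.0  # no DC
    white = rng.normal(size=(n, ps, ps))
    spec = np.fft.fft2(white, axes=(1, 2)) * amp[None, :, :]
    field = np.real(np.fft.ifft2(spec, axes=(1, 2)))
    sd = field.std()
    return field / sd if sd > 0 else field


def _add_edges(patches: np.ndarray, density: float, edge_amp: float, rng: np.random.Generator) -> None:
    """Superimpose a Poisson number of oriented line segments per patch.

    Amplitude and density are calibrated so oriented-filter responses on the
    stack have natural-image-like excess kurtosis (~3-5) while the 1/f^2
    field keeps adjacent-pixel correlations > 0.3.
    """
    n, ps, _ = patches.shape
    yy, xx = np.mgrid[0:ps, 0:ps].astype(float)
    counts = rng.poisson(density, size=n)
    for i in range(n):
        for _ in range(counts[i]):
            angle = rng.uniform(0, np.pi)
            cx, cy = rng.uniform(0, ps, size=2)
            nx, ny = np.cos(angle), np.sin(angle)
            # signed distance to the line through (cx,cy) with normal (nx,ny)
            d = (xx - cx) * nx + (yy - cy) * ny
            along = -(xx - cx) * ny + (yy - cy) * nx
            seg = np.exp(-0.5 * (d / 0.8) ** 2) * (np.abs(along) < ps / 2.5)
            patches[i] += rng.choice([-1.0, 1.0]) * edge_amp * seg


def gen_image_patches(
    spec: PatchSpec, n_patches: int, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Returns (patches, on_rates, off_rates).

    ``patches``: (n, ps, ps) zero-mean, unit-variance stack.
    ``on_rates``/``off_rates``: (n, ps*ps) non-negative Poisson rates in Hz,
    rate = rate_scale * max(+/-pixel, 0); ON(i)*OFF(i) = 0 per pixel.
    """
    rng = _rng(seed)
    ps = spec.patch_size
    patches = _pink_field(n_patches, ps, spec.spectral_exponent, rng)
    _add_edges(patches, spec.edge_density, spec.edge_amp, rng)
    patches -= patches.mean(axis=(1, 2), keepdims=True)
    sd = patches.std()
    if sd > 0:
        patches /= sd
    flat = patches.reshape(n_patches, ps * ps)
    on = spec.rate_scale * np.maximum(flat, 0.0)
    off = spec.rate_scale * np.maximum(-flat, 0.0)
    return patches, on, off


def load_grayscale_patches(paths, spec: PatchSpec, n_patches: int, seed: int):
    """Sample patches from user-supplied grayscale images (PNG/TIFF).

    Fidelity alternative to the synthetic generator; same output contract as
    :func:`gen_image_patches`.
    """
    from imageio.v3 import imread

    rng = _rng(seed)
    ps = spec.patch_size
    images = []
    for p in paths:
        img = np.asarray(imread(p), dtype=float)
        if img.ndim == 3:
            img = img.mean(axis=2)
        images.append(img)
    patches = np.empty((n_patches, ps, ps))
    for i in range(n_patches):
        img = images[rng.integers(len(images))]
        r = rng.integers(0, img.shape[0] - ps + 1)
        c = rng.integers(0, img.shape[1] - ps + 1)
        patches[i] = img[r : r + ps, c : c + ps]
    patches -= patches.mean(axis=(1, 2), keepdims=True)
    sd = patches.std()
    if sd > 0:
        patches /= sd
    flat = patches.reshape(n_patches, ps * ps)
    return patches, spec.rate_scale * np.maximum(flat, 0), spec.rate_scale * np.maximum(-flat, 0)


def apply_linear_mixing(batch: InputBatch, L: np.ndarray) -> InputBatch:
    """Transform each sample x -> L x. The latent is unchanged; group metadata
    is kept but flagged ``mixed`` (group projections are undefined after
    mixing)."""
    L = np.asarray(L, dtype=float)
    n = batch.n_channels
    if L.shape != (n, n):
        raise ValueError(f"L must be {n}x{n}")
    if not np.all(np.isfinite(L)) or np.linalg.matrix_rank(L) < n:
        raise ValueError("L must be finite and full rank")
    return InputBatch(
        data=batch.data @ L.T,
        groups=batch.groups,
        latent=batch.latent,
        seed=batch.seed,
        mixed=True,
        meta=dict(batch.meta),
    )
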