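"""Analysis computations: whitening, output SNR, optimal linear decoding,
tuning-curve estimation, FWHM, linear Fisher information, weight-width
correlation and receptive-field localization."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "TuningCurveSet",
    "whitening_matrix",
    "output_snr",
    "optimal_linear_decoder",
    "estimate_tuning",
    "fwhm",
    "fisher_information",
    "weight_width_correlation",
    "rf_localization_index",
]


def whitening_matrix(X: np.ndarray, pseudo_inverse: bool = False, rtol: float = 1e-10) -> np.ndarray:
    """Symmetric (ZCA) whitening matrix M = R D^{-1/2} R^T from the
    eigendecomposition <x x^T> = R D R^T of the sample second-moment matrix.

    The whitened data M X has identity sample covariance. Rank-deficient input
    raises unless ``pseudo_inverse`` is set, in which case the deficient
    directions are dropped (D^{-1/2} -> 0) and the effective rank is reported
    via the returned matrix's attached rank (see return docstring).
    """
    X = np.asarray(X, dtype=float)
    C = X.T @ X / len(X)
    d, R = np.linalg.eigh(C)
    tol = rtol * d.max()
    deficient = d <= tol
    if deficient.any() and not pseudo_inverse:
        raise np.linalg.LinAlgError(
            f"covariance is rank deficient (rank {int((~deficient).sum())}/{len(d)}); "
            "pass pseudo_inverse=True to proceed"
        )
    inv_sqrt = np.where(deficient, 0.0, 1.0 / np.sqrt(np.where(deficient, 1.0, d)))
    return (R * inv_sqrt) @ R.T


def output_snr(y: np.ndarray, latent: np.ndarray) -> float:
    """Signal-to-noise ratio of y with respect to the latent signal.

    Defined as explained variance over residual variance from the ordinary
    regression of y on the latent (with intercept). Returns ``inf`` when the
    residual variance is numerically zero, 0.0 for constant y.
    """
    y = np.asarray(y, dtype=float)
    s = np.asarray(latent, dtype=float)
    if y.shape != s.shape:
        raise ValueError("y and latent must have equal length")
    vy = np.var(y)
    if vy == 0:
        return 0.0
    vs = np.var(s)
    if vs == 0:
        return 0.0
    beta = np.cov(y, s)[0, 1] / vs
    pred_var = beta**2 * vs
    resid_var = vy - pred_var
    if resid_var <= 1e-12 * vy:
        return np.inf
    return float(pred_var / resid_var)


def optimal_linear_decoder(X: np.ndarray, latent: np.ndarray, ridge_tol: float = 1e-10):
    """Ordinary least squares of the latent on X (with intercept).

    Returns (weights, snr) where snr is the output SNR of the fitted readout —
    the oracle against which a learned neuron's SNR is compared. A singular
    design falls back to the minimum-norm (ridge-like) lstsq solution.
    """
    X = np.asarray(X, dtype=float)
    s = np.asarray(latent, dtype=float)
    Xc = X - X.mean(axis=0)
    sc = s - s.mean()
    beta, *_ = np.linalg.lstsq(Xc, sc, rcond=ridge_tol)
    yhat = Xc @ beta
    return beta, output_snr(yhat, s)


@dataclass
class TuningCurveSet:
    """Binned tuning curves over a circular latent on [0, 1)."""

    theta_grid: np.ndarray  # (n_bins,) bin centers
    mean_response: np.ndarray  # (n_neurons, n_bins)
    response_sd: np.ndarray  # (n_neurons, n_bins)
    n_per_bin: np.ndarray  # (n_bins,)
    response_cov: np.ndarray | None = None  # (n_bins, n_neurons, n_neurons)


def estimate_tuning(
    Y: np.ndarray, theta: np.ndarray, n_bins: int = 64, min_count: int = 50,
    with_cov: bool = False,
) -> TuningCurveSet:
    """Bin responses by the circular latent; per-neuron mean and sd per bin.

    ``Y``: (n_samples, n_neurons); ``theta``: (n_samples,) values in [0, 1).
    Raises when any bin holds fewer than ``min_count`` samples (the latent
    walk has then not mixed enough — use more samples).
    """
    if n_bins < 16:
        raise ValueError("n_bins must be >= 16")
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    theta = np.mod(np.asarray(theta, dtype=float), 1.0)
    bins = np.minimum((theta * n_bins).astype(int), n_bins - 1)
    counts = np.bincount(bins, minlength=n_bins)
    if counts.min() < min_count:
        raise ValueError(
            f"bin occupancy too low (min {counts.min()} < {min_count}); increase samples"
        )
    n_neurons = Y.shape[1]
    mean = np.zeros((n_neurons, n_bins))
    sd = np.zeros((n_neurons, n_bins))
    cov = np.zeros((n_bins, n_neurons, n_neurons)) if with_cov else None
    for b in range(n_bins):
        yb = Y[bins == b]
        mean[:, b] = yb.mean(axis=0)
        sd[:, b] = yb.std(axis=0, ddof=1)
        if with_cov:
            cov[b] = np.cov(yb.T, ddof=1).reshape(n_neurons, n_neurons)
    grid = (np.arange(n_bins) + 0.5) / n_bins
    return TuningCurveSet(grid, mean, sd, counts, cov)


def fwhm(curve: np.ndarray, theta_grid: np.ndarray) -> float:
    """Full width at half maximum of a circular tuning curve, in latent units.

    Baseline = curve minimum; half level = baseline + (max - baseline)/2.
    The width is the circular distance between the two half-level crossings
    bracketing the (unique) global peak, linearly interpolated between bins.
    Invariant to affine rescaling y -> a y + b, a > 0.
    """
    c = np.asarray(curve, dtype=float)
    g = np.asarray(theta_grid, dtype=float)
    n = len(c)
    lo, hi = c.min(), c.max()
    if hi - lo <= 0:
        raise ValueError("flat curve: FWHM undefined")
    half = lo + 0.5 * (hi - lo)
    peak = int(np.argmax(c))

    def cross(direction: int) -> float:
        """Circular distance from the peak to the half-level crossing."""
        for k in range(1, n):
            i = (peak + direction * k) % n
            j = (peak + direction * (k - 1)) % n
            if c[i] <= half:
                # linear interpolation between bins j (above) and i (below)
                frac = (c[j] - half) / (c[j] - c[i])
                return (k - 1 + frac) * (1.0 / n)
        # never crossed: curve stays above half all the way around
        return 0.5

    return min(cross(+1) + cross(-1), 1.0)


def fisher_information(tuning: TuningCurveSet, reg: float = 1e-9) -> float:
    """Mean linear Fisher information J(theta) = f'(theta)^T Sigma^{-1} f'(theta).

    f' is computed by circular central differences of the mean tuning curves;
    Sigma is the per-bin response covariance when available (diagonal
    variances otherwise), regularized by adding ``reg * mean(diag)`` to the
    diagonal. Returns the average of J over theta bins. Additive over
    independent neurons and invariant to neuron relabeling.
    """
    f = tuning.mean_response  # (M, B)
    M, B = f.shape
    if B < 32:
        raise ValueError("need >= 32 bins for the derivative estimate")
    dtheta = 1.0 / B
    fp = (np.roll(f, -1, axis=1) - np.roll(f, 1, axis=1)) / (2 * dtheta)
    J = np.empty(B)
    for b in range(B):
        if tuning.response_cov is not None:
            S = tuning.response_cov[b].copy()
        else:
            S = np.diag(tuning.response_sd[:, b] ** 2)
        lam = max(np.trace(S) / M, 1e-300) * reg
        S[np.diag_indices(M)] += lam
        J[b] = float(fp[:, b] @ np.linalg.solve(S, fp[:, b]))
    return float(J.mean())


def weight_width_correlation(W: np.ndarray, input_widths: np.ndarray) -> float:
    """Pearson correlation between per-input tuning width and the mean
    absolute feedforward weight (averaged over output neurons): rho_sigma_w."""
    W = np.asarray(W, dtype=float)
    widths = np.asarray(input_widths, dtype=float)
    if W.ndim != 2 or W.shape[1] != widths.shape[0]:
        raise ValueError("W must be (n_outputs, n_inputs) matching input_widths")
    if np.std(widths) == 0:
        raise ValueError("degenerate: all input widths equal")
    mean_abs_w = np.abs(W).mean(axis=0)
    r, _ = stats.pearsonr(widths, mean_abs_w)
    return float(r)


def rf_localization_index(rf_map: np.ndarray, k: int | None = None) -> float:
    """Fraction of receptive-field energy captured by the best k x k window.

    ``rf_map`` is the ON-OFF weight difference on the patch grid; k defaults
    to patch_size // 4. Returns a value in (0, 1]; 1 = perfectly localized.
    """
    m = np.asarray(rf_map, dtype=float)
    if m.ndim != 2:
        raise ValueError("rf_map must be 2-D")
    total = float((m**2).sum())
    if total == 0:
        raise ValueError("all-zero receptive field")
    if k is None:
        k = max(1, m.shape[0] // 4)
    e = m**2
    # summed-area table for all k x k windows
    S = np.zeros((e.shape[0] + 1, e.shape[1] + 1))
    S[1:, 1:] = e.cumsum(0).cumsum(1)
    win = S[k:, k:] - S[:-k, k:] - S[k:, :-k] + S[:-k, :-k]
    return float(win.max() / total)
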