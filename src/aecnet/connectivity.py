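"""Leakage-corrected amplitude-envelope connectivity.

The connectivity estimator follows the standard MEG source-space
pipeline: node time series are filtered into canonical frequency bands
with linear-phase FIR filters, symmetrically orthogonalized to remove
zero-lag signal leakage introduced by the inverse problem, converted to
amplitude envelopes via the Hilbert transform, and correlated pairwise
(Pearson) within fixed time windows. Task-window correlations are
expressed as fractional change from the mean pre-stimulus baseline.

The symmetric orthogonalization is the closest-orthogonal-matrix
approach: given node series stacked as columns of ``A``, find the
matrix ``O @ diag(d)`` with mutually orthogonal columns minimising the
Frobenius distance to ``A``, by alternating a Procrustes rotation (polar
factor of ``A @ diag(d)``) with per-node rescaling. All nodes are
treated equivalently — no seed node is privileged, unlike pairwise
regression-based leakage correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

#: Canonical frequency bands, Hz.
BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 7.0),
    "alpha": (8.0, 12.0),
    "beta": (13.0, 29.0),
    "gamma": (30.0, 55.0),
}

#: Pre-stimulus baseline window, seconds.
BASELINE_WINDOW: tuple[float, float] = (-5.0, 0.0)

#: Task windows, seconds.
TASK_WINDOWS: tuple[tuple[float, float], ...] = ((0.0, 5.0), (5.0, 10.0), (10.0, 15.0))


def band_edges(band: str | tuple[float, float]) -> tuple[float, float]:
    if isinstance(band, str):
        try:
            return BANDS[band]
        except KeyError:
            raise ValueError(f"unknown band {band!r}; known: {sorted(BANDS)}") from None
    lo, hi = band
    if not 0 < lo < hi:
        raise ValueError(f"invalid band edges {band}")
    return float(lo), float(hi)


def design_band_fir(band, fs: float) -> np.ndarray:
    """Design an odd-length linear-phase FIR band-pass (Hamming window).

    The number of taps is chosen so the transition band is half the low
    edge (and no wider than the headroom to Nyquist above the high
    edge), giving ≥ 40 dB stopband attenuation one octave outside the
    band.
    """
    lo, hi = band_edges(band)
    if hi >= fs / 2:
        raise ValueError(f"band edge {hi} Hz at or above Nyquist ({fs / 2} Hz)")
    trans = min(lo / 2.0, (fs / 2.0 - hi) * 0.9)
    numtaps = int(np.ceil(3.3 * fs / trans)) | 1
    return signal.firwin(numtaps, [lo, hi], pass_zero=False, fs=fs)


def band_filter(data: np.ndarray, band, fs: float) -> np.ndarray:
    """Band-pass filter along the last axis with group-delay compensation.

    Filtering uses centred convolution with symmetric odd-length taps,
    i.e. a zero-delay linear-phase filter, so envelope timing is not
    shifted. Works on any leading shape (trials × nodes × samples, or
    nodes × samples).
    """
    taps = design_band_fir(band, fs)
    if data.shape[-1] < len(taps) // 2:
        logger.warning(
            "signal shorter (%d) than half the filter (%d taps); edge effects dominate",
            data.shape[-1],
            len(taps),
        )
    shape = data.shape
    flat = data.reshape(-1, shape[-1])
    out = signal.fftconvolve(flat, taps[None, :], mode="same", axes=-1)
    return out.reshape(shape)


def orthogonalize(
    node_series: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> np.ndarray:
    """Symmetric (closest-orthogonal-matrix) leakage correction.

    Parameters
    ----------
    node_series : ndarray, shape (n_nodes, n_samples)
        Band-limited node time series; requires n_samples ≥ n_nodes and
        full row rank. Series are mean-centred internally so that zero
        dot product implies zero Pearson correlation.

    Returns
    -------
    ndarray, shape (n_nodes, n_samples)
        The closest (Frobenius) set of mutually uncorrelated series:
        all pairwise zero-lag correlations are numerically zero.

    Raises
    ------
    ValueError
        On rank deficiency, or non-convergence within ``max_iter``
        alternations (the final residual is reported).
    """
    x = np.asarray(node_series, dtype=float)
    n, t = x.shape
    if t < n:
        raise ValueError(f"need at least as many samples ({t}) as nodes ({n})")
    a = (x - x.mean(axis=1, keepdims=True)).T  # (T, n), zero-mean columns
    d = np.linalg.norm(a, axis=0)
    if np.any(d == 0):
        raise ValueError("rank-deficient input: a node series is constant")
    norm_a = np.linalg.norm(a)
    prev = np.inf
    for it in range(max_iter):
        u, s, vt = np.linalg.svd(a * d, full_matrices=False)
        if s[-1] < 1e-12 * s[0]:
            raise ValueError(
                f"rank-deficient input: singular value ratio {s[-1] / s[0]:.2e}"
            )
        o = u @ vt
        d = np.einsum("ts,ts->s", a, o)
        resid = np.linalg.norm(a - o * d) / norm_a
        if abs(prev - resid) < tol:
            break
        prev = resid
    else:
        raise ValueError(
            f"orthogonalization did not converge in {max_iter} iterations "
            f"(relative residual {resid:.3e})"
        )
    # columns of o are orthonormal and lie in span(a) => zero-mean, so
    # pairwise Pearson correlations of the output are exactly zero.
    return (o * d).T


def envelope(band_series: np.ndarray) -> np.ndarray:
    """Amplitude envelope: modulus of the analytic signal (last axis)."""
    if not np.all(np.isfinite(band_series)):
        raise ValueError("non-finite values in input")
    return np.abs(signal.hilbert(band_series, axis=-1))


def _pearson_matrix(seg: np.ndarray) -> np.ndarray:
    """Node × node Pearson correlation of (n_nodes, n_samples) with a
    zero-variance guard: degenerate rows yield zero correlations."""
    x = seg - seg.mean(axis=1, keepdims=True)
    sd = x.std(axis=1)
    bad = sd == 0
    if bad.any():
        logger.warning("%d zero-variance envelope(s) in window; correlations set to 0", bad.sum())
        sd = np.where(bad, 1.0, sd)
    c = (x / sd[:, None]) @ (x / sd[:, None]).T / x.shape[1]
    c[bad, :] = 0.0
    c[:, bad] = 0.0
    np.fill_diagonal(c, 0.0)
    return np.clip(c, -1.0, 1.0)


def windowed_aec(
    envelopes: np.ndarray,
    times: np.ndarray,
    windows,
) -> dict[tuple[float, float], np.ndarray]:
    """Trial-aggregated AEC per time window.

    Parameters
    ----------
    envelopes : ndarray, (n_trials, n_nodes, n_samples)
    times : ndarray, seconds relative to onset
    windows : iterable of (t0, t1) half-open windows

    Per trial and window the Pearson correlation between each pair of
    node envelopes is computed; trials are aggregated by Fisher
    z-transform, mean, inverse transform. Diagonals are zero by
    convention.
    """
    env = np.asarray(envelopes)
    if env.ndim == 2:
        env = env[None]
    out = {}
    for w in windows:
        w = (float(w[0]), float(w[1]))
        idx = (times >= w[0]) & (times < w[1])
        if idx.sum() < 10:
            raise ValueError(f"window {w} contains fewer than 10 samples")
        zs = []
        for trial in env:
            r = _pearson_matrix(trial[:, idx])
            zs.append(np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15)))
        out[w] = np.tanh(np.mean(zs, axis=0))
    return out


def baseline_fractional_change(
    task_aec: np.ndarray,
    baseline_aec: np.ndarray,
    eps: float = 1e-3,
) -> tuple[np.ndarray, np.ndarray]:
    """Fractional change of task AEC from baseline, with a small-baseline guard.

    Entrywise ``(task − baseline) / denom`` where ``denom`` is the
    baseline clamped away from zero: magnitude at least ``eps``, sign of
    the baseline preserved (zero baseline counts as positive). Returns
    the baselined matrix and a boolean mask of guarded entries
    (|baseline| < eps), which downstream statistics may exclude.
    """
    task = np.asarray(task_aec, float)
    base = np.asarray(baseline_aec, float)
    if task.shape != base.shape:
        raise ValueError("task and baseline matrices must be conformant")
    sign = np.where(base < 0, -1.0, 1.0)
    denom = sign * np.maximum(np.abs(base), eps)
    mask = np.abs(base) < eps
    if mask.any():
        logger.info("%d entries below the baseline guard eps=%g", int(mask.sum()), eps)
    return (task - base) / denom, mask


@dataclass
class AECResult:
    """Per (band, task window) AEC matrices for one subject.

    ``baselined[band][window]`` holds the fractional-change matrix,
    ``raw`` the un-baselined task matrices, ``baseline_raw[band]`` the
    baseline-window matrix, and ``guard_mask`` the entries where the
    baseline magnitude fell below the epsilon guard.
    """

    bands: tuple
    windows: tuple
    raw: dict = field(default_factory=dict)
    baselined: dict = field(default_factory=dict)
    baseline_raw: dict = field(default_factory=dict)
    guard_mask: dict = field(default_factory=dict)


def aec_pipeline(
    epochs,
    bands=("theta", "alpha", "beta", "gamma"),
    task_windows=TASK_WINDOWS,
    baseline_window=BASELINE_WINDOW,
    condition: str | None = "Social",
    leakage_correction: bool = True,
    eps: float = 1e-3,
) -> AECResult:
    """Full per-subject connectivity pipeline on kept trials.

    Order is fixed: band filter → symmetric orthogonalization (per
    trial, over the full epoch so baseline and task share one leakage
    correction) → Hilbert envelope → windowed AEC → fractional-change
    baselining.
    """
    sel = epochs.select(condition=condition)
    if sel.n_trials == 0:
        raise ValueError("no kept trials to analyse")
    result = AECResult(bands=tuple(bands), windows=tuple(task_windows))
    for band in bands:
        filt = band_filter(sel.data, band, sel.fs)
        if leakage_correction:
            filt = np.stack([orthogonalize(trial) for trial in filt])
        env = envelope(filt)
        mats = windowed_aec(env, sel.times, list(task_windows) + [baseline_window])
        base_key = (float(baseline_window[0]), float(baseline_window[1]))
        base = mats.pop(base_key)
        result.baseline_raw[band] = base
        result.raw[band] = {}
        result.baselined[band] = {}
        result.guard_mask[band] = {}
        for w, m in mats.items():
            bl, mask = baseline_fractional_change(m, base, eps=eps)
            result.raw[band][w] = m
            result.baselined[band][w] = bl
            result.guard_mask[band][w] = mask
    return result
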