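"""LCMV beamforming onto atlas node centroids.

The spatial filter for each node is the linearly constrained minimum
variance solution: unit gain at the node's lead-field column while
minimising output variance, computed from the sensor covariance
regularised by 5% of the mean sensor power,

    Cr = C + reg * (trace(C) / n_channels) * I
    w  = Cr^{-1} L / (L^T Cr^{-1} L).

Free-orientation (3-column) lead fields are reduced to the dominant
orientation — the principal eigenvector of the 3×3 source-power matrix
(L^T Cr^{-1} L)^{-1} — before the scalar weights are formed. The neural
activity index divides each weight vector by its Euclidean norm, the
white-noise projection that makes unit-variance sensor noise map to
unit source variance, so source amplitudes are comparable across nodes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_REG_FRACTION = 0.05


@dataclass
class LCMVWeights:
    """Beamformer weights for a set of nodes.

    ``weights`` (n_nodes × n_channels) satisfy the unit-gain constraint
    ``weights[i] @ lead_field[:, i] == 1``; ``nai_weights`` are the
    noise-normalised rows used to produce the neural activity index.
    ``orientations`` holds the chosen dipole orientation per node for
    free-orientation lead fields, else None.
    """

    weights: np.ndarray
    nai_weights: np.ndarray
    orientations: np.ndarray | None = None
    reg_fraction: float = DEFAULT_REG_FRACTION


def sensor_covariance(epochs) -> np.ndarray:
    """Covariance over the concatenated kept-trial samples.

    Per-channel means are removed; the result is symmetric PSD. A
    rank-deficiency warning (not an error) is issued when there are
    fewer samples than channels — regularization downstream handles it.
    """
    sel = epochs.select(kept_only=True)
    if sel.n_trials < 2:
        raise ValueError("need at least 2 kept trials for a covariance estimate")
    x = np.concatenate(list(sel.data), axis=-1)  # channels × (trials*samples)
    n_ch, n_s = x.shape
    if n_s < n_ch:
        warnings.warn(
            f"covariance rank-deficient: {n_s} samples < {n_ch} channels", stacklevel=2
        )
    x = x - x.mean(axis=1, keepdims=True)
    c = (x @ x.T) / (n_s - 1)
    return (c + c.T) / 2


def _dominant_orientation(l3: np.ndarray, c_inv: np.ndarray) -> np.ndarray:
    """Principal eigenvector of the 3×3 source-power matrix (L^T Cr^-1 L)^-1."""
    k = l3.T @ c_inv @ l3
    s = np.linalg.inv(k)
    vals, vecs = np.linalg.eigh((s + s.T) / 2)
    u = vecs[:, -1]
    return u


def lcmv_weights(
    lead_field: np.ndarray,
    covariance: np.ndarray,
    reg_fraction: float = DEFAULT_REG_FRACTION,
) -> LCMVWeights:
    """Compute LCMV weights with fractional trace regularization.

    Parameters
    ----------
    lead_field : ndarray
        (n_channels, n_nodes) for fixed orientation or
        (n_channels, n_nodes, 3) for free orientation.
    covariance : ndarray
        Symmetric sensor covariance.
    reg_fraction : float
        Diagonal loading as a fraction of mean sensor power
        (trace / n_channels); 0 disables regularization.

    Notes
    -----
    For free-orientation lead fields the dominant orientation's sign is
    arbitrary; a deterministic convention is applied by flipping the
    orientation (and with it the weight vector) so the weight's
    largest-magnitude element is positive. Envelope analyses downstream
    are sign-invariant, but determinism requires a rule. Fixed-
    orientation lead fields leave no sign freedom — the unit-gain
    constraint pins the sign — so no flip is applied there.
    """
    c = np.asarray(covariance, float)
    if not np.allclose(c, c.T, atol=1e-10 * max(1.0, np.abs(c).max())):
        raise ValueError("covariance must be symmetric")
    if reg_fraction < 0:
        raise ValueError("reg_fraction must be nonnegative")
    lf = np.asarray(lead_field, float)
    n_ch = c.shape[0]
    cr = c + reg_fraction * (np.trace(c) / n_ch) * np.eye(n_ch)
    try:
        c_inv = np.linalg.inv(cr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("regularized covariance is singular; increase reg_fraction") from exc

    orientations = None
    if lf.ndim == 3:
        n_nodes = lf.shape[1]
        orientations = np.empty((n_nodes, 3))
        eff = np.empty((n_ch, n_nodes))
        for i in range(n_nodes):
            u = _dominant_orientation(lf[:, i, :], c_inv)
            orientations[i] = u
            eff[:, i] = lf[:, i, :] @ u
        lf = eff
    elif lf.ndim != 2:
        raise ValueError("lead field must be 2-D (fixed) or 3-D (free orientation)")

    if np.any(np.linalg.norm(lf, axis=0) == 0):
        bad = int(np.nonzero(np.linalg.norm(lf, axis=0) == 0)[0][0])
        raise ValueError(f"lead-field column for node {bad} is all-zero")

    a = c_inv @ lf  # channels × nodes
    denom = np.einsum("cn,cn->n", lf, a)
    if np.any(np.abs(denom) < 1e-300):
        bad = int(np.argmin(np.abs(denom)))
        raise ValueError(f"singular LCMV denominator at node {bad}")
    w = (a / denom).T  # nodes × channels, unit gain

    if orientations is not None:
        # sign convention: flip orientation and weights together, which
        # preserves w @ (L @ u) == 1
        flip = np.sign(w[np.arange(w.shape[0]), np.argmax(np.abs(w), axis=1)])
        flip[flip == 0] = 1.0
        w = w * flip[:, None]
        orientations *= flip[:, None]

    nai = w / np.linalg.norm(w, axis=1, keepdims=True)
    return LCMVWeights(
        weights=w, nai_weights=nai, orientations=orientations, reg_fraction=reg_fraction
    )


def project_to_sources(epochs, weights, use_nai: bool = True):
    """Apply beamformer weights to sensor epochs, yielding node epochs.

    ``weights`` may be an :class:`LCMVWeights` or a raw (n_nodes ×
    n_channels) array. With ``use_nai`` (default) the noise-normalised
    weights are used, producing the neural activity index.
    """
    w = weights.nai_weights if use_nai and hasattr(weights, "nai_weights") else (
        weights.weights if hasattr(weights, "weights") else np.asarray(weights, float)
    )
    if w.shape[1] != epochs.data.shape[1]:
        raise ValueError(
            f"weight channels ({w.shape[1]}) do not match epoch channels "
            f"({epochs.data.shape[1]})"
        )
    data = np.einsum("nc,tcs->tns", w, epochs.data)
    return replace(epochs, data=data)
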