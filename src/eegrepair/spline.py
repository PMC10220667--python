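"""Spherical-spline interpolation of bad channels (comparison baseline).

The classic scalp-potential interpolation: electrode positions are
projected onto a unit sphere, and a bad channel's value at each instant is
a weighted sum of the good channels' values, with weights derived from the
spherical-spline kernel

    g(cos gamma) = 1/(4 pi) * sum_{n=1}^{N} (2n+1) / (n (n+1))^m * P_n(cos gamma)

(P_n the Legendre polynomials, m the stiffness).  The spline system carries
an affine constraint, so constants are interpolated exactly.  Being purely
spatial, the method replaces a bad channel's *entire* time series and
ignores temporal correlations — which is exactly why it serves as the
baseline against blockwise low-rank completion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import legendre

from .exceptions import EegRepairError
from .recording import Recording

__all__ = [
    "Montage",
    "project_to_sphere",
    "interpolation_matrix",
    "interpolate_bads",
    "interpolate_block",
    "idealized_montage",
]


@dataclass
class Montage:
    """Channel labels plus unit-sphere 3-D positions."""

    labels: list[str]
    positions: np.ndarray  # n x 3, unit norm

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.labels), 3):
            raise ValueError("positions must be n_channels x 3")

    def index(self, labels) -> np.ndarray:
        lut = {lab: i for i, lab in enumerate(self.labels)}
        return np.array([lut[lab] for lab in labels], dtype=int)


def project_to_sphere(positions, labels=None) -> Montage:
    """Normalize each electrode position onto the unit sphere."""
    positions = np.asarray(positions, dtype=float)
    norms = np.linalg.norm(positions, axis=1)
    zero = np.flatnonzero(norms == 0)
    labels = list(labels) if labels is not None else [
        f"E{i + 1}" for i in range(len(positions))
    ]
    if zero.size:
        raise EegRepairError(
            f"zero-norm electrode position(s): {[labels[i] for i in zero]}"
        )
    return Montage(labels, positions / norms[:, None])


def _g_kernel(cosang: np.ndarray, stiffness: int, n_terms: int) -> np.ndarray:
    """Spherical-spline kernel as a truncated Legendre series."""
    coeffs = np.zeros(n_terms + 1)
    for n in range(1, n_terms + 1):
        coeffs[n] = (2 * n + 1) / (n * (n + 1)) ** stiffness
    return legendre.legval(np.clip(cosang, -1.0, 1.0), coeffs) / (4 * np.pi)


def interpolation_matrix(
    montage: Montage,
    good_idx,
    bad_idx,
    stiffness: int = 4,
    n_terms: int = 7,
    reg: float = 1e-5,
) -> np.ndarray:
    """Weights mapping good-channel values to bad-channel estimates.

    Solves the regularized spline system with the constant-term constraint;
    the returned |bad| x |good| matrix applied to good-channel values (at
    any one instant) yields the bad-channel estimates.  Rows sum to 1, so a
    constant field is reproduced exactly.
    """
    good_idx = np.asarray(good_idx, dtype=int)
    bad_idx = np.asarray(bad_idx, dtype=int)
    if good_idx.size < 4:
        raise EegRepairError("need at least 4 good channels for spline interpolation")
    if np.intersect1d(good_idx, bad_idx).size:
        raise EegRepairError("good and bad channel sets overlap")
    pos = montage.positions
    pg, pb = pos[good_idx], pos[bad_idx]
    g_gg = _g_kernel(pg @ pg.T, stiffness, n_terms)
    g_bg = _g_kernel(pb @ pg.T, stiffness, n_terms)
    ng = good_idx.size
    sys = np.empty((ng + 1, ng + 1))
    sys[:ng, :ng] = g_gg + reg * np.eye(ng)
    sys[:ng, ng] = 1.0
    sys[ng, :ng] = 1.0
    sys[ng, ng] = 0.0
    try:
        sys_inv = np.linalg.pinv(sys)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise EegRepairError(
            "singular spline system; try a larger regularization"
        ) from exc
    if not np.all(np.isfinite(sys_inv)):
        raise EegRepairError("singular spline system; try a larger regularization")
    ext = np.hstack([g_bg, np.ones((bad_idx.size, 1))])
    return ext @ sys_inv[:, :ng]


def interpolate_bads(
    rec: Recording,
    bad_channels,
    montage: Montage,
    stiffness: int = 4,
    n_terms: int = 7,
    reg: float = 1e-5,
) -> Recording:
    """Replace each bad channel's entire time series by its spline estimate.

    ``bad_channels`` may be indices or labels present in the montage.
    """
    if len(bad_channels) == 0:
        return rec.copy()
    if isinstance(bad_channels[0], str):
        bad_idx = montage.index(bad_channels)
    else:
        bad_idx = np.asarray(bad_channels, dtype=int)
    all_idx = np.arange(rec.n_channels)
    good_idx = np.setdiff1d(all_idx, bad_idx)
    if good_idx.size == 0:
        raise EegRepairError("all channels are bad; nothing to interpolate from")
    w = interpolation_matrix(montage, good_idx, bad_idx, stiffness, n_terms, reg)
    out = rec.copy()
    out.data[bad_idx] = w @ rec.data[good_idx]
    out.mask[bad_idx] = True
    return out


def interpolate_block(
    values: np.ndarray,
    mask: np.ndarray,
    montage: Montage,
    **kwargs,
) -> np.ndarray:
    """Block-level comparator: mark every channel containing any corrupted
    value as bad and spline-interpolate its whole series from the clean
    channels."""
    bad_rows = np.flatnonzero(~mask.all(axis=1))
    if bad_rows.size == 0:
        return values.copy()
    good_rows = np.setdiff1d(np.arange(values.shape[0]), bad_rows)
    w = interpolation_matrix(montage, good_rows, bad_rows, **kwargs)
    out = values.copy()
    out[bad_rows] = w @ values[good_rows]
    return out


def idealized_montage(n_channels: int = 128, labels=None) -> Montage:
    """Deterministic idealized EEG cap: a Fibonacci lattice over the upper
    spherical cap (z > -0.25), mimicking high-density scalp coverage."""
    z_min = -0.25
    i = np.arange(n_channels)
    z = 1.0 - (1.0 - z_min) * (i + 0.5) / n_channels
    phi = i * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    pos = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    if labels is None:
        labels = [f"E{k + 1}" for k in range(n_channels)]
    return Montage(list(labels), pos)
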