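"""Thin-plate-spline bending energy and tangent sliding of semi-landmarks.

The bending energy of a displacement field applied to a reference
configuration is the quadratic form ``d' Lk d`` (summed over the x and y
components), where ``Lk`` is the upper-left p x p block of the inverse of the
TPS system matrix built on the reference.  Affine displacement fields have
exactly zero bending energy.

Semi-landmarks are slid along their local curve tangents so as to minimize
this bending energy relative to the reference (the Procrustes consensus
during superimposition), which removes the arbitrary along-curve component of
their placement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .scheme import SemiLandmarkScheme

log = logging.getLogger(__name__)


def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    # U(r) = r^2 log r^2, with U(0) = 0
    out = np.zeros_like(r2)
    nz = r2 > 0
    out[nz] = r2[nz] * np.log(r2[nz])
    return out


@dataclass
class BendingEnergyModel:
    """Bending-energy quadratic form on per-point displacements."""

    reference: np.ndarray  # (p, 2)
    Lk: np.ndarray         # (p, p), symmetric PSD

    @property
    def n_points(self) -> int:
        return self.reference.shape[0]

    def energy(self, target: np.ndarray) -> float:
        """Bending energy of the displacement taking the reference to ``target``."""
        d = np.asarray(target, float) - self.reference
        return float(d[:, 0] @ self.Lk @ d[:, 0] + d[:, 1] @ self.Lk @ d[:, 1])


def bending_energy_model(reference: np.ndarray) -> BendingEnergyModel:
    """Build the TPS bending-energy matrix for a 2D reference configuration.

    Assembles ``L = [[K, Q], [Q', 0]]`` with ``K_ij = U(|x_i - x_j|)`` and
    ``Q = [1, x, y]``, and extracts the upper-left p x p block of ``L^-1``.

    Raises
    ------
    ValueError
        If the reference points are collinear (singular TPS system).
    """
    ref = np.asarray(reference, dtype=float)
    p = ref.shape[0]
    if p < 4:
        raise ValueError("bending energy needs at least 4 reference points")
    # collinearity check via rank of the centered coordinates
    if np.linalg.matrix_rank(ref - ref.mean(axis=0), tol=1e-10) < 2:
        raise ValueError(
            "reference points are collinear; TPS system is singular "
            "(jitter the points to break collinearity)"
        )
    K = _tps_kernel(cdist(ref, ref, "sqeuclidean"))
    Q = np.column_stack([np.ones(p), ref])
    L = np.zeros((p + 3, p + 3))
    L[:p, :p] = K
    L[:p, p:] = Q
    L[p:, :p] = Q.T
    Linv = np.linalg.inv(L)
    Lk = Linv[:p, :p]
    Lk = 0.5 * (Lk + Lk.T)  # enforce exact symmetry
    return BendingEnergyModel(reference=ref, Lk=Lk)


def slide_shape(
    shape: np.ndarray,
    model: BendingEnergyModel,
    scheme: SemiLandmarkScheme,
) -> np.ndarray:
    """Slide one shape's semi-landmarks along their tangents.

    Each semi-landmark moves only along the chord direction between its two
    neighbours on the curve chain; the vector of slide magnitudes solves the
    linear system that minimizes bending energy relative to the model's
    reference.  Fixed landmarks never move.
    """
    y = np.asarray(shape, dtype=float).copy()
    triplets = scheme.slider_triplets
    sliders = []
    tangents = []
    for before, mid, after in triplets:
        t = y[after] - y[before]
        norm = np.linalg.norm(t)
        if norm < 1e-12:
            log.warning("degenerate tangent at point %d; held fixed", mid)
            continue
        sliders.append(mid)
        tangents.append(t / norm)
    if not sliders:
        return y
    s_idx = np.asarray(sliders)
    U = np.asarray(tangents)           # (s, 2) unit tangents
    Lk = model.Lk
    Lsub = Lk[np.ix_(s_idx, s_idx)]    # (s, s)
    # A_ik = (u_i . u_k) Lk[s_i, s_k];  b_i = u_i . (Lk d)_{s_i}
    A = (U @ U.T) * Lsub
    d = y - model.reference
    g = Lk @ d                          # (p, 2)
    b = np.einsum("ij,ij->i", U, g[s_idx])
    t, *_ = np.linalg.lstsq(A, -b, rcond=None)
    # Trust region: the tangent linearization is only valid locally, and a
    # slide past a neighbouring point breaks the curve ordering (points then
    # "crawl" and bunch up over repeated passes).  Scale the whole step so no
    # semi-landmark moves more than a fraction of the gap to its neighbours;
    # a common scaling of the optimal step of a convex quadratic still
    # strictly decreases the energy.
    before_idx = np.asarray([tr[0] for tr in triplets if tr[1] in set(sliders)])
    after_idx = np.asarray([tr[2] for tr in triplets if tr[1] in set(sliders)])
    gap = np.minimum(
        np.linalg.norm(y[s_idx] - y[before_idx], axis=1),
        np.linalg.norm(y[after_idx] - y[s_idx], axis=1),
    )
    limit = 0.45 * gap
    with np.errstate(divide="ignore"):
        alpha = float(np.min(np.where(np.abs(t) > 0, limit / np.abs(t), np.inf)))
    t = t * min(1.0, alpha)
    y[s_idx] += t[:, None] * U
    return y
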