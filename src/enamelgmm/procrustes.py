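"""Curve resampling and generalized Procrustes superimposition.

Configurations are (p, 2) arrays: 8 fixed landmarks followed by the
semi-landmarks curve by curve (see :mod:`enamelgmm.scheme`).  Superimposition
removes position (centering), size (unit centroid size) and orientation
(rotation-only orthogonal least squares against the iteratively updated
consensus).  When sliding is enabled, semi-landmarks are slid along their
curve tangents against the consensus between superimposition passes, using
the thin-plate-spline bending-energy criterion.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .bending import bending_energy_model, slide_shape
from .scheme import SemiLandmarkScheme
from .tps import RawSpecimen

log = logging.getLogger(__name__)


def centroid_size(config: np.ndarray) -> float:
    """Square root of the summed squared deviations of points from their centroid."""
    pts = np.asarray(config, dtype=float)
    dev = pts - pts.mean(axis=0)
    cs = float(np.sqrt((dev**2).sum()))
    if cs == 0.0:
        raise ValueError("degenerate configuration: all points identical (zero size)")
    return cs


def _polyline_resample(poly: np.ndarray, m: int) -> np.ndarray:
    """m points equally spaced in arc length strictly inside the polyline."""
    poly = np.asarray(poly, dtype=float)
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    total = seg.sum()
    if total <= 0:
        raise ValueError("zero-length curve cannot be resampled")
    s = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.arange(1, m + 1) / (m + 1) * total
    x = np.interp(targets, s, poly[:, 0])
    y = np.interp(targets, s, poly[:, 1])
    return np.column_stack([x, y])


def resample_curves(spec: RawSpecimen, scheme: SemiLandmarkScheme) -> np.ndarray:
    """Replace raw digitized curves by equidistant semi-landmarks.

    Returns the (p, 2) configuration in scheme point order: the 8 fixed
    landmarks, then ``counts_per_curve[c]`` points equally spaced in arc
    length along each curve polyline (flanking landmarks excluded).
    """
    parts = [spec.fixed_landmarks]
    for c, poly in enumerate(spec.curves):
        parts.append(_polyline_resample(poly, scheme.counts_per_curve[c]))
    config = np.vstack(parts)
    assert config.shape == (scheme.n_points, 2)
    return config


def _center_scale(config: np.ndarray) -> tuple[np.ndarray, float]:
    pts = np.asarray(config, dtype=float)
    centered = pts - pts.mean(axis=0)
    cs = float(np.sqrt((centered**2).sum()))
    if cs == 0:
        raise ValueError("degenerate configuration (zero centroid size)")
    return centered / cs, cs


def _optimal_rotation(shape: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation-only (det +1) least-squares rotation aligning shape to target."""
    H = shape.T @ target
    Uv, _, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(Uv @ Vt))
    D = np.diag([1.0, sign])
    return Uv @ D @ Vt


def _canonical_frame(consensus: np.ndarray) -> np.ndarray:
    """Proper rotation taking the consensus principal axis onto x."""
    c = consensus - consensus.mean(axis=0)
    evals, evecs = np.linalg.eigh(c.T @ c)
    v1 = evecs[:, -1]
    proj = c @ v1
    s = float(np.sum(proj**3))
    if s == 0.0:
        s = float(proj[int(np.argmax(np.abs(proj)))])
    if s < 0:
        v1 = -v1
    v2 = np.array([-v1[1], v1[0]])
    return np.column_stack([v1, v2])


@dataclass
class AlignedSample:
    """Procrustes-superimposed sample of configurations."""

    shapes: np.ndarray          # (n, p, 2)
    centroid_sizes: np.ndarray  # (n,)
    consensus: np.ndarray       # (p, 2)
    scheme: SemiLandmarkScheme | None
    slid: bool
    converged: bool = True

    @property
    def n(self) -> int:
        return self.shapes.shape[0]

    @property
    def n_points(self) -> int:
        return self.shapes.shape[1]

    @property
    def coords(self) -> np.ndarray:
        """n x 2p matrix of Procrustes coordinates (x1, y1, ..., xp, yp)."""
        return self.shapes.reshape(self.n, -1)


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Partial Procrustes distance between two configurations.

    Both are centered, scaled to unit centroid size, and ``a`` is rotated
    onto ``b``; the distance is the root summed squared difference.
    """
    sa, _ = _center_scale(np.asarray(a, float))
    sb, _ = _center_scale(np.asarray(b, float))
    R = _optimal_rotation(sa, sb)
    return float(np.linalg.norm(sa @ R - sb))


def gpa(
    configs: list[np.ndarray] | np.ndarray,
    scheme: SemiLandmarkScheme | None = None,
    slide: bool = False,
    max_iter: int = 100,
    tol: float = 1e-6,
    slide_cycles: int = 5,
) -> AlignedSample:
    """Generalized Procrustes superimposition, optionally with sliding.

    Parameters
    ----------
    configs:
        n configurations of identical p (each (p, 2)).
    scheme:
        Required when ``slide`` is true (defines the slider triplets).
    slide:
        Interleave bending-energy sliding of semi-landmarks against the
        current consensus; ``slide_cycles`` GPA+slide cycles are run, each
        followed by re-centering/re-scaling.
    """
    arr = np.asarray([np.asarray(c, float) for c in configs])
    if arr.ndim != 3 or arr.shape[2] != 2:
        raise ValueError("configs must be n configurations of (p, 2) points")
    n, p, _ = arr.shape
    if n < 2:
        raise ValueError("GPA needs at least 2 configurations")
    if slide and scheme is None:
        raise ValueError("sliding requires a SemiLandmarkScheme")
    if slide and scheme.n_points != p:
        raise ValueError(f"scheme has {scheme.n_points} points, configs have {p}")

    shapes = np.empty_like(arr)
    sizes = np.empty(n)
    for i, c in enumerate(arr):
        shapes[i], sizes[i] = _center_scale(c)

    def _superimpose(shapes: np.ndarray, consensus: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
        conv = False
        for _ in range(max_iter):
            for i in range(n):
                R = _optimal_rotation(shapes[i], consensus)
                shapes[i] = shapes[i] @ R
            new_consensus, _ = _center_scale(shapes.mean(axis=0))
            change = np.linalg.norm(new_consensus - consensus)
            consensus = new_consensus
            if change < tol:
                conv = True
                break
        return shapes, consensus, conv

    consensus = shapes[0].copy()
    shapes, consensus, converged = _superimpose(shapes, consensus)

    if slide:
        # Slides are re-solved from the fixed unslid base configurations each
        # cycle (rotated into the current frame), rather than accumulated on
        # previously slid shapes: accumulation lets semi-landmarks crawl
        # unboundedly along the outline as the consensus follows them.
        base = shapes.copy()
        for _ in range(slide_cycles):
            model = bending_energy_model(consensus)
            before = consensus.copy()
            for i in range(n):
                y0 = base[i] @ _optimal_rotation(base[i], consensus)
                shapes[i], _ = _center_scale(slide_shape(y0, model, scheme))
            shapes, consensus, converged = _superimpose(shapes, consensus)
            if np.linalg.norm(consensus - before) < tol:
                break

    if not converged:
        warnings.warn("GPA did not converge within max_iter; returning best result")

    # Canonical orientation: the Procrustes solution is defined only up to a
    # global rotation, so pin it by rotating the consensus principal axis
    # onto x (sign fixed by the third moment).  This makes the output
    # invariant to similarity transforms of the inputs and re-alignment a
    # no-op.
    G = _canonical_frame(consensus)
    shapes = shapes @ G
    # final exact re-centering so invariants hold to machine precision;
    # the reported consensus is the coordinate-wise mean of the aligned shapes
    for i in range(n):
        shapes[i], _ = _center_scale(shapes[i])
    return AlignedSample(
        shapes=shapes,
        centroid_sizes=sizes,
        consensus=shapes.mean(axis=0),
        scheme=scheme,
        slid=slide,
        converged=converged,
    )


def align_to_consensus(config: np.ndarray, consensus: np.ndarray) -> np.ndarray:
    """Single orthogonal Procrustes fit of one configuration onto a consensus.

    Used to place an unknown specimen into an existing shape space: center,
    scale to unit centroid size, rotate onto the consensus.
    """
    s, _ = _center_scale(np.asarray(config, float))
    R = _optimal_rotation(s, np.asarray(consensus, float))
    return s @ R
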