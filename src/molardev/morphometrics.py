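"""2D outline morphometrics of molar occlusal shapes.

The occlusal outline of a tooth is resampled to 64 points at equal angular
steps around its centroid, expanded as a Fourier series of the
centroid-radius function r(theta), and described by 14 size-standardized
shape variables (the first seven cosine and sine harmonic amplitudes, each
divided by the zeroth harmonic a0, which carries size). Shape sets are
summarized with a PCA on the variance-covariance matrix of the
coefficients; maximal length and width come from the principal axes of the
raw outline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Outline",
    "ShapeCoefficients",
    "SizeMeasures",
    "PcaResult",
    "resample_outline",
    "radial_fourier",
    "reconstruct_radius",
    "length_width",
    "shape_pca",
]


def _signed_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _polygon_centroid(pts: np.ndarray) -> np.ndarray:
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = 0.5 * cross.sum()
    if area == 0:
        raise ValueError("degenerate outline: zero area")
    cx = np.sum((x + xn) * cross) / (6.0 * area)
    cy = np.sum((y + yn) * cross) / (6.0 * area)
    return np.array([cx, cy])


@dataclass
class Outline:
    """A closed 2D tooth outline.

    ``points`` are ordered (x, y) vertices stored anticlockwise, the last
    vertex not repeating the first. ``anterior_index`` marks the vertex at
    the anterior pole, which fixes the angular starting point of the radial
    expansion.
    """

    points: np.ndarray
    tooth_id: str = "tooth"
    tooth_type: str = "UM1"
    anterior_index: int = 0
    center: np.ndarray | None = None  # set by resample_outline

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 8:
            raise ValueError("outline needs at least 8 (x, y) points")
        if _signed_area(pts) < 0:  # store anticlockwise
            pts = pts[::-1].copy()
            if self.anterior_index != 0:
                self.anterior_index = len(pts) - self.anterior_index
        self.points = pts

    @property
    def centroid(self) -> np.ndarray:
        return _polygon_centroid(self.points)


@dataclass
class ShapeCoefficients:
    """Size-standardized radial Fourier descriptors of one outline.

    ``a`` and ``b`` hold the cosine/sine harmonic amplitudes k = 1..K, each
    divided by the zeroth harmonic ``a0`` (the mean radius, retained as
    size). The 2K shape values are invariant to translation and uniform
    scaling; the anterior starting point fixes the phase.
    """

    tooth_id: str
    a0: float
    a: np.ndarray
    b: np.ndarray

    @property
    def values(self) -> np.ndarray:
        """The shape variables in the order a1..aK, b1..bK."""
        return np.concatenate([self.a, self.b])


@dataclass
class SizeMeasures:
    tooth_id: str
    length: float
    width: float

    @property
    def ratio(self) -> float:
        return self.length / self.width


@dataclass
class PcaResult:
    """Covariance PCA of a coefficient matrix (teeth x variables)."""

    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    loadings: np.ndarray   # columns are principal axes
    scores: np.ndarray     # centered data projected on the axes


def _ray_radius(pts: np.ndarray, centroid: np.ndarray, angles: np.ndarray) -> np.ndarray:
    """Distance from the centroid to the outline along each ray direction.

    Intersects each ray with every polygon edge and keeps the farthest
    forward crossing; also verifies (by crossing parity) that the centroid
    lies inside the polygon.
    """
    p1 = pts - centroid
    p2 = np.roll(pts, -1, axis=0) - centroid
    # winding number of the boundary around the centroid: +/-1 iff inside
    va = np.arctan2(p1[:, 1], p1[:, 0])
    dva = np.mod(np.diff(np.append(va, va[0])) + math.pi, 2 * math.pi) - math.pi
    if abs(round(dva.sum() / (2 * math.pi))) != 1:
        raise ValueError(
            "the centroid lies outside the outline: a radial expansion is "
            "undefined (an elliptic-Fourier variant would be needed)"
        )
    e = p2 - p1                      # (m, 2) edge vectors
    tol = 1e-9
    radii = np.empty(len(angles))
    for i, theta in enumerate(angles):
        d = np.array([math.cos(theta), math.sin(theta)])
        denom = d[0] * e[:, 1] - d[1] * e[:, 0]
        ok = np.abs(denom) > 1e-300
        safe = np.where(ok, denom, 1.0)
        s = np.where(ok, (p1[:, 0] * d[1] - p1[:, 1] * d[0]) / safe, np.nan)
        t = np.where(ok, (p1[:, 0] * e[:, 1] - p1[:, 1] * e[:, 0]) / safe, np.nan)
        hit = ok & (s >= -tol) & (s < 1.0 + tol) & (t > 0.0)
        if not hit.any():
            raise ValueError(
                "no boundary crossing along a ray from the centroid: the outline "
                "is not star-shaped about its centroid"
            )
        radii[i] = float(np.max(t[hit]))
    return radii


def resample_outline(outline: Outline, n: int = 64) -> Outline:
    """Resample to ``n`` points at equal angular steps about the centroid.

    The first resampled point lies on the ray through the anterior vertex,
    so the anterior pole defines theta = 0.
    """
    pts = outline.points
    c = _polygon_centroid(pts)
    anterior = pts[outline.anterior_index] - c
    theta0 = math.atan2(anterior[1], anterior[0])
    angles = theta0 + 2.0 * math.pi * np.arange(n) / n
    r = _ray_radius(pts, c, angles)
    new = c + np.column_stack([r * np.cos(angles), r * np.sin(angles)])
    return Outline(
        points=new,
        tooth_id=outline.tooth_id,
        tooth_type=outline.tooth_type,
        anterior_index=0,
        center=c,
    )


def radial_fourier(outline: Outline, harmonics: int = 7) -> ShapeCoefficients:
    """Fourier series of the centroid-radius function of a resampled outline.

    Expects points at equal angular steps starting at the anterior pole
    (see :func:`resample_outline`). Returns a0 (mean radius, size) and the
    2*harmonics shape variables a_k/a0, b_k/a0.
    """
    pts = outline.points
    n = len(pts)
    if harmonics > n // 2:
        raise ValueError(f"{harmonics} harmonics alias with only {n} points")
    c = outline.center if outline.center is not None else _polygon_centroid(pts)
    rel = pts - c
    r = np.hypot(rel[:, 0], rel[:, 1])
    # verify the equal-angle convention rather than silently mis-ordering
    ang = np.unwrap(np.arctan2(rel[:, 1], rel[:, 0]))
    step = np.diff(ang)
    if not np.allclose(step, 2 * math.pi / n, atol=1e-6):
        raise ValueError("outline is not equal-angle resampled; call resample_outline first")
    F = np.fft.rfft(r)
    a0 = float(F[0].real) / n
    a = 2.0 * F[1 : harmonics + 1].real / n
    b = -2.0 * F[1 : harmonics + 1].imag / n
    return ShapeCoefficients(tooth_id=outline.tooth_id, a0=a0, a=a / a0, b=b / a0)


def reconstruct_radius(coeffs: ShapeCoefficients, n: int, harmonics: int | None = None) -> np.ndarray:
    """Radius function rebuilt from the first ``harmonics`` harmonics."""
    K = len(coeffs.a) if harmonics is None else harmonics
    theta = 2.0 * math.pi * np.arange(n) / n
    r = np.full(n, coeffs.a0)
    for k in range(1, K + 1):
        r += coeffs.a0 * (
            coeffs.a[k - 1] * np.cos(k * theta) + coeffs.b[k - 1] * np.sin(k * theta)
        )
    return r


def length_width(outline: Outline) -> SizeMeasures:
    """Maximal length and width along the outline's principal axes."""
    pts = outline.points
    centered = pts - pts.mean(axis=0)
    cov = np.cov(centered.T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evecs = evecs[:, order]
    proj = centered @ evecs
    extents = proj.max(axis=0) - proj.min(axis=0)
    length, width = float(max(extents)), float(min(extents))
    if width <= 1e-9 * max(length, 1e-300):
        raise ValueError("degenerate (collinear) outline")
    return SizeMeasures(tooth_id=outline.tooth_id, length=length, width=width)


def shape_pca(coefficients) -> PcaResult:
    """PCA on the variance-covariance matrix of shape coefficients.

    ``coefficients`` is a (teeth x variables) array or DataFrame; no
    correlation scaling is applied (covariance PCA, sample n-1 denominator).
    """
    X = np.asarray(
        coefficients.values if isinstance(coefficients, pd.DataFrame) else coefficients,
        float,
    )
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need at least 3 teeth")
    if not np.isfinite(X).all():
        raise ValueError("coefficient matrix contains missing values")
    Xc = X - X.mean(axis=0)
    cov = (Xc.T @ Xc) / (X.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # sign convention: largest-magnitude loading positive
    for j in range(evecs.shape[1]):
        k = np.argmax(np.abs(evecs[:, j]))
        if evecs[k, j] < 0:
            evecs[:, j] = -evecs[:, j]
    total = evals.sum()
    percent = 100.0 * evals / total if total > 0 else np.zeros_like(evals)
    return PcaResult(
        eigenvalues=evals,
        percent_variance=percent,
        loadings=evecs,
        scores=Xc @ evecs,
    )
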