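"""MUCCSS: multicentred constrained size-and-shape coordinates.

The low-detail representation of a suite is 5 landmarks: N1/N9 and C1'
of the first residue, the central P, and C1' and N1/N9 of the second
residue.  After subtracting P from the C1' positions and each C1' from
its glycosidic nitrogen, rotation is removed by a canonical frame built
on the P-C1'-C1' triangle, leaving

    W = (d2, d3, alpha, s1, s2)

with the two pseudo-bond lengths d2, d3 > 0, their opening angle
alpha in (0, pi), and the two unit glycosidic directions s1, s2 on the
2-sphere -- 7 degrees of freedom, matching the 7 dihedrals of the
high-detail torus representation.  The space is a Riemannian product
(flat on the first three factors, great-circle metric on the spheres);
this module provides the product metric, Fréchet means, tangent-space
coordinates at a base point, and tangent covariance matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .suite_geometry import GeometryError

__all__ = [
    "ChartError",
    "LandmarkSet",
    "MuccssPoint",
    "FrechetSummary",
    "canonical_frame",
    "to_muccss",
    "muccss_distance",
    "frechet_mean",
    "tangent_coords",
    "tangent_covariance",
    "frechet_summary",
]


class ChartError(ValueError):
    """A point falls outside the hemisphere chart at the base point."""


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-10:
        raise GeometryError(f"zero-length {what}")
    return v / n


@dataclass(frozen=True)
class LandmarkSet:
    """The 5 low-detail landmarks, ordered N1/N9(i-1), C1'(i-1), P(i),
    C1'(i), N1/N9(i); shape (5, 3), Angstrom."""

    points: np.ndarray

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (5, 3):
            raise ValueError("landmarks must be a (5, 3) array")
        object.__setattr__(self, "points", pts)

    @classmethod
    def from_suite(cls, suite) -> "LandmarkSet":
        return cls(suite.landmarks())


@dataclass(frozen=True)
class MuccssPoint:
    """A point W = (d2, d3, alpha, s1, s2) of the MUCCSS space.

    d2, d3 in Angstrom (> 0); alpha in radians, strictly inside (0, pi);
    s1, s2 unit 3-vectors (glycosidic directions in the canonical frame).
    """

    d2: float
    d3: float
    alpha: float
    s1: np.ndarray
    s2: np.ndarray

    def __post_init__(self):
        if not (self.d2 > 0 and self.d3 > 0):
            raise ValueError("pseudo-bond lengths must be positive")
        if not 0.0 < self.alpha < np.pi:
            raise ValueError("opening angle must lie strictly in (0, pi)")
        for name in ("s1", "s2"):
            s = np.asarray(getattr(self, name), dtype=float)
            if s.shape != (3,) or abs(np.linalg.norm(s) - 1.0) > 1e-12:
                raise ValueError(f"{name} must be a unit 3-vector")
            object.__setattr__(self, name, s)

    @property
    def spheres(self) -> tuple[np.ndarray, np.ndarray]:
        return self.s1, self.s2

    def polar(self) -> dict:
        """Polar angles (theta from the +z axis, phi in the x-y plane),
        degrees, of both glycosidic directions."""
        out = {}
        for i, s in enumerate(self.spheres, start=1):
            out[f"theta{i}"] = float(np.degrees(np.arccos(np.clip(s[2], -1, 1))))
            out[f"phi{i}"] = float(np.degrees(np.arctan2(s[1], s[0])) % 360.0)
        return out

    def flat(self) -> np.ndarray:
        return np.array([self.d2, self.d3, self.alpha])


def canonical_frame(v, w) -> np.ndarray:
    """Orthogonal frame R = (e1|e2|e3), det +1, aligning the triangle
    (0, v, w) with the x-y plane.

    e1 points along w - v (so the later-in-sequence C1' has the larger
    x-projection), e2 is the in-plane normal component of v (both v and
    w then share the same positive y-projection), e3 = e1 x e2.
    """
    v = np.asarray(v, dtype=float)
    w = np.asarray(w, dtype=float)
    if np.linalg.norm(v) < 1e-10 or np.linalg.norm(w) < 1e-10:
        raise GeometryError("degenerate frame: zero pseudo-bond")
    e1 = w - v
    n1 = np.linalg.norm(e1)
    if n1 < 1e-10 or np.linalg.norm(np.cross(v, w)) < 1e-10:
        raise GeometryError("degenerate frame: pseudo-bonds parallel")
    e1 = e1 / n1
    e2 = v - e1 * (e1 @ v)
    e2 = _unit(e2, "frame vector e2")
    e3 = np.cross(e1, e2)
    return np.column_stack([e1, e2, e3])


def to_muccss(landmarks: LandmarkSet) -> MuccssPoint:
    """MUCCSS coordinates of a 5-landmark configuration.

    The measured glycosidic bond vectors are normalised to unit length
    (their lengths are treated as a known constant; only the directions
    carry information).
    """
    if isinstance(landmarks, np.ndarray):
        landmarks = LandmarkSet(landmarks)
    x1, x2, x3, x4, x5 = landmarks.points
    y1, v, w, y2 = x1 - x2, x2 - x3, x4 - x3, x5 - x4
    R = canonical_frame(v, w)
    d2 = float(np.linalg.norm(v))
    d3 = float(np.linalg.norm(w))
    alpha = float(np.arccos(np.clip((v @ w) / (d2 * d3), -1.0, 1.0)))
    s1 = R.T @ _unit(y1, "glycosidic bond 1")
    s2 = R.T @ _unit(y2, "glycosidic bond 2")
    # guard rounding so the invariant |s|=1 holds to 1e-12
    s1 /= np.linalg.norm(s1)
    s2 /= np.linalg.norm(s2)
    return MuccssPoint(d2=d2, d3=d3, alpha=alpha, s1=s1, s2=s2)


def _arc(a: np.ndarray, b: np.ndarray) -> float:
    # atan2 form: accurate for nearly parallel and nearly antipodal pairs
    return float(np.arctan2(np.linalg.norm(np.cross(a, b)), a @ b))


def muccss_distance(w1: MuccssPoint, w2: MuccssPoint) -> float:
    """Product metric: flat on (d2, d3, alpha), great-circle arcs on the
    two spheres, every factor entering once, unweighted."""
    flat = w1.flat() - w2.flat()
    return float(np.sqrt(flat @ flat + _arc(w1.s1, w2.s1) ** 2
                         + _arc(w1.s2, w2.s2) ** 2))


# ---------------------------------------------------------------------------
# spherical helpers

def _slog(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Riemannian log of q at p on the unit sphere (3-vector in T_p S^2)."""
    t = _arc(p, q)
    u = q - p * (p @ q)
    nu = np.linalg.norm(u)
    if nu < 1e-14:
        if p @ q > 0:  # same point to numerical precision
            return np.zeros(3)
        raise GeometryError("antipodal points: spherical log undefined")
    return (t / nu) * u


def _sexp(p: np.ndarray, v: np.ndarray) -> np.ndarray:
    t = np.linalg.norm(v)
    if t < 1e-16:
        return p.copy()
    q = np.cos(t) * p + np.sin(t) * (v / t)
    return q / np.linalg.norm(q)


def _sphere_mean(points: np.ndarray, tol: float = 1e-10,
                 max_iter: int = 1000) -> np.ndarray:
    """Intrinsic (Fréchet) mean on S^2 by tangent-average fixed point,
    initialised at the normalised chordal mean; suited to the
    concentrated samples produced by per-cluster use."""
    m = points.mean(axis=0)
    nm = np.linalg.norm(m)
    m = points[0].copy() if nm < 1e-12 else m / nm
    for _ in range(max_iter):
        v = np.mean([_slog(m, p) for p in points], axis=0)
        if np.linalg.norm(v) < tol:
            return m
        m = _sexp(m, v)
    raise GeometryError(
        f"spherical mean did not converge in {max_iter} iterations "
        f"(last gradient norm {np.linalg.norm(v):.3e}); sample may not "
        "be concentrated")


def frechet_mean(samples: Sequence[MuccssPoint]) -> MuccssPoint:
    """Fréchet mean of MUCCSS points: arithmetic on the flat factors
    (exact closed form), iterative intrinsic mean on each sphere."""
    if len(samples) == 0:
        raise ValueError("cannot average an empty sample")
    if len(samples) == 1:
        return samples[0]
    flat = np.mean([s.flat() for s in samples], axis=0)
    m1 = _sphere_mean(np.array([s.s1 for s in samples]))
    m2 = _sphere_mean(np.array([s.s2 for s in samples]))
    return MuccssPoint(d2=float(flat[0]), d3=float(flat[1]),
                       alpha=float(flat[2]), s1=m1, s2=m2)


_STD_BASIS = np.eye(3)


def _chart_basis(base_s: np.ndarray) -> np.ndarray:
    """(3, 2) orthonormal basis Q of the tangent plane at ``base_s``.

    The helper axis is the standard basis vector least aligned with the
    base direction (lowest index on ties), following the robustified
    residual-coordinate construction; Q = (b | c) with
    b = normalised component of that axis orthogonal to base_s and
    c = b x base_s.
    """
    k = int(np.argmin(np.abs(_STD_BASIS @ base_s)))
    a = _STD_BASIS[k]
    b = a - base_s * (a @ base_s)
    b = _unit(b, "chart basis")
    c = np.cross(b, base_s)
    return np.column_stack([b, c])


def tangent_coords(w: MuccssPoint, base: MuccssPoint) -> np.ndarray:
    """Length-7 tangent-space coordinates of ``w`` at ``base``:
    (d2-d2*, d3-d3*, alpha-alpha*, s~1, s~2).

    Each s~i is the orthogonal projection of the unit direction s_i onto
    the tangent plane of the sphere at the base direction, expressed in
    the deterministic 2D basis of :func:`_chart_basis`; the map is
    bijective only on the open hemisphere around the base, which is
    enforced (s_i . s_i* > 0).
    """
    out = np.empty(7)
    out[:3] = w.flat() - base.flat()
    for i, (s, s_base) in enumerate(zip(w.spheres, base.spheres)):
        if s @ s_base <= 0.0:
            raise ChartError(
                f"s{i + 1} outside the hemisphere chart at the base point "
                f"(cos angle = {s @ s_base:.3f})")
        Q = _chart_basis(s_base)
        out[3 + 2 * i: 5 + 2 * i] = Q.T @ s
    return out


def tangent_covariance(samples: Sequence[MuccssPoint],
                       base: MuccssPoint) -> np.ndarray:
    """7x7 tangent covariance 1/(n-1) sum_j t_j t_j^T with
    t_j = tangent_coords(sample_j, base).

    The estimator is uncentred: at a Fréchet mean the flat components
    average to zero and the spherical residuals are treated as
    deviations by construction.
    """
    n = len(samples)
    if n < 2:
        raise ValueError("tangent covariance needs at least 2 samples")
    T = np.array([tangent_coords(s, base) for s in samples])
    return T.T @ T / (n - 1)


@dataclass(frozen=True)
class FrechetSummary:
    """Per-cluster summary: Fréchet mean, tangent covariance, size, and
    the Fréchet function value at the mean."""

    mean: MuccssPoint
    covariance: np.ndarray
    n: int
    frechet_value: float

    def __post_init__(self):
        cov = np.asarray(self.covariance, dtype=float)
        if cov.shape != (7, 7) or not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("covariance must be symmetric 7x7")
        object.__setattr__(self, "covariance", cov)


def frechet_summary(samples: Sequence[MuccssPoint]) -> FrechetSummary:
    """Convenience: mean, covariance (zero matrix for n = 1) and Fréchet
    function value for one cluster's LD members."""
    mean = frechet_mean(samples)
    n = len(samples)
    cov = (tangent_covariance(samples, mean) if n >= 2
           else np.zeros((7, 7)))
    fval = float(np.mean([muccss_distance(mean, s) ** 2 for s in samples]))
    return FrechetSummary(mean=mean, covariance=cov, n=n, frechet_value=fval)
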