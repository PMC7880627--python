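"""Linear-algebra core for binocular gaze geometry.

The coordinate convention is fixed throughout the package: the first axis is
horizontal (positive toward the observer's right eye), the second axis is the
up direction, and the third axis is depth, pointing away from the observer.
All lengths are in centimetres.  The two eye centres sit symmetrically on the
horizontal axis at (-a, 0, 0) and (a, 0, 0), where 2a is the interocular
distance.

The point of regard of two (generally skew) gaze rays is defined as the point
minimising the sum of squared Euclidean distances to the two rays.  Squared
distance of a point to a ray is measured with the projector matrix
``P = I - v v^T`` of the unit ray direction ``v``: ``P`` annihilates the
component along the ray and leaves the orthogonal complement unchanged, so
``(x - p)^T P (x - p)`` is the squared distance from ``x`` to the line through
``p`` along ``v``.  Setting the gradient of the summed squared distances to
zero turns the minimisation into a single 3x3 linear solve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EyeGeometry",
    "GazeRay",
    "VergenceEstimate",
    "projector",
    "point_ray_sq_distance",
    "vergence_point",
    "target_rays",
]

#: Two unit directions are treated as parallel when |1 - |e_l . e_r|| falls
#: below this tolerance; the 3x3 system's condition number explodes there.
PARALLEL_TOL = 1e-12

_UNIT_TOL = 1e-9


def _as_vec3(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValueError(f"{name} must be finite, got {v}")
    return v


@dataclass(frozen=True)
class EyeGeometry:
    """Observer geometry: symmetric eye centres and a fixated target.

    Parameters
    ----------
    interocular_distance : float
        Distance between the two eye centres (2a), cm.  Must be positive.
    target : array-like of shape (3,)
        Fixated point of interest, cm.  Its third (depth) component must be
        positive, i.e. in front of the observer.
    up : array-like of shape (3,)
        Unit up direction; defaults to (0, 1, 0).
    """

    interocular_distance: float = 6.0
    target: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 50.0]))
    up: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))

    def __post_init__(self):
        if self.interocular_distance <= 0:
            raise ValueError(
                f"interocular_distance must be > 0, got {self.interocular_distance}"
            )
        t = _as_vec3(self.target, "target")
        if t[2] <= 0:
            raise ValueError(f"target depth must be > 0 (in front), got {t[2]}")
        u = _as_vec3(self.up, "up")
        n = np.linalg.norm(u)
        if abs(n - 1.0) > _UNIT_TOL:
            raise ValueError(f"up must be a unit vector, norm is {n}")
        object.__setattr__(self, "target", t)
        object.__setattr__(self, "up", u)

    @property
    def half_interocular(self) -> float:
        """a, half the interocular distance, cm."""
        return self.interocular_distance / 2.0

    @property
    def eye_left(self) -> np.ndarray:
        """Left eye centre (-a, 0, 0); derived, never stored."""
        return np.array([-self.half_interocular, 0.0, 0.0])

    @property
    def eye_right(self) -> np.ndarray:
        """Right eye centre (a, 0, 0)."""
        return np.array([self.half_interocular, 0.0, 0.0])


@dataclass(frozen=True)
class GazeRay:
    """A ray from an eye centre with a unit direction."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        o = _as_vec3(self.origin, "origin")
        d = _as_vec3(self.direction, "direction")
        n = np.linalg.norm(d)
        if abs(n - 1.0) > _UNIT_TOL:
            raise ValueError(f"direction must be unit length, norm is {n}")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "direction", d)

    @classmethod
    def through(cls, origin, point) -> "GazeRay":
        """Ray from ``origin`` toward ``point`` (normalised)."""
        o = _as_vec3(origin, "origin")
        p = _as_vec3(point, "point")
        d = p - o
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("point coincides with the ray origin")
        return cls(o, d / n)


@dataclass(frozen=True)
class VergenceEstimate:
    """Least-squares vergence point of two gaze rays.

    ``point`` is None when the rays are parallel within tolerance
    (``degenerate`` is True): two parallel lines have no unique closest point.
    ``residual`` is the summed squared distance of the point to the two rays,
    in cm^2.
    """

    point: np.ndarray | None
    residual: float
    degenerate: bool

    def __post_init__(self):
        if not self.degenerate and self.residual < -1e-12:
            raise ValueError(f"residual must be >= 0, got {self.residual}")


def projector(direction) -> np.ndarray:
    """Projector matrix ``I - v v^T`` onto the complement of unit vector v.

    Symmetric and idempotent; annihilates ``direction`` and fixes every vector
    orthogonal to it, so ``x^T (I - v v^T) x`` is the squared distance from
    ``x`` to the line through the origin along ``v``.
    """
    v = _as_vec3(direction, "direction")
    n = np.linalg.norm(v)
    if abs(n - 1.0) > _UNIT_TOL:
        raise ValueError(f"projector requires a unit direction, norm is {n}")
    return np.eye(3) - np.outer(v, v)


def point_ray_sq_distance(x, ray: GazeRay) -> float:
    """Squared Euclidean distance (cm^2) from ``x`` to the infinite line of ``ray``."""
    xv = _as_vec3(x, "x")
    d = xv - ray.origin
    return float(d @ projector(ray.direction) @ d)


def vergence_point(
    left: GazeRay, right: GazeRay, parallel_tol: float = PARALLEL_TOL
) -> VergenceEstimate:
    """Point minimising the summed squared distances to two gaze rays.

    Solves ``(E_l + E_r) x = E_l p_l + E_r p_r`` where ``E_l, E_r`` are the
    projectors of the two ray directions.  The system is uniquely solvable
    exactly when the directions are not parallel; parallel rays yield a
    degenerate estimate instead of a crash, so Monte Carlo callers can count
    them.  Points behind the observer (negative depth) are returned as-is.
    """
    el, er = left.direction, right.direction
    if abs(1.0 - abs(float(el @ er))) < parallel_tol:
        return VergenceEstimate(point=None, residual=np.nan, degenerate=True)
    El = np.eye(3) - np.outer(el, el)
    Er = np.eye(3) - np.outer(er, er)
    x = np.linalg.solve(El + Er, El @ left.origin + Er @ right.origin)
    dl = x - left.origin
    dr = x - right.origin
    residual = float(dl @ El @ dl + dr @ Er @ dr)
    return VergenceEstimate(point=x, residual=max(residual, 0.0), degenerate=False)


def target_rays(geometry: EyeGeometry) -> tuple[GazeRay, GazeRay]:
    """Noise-free unit rays from the two eye centres to the target."""
    return (
        GazeRay.through(geometry.eye_left, geometry.target),
        GazeRay.through(geometry.eye_right, geometry.target),
    )
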