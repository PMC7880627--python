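"""Closed-form depth-bias ratios for paired symmetric gaze errors.

For a target at unit depth on the symmetry axis, ``z = (0, 0, 1)``, and eyes
at ``(+-a, 0, 0)``, the mean depth of the least-squares vergence points of a
pair of error instances admits simple closed forms:

* purely horizontal errors ``eta_l, eta_r`` paired with the *reversed* pair
  ``(eta_r, eta_l)``::

      z'/z = 4 a^2 / (4 a^2 - (eta_l - eta_r)^2)     >= 1

  valid while ``(eta_l - eta_r)^2 < 4 a^2`` (beyond that the paired rays
  meet behind the observer);

* purely vertical errors ``nu_l, nu_r`` paired with the *negated* pair
  ``(-nu_l, -nu_r)``::

      z'/z = (4 a^2 + a^2 (nu_l + nu_r)^2)
             / ((nu_l - nu_r)^2 + 4 a^2 + a^2 (nu_l + nu_r)^2)   <= 1

  with no restriction on the noise.

Any centrally symmetric error distribution can be partitioned into such
pairs, so horizontal noise biases the mean vergence depth away from the
observer and vertical noise biases it toward the observer.

Error convention.  The closed forms treat an error component as a lateral
displacement added to the eye-to-target offset at unit depth (ray direction
``(+-a + eta, nu, 1)``), i.e. a tangent-plane displacement; for small angles
this coincides with the angular error in radians.  Under this convention the
identities above are exact (machine precision); adding the same error to the
*normalised* ray instead agrees only to O(a^2 * error).  Scaling the target
distance is equivalent to rescaling ``a``, so general geometries are handled
by the solver, not by these forms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import GazeRay, vergence_point

__all__ = [
    "BiasRatio",
    "depth_ratio_horizontal",
    "depth_ratio_vertical",
    "paired_mean_depth",
]


@dataclass(frozen=True)
class BiasRatio:
    """Mean-depth ratio z'/z of a paired error instance (target at z = 1)."""

    ratio: float
    half_interocular: float


def depth_ratio_horizontal(a: float, eta_l: float, eta_r: float) -> BiasRatio:
    """Closed-form mean depth ratio for a horizontal error pair and its reverse.

    Requires ``(eta_l - eta_r)^2 < 4 a^2``; at equality the paired rays are
    parallel and beyond it their intersection lies behind the observer, so
    the ratio diverges to +infinity as the bound is approached.
    """
    if a <= 0:
        raise ValueError(f"half interocular distance a must be > 0, got {a}")
    d2 = (eta_l - eta_r) ** 2
    if d2 >= 4 * a * a:
        raise ValueError(
            f"(eta_l - eta_r)^2 = {d2:g} >= 4a^2 = {4 * a * a:g}: "
            "paired rays diverge (intersection behind the observer)"
        )
    return BiasRatio(ratio=4 * a * a / (4 * a * a - d2), half_interocular=a)


def depth_ratio_vertical(a: float, nu_l: float, nu_r: float) -> BiasRatio:
    """Closed-form mean depth ratio for a vertical error pair and its negation.

    Always in (0, 1], with equality exactly when ``nu_l == nu_r``.
    """
    if a <= 0:
        raise ValueError(f"half interocular distance a must be > 0, got {a}")
    s2 = a * a * (nu_l + nu_r) ** 2
    num = 4 * a * a + s2
    return BiasRatio(ratio=num / ((nu_l - nu_r) ** 2 + num), half_interocular=a)


def _solver_depth(a: float, eps_l: np.ndarray, eps_r: np.ndarray) -> float:
    """Depth of the LSE vergence point for one error instance.

    Errors are tangent-plane displacements added to the unnormalised
    eye-to-target offsets (see module docstring).
    """
    pl = np.array([-a, 0.0, 0.0])
    pr = np.array([a, 0.0, 0.0])
    z = np.array([0.0, 0.0, 1.0])
    dl = (z - pl) + eps_l
    dr = (z - pr) + eps_r
    left = GazeRay(pl, dl / np.linalg.norm(dl))
    right = GazeRay(pr, dr / np.linalg.norm(dr))
    est = vergence_point(left, right)
    if est.degenerate:
        raise ValueError("pair member yields parallel rays (degenerate estimate)")
    return float(est.point[2])


def paired_mean_depth(a: float, eps_l, eps_r, pairing: str = "reversed") -> float:
    """Mean solver depth of an error pair and its symmetric counterpart.

    ``pairing='reversed'`` pairs ``(eps_l, eps_r)`` with ``(eps_r, eps_l)``
    (the natural pairing for horizontal errors); ``pairing='negated'`` pairs
    it with ``(-eps_l, -eps_r)`` (the natural pairing for vertical errors).
    This is the general numerical oracle behind both closed forms.
    """
    if a <= 0:
        raise ValueError(f"half interocular distance a must be > 0, got {a}")
    el = np.asarray(eps_l, dtype=float)
    er = np.asarray(eps_r, dtype=float)
    if el.shape != (3,) or er.shape != (3,):
        raise ValueError("eps_l and eps_r must be 3-vectors")
    if pairing == "reversed":
        counterpart = (er, el)
    elif pairing == "negated":
        counterpart = (-el, -er)
    else:
        raise ValueError(f"pairing must be 'reversed' or 'negated', got {pairing!r}")
    return 0.5 * (_solver_depth(a, el, er) + _solver_depth(a, *counterpart))
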