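"""Angular noise model on gaze rays and Monte Carlo vergence simulation.

Variable error (imprecision) is modelled per eye as a zero-mean Gaussian
angular deviation with independent horizontal and vertical components;
systematic error (inaccuracy) as a constant angular offset.  User-facing
units are degrees.  Internally angles are converted to radians and used
directly as direction-vector components: for the small angles involved the
linear approximation ``sin(phi) ~ phi`` makes adding the error vector to a
unit gaze ray (followed by renormalisation) equivalent to rotating it.

The error vector lies in the horizontal-vertical plane (third component 0);
since fixated targets sit near the depth axis this is an excellent proxy for
a perturbation orthogonal to the ray.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .geometry import EyeGeometry, GazeRay, PARALLEL_TOL, target_rays

__all__ = [
    "NoiseSpec",
    "SimulationSummary",
    "SimulationResult",
    "sample_error",
    "perturb_ray",
    "simulate",
    "simulate_from_errors",
    "summarize",
    "systematic_scenarios",
    "TABLE1_CONDITIONS",
    "run_table1",
]

DEG = np.pi / 180.0


@dataclass(frozen=True)
class NoiseSpec:
    """Per-eye angular noise standard deviations and constant offsets, degrees.

    Horizontal and vertical components are uncorrelated and the two eyes are
    independent (diagonal covariance).  ``seed`` makes a simulation run
    reproducible when no generator is passed explicitly.
    """

    sigma_h_left: float = 0.0
    sigma_v_left: float = 0.0
    sigma_h_right: float = 0.0
    sigma_v_right: float = 0.0
    offset_h_left: float = 0.0
    offset_v_left: float = 0.0
    offset_h_right: float = 0.0
    offset_v_right: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        for name in ("sigma_h_left", "sigma_v_left", "sigma_h_right", "sigma_v_right"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")

    @classmethod
    def symmetric(cls, sigma_h: float, sigma_v: float, seed: int | None = None) -> "NoiseSpec":
        """Same horizontal/vertical noise in both eyes, no offsets."""
        return cls(
            sigma_h_left=sigma_h, sigma_v_left=sigma_v,
            sigma_h_right=sigma_h, sigma_v_right=sigma_v, seed=seed,
        )

    def mirrored(self) -> "NoiseSpec":
        """Left/right-swapped spec (same seed)."""
        return NoiseSpec(
            sigma_h_left=self.sigma_h_right, sigma_v_left=self.sigma_v_right,
            sigma_h_right=self.sigma_h_left, sigma_v_right=self.sigma_v_left,
            offset_h_left=self.offset_h_right, offset_v_left=self.offset_v_right,
            offset_h_right=self.offset_h_left, offset_v_right=self.offset_v_left,
            seed=self.seed,
        )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SimulationSummary:
    """Summary statistics of a Monte Carlo batch of vergence estimates.

    ``mean_point`` is the arithmetic mean of the estimated points (cm);
    ``mean_error`` the mean Euclidean distance to the true target;
    ``mean_error_xyz`` the per-axis mean absolute deviations; the ``std``
    fields are the sample standard deviations of the same quantities.
    Degenerate (parallel-ray) draws are counted but excluded from the
    statistics; estimates behind the observer are included.
    """

    n_samples: int
    n_degenerate: int
    mean_point: np.ndarray
    mean_error: float
    std_error: float
    mean_error_xyz: np.ndarray
    std_xyz: np.ndarray

    def to_dict(self) -> dict:
        return {
            "n_samples": int(self.n_samples),
            "n_degenerate": int(self.n_degenerate),
            "mean_point": [float(v) for v in self.mean_point],
            "mean_error": float(self.mean_error),
            "std_error": float(self.std_error),
            "mean_error_xyz": [float(v) for v in self.mean_error_xyz],
            "std_xyz": [float(v) for v in self.std_xyz],
        }


@dataclass(frozen=True)
class SimulationResult:
    """Raw points of a simulation run plus their summary.

    ``points`` has one row per draw; degenerate draws are NaN rows and are
    flagged in ``degenerate``.
    """

    points: np.ndarray
    degenerate: np.ndarray
    summary: SimulationSummary


def sample_error(spec: NoiseSpec, eye: str, rng: np.random.Generator, size: int | None = None) -> np.ndarray:
    """Draw angular error vector(s) for one eye, as direction components.

    Returns ``(offset_h + eta, offset_v + nu, 0)`` with ``eta ~ N(0, sigma_h^2)``
    and ``nu ~ N(0, sigma_v^2)``, all converted from degrees to radians.
    With ``size=None`` a single 3-vector is returned, otherwise ``(size, 3)``.
    """
    if eye not in ("left", "right"):
        raise ValueError(f"eye must be 'left' or 'right', got {eye!r}")
    sh = getattr(spec, f"sigma_h_{eye}") * DEG
    sv = getattr(spec, f"sigma_v_{eye}") * DEG
    oh = getattr(spec, f"offset_h_{eye}") * DEG
    ov = getattr(spec, f"offset_v_{eye}") * DEG
    n = 1 if size is None else size
    eps = np.zeros((n, 3))
    eps[:, 0] = oh + rng.normal(0.0, sh, n)
    eps[:, 1] = ov + rng.normal(0.0, sv, n)
    return eps[0] if size is None else eps


def perturb_ray(ray: GazeRay, epsilon) -> GazeRay:
    """Add an error vector to the ray direction and renormalise."""
    eps = np.asarray(epsilon, dtype=float)
    d = ray.direction + eps
    n = np.linalg.norm(d)
    if n < 1e-12:
        raise ValueError("perturbation cancels the ray direction to the zero vector")
    return GazeRay(ray.origin, d / n)


def _batch_vergence(pl, pr, dl, dr, parallel_tol=PARALLEL_TOL):
    """Vectorised least-squares vergence solve for (n,3) direction arrays.

    Returns (points, degenerate): degenerate rows are NaN.
    """
    n = dl.shape[0]
    dots = np.abs(np.einsum("ij,ij->i", dl, dr))
    degenerate = np.abs(1.0 - dots) < parallel_tol
    eye = np.eye(3)
    El = eye[None, :, :] - dl[:, :, None] * dl[:, None, :]
    Er = eye[None, :, :] - dr[:, :, None] * dr[:, None, :]
    A = El + Er
    b = np.einsum("nij,j->ni", El, pl) + np.einsum("nij,j->ni", Er, pr)
    points = np.full((n, 3), np.nan)
    ok = ~degenerate
    if ok.any():
        points[ok] = np.linalg.solve(A[ok], b[ok][:, :, None])[:, :, 0]
    return points, degenerate


def simulate_from_errors(geometry: EyeGeometry, eps_l: np.ndarray, eps_r: np.ndarray) -> SimulationResult:
    """Reconstruct vergence points from explicit per-draw error vectors.

    ``eps_l``/``eps_r`` are (n, 3) arrays of direction-component errors
    (radians) added to the noise-free unit rays toward the target.  This is
    the shared backend of :func:`simulate`, the covariance resampler and the
    fixation-averaging recipe.
    """
    left, right = target_rays(geometry)
    dl = left.direction[None, :] + eps_l
    dr = right.direction[None, :] + eps_r
    dl = dl / np.linalg.norm(dl, axis=1, keepdims=True)
    dr = dr / np.linalg.norm(dr, axis=1, keepdims=True)
    points, degenerate = _batch_vergence(left.origin, right.origin, dl, dr)
    summary = summarize(points, geometry, n_degenerate=int(degenerate.sum()))
    return SimulationResult(points=points, degenerate=degenerate, summary=summary)


def simulate(
    geometry: EyeGeometry,
    spec: NoiseSpec,
    n: int,
    rng: np.random.Generator | int | None = None,
) -> SimulationResult:
    """Monte Carlo simulation of ``n`` noisy vergence estimates.

    Each draw perturbs the noise-free target rays with independent per-eye
    errors and reconstructs the least-squares vergence point.  Degenerate
    (parallel) draws are counted, not fatal.  Reproducible given
    ``spec.seed`` or an explicit ``rng``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    eps_l = sample_error(spec, "left", rng, size=n)
    eps_r = sample_error(spec, "right", rng, size=n)
    return simulate_from_errors(geometry, eps_l, eps_r)


def summarize(points: np.ndarray, geometry: EyeGeometry, n_degenerate: int = 0) -> SimulationSummary:
    """Summary statistics over non-degenerate (non-NaN) estimates."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"points must be (n, 3), got shape {pts.shape}")
    valid = pts[~np.isnan(pts[:, 0])]
    if len(valid) == 0:
        raise ValueError("no non-degenerate estimates to summarise")
    dev = valid - geometry.target[None, :]
    dist = np.linalg.norm(dev, axis=1)
    abs_dev = np.abs(dev)
    ddof = 1 if len(valid) > 1 else 0
    return SimulationSummary(
        n_samples=len(pts),
        n_degenerate=int(n_degenerate),
        mean_point=valid.mean(axis=0),
        mean_error=float(dist.mean()),
        std_error=float(dist.std(ddof=ddof)),
        mean_error_xyz=abs_dev.mean(axis=0),
        std_xyz=abs_dev.std(axis=0, ddof=ddof),
    )


def systematic_scenarios(sigma: float = 0.16, offset: float = 1.0) -> dict[str, NoiseSpec]:
    """The six canonical 1-degree systematic-offset configurations.

    Baseline Gaussian noise of ``sigma`` degrees in both directions of both
    eyes, plus a constant ``offset`` applied as:

    a. left eye rotated horizontally outward (away from the nose);
    b. left eye rotated toward the right eye's direction;
    c. both eyes rotated in the same horizontal direction;
    d. both eyes rotated inward;
    e. both eyes rotated outward;
    f. opposite vertical rotations.

    Sign convention: positive horizontal offsets rotate toward +x, so outward
    for the left eye (at -a) is negative and inward positive; for the right
    eye the reverse.
    """
    base = dict(sigma_h_left=sigma, sigma_v_left=sigma,
                sigma_h_right=sigma, sigma_v_right=sigma)
    return {
        "a": NoiseSpec(**base, offset_h_left=-offset),
        "b": NoiseSpec(**base, offset_h_left=+offset),
        "c": NoiseSpec(**base, offset_h_left=+offset, offset_h_right=+offset),
        "d": NoiseSpec(**base, offset_h_left=+offset, offset_h_right=-offset),
        "e": NoiseSpec(**base, offset_h_left=-offset, offset_h_right=+offset),
        "f": NoiseSpec(**base, offset_v_left=+offset, offset_v_right=-offset),
    }


#: The nine canonical simulation conditions: target depth (cm), horizontal
#: and vertical noise standard deviation (degrees), at 6 cm interocular
#: distance.
TABLE1_CONDITIONS: list[tuple[float, float, float]] = [
    (50.0, 1.5, 1.5), (50.0, 1.5, 0.16), (50.0, 0.16, 1.5),
    (70.0, 1.5, 1.5), (70.0, 1.5, 0.16), (70.0, 0.16, 1.5),
    (110.0, 1.5, 1.5), (110.0, 1.5, 0.16), (110.0, 0.16, 1.5),
]


def run_table1(n: int = 10_000, seed: int | None = None, interocular: float = 6.0):
    """Run all nine canonical conditions and tabulate the summary columns.

    Returns a pandas DataFrame with columns: target_distance_cm, sigma_x_deg,
    sigma_y_deg, mean_z_cm, mean_error_cm, std_error_cm, error_{x,y,z}_cm,
    std_{x,y,z}_cm, n_degenerate.
    """
    import pandas as pd

    streams = np.random.SeedSequence(seed).spawn(len(TABLE1_CONDITIONS))
    rows = []
    for (z, sh, sv), ss in zip(TABLE1_CONDITIONS, streams):
        geom = EyeGeometry(interocular_distance=interocular, target=[0.0, 0.0, z])
        res = simulate(geom, NoiseSpec.symmetric(sh, sv), n, rng=np.random.default_rng(ss))
        s = res.summary
        rows.append({
            "target_distance_cm": z, "sigma_x_deg": sh, "sigma_y_deg": sv,
            "mean_z_cm": s.mean_point[2],
            "mean_error_cm": s.mean_error, "std_error_cm": s.std_error,
            "error_x_cm": s.mean_error_xyz[0], "error_y_cm": s.mean_error_xyz[1],
            "error_z_cm": s.mean_error_xyz[2],
            "std_x_cm": s.std_xyz[0], "std_y_cm": s.std_xyz[1],
            "std_z_cm": s.std_xyz[2],
            "n_degenerate": s.n_degenerate,
        })
    return pd.DataFrame(rows)
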