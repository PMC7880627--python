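"""Synthetic fixation-table generator with a ring-target study design.

Emulates a binocular fixation experiment: observers fixate 12 targets on a
ring of 7 degrees eccentricity plus a central target, shown on a monitor at
two viewing distances, under four viewing conditions (monocular left/right,
binocular left/right eye), five repetitions each.  Raw eye positions are
target positions in screen pixels plus Gaussian noise whose 2x2 covariance
(in squared degrees of visual angle) is a per-condition design parameter.

The generator models only the stationary fixation scatter: no saccade
dynamics, drift, undershoot/correction sequences or blinks.  Fixation counts
per target visit are drawn as 2 + Bernoulli(p_extra) and durations from a
truncated log-normal; both are design parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .fixation_stats import REQUIRED_COLUMNS

__all__ = ["ExperimentDesign", "ScreenSpec", "target_layout", "generate"]

CONDITION_EYE = {"ML": "L", "MR": "R", "BL": "L", "BR": "R"}


@dataclass(frozen=True)
class ScreenSpec:
    """Display geometry used to convert visual angle to pixels."""

    width_m: float = 0.52
    height_m: float = 0.32
    res_x: int = 1920
    res_y: int = 1200

    @property
    def pitch_x_cm(self) -> float:
        return self.width_m * 100.0 / self.res_x

    @property
    def pitch_y_cm(self) -> float:
        return self.height_m * 100.0 / self.res_y

    @property
    def center_px(self) -> np.ndarray:
        return np.array([self.res_x / 2.0, self.res_y / 2.0])


def _default_covs() -> dict:
    # Binocular-viewing fixation scatter is a little tighter than monocular;
    # magnitudes chosen so marginal SDs are of order 1 degree of visual angle,
    # with vertical noise slightly dominant.
    mono = np.array([[0.9, 0.1], [0.1, 1.2]])
    bino = np.array([[0.6, 0.05], [0.05, 0.8]])
    return {"ML": mono, "MR": mono.copy(), "BL": bino, "BR": bino.copy()}


@dataclass(frozen=True)
class ExperimentDesign:
    """Study-design parameters of the synthetic experiment.

    ``per_condition_cov`` maps each viewing condition to the 2x2 fixation
    covariance in squared degrees of visual angle.  Durations are drawn from
    a log-normal with the given mean/SD (ms), truncated below at
    ``duration_floor_ms``.  ``fixations_extra_p`` is the Bernoulli
    probability of a third fixation on a target visit (2 + Bernoulli(p), so
    p = 0.3 gives a mean of 2.3 fixations per target).
    """

    distances_cm: tuple = (70.0, 110.0)
    conditions: tuple = ("ML", "MR", "BL", "BR")
    repetitions: int = 5
    n_ring_targets: int = 12
    eccentricity_deg: float = 7.0
    screen: ScreenSpec = field(default_factory=ScreenSpec)
    per_condition_cov: dict = field(default_factory=_default_covs)
    duration_mean_ms: float = 821.0
    duration_sd_ms: float = 494.0
    duration_floor_ms: float = 0.0
    fixations_extra_p: float = 0.3
    seed: int | None = None

    def __post_init__(self):
        for c in self.conditions:
            if c not in CONDITION_EYE:
                raise ValueError(f"unknown condition {c!r}; expected one of {list(CONDITION_EYE)}")
            s = np.asarray(self.per_condition_cov[c], dtype=float)
            if s.shape != (2, 2) or not np.allclose(s, s.T):
                raise ValueError(f"covariance for {c} must be symmetric 2x2")
            if np.linalg.eigvalsh(s)[0] < 0:
                raise ValueError(f"covariance for {c} must be positive semi-definite")
        if not 0 <= self.fixations_extra_p <= 1:
            raise ValueError("fixations_extra_p must be in [0, 1]")

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["per_condition_cov"] = {
            k: np.asarray(v, dtype=float).tolist() for k, v in self.per_condition_cov.items()
        }
        return d


def target_layout(design: ExperimentDesign, distance_cm: float) -> np.ndarray:
    """Pixel coordinates of the centre target and the ring targets.

    Row 0 is the screen centre; rows 1..n are the ring targets, placed
    evenly over 360 degrees starting at 12 o'clock, at the design
    eccentricity.  Opposite ring targets subtend twice the eccentricity.
    Raises if the ring does not fit on the screen at this distance.
    """
    if distance_cm <= 0:
        raise ValueError(f"distance_cm must be > 0, got {distance_cm}")
    scr = design.screen
    r_cm = distance_cm * np.tan(np.radians(design.eccentricity_deg))
    r_px = np.array([r_cm / scr.pitch_x_cm, r_cm / scr.pitch_y_cm])
    if r_cm > scr.width_m * 50 or r_cm > scr.height_m * 50:
        raise ValueError(
            f"ring radius {r_cm:.1f} cm exceeds screen bounds "
            f"({scr.width_m * 50:.0f} x {scr.height_m * 50:.0f} cm half-extents)"
        )
    # phase 0 at 12 o'clock, proceeding clockwise in screen coordinates
    phases = np.pi / 2 - 2 * np.pi * np.arange(design.n_ring_targets) / design.n_ring_targets
    ring = scr.center_px + np.stack(
        [r_px[0] * np.cos(phases), r_px[1] * np.sin(phases)], axis=1
    )
    return np.vstack([scr.center_px, ring])


def _deg_to_px(design: ExperimentDesign, distance_cm: float) -> np.ndarray:
    scr = design.screen
    cm_per_deg = distance_cm * np.tan(np.radians(1.0))
    return np.array([cm_per_deg / scr.pitch_x_cm, cm_per_deg / scr.pitch_y_cm])


def _duration_params(design: ExperimentDesign) -> tuple[float, float]:
    m, s = design.duration_mean_ms, design.duration_sd_ms
    sigma2 = np.log1p((s / m) ** 2)
    return np.log(m) - sigma2 / 2.0, np.sqrt(sigma2)


def generate(design: ExperimentDesign, n_observers: int = 1,
             rng: np.random.Generator | int | None = None) -> pd.DataFrame:
    """Generate a fixation table with the design's statistical structure.

    Per observer, distance, condition and repetition there are 12 ring-target
    visits interleaved with 12 centre-target visits; each visit contributes
    2 + Bernoulli(p) fixations.  Fixation positions are the target pixel
    position plus Gaussian noise with the condition's covariance (degrees,
    converted to pixels via the screen geometry and viewing distance).
    Reproducible given ``design.seed`` or an explicit generator.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    mu, sig = _duration_params(design)
    rows = []
    for obs in range(1, n_observers + 1):
        for dist in design.distances_cm:
            layout = target_layout(design, dist)
            px_per_deg = _deg_to_px(design, dist)
            for cond in design.conditions:
                cov = np.asarray(design.per_condition_cov[cond], dtype=float)
                chol = np.linalg.cholesky(cov + 1e-15 * np.eye(2))
                eye = CONDITION_EYE[cond]
                for rep in range(1, design.repetitions + 1):
                    t_ms = 0.0
                    order = rng.permutation(design.n_ring_targets) + 1
                    # each ring target presentation is preceded by a centre fixation
                    visits = [v for t in order for v in (0, int(t))]
                    for tid in visits:
                        n_fix = 2 + (rng.random() < design.fixations_extra_p)
                        for _ in range(n_fix):
                            dur = float(np.exp(rng.normal(mu, sig)))
                            while dur < design.duration_floor_ms:
                                dur = float(np.exp(rng.normal(mu, sig)))
                            noise_deg = chol @ rng.normal(0.0, 1.0, 2)
                            pos = layout[tid] + noise_deg * px_per_deg
                            rows.append((obs, dist, cond, rep, tid, eye,
                                         t_ms, dur, pos[0], pos[1]))
                            t_ms += dur + 50.0
    table = pd.DataFrame(rows, columns=REQUIRED_COLUMNS)
    table.attrs["units"] = "px"
    table.attrs["design"] = design.to_jsonable()
    return table
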