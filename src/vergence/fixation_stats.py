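"""Analysis pipeline for pre-segmented binocular fixation tables.

Works on raw, pre-calibration eye positions (pupil-centre minus corneal
reflection, in eye-camera pixel units) labelled by observer, viewing
distance, viewing condition (monocular/binocular x left/right eye),
repetition and fixation target.  The pipeline:

1. filters out short fixations and per-cluster outliers;
2. summarises each target cluster by its 2x2 sample covariance and the
   corresponding 95% error ellipse;
3. compares covariance structures with an affine-invariant Riemannian
   metric, pairwise-distance distributions and two-sample KS tests;
4. converts pixel units to degrees of visual angle using the known angular
   span of diametrically opposite ring targets;
5. feeds mean covariances back into the Monte Carlo vergence simulator to
   quantify the depth bias implied by measured fixation noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import EyeGeometry
from .noise_sim import DEG, SimulationResult, simulate_from_errors

__all__ = [
    "REQUIRED_COLUMNS",
    "CovSummary",
    "DistanceDistribution",
    "PreprocessResult",
    "KSResult",
    "validate_table",
    "preprocess",
    "covariance",
    "per_target_covariances",
    "cov_distance",
    "mean_covariance",
    "pairwise_distances",
    "ks_compare",
    "to_degrees",
    "resample_vergence",
]

REQUIRED_COLUMNS = [
    "observer_id", "distance_cm", "condition", "repetition",
    "target_id", "eye", "t_start_ms", "duration_ms", "raw_x", "raw_y",
]

#: chi-square(2 dof) 0.95 quantile; scales eigenvalues to a 95% coverage
#: ellipse for a bivariate Gaussian.
CHI2_95_2DOF = 5.991

CLUSTER_KEY = ["observer_id", "distance_cm", "condition", "eye", "target_id"]

RING_TARGETS = tuple(range(1, 13))


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the fixation-table schema and basic invariants."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"fixation table is missing columns: {missing}")
    if len(table) == 0:
        raise ValueError("fixation table is empty")
    if (table["duration_ms"] <= 0).any():
        raise ValueError("fixation durations must be > 0 ms")
    bad = set(table["target_id"].unique()) - set(range(0, 13))
    if bad:
        raise ValueError(f"invalid target ids (expected 0..12): {sorted(bad)}")
    return table


@dataclass(frozen=True)
class CovSummary:
    """Sample covariance of a fixation cluster with its 95% error ellipse.

    ``semi_axes`` are sqrt(5.991 * lambda_i) in data units, ordered
    descending; ``angle`` is the orientation of the principal eigenvector in
    radians, in (-pi/2, pi/2].
    """

    sigma: np.ndarray
    n: int
    center: np.ndarray
    semi_axes: np.ndarray
    angle: float


@dataclass(frozen=True)
class DistanceDistribution:
    """Multiset of pairwise covariance distances with their pair labels."""

    values: np.ndarray
    labels: list = field(default_factory=list)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if (v < 0).any():
            raise ValueError("covariance distances must be >= 0")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class PreprocessResult:
    table: pd.DataFrame
    n_short_removed: int
    n_outliers_removed: int
    n_clusters_skipped: int

    def to_dict(self) -> dict:
        return {
            "n_short_removed": int(self.n_short_removed),
            "n_outliers_removed": int(self.n_outliers_removed),
            "n_clusters_skipped": int(self.n_clusters_skipped),
            "outlier_rule": "single pass, Euclidean distance > 2 pooled SDs "
                            "(pooled SD = sqrt of summed per-axis variances)",
        }


@dataclass(frozen=True)
class KSResult:
    statistic: float
    p_value: float
    significant_at_0_05: bool


def preprocess(table: pd.DataFrame, min_duration_ms: float = 100.0, n_sd: float = 2.0) -> PreprocessResult:
    """Duration filter plus single-pass per-cluster outlier removal.

    Fixations shorter than ``min_duration_ms`` are removed (exactly 100 ms is
    retained: the boundary is strict).  Then, within each
    (observer, distance, condition, eye, target) cluster, points whose
    Euclidean distance from the cluster mean exceeds ``n_sd`` pooled standard
    deviations are dropped.  The pooled SD is the square root of the summed
    per-axis sample variances, i.e. the RMS radial spread.  Clusters with
    fewer than two fixations keep all points (the rule needs a spread
    estimate) and are counted in ``n_clusters_skipped``.
    """
    validate_table(table)
    kept = table[table["duration_ms"] >= min_duration_ms].copy()
    n_short = len(table) - len(kept)
    if len(kept) == 0:
        raise ValueError("no fixations remain after the duration filter")

    keep_mask = np.ones(len(kept), dtype=bool)
    n_skipped = 0
    pos = kept[["raw_x", "raw_y"]].to_numpy(dtype=float)
    for _, idx in kept.groupby(CLUSTER_KEY, sort=False).indices.items():
        if len(idx) < 2:
            n_skipped += 1
            continue
        pts = pos[idx]
        centered = pts - pts.mean(axis=0)
        pooled_sd = np.sqrt(centered.var(axis=0, ddof=1).sum())
        if pooled_sd == 0:
            continue
        r = np.linalg.norm(centered, axis=1)
        keep_mask[idx[r > n_sd * pooled_sd]] = False
    out = kept.iloc[keep_mask].reset_index(drop=True)
    out.attrs = dict(table.attrs)
    return PreprocessResult(
        table=out,
        n_short_removed=n_short,
        n_outliers_removed=int((~keep_mask).sum()),
        n_clusters_skipped=n_skipped,
    )


def covariance(points) -> CovSummary:
    """Unbiased 2x2 sample covariance of a point cluster, with 95% ellipse."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"points must be (n, 2), got shape {pts.shape}")
    if len(pts) < 2:
        raise ValueError(f"need >= 2 points for a covariance, got {len(pts)}")
    center = pts.mean(axis=0)
    sigma = np.cov(pts, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(sigma)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    principal = evecs[:, order[0]]
    angle = float(np.arctan2(principal[1], principal[0]))
    if angle <= -np.pi / 2:
        angle += np.pi
    elif angle > np.pi / 2:
        angle -= np.pi
    return CovSummary(
        sigma=sigma,
        n=len(pts),
        center=center,
        semi_axes=np.sqrt(CHI2_95_2DOF * evals),
        angle=angle,
    )


def per_target_covariances(
    table: pd.DataFrame,
    group_cols=("distance_cm", "condition"),
    targets=RING_TARGETS,
) -> dict:
    """Per-target :func:`covariance` summaries for each group of the table.

    Returns ``{group_key: {target_id: CovSummary}}``; the centre target (0)
    is excluded by default.  Targets with fewer than two fixations in a
    group are silently omitted.
    """
    validate_table(table)
    out: dict = {}
    for key, grp in table.groupby(list(group_cols), sort=True):
        per_target = {}
        for t, tgrp in grp.groupby("target_id"):
            if t not in targets or len(tgrp) < 2:
                continue
            per_target[int(t)] = covariance(tgrp[["raw_x", "raw_y"]].to_numpy())
        if per_target:
            out[key] = per_target
    return out


def _check_spd(sigma, name: str, min_eig: float = 1e-12) -> np.ndarray:
    s = np.asarray(sigma, dtype=float)
    if s.shape != (2, 2):
        raise ValueError(f"{name} must be 2x2, got shape {s.shape}")
    if not np.allclose(s, s.T, atol=1e-10):
        raise ValueError(f"{name} is not symmetric")
    lo = float(np.linalg.eigvalsh(s)[0])
    if lo <= min_eig:
        raise ValueError(
            f"{name} is not positive definite: smallest eigenvalue {lo:g} <= {min_eig:g}"
        )
    return s


def cov_distance(sigma1, sigma2) -> float:
    """Affine-invariant Riemannian distance between two SPD matrices.

    ``d = || log(S1^(-1/2) S2 S1^(-1/2)) ||_F``, computed by
    eigendecomposition.  Symmetric, zero iff the matrices are equal, and
    invariant both under congruence by any invertible matrix and under
    joint inversion.
    """
    s1 = _check_spd(sigma1, "sigma1")
    s2 = _check_spd(sigma2, "sigma2")
    w, u = np.linalg.eigh(s1)
    inv_sqrt = u @ np.diag(1.0 / np.sqrt(w)) @ u.T
    m = inv_sqrt @ s2 @ inv_sqrt
    m = 0.5 * (m + m.T)  # symmetrisation guard against roundoff
    ev = np.linalg.eigvalsh(m)
    return float(np.sqrt(np.sum(np.log(ev) ** 2)))


def mean_covariance(sigmas) -> np.ndarray:
    """Element-wise arithmetic mean of a set of SPD matrices (SPD by convexity)."""
    mats = [_check_spd(s, f"sigmas[{i}]") for i, s in enumerate(sigmas)]
    if not mats:
        raise ValueError("mean_covariance needs at least one matrix")
    return np.mean(mats, axis=0)


def pairwise_distances(sigmas) -> DistanceDistribution:
    """Distances between all unordered pairs of a labelled covariance set.

    ``sigmas`` is a mapping label -> 2x2 SPD matrix (or a sequence, which is
    labelled by position).  For 12 matrices this yields C(12,2) = 66 values.
    """
    if isinstance(sigmas, dict):
        items = list(sigmas.items())
    else:
        items = list(enumerate(sigmas))
    if len(items) < 2:
        raise ValueError(f"need >= 2 covariance matrices, got {len(items)}")
    labels, values = [], []
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            values.append(cov_distance(items[i][1], items[j][1]))
            labels.append((items[i][0], items[j][0]))
    return DistanceDistribution(values=np.asarray(values), labels=labels)


def ks_compare(d1, d2, alpha: float = 0.05) -> KSResult:
    """Two-sample Kolmogorov-Smirnov comparison of two distance distributions.

    The statistic is the maximum vertical distance between the two empirical
    CDFs; the significance flag is based on the p-value at ``alpha``.
    """
    v1 = d1.values if isinstance(d1, DistanceDistribution) else np.asarray(d1, dtype=float)
    v2 = d2.values if isinstance(d2, DistanceDistribution) else np.asarray(d2, dtype=float)
    if len(v1) == 0 or len(v2) == 0:
        raise ValueError("both distance distributions must be non-empty")
    res = stats.ks_2samp(v1, v2, method="auto")
    return KSResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        significant_at_0_05=bool(res.pvalue < alpha),
    )


@dataclass(frozen=True)
class ToDegreesResult:
    """Converted table plus the per-viewing-distance scale factors (deg/unit)."""

    table: pd.DataFrame
    deg_per_unit: dict


def to_degrees(table: pd.DataFrame, ring_span_deg: float = 14.0) -> ToDegreesResult:
    """Rescale raw coordinates to degrees using opposite ring targets.

    Diametrically opposite ring targets (1-7, 2-8, ...) subtend
    ``ring_span_deg`` degrees of visual angle.  For each viewing distance
    the scale factor is ``ring_span_deg`` divided by the mean raw distance
    between opposite cluster centres, estimated per
    (observer, condition, eye) group and averaged.  The factor is uniform
    within a viewing distance - but must be estimated per distance, since
    the pixel extent of a fixed visual angle grows with distance.
    Invariant under table-wide translation.
    """
    validate_table(table)
    out = table.copy()
    scales: dict = {}
    for dist, dgrp in table.groupby("distance_cm", sort=True):
        spans = []
        for _, grp in dgrp.groupby(["observer_id", "condition", "eye"], sort=False):
            centers = grp[grp["target_id"].isin(RING_TARGETS)].groupby("target_id")[
                ["raw_x", "raw_y"]].mean()
            for t in range(1, 7):
                opp = t + 6
                if t in centers.index and opp in centers.index:
                    spans.append(float(np.linalg.norm(centers.loc[t] - centers.loc[opp])))
        if not spans:
            raise ValueError(
                f"no opposite ring-target pairs at distance {dist}; "
                "cannot estimate the pixel-to-degree scale"
            )
        scale = ring_span_deg / float(np.mean(spans))
        scales[float(dist)] = scale
        mask = out["distance_cm"] == dist
        out.loc[mask, ["raw_x", "raw_y"]] *= scale
    out.attrs = dict(table.attrs)
    out.attrs["units"] = "deg"
    return ToDegreesResult(table=out, deg_per_unit=scales)


def _sample_correlated_angles(cov_rad2: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw (n, 3) error vectors from a full 2x2 angular covariance (rad^2).

    The horizontal standard normals are drawn first, then the vertical ones,
    so a diagonal covariance reproduces the independent-component sampler
    draw-for-draw.
    """
    L = np.linalg.cholesky(cov_rad2)
    uh = rng.normal(0.0, 1.0, n)
    uv = rng.normal(0.0, 1.0, n)
    eps = np.zeros((n, 3))
    eps[:, 0] = L[0, 0] * uh
    eps[:, 1] = L[1, 0] * uh + L[1, 1] * uv
    return eps


def resample_vergence(
    mean_cov,
    convert_to_deg: float,
    geometry: EyeGeometry,
    n: int,
    rng: np.random.Generator | int | None = None,
) -> SimulationResult:
    """Monte Carlo vergence simulation driven by a measured 2x2 covariance.

    ``mean_cov`` (in squared degrees, possibly correlated) is rescaled so
    that the mean of its two marginal standard deviations equals
    ``convert_to_deg`` degrees of visual angle, then used as the angular
    error covariance of both eyes (independent draws per eye).  This
    generalises the diagonal noise specification to correlated noise.
    """
    s = _check_spd(mean_cov, "mean_cov", min_eig=-np.inf)
    if convert_to_deg < 0:
        raise ValueError(f"convert_to_deg must be >= 0, got {convert_to_deg}")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    mean_sd = 0.5 * (np.sqrt(s[0, 0]) + np.sqrt(s[1, 1]))
    if mean_sd == 0 or convert_to_deg == 0:
        eps_l = np.zeros((n, 3))
        eps_r = np.zeros((n, 3))
    else:
        scaled = s * (convert_to_deg / mean_sd) ** 2 * DEG**2
        _check_spd(scaled / DEG**2, "scaled mean_cov")
        eps_l = _sample_correlated_angles(scaled, n, rng)
        eps_r = _sample_correlated_angles(scaled, n, rng)
    return simulate_from_errors(geometry, eps_l, eps_r)
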