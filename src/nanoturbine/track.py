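"""Rotation analysis of single-molecule localization data.

The pipeline mirrors the standard workflow for fluorophore-tip tracking
of nanopore-docked rotors: quality filtering on localization uncertainty,
local-density filtering to drop free-diffusing particles, Euclidean
(density-based) clustering into per-rotor point clouds, an algebraic
circle fit, an annulus-vs-centre density validity test, unwrapped
cumulative angles, a mean-square angular displacement (MSD) fit to

    MSD(t) = omega_d^2 t^2 + 2 D_r t

and a slender-rod torque estimate Gamma = xi_r * omega_d.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.cluster import DBSCAN

from .synth import LocalizationSet

__all__ = [
    "Circle",
    "AngularTrajectory",
    "MSDCurve",
    "MSDFit",
    "RotorResult",
    "TorqueParams",
    "AnalysisConfig",
    "filter_by_uncertainty",
    "filter_by_density",
    "cluster_localizations",
    "fit_circle",
    "annulus_validity",
    "extract_cumulative_angle",
    "compute_msd",
    "fit_msd",
    "estimate_torque",
    "rotational_drag_coefficient",
    "summarize_speeds",
    "analyze_dataset",
]


class CircleFitError(ValueError):
    """Raised when a circle cannot be fitted (too few / collinear points)."""


@dataclass(frozen=True)
class Circle:
    center: tuple[float, float]
    radius: float
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")


@dataclass
class AngularTrajectory:
    """Unwrapped cumulative angle versus time for one rotor."""

    times: np.ndarray  # s
    cum_angle: np.ndarray  # rad, starts at 0
    frames: np.ndarray  # original frame indices

    def __post_init__(self) -> None:
        if len(self.times) != len(self.cum_angle):
            raise ValueError("times and cum_angle must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def net_displacement(self) -> float:
        return float(self.cum_angle[-1] - self.cum_angle[0]) if len(self.cum_angle) else 0.0

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0]) if len(self.times) else 0.0


@dataclass
class MSDCurve:
    lags: np.ndarray  # s, strictly increasing, excludes lag 0
    msd: np.ndarray  # rad^2
    counts: np.ndarray  # pairs per lag


@dataclass
class MSDFit:
    omega_d: float  # rad/s, signed
    D_r: float  # rad^2/s
    rss: float
    offset: Optional[float] = None

    @property
    def omega_rev(self) -> float:
        """Signed speed in revolutions per second."""
        return self.omega_d / (2.0 * math.pi)


@dataclass(frozen=True)
class TorqueParams:
    """Rotational drag model of the crossbar load.

    Slender rod of length L and diameter d rotating about a perpendicular
    axis through its midpoint, in a fluid of the given viscosity;
    wall_correction >= 1 scales the bulk drag for surface proximity.
    """

    viscosity: float = 1.0e-3  # Pa s
    L: float = 300.0  # nm
    d: float = 7.0  # nm
    wall_correction: float = 1.0

    def __post_init__(self) -> None:
        if self.viscosity <= 0:
            raise ValueError("viscosity must be positive")
        if not (self.L > self.d > 0):
            raise ValueError("need L > d > 0")
        if self.wall_correction < 1.0:
            raise ValueError("wall_correction must be >= 1")


@dataclass
class RotorResult:
    id: int
    circle: Optional[Circle]
    valid: bool
    annulus_density: float = float("nan")
    center_density: float = float("nan")
    omega_rev: Optional[float] = None  # rev/s, signed
    D_r: Optional[float] = None
    torque: Optional[float] = None  # pN nm
    n_localizations: int = 0
    note: str = ""


@dataclass
class AnalysisConfig:
    """All thresholds of the pipeline, defaulting to the standard values
    (uncertainty < 50 nm; >= 15 neighbours in 50 nm; DBSCAN eps 50 nm /
    min 15 points; +-1 nm annulus)."""

    max_uncertainty: float = 50.0
    density_min_neighbors: int = 15
    density_radius: float = 50.0
    cluster_eps: float = 50.0
    cluster_min_pts: int = 15
    annulus_half_width: float = 1.0
    max_gap: int = 50
    max_lag_fraction: float = 0.25
    include_offset: bool = True
    weighted_fit: bool = True
    torque: TorqueParams = field(default_factory=TorqueParams)

    def as_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "max_uncertainty",
                "density_min_neighbors",
                "density_radius",
                "cluster_eps",
                "cluster_min_pts",
                "annulus_half_width",
                "max_gap",
                "max_lag_fraction",
                "include_offset",
                "weighted_fit",
            )
        }
        d.update(
            torque_viscosity=self.torque.viscosity,
            torque_L=self.torque.L,
            torque_d=self.torque.d,
            torque_wall_correction=self.torque.wall_correction,
        )
        return d


# ---------------------------------------------------------------------------
# filtering and clustering


def filter_by_uncertainty(
    locs: LocalizationSet, max_uncertainty: float = 50.0
) -> LocalizationSet:
    """Keep records with reported uncertainty strictly below the threshold."""
    if len(locs) == 0:
        return locs
    return locs.subset(locs.uncertainty < max_uncertainty)


def filter_by_density(
    locs: LocalizationSet, min_neighbors: int = 15, radius: float = 50.0
) -> LocalizationSet:
    """Keep records with >= min_neighbors *other* records within ``radius``.

    All frames are pooled, i.e. the neighbourhood is evaluated on the
    full time-integrated point cloud, which is what rules out
    free-diffusing particles that never revisit the same spot.
    """
    if len(locs) == 0:
        return locs
    tree = cKDTree(locs.xy)
    counts = tree.query_ball_point(locs.xy, r=radius, return_length=True)
    return locs.subset(counts - 1 >= min_neighbors)  # subtract self


def cluster_localizations(
    locs: LocalizationSet, eps: float = 50.0, min_pts: int = 15
) -> list[LocalizationSet]:
    """Euclidean density-based clustering (DBSCAN) into per-rotor sets.

    Noise points are discarded; clusters are returned largest first.
    """
    if len(locs) < min_pts:
        return []
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(locs.xy)
    clusters = []
    for lab in sorted(set(labels) - {-1}):
        clusters.append(locs.subset(labels == lab))
    clusters.sort(key=len, reverse=True)
    return clusters


# ---------------------------------------------------------------------------
# geometry


def fit_circle(points: np.ndarray) -> Circle:
    """Algebraic (Kåsa) least-squares circle fit.

    Solves the linear system x^2 + y^2 = 2 a x + 2 b y + c for the
    center (a, b) and radius sqrt(c + a^2 + b^2). Exact for points lying
    exactly on a circle; raises CircleFitError for < 3 points or a
    collinear/degenerate configuration.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    if len(pts) < 3:
        raise CircleFitError("need at least 3 points")
    # center the data for conditioning; the fit is translation-equivariant
    mean = pts.mean(axis=0)
    q = pts - mean
    A = np.column_stack([2.0 * q, np.ones(len(q))])
    rhs = (q**2).sum(axis=1)
    sol, _res, rank, _sv = np.linalg.lstsq(A, rhs, rcond=None)
    if rank < 3:
        raise CircleFitError("degenerate (collinear) point configuration")
    a, b, c = sol
    r2 = c + a * a + b * b
    if r2 <= 0:
        raise CircleFitError("degenerate circle fit (non-positive radius)")
    return Circle(
        center=(float(a + mean[0]), float(b + mean[1])),
        radius=float(np.sqrt(r2)),
        n_points=len(pts),
    )


def annulus_validity(
    points: np.ndarray, circle: Circle, half_width: float = 1.0
) -> tuple[bool, float, float]:
    """Annulus-vs-centre density test for a genuinely circular trajectory.

    Compares the point density inside the annulus R +- half_width around
    the fitted perimeter (area 4*pi*R*w) with the density inside the
    equal-area central disk of radius 2*sqrt(R*w). Valid iff the annulus
    density is strictly higher; ties are invalid.
    """
    pts = np.asarray(points, dtype=float)
    R, w = circle.radius, half_width
    if R <= w:
        return False, float("nan"), float("nan")
    r = np.hypot(pts[:, 0] - circle.center[0], pts[:, 1] - circle.center[1])
    area = 4.0 * math.pi * R * w
    n_annulus = int(np.count_nonzero((r >= R - w) & (r <= R + w)))
    r_center = 2.0 * math.sqrt(R * w)
    n_center = int(np.count_nonzero(r <= r_center))
    rho_a = n_annulus / area
    rho_c = n_center / area  # same area by construction
    return rho_a > rho_c, rho_a, rho_c


# ---------------------------------------------------------------------------
# angles and MSD


def _wrap_increments(dtheta: np.ndarray) -> np.ndarray:
    """Wrap raw angle differences into (-pi, pi]."""
    w = (dtheta + math.pi) % (2.0 * math.pi) - math.pi
    w[w == -math.pi] = math.pi
    return w


def extract_cumulative_angle(
    points: np.ndarray,
    circle: Circle,
    frame_rate: float,
    frames: Optional[np.ndarray] = None,
    max_gap: int = 50,
) -> AngularTrajectory:
    """Per-frame angular positions unwrapped into a cumulative angle.

    Angles are atan2 about the fitted center; consecutive differences are
    wrapped into (-pi, pi] (assumes < half a turn of net motion between
    observations, including across short detection gaps) and summed from
    zero. Gaps longer than ``max_gap`` frames split the trajectory; the
    longest segment is kept with a warning.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if frames is None:
        frames = np.arange(n)
    frames = np.asarray(frames, dtype=np.int64)
    order = np.argsort(frames, kind="stable")
    frames = frames[order]
    pts = pts[order]
    if len(frames) and np.any(np.diff(frames) == 0):
        # contamination can put two records in one frame; keep the one
        # radially closest to the fitted circle
        resid = np.abs(
            np.hypot(pts[:, 0] - circle.center[0], pts[:, 1] - circle.center[1])
            - circle.radius
        )
        best = pd.Series(resid).groupby(frames).idxmin().to_numpy()
        frames, pts = frames[best], pts[best]
    n = len(pts)
    theta = np.arctan2(pts[:, 1] - circle.center[1], pts[:, 0] - circle.center[0])

    gaps = np.diff(frames)
    breaks = np.nonzero(gaps > max_gap)[0]
    if len(breaks):
        warnings.warn(
            f"{len(breaks)} gap(s) longer than {max_gap} frames; keeping the "
            "longest contiguous segment",
            stacklevel=2,
        )
        bounds = np.concatenate([[0], breaks + 1, [n]])
        seg_lengths = np.diff(bounds)
        k = int(np.argmax(seg_lengths))
        sl = slice(bounds[k], bounds[k + 1])
        frames, theta = frames[sl], theta[sl]

    incr = _wrap_increments(np.diff(theta))
    cum = np.concatenate([[0.0], np.cumsum(incr)])
    times = frames / frame_rate
    return AngularTrajectory(times=times, cum_angle=cum, frames=frames)


def compute_msd(
    traj: AngularTrajectory,
    max_lag_fraction: float = 0.25,
    lag_stride: int = 1,
) -> MSDCurve:
    """Mean-square angular displacement over all overlapping pairs.

    MSD(tau_k) averages (theta_{i+k} - theta_i)^2 over every ordered pair
    of observations separated by exactly k frames, for integer frame lags
    k (in steps of ``lag_stride``) up to max_lag_fraction of the
    trajectory duration. Missing frames simply contribute no pairs.
    """
    n = len(traj.cum_angle)
    if n < 10:
        raise ValueError("trajectory too short for MSD (need >= 10 points)")
    f0 = traj.frames - traj.frames[0]
    span = int(f0[-1])
    max_k = max(1, int(math.floor(max_lag_fraction * span)))
    # dense frame-indexed array with NaN holes for missing frames
    dense = np.full(span + 1, np.nan)
    dense[f0] = traj.cum_angle
    dt = traj.duration / span  # seconds per frame
    ks = np.arange(lag_stride, max_k + 1, lag_stride, dtype=int)
    lags, msd, counts = [], [], []
    for k in ks:
        diff = dense[k:] - dense[:-k]
        good = ~np.isnan(diff)
        m = int(np.count_nonzero(good))
        if m == 0:
            continue
        lags.append(k * dt)
        msd.append(float(np.mean(diff[good] ** 2)))
        counts.append(m)
    if not lags:
        raise ValueError("no valid lag pairs")
    return MSDCurve(
        lags=np.asarray(lags), msd=np.asarray(msd), counts=np.asarray(counts)
    )


def _nnls_quadratic_linear(A: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least squares with the first two coefficients constrained >= 0
    (any further columns free), solved exactly by active-set enumeration:
    with two bound constraints the best solution is the lowest-residual
    feasible candidate among the four sign patterns."""
    ncol = A.shape[1]

    def sub_solve(fixed: tuple[int, ...]) -> np.ndarray:
        free = [j for j in range(ncol) if j not in fixed]
        x = np.zeros(ncol)
        if free:
            x[free] = np.linalg.lstsq(A[:, free], y, rcond=None)[0]
        return x

    best, best_rss = None, np.inf
    for fixed in ((), (0,), (1,), (0, 1)):
        x = sub_solve(fixed)
        if x[0] < 0 or x[1] < 0:
            continue
        rss = float(np.sum((A @ x - y) ** 2))
        if rss < best_rss:
            best, best_rss = x, rss
    assert best is not None  # (0, 1) pattern is always feasible
    return best


def fit_msd(
    msd: MSDCurve,
    net_displacement: float,
    include_offset: bool = True,
    weighted: bool = True,
) -> MSDFit:
    """Fit MSD(t) = omega_d^2 t^2 + 2 D_r t (+ optional constant offset).

    Least squares in (a, b) = (omega_d^2, 2 D_r) constrained to a, b >= 0;
    the sign of omega_d is taken from the net cumulative displacement
    since the MSD itself is blind to direction.

    ``weighted`` applies inverse-variance weights using the first-order
    variance of an overlapping-pair MSD estimator,
    var[MSD(tau_k)] ~ MSD(tau_k)^2 * 2k / n_k: without down-weighting,
    the large random error of the long-lag points swamps the linear
    (diffusive) term. ``include_offset`` adds a free constant absorbing
    the static localization-noise floor 2*(sigma/R)^2; without it that
    floor is misattributed to D_r. Both default on; on exact model data
    the fit is exact either way.
    """
    if len(msd.lags) < 3:
        raise ValueError("need at least 3 lag points")
    t = msd.lags
    y = msd.msd
    if weighted:
        # if the curve lies exactly in the model span, weights are
        # irrelevant; keep the well-conditioned unweighted solution
        A0 = np.column_stack([t**2, t, np.ones_like(t)] if include_offset else [t**2, t])
        sol0 = np.linalg.lstsq(A0, y, rcond=None)[0]
        scale = max(float(np.max(np.abs(y))), 1.0)
        if np.max(np.abs(A0 @ sol0 - y)) <= 1e-12 * scale:
            weighted = False
    if weighted:
        k = np.arange(1, len(t) + 1, dtype=float)
        sd = np.maximum(y, 1e-12) * np.sqrt(2.0 * k / np.maximum(msd.counts, 1))
        w = 1.0 / sd
    else:
        w = np.ones_like(t)
    A = np.column_stack([t**2, t])
    if include_offset:
        A = np.column_stack([A, np.ones_like(t)])
    Aw = A * w[:, None]
    yw = y * w
    sol = _nnls_quadratic_linear(Aw, yw)
    a, b = float(sol[0]), float(sol[1])
    offset = float(sol[2]) if include_offset else None
    rss = float(np.sum((A @ sol - y) ** 2))
    sign = 1.0 if net_displacement >= 0 else -1.0
    return MSDFit(
        omega_d=float(sign * math.sqrt(a)) if a > 0 else 0.0,
        D_r=b / 2.0,
        rss=rss,
        offset=offset,
    )


# ---------------------------------------------------------------------------
# torque


def rotational_drag_coefficient(params: TorqueParams) -> float:
    """Tirado–García de la Torre rotational drag of a rod about its
    perpendicular mid-axis, in pN nm s.

    xi_r = pi * eta * L^3 / [3 (ln p - 0.662 + 0.917/p - 0.050/p^2)],
    p = L/d. Input viscosity in Pa s and lengths in nm.
    """
    p = params.L / params.d
    if p <= 1:
        raise ValueError("aspect ratio L/d must exceed 1")
    end = math.log(p) - 0.662 + 0.917 / p - 0.050 / p**2
    if end <= 0:
        raise ValueError("aspect ratio too small for the slender-rod formula")
    L_m = params.L * 1e-9
    xi_si = math.pi * params.viscosity * L_m**3 / (3.0 * end)  # N m s
    return xi_si * 1e21  # -> pN nm s


def estimate_torque(omega_d: float, params: TorqueParams) -> float:
    """Torque (pN nm) needed to spin the crossbar at omega_d (rad/s):
    Gamma = wall_correction * xi_r * omega_d. Bulk drag by default;
    near-wall enhancement can be folded into wall_correction."""
    return params.wall_correction * rotational_drag_coefficient(params) * omega_d


# ---------------------------------------------------------------------------
# summaries and the full chain


def summarize_speeds(results: list[RotorResult]) -> pd.DataFrame:
    """Box-plot style summary of the valid rotors' signed speeds (rev/s):
    median, quartiles, 1.5*IQR whisker bounds, mean, s.e.m., n."""
    speeds = np.array([r.omega_rev for r in results if r.valid and r.omega_rev is not None])
    if speeds.size == 0:
        return pd.DataFrame(
            columns=[
                "n", "median", "q1", "q3", "whisker_low", "whisker_high",
                "mean", "sem",
            ]
        )
    q1, med, q3 = np.percentile(speeds, [25, 50, 75])
    iqr = q3 - q1
    sem = float(np.std(speeds, ddof=1) / math.sqrt(speeds.size)) if speeds.size > 1 else float("nan")
    return pd.DataFrame(
        [
            {
                "n": speeds.size,
                "median": float(med),
                "q1": float(q1),
                "q3": float(q3),
                "whisker_low": float(q1 - 1.5 * iqr),
                "whisker_high": float(q3 + 1.5 * iqr),
                "mean": float(np.mean(speeds)),
                "sem": sem,
            }
        ]
    )


def analyze_dataset(
    locs: LocalizationSet, config: AnalysisConfig | None = None
) -> list[RotorResult]:
    """Full chain: uncertainty filter -> density filter -> cluster ->
    circle fit -> annulus validity -> cumulative angle -> MSD fit ->
    torque, one RotorResult per cluster. Per-cluster failures are
    reported as invalid results; the batch never aborts."""
    cfg = config or AnalysisConfig()
    if len(locs) == 0:
        return []
    locs = filter_by_uncertainty(locs, cfg.max_uncertainty)
    locs = filter_by_density(locs, cfg.density_min_neighbors, cfg.density_radius)
    clusters = cluster_localizations(locs, cfg.cluster_eps, cfg.cluster_min_pts)
    results: list[RotorResult] = []
    for i, cl in enumerate(clusters):
        pts = cl.xy
        try:
            circle = fit_circle(pts)
        except CircleFitError as exc:
            results.append(
                RotorResult(id=i, circle=None, valid=False,
                            n_localizations=len(cl), note=f"circle fit failed: {exc}")
            )
            continue
        valid, rho_a, rho_c = annulus_validity(pts, circle, cfg.annulus_half_width)
        res = RotorResult(
            id=i, circle=circle, valid=valid,
            annulus_density=rho_a, center_density=rho_c,
            n_localizations=len(cl),
        )
        if not valid:
            res.note = "failed annulus validity test"
            results.append(res)
            continue
        try:
            traj = extract_cumulative_angle(
                pts, circle, cl.frame_rate, frames=cl.frames, max_gap=cfg.max_gap
            )
            curve = compute_msd(traj, cfg.max_lag_fraction)
            fit = fit_msd(
                curve, traj.net_displacement, cfg.include_offset, cfg.weighted_fit
            )
        except ValueError as exc:
            res.valid = False
            res.note = f"motion analysis failed: {exc}"
            results.append(res)
            continue
        res.omega_rev = fit.omega_rev
        res.D_r = fit.D_r
        res.torque = estimate_torque(fit.omega_d, cfg.torque)
        results.append(res)
    return results
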