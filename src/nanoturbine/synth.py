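"""Synthetic single-molecule localization data for rotor experiments.

Generates ThunderSTORM-style localization tables with the statistical
structure the rotation-analysis pipeline assumes: a fluorophore-labelled
tip driven around a pore axis (angular drift + rotational diffusion),
rendered with isotropic Gaussian localization noise and per-frame
detection dropout, plus freely diffusing particles as negative controls.
Every generator is deterministic given its seed and returns a full
ground-truth manifest for recovery tests.

Conventions: coordinates in nm, frames 0-based, mathematical y-up frame
(positive angular velocity = anticlockwise), which the package identifies
with the view from the cis side of the membrane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "RotorTruth",
    "AcquisitionParams",
    "LocalizationSet",
    "simulate_angle_series",
    "render_localizations",
    "simulate_diffuser",
    "generate_array_dataset",
]

#: column order of the localization table (ThunderSTORM dialect)
LOC_COLUMNS = ["frame", "x", "y", "uncertainty"]


@dataclass(frozen=True)
class RotorTruth:
    """Ground-truth parameters of one driven rotor.

    Parameters
    ----------
    omega_d:
        Signed angular drift velocity in rad/s. Positive = anticlockwise
        in the y-up frame (cis-side view).
    D_r:
        Rotational diffusion coefficient in rad^2/s.
    radius:
        Rotation radius of the labelled tip in nm (~150 nm for a 300 nm
        crossbar pivoting about its middle).
    center:
        Pore-axis position (x, y) in nm.
    theta0:
        Initial angle in rad.
    """

    omega_d: float
    D_r: float = 0.0
    radius: float = 150.0
    center: tuple[float, float] = (0.0, 0.0)
    theta0: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.omega_d):
            raise ValueError("omega_d must be finite")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.D_r < 0:
            raise ValueError("D_r must be non-negative")


@dataclass(frozen=True)
class AcquisitionParams:
    """Camera/localization acquisition model.

    ``uncertainty_model`` gives the (mean, sd) in nm of the truncated
    Gaussian from which each record's *reported* uncertainty is drawn;
    as in real localization software the report is independent of the
    realized positional error.
    """

    frame_rate: float = 200.0
    n_frames: int = 8000
    loc_noise_sigma: float = 15.0
    detection_prob: float = 1.0
    uncertainty_model: tuple[float, float] = (15.0, 5.0)
    uncertainty_floor: float = 1.0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if not (0.0 < self.detection_prob <= 1.0):
            raise ValueError("detection_prob must be in (0, 1]")
        if self.loc_noise_sigma < 0:
            raise ValueError("loc_noise_sigma must be non-negative")
        if self.n_frames < 1:
            raise ValueError("n_frames must be at least 1")

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate


@dataclass
class LocalizationSet:
    """Ordered per-frame sub-diffraction localizations.

    ``data`` has columns frame, x, y, uncertainty, sorted by frame;
    the acquisition frame rate rides along so downstream code can turn
    frame indices into seconds.
    """

    data: pd.DataFrame
    frame_rate: float

    def __post_init__(self) -> None:
        missing = [c for c in LOC_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"localization table missing columns: {missing}")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        self.data = self.data.loc[:, LOC_COLUMNS].reset_index(drop=True)
        if not self.data["frame"].is_monotonic_increasing:
            self.data = self.data.sort_values("frame", kind="stable").reset_index(
                drop=True
            )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def frames(self) -> np.ndarray:
        return self.data["frame"].to_numpy(dtype=np.int64)

    @property
    def xy(self) -> np.ndarray:
        return self.data[["x", "y"]].to_numpy(dtype=float)

    @property
    def uncertainty(self) -> np.ndarray:
        return self.data["uncertainty"].to_numpy(dtype=float)

    def subset(self, mask: np.ndarray) -> "LocalizationSet":
        return LocalizationSet(self.data.loc[mask].reset_index(drop=True), self.frame_rate)

    @staticmethod
    def empty(frame_rate: float = 200.0) -> "LocalizationSet":
        df = pd.DataFrame({c: pd.Series(dtype=float) for c in LOC_COLUMNS})
        return LocalizationSet(df, frame_rate)


def simulate_angle_series(
    truth: RotorTruth, acq: AcquisitionParams, seed: int
) -> np.ndarray:
    """Euler–Maruyama angular trajectory: drift + rotational diffusion.

    theta_{k+1} = theta_k + omega_d*dt + sqrt(2*D_r*dt)*N(0,1), with
    dt = 1/frame_rate. Returns one angle per frame (length n_frames).
    """
    if acq.n_frames < 2:
        raise ValueError("need at least 2 frames")
    rng = np.random.default_rng(seed)
    dt = acq.dt
    increments = truth.omega_d * dt + np.sqrt(2.0 * truth.D_r * dt) * rng.standard_normal(
        acq.n_frames - 1
    )
    theta = np.empty(acq.n_frames)
    theta[0] = truth.theta0
    theta[1:] = truth.theta0 + np.cumsum(increments)
    return theta


def _draw_uncertainties(n: int, acq: AcquisitionParams, rng: np.random.Generator) -> np.ndarray:
    mean, sd = acq.uncertainty_model
    u = mean + sd * rng.standard_normal(n)
    return np.maximum(u, acq.uncertainty_floor)


def render_localizations(
    angles: np.ndarray, truth: RotorTruth, acq: AcquisitionParams, seed: int
) -> LocalizationSet:
    """Turn an angle series into a localization table.

    Each retained frame yields one record at
    center + radius*(cos theta, sin theta) + N(0, loc_noise_sigma) per axis;
    frames are dropped independently with probability 1 - detection_prob and
    the reported uncertainty is drawn from the acquisition's uncertainty model.
    """
    angles = np.asarray(angles, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(angles)
    detected = (
        np.ones(n, dtype=bool)
        if acq.detection_prob >= 1.0
        else rng.random(n) < acq.detection_prob
    )
    frames = np.nonzero(detected)[0]
    th = angles[detected]
    cx, cy = truth.center
    x = cx + truth.radius * np.cos(th)
    y = cy + truth.radius * np.sin(th)
    if acq.loc_noise_sigma > 0:
        x = x + acq.loc_noise_sigma * rng.standard_normal(len(frames))
        y = y + acq.loc_noise_sigma * rng.standard_normal(len(frames))
    unc = _draw_uncertainties(len(frames), acq, rng)
    df = pd.DataFrame({"frame": frames, "x": x, "y": y, "uncertainty": unc})
    return LocalizationSet(df, acq.frame_rate)


def simulate_rotor(
    truth: RotorTruth, acq: AcquisitionParams, seed: int
) -> LocalizationSet:
    """Convenience: simulate_angle_series + render_localizations with
    independent sub-streams derived from one seed."""
    ss = np.random.SeedSequence(seed)
    s_angle, s_render = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2)]
    angles = simulate_angle_series(truth, acq, s_angle)
    return render_localizations(angles, truth, acq, s_render)


def simulate_diffuser(
    D_t: float,
    start: tuple[float, float],
    acq: AcquisitionParams,
    seed: int,
) -> LocalizationSet:
    """2D Brownian walk sampled at frame times (negative control).

    D_t in nm^2/s; per-step displacement sd = sqrt(2*D_t*dt) per axis.
    Uses the same localization-noise / detection / uncertainty model as
    the rotor renderer.
    """
    if D_t < 0:
        raise ValueError("D_t must be non-negative")
    rng = np.random.default_rng(seed)
    n = acq.n_frames
    dt = acq.dt
    step_sd = np.sqrt(2.0 * D_t * dt)
    steps = step_sd * rng.standard_normal((n - 1, 2)) if n > 1 else np.empty((0, 2))
    pos = np.vstack([np.array(start, dtype=float), np.array(start) + np.cumsum(steps, axis=0)])
    detected = (
        np.ones(n, dtype=bool)
        if acq.detection_prob >= 1.0
        else rng.random(n) < acq.detection_prob
    )
    frames = np.nonzero(detected)[0]
    xy = pos[detected]
    if acq.loc_noise_sigma > 0:
        xy = xy + acq.loc_noise_sigma * rng.standard_normal(xy.shape)
    unc = _draw_uncertainties(len(frames), acq, rng)
    df = pd.DataFrame(
        {"frame": frames, "x": xy[:, 0], "y": xy[:, 1], "uncertainty": unc}
    )
    return LocalizationSet(df, acq.frame_rate)


@dataclass
class EmitterTruth:
    """One entry of the ground-truth manifest of an array dataset."""

    emitter_id: int
    kind: str  # "rotor" | "diffuser"
    params: dict = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


def generate_array_dataset(
    rotors: list[RotorTruth],
    diffusers: list[tuple[float, tuple[float, float]]],
    acq: AcquisitionParams,
    seed: int,
) -> tuple[LocalizationSet, list[EmitterTruth]]:
    """Merge several emitters into one field-of-view localization table.

    ``diffusers`` is a list of (D_t, start) pairs. Rotor centers closer
    than 4*radius are flagged as overlapping in the manifest (clusters
    may merge downstream) with a warning. Returns the frame-sorted merged
    table and the manifest mapping each emitter to its truth parameters.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(rotors) + len(diffusers))
    tables: list[pd.DataFrame] = []
    manifest: list[EmitterTruth] = []

    overlap: set[int] = set()
    for i, a in enumerate(rotors):
        for j in range(i + 1, len(rotors)):
            b = rotors[j]
            min_sep = 4.0 * max(a.radius, b.radius)
            d = np.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
            if d <= min_sep:
                overlap.update((i, j))
    if overlap:
        warnings.warn(
            f"rotor centers {sorted(overlap)} are separated by <= 4*radius; "
            "clusters may overlap",
            stacklevel=2,
        )

    eid = 0
    for i, truth in enumerate(rotors):
        sub = int(children[eid].generate_state(1)[0] % (2**31))
        locs = simulate_rotor(truth, acq, sub)
        tables.append(locs.data)
        flags = ["overlap"] if i in overlap else []
        manifest.append(
            EmitterTruth(
                emitter_id=eid,
                kind="rotor",
                params={
                    "omega_d": truth.omega_d,
                    "D_r": truth.D_r,
                    "radius": truth.radius,
                    "center_x": truth.center[0],
                    "center_y": truth.center[1],
                    "theta0": truth.theta0,
                },
                flags=flags,
            )
        )
        eid += 1
    for D_t, start in diffusers:
        sub = int(children[eid].generate_state(1)[0] % (2**31))
        locs = simulate_diffuser(D_t, start, acq, sub)
        tables.append(locs.data)
        manifest.append(
            EmitterTruth(
                emitter_id=eid,
                kind="diffuser",
                params={"D_t": D_t, "start_x": start[0], "start_y": start[1]},
            )
        )
        eid += 1

    if tables:
        merged = pd.concat(tables, ignore_index=True)
        merged = merged.sort_values("frame", kind="stable").reset_index(drop=True)
    else:
        merged = LocalizationSet.empty(acq.frame_rate).data
    return LocalizationSet(merged, acq.frame_rate), manifest
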