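"""Voxel-binned post-processing of particle trajectories.

Reproduces the standard MD post-processing recipe for solvent and ion
trajectories around a nanostructure: bin the system into small voxels
(~1 Angstrom by default), count per-voxel concentration, estimate the
flux with a centred finite-difference velocity, form the net charge
density as c_Na - c_Cl, and multiply by the applied field to obtain a
3D solvent-force map.

Trajectories enter as a flat table (id, frame, x, y, z, species, charge);
conversion from MD trajectory formats is upstream and out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VoxelGrid",
    "GridSpec",
    "bin_concentration",
    "bin_flux",
    "charge_density",
    "solvent_force_map",
    "WATER_NUMBER_DENSITY",
]

#: uniform water-oxygen number density (nm^-3) used when converting
#: per-voxel solvent forces to per-molecule forces
WATER_NUMBER_DENSITY = 33.0

TRACK_COLUMNS = ["id", "frame", "x", "y", "z"]


@dataclass(frozen=True)
class GridSpec:
    """Regular grid: origin (nm), isotropic or per-axis spacing (nm,
    default 0.1 nm = 1 Angstrom), voxel counts, per-axis periodic flags."""

    origin: tuple[float, float, float]
    dims: tuple[int, int, int]
    spacing: float | tuple[float, float, float] = 0.1
    periodic: tuple[bool, bool, bool] = (False, False, False)

    def __post_init__(self) -> None:
        sp = np.broadcast_to(np.asarray(self.spacing, dtype=float), (3,))
        if np.any(sp <= 0):
            raise ValueError("spacing must be positive")
        if any(d < 1 for d in self.dims):
            raise ValueError("dims must be >= 1 along every axis")

    @property
    def spacing_vec(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.spacing, dtype=float), (3,)).copy()

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing_vec))

    @property
    def extent(self) -> np.ndarray:
        return np.asarray(self.dims) * self.spacing_vec

    def voxel_indices(self, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map positions (n, 3) to integer voxel indices (n, 3).

        Periodic axes wrap into the box; on non-periodic axes, particles
        outside the grid get an in-bounds=False flag (overflow).
        """
        pos = np.asarray(positions, dtype=float) - np.asarray(self.origin)
        sp = self.spacing_vec
        ext = self.extent
        for ax in range(3):
            if self.periodic[ax]:
                pos[:, ax] %= ext[ax]
        idx = np.floor(pos / sp).astype(np.int64)
        dims = np.asarray(self.dims)
        in_bounds = np.all((idx >= 0) & (idx < dims), axis=1)
        return idx, in_bounds


@dataclass
class VoxelGrid:
    """Regular 3D grid of scalar (dims) or vector (dims + (3,)) values."""

    spec: GridSpec
    values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shape = tuple(self.spec.dims)
        if self.values.shape not in (shape, shape + (3,)):
            raise ValueError(
                f"values shape {self.values.shape} does not match dims {shape}"
            )

    @property
    def is_vector(self) -> bool:
        return self.values.ndim == 4

    def congruent_with(self, other: "VoxelGrid") -> bool:
        return (
            tuple(self.spec.dims) == tuple(other.spec.dims)
            and np.allclose(self.spec.origin, other.spec.origin)
            and np.allclose(self.spec.spacing_vec, other.spec.spacing_vec)
        )


def _validate_tracks(tracks: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRACK_COLUMNS if c not in tracks.columns]
    if missing:
        raise ValueError(f"track table missing columns: {missing}")
    if len(tracks) == 0:
        raise ValueError("track table is empty")
    pos = tracks[["x", "y", "z"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(pos)):
        raise ValueError("non-finite positions in track table")
    return tracks


def bin_concentration(
    tracks: pd.DataFrame, spec: GridSpec, species: str | None = None
) -> VoxelGrid:
    """Per-voxel number density averaged over frames.

    density = (occupancy count) / (voxel volume * n_frames), where
    n_frames is the number of distinct frames in the table. Particles
    outside a non-periodic grid are tallied in an overflow count (with a
    warning) so that sum(density)*volume + overflow/n_frames equals the
    mean particle count per frame exactly.
    """
    tracks = _validate_tracks(tracks)
    if species is not None:
        tracks = tracks[tracks["species"] == species]
        if len(tracks) == 0:
            raise ValueError(f"no rows with species {species!r}")
    n_frames = int(tracks["frame"].nunique())
    pos = tracks[["x", "y", "z"]].to_numpy(dtype=float)
    idx, in_bounds = spec.voxel_indices(pos)
    overflow = int(np.count_nonzero(~in_bounds))
    if overflow:
        warnings.warn(
            f"{overflow} localizations fell outside the (non-periodic) grid; "
            "counted in the overflow bin",
            stacklevel=2,
        )
    counts = np.zeros(spec.dims, dtype=float)
    np.add.at(counts, tuple(idx[in_bounds].T), 1.0)
    density = counts / (spec.voxel_volume * n_frames)
    return VoxelGrid(
        spec=spec,
        values=density,
        metadata={
            "kind": "concentration",
            "species": species,
            "n_frames": n_frames,
            "overflow_count": overflow,
        },
    )


def bin_flux(
    tracks: pd.DataFrame, spec: GridSpec, dt: float = 1.0, species: str | None = None
) -> VoxelGrid:
    """Per-voxel flux from centred finite-difference velocities.

    For each particle, v_k = (r_{k+1} - r_{k-1}) / (2 dt) on contiguous
    frame triplets; the velocity is assigned to the voxel containing the
    central position r_k, and the voxel flux is the mean assigned
    velocity times the local density of the central samples (count /
    voxel volume / number of central frames). Track endpoints carry no
    centred difference and are skipped.
    """
    tracks = _validate_tracks(tracks)
    if species is not None:
        tracks = tracks[tracks["species"] == species]
        if len(tracks) == 0:
            raise ValueError(f"no rows with species {species!r}")
    if dt <= 0:
        raise ValueError("dt must be positive")

    group_cols = ["id", "species"] if "species" in tracks.columns else ["id"]
    tracks = tracks.sort_values(group_cols + ["frame"], kind="stable")
    centers: list[np.ndarray] = []
    velocities: list[np.ndarray] = []
    for _pid, g in tracks.groupby(group_cols, sort=False):
        if len(g) < 3:
            continue
        frames = g["frame"].to_numpy(dtype=np.int64)
        pos = g[["x", "y", "z"]].to_numpy(dtype=float)
        contiguous = (frames[2:] - frames[1:-1] == 1) & (frames[1:-1] - frames[:-2] == 1)
        if not contiguous.any():
            continue
        v = (pos[2:] - pos[:-2]) / (2.0 * dt)
        centers.append(pos[1:-1][contiguous])
        velocities.append(v[contiguous])
    if not centers:
        raise ValueError("no track has >= 3 contiguous frames; cannot form fluxes")
    cpos = np.concatenate(centers)
    cvel = np.concatenate(velocities)
    n_center_frames = int(tracks["frame"].nunique()) - 2
    n_center_frames = max(n_center_frames, 1)

    idx, in_bounds = spec.voxel_indices(cpos)
    if np.count_nonzero(~in_bounds):
        warnings.warn(
            f"{int(np.count_nonzero(~in_bounds))} velocity samples outside the grid; dropped",
            stacklevel=2,
        )
    idx = idx[in_bounds]
    cvel = cvel[in_bounds]
    counts = np.zeros(spec.dims, dtype=float)
    vsum = np.zeros(tuple(spec.dims) + (3,), dtype=float)
    np.add.at(counts, tuple(idx.T), 1.0)
    np.add.at(vsum, tuple(idx.T), cvel)
    # mean velocity * density  ==  velocity sum / (volume * frames)
    flux = vsum / (spec.voxel_volume * n_center_frames)
    return VoxelGrid(
        spec=spec,
        values=flux,
        metadata={
            "kind": "flux",
            "species": species,
            "n_frames": n_center_frames,
            "n_samples": int(counts.sum()),
        },
    )


def charge_density(conc_Na: VoxelGrid, conc_Cl: VoxelGrid) -> VoxelGrid:
    """Net local charge density (elementary charges / volume):
    voxelwise c_Na - c_Cl on congruent grids."""
    if conc_Na.is_vector or conc_Cl.is_vector:
        raise ValueError("charge_density expects scalar concentration grids")
    if not conc_Na.congruent_with(conc_Cl):
        raise ValueError("concentration grids are not congruent")
    return VoxelGrid(
        spec=conc_Na.spec,
        values=conc_Na.values - conc_Cl.values,
        metadata={"kind": "charge_density"},
    )


def solvent_force_map(
    charge: VoxelGrid,
    E: tuple[float, float, float],
    per_water_molecule: bool = False,
    water_number_density: float = WATER_NUMBER_DENSITY,
) -> VoxelGrid:
    """Force map: per-voxel force = net charge in voxel x field.

    charge (e / volume) * E * voxel_volume gives the total electric force
    on the fluid in each voxel (units: e * field units). With
    ``per_water_molecule`` the map is divided by the number of water
    oxygens per voxel under the uniform-density convention (33 nm^-3),
    giving the force to apply to each water molecule.
    """
    if charge.is_vector:
        raise ValueError("solvent_force_map expects a scalar charge grid")
    Evec = np.asarray(E, dtype=float)
    if Evec.shape != (3,) or not np.all(np.isfinite(Evec)):
        raise ValueError("E must be a finite 3-vector")
    vol = charge.spec.voxel_volume
    force = charge.values[..., None] * Evec[None, None, None, :] * vol
    meta = {
        "kind": "force",
        "E": [float(x) for x in Evec],
        "per_water_molecule": bool(per_water_molecule),
    }
    if per_water_molecule:
        force = force / (water_number_density * vol)
        meta["water_number_density"] = water_number_density
    return VoxelGrid(spec=charge.spec, values=force, metadata=meta)
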