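"""Readers/writers for the package's external formats.

Localization tables use the ThunderSTORM CSV dialect
(``frame,"x [nm]","y [nm]","uncertainty [nm]"``); frames are 0-based by
default with a dialect flag for 1-based exports. Truth manifests are
flat key-value text, one emitter per block. Voxel grids round-trip via a
self-describing .npz container plus an optional CSV of nonzero voxels.
"""

from __future__ import annotations

import io as _io
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .flowvox import GridSpec, VoxelGrid
from .synth import LOC_COLUMNS, EmitterTruth, LocalizationSet
from .track import RotorResult

__all__ = [
    "write_localizations_csv",
    "read_localizations_csv",
    "write_manifest",
    "read_manifest",
    "write_results_csv",
    "write_voxel_grid",
    "read_voxel_grid",
    "voxel_grid_to_csv",
    "load_config",
    "setup_run_log",
]

THUNDERSTORM_HEADER = ["frame", "x [nm]", "y [nm]", "uncertainty [nm]"]


def write_localizations_csv(
    locs: LocalizationSet, path: str | Path, one_based_frames: bool = False
) -> None:
    df = locs.data.copy()
    if one_based_frames:
        df["frame"] = df["frame"] + 1
    with open(path, "w") as fh:
        # ThunderSTORM quotes the unit-bearing column names
        fh.write('frame,"x [nm]","y [nm]","uncertainty [nm]"\n')
        df.to_csv(fh, index=False, header=False)


def read_localizations_csv(
    path: str | Path, frame_rate: float = 200.0, one_based_frames: bool = False
) -> LocalizationSet:
    df = pd.read_csv(path)
    rename = {}
    for col in df.columns:
        base = col.split("[")[0].strip().strip('"').lower()
        if base in ("frame", "x", "y", "uncertainty"):
            rename[col] = base
    df = df.rename(columns=rename)
    missing = [c for c in LOC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing localization columns {missing}")
    df = df.loc[:, LOC_COLUMNS]
    bad = ~np.isfinite(df.to_numpy(dtype=float)).all(axis=1)
    n_bad = int(bad.sum())
    if n_bad:
        if n_bad > 0.10 * len(df):
            raise ValueError(
                f"{path}: {n_bad}/{len(df)} malformed rows (>10%); aborting"
            )
        logging.getLogger("nanoturbine").warning(
            "%s: skipped %d malformed rows", path, n_bad
        )
        df = df.loc[~bad]
    if one_based_frames:
        df["frame"] = df["frame"] - 1
    df["frame"] = df["frame"].astype(np.int64)
    return LocalizationSet(df.reset_index(drop=True), frame_rate)


def write_manifest(manifest: list[EmitterTruth], path: str | Path) -> None:
    """Flat key-value text file, one emitter per blank-line-separated block."""
    with open(path, "w") as fh:
        for em in manifest:
            fh.write(f"emitter_id = {em.emitter_id}\n")
            fh.write(f"kind = {em.kind}\n")
            for k, v in em.params.items():
                fh.write(f"{k} = {v!r}\n")
            if em.flags:
                fh.write(f"flags = {','.join(em.flags)}\n")
            fh.write("\n")


def read_manifest(path: str | Path) -> list[EmitterTruth]:
    manifest: list[EmitterTruth] = []
    block: dict[str, str] = {}

    def flush() -> None:
        if not block:
            return
        flags = block.pop("flags", "")
        eid = int(block.pop("emitter_id"))
        kind = block.pop("kind")
        params = {k: float(v) for k, v in block.items()}
        manifest.append(
            EmitterTruth(
                emitter_id=eid,
                kind=kind,
                params=params,
                flags=[f for f in flags.split(",") if f],
            )
        )
        block.clear()

    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            flush()
            continue
        key, _, val = line.partition("=")
        block[key.strip()] = val.strip()
    flush()
    return manifest


def write_results_csv(results: list[RotorResult], path: str | Path) -> None:
    rows = []
    for r in results:
        rows.append(
            {
                "id": r.id,
                "center_x": r.circle.center[0] if r.circle else np.nan,
                "center_y": r.circle.center[1] if r.circle else np.nan,
                "radius_nm": r.circle.radius if r.circle else np.nan,
                "valid": r.valid,
                "omega_rev_s": r.omega_rev if r.omega_rev is not None else np.nan,
                "D_r": r.D_r if r.D_r is not None else np.nan,
                "torque_pNnm": r.torque if r.torque is not None else np.nan,
                "n_localizations": r.n_localizations,
                "note": r.note,
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "id", "center_x", "center_y", "radius_nm", "valid",
            "omega_rev_s", "D_r", "torque_pNnm", "n_localizations", "note",
        ],
    ).to_csv(path, index=False)


def write_voxel_grid(grid: VoxelGrid, path: str | Path) -> None:
    """Self-describing container: origin/spacing/dims/periodic header plus
    the value array (numpy .npz)."""
    np.savez_compressed(
        path,
        origin=np.asarray(grid.spec.origin, dtype=float),
        spacing=grid.spec.spacing_vec,
        dims=np.asarray(grid.spec.dims, dtype=np.int64),
        periodic=np.asarray(grid.spec.periodic, dtype=bool),
        values=grid.values,
        metadata=np.frombuffer(
            yaml.safe_dump(grid.metadata).encode(), dtype=np.uint8
        ),
    )


def read_voxel_grid(path: str | Path) -> VoxelGrid:
    with np.load(path) as z:
        spec = GridSpec(
            origin=tuple(z["origin"]),
            dims=tuple(int(d) for d in z["dims"]),
            spacing=tuple(z["spacing"]),
            periodic=tuple(bool(b) for b in z["periodic"]),
        )
        meta = yaml.safe_load(_io.BytesIO(z["metadata"].tobytes())) or {}
        return VoxelGrid(spec=spec, values=z["values"], metadata=meta)


def voxel_grid_to_csv(grid: VoxelGrid, path: str | Path, threshold: float = 0.0) -> None:
    """CSV export of voxels whose value magnitude exceeds ``threshold``."""
    vals = grid.values
    mag = np.linalg.norm(vals, axis=-1) if grid.is_vector else np.abs(vals)
    idx = np.argwhere(mag > threshold)
    sp = grid.spec.spacing_vec
    origin = np.asarray(grid.spec.origin)
    centers = origin + (idx + 0.5) * sp
    cols = {
        "ix": idx[:, 0], "iy": idx[:, 1], "iz": idx[:, 2],
        "x": centers[:, 0], "y": centers[:, 1], "z": centers[:, 2],
    }
    if grid.is_vector:
        sel = vals[idx[:, 0], idx[:, 1], idx[:, 2]]
        cols.update(vx=sel[:, 0], vy=sel[:, 1], vz=sel[:, 2])
    else:
        cols["value"] = vals[idx[:, 0], idx[:, 1], idx[:, 2]]
    pd.DataFrame(cols).to_csv(path, index=False)


def load_config(path: str | Path | None) -> dict:
    """YAML (or flat ``key = value``) configuration file -> dict."""
    if path is None:
        return {}
    text = Path(path).read_text()
    try:
        cfg = yaml.safe_load(text)
        if isinstance(cfg, dict):
            return cfg
    except yaml.YAMLError:
        pass
    cfg = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition("=")
        cfg[key.strip()] = yaml.safe_load(val.strip())
    return cfg


def setup_run_log(path: str | Path, config: dict) -> logging.Logger:
    """Plain-text run log; the fully resolved configuration is echoed so a
    rerun with the same file + seed is reproducible."""
    from . import __version__

    logger = logging.getLogger("nanoturbine")
    logger.setLevel(logging.INFO)
    for h in list(logger.handlers):
        logger.removeHandler(h)
    handler = logging.FileHandler(path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.info("nanoturbine version %s", __version__)
    for key in sorted(config):
        logger.info("config %s = %r", key, config[key])
    return logger
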