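"""File formats: trajectory CSV, labeled databases, and model archives.

Trajectories travel as delimited text with a ``t,x,y,d`` header.  Labeled
databases are a directory of trajectory CSVs plus a ``manifest.csv``
(columns ``file,label,disability,writer,alphabet``).  A learned model is a
single zip archive of ``.npy`` arrays plus a JSON manifest, written
deterministically so that save → load → save is byte-identical.
"""

from __future__ import annotations

import io as _io
import json
import zipfile
from pathlib import Path

import numpy as np
import pandas as pd

from .domains import DomainSpec
from .model import ModelConfig, ModelParameters
from .simulate import LabeledTrajectory
from .trajectory import RawTrajectory

__all__ = [
    "TrajectoryParseError",
    "ModelFileError",
    "read_trajectory",
    "write_trajectory",
    "read_database",
    "write_database",
    "save_model",
    "load_model",
    "MODEL_SCHEMA_VERSION",
]

MODEL_SCHEMA_VERSION = 1


class TrajectoryParseError(ValueError):
    """A trajectory file is malformed; the message names the offending row."""


class ModelFileError(ValueError):
    """A model archive is unreadable, truncated, or of an unknown schema."""


def read_trajectory(path, y_down: bool = False) -> tuple[RawTrajectory, dict]:
    """Read a ``t,x,y,d`` CSV; returns the trajectory and any label metadata.

    ``y_down=True`` converts screen coordinates (y grows downward) to the
    mathematical convention (y up) used throughout the package, by negating
    y.  Extra constant columns (``label``, ``disability``, ``writer``,
    ``alphabet``) are returned in the metadata dict.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise TrajectoryParseError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = {"t", "x", "y", "d"} - set(df.columns)
    if missing:
        raise TrajectoryParseError(f"{path}: missing columns {sorted(missing)}")
    for col in ("t", "x", "y", "d"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.index[vals.isna() & df[col].notna()]
        if len(bad) or vals.isna().any():
            row = int((vals.index[vals.isna()])[0])
            raise TrajectoryParseError(
                f"{path}: non-numeric value in column {col!r} at data row {row + 1} "
                f"(file line {row + 2})"
            )
        df[col] = vals
    t = df["t"].to_numpy()
    drops = np.flatnonzero(np.diff(t) <= 0)
    if drops.size:
        row = int(drops[0]) + 1
        raise TrajectoryParseError(
            f"{path}: non-monotone t at data row {row + 1} (file line {row + 2})"
        )
    y = -df["y"].to_numpy() if y_down else df["y"].to_numpy()
    traj = RawTrajectory(t=t, x=df["x"].to_numpy(), y=y, d=df["d"].to_numpy())
    meta = {}
    for col in ("label", "disability", "writer", "alphabet"):
        if col in df.columns:
            meta[col] = df[col].iloc[0]
    return traj, meta


def write_trajectory(traj: RawTrajectory, path, meta: dict | None = None) -> None:
    """Write a trajectory CSV; a read round-trip reproduces samples exactly."""
    df = pd.DataFrame({"t": traj.t, "x": traj.x, "y": traj.y, "d": traj.d})
    for key, val in (meta or {}).items():
        df[key] = val
    df.to_csv(path, index=False, float_format="%.17g")


def write_database(database, directory, seed: int | None = None, config: dict | None = None) -> None:
    """Write labeled trajectories as CSVs plus a manifest (and config snapshot)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, item in enumerate(database):
        fname = f"traj_{i:04d}_{item.label}_h{item.level}.csv"
        write_trajectory(item.trajectory, directory / fname)
        rows.append(
            {
                "file": fname,
                "label": item.label,
                "disability": item.level,
                "writer": item.writer,
                "alphabet": item.alphabet,
            }
        )
    pd.DataFrame(rows).to_csv(directory / "manifest.csv", index=False)
    if seed is not None or config is not None:
        snapshot = {"seed": seed, "config": config or {}}
        (directory / "generation.json").write_text(json.dumps(snapshot, indent=2))


def read_database(directory) -> list[LabeledTrajectory]:
    """Read a database directory written by :func:`write_database`."""
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    out = []
    for _, row in manifest.iterrows():
        traj, _ = read_trajectory(directory / row["file"])
        out.append(
            LabeledTrajectory(
                traj,
                label=str(row["label"]),
                level=int(row["disability"]),
                writer=str(row.get("writer", "")),
                alphabet=int(row["alphabet"]),
            )
        )
    return out


# -- model archives ---------------------------------------------------------


def _config_manifest(config: ModelConfig) -> dict:
    return {
        "symbols": list(config.symbols),
        "levels": list(config.levels),
        "n_via_points": config.n_via_points,
        "alpha": config.alpha,
        "pos_kernel_order": config.pos_kernel_order,
        "pos_kernel_var": config.pos_kernel_var,
        "vel_kernel_order": config.vel_kernel_order,
        "vel_kernel_var": config.vel_kernel_var,
        "velocity_scale": config.velocity_scale,
        "position_scale": config.position_scale,
        "size_scale": config.size_scale,
        "a_scale": config.a_scale,
        "domains": {
            key: {"name": d.name, "has_well": d.has_well, "step": d.step}
            for key, d in config.domains.items()
        },
    }


def save_model(model: ModelParameters, path) -> None:
    """Write a model as a deterministic zip archive of arrays + manifest.

    Arrays are stored uncompressed in sorted key order with a fixed
    timestamp, so identical models produce byte-identical files.
    """
    manifest = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "config": _config_manifest(model.config),
        "counts_keys": sorted(model.counts),
        "tables_keys": sorted(model.tables),
        "aux_keys": sorted(model.aux_stats),
    }
    arrays: dict[str, np.ndarray] = {}
    for key in sorted(model.counts):
        arrays[f"counts/{key}"] = model.counts[key]
    for key in sorted(model.tables):
        arrays[f"tables/{key}"] = model.tables[key]
    for key in sorted(model.aux_stats):
        arrays[f"aux/{key}"] = model.aux_stats[key]
    for key in sorted(model.config.domains):
        arrays[f"domains/{key}"] = model.config.domains[key].values
    arrays["exemplar_counts"] = model.exemplar_counts

    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_STORED) as zf:
        info = zipfile.ZipInfo("manifest.json", date_time=(1980, 1, 1, 0, 0, 0))
        zf.writestr(info, json.dumps(manifest, indent=2, sort_keys=True))
        for name in sorted(arrays):
            buf = _io.BytesIO()
            np.lib.format.write_array(buf, np.ascontiguousarray(arrays[name]))
            info = zipfile.ZipInfo(f"{name}.npy", date_time=(1980, 1, 1, 0, 0, 0))
            zf.writestr(info, buf.getvalue())


def load_model(path) -> ModelParameters:
    """Read a model archive; tables round-trip bit-exactly."""
    try:
        with zipfile.ZipFile(path) as zf:
            manifest = json.loads(zf.read("manifest.json"))
            version = manifest.get("schema_version")
            if version != MODEL_SCHEMA_VERSION:
                raise ModelFileError(
                    f"{path}: schema version {version!r} != {MODEL_SCHEMA_VERSION}"
                )

            def arr(name):
                return np.lib.format.read_array(_io.BytesIO(zf.read(f"{name}.npy")))

            cfg_m = manifest["config"]
            domains = {
                key: DomainSpec(
                    name=spec["name"],
                    values=arr(f"domains/{key}"),
                    has_well=spec["has_well"],
                    step=spec["step"],
                )
                for key, spec in cfg_m["domains"].items()
            }
            config = ModelConfig(
                symbols=tuple(cfg_m["symbols"]),
                levels=tuple(cfg_m["levels"]),
                n_via_points=cfg_m["n_via_points"],
                domains=domains,
                alpha=cfg_m["alpha"],
                pos_kernel_order=cfg_m["pos_kernel_order"],
                pos_kernel_var=cfg_m["pos_kernel_var"],
                vel_kernel_order=cfg_m["vel_kernel_order"],
                vel_kernel_var=cfg_m["vel_kernel_var"],
                velocity_scale=cfg_m["velocity_scale"],
                position_scale=cfg_m["position_scale"],
                size_scale=cfg_m["size_scale"],
                a_scale=cfg_m["a_scale"],
            )
            counts = {key: arr(f"counts/{key}") for key in manifest["counts_keys"]}
            tables = {key: arr(f"tables/{key}") for key in manifest["tables_keys"]}
            aux = {key: arr(f"aux/{key}") for key in manifest["aux_keys"]}
            exemplar_counts = arr("exemplar_counts")
    except (zipfile.BadZipFile, KeyError, EOFError, OSError) as exc:
        raise ModelFileError(f"{path}: corrupt or truncated model archive ({exc})") from exc
    return ModelParameters(
        config=config,
        counts=counts,
        tables=tables,
        aux_stats=aux,
        exemplar_counts=exemplar_counts,
    )
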