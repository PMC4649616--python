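"""File I/O and run provenance.

Interchange formats are deliberately plain: CSV/TSV with unit-suffixed
headers (``time_s``, ``x_um``, ``force_pN``, ``radius_um`` ...) plus JSON
sidecars/manifests for metadata, and JSON/YAML for configurations.  Every
CLI invocation writes one RunManifest next to its outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .microrheology import BeadTrajectory
from .spatial import NucleolusCloud

__all__ = [
    "RunManifest",
    "read_trajectory",
    "write_trajectory",
    "read_cloud",
    "write_clouds",
    "write_manifest",
]

TRAJ_COLUMNS = ("time_s", "x_um", "force_pN")
CLOUD_COLUMNS = ("nucleus_id", "x_um", "y_um", "z_um", "radius_um")


@dataclass(frozen=True)
class RunManifest:
    """Provenance record written alongside every CLI output."""

    command: str
    config_hash: str
    seed: int
    tool_version: str
    timestamp: str
    inputs: tuple = ()
    outputs: tuple = ()


def config_hash(config: dict) -> str:
    """Stable hex digest of a JSON-serialisable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(out_dir, command: str, config: dict, seed: int, inputs=(), outputs=()):
    from . import __version__

    manifest = RunManifest(
        command=command,
        config_hash=config_hash(config),
        seed=int(seed),
        tool_version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(),
        inputs=tuple(str(p) for p in inputs),
        outputs=tuple(str(p) for p in outputs),
    )
    path = Path(out_dir) / "run_manifest.json"
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(asdict(manifest), indent=2) + "\n")
    return manifest


# ---------------------------------------------------------------------------
# trajectories


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_trajectory(path, traj: BeadTrajectory, metadata: dict | None = None) -> None:
    """Write a trajectory CSV plus its JSON sidecar (bead radius etc.)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"time_s": traj.times, "x_um": traj.displacement, "force_pN": traj.force}
    ).to_csv(path, index=False)
    meta = {"bead_radius_um": traj.bead_radius}
    meta.update(metadata or {})
    _sidecar(path).write_text(json.dumps(meta, indent=2) + "\n")


def read_trajectory(path) -> tuple[BeadTrajectory, dict]:
    """Read a trajectory CSV (+ sidecar).  Columns: time_s, x_um, force_pN."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in TRAJ_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    t = df["time_s"].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: column time_s must be strictly increasing")
    meta: dict = {}
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    radius = float(meta.get("bead_radius_um", 1.4))
    traj = BeadTrajectory(
        times=t,
        displacement=df["x_um"].to_numpy(float),
        force=df["force_pN"].to_numpy(float),
        bead_radius=radius,
    )
    return traj, meta


# ---------------------------------------------------------------------------
# point clouds


def write_clouds(path, clouds: dict, manifest: dict | None = None) -> None:
    """Write {nucleus_id: NucleolusCloud} as one TSV, plus a cohort manifest
    JSON mapping nucleus_id -> {g_multiple, time_s} when given."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frames = []
    for nid, cloud in clouds.items():
        frames.append(
            pd.DataFrame(
                {
                    "nucleus_id": nid,
                    "x_um": cloud.positions[:, 0],
                    "y_um": cloud.positions[:, 1],
                    "z_um": cloud.positions[:, 2],
                    "radius_um": cloud.radii,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
    if manifest is not None:
        _sidecar(path).write_text(json.dumps(manifest, indent=2) + "\n")


def read_cloud(path, manifest_path=None, frame: str = "raw") -> dict:
    """Read a point-cloud TSV into {nucleus_id: (cloud, metadata)}.

    When a manifest is supplied every nucleus_id in the file must have an
    entry; negative radii are rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CLOUD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if (df["radius_um"] <= 0).any():
        bad = df.loc[df["radius_um"] <= 0, "nucleus_id"].unique()
        raise ValueError(f"{path}: non-positive radius_um for nucleus id(s) {list(bad)}")
    manifest = None
    mp = Path(manifest_path) if manifest_path else _sidecar(path)
    if manifest_path or mp.exists():
        manifest = json.loads(Path(mp).read_text())
    out = {}
    for nid, grp in df.groupby("nucleus_id", sort=False):
        meta = {}
        if manifest is not None:
            key = str(nid)
            if key not in manifest:
                raise ValueError(f"{path}: nucleus_id {nid!r} missing from manifest")
            meta = manifest[key]
        cloud = NucleolusCloud(
            positions=grp[["x_um", "y_um", "z_um"]].to_numpy(float),
            radii=grp["radius_um"].to_numpy(float),
            frame=frame,
        )
        out[nid] = (cloud, meta)
    return out
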