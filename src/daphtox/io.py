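"""File I/O: frame stacks, truth/trajectory CSVs, YAML configs, manifests."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .simulator import PHASE_NAMES, AnimalGroundTruth

__all__ = [
    "read_stack",
    "write_stack",
    "write_truth_csv",
    "read_truth_csv",
    "load_yaml",
    "write_manifest",
]


def read_stack(path) -> np.ndarray:
    """Read a frame stack: multi-page TIFF, a video file, or a PNG directory."""
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("*.png")) or sorted(path.glob("*.tif*"))
        if not files:
            raise FileNotFoundError(f"no PNG/TIFF frames in {path}")
        return np.stack([iio.imread(f) for f in files])
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path)
    return np.asarray(iio.imread(path))


def write_stack(path, frames: np.ndarray) -> None:
    """Write frames as a multi-page TIFF (or PNG sequence for a directory)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, np.asarray(frames))
    else:
        path.mkdir(parents=True, exist_ok=True)
        for i, frame in enumerate(frames):
            iio.imwrite(path / f"frame_{i:05d}.png", frame)


def write_truth_csv(path, truths: list[AnimalGroundTruth]) -> None:
    """Ground truth CSV: animal_id, frame, t_s, x_mm, y_mm, phase."""
    parts = []
    for tr in truths:
        parts.append(
            pd.DataFrame(
                {
                    "animal_id": tr.animal_id,
                    "frame": np.arange(tr.n_frames),
                    "t_s": tr.t_s,
                    "x_mm": tr.x_mm,
                    "y_mm": tr.y_mm,
                    "phase": [PHASE_NAMES[p] for p in tr.phase],
                }
            )
        )
    df = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(
        columns=["animal_id", "frame", "t_s", "x_mm", "y_mm", "phase"]
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_truth_csv(path, body_length_mm: float = 0.6) -> list[AnimalGroundTruth]:
    df = pd.read_csv(path)
    truths = []
    codes = {name: i for i, name in enumerate(PHASE_NAMES)}
    for aid, sub in df.groupby("animal_id"):
        sub = sub.sort_values("frame")
        phase = np.array([codes[p] for p in sub["phase"]], dtype=np.uint8)
        truths.append(
            AnimalGroundTruth(
                animal_id=int(aid),
                t_s=sub["t_s"].to_numpy(float),
                x_mm=sub["x_mm"].to_numpy(float),
                y_mm=sub["y_mm"].to_numpy(float),
                phase=phase,
                immobile=bool((phase == codes["immobile"]).all()),
                body_length_mm=body_length_mm,
            )
        )
    return truths


def load_yaml(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path} must contain a YAML mapping")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, config: dict, seed: int) -> Path:
    """Record the run: config snapshot, seed, version, file checksums."""
    from . import __version__

    out_dir = Path(out_dir)
    manifest_path = out_dir / "manifest.json"
    files = {
        str(p.relative_to(out_dir)): _sha256(p)
        for p in sorted(out_dir.rglob("*"))
        if p.is_file() and p != manifest_path
    }
    manifest = {
        "config": config,
        "seed": seed,
        "version": __version__,
        "files": files,
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest_path
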