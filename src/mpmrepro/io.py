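"""NIfTI-1 and manifest plumbing."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .grids import Grid


def save_nifti(
    volume: np.ndarray, grid: Grid, path: str | Path, sidecar: dict | None = None
) -> Path:
    """Write a volume as NIfTI-1 with the grid's RAS affine; an optional JSON
    sidecar (acquisition parameters, seeds, flags) goes next to it."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float32), grid.affine)
    nib.save(img, str(path))
    if sidecar is not None:
        path.with_suffix("").with_suffix(".json").write_text(
            json.dumps(sidecar, indent=2, default=_jsonable)
        )
    return path


def load_nifti(path: str | Path) -> tuple[np.ndarray, Grid]:
    img = nib.load(str(path))
    vox = float(img.affine[0, 0])
    data = np.asarray(img.dataobj, dtype=float)
    grid = Grid(tuple(data.shape[:3]), vox)
    if not np.allclose(img.affine, grid.affine, atol=1e-4):
        raise ValueError(f"{path}: affine is not a centred isotropic RAS grid")
    return data, grid


def load_sidecar(path: str | Path) -> dict:
    return json.loads(Path(path).with_suffix("").with_suffix(".json").read_text())


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def config_hash(config: dict) -> str:
    """Stable hash of a configuration dictionary."""
    canon = json.dumps(config, sort_keys=True, default=_jsonable)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


class RunManifest:
    """Per-run record of configuration, seeds, outputs and warnings."""

    def __init__(self, config: dict, seed: int, path: str | Path):
        self.path = Path(path)
        self.data = {
            "config": config,
            "config_hash": config_hash(config),
            "seed": seed,
            "tool": "mpmrepro",
            "outputs": {},
            "warnings": [],
        }
        if self.path.exists():
            existing = json.loads(self.path.read_text())
            if existing.get("config_hash") == self.data["config_hash"]:
                self.data = existing

    def add_output(self, stage: str, key: str, file_path: str | Path):
        self.data["outputs"].setdefault(stage, {})[key] = str(file_path)

    def warn(self, message: str):
        self.data["warnings"].append(message)

    def save(self):
        self.path.parent.mkdir(parents=True, exist_ok=True)
        self.path.write_text(json.dumps(self.data, indent=2, default=_jsonable))
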