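"""Reading and writing: NIfTI volumes, NPZ stacks, evaluation CSVs,
checkpoints and run manifests."""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .metrics import EvalRecord

__all__ = [
    "load_nifti", "save_nifti", "load_npz_stack", "records_to_csv",
    "records_from_csv", "save_checkpoint", "load_checkpoint", "write_manifest",
]


def load_nifti(path) -> tuple[np.ndarray, np.ndarray, tuple]:
    """Return (array, affine, voxel spacing). Axis order is whatever the file
    stores; slicing conventions are up to the caller."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[: data.ndim])
    return data, img.affine, spacing


def save_nifti(path, array: np.ndarray, affine: np.ndarray | None = None):
    nib.save(nib.Nifti1Image(np.asarray(array), np.eye(4) if affine is None else affine),
             str(path))


def load_npz_stack(path) -> dict:
    with np.load(str(path)) as z:
        return {k: z[k] for k in z.files}


def records_to_csv(records: list[EvalRecord], path) -> Path:
    path = Path(path)
    pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(path, index=False)
    return path


def records_from_csv(path) -> list[EvalRecord]:
    df = pd.read_csv(path)
    return [EvalRecord(str(r.case_id), int(r.class_id), float(r.dsc), float(r.hd95))
            for r in df.itertuples()]


def save_checkpoint(path, model, config=None, extra: dict | None = None):
    """Model weights (incl. BN running stats) as NPZ with the config embedded."""
    state = model.state_dict()
    meta = {"config": _cfg_dict(config) if config is not None else None,
            "extra": extra or {}}
    np.savez(str(path), __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path) -> tuple[dict, dict]:
    """Return (state dict, metadata dict)."""
    with np.load(str(path)) as z:
        state = {k: z[k] for k in z.files if k != "__meta__"}
        meta = json.loads(bytes(z["__meta__"]).decode()) if "__meta__" in z.files else {}
    return state, meta


def _cfg_dict(cfg):
    if dataclasses.is_dataclass(cfg):
        return dataclasses.asdict(cfg)
    return cfg


def write_manifest(path, command: str, config, seed: int | None,
                   outputs: list[str]) -> Path:
    """One manifest per artifact-producing run: config snapshot, seed,
    package version, command and timestamps."""
    from . import __version__

    path = Path(path)
    manifest = {
        "command": command,
        "config": _cfg_dict(config),
        "seed": seed,
        "package_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "outputs": outputs,
    }
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
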