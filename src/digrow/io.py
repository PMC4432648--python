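"""Grid CSV, PNG rendering and run-manifest writers.

Grid CSV dialect: comma-separated integers 0/1/2 = S/X/M, one row per
lattice row, no header.  The iridophore mask, when present, is stored next
to the grid as ``<name>.mask.csv`` with 0/1 entries.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import __version__
from .model import LatticeState, ModelParams

__all__ = ["write_grid_csv", "read_grid_csv", "render_png", "write_manifest"]

# Fig-1 color key: X yellow, M black, S white, masked nodes shaded gray
_COLORS = {0: (255, 255, 255), 1: (250, 200, 30), 2: (20, 20, 20)}
_MASK_SHADE = 0.55


def write_grid_csv(state: LatticeState, path: str | Path) -> Path:
    path = Path(path)
    occ = np.atleast_2d(state.occupancy)
    np.savetxt(path, occ, fmt="%d", delimiter=",")
    if state.irido_mask.any():
        np.savetxt(path.with_suffix(".mask.csv"),
                   np.atleast_2d(state.irido_mask).astype(int),
                   fmt="%d", delimiter=",")
    return path


def read_grid_csv(path: str | Path) -> LatticeState:
    path = Path(path)
    occ = np.loadtxt(path, delimiter=",", dtype=np.int8, ndmin=2)
    mask_path = path.with_suffix(".mask.csv")
    mask = None
    if mask_path.exists():
        mask = np.loadtxt(mask_path, delimiter=",", dtype=bool, ndmin=2)
    if occ.shape[0] == 1:
        occ = occ[0]
        mask = mask[0] if mask is not None else None
    return LatticeState(occ, mask)


def render_png(state: LatticeState, path: str | Path, scale: int = 4) -> Path:
    """Render the grid as a PNG (X yellow, M black, S white, mask shaded)."""
    from PIL import Image

    occ = np.atleast_2d(state.occupancy)
    mask = np.atleast_2d(state.irido_mask)
    rgb = np.zeros(occ.shape + (3,), dtype=np.uint8)
    for code, color in _COLORS.items():
        rgb[occ == code] = color
    rgb[mask] = (rgb[mask] * _MASK_SHADE).astype(np.uint8)
    img = Image.fromarray(rgb, mode="RGB")
    if scale > 1:
        img = img.resize((img.width * scale, img.height * scale), Image.NEAREST)
    path = Path(path)
    img.save(path)
    return path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(
    path: str | Path,
    params: ModelParams,
    extra: dict | None = None,
    files: list[Path] | None = None,
) -> Path:
    """JSON manifest sufficient to re-run a result bit-identically."""
    manifest = {
        "code_version": __version__,
        "params": asdict(params),
        **(extra or {}),
        "files": {str(f): _sha256(Path(f)) for f in (files or []) if Path(f).exists()},
    }
    path = Path(path)
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
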