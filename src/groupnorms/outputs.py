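"""Tabular and image outputs with reproducibility manifests.

Every CSV written here gets a ``*.manifest.json`` sidecar echoing the full
configuration that produced it, so any table can be regenerated from its
manifest alone.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional, Tuple, Union

import numpy as np
import pandas as pd
from PIL import Image

from . import __version__
from .observables import Trajectory

#: Snapshot color map, keyed by the 4-state encoding: behavior 1 in group 1
#: is blue, behavior 2 in group 1 yellow, behavior 1 in group 2 green and
#: behavior 2 in group 2 red.
SNAPSHOT_COLORS: Dict[int, Tuple[int, int, int]] = {
    0: (0, 0, 255),      # behavior 1, group 1: blue
    1: (255, 255, 0),    # behavior 2, group 1: yellow
    2: (0, 255, 0),      # behavior 1, group 2: green
    3: (255, 0, 0),      # behavior 2, group 2: red
}

TIMESERIES_COLUMNS = ("step", "rho1", "rho1_group1", "rho1_group2")


def make_manifest(settings: Optional[dict] = None, **extra) -> dict:
    """Configuration echo attached to every output."""
    manifest = {"package": "groupnorms", "version": __version__}
    if settings:
        manifest["settings"] = settings
    manifest.update(extra)
    return manifest


def _manifest_path(path: Path) -> Path:
    return path.with_name(path.stem + ".manifest.json")


def _write_manifest(path: Path, manifest: Optional[dict]) -> None:
    if manifest is None:
        return
    _manifest_path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")


def write_timeseries(
    trajectory: Trajectory, path: Union[str, Path], manifest: Optional[dict] = None
) -> Path:
    """Write one run's time course as a tidy CSV (one row per step)."""
    path = Path(path)
    frame = pd.DataFrame({
        "step": np.arange(len(trajectory.rho1)),
        "rho1": trajectory.rho1,
        "rho1_group1": trajectory.rho1_g1,
        "rho1_group2": trajectory.rho1_g2,
    })
    frame.to_csv(path, index=False)
    if manifest is not None:
        manifest = dict(manifest)
        manifest.update(
            converged=trajectory.converged,
            converged_at=trajectory.converged_at,
            steady_rho1=trajectory.steady_rho1,
            group1_fraction=trajectory.group1_fraction,
        )
    _write_manifest(path, manifest)
    return path


def write_sweep(
    result: pd.DataFrame, path: Union[str, Path], manifest: Optional[dict] = None
) -> Path:
    """Write a sweep table (one row per grid point x replicate) as CSV."""
    path = Path(path)
    result.to_csv(path, index=False)
    _write_manifest(path, manifest)
    return path


def read_sweep(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path)


def export_snapshot(
    grid: np.ndarray, path: Union[str, Path], scale: int = 4
) -> Tuple[Path, Path]:
    """Export a 4-state grid as a PNG plus a plain-text integer sidecar.

    Returns (png_path, txt_path).  ``scale`` is the pixel size per site.
    """
    grid = np.asarray(grid)
    if grid.ndim != 2 or not np.isin(grid, list(SNAPSHOT_COLORS)).all():
        raise ValueError("snapshot grid must be 2-D with states in {0, 1, 2, 3}")
    palette = np.array([SNAPSHOT_COLORS[k] for k in range(4)], dtype=np.uint8)
    rgb = palette[grid]
    if scale > 1:
        rgb = np.repeat(np.repeat(rgb, scale, axis=0), scale, axis=1)
    path = Path(path)
    png_path = path if path.suffix == ".png" else path.with_suffix(".png")
    Image.fromarray(rgb).save(png_path)
    txt_path = png_path.with_suffix(".txt")
    np.savetxt(txt_path, grid, fmt="%d")
    return png_path, txt_path
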