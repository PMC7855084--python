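"""File I/O: TIFF stacks, provenance-stamped CSVs and YAML configuration."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import tifffile
import yaml

from .phantoms import VoxelVolume
from .pipeline import PipelineConfig

__all__ = [
    "read_stack",
    "write_stack",
    "write_csv_with_provenance",
    "read_result_csv",
    "load_config",
]


def write_stack(path, volume: VoxelVolume) -> Path:
    """Write a volume as a multi-page 8-bit TIFF stack.

    Binary volumes are stored as 0/255; grey occupancy volumes are scaled
    from [0, 1] to 0..255.  The crop is materialised to the full domain so
    stacks are self-contained.
    """
    path = Path(path)
    arr = volume.full_array()
    if arr.dtype == bool:
        data = (arr.astype(np.uint8)) * 255
    else:
        data = np.clip(np.round(np.asarray(arr, dtype=float) * 255.0), 0, 255).astype(np.uint8)
    tifffile.imwrite(path, data, photometric="minisblack",
                     metadata={"voxel_size_um": volume.voxel_size})
    return path


def read_stack(path, voxel_size: Optional[float] = None) -> VoxelVolume:
    """Read an 8-bit multi-page TIFF stack into a :class:`VoxelVolume`.

    A stack containing only {0, 255} is interpreted as binary; anything else
    is returned as grey occupancy in [0, 1] (256 levels preserved up to the
    1/255 quantisation).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such stack: {path}")
    data = tifffile.imread(path)
    if data.dtype != np.uint8:
        raise ValueError(f"{path}: expected an 8-bit stack, got {data.dtype}")
    if data.ndim == 2:
        data = data[None]
    if voxel_size is None:
        voxel_size = 1.0
        try:
            with tifffile.TiffFile(path) as tf:
                meta = tf.shaped_metadata or ()
                for m in meta:
                    if "voxel_size_um" in m:
                        voxel_size = float(m["voxel_size_um"])
        except Exception:
            pass
    levels = np.unique(data)
    if set(levels.tolist()) <= {0, 255}:
        values: np.ndarray = data == 255
    else:
        values = (data / 255.0).astype(np.float32)
    return VoxelVolume(values=values, voxel_size=voxel_size)


def write_csv_with_provenance(
    df: pd.DataFrame,
    path,
    config_digest: str,
    seed: Optional[int],
) -> Path:
    """Write a CSV with a leading provenance comment (config hash, seed)."""
    path = Path(path)
    seed_part = "none" if seed is None else str(seed)
    with open(path, "w") as fh:
        fh.write(f"# osteomorph config={config_digest} seed={seed_part}\n")
        df.to_csv(fh, index=False)
    return path


def read_result_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def load_config(path) -> PipelineConfig:
    """Load a YAML pipeline configuration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such config: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(raw)
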