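"""File-format plumbing: TIFF/PNG images, schema-checked CSV tables, YAML configs.

Conventions: 16-bit grayscale TIFF (single channel, uncompressed) for
images; CSV with unit-suffixed column names for tables; YAML for configs.
CSV schemas are validated on read so a truncated or foreign file fails
loudly rather than propagating NaNs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "read_image",
    "write_image",
    "read_table",
    "write_table",
    "read_config",
    "write_config",
    "read_occupancy_csv",
    "write_occupancy_csv",
    "DROPLET_COLUMNS",
    "CRYSTAL_COLUMNS",
    "TRACE_COLUMNS",
]

DROPLET_COLUMNS = ["droplet_id", "center_x_px", "center_y_px", "diameter_um"]
CRYSTAL_COLUMNS = ["droplet_id", "length_um", "width_um", "orientation_deg"]
TRACE_COLUMNS = ["t_ms", "cv"]
OCCUPANCY_COLUMNS = ["crystals_per_droplet", "count"]


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale TIFF or PNG image (or TIFF stack) as an array."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path)
    import imageio.v3 as iio

    img = iio.imread(path)
    if img.ndim == 3 and img.shape[-1] in (3, 4):  # collapse RGB(A) grayscale
        img = img[..., 0]
    return img


def write_image(path: str | Path, image: np.ndarray) -> Path:
    """Write an image or stack as uncompressed single-channel TIFF/PNG."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image, photometric="minisblack")
    else:
        import imageio.v3 as iio

        iio.imwrite(path, image)
    return path


def write_table(path: str | Path, frame: pd.DataFrame) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)
    return path


def read_table(path: str | Path, required: Iterable[str] | None = None) -> pd.DataFrame:
    """Read a CSV table, checking that ``required`` columns are present."""
    frame = pd.read_csv(path)
    if required is not None:
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing}")
    return frame


def write_occupancy_csv(path: str | Path, histogram: Mapping[int, int]) -> Path:
    frame = pd.DataFrame(
        sorted(histogram.items()), columns=OCCUPANCY_COLUMNS
    )
    return write_table(path, frame)


def read_occupancy_csv(path: str | Path) -> dict[int, int]:
    frame = read_table(path, required=OCCUPANCY_COLUMNS)
    if (frame["count"] < 0).any() or (frame["crystals_per_droplet"] < 0).any():
        raise ValueError(f"{path}: occupancy histogram entries must be >= 0")
    return {int(k): int(v) for k, v in zip(frame["crystals_per_droplet"], frame["count"])}


def write_config(path: str | Path, config: Mapping) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(dict(config), fh, sort_keys=True)
    return path


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return cfg
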