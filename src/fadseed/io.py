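"""Table and raster I/O with versioned CSV schemas.

Every CSV written by the package starts with a comment header line
``# fadseed schema=<name> version=<v>``; readers skip comment lines and
preserve unknown columns, never dropping them.  CSVs use UTF-8, a header
row, "." as the decimal separator, and empty fields for missing values.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from PIL import Image

SCHEMA_VERSION = 1

#: Canonical column sets, by schema name.
SCHEMAS = {
    "seeds": [
        "seed_id",
        "plant_id",
        "whorl_index",
        "seed_area_px",
        "spot_area_px",
        "spot_cover_pct",
        "elaiosome_area_px",
        "category",
    ],
    "plants": [
        "plant_id",
        "light_regime",
        "flowers_per_whorl",
        "n_whorls",
        "total_flowers",
    ],
    "germination": ["seed_id", "category", "day", "germinated"],
    "trials": ["trial_id", "session", "time", "removed_category"],
    "grid_layout": ["row", "col", "category"],
    "grid_events": ["event_index", "time", "row", "col"],
}


def write_table(df: pd.DataFrame, path: str | Path, schema: Optional[str] = None) -> None:
    """Write a CSV with a schema comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    name = schema or "generic"
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# fadseed schema={name} version={SCHEMA_VERSION}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a package CSV, skipping schema comment lines."""
    return pd.read_csv(path, comment="#")


def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as a single-channel 0/255 PNG."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray((np.asarray(mask, bool) * 255).astype(np.uint8), mode="L").save(path)


def read_mask_png(path: str | Path) -> np.ndarray:
    """Read a 0/255 single-channel PNG back into a boolean mask."""
    return np.asarray(Image.open(path).convert("L")) > 127


def write_image_png(pixels: np.ndarray, path: str | Path) -> None:
    """Write an 8-bit RGB raster as PNG."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(np.asarray(pixels, np.uint8), mode="RGB").save(path)


def read_image_png(path: str | Path) -> np.ndarray:
    """Read a raster as an 8-bit RGB array."""
    return np.asarray(Image.open(path).convert("RGB"))
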