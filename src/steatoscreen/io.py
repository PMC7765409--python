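"""File formats: TIFF field images, CSV tables, YAML configs, JSON reports.

Images are written one single-channel 16-bit TIFF per channel, named
``{plate}_{well}_{field}_{channel}.tif``. Tables round-trip through CSV with
full float precision, so calls recomputed from a written plate summary are
bit-identical to the originals.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .synthetic import WELL_SUMMARY_COLUMNS, FieldImage

__all__ = [
    "write_field_tiffs",
    "read_field_tiffs",
    "write_table",
    "read_well_summary",
    "write_qc_json",
    "write_yaml",
    "read_yaml",
    "sha256_of",
]

CHANNEL_NAMES = ("nuclei", "lipid")


def _to_uint16(arr: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(arr), 0, 65535).astype(np.uint16)


def write_field_tiffs(
    image: FieldImage, outdir, plate: str, well: str, field: int
) -> list[Path]:
    """Write the two channels of one field as 16-bit TIFFs; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, arr in zip(CHANNEL_NAMES, (image.nuclear, image.lipid)):
        path = outdir / f"{plate}_{well}_{field}_{name}.tif"
        tifffile.imwrite(path, _to_uint16(arr))
        paths.append(path)
    return paths


def read_field_tiffs(outdir, plate: str, well: str, field: int) -> FieldImage:
    outdir = Path(outdir)
    arrays = []
    for name in CHANNEL_NAMES:
        path = outdir / f"{plate}_{well}_{field}_{name}.tif"
        arrays.append(tifffile.imread(path).astype(float))
    return FieldImage(nuclear=arrays[0], lipid=arrays[1])


def write_table(df: pd.DataFrame, path) -> Path:
    """Write a CSV preserving full float precision (repr round-trip)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_well_summary(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(WELL_SUMMARY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"well summary missing columns: {sorted(missing)}")
    return df


def write_qc_json(qc, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = dataclasses.asdict(qc) if dataclasses.is_dataclass(qc) else dict(qc)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def write_yaml(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(obj, sort_keys=True))
    return path


def read_yaml(path):
    return yaml.safe_load(Path(path).read_text())


def sha256_of(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
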