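"""Plain-file input/output: multi-band TIFF rasters and sample CSVs."""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import tifffile

from .synthetic import BAND_NAMES, BandStack, SampleRecord

RECORD_HEADER = ("plot_id", "density", "nitrogen", "replicate", "date", "scenario", "lai_true")


def write_bandstack_tiff(stack: BandStack, path) -> None:
    """Five-band float32 TIFF in canonical band order B, G, R, RE, NIR."""
    arr = stack.as_array().astype(np.float32)
    tifffile.imwrite(
        path, arr, photometric="minisblack",
        description=json.dumps({"bands": list(BAND_NAMES)}),
    )


def read_bandstack_tiff(path) -> BandStack:
    arr = tifffile.imread(path)
    if arr.ndim != 3 or arr.shape[0] != len(BAND_NAMES):
        raise ValueError(f"expected a (5, H, W) raster, got shape {arr.shape}")
    return BandStack({b: arr[i].astype(np.float64) for i, b in enumerate(BAND_NAMES)})


def write_records_csv(records: list[SampleRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(RECORD_HEADER)
        for r in records:
            writer.writerow(
                [r.plot_id, r.density_label, r.nitrogen_label, r.replicate,
                 r.date_index, r.scenario, f"{r.lai_true:.6f}"]
            )


def read_records_csv(path) -> list[SampleRecord]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                SampleRecord(
                    plot_id=row["plot_id"], density_label=row["density"],
                    nitrogen_label=row["nitrogen"], replicate=int(row["replicate"]),
                    date_index=int(row["date"]), scenario=row["scenario"],
                    lai_true=float(row["lai_true"]),
                )
            )
    return out


def write_lai_map_tiff(lai_map: np.ndarray, path) -> None:
    """Single-band float LAI raster tagged with its units (m2/m2)."""
    tifffile.imwrite(
        path, np.asarray(lai_map, dtype=np.float32),
        description=json.dumps({"quantity": "LAI", "units": "m2/m2"}),
    )


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
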