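"""CSV/JSON round-tripping and run manifests.

All tables are plain UTF-8 CSV with a mandatory header row, comma separator
and dot decimal; Gy units are implicit in the ``*_Gy`` column names.  Floats
are written at full ``repr`` precision so a write-read cycle preserves every
metric exactly.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .protocol import COLOURS

LABEL_COLUMNS = ["patient_id", "fraction", "roi", "colour"]


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_labels(path) -> pd.DataFrame:
    """Read a flag-colour CSV (ground truth or decisions)."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(LABEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = set(df["colour"].unique()) - set(COLOURS)
    if bad:
        raise ValueError(f"{path}: unknown colours {sorted(bad)}")
    df["fraction"] = df["fraction"].astype(int)
    return df


def read_planned_metrics(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"patient_id", "roi", "metric", "value_Gy"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_prescriptions(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"patient_id", "roi", "dpre_Gy"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_courses(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"patient_id", "n_fractions"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df["n_fractions"] = df["n_fractions"].astype(int)
    return df


def write_json(data: Mapping, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2, sort_keys=False)
        fh.write("\n")


@dataclass
class RunManifest:
    """Everything needed to reproduce a run: config, seed, versions, paths."""

    command: str
    seed: int | None = None
    config: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        from . import __version__

        return {
            "command": self.command,
            "seed": self.seed,
            "config": self.config,
            "inputs": {k: str(v) for k, v in self.inputs.items()},
            "outputs": {k: str(v) for k, v in self.outputs.items()},
            "versions": {"artflag": __version__, "python": platform.python_version()},
            "timestamp": datetime.now(timezone.utc).isoformat(),
        }

    def write(self, path) -> None:
        write_json(self.to_dict(), path)


def read_rtdose(path):
    """Optional DICOM RTDOSE reader (requires pydicom): returns a DoseGrid.

    The dose array is reordered to (x, y, z)-style axis order with spacing in
    mm.  Structure-set rasterisation is not provided; masks are expected on
    the same lattice from upstream tooling or the synthetic module.
    """
    import pydicom

    from .grids import DoseGrid

    ds = pydicom.dcmread(path)
    values = ds.pixel_array * float(ds.DoseGridScaling)  # frames, rows, cols
    values = np.transpose(values, (2, 1, 0))
    spacing = (
        float(ds.PixelSpacing[1]),
        float(ds.PixelSpacing[0]),
        abs(float(ds.GridFrameOffsetVector[1]) - float(ds.GridFrameOffsetVector[0]))
        if len(ds.GridFrameOffsetVector) > 1 else 1.0,
    )
    origin = tuple(float(v) for v in ds.ImagePositionPatient)
    return DoseGrid(values, spacing=spacing, origin=origin)
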