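"""On-disk formats: TIFF movies, CSV tables, JSON reports, YAML configs."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .config import AnalysisConfig, ImagingConfig, TrackingConfig
from .geometry import CellGeometry


def write_movie(path, frames: np.ndarray) -> None:
    tifffile.imwrite(str(path), frames.astype(np.uint16), photometric="minisblack")


def read_movie(path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(path, obj) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")
    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def write_geometries(path, geometries: list[CellGeometry],
                     cell_ids=None) -> None:
    ids = cell_ids if cell_ids is not None else range(len(geometries))
    records = [{"cell_id": int(i), **g.to_dict()}
               for i, g in zip(ids, geometries)]
    write_json(path, records)


def read_geometries(path) -> dict[int, CellGeometry]:
    return {rec["cell_id"]: CellGeometry.from_dict(rec)
            for rec in read_json(path)}


def write_config(path, imaging: ImagingConfig, tracking: TrackingConfig,
                 analysis: AnalysisConfig, extra: dict | None = None) -> None:
    doc = {"imaging": imaging.to_dict(), "tracking": tracking.to_dict(),
           "analysis": analysis.to_dict()}
    if extra:
        doc.update(extra)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def read_config(path):
    doc = yaml.safe_load(Path(path).read_text())
    return (ImagingConfig.from_dict(doc["imaging"]),
            TrackingConfig.from_dict(doc["tracking"]),
            AnalysisConfig.from_dict(doc["analysis"]),
            {k: v for k, v in doc.items()
             if k not in ("imaging", "tracking", "analysis")})


def file_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def config_hash(imaging: ImagingConfig, tracking: TrackingConfig,
                analysis: AnalysisConfig, seed: int) -> str:
    blob = json.dumps({"imaging": imaging.to_dict(),
                       "tracking": tracking.to_dict(),
                       "analysis": analysis.to_dict(),
                       "seed": seed}, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
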