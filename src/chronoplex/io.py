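"""Readers and writers for the plain-text/TIFF interchange formats.

Traces travel as CSV (columns ``time_h, value, channel, animal_id,
genotype``), volumetric time-lapses as multi-page TIFF (plane order t-major,
then z) with a JSON sidecar recording shape, frame interval and pixel size,
junction annotations and ground truth as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import tifffile

from .datatypes import JunctionAnnotation, LuminometryTrace, PhotometryTrace, VolumetricTimelapse

PathLike = Union[str, Path]

TRACE_COLUMNS = ["time_h", "value", "channel", "animal_id", "genotype"]


def write_trace_csv(trace: Union[PhotometryTrace, LuminometryTrace], path: PathLike) -> None:
    if isinstance(trace, LuminometryTrace):
        df = pd.DataFrame({
            "time_h": trace.time_h, "value": trace.counts, "channel": "luminometry",
            "animal_id": trace.well_id, "genotype": "",
        })
    else:
        df = pd.DataFrame({
            "time_h": trace.time_h, "value": trace.value, "channel": "green_470",
            "animal_id": trace.animal_id, "genotype": trace.genotype,
        })
    header_meta = ""
    if isinstance(trace, PhotometryTrace):
        header_meta = (
            f"# start_clock_h={trace.start_clock_h} lights_off_clock_h={trace.lights_off_clock_h} "
            f"light_schedule={trace.light_schedule}\n"
        )
    with open(path, "w") as fh:
        fh.write(header_meta)
        df.to_csv(fh, index=False)


def read_trace_csv(path: PathLike) -> Union[PhotometryTrace, LuminometryTrace]:
    """Read a trace CSV, validating columns, numerics and time monotonicity."""
    meta = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for token in first[1:].split():
                if "=" in token:
                    k, v = token.split("=", 1)
                    meta[k] = v
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    missing = [c for c in ("time_h", "value") if c not in df.columns]
    if missing:
        raise ValueError(f"trace CSV missing required columns: {missing}")
    for col in ("time_h", "value"):
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ValueError(f"column {col!r} contains non-numeric values")
    if df["time_h"].isna().any() or df["value"].isna().any():
        raise ValueError("trace CSV contains missing values")
    df = df.sort_values("time_h", kind="stable").reset_index(drop=True)
    if (df["time_h"].diff().iloc[1:] <= 0).any():
        raise ValueError("duplicate time stamps in trace CSV")
    channel = str(df["channel"].iloc[0]) if "channel" in df.columns and len(df) else ""
    if channel == "luminometry":
        return LuminometryTrace(
            time_h=df["time_h"].to_numpy(), counts=df["value"].to_numpy(),
            well_id=str(df["animal_id"].iloc[0]) if "animal_id" in df.columns else "well",
        )
    return PhotometryTrace(
        time_h=df["time_h"].to_numpy(), value=df["value"].to_numpy(),
        animal_id=str(df["animal_id"].iloc[0]) if "animal_id" in df.columns else "animal",
        genotype=str(df["genotype"].iloc[0]) if "genotype" in df.columns and pd.notna(df["genotype"].iloc[0]) else "reporter",
        light_schedule=meta.get("light_schedule", "LD"),
        start_clock_h=float(meta.get("start_clock_h", 13.0)),
        lights_off_clock_h=float(meta.get("lights_off_clock_h", 19.0)),
    )


def write_timelapse_tiff(movie: VolumetricTimelapse, path: PathLike, sidecar: Optional[PathLike] = None) -> None:
    """Write a (T, Z, Y, X) movie as a t-major multi-page TIFF plus JSON sidecar."""
    path = Path(path)
    t, z, y, x = movie.data.shape
    tifffile.imwrite(path, movie.data.reshape(t * z, y, x).astype(np.float32))
    sidecar = Path(sidecar) if sidecar else path.with_suffix(".json")
    sidecar.write_text(json.dumps({
        "shape": [t, z, y, x],
        "frame_interval_min": movie.frame_interval_min,
        "pixel_um": movie.pixel_um,
        "n_repeats_averaged": movie.n_repeats_averaged,
    }, indent=2))


def read_timelapse_tiff(path: PathLike, sidecar: Optional[PathLike] = None) -> VolumetricTimelapse:
    """Read a multi-page TIFF back into a (T, Z, Y, X) volume via its sidecar."""
    path = Path(path)
    sidecar = Path(sidecar) if sidecar else path.with_suffix(".json")
    try:
        meta = json.loads(sidecar.read_text())
        t, z, y, x = meta["shape"]
    except (json.JSONDecodeError, KeyError, ValueError, FileNotFoundError) as exc:
        raise ValueError(f"corrupt or missing sidecar {sidecar}: {exc}") from exc
    pages = tifffile.imread(path)
    pages = np.atleast_3d(pages)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.shape[0] != t * z:
        raise ValueError(f"page-count mismatch: sidecar implies {t * z} pages, file has {pages.shape[0]}")
    return VolumetricTimelapse(
        data=pages.reshape(t, z, y, x).astype(float),
        frame_interval_min=float(meta.get("frame_interval_min", 30.0)),
        pixel_um=float(meta.get("pixel_um", 1.0)),
        n_repeats_averaged=int(meta.get("n_repeats_averaged", 1)),
    )


def write_junction_json(junctions, path: PathLike) -> None:
    objs = []
    for j in junctions:
        objs.append({
            "apical_point": list(map(float, j.apical_point)),
            "basal_point": list(map(float, j.basal_point)),
            "lateral_polyline": np.asarray(j.lateral_polyline).tolist(),
            "vesicles": np.asarray(j.vesicles).tolist(),
            "gap_measurements_um": np.asarray(j.gap_measurements_um).tolist(),
            "image_id": j.image_id,
            "animal_id": j.animal_id,
        })
    Path(path).write_text(json.dumps(objs, indent=2))


def read_junction_json(path: PathLike):
    objs = json.loads(Path(path).read_text())
    return [
        JunctionAnnotation(
            apical_point=tuple(o["apical_point"]), basal_point=tuple(o["basal_point"]),
            lateral_polyline=np.asarray(o["lateral_polyline"]),
            vesicles=np.asarray(o["vesicles"]).reshape(-1, 2),
            gap_measurements_um=np.asarray(o.get("gap_measurements_um", [])),
            image_id=o.get("image_id", "image"), animal_id=o.get("animal_id", "animal"),
        )
        for o in objs
    ]
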