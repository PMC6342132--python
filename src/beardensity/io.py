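"""Plain-text readers and writers for the pipeline's artifacts.

Formats: detectors and captures as TSV, gridded covariates as TSV
(x, y, covariate...) or ESRI ASCII, polygons as GeoJSON, fits as JSON.
All writers use '.' decimals, UTF-8 and LF endings so outputs are
bit-stable across reruns.
"""
from __future__ import annotations

import json

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .containers import CaptureHistory, DetectorArray, MaskGrid

_CSV_KW = dict(sep="\t", index=False, float_format="%.8g", lineterminator="\n")


def write_detectors(detectors: DetectorArray, path) -> None:
    S = detectors.n_occasions
    df = pd.DataFrame(
        {
            "id": detectors.ids,
            "x_km": detectors.x,
            "y_km": detectors.y,
            "type": detectors.det_type,
            "usage": ["".join(map(str, row)) for row in detectors.usage],
        }
    )
    if "cover" in detectors.covariates.columns:
        df["cover"] = detectors.covariates["cover"].to_numpy()
    gb = detectors.time_varying.get("GB")
    if gb is not None:
        for s in range(S):
            df[f"gb_{s + 1}"] = gb[:, s]
    df.to_csv(path, **_CSV_KW)


def read_detectors(path) -> DetectorArray:
    df = pd.read_csv(path, sep="\t", dtype={"usage": str})
    usage = np.array([[int(c) for c in u] for u in df["usage"]], dtype=np.int8)
    S = usage.shape[1]
    cov = pd.DataFrame()
    if "cover" in df.columns:
        cov["cover"] = df["cover"].to_numpy()
    tv = {}
    gb_cols = [f"gb_{s + 1}" for s in range(S)]
    if set(gb_cols) <= set(df.columns):
        tv["GB"] = df[gb_cols].to_numpy(np.int8)
    return DetectorArray(
        df["id"].to_numpy(), df["x_km"].to_numpy(float),
        df["y_km"].to_numpy(float), df["type"].to_numpy(), usage,
        covariates=cov, time_varying=tv,
    )


def write_captures(history: CaptureHistory, detectors: DetectorArray, path) -> None:
    rows = []
    for i in range(history.n_individuals):
        kd, sd = np.nonzero(history.detections[i])
        for k, s in zip(kd, sd):
            rows.append(
                (history.ids[i], history.sex[i], s + 1, detectors.ids[k])
            )
    pd.DataFrame(
        rows, columns=["individual", "sex", "occasion", "detector_id"]
    ).to_csv(path, **_CSV_KW)


def read_captures(path, detectors: DetectorArray, n_occasions=None,
                  session: str = "") -> CaptureHistory:
    df = pd.read_csv(path, sep="\t")
    S = n_occasions or detectors.n_occasions
    ids = df["individual"].drop_duplicates().to_numpy()
    id_pos = {v: i for i, v in enumerate(ids)}
    det_pos = {v: i for i, v in enumerate(detectors.ids)}
    om = np.zeros((ids.size, detectors.n_detectors, S), dtype=np.uint8)
    sex = np.empty(ids.size, dtype=object)
    for row in df.itertuples(index=False):
        i = id_pos[row.individual]
        om[i, det_pos[row.detector_id], row.occasion - 1] = 1
        sex[i] = row.sex
    return CaptureHistory(ids, sex.astype(str), om, session)


def write_grid(grid: MaskGrid, path) -> None:
    df = pd.DataFrame({"x": grid.x, "y": grid.y})
    for col in grid.covariates.columns:
        df[col] = grid.covariates[col].to_numpy()
    df.to_csv(path, **_CSV_KW)


def read_grid(path, spacing: float) -> MaskGrid:
    df = pd.read_csv(path, sep="\t")
    cov = df.drop(columns=["x", "y"])
    return MaskGrid(df["x"].to_numpy(float), df["y"].to_numpy(float),
                    spacing, cov)


def write_polygon(poly, path, properties=None) -> None:
    gj = {
        "type": "Feature",
        "properties": properties or {},
        "geometry": mapping(poly),
    }
    with open(path, "w") as fh:
        json.dump(gj, fh)


def read_polygon(path):
    with open(path) as fh:
        gj = json.load(fh)
    geom = gj["geometry"] if gj.get("type") == "Feature" else gj
    return shape(geom)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, np.ndarray):
        return v.tolist()
    raise TypeError(f"not JSON serializable: {type(v)}")
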