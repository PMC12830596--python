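"""Readers and writers for the package's versioned CSV/JSON formats.

Every table is written with a leading comment line ``# mitovar-schema:
<name>/<version>`` and readers reject unknown schema versions.  Intensities
are arbitrary fluorescence units throughout; annotation coordinates are
(VDAC1, OXPHOS) = (x, y).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from mitovar.classify import PolygonAnnotation
from mitovar.cohort import PyroseqRecord, QPCRPlate

logger = logging.getLogger("mitovar")

SCHEMAS = {
    "fibre_table": 1,
    "control_table": 1,
    "label_table": 1,
    "certainty_table": 1,
    "pyroseq_table": 1,
    "qpcr_plate": 1,
    "benchmark_table": 1,
    "summary_table": 1,
}

_FIBRE_REQUIRED = ("fibre_id", "patient", "muscle", "biopsy", "section", "vdac1")


def _header_line(schema: str) -> str:
    return f"# mitovar-schema: {schema}/{SCHEMAS[schema]}"


def write_table(df: pd.DataFrame, path, schema: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header_line(schema) + "\n")
        df.to_csv(fh, index=False)


def read_table(path, schema: str) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# mitovar-schema:"):
            raise ValueError(f"{path}: missing schema header")
        declared = first.split(":", 1)[1].strip()
        expected = f"{schema}/{SCHEMAS[schema]}"
        if declared != expected:
            raise ValueError(f"{path}: schema {declared!r} does not match expected {expected!r}")
        return pd.read_csv(fh)


def ingest_fibre_table(path, proteins: list[str] | None = None) -> pd.DataFrame:
    """Read and validate a fibre intensity table.

    Requires identifier columns plus ``vdac1`` and at least one protein
    intensity column.  Rows with non-finite or non-positive intensities are
    dropped with a logged count.
    """
    df = read_table(path, "fibre_table")
    missing = [c for c in _FIBRE_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if proteins is None:
        known = set(_FIBRE_REQUIRED) | {"batch", "in_ground_truth_region"}
        proteins = [c for c in df.columns
                    if c not in known and not c.startswith("true_")
                    and pd.api.types.is_numeric_dtype(df[c])]
    if not proteins:
        raise ValueError(f"{path}: no protein intensity columns found")
    intensity_cols = ["vdac1"] + proteins
    values = df[intensity_cols].to_numpy(dtype=float)
    ok = np.isfinite(values).all(axis=1) & (values > 0).all(axis=1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("%s: dropped %d row(s) with non-finite or non-positive intensities",
                       path, n_dropped)
    return df[ok].reset_index(drop=True)


# -- annotations -------------------------------------------------------------


def write_annotations(annotations: list[PolygonAnnotation], path) -> None:
    payload = {
        "schema": "mitovar-annotations/1",
        "coordinates": "(vdac1, oxphos)",
        "annotations": [
            {
                "investigator": a.investigator, "protein": a.protein,
                "scope": a.scope, "category": a.category,
                "vertices": [[float(x), float(y)] for x, y in a.vertices],
            }
            for a in annotations
        ],
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(payload, indent=1))


def read_annotations(path) -> list[PolygonAnnotation]:
    payload = json.loads(Path(path).read_text())
    if payload.get("schema") != "mitovar-annotations/1":
        raise ValueError(f"{path}: unknown annotation schema {payload.get('schema')!r}")
    return [
        PolygonAnnotation(
            investigator=a["investigator"], protein=a["protein"], scope=a["scope"],
            category=a["category"], vertices=[tuple(v) for v in a["vertices"]],
        )
        for a in payload["annotations"]
    ]


# -- qPCR and pyrosequencing -------------------------------------------------


def write_qpcr_plate(plate: QPCRPlate, path) -> None:
    rows = []
    for target, series in plate.dilution_series.items():
        for copies, reps in series:
            for i, cq in enumerate(reps):
                rows.append({"target": target, "role": "standard", "sample": f"{copies:g}",
                             "copies": copies, "replicate": i + 1, "cq": cq})
    for biopsy, targets in plate.biopsy_cq.items():
        for target, reps in targets.items():
            for i, cq in enumerate(reps):
                rows.append({"target": target, "role": "sample", "sample": biopsy,
                             "copies": np.nan, "replicate": i + 1, "cq": cq})
    write_table(pd.DataFrame(rows), path, "qpcr_plate")


def read_qpcr_plate(path) -> tuple[dict, dict]:
    """Read a qPCR plate CSV into (dilution_series, biopsy_cq) mappings."""
    df = read_table(path, "qpcr_plate")
    dilution_series: dict[str, list[tuple[float, list[float]]]] = {}
    std = df[df["role"] == "standard"]
    for target, sub in std.groupby("target"):
        series = [
            (float(copies), grp["cq"].tolist())
            for copies, grp in sub.groupby("copies")
        ]
        series.sort(key=lambda t: -t[0])
        dilution_series[target] = series
    biopsy_cq: dict[str, dict[str, list[float]]] = {}
    for (sample, target), grp in df[df["role"] == "sample"].groupby(["sample", "target"]):
        biopsy_cq.setdefault(sample, {})[target] = grp["cq"].tolist()
    return dilution_series, biopsy_cq


def write_pyroseq(records: list[PyroseqRecord], path) -> None:
    rows = [
        {"biopsy": r.biopsy, "rep1": r.replicates[0], "rep2": r.replicates[1],
         "rep3": r.replicates[2], "is_standard": r.is_standard,
         "true_heteroplasmy": r.true_heteroplasmy}
        for r in records
    ]
    write_table(pd.DataFrame(rows), path, "pyroseq_table")


def read_pyroseq(path) -> list[PyroseqRecord]:
    df = read_table(path, "pyroseq_table")
    return [
        PyroseqRecord(
            biopsy=row["biopsy"],
            replicates=[row["rep1"], row["rep2"], row["rep3"]],
            true_heteroplasmy=row.get("true_heteroplasmy", np.nan),
            is_standard=bool(row.get("is_standard", False)),
        )
        for _, row in df.iterrows()
    ]


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
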