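"""On-disk formats: single-subject JSON dataset files and CSV result tables.

The dataset schema is a documented open JSON format (schema_version
"lvdecomp-1"): coordinates in millimetres in a right-handed patient frame, z
decreasing from base to apex, slices 0-indexed from the base. Unknown fields
are rejected on read; a write→read round trip is lossless (JSON floats use
shortest-repr encoding).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import shapely
from pydantic import BaseModel, ConfigDict, ValidationError

from .decomposition import DecompositionResult
from .errors import InvalidContourError, SchemaError
from .geometry import PlanarContour
from .phantom import GroundTruth
from .volumetry import (
    AVPlaneLandmarkPair,
    CineStudy,
    ShortAxisSlice,
    SubjectMetadata,
)

SCHEMA_VERSION = "lvdecomp-1"

__all__ = [
    "SCHEMA_VERSION",
    "RESULT_COLUMNS",
    "read_dataset",
    "write_dataset",
    "result_row",
    "write_results_table",
    "read_results_table",
]


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class _SliceDoc(_Model):
    index: int
    z_position_mm: float
    epicardium_ed: Optional[list[tuple[float, float]]] = None
    epicardium_es: Optional[list[tuple[float, float]]] = None
    endocardium_ed: Optional[list[tuple[float, float]]] = None
    endocardium_es: Optional[list[tuple[float, float]]] = None
    insertion_anterior: Optional[tuple[float, float]] = None
    insertion_inferior: Optional[tuple[float, float]] = None


class _LandmarkDoc(_Model):
    view: str
    side: int
    position_ed_mm: tuple[float, float, float]
    position_es_mm: tuple[float, float, float]
    long_axis_direction: tuple[float, float, float]


class _MetadataDoc(_Model):
    group: str = "control"
    infarct_size_pct: Optional[float] = None
    transmurality_pct: Optional[float] = None
    heart_rate_bpm: Optional[float] = None


class _GroundTruthDoc(_Model):
    v_long_true_ml: float
    v_sep_true_ml: float
    v_lat_true_ml: float
    sv_true_ml: float
    pct_long_true: float
    pct_sep_true: float
    pct_lat_true: float


class _DatasetDoc(_Model):
    schema_version: str
    spacing_mm: float
    slices: list[_SliceDoc]
    av_landmarks: list[_LandmarkDoc]
    metadata: _MetadataDoc
    ground_truth: Optional[_GroundTruthDoc] = None


def _contour_from_doc(
    points: Optional[list[tuple[float, float]]], slice_index: int, name: str
) -> Optional[PlanarContour]:
    if points is None:
        return None
    try:
        contour = PlanarContour(np.asarray(points, dtype=float))
    except InvalidContourError as exc:
        raise SchemaError(f"slice {slice_index}, {name}: {exc}") from exc
    poly = shapely.Polygon(contour.points)
    if not poly.is_valid:
        raise SchemaError(
            f"slice {slice_index}, {name}: contour is self-intersecting"
        )
    return contour


def read_dataset(path: str | Path) -> CineStudy:
    """Read and validate a single-subject dataset file into a CineStudy."""
    path = Path(path)
    try:
        doc = _DatasetDoc.model_validate_json(path.read_text())
    except ValidationError as exc:
        raise SchemaError(f"{path.name}: {exc}") from exc
    if doc.schema_version != SCHEMA_VERSION:
        raise SchemaError(
            f"{path.name}: unsupported schema_version {doc.schema_version!r} "
            f"(expected {SCHEMA_VERSION!r})"
        )
    slices = []
    for s in doc.slices:
        slices.append(
            ShortAxisSlice(
                index=s.index,
                z_position=s.z_position_mm,
                epicardium_ed=_contour_from_doc(s.epicardium_ed, s.index, "epicardium_ed"),
                epicardium_es=_contour_from_doc(s.epicardium_es, s.index, "epicardium_es"),
                endocardium_ed=_contour_from_doc(s.endocardium_ed, s.index, "endocardium_ed"),
                endocardium_es=_contour_from_doc(s.endocardium_es, s.index, "endocardium_es"),
                insertion_anterior=s.insertion_anterior,
                insertion_inferior=s.insertion_inferior,
            )
        )
    landmarks = [
        AVPlaneLandmarkPair(
            view=lm.view,
            side=lm.side,
            position_ed=np.array(lm.position_ed_mm),
            position_es=np.array(lm.position_es_mm),
            long_axis_direction=np.array(lm.long_axis_direction),
        )
        for lm in doc.av_landmarks
    ]
    gt = GroundTruth(**doc.ground_truth.model_dump()) if doc.ground_truth else None
    study = CineStudy(
        slices=slices,
        av_landmarks=landmarks,
        spacing=doc.spacing_mm,
        metadata=SubjectMetadata(**doc.metadata.model_dump()),
        ground_truth=gt,
    )
    study.validate()
    return study


def _contour_to_doc(c: Optional[PlanarContour]):
    return None if c is None else [tuple(p) for p in c.points.tolist()]


def write_dataset(study: CineStudy, path: str | Path) -> None:
    """Serialize a CineStudy to the JSON dataset format."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "spacing_mm": study.spacing,
        "slices": [
            {
                "index": s.index,
                "z_position_mm": s.z_position,
                "epicardium_ed": _contour_to_doc(s.epicardium_ed),
                "epicardium_es": _contour_to_doc(s.epicardium_es),
                "endocardium_ed": _contour_to_doc(s.endocardium_ed),
                "endocardium_es": _contour_to_doc(s.endocardium_es),
                "insertion_anterior": s.insertion_anterior,
                "insertion_inferior": s.insertion_inferior,
            }
            for s in study.slices
        ],
        "av_landmarks": [
            {
                "view": lm.view,
                "side": lm.side,
                "position_ed_mm": lm.position_ed.tolist(),
                "position_es_mm": lm.position_es.tolist(),
                "long_axis_direction": lm.long_axis_direction.tolist(),
            }
            for lm in study.av_landmarks
        ],
        "metadata": {
            "group": study.metadata.group,
            "infarct_size_pct": study.metadata.infarct_size_pct,
            "transmurality_pct": study.metadata.transmurality_pct,
            "heart_rate_bpm": study.metadata.heart_rate_bpm,
        },
        "ground_truth": (
            None
            if study.ground_truth is None
            else {
                "v_long_true_ml": study.ground_truth.v_long_true_ml,
                "v_sep_true_ml": study.ground_truth.v_sep_true_ml,
                "v_lat_true_ml": study.ground_truth.v_lat_true_ml,
                "sv_true_ml": study.ground_truth.sv_true_ml,
                "pct_long_true": study.ground_truth.pct_long_true,
                "pct_sep_true": study.ground_truth.pct_sep_true,
                "pct_lat_true": study.ground_truth.pct_lat_true,
            }
        ),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


#: fixed column order of the per-subject results table
RESULT_COLUMNS = [
    "subject_id",
    "group",
    "EDV_mL",
    "ESV_mL",
    "SV_mL",
    "EF_pct",
    "AVPD_mm",
    "basal_area_cm2",
    "pct_long",
    "pct_sep",
    "pct_lat",
    "internal_validation_sum_pct",
    "infarct_size_pct",
]


def result_row(subject_id: str, study: CineStudy, result: DecompositionResult) -> dict:
    """One results-table row for a decomposed subject."""
    vol = result.volumes
    return {
        "subject_id": subject_id,
        "group": study.metadata.group,
        "EDV_mL": vol.edv_ml,
        "ESV_mL": vol.esv_ml,
        "SV_mL": vol.sv_ml,
        "EF_pct": vol.ef_pct,
        "AVPD_mm": result.avpd_mm,
        "basal_area_cm2": result.basal_area_cm2,
        "pct_long": result.pct_long,
        "pct_sep": result.pct_sep,
        "pct_lat": result.pct_lat,
        "internal_validation_sum_pct": result.internal_validation_sum,
        "infarct_size_pct": study.metadata.infarct_size_pct,
    }


def write_results_table(rows: list[dict] | pd.DataFrame, path: str | Path) -> None:
    df = pd.DataFrame(rows)
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"results table missing columns: {missing}")
    df[RESULT_COLUMNS].to_csv(path, index=False)


def read_results_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"results table missing columns: {missing}")
    return df
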