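"""Slice-summation LV volumetry and atrioventricular plane displacement.

Volumes follow the standard short-axis slab summation: each slice contributes
its contour area times the slice spacing (8 mm contiguous slices by default in
the acquisition emulated here); no partial basal-slab correction is applied at
the AV plane. AVPD is the mean long-axis projection of the systolic
displacement of six AV-plane landmarks (two per long-axis view), signed so
that apex-directed motion is positive.

Units: mm/mm²/mm³ internally; mL and cm² at reporting boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from typing import TYPE_CHECKING, Any, Optional, Sequence

import numpy as np

from .errors import (
    EmptyStackError,
    InsufficientSlicesError,
    InvalidAxisError,
    LandmarkSetError,
    NegativeStrokeVolumeError,
    StudyValidationError,
)
from .geometry import PlanarContour, polygon_area

if TYPE_CHECKING:  # pragma: no cover
    from .phantom import GroundTruth, PhantomSpec

VIEWS = ("two-chamber", "three-chamber", "four-chamber")
SIDES = (1, 2)

__all__ = [
    "VIEWS",
    "SIDES",
    "ShortAxisSlice",
    "AVPlaneLandmarkPair",
    "VolumeResult",
    "AvpdMeasurement",
    "SubjectMetadata",
    "CineStudy",
    "stack_volume",
    "volume_result",
    "basal_epicardial_area",
    "point_avpd",
    "mean_avpd",
]


@dataclass
class ShortAxisSlice:
    """One short-axis imaging plane; index 0 is the most basal slice.

    Contours may be absent (``None``) when the plane lies outside the LV in
    the given frame, e.g. basal slices traversed by the AV plane at ES or
    apical slices without a lumen.
    """

    index: int
    z_position: float
    epicardium_ed: Optional[PlanarContour] = None
    epicardium_es: Optional[PlanarContour] = None
    endocardium_ed: Optional[PlanarContour] = None
    endocardium_es: Optional[PlanarContour] = None
    insertion_anterior: Optional[tuple[float, float]] = None
    insertion_inferior: Optional[tuple[float, float]] = None

    def contour(self, surface: str, frame: str) -> Optional[PlanarContour]:
        attr = f"{surface}_{frame.lower()}"
        if not hasattr(self, attr):
            raise ValueError(f"unknown surface/frame: {surface}/{frame}")
        return getattr(self, attr)

    @property
    def has_insertions(self) -> bool:
        return self.insertion_anterior is not None and self.insertion_inferior is not None


@dataclass
class AVPlaneLandmarkPair:
    """One AV-plane landmark tracked from ED to ES in a long-axis view."""

    view: str
    side: int
    position_ed: np.ndarray
    position_es: np.ndarray
    long_axis_direction: np.ndarray  # unit vector, base -> apex

    def __post_init__(self) -> None:
        if self.view not in VIEWS:
            raise LandmarkSetError(f"unknown long-axis view {self.view!r}")
        if self.side not in SIDES:
            raise LandmarkSetError(f"landmark side must be 1 or 2, got {self.side}")
        self.position_ed = np.asarray(self.position_ed, dtype=float).reshape(3)
        self.position_es = np.asarray(self.position_es, dtype=float).reshape(3)
        self.long_axis_direction = np.asarray(
            self.long_axis_direction, dtype=float
        ).reshape(3)


@dataclass(frozen=True)
class VolumeResult:
    """EDV/ESV with derived SV and EF (SV = EDV − ESV, EF = 100·SV/EDV)."""

    edv_ml: float
    esv_ml: float
    sv_ml: float
    ef_pct: float


@dataclass(frozen=True)
class AvpdMeasurement:
    per_point_displacements: tuple[float, ...]
    avpd_mean: float


@dataclass
class SubjectMetadata:
    group: str = "control"
    infarct_size_pct: Optional[float] = None
    transmurality_pct: Optional[float] = None
    heart_rate_bpm: Optional[float] = None


@dataclass
class CineStudy:
    """Per-subject analysis unit: ED/ES contour stacks, six AV-plane landmark
    pairs, slice spacing and subject metadata."""

    slices: list[ShortAxisSlice]
    av_landmarks: list[AVPlaneLandmarkPair]
    spacing: float
    metadata: SubjectMetadata = field(default_factory=SubjectMetadata)
    ground_truth: Optional["GroundTruth"] = None
    phantom_spec: Optional["PhantomSpec"] = None

    def validate(self) -> None:
        if not self.slices:
            raise StudyValidationError("study has no slices")
        _check_landmark_set(self.av_landmarks)
        if self.spacing <= 0:
            raise StudyValidationError(f"spacing must be > 0, got {self.spacing}")
        z = np.array([s.z_position for s in self.slices])
        idx = np.array([s.index for s in self.slices])
        if np.any(np.diff(idx) != 1) or idx[0] != 0:
            raise StudyValidationError("slice indices must be 0,1,2,... from the base")
        if len(z) > 1:
            dz = np.diff(z)
            if np.any(dz >= 0):
                raise StudyValidationError(
                    "slices must be ordered base->apex with strictly decreasing z"
                )
            if np.max(np.abs(-dz - self.spacing)) > 1e-6:
                raise StudyValidationError(
                    "slice z positions are not uniformly spaced at the stated spacing"
                )
        for s in self.slices:
            for frame in ("ED", "ES"):
                epi = s.contour("epicardium", frame)
                endo = s.contour("endocardium", frame)
                if epi is not None and endo is not None:
                    if polygon_area(endo) >= polygon_area(epi):
                        raise StudyValidationError(
                            f"slice {s.index} {frame}: endocardial area >= epicardial area"
                        )


def stack_volume(
    slices: Sequence[ShortAxisSlice], surface: str, frame: str, spacing: float
) -> float:
    """Slab-summed volume in mL over slices carrying the requested contour."""
    if spacing <= 0:
        raise ValueError(f"spacing must be > 0, got {spacing}")
    contours = [s.contour(surface, frame) for s in slices]
    present = [c for c in contours if c is not None]
    if not present:
        raise EmptyStackError(f"no slice carries a {surface} contour in {frame}")
    return sum(polygon_area(c) for c in present) * spacing / 1000.0


def volume_result(edv_ml: float, esv_ml: float) -> VolumeResult:
    if edv_ml <= 0:
        raise NegativeStrokeVolumeError(f"EDV must be positive, got {edv_ml}")
    if esv_ml < 0:
        raise NegativeStrokeVolumeError(f"ESV must be non-negative, got {esv_ml}")
    if esv_ml > edv_ml:
        raise NegativeStrokeVolumeError(
            f"ESV ({esv_ml}) exceeds EDV ({edv_ml}); check frame assignment"
        )
    sv = edv_ml - esv_ml
    return VolumeResult(edv_ml=edv_ml, esv_ml=esv_ml, sv_ml=sv, ef_pct=100.0 * sv / edv_ml)


def basal_epicardial_area(
    slices: Sequence[ShortAxisSlice], frame: str = "ED"
) -> tuple[float, tuple[int, int]]:
    """Mean epicardial area (cm²) of the two largest basal slices.

    Candidates are restricted to the basal half of the stack (indices below
    ceil(n/2)) so that mid-ventricular slices of a dilated ventricle are never
    selected; ties are broken toward the base. Returns the selected slice
    indices for audit.
    """
    n = len(slices)
    basal_cut = ceil(n / 2)
    eligible = [
        s
        for s in slices
        if s.index < basal_cut and s.contour("epicardium", frame) is not None
    ]
    if len(eligible) < 2:
        raise InsufficientSlicesError(
            f"need >= 2 basal slices with an epicardial {frame} contour, got {len(eligible)}"
        )
    ranked = sorted(
        eligible,
        key=lambda s: (-polygon_area(s.contour("epicardium", frame)), s.index),
    )
    chosen = ranked[:2]
    mean_mm2 = float(
        np.mean([polygon_area(s.contour("epicardium", frame)) for s in chosen])
    )
    return mean_mm2 / 100.0, (chosen[0].index, chosen[1].index)


def point_avpd(pair: AVPlaneLandmarkPair) -> float:
    """Long-axis projection (mm) of the ED→ES landmark displacement.

    Positive when the AV plane moves toward the apex in systole; in-plane
    translation orthogonal to the axis contributes nothing.
    """
    axis = pair.long_axis_direction
    norm = np.linalg.norm(axis)
    if norm <= 1e-12:
        raise InvalidAxisError("long-axis direction has zero norm")
    return float(np.dot(pair.position_es - pair.position_ed, axis / norm))


def _check_landmark_set(pairs: Sequence[AVPlaneLandmarkPair]) -> None:
    keys = [(p.view, p.side) for p in pairs]
    expected = {(v, s) for v in VIEWS for s in SIDES}
    if len(pairs) != 6 or set(keys) != expected or len(set(keys)) != 6:
        missing = sorted(expected - set(keys))
        extra = sorted(k for k in set(keys) if keys.count(k) > 1)
        raise LandmarkSetError(
            f"expected one landmark pair per view-side; missing={missing}, duplicated={extra}"
        )


def mean_avpd(pairs: Sequence[AVPlaneLandmarkPair]) -> AvpdMeasurement:
    """AVPD as the arithmetic mean of the six per-landmark displacements."""
    _check_landmark_set(pairs)
    values = tuple(point_avpd(p) for p in pairs)
    return AvpdMeasurement(
        per_point_displacements=values, avpd_mean=float(np.mean(values))
    )
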