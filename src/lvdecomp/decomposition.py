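"""Decomposition of LV stroke volume into longitudinal, septal and lateral
pumping.

The longitudinal (piston) component is AVPD times the epicardial area of the
two largest basal slices. The radial component is the volume swept between the
superimposed ED and ES epicardial contours, integrated slice by slice from
base to apex and partitioned into septal and lateral sectors by the RV
insertion points. Septal motion toward the LV lumen counts positive; motion
toward the RV (dyskinesia) counts negative. Percentages are referenced to the
stroke volume from standard volumetry, and their sum is reported as the
internal validation (100% in theory).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .errors import (
    DecompositionError,
    InvalidAreaError,
    LVDecompError,
    NoSeptalDefinitionError,
)
from .geometry import (
    AngularWindow,
    polar_resample,
    polygon_centroid,
    septal_window,
    swept_sector_area,
)
from .volumetry import (
    CineStudy,
    ShortAxisSlice,
    VolumeResult,
    basal_epicardial_area,
    mean_avpd,
    stack_volume,
    volume_result,
)

__all__ = [
    "DecompositionConfig",
    "DecompositionResult",
    "longitudinal_volume",
    "radial_volumes",
    "decompose",
    "internal_validation",
]


@dataclass(frozen=True)
class DecompositionConfig:
    """Tunables of the contour pipeline.

    n_theta: angular grid resolution of the polar resampling (720 = 0.5°,
    giving <0.2% area discretization error on smooth physiological contours).
    """

    n_theta: int = 720


@dataclass
class DecompositionResult:
    avpd_mm: float
    basal_area_cm2: float
    basal_slice_indices: tuple[int, int]
    v_long_ml: float
    v_sep_ml: float
    v_lat_ml: float
    sv_reference_ml: float
    sv_source: str  # "endocardial" or "epicardial"
    pct_long: float
    pct_sep: float
    pct_lat: float
    internal_validation_sum: float
    volumes: Optional[VolumeResult] = None
    windows: dict[int, AngularWindow] = field(default_factory=dict)


def longitudinal_volume(avpd_mm: float, basal_area_cm2: float) -> float:
    """Piston volume in mL: AVPD (mm -> cm) times basal epicardial area (cm²)."""
    if basal_area_cm2 <= 0:
        raise InvalidAreaError(f"basal area must be positive, got {basal_area_cm2}")
    return avpd_mm / 10.0 * basal_area_cm2


def radial_volumes(
    slices: Sequence[ShortAxisSlice],
    spacing: float,
    n_theta: int = 720,
) -> tuple[float, float, dict[int, AngularWindow]]:
    """Septal and lateral swept volumes (mL) summed base->apex.

    Each slice with both ED and ES epicardial contours contributes its swept
    sector areas times the spacing; the common polar center of a slice is the
    centroid of its ED epicardial contour. Slices without their own RV
    insertion landmarks inherit the septal window of the nearest annotated
    slice (toward the base on ties). Slices lacking an ES contour (e.g. basal
    planes traversed by the AV plane in systole) contribute zero.

    Returns (v_sep, v_lat, windows) with the per-slice windows kept for audit.
    """
    annotated = [
        s
        for s in slices
        if s.has_insertions and s.contour("epicardium", "ED") is not None
    ]
    if not annotated:
        raise NoSeptalDefinitionError(
            "no slice carries RV insertion landmarks; septum undefined"
        )
    donor_windows: dict[int, AngularWindow] = {}
    for s in annotated:
        center = polygon_centroid(s.contour("epicardium", "ED"))
        donor_windows[s.index] = septal_window(
            s.insertion_anterior, s.insertion_inferior, center
        )

    v_sep_mm3 = 0.0
    v_lat_mm3 = 0.0
    used: dict[int, AngularWindow] = {}
    for s in slices:
        ed = s.contour("epicardium", "ED")
        es = s.contour("epicardium", "ES")
        if ed is None or es is None:
            continue
        if s.index in donor_windows:
            window = donor_windows[s.index]
        else:
            donor = min(donor_windows, key=lambda i: (abs(i - s.index), i))
            window = donor_windows[donor]
        center = polygon_centroid(ed)
        prof_ed = polar_resample(ed, center, n_theta)
        prof_es = polar_resample(es, center, n_theta)
        v_sep_mm3 += swept_sector_area(prof_ed, prof_es, window) * spacing
        v_lat_mm3 += swept_sector_area(prof_ed, prof_es, window.complement()) * spacing
        used[s.index] = window
    return v_sep_mm3 / 1000.0, v_lat_mm3 / 1000.0, used


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, LVDecompError):
                raise DecompositionError(name, str(exc)) from exc
            return False

    return _Ctx()


def decompose(
    study: CineStudy, config: DecompositionConfig | None = None
) -> DecompositionResult:
    """Full per-subject pipeline: AVPD, basal area, longitudinal and radial
    volumes, reference SV and percentage contributions.

    The reference SV comes from endocardial volumetry when endocardial
    contours are present in both frames (clinical convention), otherwise from
    the epicardial volume difference; for an incompressible wall the two are
    identical.
    """
    if config is None:
        config = DecompositionConfig()

    with _stage("validation"):
        study.validate()
    with _stage("avpd"):
        avpd = mean_avpd(study.av_landmarks)
    with _stage("basal-area"):
        area_cm2, selected = basal_epicardial_area(study.slices, frame="ED")
    with _stage("longitudinal"):
        v_long = longitudinal_volume(avpd.avpd_mean, area_cm2)
    with _stage("radial"):
        v_sep, v_lat, windows = radial_volumes(
            study.slices, study.spacing, config.n_theta
        )

    with _stage("volumetry"):
        has_endo = any(
            s.contour("endocardium", "ED") is not None for s in study.slices
        ) and any(s.contour("endocardium", "ES") is not None for s in study.slices)
        if has_endo:
            edv = stack_volume(study.slices, "endocardium", "ED", study.spacing)
            esv = stack_volume(study.slices, "endocardium", "ES", study.spacing)
            sv_source = "endocardial"
        else:
            edv = stack_volume(study.slices, "epicardium", "ED", study.spacing)
            esv = stack_volume(study.slices, "epicardium", "ES", study.spacing)
            sv_source = "epicardial"
        volumes = volume_result(edv, esv)
        sv_ref = volumes.sv_ml

    pct_long = 100.0 * v_long / sv_ref
    pct_sep = 100.0 * v_sep / sv_ref
    pct_lat = 100.0 * v_lat / sv_ref
    return DecompositionResult(
        avpd_mm=avpd.avpd_mean,
        basal_area_cm2=area_cm2,
        basal_slice_indices=selected,
        v_long_ml=v_long,
        v_sep_ml=v_sep,
        v_lat_ml=v_lat,
        sv_reference_ml=sv_ref,
        sv_source=sv_source,
        pct_long=pct_long,
        pct_sep=pct_sep,
        pct_lat=pct_lat,
        internal_validation_sum=pct_long + pct_sep + pct_lat,
        volumes=volumes,
        windows=windows,
    )


def internal_validation(result: DecompositionResult) -> float:
    """Sum of the three percentage contributions (theoretical value: 100%)."""
    return result.pct_long + result.pct_sep + result.pct_lat
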