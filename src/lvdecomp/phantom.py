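"""Parametric piston-pump LV phantom with analytic ground truth.

The phantom models the LV epicardium at end-diastole as a truncated prolate
ellipsoid (apex at z = 0, base plane at z = L). Systole is prescribed
epicardium-led, as a piston-pump: the AV plane translates apically by the
prescribed AVPD while, below the new base plane, the epicardial radius shrinks
by a sector-dependent fraction (septal vs lateral, with a short cosine blend
between sectors so contours stay smooth and star-shaped). The endocardium is
derived from the epicardium by conserving total wall volume between frames
(incompressible myocardium), so stroke volume is identical from endocardial
and epicardial delineations by construction.

Because the kinematics are analytic, the true longitudinal, septal and lateral
contributions are available in closed form / by quadrature, independent of the
contour pipeline:

    v_long_true = integral over the swept basal slab [L-AVPD, L] of the ED
                  epicardial cross-section area,
    v_sep_true / v_lat_true = sector integrals of the radial area change below
                  the slab,

and their sum equals the epicardial (= endocardial) stroke volume exactly.

Archetype presets (control, LAD-MI, RCA-MI) are calibrated to published group
means of a chronic-infarct cohort: AVPD, basal epicardial area, EDV and SV are
pinned per group, and the radial remainder of SV is split between septum and
lateral wall in the published ratio. Cohort sampling draws spec fields from
independent truncated normals (SD = SE*sqrt(n) of the group statistics).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .errors import GenerationError
from .geometry import TWO_PI, AngularWindow, PlanarContour
from .volumetry import (
    AVPlaneLandmarkPair,
    CineStudy,
    ShortAxisSlice,
    SubjectMetadata,
)

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "CineStudy",
    "generate_study",
    "analytic_ground_truth",
    "sample_cohort",
    "sample_cohort_specs",
    "control_spec",
    "lad_spec",
    "rca_spec",
    "preset_spec",
    "GroupSampling",
    "table2_group_params",
    "GROUP_SIZES",
]

_MIN_CONTOUR_RADIUS = 2.0  # mm; below this a slice is treated as beyond the apex
_MIN_LUMEN_RADIUS = 1.0  # mm; below this no endocardial contour is drawn
_BLEND_HALF_WIDTH = np.deg2rad(5.0)  # cosine ramp spans 10 deg across each sector edge


@dataclass
class PhantomSpec:
    """Generative parameters of one synthetic LV.

    Lengths in mm, shortenings as fractions of the ED epicardial radius
    (negative = dyskinetic outward motion), angles in degrees.
    """

    base_epi_radius: float = 35.77
    long_axis_length: float = 90.0
    wall_thickness: float = 6.5
    avpd: float = 15.4
    radial_shortening_septal: float = 0.075
    radial_shortening_lateral: float = 0.117
    truncation_fraction: float = 0.5
    septal_window_deg: float = 120.0
    septal_center_deg: float = 180.0
    n_slices: Optional[int] = None
    spacing: float = 8.0  # contiguous slices, no gap
    noise_sd: float = 0.0
    seed: int = 0
    n_vertices: int = 360
    group: str = "control"
    infarct_size_pct: Optional[float] = None
    transmurality_pct: Optional[float] = None
    heart_rate_bpm: float = 62.0

    def __post_init__(self) -> None:
        if self.base_epi_radius <= 0 or self.long_axis_length <= 0 or self.spacing <= 0:
            raise GenerationError("radii, lengths and spacing must be positive")
        if not (0.0 < self.truncation_fraction <= 1.0):
            raise GenerationError("truncation_fraction must lie in (0, 1]")
        if self.wall_thickness <= 0 or self.wall_thickness >= self.base_epi_radius:
            raise GenerationError("wall thickness must lie in (0, base radius)")
        if not (0.0 <= self.avpd < self.long_axis_length):
            raise GenerationError("AVPD must lie in [0, long-axis length)")
        for s in (self.radial_shortening_septal, self.radial_shortening_lateral):
            if abs(s) >= 1.0:
                raise GenerationError("|radial shortening| must be < 1")
        if not (0.0 < self.septal_window_deg < 360.0):
            raise GenerationError("septal window must lie in (0, 360) degrees")
        if self.noise_sd < 0:
            raise GenerationError("noise_sd must be >= 0")

    # ---- derived geometry -------------------------------------------------
    @property
    def half_axis(self) -> float:
        """Semi-axis c of the generating ellipsoid along z (apex at z=0)."""
        return self.long_axis_length / (2.0 * self.truncation_fraction)

    @property
    def equatorial_radius(self) -> float:
        c, base_l = self.half_axis, self.long_axis_length
        u = (base_l - c) / c
        return self.base_epi_radius / np.sqrt(1.0 - u * u)

    def epi_radius_ed(self, z):
        """ED epicardial radius at height z (mm above the apex), vectorized."""
        c = self.half_axis
        u = (np.asarray(z, dtype=float) - c) / c
        return self.equatorial_radius * np.sqrt(np.clip(1.0 - u * u, 0.0, None))

    @property
    def septal_window(self) -> AngularWindow:
        half = np.deg2rad(self.septal_window_deg) / 2.0
        center = np.deg2rad(self.septal_center_deg)
        return AngularWindow(center - half, center + half, "septal")

    def shortening(self, theta):
        """Radial shortening fraction at angle theta (blended sector profile)."""
        win = self.septal_window
        h = _BLEND_HALF_WIDTH
        d0 = _wrap_pi(np.asarray(theta) - win.start)
        d1 = _wrap_pi(win.end - np.asarray(theta))
        weight = _ramp(d0, h) * _ramp(d1, h)
        return self.radial_shortening_lateral + weight * (
            self.radial_shortening_septal - self.radial_shortening_lateral
        )


def _wrap_pi(a):
    return np.mod(np.asarray(a) + np.pi, TWO_PI) - np.pi


def _ramp(d, h):
    """0 below -h, 1 above +h, cosine-smooth in between."""
    return np.where(
        d <= -h, 0.0, np.where(d >= h, 1.0, 0.5 * (1.0 + np.sin(0.5 * np.pi * d / h)))
    )


# ---- analytic volumes ------------------------------------------------------


def _int_r2(spec: PhantomSpec, z0: float, z1: float) -> float:
    """Closed-form integral of epicardial radius^2 dz over [z0, z1] (mm^3)."""
    c, r_eq = spec.half_axis, spec.equatorial_radius

    def antideriv(z):
        return z - (z - c) ** 3 / (3.0 * c * c)

    return r_eq**2 * (antideriv(z1) - antideriv(z0))


def _epi_volume_ed(spec: PhantomSpec) -> float:
    return np.pi * _int_r2(spec, 0.0, spec.long_axis_length)


def _endo_volume_ed(spec: PhantomSpec, wall: Optional[float] = None) -> float:
    """ED endocardial cavity volume (mm^3) for a uniform wall thickness."""
    w = spec.wall_thickness if wall is None else wall
    r_eq, c, base_l = spec.equatorial_radius, spec.half_axis, spec.long_axis_length
    if w >= r_eq:
        return 0.0
    z_apex = c - c * np.sqrt(1.0 - (w / r_eq) ** 2)  # lumen apex where r(z) = w
    z_apex = max(z_apex, 0.0)
    val, _ = quad(
        lambda z: np.pi * max(spec.epi_radius_ed(z) - w, 0.0) ** 2, z_apex, base_l
    )
    return val


def _mean_sq_remaining(spec: PhantomSpec, m: int = 7200) -> float:
    """Angular mean of (1 - shortening)^2, i.e. the ES/ED epi area ratio."""
    theta = np.arange(m) * (TWO_PI / m)
    return float(np.mean((1.0 - spec.shortening(theta)) ** 2))


def _es_shoulder_length(spec: PhantomSpec) -> float:
    """Axial length (mm) over which the ES cavity tapers to the closed
    mitral annulus (13% of the long axis, ~12 mm for a normal ventricle)."""
    return min(0.13 * spec.long_axis_length, 0.4 * (spec.long_axis_length - spec.avpd))


def _es_cavity_taper(spec: PhantomSpec, z):
    """Basal taper factor g(z) of the ES endocardial cavity.

    1 below the shoulder, falling smoothly to 0 at the ES base plane (with
    zero slope of the cross-sectional area at closure): at end-systole the
    cavity closes toward the mitral annulus rather than ending in a wide
    flat cut.
    """
    z = np.asarray(z, dtype=float)
    base_es = spec.long_axis_length - spec.avpd
    lam = _es_shoulder_length(spec)
    u = np.clip((z - (base_es - lam)) / lam, 0.0, 1.0)
    return 1.0 - u * u


def _endo_es_scale(spec: PhantomSpec) -> float:
    """Scale factor k0 mapping the (tapered) ES epicardial shape to the ES
    endocardium so that total wall volume is conserved between frames."""
    wall = _epi_volume_ed(spec) - _endo_volume_ed(spec)
    base_es = spec.long_axis_length - spec.avpd
    kappa = _mean_sq_remaining(spec)
    v_epi_es = kappa * np.pi * _int_r2(spec, 0.0, base_es)
    v_endo_es = v_epi_es - wall
    if v_endo_es <= 0.0:
        raise GenerationError(
            "prescribed kinematics leave no end-systolic cavity (ESV <= 0)"
        )
    lam = _es_shoulder_length(spec)
    v_taper, _ = quad(
        lambda z: kappa
        * np.pi
        * float(spec.epi_radius_ed(z)) ** 2
        * float(_es_cavity_taper(spec, z)) ** 2,
        0.0,
        base_es,
        points=[base_es - lam],
    )
    k0 = float(np.sqrt(v_endo_es / v_taper))
    if k0 >= 0.98:
        raise GenerationError(
            "wall too thin: ES endocardium would reach the epicardium"
        )
    return k0


@dataclass(frozen=True)
class GroundTruth:
    """Analytic (continuous, pipeline-independent) decomposition of the
    phantom's stroke volume; the three components sum to sv_true exactly."""

    v_long_true_ml: float
    v_sep_true_ml: float
    v_lat_true_ml: float
    sv_true_ml: float
    pct_long_true: float
    pct_sep_true: float
    pct_lat_true: float


def analytic_ground_truth(spec: PhantomSpec, m_theta: int = 7200) -> GroundTruth:
    """Quadrature of the generative model, independent of the contour pipeline."""
    base_l, d = spec.long_axis_length, spec.avpd
    v_long = np.pi * _int_r2(spec, base_l - d, base_l) / 1000.0

    theta = np.arange(m_theta) * (TWO_PI / m_theta)
    g = 1.0 - (1.0 - spec.shortening(theta)) ** 2
    dtheta = TWO_PI / m_theta
    iz2 = _int_r2(spec, 0.0, base_l - d)
    sep_mask = spec.septal_window.contains(theta)
    v_sep = 0.5 * iz2 * float(np.sum(g[sep_mask])) * dtheta / 1000.0
    v_lat = 0.5 * iz2 * float(np.sum(g[~sep_mask])) * dtheta / 1000.0

    sv = v_long + v_sep + v_lat
    if sv > 0:
        pcts = (100.0 * v_long / sv, 100.0 * v_sep / sv, 100.0 * v_lat / sv)
    else:
        pcts = (np.nan, np.nan, np.nan)
    return GroundTruth(
        v_long_true_ml=v_long,
        v_sep_true_ml=v_sep,
        v_lat_true_ml=v_lat,
        sv_true_ml=sv,
        pct_long_true=pcts[0],
        pct_sep_true=pcts[1],
        pct_lat_true=pcts[2],
    )


# ---- contour synthesis -----------------------------------------------------


def _circle_contour(radii, theta) -> PlanarContour:
    pts = np.stack([radii * np.cos(theta), radii * np.sin(theta)], axis=1)
    return PlanarContour(pts)


_LANDMARK_ANGLES_DEG = {
    ("two-chamber", 1): 90.0,
    ("two-chamber", 2): 270.0,
    ("three-chamber", 1): 150.0,
    ("three-chamber", 2): 330.0,
    ("four-chamber", 1): 30.0,
    ("four-chamber", 2): 210.0,
}


def generate_study(spec: PhantomSpec) -> CineStudy:
    """Synthesize the contour stacks, insertion landmarks and AV-plane
    landmark pairs of one subject; reproducible from ``spec.seed``.

    Gaussian radial noise of SD ``noise_sd`` is added independently per
    contour vertex when ``noise_sd > 0``. RV insertion landmarks are placed on
    slices where the epicardial radius exceeds 40% of the basal radius
    (apical slices, where the RV is no longer visible, are left unannotated
    and inherit their septal window downstream).
    """
    rng = np.random.default_rng(spec.seed)
    base_l, d, spacing = spec.long_axis_length, spec.avpd, spec.spacing
    n_slices = spec.n_slices or max(int(base_l // spacing), 3)
    theta_v = np.arange(spec.n_vertices) * (TWO_PI / spec.n_vertices)
    s_theta = spec.shortening(theta_v)
    k_endo = _endo_es_scale(spec)
    win = spec.septal_window

    def noisy(r_base) -> np.ndarray:
        r = np.broadcast_to(np.asarray(r_base, dtype=float), theta_v.shape).copy()
        if spec.noise_sd > 0:
            r += rng.normal(0.0, spec.noise_sd, spec.n_vertices)
        if np.any(r <= 0.2):
            raise GenerationError(
                "generated contour has non-positive radius (noise too large "
                "or geometry too small); contour would not be star-shaped"
            )
        return r

    slices: list[ShortAxisSlice] = []
    for k in range(n_slices):
        z = base_l - spacing * (k + 0.5)
        sl = ShortAxisSlice(index=k, z_position=z)
        r_ed = float(spec.epi_radius_ed(z))
        if r_ed >= _MIN_CONTOUR_RADIUS:
            sl.epicardium_ed = _circle_contour(noisy(r_ed), theta_v)
            if r_ed - spec.wall_thickness > _MIN_LUMEN_RADIUS:
                sl.endocardium_ed = _circle_contour(
                    noisy(r_ed - spec.wall_thickness), theta_v
                )
            if z <= base_l - d + 1e-9:
                r_es = (1.0 - s_theta) * r_ed
                sl.epicardium_es = _circle_contour(noisy(r_es), theta_v)
                r_endo_es = k_endo * float(_es_cavity_taper(spec, z)) * r_es
                if float(np.min(r_endo_es)) > _MIN_LUMEN_RADIUS:
                    sl.endocardium_es = _circle_contour(noisy(r_endo_es), theta_v)
            if r_ed >= 0.4 * spec.base_epi_radius:
                sl.insertion_inferior = (
                    r_ed * np.cos(win.start),
                    r_ed * np.sin(win.start),
                )
                sl.insertion_anterior = (
                    r_ed * np.cos(win.end),
                    r_ed * np.sin(win.end),
                )
        slices.append(sl)

    axis = np.array([0.0, 0.0, -1.0])  # base -> apex
    r_base_es = float(spec.epi_radius_ed(base_l - d))
    landmarks = []
    for (view, side), ang_deg in _LANDMARK_ANGLES_DEG.items():
        phi = np.deg2rad(ang_deg)
        r_ed = spec.base_epi_radius
        r_es = (1.0 - float(spec.shortening(phi))) * r_base_es
        landmarks.append(
            AVPlaneLandmarkPair(
                view=view,
                side=side,
                position_ed=np.array([r_ed * np.cos(phi), r_ed * np.sin(phi), base_l]),
                position_es=np.array(
                    [r_es * np.cos(phi), r_es * np.sin(phi), base_l - d]
                ),
                long_axis_direction=axis,
            )
        )

    study = CineStudy(
        slices=slices,
        av_landmarks=landmarks,
        spacing=spacing,
        metadata=SubjectMetadata(
            group=spec.group,
            infarct_size_pct=spec.infarct_size_pct,
            transmurality_pct=spec.transmurality_pct,
            heart_rate_bpm=spec.heart_rate_bpm,
        ),
        ground_truth=analytic_ground_truth(spec),
        phantom_spec=spec,
    )
    study.validate()
    return study


# ---- presets calibrated to published group means ---------------------------

#: group means used for calibration: AVPD (mm), basal epicardial area (cm^2),
#: EDV (mL), SV (mL), septal and lateral contributions (% of SV), heart rate,
#: infarct size and transmurality (% | None for controls). Long-axis length is
#: a package choice (dilated ventricles are longer); see the methods note.
_GROUP_MEANS = {
    "control": dict(
        avpd=15.4, area=40.2, edv=163.0, sv=97.0, pct_sep=9.5, pct_lat=29.2,
        length=90.0, hr=62.0, infarct=None, transmurality=None,
    ),
    "rca": dict(
        avpd=13.0, area=44.5, edv=202.0, sv=98.0, pct_sep=9.9, pct_lat=34.7,
        length=95.0, hr=66.0, infarct=11.6, transmurality=75.0,
    ),
    "lad": dict(
        avpd=11.0, area=49.7, edv=277.0, sv=91.0, pct_sep=5.1, pct_lat=43.5,
        length=105.0, hr=62.0, infarct=22.3, transmurality=81.0,
    ),
}

#: group sizes of the emulated cohort
GROUP_SIZES = {"lad": 20, "rca": 16, "control": 20}

#: standard errors of the group means used for cohort spread (same units)
_GROUP_SE = {
    "control": dict(avpd=0.4, area=1.4, pct_sep=1.0, pct_lat=1.6, hr=2.0,
                    infarct=None, transmurality=None),
    "rca": dict(avpd=0.7, area=1.7, pct_sep=0.8, pct_lat=2.1, hr=2.0,
                infarct=1.0, transmurality=2.0),
    "lad": dict(avpd=0.7, area=2.7, pct_sep=1.1, pct_lat=3.4, hr=3.0,
                infarct=2.1, transmurality=2.0),
}


def _radial_split(
    spec_like: PhantomSpec, avpd: float, sv_ml: float, pct_sep: float, pct_lat: float
) -> tuple[float, float, float, float]:
    """Solve sector shortenings so the phantom's radial volumes split the
    non-piston remainder of SV in the prescribed sep:lat ratio.

    Returns (s_sep, s_lat, dv_sep/ds, dv_lat/ds) with the sensitivities (mL per
    unit shortening) used to convert percentage SDs into shortening SDs.
    """
    v_long = avpd / 10.0 * np.pi * spec_like.base_epi_radius**2 / 100.0
    radial = sv_ml - v_long
    if radial <= 0:
        raise GenerationError("SV target smaller than the piston volume alone")
    v_sep_t = radial * pct_sep / (pct_sep + pct_lat)
    v_lat_t = radial - v_sep_t
    iz2 = _int_r2(spec_like, 0.0, spec_like.long_axis_length - avpd)
    w_sep = np.deg2rad(spec_like.septal_window_deg)
    w_lat = TWO_PI - w_sep

    def solve(v_ml, w):
        x = v_ml * 1000.0 / (0.5 * iz2 * w)
        if x >= 1.0:
            raise GenerationError("required radial shortening is unphysical (>= 100%)")
        s = 1.0 - np.sqrt(1.0 - x)
        sens = 0.5 * iz2 * w * 2.0 * (1.0 - s) / 1000.0  # d v / d s, mL
        return float(s), float(sens)

    s_sep, sens_sep = solve(v_sep_t, w_sep)
    s_lat, sens_lat = solve(v_lat_t, w_lat)
    return s_sep, s_lat, sens_sep, sens_lat


def preset_spec(group: str, *, noise_sd: float = 0.0, seed: int = 0) -> PhantomSpec:
    """Phantom spec calibrated to the given group's published means."""
    if group not in _GROUP_MEANS:
        raise KeyError(f"unknown preset {group!r}; choose from {sorted(_GROUP_MEANS)}")
    m = _GROUP_MEANS[group]
    base_r = float(np.sqrt(m["area"] * 100.0 / np.pi))
    trial = PhantomSpec(
        base_epi_radius=base_r,
        long_axis_length=m["length"],
        wall_thickness=base_r / 4.0,  # placeholder, solved below
        avpd=m["avpd"],
        radial_shortening_septal=0.05,
        radial_shortening_lateral=0.05,
    )
    wall = brentq(
        lambda w: _endo_volume_ed(trial, wall=w) - m["edv"] * 1000.0,
        0.5,
        base_r - 2.0,
    )
    s_sep, s_lat, _, _ = _radial_split(trial, m["avpd"], m["sv"], m["pct_sep"], m["pct_lat"])
    return PhantomSpec(
        base_epi_radius=base_r,
        long_axis_length=m["length"],
        wall_thickness=float(wall),
        avpd=m["avpd"],
        radial_shortening_septal=s_sep,
        radial_shortening_lateral=s_lat,
        noise_sd=noise_sd,
        seed=seed,
        group=group,
        infarct_size_pct=m["infarct"],
        transmurality_pct=m["transmurality"],
        heart_rate_bpm=m["hr"],
    )


def control_spec(**kw) -> PhantomSpec:
    return preset_spec("control", **kw)


def lad_spec(**kw) -> PhantomSpec:
    return preset_spec("lad", **kw)


def rca_spec(**kw) -> PhantomSpec:
    return preset_spec("rca", **kw)


# ---- cohort sampling -------------------------------------------------------


@dataclass
class GroupSampling:
    """Per-group sampling distribution: a mean spec plus per-field SDs."""

    mean_spec: PhantomSpec
    sd: dict[str, float] = field(default_factory=dict)
    n: int = 20


#: hard validity bounds applied after truncated-normal draws
_FIELD_BOUNDS = {
    "avpd": (0.0, 30.0),
    "base_epi_radius": (10.0, 80.0),
    "radial_shortening_septal": (-0.5, 0.9),
    "radial_shortening_lateral": (-0.5, 0.9),
    "wall_thickness": (1.0, 25.0),
    "heart_rate_bpm": (30.0, 150.0),
    "infarct_size_pct": (0.0, 100.0),
    "transmurality_pct": (0.0, 100.0),
}


def table2_group_params(noise_sd: float = 0.0) -> dict[str, GroupSampling]:
    """Sampling distributions emulating the published cohort.

    Group-mean specs come from the presets; per-subject SDs are the published
    SEs scaled by sqrt(n). Percentage-scale spreads (basal area, septal and
    lateral contributions) are converted to spec-field SDs through the
    analytic sensitivities of the generative model.
    """
    params: dict[str, GroupSampling] = {}
    for group, m in _GROUP_MEANS.items():
        spec = preset_spec(group, noise_sd=noise_sd)
        se = _GROUP_SE[group]
        n = GROUP_SIZES[group]
        rt_n = np.sqrt(n)
        _, _, sens_sep, sens_lat = _radial_split(
            spec, m["avpd"], m["sv"], m["pct_sep"], m["pct_lat"]
        )
        sd = {
            "avpd": se["avpd"] * rt_n,
            # area SD (cm^2 -> mm^2) to radius SD via dA = 2*pi*r*dr
            "base_epi_radius": se["area"] * rt_n * 100.0
            / (2.0 * np.pi * spec.base_epi_radius),
            # pct SD -> volume SD (mL) -> shortening SD via d v / d s
            "radial_shortening_septal": se["pct_sep"] * rt_n / 100.0 * m["sv"] / sens_sep,
            "radial_shortening_lateral": se["pct_lat"] * rt_n / 100.0 * m["sv"] / sens_lat,
            "heart_rate_bpm": se["hr"] * rt_n,
        }
        if se["infarct"] is not None:
            sd["infarct_size_pct"] = se["infarct"] * rt_n
            sd["transmurality_pct"] = se["transmurality"] * rt_n
        params[group] = GroupSampling(mean_spec=spec, sd=sd, n=n)
    return params


def sample_cohort_specs(
    group_params: dict[str, GroupSampling] | None = None,
    n_per_group: int | dict[str, int] | None = None,
    seed: int = 0,
) -> list[PhantomSpec]:
    """Draw independent per-subject phantom specs for each group.

    Fields listed in each group's ``sd`` mapping are drawn from normals
    truncated at +/- 3 SD (then clipped to hard validity bounds); all other
    fields are inherited from the group mean spec. Reproducible from ``seed``.
    """
    if group_params is None:
        group_params = table2_group_params()
    rng = np.random.default_rng(seed)
    specs: list[PhantomSpec] = []
    for group, gp in group_params.items():
        n = gp.n if n_per_group is None else (
            n_per_group if isinstance(n_per_group, int) else n_per_group[group]
        )
        if n < 2:
            raise GenerationError(f"need n >= 2 subjects per group, got {n} for {group}")
        for _ in range(n):
            draws = {}
            for fname, sd in gp.sd.items():
                mean = getattr(gp.mean_spec, fname)
                if mean is None:
                    continue
                if sd > 0:
                    val = float(truncnorm.rvs(-3.0, 3.0, loc=mean, scale=sd, random_state=rng))
                else:
                    val = float(mean)
                lo, hi = _FIELD_BOUNDS.get(fname, (-np.inf, np.inf))
                draws[fname] = min(max(val, lo), hi)
            child_seed = int(rng.integers(0, 2**31 - 1))
            specs.append(replace(gp.mean_spec, seed=child_seed, **draws))
    return specs


def sample_cohort(
    group_params: dict[str, GroupSampling] | None = None,
    n_per_group: int | dict[str, int] | None = None,
    seed: int = 0,
) -> list[CineStudy]:
    """Sample specs (see :func:`sample_cohort_specs`) and generate the studies."""
    return [generate_study(s) for s in sample_cohort_specs(group_params, n_per_group, seed)]
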