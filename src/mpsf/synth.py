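"""Seedable synthetic cohorts of eyes with drusen and hyperreflective foci.

The generator emulates the measurement products of a longitudinal
imaging study in early/intermediate non-exudative AMD: per-eye en-face
drusen thickness maps (sums of isotropic 2D Gaussian elevations of the
RPE concentrated around the fovea), sparse hyperreflective-foci (HRF)
thickness maps (small lesion discs preferentially colocalized with
drusen), quarterly growth of both lesion types over up to five visits,
a ground-truth fundus-photo-to-OCT affine per eye with noisy keypoint
pairs, and per-stimulus retinal sensitivities drawn from a known linear
model with nested patient / eye / stimulus random intercepts and then
measured through the 4-2-1 staircase simulator.

Default parameters are calibrated so that, at baseline, about 73.5% of
stimuli overlie drusen, about 2% overlie HRF, and the mean measured
sensitivity is about 25.7 dB; the default fixed effects of the
sensitivity model equal the coefficients the analysis stage is expected
to recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .enface import EnfaceMap, QuantConfig, hrf_roi_volume, roi_mask, roi_volume
from .geometry import DEFAULT_GEOMETRY, ScanGeometry
from .grid import StimulusGrid, generate_default_grid
from .registration import AffineTransform
from .staircase import DB_MAX, DB_MIN, simulate_exam


class ConfigurationError(ValueError):
    """Raised for infeasible or inconsistent generator settings."""


# ---------------------------------------------------------------------------
# parameter blocks


@dataclass(frozen=True)
class DrusenFieldParams:
    """Shape of the per-eye drusen elevation field.

    Drusen are modelled as isotropic Gaussian elevations whose centres
    cluster around the fovea; amplitudes and footprints are log-normal.
    ``min_thickness_um`` is the segmentation resolution: final map values
    below it are recorded as zero, which bounds each druse's footprint.
    """

    mean_bumps: float = 11.8
    amplitude_median_um: float = 30.0
    amplitude_sigma_log: float = 0.9
    sigma_median_deg: float = 0.45
    sigma_sigma_log: float = 0.35
    foveal_concentration_sd_deg: float = 2.55
    background_amplitude_um: float = 0.0
    background_sigma_deg: float = 6.0
    min_thickness_um: float = 1.0
    growth_rate_per_visit: float = 1.05

    def __post_init__(self) -> None:
        if self.mean_bumps < 0:
            raise ConfigurationError("mean_bumps must be >= 0")
        if self.amplitude_median_um <= 0 or self.sigma_median_deg <= 0:
            raise ConfigurationError("amplitude and sigma medians must be positive")
        if self.growth_rate_per_visit < 1.0:
            raise ConfigurationError("growth_rate_per_visit must be >= 1")
        if self.min_thickness_um < 0:
            raise ConfigurationError("min_thickness_um must be >= 0")


@dataclass(frozen=True)
class HRFFieldParams:
    """Shape of the sparse hyperreflective-foci field.

    Foci are small parabolic-profile discs; their centres are sampled
    with probability weighted toward drusen-positive raster cells
    (HRF sit above drusen), and their total volumes are log-normal,
    truncated below at the detectability floor used by quantification.
    """

    blob_rate: float = 4.3
    volume_median_mm3: float = 1.1e-4
    volume_sigma_log: float = 0.45
    volume_floor_mm3: float = 6e-5
    radius_min_um: float = 55.0
    radius_max_um: float = 110.0
    colocalization_weight: float = 200.0
    growth_rate_per_visit: float = 1.05

    def __post_init__(self) -> None:
        if self.blob_rate < 0:
            raise ConfigurationError("blob_rate must be >= 0")
        if self.volume_median_mm3 <= 0 or self.volume_floor_mm3 <= 0:
            raise ConfigurationError("volumes must be positive")
        if not (0 < self.radius_min_um <= self.radius_max_um):
            raise ConfigurationError("invalid radius range")
        if self.colocalization_weight < 0:
            raise ConfigurationError("colocalization_weight must be >= 0")
        if self.growth_rate_per_visit < 1.0:
            raise ConfigurationError("growth_rate_per_visit must be >= 1")


@dataclass(frozen=True)
class TrueEffects:
    """Generative linear model for per-stimulus retinal sensitivity (dB).

    sensitivity = intercept + beta_visit * visit + beta_ecc * ecc
                  + beta_drusen * V_d + beta_hrf * V_h
                  + beta_drusen_visit * V_d * visit
                  + beta_drusen_ecc * V_d * ecc
                  + u_patient + u_eye + u_spot  (+ residual),  clamped to 0-34

    with volumes in 1e-3 mm^3 units and eccentricity in degrees.
    The default coefficients are the effect sizes the analysis stage is
    designed to recover; the intercept is set so the baseline marginal
    mean of *measured* sensitivity is ~25.7 dB under the default fields.
    """

    intercept_db: float = 26.43
    beta_drusen: float = -0.991
    beta_hrf: float = -5.230
    beta_visit: float = 0.242
    beta_ecc: float = 0.086
    beta_drusen_visit: float = -0.02
    beta_drusen_ecc: float = -0.02
    sd_patient: float = 1.5
    sd_eye: float = 1.0
    sd_spot: float = 1.5
    sd_resid: float = 1.0

    def __post_init__(self) -> None:
        for sd in (self.sd_patient, self.sd_eye, self.sd_spot, self.sd_resid):
            if sd < 0:
                raise ConfigurationError("random-effect SDs must be >= 0")

    def linear_predictor(self, visit, ecc_deg, drusen_vol, hrf_vol):
        return (self.intercept_db
                + self.beta_visit * visit
                + self.beta_ecc * ecc_deg
                + self.beta_drusen * drusen_vol
                + self.beta_hrf * hrf_vol
                + self.beta_drusen_visit * drusen_vol * visit
                + self.beta_drusen_ecc * drusen_vol * ecc_deg)


@dataclass(frozen=True)
class ObserverParams:
    """Psychometric parameters shared by all simulated examinations."""

    slope_sd_db: float = 0.5
    false_pos_rate: float = 0.03
    false_neg_rate: float = 0.03
    start_level_db: float = 17.0


@dataclass(frozen=True)
class RegistrationTruthParams:
    """Family of ground-truth fundus-photo frames and keypoint noise."""

    cfp_scale_px_per_deg: float = 30.0
    rotation_max_deg: float = 5.0
    axis_scale_min: float = 0.9
    axis_scale_max: float = 1.1
    fovea_cfp_centre: tuple[float, float] = (400.0, 300.0)
    fovea_cfp_jitter_px: float = 50.0
    n_keypoints: int = 6
    keypoint_jitter_px: float = 0.5

    def __post_init__(self) -> None:
        if self.n_keypoints < 3:
            raise ConfigurationError("need at least 3 keypoints per eye")
        if not (0 < self.axis_scale_min <= self.axis_scale_max):
            raise ConfigurationError("invalid axis scale range")


@dataclass(frozen=True)
class CohortConfig:
    """Everything needed to simulate one longitudinal cohort."""

    n_patients: int = 35
    n_eyes: int = 51
    n_visits: int = 5
    geometry: ScanGeometry = DEFAULT_GEOMETRY
    drusen: DrusenFieldParams = DrusenFieldParams()
    hrf: HRFFieldParams = HRFFieldParams()
    effects: TrueEffects = TrueEffects()
    observer: ObserverParams = ObserverParams()
    registration: RegistrationTruthParams = RegistrationTruthParams()
    quant: QuantConfig = QuantConfig()
    growth_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_visits < 1:
            raise ConfigurationError("need at least one patient and one visit")
        if not (self.n_patients <= self.n_eyes <= 2 * self.n_patients):
            raise ConfigurationError(
                "n_eyes must lie between n_patients and 2 * n_patients")


# ---------------------------------------------------------------------------
# field simulation


def simulate_drusen_field(
    geometry: ScanGeometry,
    params: DrusenFieldParams,
    rng_seed,
    fovea_px: tuple[float, float] | None = None,
) -> EnfaceMap:
    """Draw one drusen thickness map (um) on the raster.

    The number of drusen is Poisson; each is an isotropic Gaussian
    elevation in physical (mm) coordinates, its centre normal around the
    fovea.  Values below ``min_thickness_um`` are zeroed afterwards.
    Identical seeds give bit-identical maps.
    """
    rng = _as_rng(rng_seed)
    if fovea_px is None:
        fovea_px = geometry.centre_px
    values = np.zeros(geometry.shape)
    n_bumps = rng.poisson(params.mean_bumps)
    for _ in range(n_bumps):
        cx_deg, cy_deg = rng.normal(0.0, params.foveal_concentration_sd_deg, 2)
        amp = params.amplitude_median_um * math.exp(
            rng.normal(0.0, params.amplitude_sigma_log))
        sigma_deg = params.sigma_median_deg * math.exp(
            rng.normal(0.0, params.sigma_sigma_log))
        _add_gaussian_bump(values, geometry, fovea_px, cx_deg, cy_deg,
                           amp, sigma_deg, params.min_thickness_um)
    if params.background_amplitude_um > 0:
        _add_gaussian_bump(values, geometry, fovea_px, 0.0, 0.0,
                           params.background_amplitude_um,
                           params.background_sigma_deg, 0.0)
    if params.min_thickness_um > 0:
        values[values < params.min_thickness_um] = 0.0
    return EnfaceMap(values, geometry)


def _as_rng(rng_seed) -> np.random.Generator:
    if isinstance(rng_seed, np.random.Generator):
        return rng_seed
    return np.random.default_rng(rng_seed)


def _add_gaussian_bump(values, geometry, fovea_px, cx_deg, cy_deg,
                       amplitude_um, sigma_deg, min_thickness_um) -> None:
    """Accumulate one isotropic Gaussian elevation in place.

    Evaluation is restricted to the bounding box where the bump exceeds
    max(min_thickness_um, 1e-3) um, which keeps the truncated volume
    below ~0.02% of the analytic Gaussian volume.
    """
    sigma_mm = sigma_deg * geometry.mm_per_degree
    cutoff = max(min_thickness_um, 1e-3)
    if amplitude_um <= cutoff:
        return
    r_max_mm = sigma_mm * math.sqrt(2.0 * math.log(amplitude_um / cutoff))
    cx_px = fovea_px[0] + cx_deg * geometry.mm_per_degree / geometry.ascan_spacing_mm
    cy_px = fovea_px[1] + cy_deg * geometry.mm_per_degree / geometry.bscan_spacing_mm
    rx_px = r_max_mm / geometry.ascan_spacing_mm
    ry_px = r_max_mm / geometry.bscan_spacing_mm
    i_lo = max(0, math.ceil(cx_px - rx_px))
    i_hi = min(geometry.n_ascan - 1, math.floor(cx_px + rx_px))
    j_lo = max(0, math.ceil(cy_px - ry_px))
    j_hi = min(geometry.n_bscan - 1, math.floor(cy_px + ry_px))
    if i_hi < i_lo or j_hi < j_lo:
        return
    dx_mm = (np.arange(i_lo, i_hi + 1) - cx_px) * geometry.ascan_spacing_mm
    dy_mm = (np.arange(j_lo, j_hi + 1) - cy_px) * geometry.bscan_spacing_mm
    r2 = dx_mm[None, :] ** 2 + dy_mm[:, None] ** 2
    bump = amplitude_um * np.exp(-r2 / (2.0 * sigma_mm**2))
    bump[bump < cutoff] = 0.0
    values[j_lo:j_hi + 1, i_lo:i_hi + 1] += bump


def simulate_hrf_field(
    geometry: ScanGeometry,
    drusen_map: EnfaceMap,
    params: HRFFieldParams,
    rng_seed,
) -> EnfaceMap:
    """Draw one sparse HRF thickness map (um) on the raster.

    Focus count is Poisson; each centre is a raster cell sampled with
    weight ``1 + colocalization_weight`` on drusen-positive cells versus
    1 elsewhere, so large weights confine foci to drusen.  Each focus is
    a parabolic disc whose radius is uniform and whose total volume is
    log-normal truncated at the floor.
    """
    if drusen_map.geometry.shape != geometry.shape:
        from .enface import ShapeError
        raise ShapeError("drusen map raster does not match geometry")
    rng = _as_rng(rng_seed)
    values = np.zeros(geometry.shape)
    n_blobs = rng.poisson(params.blob_rate)
    if n_blobs == 0:
        return EnfaceMap(values, geometry)
    weights = np.where(drusen_map.values > 0, 1.0 + params.colocalization_weight, 1.0)
    flat = weights.ravel()
    probs = flat / flat.sum()
    cells = rng.choice(flat.size, size=n_blobs, p=probs)
    for cell in cells:
        j, i = divmod(int(cell), geometry.n_ascan)
        radius_um = rng.uniform(params.radius_min_um, params.radius_max_um)
        volume = params.volume_median_mm3 * math.exp(
            rng.normal(0.0, params.volume_sigma_log))
        volume = max(volume, params.volume_floor_mm3)
        _add_parabolic_disc(values, geometry, float(i), float(j), radius_um, volume)
    return EnfaceMap(values, geometry)


def _add_parabolic_disc(values, geometry, cx_px, cy_px, radius_um, volume_mm3) -> None:
    """Accumulate a parabolic-profile disc of the given total volume."""
    r_mm = radius_um / 1000.0
    peak_um = 2.0 * volume_mm3 / (math.pi * r_mm**2) * 1000.0
    rx_px = r_mm / geometry.ascan_spacing_mm
    ry_px = r_mm / geometry.bscan_spacing_mm
    i_lo = max(0, math.ceil(cx_px - rx_px))
    i_hi = min(geometry.n_ascan - 1, math.floor(cx_px + rx_px))
    j_lo = max(0, math.ceil(cy_px - ry_px))
    j_hi = min(geometry.n_bscan - 1, math.floor(cy_px + ry_px))
    if i_hi < i_lo or j_hi < j_lo:
        return
    dx_mm = (np.arange(i_lo, i_hi + 1) - cx_px) * geometry.ascan_spacing_mm
    dy_mm = (np.arange(j_lo, j_hi + 1) - cy_px) * geometry.bscan_spacing_mm
    r2 = dx_mm[None, :] ** 2 + dy_mm[:, None] ** 2
    disc = peak_um * np.maximum(1.0 - r2 / r_mm**2, 0.0)
    values[j_lo:j_hi + 1, i_lo:i_hi + 1] += disc


# ---------------------------------------------------------------------------
# eye state and longitudinal evolution


@dataclass
class EyeState:
    """One eye at one visit, with its ground truth."""

    patient_id: int
    eye_id: int
    laterality: str
    drusen_map: EnfaceMap
    hrf_map: EnfaceMap
    fovea_px: tuple[float, float]
    fovea_cfp: tuple[float, float]
    cfp_scale_px_per_deg: float
    true_transform: AffineTransform
    u_patient: float
    u_eye: float
    u_spot: np.ndarray

    def __post_init__(self) -> None:
        g = self.drusen_map.geometry
        fx, fy = self.fovea_px
        if not (0 <= fx <= g.n_ascan - 1 and 0 <= fy <= g.n_bscan - 1):
            raise ConfigurationError("fovea lies outside the raster")


def advance_visit(
    state: EyeState,
    drusen_growth: float,
    hrf_growth: float,
    rng_seed=None,
    noise_sd: float = 0.0,
) -> EyeState:
    """Evolve an eye by one visit: multiplicative lesion growth.

    Both maps scale by their growth factors, optionally perturbed by a
    log-normal factor with the given SD; random intercepts are carried
    over unchanged (longitudinal correlation enters only through them).
    """
    if drusen_growth < 1.0 or hrf_growth < 1.0:
        raise ConfigurationError("growth factors must be >= 1")
    gd, gh = float(drusen_growth), float(hrf_growth)
    if noise_sd > 0:
        rng = _as_rng(rng_seed)
        gd *= math.exp(rng.normal(0.0, noise_sd))
        gh *= math.exp(rng.normal(0.0, noise_sd))
        gd, gh = max(gd, 1.0), max(gh, 1.0)
    return replace(state,
                   drusen_map=state.drusen_map.scaled(gd),
                   hrf_map=state.hrf_map.scaled(gh))


def true_sensitivity(
    visit: int,
    ecc_deg: float,
    drusen_vol_e3mm3: float,
    hrf_vol_e3mm3: float,
    effects: TrueEffects,
    u_patient: float = 0.0,
    u_eye: float = 0.0,
    u_spot: float = 0.0,
) -> float:
    """Underlying sensitivity of one stimulus, clamped to the 0-34 dB range."""
    lp = effects.linear_predictor(visit, ecc_deg, drusen_vol_e3mm3, hrf_vol_e3mm3)
    return float(min(DB_MAX, max(DB_MIN, lp + u_patient + u_eye + u_spot)))


# ---------------------------------------------------------------------------
# cohort assembly


@dataclass
class VisitRecord:
    """Maps and measured sensitivities of one eye-visit."""

    visit: int
    drusen_map: EnfaceMap
    hrf_map: EnfaceMap
    true_spot_px: np.ndarray          # (45, 2) ground-truth raster positions
    true_drusen_vol_e3mm3: np.ndarray
    true_hrf_vol_e3mm3: np.ndarray
    true_sensitivity_db: np.ndarray
    measured_sensitivity_db: np.ndarray


@dataclass
class EyeRecord:
    """One eye's ground truth and its longitudinal visit records."""

    state: EyeState
    keypoints: pd.DataFrame
    visits: list[VisitRecord]


@dataclass
class CohortBundle:
    """A complete simulated cohort."""

    config: CohortConfig
    grid: StimulusGrid
    master_seed: int
    eyes: list[EyeRecord]

    def keypoint_table(self) -> pd.DataFrame:
        """All keypoint pairs, one block per eye."""
        return pd.concat([e.keypoints for e in self.eyes], ignore_index=True)

    def truth_table(self) -> pd.DataFrame:
        """Ground-truth per spot x visit rows (generator-side bookkeeping)."""
        rows = []
        ecc = self.grid.eccentricities_deg
        for eye in self.eyes:
            st = eye.state
            for vr in eye.visits:
                for k, sid in enumerate(self.grid.spot_ids):
                    rows.append((
                        st.patient_id, st.eye_id, st.laterality, vr.visit, sid,
                        float(ecc[k]),
                        vr.true_drusen_vol_e3mm3[k], vr.true_hrf_vol_e3mm3[k],
                        vr.true_sensitivity_db[k], vr.measured_sensitivity_db[k],
                    ))
        return pd.DataFrame(rows, columns=[
            "patient_id", "eye_id", "laterality", "visit", "spot_id", "ecc_deg",
            "drusen_vol_e3mm3", "hrf_vol_e3mm3",
            "true_sensitivity_db", "sensitivity_db",
        ])


def _eye_seed(master_seed: int, eye_index: int, channel: int,
              visit: int = 0) -> np.random.Generator:
    """Counter-based per-eye stream: stable when eyes are appended."""
    ss = np.random.SeedSequence(entropy=master_seed,
                                spawn_key=(eye_index, channel, visit))
    return np.random.default_rng(ss)


def _draw_true_transform(geometry: ScanGeometry, reg: RegistrationTruthParams,
                         fovea_px, rng) -> tuple[AffineTransform, tuple[float, float]]:
    """Ground-truth CFP->SLO affine consistent with the marked CFP fovea.

    The fundus photo is modelled as an isotropically sampled image
    (``cfp_scale_px_per_deg``) rotated and mildly rescaled relative to
    the OCT raster; the OCT raster itself is strongly anisotropic, so the
    resulting affine is anisotropic.  The transform maps the CFP fovea
    exactly onto the OCT fovea.
    """
    theta = math.radians(rng.uniform(-reg.rotation_max_deg, reg.rotation_max_deg))
    sx = rng.uniform(reg.axis_scale_min, reg.axis_scale_max)
    sy = rng.uniform(reg.axis_scale_min, reg.axis_scale_max)
    fovea_cfp = (
        reg.fovea_cfp_centre[0] + rng.uniform(-reg.fovea_cfp_jitter_px,
                                              reg.fovea_cfp_jitter_px),
        reg.fovea_cfp_centre[1] + rng.uniform(-reg.fovea_cfp_jitter_px,
                                              reg.fovea_cfp_jitter_px),
    )
    d = np.diag([geometry.mm_per_degree / geometry.ascan_spacing_mm,
                 geometry.mm_per_degree / geometry.bscan_spacing_mm])
    rot = np.array([[math.cos(theta), -math.sin(theta)],
                    [math.sin(theta), math.cos(theta)]])
    # CFP px -> deg -> SLO px, with the CFP frame rotated/rescaled
    matrix = d @ rot @ np.diag([1.0 / (sx * reg.cfp_scale_px_per_deg),
                                1.0 / (sy * reg.cfp_scale_px_per_deg)])
    offset = np.asarray(fovea_px) - matrix @ np.asarray(fovea_cfp)
    return AffineTransform(matrix, offset), fovea_cfp


def _draw_keypoints(geometry: ScanGeometry, transform: AffineTransform,
                    reg: RegistrationTruthParams, rng,
                    eye_id: int) -> pd.DataFrame:
    """Corresponding keypoints spread over the raster, jittered on the SLO side."""
    margin_x = 0.1 * geometry.n_ascan
    margin_y = 0.1 * geometry.n_bscan
    x = rng.uniform(margin_x, geometry.n_ascan - 1 - margin_x, reg.n_keypoints)
    y = rng.uniform(margin_y, geometry.n_bscan - 1 - margin_y, reg.n_keypoints)
    slo = np.column_stack([x, y])
    cfp = transform.inverse().apply(slo)
    slo_noisy = slo + rng.normal(0.0, reg.keypoint_jitter_px, slo.shape)
    return pd.DataFrame({
        "eye_id": eye_id,
        "x_cfp": cfp[:, 0], "y_cfp": cfp[:, 1],
        "x_slo": slo_noisy[:, 0], "y_slo": slo_noisy[:, 1],
    })


def _assign_eyes(n_patients: int, n_eyes: int) -> list[tuple[int, int, str]]:
    """(patient_id, eye_id, laterality) triples; earliest patients get 2 eyes."""
    n_bilateral = n_eyes - n_patients
    out = []
    eye_id = 0
    for p in range(n_patients):
        lats = ("OD", "OS") if p < n_bilateral else (("OD",) if p % 2 == 0 else ("OS",))
        for lat in lats:
            out.append((p, eye_id, lat))
            eye_id += 1
    return out


def simulate_cohort(
    config: CohortConfig,
    master_seed: int,
    grid: StimulusGrid | None = None,
) -> CohortBundle:
    """Simulate a full longitudinal cohort, deterministically per seed.

    Every random stream is derived from ``master_seed`` with a
    counter-based scheme keyed on (eye index, channel, visit), so adding
    eyes or visits never reshuffles existing ones.
    """
    if grid is None:
        grid = generate_default_grid()
    geom = config.geometry
    ecc = grid.eccentricities_deg
    eyes: list[EyeRecord] = []
    patient_u: dict[int, float] = {}

    for patient_id, eye_id, laterality in _assign_eyes(config.n_patients,
                                                       config.n_eyes):
        rng_struct = _eye_seed(master_seed, eye_id, channel=0)
        if patient_id not in patient_u:
            # patient intercept drawn from the first eye's stream
            patient_u[patient_id] = rng_struct.normal(0.0, config.effects.sd_patient)
        u_patient = patient_u[patient_id]
        u_eye = rng_struct.normal(0.0, config.effects.sd_eye)
        u_spot = rng_struct.normal(0.0, config.effects.sd_spot, len(grid))

        fovea_px = (geom.centre_px[0] + rng_struct.uniform(-5.0, 5.0),
                    geom.centre_px[1] + rng_struct.uniform(-2.0, 2.0))
        transform, fovea_cfp = _draw_true_transform(geom, config.registration,
                                                    fovea_px, rng_struct)
        keypoints = _draw_keypoints(geom, transform, config.registration,
                                    rng_struct, eye_id)

        drusen0 = simulate_drusen_field(geom, config.drusen,
                                        _eye_seed(master_seed, eye_id, channel=1),
                                        fovea_px=fovea_px)
        hrf0 = simulate_hrf_field(geom, drusen0, config.hrf,
                                  _eye_seed(master_seed, eye_id, channel=2))
        state = EyeState(patient_id=patient_id, eye_id=eye_id,
                         laterality=laterality, drusen_map=drusen0, hrf_map=hrf0,
                         fovea_px=fovea_px, fovea_cfp=fovea_cfp,
                         cfp_scale_px_per_deg=config.registration.cfp_scale_px_per_deg,
                         true_transform=transform,
                         u_patient=u_patient, u_eye=u_eye, u_spot=u_spot)

        # ground-truth raster positions of the stimuli, via the true transform
        cfp_pts = (np.asarray(fovea_cfp)
                   + config.registration.cfp_scale_px_per_deg * grid.coords_deg)
        true_px = transform.apply(cfp_pts)

        visits: list[VisitRecord] = []
        cur = state
        for visit in range(config.n_visits):
            if visit > 0:
                cur = advance_visit(
                    cur, config.drusen.growth_rate_per_visit,
                    config.hrf.growth_rate_per_visit,
                    _eye_seed(master_seed, eye_id, channel=3, visit=visit),
                    noise_sd=config.growth_noise_sd)
            vd = np.empty(len(grid))
            vh = np.empty(len(grid))
            for k in range(len(grid)):
                mask = roi_mask((true_px[k, 0], true_px[k, 1]), config.quant, geom)
                vd[k] = roi_volume(cur.drusen_map, mask) * 1e3
                vh[k] = hrf_roi_volume(cur.hrf_map, mask, config.quant) * 1e3
            rng_resid = _eye_seed(master_seed, eye_id, channel=4, visit=visit)
            resid = rng_resid.normal(0.0, config.effects.sd_resid, len(grid))
            truth = np.array([
                true_sensitivity(visit, float(ecc[k]), vd[k], vh[k],
                                 config.effects, u_patient, u_eye,
                                 float(u_spot[k]))
                for k in range(len(grid))
            ])
            truth = np.clip(truth + resid, DB_MIN, DB_MAX)
            measured = simulate_exam(
                truth,
                _eye_seed(master_seed, eye_id, channel=5, visit=visit),
                slope_sd_db=config.observer.slope_sd_db,
                false_pos_rate=config.observer.false_pos_rate,
                false_neg_rate=config.observer.false_neg_rate,
                start_level_db=config.observer.start_level_db)
            visits.append(VisitRecord(
                visit=visit, drusen_map=cur.drusen_map, hrf_map=cur.hrf_map,
                true_spot_px=true_px, true_drusen_vol_e3mm3=vd,
                true_hrf_vol_e3mm3=vh, true_sensitivity_db=truth,
                measured_sensitivity_db=measured))
        eyes.append(EyeRecord(state=state, keypoints=keypoints, visits=visits))

    return CohortBundle(config=config, grid=grid, master_seed=master_seed,
                        eyes=eyes)
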