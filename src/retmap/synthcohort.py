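"""Synthetic eyes, microperimetry exams and landmark sets.

The generator emulates the statistical structure the downstream analysis
assumes, so that every pipeline stage has ground truth:

* smooth radial layer-thickness topography calibrated so cohort-level
  regional means converge to the normative "overall" targets in
  :mod:`retmap.config` (ONL/EZ thickest at the fovea, RNFL thickest in the
  perifovea with a nasal skew);
* a fovea-centred 45-stimulus grid with the 9/12/20/4 ETDRS composition;
* two devices x two runs per eye, each exam observed through a ground-truth
  affine between the device image and the OCT en-face frame, with vessel
  junction landmark correspondences (optionally jittered);
* pointwise sensitivity generated from a linear predictor over the true
  140 μm-disc layer thicknesses, a patient-level random intercept and a
  residual, then measured by a simulated 4-2 staircase.

A single integer seed fans out through ``numpy.random.SeedSequence``:
``SeedSequence(seed)`` spawns one child per eye; each eye child spawns a
demographics stream, a phenotype stream and one stream per exam (transform,
landmark jitter and staircase draws).  Identical seeds therefore give
bit-identical cohorts and output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import json
import numpy as np
import pandas as pd
import tifffile
from scipy.special import expit

from .config import (
    BOUNDARY_ORDER,
    ETDRS_FOVEA_RADIUS_MM,
    ETDRS_PARAFOVEA_RADIUS_MM,
    ETDRS_PERIFOVEA_RADIUS_MM,
    LAYERS,
    OVERALL_THICKNESS_MEAN_UM,
    DeviceParams,
    PipelineConfig,
    SensitivityModel,
    layer_scale_cv,
)
from .project import EnFaceFrame, disc_pixel_set, eccentricity_of
from .register import Transform2D

EXAM_ORDER: tuple[tuple[str, int], ...] = (("MP3", 1), ("MP3", 2), ("MAIA", 1), ("MAIA", 2))

_BORDER_TOL_MM = 1e-6


# ---------------------------------------------------------------------------
# Stimulus grid
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StimulusGrid:
    """45 test locations in fovea-relative degrees with ETDRS region labels."""

    points_deg: np.ndarray        # (n, 2)
    stimulus_ids: np.ndarray      # (n,)
    regions: tuple[str, ...]

    def __len__(self) -> int:
        return self.points_deg.shape[0]

    @property
    def eccentricity_deg(self) -> np.ndarray:
        return eccentricity_of(self.points_deg)

    def region_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.regions:
            out[r] = out.get(r, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stimulus_id": self.stimulus_ids,
                "x_deg": self.points_deg[:, 0],
                "y_deg": self.points_deg[:, 1],
                "region": list(self.regions),
                "eccentricity_deg": self.eccentricity_deg,
            }
        )


def classify_region(points_deg: np.ndarray, um_per_degree: float = 288.0) -> list[str]:
    """ETDRS region of fovea-relative positions (degrees).

    Fovea: central disc of 1 mm diameter; parafovea: 1-3 mm annulus;
    perifovea: 3-6 mm annulus; border: exactly on the 3 mm circle separating
    parafovea from perifovea (to within 1e-6 mm).
    """
    pts = np.atleast_2d(np.asarray(points_deg, float))
    r_mm = np.hypot(pts[:, 0], pts[:, 1]) * um_per_degree / 1000.0
    labels = []
    for r in r_mm:
        if abs(r - ETDRS_PARAFOVEA_RADIUS_MM) <= _BORDER_TOL_MM:
            labels.append("border")
        elif r < ETDRS_FOVEA_RADIUS_MM:
            labels.append("fovea")
        elif r < ETDRS_PARAFOVEA_RADIUS_MM:
            labels.append("parafovea")
        else:
            # clipped at the ETDRS outer ring; the default grid stays within
            labels.append("perifovea")
    return labels


def make_default_grid(config: Optional[PipelineConfig] = None) -> StimulusGrid:
    """The fixed fovea-centred 45-stimulus test grid.

    Concentric rings whose radii (in retinal mm, converted through the
    configured μm/degree scale) give exactly 9 foveal, 12 parafoveal and 20
    perifoveal stimuli, with 4 stimuli on the parafovea/perifovea border.
    Deterministic.
    """
    config = config or PipelineConfig()
    deg_per_mm = config.deg_per_mm
    pts = []
    for ring in config.rings:
        r_deg = ring.radius_mm * deg_per_mm
        for k in range(ring.count):
            a = np.deg2rad(ring.phase_deg + 360.0 * k / ring.count)
            pts.append((r_deg * np.cos(a), r_deg * np.sin(a)))
    points = np.array(pts)
    regions = tuple(classify_region(points, config.um_per_degree))
    return StimulusGrid(points, np.arange(1, len(points) + 1), regions)


# ---------------------------------------------------------------------------
# Layer topography: smooth radial mean profiles calibrated to the normative
# regional targets, shared by all eyes up to a per-eye lognormal scale.
# ---------------------------------------------------------------------------


def _region_basis(r_mm: np.ndarray, w_in: float, w_out: float) -> np.ndarray:
    """Smooth partition of unity over (fovea, parafovea, perifovea)."""
    s1 = expit((r_mm - ETDRS_FOVEA_RADIUS_MM) / w_in)
    s2 = expit((r_mm - ETDRS_PARAFOVEA_RADIUS_MM) / w_out)
    return np.stack([1.0 - s1, s1 * (1.0 - s2), s1 * s2])


class _Geometry:
    """Raster geometry, calibrated profiles and per-stimulus disc caches.

    Everything here depends only on the configuration's geometric and
    profile parameters, so instances are memoised process-wide.
    """

    def __init__(self, config: PipelineConfig):
        self.frame = EnFaceFrame.from_config(config)
        w = self.frame.width_px
        axis_deg = (np.arange(w) + 0.5) / config.px_per_degree - config.extent_deg / 2.0
        self.x_deg, self.y_deg = np.meshgrid(axis_deg, axis_deg)
        self.r_deg = np.hypot(self.x_deg, self.y_deg)
        self.r_mm = self.r_deg * config.um_per_degree / 1000.0

        # scan-clipped ETDRS region masks over the full raster
        self.region_masks = {
            "fovea": self.r_mm < ETDRS_FOVEA_RADIUS_MM,
            "parafovea": (self.r_mm >= ETDRS_FOVEA_RADIUS_MM)
            & (self.r_mm < ETDRS_PARAFOVEA_RADIUS_MM),
            "perifovea": (self.r_mm >= ETDRS_PARAFOVEA_RADIUS_MM)
            & (self.r_mm <= ETDRS_PERIFOVEA_RADIUS_MM),
        }

        basis = _region_basis(
            self.r_mm, config.profile_width_inner_mm, config.profile_width_outer_mm
        )
        # solve for basis coefficients so raster regional means equal targets
        M = np.array(
            [
                [basis[j][self.region_masks[m]].mean() for j in range(3)]
                for m in ("fovea", "parafovea", "perifovea")
            ]
        )
        self.profile_coeffs = {
            layer: np.linalg.solve(M, np.array(targets))
            for layer, targets in OVERALL_THICKNESS_MEAN_UM.items()
        }

        # base (scale-1) thickness fields; RNFL gets a linear nasal skew that
        # preserves regional means (masks are symmetric in x)
        skew = 1.0 + config.rnfl_nasal_skew * self.x_deg / (config.extent_deg / 2.0)
        self.base_fields = {}
        for layer, c in self.profile_coeffs.items():
            f = np.tensordot(c, basis, axes=1)
            if layer == "RNFL":
                f = f * skew
            self.base_fields[layer] = f

        # per-stimulus disc pixel sets at the true (identity-registered)
        # positions, and the corresponding base disc-mean thicknesses
        self.grid = make_default_grid(config)
        self.grid_oct_px = self.frame.deg_to_px(self.grid.points_deg)
        self.disc_sets = [
            disc_pixel_set(self.frame, (x, y), config.sampling_radius_um)
            for x, y in self.grid_oct_px
        ]
        self.base_disc_mean = {
            layer: np.array([f[iy, ix].mean() for iy, ix in self.disc_sets])
            for layer, f in self.base_fields.items()
        }
        self.grid_ecc = self.grid.eccentricity_deg


_GEOMETRY_CACHE: dict[str, _Geometry] = {}


def _geometry(config: PipelineConfig) -> _Geometry:
    key = json.dumps(
        [
            config.extent_deg, config.px_per_degree, config.um_per_degree,
            config.sampling_radius_um, config.rnfl_nasal_skew,
            config.profile_width_inner_mm, config.profile_width_outer_mm,
            [(r.radius_mm, r.count, r.phase_deg) for r in config.rings],
        ]
    )
    if key not in _GEOMETRY_CACHE:
        _GEOMETRY_CACHE[key] = _Geometry(config)
    return _GEOMETRY_CACHE[key]


# ---------------------------------------------------------------------------
# Eyes
# ---------------------------------------------------------------------------


@dataclass
class EyePhenotype:
    """One synthetic eye: boundary surfaces, landmarks and ground truth."""

    eye_id: str
    age: float
    fovea_center: tuple[float, float]        # (x°, y°), 0 = scan centre
    boundary_surfaces: dict[str, np.ndarray]  # boundary name -> depth μm raster
    landmarks: np.ndarray                     # (k, 2) vessel junctions, degrees
    random_intercept: float                   # patient-level b_i, dB
    seed: int
    layer_scales: dict[str, float] = field(default_factory=dict)

    def thickness_field(self, layer: str) -> np.ndarray:
        from .config import LAYER_BOUNDARIES

        inner, outer = LAYER_BOUNDARIES[layer]
        return self.boundary_surfaces[outer] - self.boundary_surfaces[inner]


def _draw_age(rng: np.random.Generator, config: PipelineConfig) -> float:
    """Gaussian age truncated at the inclusion threshold."""
    for _ in range(1000):
        a = rng.normal(config.age_mean, config.age_sd)
        if a >= config.age_min:
            return float(a)
    return float(config.age_min)  # pragma: no cover


def make_eye(
    age: float,
    seed: int,
    config: Optional[PipelineConfig] = None,
    eye_id: Optional[str] = None,
) -> EyePhenotype:
    """Generate one eye's boundary surfaces, landmarks and random intercept.

    Surfaces are the shared calibrated radial profiles scaled by per-eye,
    per-layer lognormal factors with mean exactly 1, stacked into strictly
    ordered boundary depths.  Raises ``ValueError`` below the inclusion age.
    """
    config = config or PipelineConfig()
    if age < config.age_min:
        raise ValueError(f"age {age:.1f} below inclusion threshold {config.age_min}")
    geom = _geometry(config)
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    scales = {}
    for layer in LAYERS:
        cv = layer_scale_cv(layer)
        sigma = np.sqrt(np.log1p(cv**2))
        scales[layer] = float(np.exp(rng.normal(-0.5 * sigma**2, sigma)))
    b_i = float(rng.normal(0.0, config.model.sigma_b))

    half = config.extent_deg / 2.0
    n_lm = max(config.n_landmarks, 8)
    landmarks = rng.uniform(-0.9 * half, 0.9 * half, size=(n_lm, 2))

    ilm = config.ilm_bowl_um * (geom.r_deg / half) ** 2
    surfaces = {"ILM": ilm}
    depth = ilm
    for layer, gap in (("RNFL", None), ("GCL", None)):
        depth = depth + scales[layer] * geom.base_fields[layer]
        surfaces["RNFL_GCL" if layer == "RNFL" else "GCL_IPL"] = depth
    depth = depth + config.inner_gap_um
    surfaces["OPL_ONL"] = depth
    depth = depth + scales["ONL"] * geom.base_fields["ONL"]
    surfaces["ELM"] = depth
    depth = depth + config.inner_segment_um
    surfaces["EZ_inner"] = depth
    depth = depth + scales["EZ"] * geom.base_fields["EZ"]
    surfaces["IZ_outer"] = depth

    return EyePhenotype(
        eye_id=eye_id or f"eye{seed:08x}",
        age=age,
        fovea_center=(0.0, 0.0),
        boundary_surfaces=surfaces,
        landmarks=landmarks,
        random_intercept=b_i,
        seed=int(seed),
        layer_scales=scales,
    )


# ---------------------------------------------------------------------------
# Sensitivity model and staircase psychophysics
# ---------------------------------------------------------------------------


def _linear_predictor(
    model: SensitivityModel,
    beta0: float,
    thickness: dict[str, np.ndarray],
    ecc_deg: np.ndarray,
    age: float,
    device: str,
    run: int,
) -> np.ndarray:
    lin = beta0 + model.beta_ecc * ecc_deg + model.beta_age * age
    for layer, beta in model.layer_betas().items():
        lin = lin + beta * thickness[layer]
    if device == "MAIA":
        lin = lin + model.beta_device
    if run == 2:
        lin = lin + model.beta_run
    return lin


def true_sensitivity(
    eye: EyePhenotype,
    model: SensitivityModel,
    point_deg: tuple[float, float],
    device: str,
    run: int,
    config: Optional[PipelineConfig] = None,
) -> float:
    """Noise-free sensitivity (dB) at one grid point of one exam.

    Uses the ground-truth 140 μm-disc mean thicknesses (no measurement
    noise), adds the device/run offsets and the eye's random intercept, and
    clamps to the device dynamic range.  Returns NaN for a point outside the
    scan extent.
    """
    config = config or PipelineConfig()
    frame = EnFaceFrame.from_config(config)
    px = frame.deg_to_px(np.asarray(point_deg, float))
    if not frame.contains_px(px):
        return float("nan")
    iy, ix = disc_pixel_set(frame, (px[0], px[1]), config.sampling_radius_um)
    thickness = {
        layer: np.array([eye.thickness_field(layer)[iy, ix].mean()])
        for layer in LAYERS
    }
    beta0 = resolve_intercept(model, config)
    ecc = np.array([float(np.hypot(point_deg[0], point_deg[1]))])
    lin = _linear_predictor(model, beta0, thickness, ecc, eye.age, device, run)
    dev = config.devices[device]
    return float(np.clip(lin + eye.random_intercept, dev.db_min, dev.db_max)[0])


#: reversals required and averaged per estimate rule:
#: ``reversal_mean`` stops after the 4th reversal and averages the last two
#: reversal intensities (both in the 2 dB phase, bracketing the threshold
#: from opposite sides — near-unbiased over the whole operating range);
#: ``midpoint`` stops after the 2nd reversal and reports the midpoint of the
#: final seen/not-seen bracket; ``last_seen`` stops after the 2nd reversal
#: and reports the last seen intensity (device-style readout, ~1 dB low).
_ESTIMATE_RULES: dict[str, tuple[int, int]] = {
    "reversal_mean": (4, 2),   # (reversals to stop at, reversals to skip)
    "midpoint": (2, 1),
    "last_seen": (2, 1),
}


def _staircase_batch(
    thresholds: np.ndarray,
    device: DeviceParams,
    rng: np.random.Generator,
    slope_db: float = 1.0,
    estimate: str = "reversal_mean",
    max_steps: int = 100,
) -> np.ndarray:
    """Vectorised 4-2 staircases, one per threshold.

    Presentation at intensity I is "seen" with probability
    ``expit((t - I)/slope)``.  Intensity moves 4 dB towards the threshold
    until the first response reversal, then 2 dB.  Termination and the
    threshold estimate follow the configured rule (see ``_ESTIMATE_RULES``).
    A response sequence that cannot be bracketed terminates at the range
    limit (ceiling/floor).
    """
    if estimate not in _ESTIMATE_RULES:
        raise ValueError(f"unknown estimate rule {estimate!r}")
    n_rev_stop, n_rev_skip = _ESTIMATE_RULES[estimate]
    t = np.asarray(thresholds, float)
    n = t.shape[0]
    lo, hi = device.db_min, device.db_max
    I = np.full(n, float(device.staircase_start))
    step = np.full(n, 4.0)
    rev = np.zeros(n, dtype=int)
    prev = np.zeros(n, dtype=bool)
    has_prev = np.zeros(n, dtype=bool)
    last_seen = np.full(n, np.nan)
    last_not = np.full(n, np.nan)
    rev_sum = np.zeros(n)
    est = np.full(n, np.nan)
    active = np.ones(n, dtype=bool)

    for _ in range(max_steps):
        if not active.any():
            break
        u = rng.random(n)  # full-width draw keeps the stream layout fixed
        seen = u < expit((t - I) / slope_db)
        sa = active & seen
        na = active & ~seen
        last_seen[sa] = I[sa]
        last_not[na] = I[na]

        reversal = active & has_prev & (seen != prev)
        rev[reversal] += 1
        step[reversal] = 2.0
        rev_sum[reversal & (rev > n_rev_skip)] += I[reversal & (rev > n_rev_skip)]
        done = reversal & (rev >= n_rev_stop)

        ceil = sa & (I >= hi) & ~done     # seen at the brightest attenuation
        floor = na & (I <= lo) & ~done    # not seen at the dimmest
        est[ceil] = hi
        est[floor] = lo

        prev[active] = seen[active]
        has_prev[active] = True
        active = active & ~done & ~ceil & ~floor
        move = np.where(seen, step, -step)
        I[active] = np.clip(I[active] + move[active], lo, hi)

    pend = np.isnan(est)  # terminated by reversal count
    if estimate == "reversal_mean":
        est[pend] = rev_sum[pend] / (n_rev_stop - n_rev_skip)
    elif estimate == "midpoint":
        est[pend] = 0.5 * (last_seen[pend] + last_not[pend])
    else:  # last_seen
        est[pend] = last_seen[pend]
    return np.clip(est, lo, hi)


def run_staircase(
    true_threshold: float,
    device: DeviceParams,
    rng: np.random.Generator,
    slope_db: float = 1.0,
    estimate: str = "reversal_mean",
) -> float:
    """Simulate one 4-2 staircase measurement of ``true_threshold`` (dB)."""
    return float(
        _staircase_batch(np.array([true_threshold]), device, rng, slope_db, estimate)[0]
    )


# ---------------------------------------------------------------------------
# Intercept calibration
# ---------------------------------------------------------------------------

_INTERCEPT_CACHE: dict[tuple, float] = {}
_CALIBRATION_SEED = 202_406_170  # internal, independent of user seeds


def calibrated_intercept(model: SensitivityModel, config: PipelineConfig) -> float:
    """Intercept giving an MP-3 run-1 population mean of ``target_mean_db``.

    The calibration runs through the full measurement chain: the expected
    linear predictor over the 45-point grid plus the mean measurement bias of
    the staircase (range clamping included), estimated once by a
    deterministic internal Monte-Carlo.
    """
    geom = _geometry(config)
    key = (
        json.dumps(model.model_dump(mode="json"), sort_keys=True),
        json.dumps(config.devices["MP3"].model_dump(mode="json"), sort_keys=True),
        config.staircase_slope_db,
        config.staircase_estimate,
        id(geom),
    )
    if key in _INTERCEPT_CACHE:
        return _INTERCEPT_CACHE[key]

    lin_pts = model.beta_ecc * geom.grid_ecc + model.beta_age * config.age_mean
    for layer, beta in model.layer_betas().items():
        lin_pts = lin_pts + beta * geom.base_disc_mean[layer]
    lin_mean = float(lin_pts.mean())
    topo_sd = float(lin_pts.std())

    latent_sd = float(np.sqrt(topo_sd**2 + model.sigma_b**2 + model.sigma_e**2))
    rng = np.random.default_rng(np.random.SeedSequence(_CALIBRATION_SEED))
    dev = config.devices["MP3"]
    target = model.target_mean_db
    true_t = np.clip(
        rng.normal(target, np.hypot(topo_sd, model.sigma_b), 50_000),
        dev.db_min, dev.db_max,
    )
    latent = true_t + rng.normal(0.0, model.sigma_e, true_t.shape)
    measured = _staircase_batch(
        latent, dev, rng, config.staircase_slope_db, config.staircase_estimate
    )
    bias = float(measured.mean() - target)

    beta0 = target - lin_mean - bias
    _INTERCEPT_CACHE[key] = beta0
    return beta0


def resolve_intercept(model: SensitivityModel, config: PipelineConfig) -> float:
    return model.beta0 if model.beta0 is not None else calibrated_intercept(model, config)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


@dataclass
class Cohort:
    """In-memory result of a cohort simulation."""

    config: PipelineConfig
    grid: StimulusGrid
    frame: EnFaceFrame
    eyes: list[EyePhenotype]
    exams: pd.DataFrame                      # eye_id, device, run, stimulus_id, px_x, px_y, db
    landmarks: dict[str, pd.DataFrame]       # exam key -> correspondence table
    truth: dict

    def exam_keys(self) -> list[str]:
        return list(self.landmarks.keys())

    def write(self, out_dir) -> Path:
        return write_cohort(self, out_dir)


def exam_key(eye_id: str, device: str, run: int) -> str:
    return f"{eye_id}_{device}_run{run}"


def _random_exam_transform(rng: np.random.Generator, config: PipelineConfig) -> Transform2D:
    """Ground-truth device->OCT affine: rotation, per-axis scale, shear, shift."""
    th = np.deg2rad(rng.uniform(-config.max_rotation_deg, config.max_rotation_deg))
    sx, sy = np.exp(rng.uniform(-config.max_log_scale, config.max_log_scale, 2))
    shear = rng.uniform(-config.max_shear, config.max_shear)
    if config.transform_family == "similarity":
        sy = sx
        shear = 0.0
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    A = R @ np.array([[sx, shear * sx], [0.0, sy]])
    t = rng.uniform(-config.max_translation_px, config.max_translation_px, 2)
    return Transform2D(np.hstack([A, t[:, None]]))


def simulate_cohort(
    n_eyes: Optional[int] = None,
    model: Optional[SensitivityModel] = None,
    config: Optional[PipelineConfig] = None,
    seed: Optional[int] = None,
    out_dir=None,
) -> Cohort:
    """Simulate a full cohort: eyes, four exams each, landmark files.

    Each eye receives 2 devices x 2 runs over the default grid.  Device-image
    stimulus coordinates are the true OCT positions pushed through the
    inverse of a per-exam ground-truth affine; landmark correspondence tables
    carry the same transform plus optional Gaussian pixel jitter on the
    device side.  When ``out_dir`` is given, all external files are written.
    """
    config = config or PipelineConfig()
    if n_eyes is not None:
        config = config.model_copy(update={"n_eyes": n_eyes})
    if seed is not None:
        config = config.model_copy(update={"seed": seed})
    if model is not None:
        config = config.model_copy(update={"model": model})
    model = config.model
    geom = _geometry(config)
    frame, grid = geom.frame, geom.grid
    beta0 = resolve_intercept(model, config)

    root = np.random.SeedSequence(config.seed)
    eye_streams = root.spawn(config.n_eyes)

    eyes: list[EyePhenotype] = []
    landmark_files: dict[str, pd.DataFrame] = {}
    exam_rows = []
    truth_eyes = {}
    truth_transforms = {}

    for i, ess in enumerate(eye_streams):
        demo_ss, pheno_ss, *exam_ss = ess.spawn(2 + len(EXAM_ORDER))
        age = _draw_age(np.random.default_rng(demo_ss), config)
        eye = make_eye(
            age, int(pheno_ss.generate_state(1)[0]), config, eye_id=f"eye{i:03d}"
        )
        eyes.append(eye)
        truth_eyes[eye.eye_id] = {
            "age": eye.age,
            "random_intercept": eye.random_intercept,
            "layer_scales": eye.layer_scales,
            "seed": eye.seed,
        }

        # ground-truth disc thickness is linear in the per-eye scales
        thickness = {
            layer: eye.layer_scales[layer] * geom.base_disc_mean[layer]
            for layer in LAYERS
        }
        lm_oct = frame.deg_to_px(eye.landmarks)
        grid_oct = geom.grid_oct_px

        for (device, run), xss in zip(EXAM_ORDER, exam_ss):
            rng = np.random.default_rng(xss)
            T = _random_exam_transform(rng, config)
            Tinv = T.inverse()
            key = exam_key(eye.eye_id, device, run)
            truth_transforms[key] = [float(v) for v in T.matrix.ravel()]

            device_px = Tinv.apply(grid_oct)
            lm_device = Tinv.apply(lm_oct)
            if config.landmark_jitter_px > 0:
                lm_device = lm_device + rng.normal(
                    0.0, config.landmark_jitter_px, lm_device.shape
                )
            landmark_files[key] = pd.DataFrame(
                {
                    "px_x_device": lm_device[:, 0],
                    "px_y_device": lm_device[:, 1],
                    "px_x_oct": lm_oct[:, 0],
                    "px_y_oct": lm_oct[:, 1],
                }
            )

            dev = config.devices[device]
            lin = _linear_predictor(
                model, beta0, thickness, geom.grid_ecc, eye.age, device, run
            )
            true_t = np.clip(lin + eye.random_intercept, dev.db_min, dev.db_max)
            latent = true_t + rng.normal(0.0, model.sigma_e, true_t.shape)
            db = _staircase_batch(
                latent, dev, rng, config.staircase_slope_db, config.staircase_estimate
            )
            for j, sid in enumerate(grid.stimulus_ids):
                exam_rows.append(
                    (eye.eye_id, device, run, int(sid),
                     device_px[j, 0], device_px[j, 1], db[j])
                )

    exams = pd.DataFrame(
        exam_rows, columns=["eye_id", "device", "run", "stimulus_id", "px_x", "px_y", "db"]
    )
    truth = {
        "beta0": beta0,
        "model": model.model_dump(mode="json"),
        "seed": config.seed,
        "eyes": truth_eyes,
        "transforms": truth_transforms,
    }
    cohort = Cohort(config, grid, frame, eyes, exams, landmark_files, truth)
    if out_dir is not None:
        write_cohort(cohort, out_dir)
    return cohort


def write_cohort(cohort: Cohort, out_dir) -> Path:
    """Write the cohort's external files (TIFF boundaries, CSVs, truth.json)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = cohort.config
    for eye in cohort.eyes:
        eye_dir = out / "eyes" / eye.eye_id
        eye_dir.mkdir(parents=True, exist_ok=True)
        stack = np.stack(
            [eye.boundary_surfaces[b] for b in BOUNDARY_ORDER]
        ).astype(np.float32)
        tifffile.imwrite(eye_dir / "boundaries.tiff", stack)
        meta = {
            "eye_id": eye.eye_id,
            "age": eye.age,
            "page_order": list(BOUNDARY_ORDER),
            "units": "um_depth_from_inner_surface",
            "extent_deg": cfg.extent_deg,
            "px_per_degree": cfg.px_per_degree,
            "um_per_degree": cfg.um_per_degree,
            "fovea_px": list(cohort.frame.fovea_px),
        }
        with open(eye_dir / "meta.json", "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
            fh.write("\n")
    cohort.exams.to_csv(out / "exams.csv", index=False)
    for key, df in cohort.landmarks.items():
        df.to_csv(out / f"landmarks_{key}.csv", index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(cohort.truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    cfg.to_json(out / "config.json")
    return out


# ---------------------------------------------------------------------------
# Fast generator for statistical simulations
# ---------------------------------------------------------------------------


def simulate_pointwise(
    config: Optional[PipelineConfig] = None,
    seed: Optional[int] = None,
    n_eyes: Optional[int] = None,
) -> pd.DataFrame:
    """Analysis-ready pointwise table generated without rasters or files.

    Statistically identical to running the full simulate->register->project->
    quantify chain with noise-free registration: thickness columns are the
    ground-truth disc means.  Intended for replicate-heavy statistical
    simulations (coverage, selection and type-I studies).
    """
    config = config or PipelineConfig()
    if n_eyes is not None:
        config = config.model_copy(update={"n_eyes": n_eyes})
    if seed is not None:
        config = config.model_copy(update={"seed": seed})
    model = config.model
    geom = _geometry(config)
    beta0 = resolve_intercept(model, config)
    npts = len(geom.grid)

    root = np.random.SeedSequence(config.seed)
    eye_streams = root.spawn(config.n_eyes)

    frames = []
    for i, ess in enumerate(eye_streams):
        demo_ss, pheno_ss, *exam_ss = ess.spawn(2 + len(EXAM_ORDER))
        rng_demo = np.random.default_rng(demo_ss)
        age = _draw_age(rng_demo, config)
        rng_ph = np.random.default_rng(np.random.SeedSequence(int(pheno_ss.generate_state(1)[0])))
        scales = {}
        for layer in LAYERS:
            cv = layer_scale_cv(layer)
            sigma = np.sqrt(np.log1p(cv**2))
            scales[layer] = float(np.exp(rng_ph.normal(-0.5 * sigma**2, sigma)))
        b_i = float(rng_ph.normal(0.0, model.sigma_b))
        thickness = {l: scales[l] * geom.base_disc_mean[l] for l in LAYERS}

        for (device, run), xss in zip(EXAM_ORDER, exam_ss):
            rng = np.random.default_rng(xss)
            _ = _random_exam_transform(rng, config)  # keep stream layout aligned
            if config.landmark_jitter_px > 0:
                _ = rng.normal(0.0, config.landmark_jitter_px, (max(config.n_landmarks, 8), 2))
            dev = config.devices[device]
            lin = _linear_predictor(model, beta0, thickness, geom.grid_ecc, age, device, run)
            true_t = np.clip(lin + b_i, dev.db_min, dev.db_max)
            latent = true_t + rng.normal(0.0, model.sigma_e, npts)
            db = _staircase_batch(
                latent, dev, rng, config.staircase_slope_db, config.staircase_estimate
            )
            frames.append(
                pd.DataFrame(
                    {
                        "eye_id": f"eye{i:03d}",
                        "device": device,
                        "run": run,
                        "stimulus_id": geom.grid.stimulus_ids,
                        "db": db,
                        "EZ": thickness["EZ"],
                        "ONL": thickness["ONL"],
                        "GCL": thickness["GCL"],
                        "RNFL": thickness["RNFL"],
                        "region": list(geom.grid.regions),
                        "eccentricity": geom.grid_ecc,
                        "age": age,
                        "status": "sampled",
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)
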