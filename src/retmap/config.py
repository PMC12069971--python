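"""Configuration models and normative calibration targets.

All geometric constants (degree/μm/pixel conversions), device properties and
generating-model parameters flow through :class:`PipelineConfig` so that every
stage of the pipeline shares a single, serialisable source of truth.
"""

from __future__ import annotations

import hashlib
import json
from typing import Literal, Optional

from pydantic import BaseModel, Field, field_validator, model_validator

# ---------------------------------------------------------------------------
# Anatomy: boundary surfaces and the layers measured between them.
#
# Depth is axial distance (μm) from the inner retinal surface, increasing
# towards the choroid.  Page order of boundary rasters in ``boundaries.tiff``
# is fixed to BOUNDARY_ORDER and recorded in ``meta.json``.
# ---------------------------------------------------------------------------

BOUNDARY_ORDER: tuple[str, ...] = (
    "ILM",        # internal limiting membrane
    "RNFL_GCL",   # RNFL / ganglion cell layer interface
    "GCL_IPL",    # GCL / inner plexiform layer interface
    "OPL_ONL",    # outer boundary of the outer plexiform layer (ONL start)
    "ELM",        # external limiting membrane (inner boundary)
    "EZ_inner",   # inner boundary of the ellipsoid zone
    "IZ_outer",   # outer boundary of the interdigitation zone
)

#: Layer -> (inner boundary, outer boundary).  ONL includes the Henle fibre
#: layer; EZ runs from the inner EZ boundary to the outer IZ boundary.
LAYER_BOUNDARIES: dict[str, tuple[str, str]] = {
    "RNFL": ("ILM", "RNFL_GCL"),
    "GCL": ("RNFL_GCL", "GCL_IPL"),
    "ONL": ("OPL_ONL", "ELM"),
    "EZ": ("EZ_inner", "IZ_outer"),
}

LAYERS: tuple[str, ...] = ("EZ", "ONL", "GCL", "RNFL")

REGIONS: tuple[str, ...] = ("fovea", "parafovea", "perifovea", "border")

# ETDRS ring radii in mm on the retina (diameters 1 / 3 / 6 mm).
ETDRS_FOVEA_RADIUS_MM = 0.5
ETDRS_PARAFOVEA_RADIUS_MM = 1.5
ETDRS_PERIFOVEA_RADIUS_MM = 3.0

# ---------------------------------------------------------------------------
# Normative calibration targets: volume-wide ("overall") regional thickness
# means and SDs (μm) in healthy ageing eyes, per region (fovea, parafovea,
# perifovea).  The synthetic generator is calibrated so that cohort-level
# overall regional means converge to these values.
# ---------------------------------------------------------------------------

OVERALL_THICKNESS_MEAN_UM: dict[str, tuple[float, float, float]] = {
    "EZ": (35.48, 34.32, 31.94),
    "ONL": (95.18, 67.93, 50.22),
    "GCL": (20.86, 48.22, 27.01),
    "RNFL": (11.40, 24.00, 38.78),
}

OVERALL_THICKNESS_SD_UM: dict[str, tuple[float, float, float]] = {
    "EZ": (4.42, 3.60, 2.63),
    "ONL": (9.67, 6.18, 5.36),
    "GCL": (5.20, 7.20, 4.10),
    "RNFL": (2.46, 2.98, 5.58),
}


def layer_scale_cv(layer: str) -> float:
    """Between-eye coefficient of variation for a layer's multiplicative scale.

    Taken as the mean of the regional SD/mean ratios of the normative targets,
    so that the lognormal per-eye scale factor reproduces the observed spread
    of regional means across eyes.
    """
    means = OVERALL_THICKNESS_MEAN_UM[layer]
    sds = OVERALL_THICKNESS_SD_UM[layer]
    return float(sum(s / m for s, m in zip(sds, means)) / len(means))


class DeviceParams(BaseModel):
    """Dynamic range and staircase start intensity of one MP device."""

    db_min: float = 0.0
    db_max: float
    staircase_start: float = 25.0

    @model_validator(mode="after")
    def _range_ok(self) -> "DeviceParams":
        if not self.db_min < self.db_max:
            raise ValueError("db_min must be below db_max")
        if not self.db_min <= self.staircase_start <= self.db_max:
            raise ValueError("staircase start must lie inside the dynamic range")
        return self


class SensitivityModel(BaseModel):
    """Linear predictor of pointwise sensitivity (dB).

    sensitivity = beta0 + beta_EZ*EZ + beta_ONL*ONL + beta_GCL*GCL
                + beta_RNFL*RNFL + beta_device*[MAIA] + beta_run*[run 2]
                + beta_ecc*R + beta_age*age + b_i + e

    with thicknesses in μm (140 μm-disc means), eccentricity R in degrees,
    age in years, a patient-level random intercept b_i ~ N(0, sigma_b^2) and
    residual e ~ N(0, sigma_e^2).  ``beta0=None`` means "calibrate at run time
    so the MP-3 run-1 population mean equals ``target_mean_db``".

    Defaults carry the multivariable structure-function estimates for the
    layer terms, the device offset, and a small run effect; age and
    eccentricity have no direct effect by default — their marginal
    associations with sensitivity arise through the layer topography.
    """

    beta0: Optional[float] = None
    beta_EZ: float = 0.053
    beta_ONL: float = 0.031
    beta_GCL: float = 0.028
    beta_RNFL: float = -0.011
    beta_device: float = -3.335
    beta_run: float = 0.168
    beta_ecc: float = 0.0
    beta_age: float = 0.0
    sigma_b: float = Field(1.5, ge=0.0)
    sigma_e: float = Field(2.0, gt=0.0)
    target_mean_db: float = 28.65

    def layer_betas(self) -> dict[str, float]:
        return {
            "EZ": self.beta_EZ,
            "ONL": self.beta_ONL,
            "GCL": self.beta_GCL,
            "RNFL": self.beta_RNFL,
        }


class GridRing(BaseModel):
    radius_mm: float = Field(ge=0.0)
    count: int = Field(ge=1)
    phase_deg: float = 0.0


def default_rings() -> list[GridRing]:
    """Fovea-centred rings giving the 9/12/20/4 ETDRS composition of the
    45-stimulus grid (1+8 foveal, 12 parafoveal, 4 on the 1.5 mm border,
    10+10 perifoveal)."""
    return [
        GridRing(radius_mm=0.0, count=1),
        GridRing(radius_mm=0.35, count=8),
        GridRing(radius_mm=0.92, count=12, phase_deg=15.0),
        GridRing(radius_mm=ETDRS_PARAFOVEA_RADIUS_MM, count=4, phase_deg=45.0),
        GridRing(radius_mm=2.02, count=10),
        GridRing(radius_mm=2.74, count=10, phase_deg=18.0),
    ]


class StatsOptions(BaseModel):
    """Options of the mixed-model stage."""

    #: count the two variance parameters in the BIC penalty
    bic_count_variance: bool = True
    #: include the four interaction terms in the all-subsets global model
    #: (default: interactions are analysed univariately only)
    dredge_interactions: bool = False
    ci_method: Literal["wald"] = "wald"
    #: estimation method used for the univariate suite
    univariate_method: Literal["ML", "REML"] = "REML"


class PipelineConfig(BaseModel):
    """Everything the simulate→register→project→quantify→analyze chain needs."""

    n_eyes: int = Field(20, ge=1)
    seed: int = 0

    # geometry
    extent_deg: float = Field(20.0, gt=0.0)
    px_per_degree: float = Field(10.0, gt=0.0)
    um_per_degree: float = Field(288.0, gt=0.0)
    sampling_radius_um: float = Field(70.0, gt=0.0)
    rings: list[GridRing] = Field(default_factory=default_rings)

    # cohort demographics (inclusion: 50 years and older)
    age_mean: float = 68.9
    age_sd: float = Field(10.9, gt=0.0)
    age_min: float = 50.0

    # synthetic anatomy
    ilm_bowl_um: float = 10.0      # shallow inner-surface curvature
    inner_gap_um: float = Field(70.0, gt=0.0)   # IPL+INL+OPL span
    inner_segment_um: float = Field(15.0, gt=0.0)  # ELM -> EZ inner
    rnfl_nasal_skew: float = 0.3   # linear nasal thickening of the RNFL
    profile_width_inner_mm: float = Field(0.22, gt=0.0)
    profile_width_outer_mm: float = Field(0.35, gt=0.0)

    # registration truth + measurement
    n_landmarks: int = Field(12, ge=3)
    landmark_jitter_px: float = Field(0.5, ge=0.0)
    max_translation_px: float = 15.0
    max_rotation_deg: float = 5.0
    max_log_scale: float = 0.03
    max_shear: float = 0.02
    transform_family: Literal["affine", "similarity"] = "affine"
    review_threshold_px: float = Field(2.0, gt=0.0)

    # psychophysics
    staircase_slope_db: float = Field(1.0, gt=0.0)
    staircase_estimate: Literal["reversal_mean", "midpoint", "last_seen"] = "reversal_mean"

    # staircase start a little below the device's expected normal sensitivity,
    # chosen so the two devices' mean measurement biases match (see methods)
    devices: dict[str, DeviceParams] = Field(
        default_factory=lambda: {
            "MP3": DeviceParams(db_max=34.0, staircase_start=27.0),
            "MAIA": DeviceParams(db_max=36.0, staircase_start=25.0),
        }
    )
    model: SensitivityModel = Field(default_factory=SensitivityModel)
    stats: StatsOptions = Field(default_factory=StatsOptions)

    @field_validator("devices")
    @classmethod
    def _two_devices(cls, v: dict[str, DeviceParams]) -> dict[str, DeviceParams]:
        if "MP3" not in v or "MAIA" not in v:
            raise ValueError("devices must include 'MP3' and 'MAIA'")
        return v

    # -- serialisation ------------------------------------------------------

    def to_json(self, path=None) -> str:
        text = json.dumps(self.model_dump(mode="json"), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.model_validate(json.load(fh))

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]

    # -- derived geometry ---------------------------------------------------

    @property
    def um_per_px(self) -> float:
        return self.um_per_degree / self.px_per_degree

    @property
    def deg_per_mm(self) -> float:
        return 1000.0 / self.um_per_degree
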