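"""End-to-end orchestration: simulate -> register -> project -> quantify -> analyze.

Stages communicate only through their declared files, so any stage can be
rerun from the previous stage's outputs and reproduce identical downstream
results.  A JSON-lines run log records per-stage record counts, the config
hash and library versions.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from .config import PipelineConfig
from .layers import descriptives_by_exam, pointwise_table, regional_summary
from .mixedstats import (
    CANDIDATE_TERMS,
    INTERACTION_TERMS,
    dredge_bic,
    spearman_matrix,
    univariate_suite,
)
from .project import EnFaceFrame, project_grid, samples_table
from .register import Correspondences, Transform2D, estimate_transform, registration_report
from .synthcohort import (
    Cohort,
    EyePhenotype,
    exam_key,
    make_default_grid,
    make_eye,
    simulate_cohort,
)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


class _RunLog:
    def __init__(self, path: Path):
        self.path = path
        path.parent.mkdir(parents=True, exist_ok=True)
        self._fh = open(path, "w")

    def write(self, stage: str, **fields):
        rec = {"stage": stage, **fields}
        self._fh.write(json.dumps(rec, sort_keys=True) + "\n")
        self._fh.flush()

    def close(self):
        self._fh.close()


def _versions() -> dict[str, str]:
    from importlib.metadata import version

    import retmap

    return {
        "retmap": retmap.__version__,
        "python": platform.python_version(),
        **{pkg: version(pkg) for pkg in
           ("numpy", "pandas", "scipy", "tifffile", "pydantic", "click")},
    }


# ---------------------------------------------------------------------------
# File-level stage runners
# ---------------------------------------------------------------------------


def load_eye(eye_dir) -> EyePhenotype:
    """Read one eye's boundary stack + metadata back from disk."""
    eye_dir = Path(eye_dir)
    with open(eye_dir / "meta.json") as fh:
        meta = json.load(fh)
    stack = tifffile.imread(eye_dir / "boundaries.tiff").astype(float)
    surfaces = {name: stack[i] for i, name in enumerate(meta["page_order"])}
    return EyePhenotype(
        eye_id=meta["eye_id"],
        age=meta["age"],
        fovea_center=(0.0, 0.0),
        boundary_surfaces=surfaces,
        landmarks=np.empty((0, 2)),
        random_intercept=float("nan"),
        seed=-1,
    )


def register_stage(cohort_dir, config: PipelineConfig, log: Optional[_RunLog] = None
                   ) -> dict[str, Transform2D]:
    """Estimate one device->OCT transform per exam from its landmark file.

    A manually corrected file ``landmarks_manual_<exam>.csv`` overrides the
    automatic one when present.
    """
    cohort_dir = Path(cohort_dir)
    exams = pd.read_csv(cohort_dir / "exams.csv")
    transforms: dict[str, Transform2D] = {}
    flagged = 0
    for eid, device, run in exams[["eye_id", "device", "run"]].drop_duplicates().itertuples(index=False):
        key = exam_key(eid, device, int(run))
        manual = cohort_dir / f"landmarks_manual_{key}.csv"
        auto = cohort_dir / f"landmarks_{key}.csv"
        if manual.exists():
            c = Correspondences.from_csv(manual, source="manual-file")
        elif auto.exists():
            c = Correspondences.from_csv(auto, source="automatic-file")
        else:
            raise StageError("register", f"no landmark file for exam {key}")
        t = estimate_transform(c, family=config.transform_family)
        report = registration_report(t, config.review_threshold_px)
        flagged += not report.passed
        transforms[key] = t
        t.to_json(cohort_dir / f"transform_{key}.json")
    if log:
        log.write("register", n_exams=len(transforms), needs_review=flagged)
    return transforms


def project_stage(cohort_dir, config: PipelineConfig, log: Optional[_RunLog] = None):
    """Project each exam's stimuli into OCT pixels; write ``samples.csv``."""
    cohort_dir = Path(cohort_dir)
    exams = pd.read_csv(cohort_dir / "exams.csv")
    frame = EnFaceFrame.from_config(config)
    grid = make_default_grid(config)
    samples_by_exam = {}
    tables = []
    for (eid, device, run), g in exams.groupby(["eye_id", "device", "run"], sort=True):
        key = exam_key(eid, device, int(run))
        t = Transform2D.from_json(cohort_dir / f"transform_{key}.json")
        samples = project_grid(t, g, frame, config.sampling_radius_um)
        samples_by_exam[key] = samples
        tables.append(samples_table(samples, grid, eid, device, int(run)))
    table = pd.concat(tables, ignore_index=True)
    table.to_csv(cohort_dir / "samples.csv", index=False)
    if log:
        missing = int((table["status"] != "sampled").sum())
        log.write("project", n_samples=len(table), missing_outside_extent=missing)
    return samples_by_exam


def quantify_stage(cohort_dir, config: PipelineConfig, samples_by_exam,
                   log: Optional[_RunLog] = None) -> pd.DataFrame:
    """Join sensitivities with disc thicknesses; write ``pointwise.csv``."""
    cohort_dir = Path(cohort_dir)
    exams = pd.read_csv(cohort_dir / "exams.csv")
    eyes = [load_eye(d) for d in sorted((cohort_dir / "eyes").iterdir())]
    grid = make_default_grid(config)
    pw = pointwise_table(eyes, exams, samples_by_exam, grid)
    pw.to_csv(cohort_dir / "pointwise.csv", index=False)
    if log:
        log.write(
            "quantify",
            n_rows=len(pw),
            dropped_missing=int(pw["EZ"].isna().sum()),
        )
    return pw


def analyze_stage(pointwise: pd.DataFrame, config: PipelineConfig, out_dir,
                  eyes: Optional[list[EyePhenotype]] = None,
                  log: Optional[_RunLog] = None) -> dict[str, pd.DataFrame]:
    """Descriptives, univariate and selected mixed models, Spearman matrix."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    table1 = descriptives_by_exam(pointwise)
    table2 = regional_summary(pointwise, eyes=eyes, config=config)
    uni = univariate_suite(pointwise, method=config.stats.univariate_method)
    global_terms = list(CANDIDATE_TERMS)
    if config.stats.dredge_interactions:
        global_terms += list(INTERACTION_TERMS)
    ranking, best = dredge_bic(
        pointwise, global_terms, config.stats.bic_count_variance
    )
    table3_multi = best.summary()
    table3_multi["n_obs"] = best.n_obs
    table4 = spearman_matrix(pointwise)

    table1.to_csv(out_dir / "table1.csv")
    table2.to_csv(out_dir / "table2.csv")
    uni.to_csv(out_dir / "table3_univariate.csv", index=False)
    table3_multi.to_csv(out_dir / "table3_multivariable.csv")
    table4.to_csv(out_dir / "table4_spearman.csv")
    ranking.to_csv(out_dir / "model_ranking.csv", index=False)
    if log:
        log.write(
            "analyze",
            n_obs_sensitivity=int(pointwise["db"].notna().sum()),
            n_obs_thickness=int(pointwise["EZ"].notna().sum()),
            best_model=ranking["terms"].iloc[0],
            best_bic=float(ranking["BIC"].iloc[0]),
        )
    return {
        "table1": table1,
        "table2": table2,
        "table3_univariate": uni,
        "table3_multivariable": table3_multi,
        "table4_spearman": table4,
        "model_ranking": ranking,
    }


def run_all(config: Optional[PipelineConfig] = None, out_dir="retmap_run") -> Path:
    """Full pipeline into ``out_dir``; returns the report directory.

    Writes every intermediate file (cohort, transforms, samples, pointwise)
    plus the report tables and a structured run log.  Deterministic for a
    fixed config.
    """
    config = config or PipelineConfig()
    out_dir = Path(out_dir)
    report_dir = out_dir / "report"
    log = _RunLog(out_dir / "run_log.jsonl")
    log.write("start", config_hash=config.config_hash(), versions=_versions(),
              n_eyes=config.n_eyes, seed=config.seed)
    try:
        cohort = simulate_cohort(config=config, out_dir=out_dir)
        log.write("simulate", n_eyes=len(cohort.eyes), n_records=len(cohort.exams))
        register_stage(out_dir, config, log)
        samples_by_exam = project_stage(out_dir, config, log)
        pointwise = quantify_stage(out_dir, config, samples_by_exam, log)
        analyze_stage(pointwise, config, report_dir, eyes=cohort.eyes, log=log)
        log.write("done", report=str(report_dir))
    except StageError:
        raise
    except Exception as err:  # tag the failing stage for the CLI
        raise StageError("pipeline", str(err)) from err
    finally:
        log.close()
    return report_dir


# ---------------------------------------------------------------------------
# Test fixtures
# ---------------------------------------------------------------------------


def make_flat_eye(thickness_um: Optional[dict[str, float]] = None,
                  config: Optional[PipelineConfig] = None,
                  eye_id: str = "flat") -> EyePhenotype:
    """Synthetic eye with spatially constant layer thicknesses (test object)."""
    config = config or PipelineConfig()
    thickness_um = thickness_um or {"RNFL": 25.0, "GCL": 35.0, "ONL": 65.0, "EZ": 30.0}
    frame = EnFaceFrame.from_config(config)
    w = frame.width_px
    zeros = np.zeros((w, w))
    surfaces = {"ILM": zeros}
    depth = zeros
    for boundary, add in (
        ("RNFL_GCL", thickness_um["RNFL"]),
        ("GCL_IPL", thickness_um["GCL"]),
        ("OPL_ONL", config.inner_gap_um),
        ("ELM", thickness_um["ONL"]),
        ("EZ_inner", config.inner_segment_um),
        ("IZ_outer", thickness_um["EZ"]),
    ):
        depth = depth + add
        surfaces[boundary] = depth
    rng = np.random.default_rng(0)
    return EyePhenotype(
        eye_id=eye_id, age=70.0, fovea_center=(0.0, 0.0),
        boundary_surfaces=surfaces,
        landmarks=rng.uniform(-8, 8, (10, 2)),
        random_intercept=0.0, seed=0,
    )


FIXTURES = {
    "noiseless-2eye": dict(n_eyes=2, landmark_jitter_px=0.0),
    "jittered-2eye": dict(n_eyes=2, landmark_jitter_px=1.0),
    "flat-eye": None,
}


def make_fixture(name: str, out_dir) -> Path:
    """Write a tiny deterministic dataset used by the test suite."""
    out_dir = Path(out_dir)
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; known: {sorted(FIXTURES)}")
    if name == "flat-eye":
        config = PipelineConfig(n_eyes=1, seed=7, landmark_jitter_px=0.0)
        cohort = simulate_cohort(config=config)
        flat = make_flat_eye(config=config, eye_id="eye000")
        flat = EyePhenotype(
            eye_id="eye000", age=flat.age, fovea_center=flat.fovea_center,
            boundary_surfaces=flat.boundary_surfaces,
            landmarks=cohort.eyes[0].landmarks,
            random_intercept=0.0, seed=7,
        )
        cohort = Cohort(config, cohort.grid, cohort.frame, [flat], cohort.exams,
                        cohort.landmarks, cohort.truth)
        return cohort.write(out_dir)
    overrides = FIXTURES[name]
    config = PipelineConfig(seed=7, **overrides)
    simulate_cohort(config=config, out_dir=out_dir)
    return out_dir
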