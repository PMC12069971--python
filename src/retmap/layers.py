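"""Layer-thickness quantification per stimulus disc and per ETDRS region.

Four thicknesses are measured between the anatomical boundary pairs defined
in :mod:`retmap.config`: RNFL (ILM to RNFL/GCL), GCL (RNFL/GCL to GCL/IPL),
ONL (outer OPL boundary to inner ELM boundary, Henle fibre layer included)
and EZ (inner EZ boundary to outer interdigitation-zone boundary).  Disc
values are unweighted means over the stimulus's pixel set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .config import LAYERS, LAYER_BOUNDARIES
from .project import EnFaceFrame, StimulusSample
from .synthcohort import EyePhenotype, StimulusGrid, _geometry


class EmptyCohort(ValueError):
    pass


@dataclass(frozen=True)
class ThicknessSet:
    """Disc-mean thicknesses (μm) of one sampled stimulus."""

    EZ: float
    ONL: float
    GCL: float
    RNFL: float
    region: str

    def as_dict(self) -> dict[str, float]:
        return {"EZ": self.EZ, "ONL": self.ONL, "GCL": self.GCL, "RNFL": self.RNFL}


def thickness_at(
    eye: EyePhenotype, sample: StimulusSample, region: str
) -> Optional[ThicknessSet]:
    """Mean layer thicknesses over one stimulus's disc pixel set.

    Returns ``None`` for a missing (outside-extent) sample, propagating
    missingness downstream.
    """
    if sample.status != "sampled":
        return None
    iy, ix = sample.pixel_set
    values = {}
    for layer, (inner, outer) in LAYER_BOUNDARIES.items():
        diff = eye.boundary_surfaces[outer][iy, ix] - eye.boundary_surfaces[inner][iy, ix]
        values[layer] = float(diff.mean())
    return ThicknessSet(region=region, **values)


def pointwise_table(
    eyes: Iterable[EyePhenotype],
    exams: pd.DataFrame,
    samples_by_exam: dict[str, list[StimulusSample]],
    grid: StimulusGrid,
) -> pd.DataFrame:
    """Analysis-ready long table: one row per stimulus observation.

    Joins measured sensitivity with the four disc thicknesses, region label,
    eccentricity and age.  Missing (outside-extent) stimuli keep their dB
    value with NaN thicknesses, mirroring how sensitivity is observed by the
    device irrespective of OCT coverage.
    """
    from .synthcohort import exam_key

    eye_map = {e.eye_id: e for e in eyes}
    region = dict(zip(grid.stimulus_ids, grid.regions))
    ecc = dict(zip(grid.stimulus_ids, grid.eccentricity_deg))
    rows = []
    for (eid, device, run), g in exams.groupby(["eye_id", "device", "run"], sort=True):
        eye = eye_map[eid]
        samples = {s.stimulus_id: s for s in samples_by_exam[exam_key(eid, device, int(run))]}
        for rec in g.itertuples(index=False):
            sid = int(rec.stimulus_id)
            s = samples[sid]
            ts = thickness_at(eye, s, region[sid])
            row = {
                "eye_id": eid,
                "device": device,
                "run": int(run),
                "stimulus_id": sid,
                "db": rec.db,
                "EZ": np.nan,
                "ONL": np.nan,
                "GCL": np.nan,
                "RNFL": np.nan,
                "region": region[sid],
                "eccentricity": ecc[sid],
                "age": eye.age,
                "status": s.status,
            }
            if ts is not None:
                row.update(ts.as_dict())
            rows.append(row)
    return pd.DataFrame(rows)


def overall_regional_means(eye: EyePhenotype, config) -> pd.DataFrame:
    """Volume-wide regional thickness means of one eye (scan-clipped masks)."""
    geom = _geometry(config)
    out = {}
    for layer in LAYERS:
        field = eye.thickness_field(layer)
        out[layer] = {
            reg: float(field[mask].mean()) for reg, mask in geom.region_masks.items()
        }
    return pd.DataFrame(out).T  # layers x regions


def regional_summary(
    pointwise: pd.DataFrame,
    eyes: Optional[Iterable[EyePhenotype]] = None,
    config=None,
) -> pd.DataFrame:
    """Regional descriptive table (mean ± SD of the four layer thicknesses).

    Pointwise block: per-stimulus observations by region, *excluding* the
    stimuli on the parafovea/perifovea border.  Overall block (when eyes are
    supplied): each eye's volume-wide regional mean over the scan-clipped
    ETDRS masks, summarised across eyes (n = number of eyes).
    """
    if len(pointwise) == 0:
        raise EmptyCohort("no pointwise records")
    regions = ("fovea", "parafovea", "perifovea")
    rows = []
    for layer in LAYERS:
        row: dict[str, object] = {"layer": layer}
        for reg in regions:
            sub = pointwise.loc[pointwise["region"] == reg, layer].dropna()
            row[f"pointwise_{reg}_mean"] = sub.mean()
            row[f"pointwise_{reg}_sd"] = sub.std()
        rows.append(row)
    table = pd.DataFrame(rows).set_index("layer")
    for reg in regions:
        table.loc["n", f"pointwise_{reg}_mean"] = float(
            pointwise.loc[pointwise["region"] == reg, "EZ"].notna().sum()
        )

    if eyes is not None:
        eyes = list(eyes)
        per_eye = [overall_regional_means(e, config) for e in eyes]
        for reg in regions:
            vals = pd.DataFrame({e.eye_id: m[reg] for e, m in zip(eyes, per_eye)})
            table.loc[LAYERS, f"overall_{reg}_mean"] = vals.mean(axis=1)
            table.loc[LAYERS, f"overall_{reg}_sd"] = vals.std(axis=1)
            table.loc["n", f"overall_{reg}_mean"] = float(len(eyes))
    return table


def descriptives_by_exam(pointwise: pd.DataFrame) -> pd.DataFrame:
    """Per device/run descriptive statistics of sensitivity and thicknesses.

    Sensitivity is summarised over all stimulus observations; thicknesses
    over the sampled (non-missing) ones only.
    """
    if len(pointwise) == 0:
        raise EmptyCohort("no pointwise records")
    rows = []
    for var in ("db", *LAYERS):
        row: dict[str, object] = {"variable": "sensitivity" if var == "db" else var}
        n_total = 0
        for (device, run), g in pointwise.groupby(["device", "run"], sort=True):
            vals = g[var].dropna()
            row[f"{device}_run{run}_mean"] = vals.mean()
            row[f"{device}_run{run}_sd"] = vals.std()
            n_total += len(vals)
        row["observations"] = n_total
        rows.append(row)
    return pd.DataFrame(rows).set_index("variable")
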