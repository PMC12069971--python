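"""Projection of stimuli into the OCT en-face frame and 70 μm disc sampling.

Coordinate conventions (used everywhere):

* en-face pixels are 0-based; pixel ``(ix, iy)`` covers ``[ix, ix+1) x
  [iy, iy+1)`` with its centre at ``(ix + 0.5, iy + 0.5)``;
* x is the A-scan axis, y the B-scan axis, both in pixels of an isotropic
  en-face raster;
* the fovea sits at ``fovea_px`` and degrees convert to pixels via
  ``px_per_degree`` and to retinal μm via ``um_per_degree``.

A stimulus is quantified over the set of pixels whose *centres* fall within
``sampling_radius_um`` (default 70 μm, i.e. a 140 μm disc) of its projected
position.  A stimulus whose mapped centre lies outside the scan extent is
marked missing; near-edge discs keep the stimulus and simply drop the pixels
outside the raster.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .register import Transform2D


class ResolutionTooCoarse(ValueError):
    """The raster is too coarse for any pixel centre to fall in the disc."""


@dataclass(frozen=True)
class EnFaceFrame:
    """Geometry of the isotropic en-face OCT raster."""

    extent_deg: float = 20.0
    px_per_degree: float = 10.0
    um_per_degree: float = 288.0
    fovea_px: tuple[float, float] | None = None

    def __post_init__(self):
        if self.px_per_degree <= 0:
            raise ValueError("px_per_degree must be positive")
        if self.fovea_px is None:
            c = self.width_px / 2.0
            object.__setattr__(self, "fovea_px", (c, c))
        fx, fy = self.fovea_px
        if not (0 <= fx <= self.width_px and 0 <= fy <= self.width_px):
            raise ValueError("fovea must lie inside the scan extent")

    @classmethod
    def from_config(cls, config) -> "EnFaceFrame":
        return cls(
            extent_deg=config.extent_deg,
            px_per_degree=config.px_per_degree,
            um_per_degree=config.um_per_degree,
        )

    @property
    def width_px(self) -> int:
        return int(round(self.extent_deg * self.px_per_degree))

    @property
    def um_per_px(self) -> float:
        return self.um_per_degree / self.px_per_degree

    def deg_to_px(self, points_deg: np.ndarray) -> np.ndarray:
        """Fovea-relative degrees -> en-face pixel coordinates."""
        pts = np.atleast_2d(np.asarray(points_deg, float))
        out = pts * self.px_per_degree + np.asarray(self.fovea_px)
        return out if np.asarray(points_deg).ndim == 2 else out[0]

    def px_to_deg(self, points_px: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_px, float))
        out = (pts - np.asarray(self.fovea_px)) / self.px_per_degree
        return out if np.asarray(points_px).ndim == 2 else out[0]

    def contains_px(self, points_px: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_px, float))
        w = self.width_px
        ok = (pts >= 0.0).all(axis=1) & (pts <= w).all(axis=1)
        return ok if np.asarray(points_px).ndim == 2 else ok[0]


@dataclass
class StimulusSample:
    stimulus_id: int
    oct_px: tuple[float, float]
    pixel_set: tuple[np.ndarray, np.ndarray]  # (iy, ix) index arrays
    status: Literal["sampled", "missing-outside-extent"]

    @property
    def n_pixels(self) -> int:
        return len(self.pixel_set[0])


def disc_pixel_set(
    frame: EnFaceFrame, center_px: tuple[float, float], radius_um: float = 70.0
) -> tuple[np.ndarray, np.ndarray]:
    """Indices (iy, ix) of raster pixels whose centres lie within the disc."""
    r_px = radius_um / frame.um_per_px
    cx, cy = center_px
    w = frame.width_px
    ix0 = max(0, int(np.floor(cx - r_px - 1)))
    ix1 = min(w, int(np.ceil(cx + r_px + 1)))
    iy0 = max(0, int(np.floor(cy - r_px - 1)))
    iy1 = min(w, int(np.ceil(cy + r_px + 1)))
    xs = np.arange(ix0, ix1) + 0.5
    ys = np.arange(iy0, iy1) + 0.5
    X, Y = np.meshgrid(xs, ys)
    inside = (X - cx) ** 2 + (Y - cy) ** 2 <= r_px**2
    iy, ix = np.nonzero(inside)
    return iy + iy0, ix + ix0


def project_grid(
    t: Transform2D,
    exam: pd.DataFrame,
    frame: EnFaceFrame,
    radius_um: float = 70.0,
) -> list[StimulusSample]:
    """Map each stimulus of one exam into OCT pixels and attach its disc.

    ``exam`` is one exam's rows of the exam table (columns ``stimulus_id``,
    ``px_x``, ``px_y``).  Status is ``missing-outside-extent`` iff the mapped
    disc centre lies outside the scan extent; otherwise the pixel set contains
    every pixel centre within ``radius_um`` of the mapped position (pixels of
    a near-edge disc beyond the raster are dropped).
    """
    device_px = exam[["px_x", "px_y"]].to_numpy(float)
    oct_px = t.apply(device_px)
    inside = frame.contains_px(oct_px)
    samples: list[StimulusSample] = []
    for sid, (x, y), ok in zip(exam["stimulus_id"].to_numpy(), oct_px, inside):
        if not ok:
            samples.append(
                StimulusSample(int(sid), (float(x), float(y)),
                               (np.empty(0, int), np.empty(0, int)),
                               "missing-outside-extent")
            )
            continue
        pix = disc_pixel_set(frame, (x, y), radius_um)
        if len(pix[0]) == 0:
            raise ResolutionTooCoarse(
                f"no pixel centre within {radius_um} μm of stimulus {sid}: "
                f"raster resolution {frame.um_per_px:.1f} μm/px is too coarse"
            )
        samples.append(StimulusSample(int(sid), (float(x), float(y)), pix, "sampled"))
    return samples


def eccentricity_of(points_deg: np.ndarray, frame: EnFaceFrame | None = None) -> np.ndarray:
    """Radial eccentricity (degrees) of fovea-relative grid positions.

    Eccentricity is a design variable of the stimulus grid: it is computed
    from the nominal fovea-relative position in degrees, isotropically, not
    from the registered pixel position.
    """
    pts = np.atleast_2d(np.asarray(points_deg, float))
    ecc = np.hypot(pts[:, 0], pts[:, 1])
    return ecc if np.asarray(points_deg).ndim == 2 else float(ecc[0])


def samples_table(
    samples: Iterable[StimulusSample],
    grid,
    eye_id: str,
    device: str,
    run: int,
) -> pd.DataFrame:
    """Flat per-exam sample table (``samples.csv`` rows)."""
    ecc = {int(s): e for s, e in zip(grid.stimulus_ids, grid.eccentricity_deg)}
    rows = [
        {
            "eye_id": eye_id,
            "device": device,
            "run": run,
            "stimulus_id": s.stimulus_id,
            "status": s.status,
            "oct_px_x": s.oct_px[0],
            "oct_px_y": s.oct_px[1],
            "eccentricity_deg": ecc[s.stimulus_id],
        }
        for s in samples
    ]
    return pd.DataFrame(rows)
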