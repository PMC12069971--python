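"""Landmark-based least-squares registration of MP device images to OCT-NIR.

A microperimetry exam reports stimulus positions in device-image pixels.  The
OCT en-face (NIR) frame is the common coordinate system of the analysis, so
each exam needs a 2-D transform estimated from vessel-junction landmark
correspondences.  At least three non-collinear pairs are required; the fit
minimises the sum of squared pixel errors.

Two transform families are supported: a full 6-parameter affine (default) and
a 4-parameter similarity (rotation + isotropic scale + translation).  There is
no outlier rejection — a poor residual raises a needs-review flag instead,
standing in for the expert review / manual re-marking step of the acquisition
protocol.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd


class RegistrationError(ValueError):
    pass


class InsufficientLandmarks(RegistrationError):
    """Fewer than three correspondence pairs."""


class DegenerateConfiguration(RegistrationError):
    """Landmarks are (numerically) collinear or coincident."""


@dataclass(frozen=True)
class Correspondences:
    """Paired landmark pixel positions, device image vs OCT-NIR."""

    device_px: np.ndarray  # (n, 2)
    oct_px: np.ndarray     # (n, 2)
    source: Literal["automatic-file", "manual-file", "in-memory"] = "in-memory"

    def __post_init__(self):
        d = np.asarray(self.device_px, float)
        o = np.asarray(self.oct_px, float)
        if d.ndim != 2 or d.shape[1] != 2 or d.shape != o.shape:
            raise RegistrationError("correspondences must be matching (n, 2) arrays")
        if not (np.isfinite(d).all() and np.isfinite(o).all()):
            raise RegistrationError("correspondences must be finite")
        object.__setattr__(self, "device_px", d)
        object.__setattr__(self, "oct_px", o)

    def __len__(self) -> int:
        return self.device_px.shape[0]

    @classmethod
    def from_csv(cls, path, source: str = "automatic-file") -> "Correspondences":
        df = pd.read_csv(path)
        cols = ["px_x_device", "px_y_device", "px_x_oct", "px_y_oct"]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise RegistrationError(f"landmark file {path} lacks columns {missing}")
        return cls(
            device_px=df[cols[:2]].to_numpy(float),
            oct_px=df[cols[2:]].to_numpy(float),
            source=source,  # type: ignore[arg-type]
        )


@dataclass
class Transform2D:
    """2x3 affine matrix mapping device pixels to OCT-NIR pixels."""

    matrix: np.ndarray  # rows (a11 a12 tx; a21 a22 ty)
    rms_residual: float = 0.0
    n_points: int = 0

    def __post_init__(self):
        m = np.asarray(self.matrix, float)
        if m.shape != (2, 3):
            raise RegistrationError("transform matrix must be 2x3")
        if not np.isfinite(m).all():
            raise RegistrationError("transform matrix must be finite")
        if self.rms_residual < 0:
            raise RegistrationError("rms_residual must be >= 0")
        self.matrix = m

    @classmethod
    def identity(cls) -> "Transform2D":
        return cls(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        out = pts @ self.matrix[:, :2].T + self.matrix[:, 2]
        return out if np.asarray(points).ndim == 2 else out[0]

    def inverse(self) -> "Transform2D":
        A = self.matrix[:, :2]
        t = self.matrix[:, 2]
        Ainv = np.linalg.inv(A)
        return Transform2D(np.hstack([Ainv, (-Ainv @ t)[:, None]]),
                           rms_residual=self.rms_residual, n_points=self.n_points)

    def compose(self, other: "Transform2D") -> "Transform2D":
        """self ∘ other: apply ``other`` first, then ``self``."""
        A = self.matrix[:, :2] @ other.matrix[:, :2]
        t = self.matrix[:, :2] @ other.matrix[:, 2] + self.matrix[:, 2]
        return Transform2D(np.hstack([A, t[:, None]]))

    def to_json(self, path=None) -> str:
        payload = {
            "matrix": [float(v) for v in self.matrix.ravel()],  # row-major 2x3
            "rms_residual": float(self.rms_residual),
            "n_points": int(self.n_points),
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "Transform2D":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.array(d["matrix"], float).reshape(2, 3),
                   rms_residual=d["rms_residual"], n_points=d["n_points"])


_COLLINEARITY_RTOL = 1e-8


def _check_degenerate(device_px: np.ndarray) -> None:
    centred = device_px - device_px.mean(axis=0)
    s = np.linalg.svd(centred, compute_uv=False)
    if s[0] == 0.0 or s[-1] < _COLLINEARITY_RTOL * s[0]:
        raise DegenerateConfiguration(
            "landmarks are collinear or coincident; cannot estimate a transform"
        )


def estimate_transform(
    c: Correspondences, family: Literal["affine", "similarity"] = "affine"
) -> Transform2D:
    """Least-squares transform estimate from landmark correspondences.

    Solves min_A sum_i ||A p_i - q_i||^2 over the requested family via the
    normal equations (numpy lstsq).  Deterministic; raises
    :class:`InsufficientLandmarks` for fewer than 3 pairs and
    :class:`DegenerateConfiguration` for a collinear design.
    """
    if len(c) < 3:
        raise InsufficientLandmarks(
            f"need at least 3 correspondence pairs, got {len(c)}"
        )
    _check_degenerate(c.device_px)
    p, q = c.device_px, c.oct_px
    n = len(c)

    if family == "affine":
        design = np.hstack([p, np.ones((n, 1))])
        sol, *_ = np.linalg.lstsq(design, q, rcond=None)
        matrix = sol.T  # (2, 3)
    elif family == "similarity":
        # params (a, b, tx, ty): [[a, -b], [b, a]] rotation-scale
        design = np.zeros((2 * n, 4))
        design[0::2, 0] = p[:, 0]
        design[0::2, 1] = -p[:, 1]
        design[0::2, 2] = 1.0
        design[1::2, 0] = p[:, 1]
        design[1::2, 1] = p[:, 0]
        design[1::2, 3] = 1.0
        rhs = q.ravel()
        (a, b, tx, ty), *_ = np.linalg.lstsq(design, rhs, rcond=None)
        matrix = np.array([[a, -b, tx], [b, a, ty]])
    else:  # pragma: no cover - guarded by config Literal
        raise ValueError(f"unknown transform family {family!r}")

    t = Transform2D(matrix, n_points=n)
    resid = t.apply(p) - q
    t.rms_residual = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return t


@dataclass(frozen=True)
class RegistrationReport:
    passed: bool
    rms_residual: float
    threshold_px: float
    n_points: int
    flag: str = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "flag", "pass" if self.passed else "needs-review")


def registration_report(t: Transform2D, threshold_px: float = 2.0) -> RegistrationReport:
    """Automated surrogate for expert review of a registration result.

    Flags ``needs-review`` when the post-fit RMS landmark residual exceeds
    ``threshold_px``.  Pipelines honour a manually corrected correspondence
    file, when present, over the automatic one.
    """
    return RegistrationReport(
        passed=t.rms_residual <= threshold_px,
        rms_residual=t.rms_residual,
        threshold_px=threshold_px,
        n_points=t.n_points,
    )
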