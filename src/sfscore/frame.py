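"""Reference geometry for the structural fragility score.

The score lives in a two-dimensional trait plane: cortical porosity (x, %)
against trabecular density (y, mg HA/cm³). The reference frame is built in two
steps:

1. **Centroid O** — the mean porosity/density of a healthy premenopausal
   reference cohort, together with the premenopausal SDs. All geometry is done
   in *standardized* coordinates (centered on O, divided by the premenopausal
   SDs), which makes distances unit-free and the score invariant to affine
   unit changes of either trait.
2. **Deterioration axis U and endpoint Z** — U points from O toward the
   fracture-derivation cloud (more porosity, less density: quadrant IV). Its
   slope is the arithmetic mean of the per-point slopes from O to each
   fracture-cohort subject in standardized space. Z is the maximal orthogonal
   projection of the fracture points onto U — the maximum observed
   deterioration — and the score scale maps the distance |O→Z| to 100 score
   units.

A subject at O therefore scores 0 and a subject at Z scores 100.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass

import numpy as np
import yaml

from .records import CohortTable, ValidationError

#: standardized |zx| below which a point contributes no usable slope
SLOPE_EPS = 1e-8

_FRAME_KEYS = ("o_x", "o_y", "s_x", "s_y", "slope", "ell_z", "scale")


class FrameError(ValueError):
    """The reference geometry cannot be constructed from the given cohorts."""


@dataclass(frozen=True)
class ReferenceFrame:
    """Fitted reference geometry.

    Attributes
    ----------
    o_x, o_y:
        Premenopausal mean cortical porosity (%) and trabecular density
        (mg HA/cm³) — the centroid O.
    s_x, s_y:
        Premenopausal sample SDs (n−1 denominator), same units, > 0.
    slope:
        Slope of the deterioration axis U in standardized space; negative
        (more porosity goes with less density).
    ell_z:
        Along-axis coordinate of the maximum-deterioration point Z, in
        standardized distance units, > 0.
    scale:
        Score units per standardized distance unit; ``scale * ell_z == 100``.
    """

    o_x: float
    o_y: float
    s_x: float
    s_y: float
    slope: float
    ell_z: float
    scale: float

    def __post_init__(self) -> None:
        if not (self.s_x > 0 and self.s_y > 0):
            raise FrameError(f"SDs must be positive, got s_x={self.s_x}, s_y={self.s_y}")
        if not self.slope < 0:
            raise FrameError(f"axis slope must be negative, got {self.slope}")
        if not self.ell_z > 0:
            raise FrameError(f"ell_z must be positive, got {self.ell_z}")
        if abs(self.scale * self.ell_z - 100.0) > 1e-9 * 100.0:
            raise FrameError(
                f"scale*ell_z must equal 100, got {self.scale * self.ell_z}"
            )

    @property
    def axis_unit(self) -> tuple[float, float]:
        """Unit vector along U in standardized space."""
        norm = math.hypot(1.0, self.slope)
        return 1.0 / norm, self.slope / norm

    def to_yaml(self, path: str | os.PathLike) -> None:
        """Serialize to YAML at full float precision (bit-exact reload)."""
        payload = {k: float(getattr(self, k)) for k in _FRAME_KEYS}
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, default_flow_style=False, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "ReferenceFrame":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)
        missing = [k for k in _FRAME_KEYS if k not in payload]
        if missing:
            raise FrameError(f"{path}: frame file missing keys {missing}")
        return cls(**{k: float(payload[k]) for k in _FRAME_KEYS})


def standardize(porosity, density, frame: ReferenceFrame):
    """Map raw trait values to standardized coordinates (zx, zy).

    ``zx = (porosity − o_x)/s_x``, ``zy = (density − o_y)/s_y``. Accepts
    scalars or arrays.
    """
    zx = (np.asarray(porosity, dtype=float) - frame.o_x) / frame.s_x
    zy = (np.asarray(density, dtype=float) - frame.o_y) / frame.s_y
    return zx, zy


def destandardize(zx, zy, frame: ReferenceFrame):
    """Inverse of :func:`standardize`."""
    porosity = np.asarray(zx, dtype=float) * frame.s_x + frame.o_x
    density = np.asarray(zy, dtype=float) * frame.s_y + frame.o_y
    return porosity, density


def fit_centroid(premeno: CohortTable) -> tuple[float, float, float, float]:
    """Fit O and the premenopausal SDs.

    Returns ``(o_x, o_y, s_x, s_y)`` with means and sample SDs (n−1).

    Raises
    ------
    FrameError
        If n < 3 or either trait has zero variance.
    """
    _require_cohort(premeno, "premenopausal_reference")
    if len(premeno) < 3:
        raise FrameError(
            f"need at least 3 premenopausal subjects to estimate SDs, got {len(premeno)}"
        )
    x = np.array(premeno.porosities(), dtype=float)
    y = np.array(premeno.densities(), dtype=float)
    s_x = float(x.std(ddof=1))
    s_y = float(y.std(ddof=1))
    if s_x == 0.0 or s_y == 0.0:
        raise FrameError("zero variance in a reference trait; cannot standardize")
    return float(x.mean()), float(y.mean()), s_x, s_y


@dataclass(frozen=True)
class AxisFit:
    """Fitted axis slope plus inclusion diagnostics."""

    slope: float
    n_used: int
    n_excluded: int


def fit_axis(
    o_x: float,
    o_y: float,
    s_x: float,
    s_y: float,
    fracture_ref: CohortTable,
    *,
    min_points: int = 2,
) -> AxisFit:
    """Fit the deterioration-axis slope as the mean of per-point slopes.

    Each fracture-cohort point contributes the slope ``zy_i / zx_i`` of the
    line from O to the point in standardized space; points with
    ``|zx_i| <= 1e-8`` (numerically vertical) are excluded and counted in the
    diagnostics.

    Raises
    ------
    FrameError
        If fewer than ``min_points`` usable points remain, or the mean slope
        is non-negative (the axis must point toward quadrant IV —
        higher porosity, lower density).
    """
    x = np.array(fracture_ref.porosities(), dtype=float)
    y = np.array(fracture_ref.densities(), dtype=float)
    zx = (x - o_x) / s_x
    zy = (y - o_y) / s_y
    usable = np.abs(zx) > SLOPE_EPS
    n_used = int(usable.sum())
    if n_used < min_points:
        raise FrameError(
            f"only {n_used} fracture-reference points usable for slope fitting "
            f"(need >= {min_points})"
        )
    slope = float(np.mean(zy[usable] / zx[usable]))
    if slope >= 0:
        raise FrameError(
            "axis does not point toward deterioration (mean slope "
            f"{slope:.4g} >= 0); fracture cohort is not displaced toward "
            "high porosity / low density"
        )
    return AxisFit(slope=slope, n_used=n_used, n_excluded=len(x) - n_used)


def locate_z(
    o_x: float,
    o_y: float,
    s_x: float,
    s_y: float,
    slope: float,
    fracture_ref: CohortTable,
) -> float:
    """Along-axis coordinate of Z: the maximal projection onto U.

    Projects every fracture-reference point onto the unit vector
    ``u = (1, slope)/√(1+slope²)`` in standardized space and returns the
    maximum. Raises :class:`FrameError` if no point projects into the
    deterioration direction (max ≤ 0).
    """
    x = np.array(fracture_ref.porosities(), dtype=float)
    y = np.array(fracture_ref.densities(), dtype=float)
    zx = (x - o_x) / s_x
    zy = (y - o_y) / s_y
    norm = math.hypot(1.0, slope)
    ell = (zx + slope * zy) / norm
    ell_z = float(ell.max())
    if ell_z <= 0:
        raise FrameError(
            "no fracture-reference point projects into the deterioration "
            "direction (all along-axis coordinates <= 0)"
        )
    return ell_z


def fit_frame(premeno: CohortTable, fracture_ref: CohortTable) -> ReferenceFrame:
    """Fit the full reference frame from the two derivation cohorts.

    Deterministic: no randomness, order-invariant.
    """
    _require_cohort(fracture_ref, "fracture_reference")
    o_x, o_y, s_x, s_y = fit_centroid(premeno)
    axis = fit_axis(o_x, o_y, s_x, s_y, fracture_ref)
    ell_z = locate_z(o_x, o_y, s_x, s_y, axis.slope, fracture_ref)
    return ReferenceFrame(
        o_x=o_x,
        o_y=o_y,
        s_x=s_x,
        s_y=s_y,
        slope=axis.slope,
        ell_z=ell_z,
        scale=100.0 / ell_z,
    )


def _require_cohort(table: CohortTable, expected: str) -> None:
    bad = [r.subject_id for r in table.records if r.cohort != expected]
    if bad:
        raise ValidationError(
            f"cohort table {table.label!r}: {len(bad)} record(s) do not carry "
            f"cohort label {expected!r} (first: {bad[0]!r})"
        )
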