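"""Structural fragility score (SFS) computation.

A subject's standardized coordinates are decomposed relative to the
deterioration axis U into:

* ``ell`` — along-axis coordinate (score units; signed),
* ``A``   — perpendicular distance to U (score units; always ≥ 0),
* ``B``   — remaining distance along U to the maximum-deterioration point Z,
  ``B = 100 − ell`` (signed).

The score is ``SFS = 100 − (A + B) = ell − A``: 0 at the premenopausal
centroid O, 100 at Z. It is deliberately *not* clamped — values below 0 mean
better-than-reference microstructure and values above 100 mean deterioration
beyond the worst derivation-cohort subject — because the score is an ordered
continuum and clamping would destroy monotonicity at the extremes.

Quadrants are assigned relative to O: I high porosity/high density, II low/high,
III low/low, IV high porosity/low density (the bone-loss-consistent region).
Exact ties fall to the "low" side.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .frame import ReferenceFrame, standardize
from .records import CohortTable

logger = logging.getLogger(__name__)

QUADRANTS = ("I", "II", "III", "IV")


@dataclass(frozen=True)
class ScoreResult:
    """Per-subject score decomposition.

    ``side`` records which side of U the subject lies on (+1 above, −1 below,
    0 on the axis): above U means a greater cortical than trabecular deficit.
    It is diagnostic context, not part of the score.
    """

    A: float
    B: float
    ell: float
    sfs: float
    quadrant: str
    side: int = 0


def decompose(porosity, density, frame: ReferenceFrame):
    """Project a point onto the deterioration axis.

    Returns ``(A, ell)`` in score units: the perpendicular distance to U and
    the along-axis coordinate. Accepts scalars or arrays.
    """
    zx, zy = standardize(porosity, density, frame)
    ux, uy = frame.axis_unit
    ell = frame.scale * (zx * ux + zy * uy)
    # signed orthogonal residual: positive above U (density side)
    resid = frame.scale * (zy * ux - zx * uy)
    return np.abs(resid), ell


def quadrant(porosity, density, frame: ReferenceFrame) -> str:
    """Classify a point into quadrant I–IV relative to the centroid O."""
    high_por = porosity > frame.o_x
    high_den = density > frame.o_y
    if high_por:
        return "I" if high_den else "IV"
    return "II" if high_den else "III"


def score(porosity: float, density: float, frame: ReferenceFrame) -> ScoreResult:
    """Score a single subject: ``SFS = 100 − (A + B)`` with ``B = 100 − ell``."""
    zx, zy = standardize(porosity, density, frame)
    ux, uy = frame.axis_unit
    ell = frame.scale * (float(zx) * ux + float(zy) * uy)
    resid = frame.scale * (float(zy) * ux - float(zx) * uy)
    A = abs(resid)
    B = 100.0 - ell
    return ScoreResult(
        A=A,
        B=B,
        ell=ell,
        sfs=100.0 - (A + B),
        quadrant=quadrant(porosity, density, frame),
        side=0 if resid == 0 else int(math.copysign(1, resid)),
    )


def score_cohort(cohort: CohortTable, frame: ReferenceFrame) -> dict[str, ScoreResult]:
    """Score every subject; returns a map keyed by subject_id."""
    if len(cohort) == 0:  # CohortTable forbids this, but be defensive
        logger.warning("scoring an empty cohort: empty result map")
        return {}
    return {
        rec.subject_id: score(rec.cortical_porosity, rec.trabecular_density, frame)
        for rec in cohort.records
    }
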