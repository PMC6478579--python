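import math

import numpy as np
import pytest

from sfscore import CohortTable, ReferenceFrame, SubjectRecord


@pytest.fixture
def simple_frame() -> ReferenceFrame:
    """Frame with O=(40, 120), SDs (10, 20), axis slope −1, |O→Z| = 2√2."""
    ell_z = 2.0 * math.sqrt(2.0)
    return ReferenceFrame(
        o_x=40.0, o_y=120.0, s_x=10.0, s_y=20.0,
        slope=-1.0, ell_z=ell_z, scale=100.0 / ell_z,
    )


def make_cohort(points, cohort="premenopausal_reference", fracture=None, prefix="S"):
    """Cohort from raw (porosity, density) pairs."""
    points = list(points)
    frac = fracture
    if frac is None and cohort in ("fracture_reference", "evaluation"):
        frac = [True] * len(points)
    records = [
        SubjectRecord(
            subject_id=f"{prefix}{i}",
            age=30.0,
            cortical_porosity=float(x),
            trabecular_density=float(y),
            fracture=None if frac is None else bool(frac[i]),
            cohort=cohort,
        )
        for i, (x, y) in enumerate(points)
    ]
    return CohortTable(records=records, label="test")


def standardized_cohort(frame, z_points, cohort="fracture_reference"):
    """Cohort whose standardized coordinates under ``frame`` equal z_points."""
    raw = [
        (frame.o_x + frame.s_x * zx, frame.o_y + frame.s_y * zy)
        for zx, zy in z_points
    ]
    return make_cohort(raw, cohort=cohort)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)
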