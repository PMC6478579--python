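"""Synthetic cohort generation.

No cohort data are deposited with the source study, so everything downstream
is exercised on synthetic cohorts that have the statistical structure the
scoring method assumes:

* **Premenopausal reference** — bivariate Gaussian cloud of (porosity,
  density) with configurable means, SDs and correlation, truncated by redraw
  to the physical ranges (porosity in [0, 100] %, density >= 0); ages uniform
  20–40.
* **Fracture-derivation cohort** — points displaced from the reference
  centroid along a latent deterioration axis (slope < 0 in standardized
  space): along-axis displacement ~ N(drift_mean, drift_sd) plus orthogonal
  Gaussian noise. The method's geometric assumption is literally true in the
  generator, which makes parameter-recovery tests interpretable.
* **Postmenopausal evaluation cohort** — a premenopausal-style draw plus
  age-dependent drift along the same axis (``drift_per_decade`` standardized
  units per decade after 50, with subject-level noise) plus orthogonal noise;
  ages uniform over ``age_range``. Fracture status is then assigned by a
  logistic model on the subject's fragility score, and cases/controls are
  sampled to fixed quotas, mirroring a matched case–control design.

Seeding: one master seed; each operation derives an independent child stream
via ``numpy.random.SeedSequence.spawn``, so every cohort in a bundle is
independently reproducible.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from typing import Optional

import numpy as np

from .frame import ReferenceFrame, fit_frame
from .records import CohortTable, SubjectRecord
from .scoring import score_cohort


class SimulationError(RuntimeError):
    """The requested cohort cannot be generated under the configuration."""


@dataclass(frozen=True)
class GeneratorConfig:
    """All distribution, drift and fracture-model parameters.

    Defaults emulate a distal-radius HR-pQCT case–control study: reference
    sample of 324 premenopausal women, 33 fractured women for the axis
    derivation, and a 99-case / 105-control postmenopausal evaluation set
    whose control-arm medians land near 39.5 % porosity and 86 mg HA/cm³
    trabecular density.
    """

    # premenopausal reference cloud
    premeno_mean_porosity: float = 36.0     # % of cortical volume
    premeno_mean_density: float = 102.0     # mg HA/cm³
    premeno_sd_porosity: float = 4.0
    premeno_sd_density: float = 25.0
    premeno_corr: float = -0.3

    # deterioration geometry (standardized space)
    axis_slope_true: float = -1.0
    aging_drift_per_decade: float = 0.9     # SD-units along the axis per decade after 50
    drift_sd: float = 0.5                   # subject-level SD of the drift
    orthogonal_noise_sd: float = 0.4        # off-axis scatter
    fracture_ref_drift_mean: float = 4.5    # along-axis displacement of the fracture cohort
    fracture_ref_drift_sd: float = 0.8

    # fracture model: P(fracture) = logistic(intercept + beta * SFS)
    fracture_intercept: float = -2.5        # log-odds
    fracture_beta: float = 0.05             # log-odds per SFS unit

    # cohort sizes and ages
    age_range: tuple[float, float] = (50.0, 80.0)
    fracture_ref_age_range: tuple[float, float] = (50.0, 90.0)
    n_premeno: int = 324
    n_fracture_ref: int = 33
    n_cases: int = 99
    n_controls: int = 105

    seed: int = 0

    def __post_init__(self) -> None:
        if self.premeno_sd_porosity <= 0 or self.premeno_sd_density <= 0:
            raise ValueError("premenopausal SDs must be positive")
        if not abs(self.premeno_corr) < 1:
            raise ValueError("|premeno_corr| must be < 1")
        if self.axis_slope_true >= 0:
            raise ValueError("axis_slope_true must be negative")
        for name in ("n_premeno", "n_fracture_ref", "n_cases", "n_controls"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be increasing")

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["age_range"] = list(self.age_range)
        d["fracture_ref_age_range"] = list(self.fracture_ref_age_range)
        return d


@dataclass(frozen=True)
class CohortBundle:
    """All three synthetic cohorts plus the true generating parameters."""

    premeno: CohortTable
    fracture_ref: CohortTable
    evaluation: CohortTable
    truth: dict


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.Generator(np.random.PCG64(s)) for s in np.random.SeedSequence(seed).spawn(n)]


def _axis_vectors(slope: float) -> tuple[np.ndarray, np.ndarray]:
    u = np.array([1.0, slope]) / np.hypot(1.0, slope)
    u_perp = np.array([-u[1], u[0]])
    return u, u_perp


def _draw_premeno_z(config: GeneratorConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Standardized correlated Gaussian pairs (zx, zy)."""
    chol = np.linalg.cholesky(
        np.array([[1.0, config.premeno_corr], [config.premeno_corr, 1.0]])
    )
    return rng.standard_normal((n, 2)) @ chol.T


def _to_raw(config: GeneratorConfig, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    por = config.premeno_mean_porosity + config.premeno_sd_porosity * z[:, 0]
    den = config.premeno_mean_density + config.premeno_sd_density * z[:, 1]
    return por, den


def _truncate_redraw(config, z, rng, extra_shift=None, max_rounds: int = 200) -> np.ndarray:
    """Redraw the base Gaussian for subjects outside physical trait ranges.

    ``extra_shift`` is a fixed per-subject standardized offset (drift + noise)
    kept constant across redraws. Errors out if the acceptance rate of the
    first round falls below 1%.
    """
    shift = np.zeros_like(z) if extra_shift is None else extra_shift
    for round_no in range(max_rounds):
        por, den = _to_raw(config, z + shift)
        bad = (por < 0.0) | (por > 100.0) | (den < 0.0)
        n_bad = int(bad.sum())
        if round_no == 0 and z.shape[0] >= 100 and n_bad > 0.99 * z.shape[0]:
            raise SimulationError(
                f"truncation acceptance below 1% ({z.shape[0] - n_bad}/{z.shape[0]}); "
                "configured distribution is incompatible with physical trait ranges"
            )
        if n_bad == 0:
            return z + shift
        z[bad] = _draw_premeno_z(config, n_bad, rng)
    raise SimulationError("truncation redraw did not converge")


def _records(prefix, ages, por, den, cohort, fracture=None) -> list[SubjectRecord]:
    recs = []
    for i in range(len(ages)):
        recs.append(
            SubjectRecord(
                subject_id=f"{prefix}{i + 1:05d}",
                age=float(ages[i]),
                cortical_porosity=float(por[i]),
                trabecular_density=float(den[i]),
                fracture=None if fracture is None else bool(fracture[i]),
                cohort=cohort,
            )
        )
    return recs


def generate_premenopausal(
    config: GeneratorConfig, seed: Optional[int] = None
) -> CohortTable:
    """Draw the premenopausal reference cohort."""
    rng = np.random.Generator(np.random.PCG64(config.seed if seed is None else seed))
    z = _draw_premeno_z(config, config.n_premeno, rng)
    z = _truncate_redraw(config, z, rng)
    por, den = _to_raw(config, z)
    ages = rng.uniform(20.0, 40.0, config.n_premeno)
    return CohortTable(
        records=_records("P", ages, por, den, "premenopausal_reference"),
        label="synthetic premenopausal reference",
    )


def generate_fracture_reference(
    config: GeneratorConfig, seed: Optional[int] = None
) -> CohortTable:
    """Draw the fracture-derivation cohort: on-axis displacement + orthogonal noise."""
    rng = np.random.Generator(np.random.PCG64(config.seed if seed is None else seed))
    n = config.n_fracture_ref
    u, u_perp = _axis_vectors(config.axis_slope_true)
    z = np.zeros((n, 2))
    need = np.ones(n, dtype=bool)
    for _ in range(200):  # redraw (t, w) for subjects outside physical ranges
        k = int(need.sum())
        if k == 0:
            break
        t = rng.normal(config.fracture_ref_drift_mean, config.fracture_ref_drift_sd, k)
        w = rng.normal(0.0, config.orthogonal_noise_sd, k)
        z[need] = t[:, None] * u + w[:, None] * u_perp
        por, den = _to_raw(config, z)
        need &= (por < 0.0) | (por > 100.0) | (den < 0.0)
    else:
        raise SimulationError("fracture-reference truncation redraw did not converge")
    por, den = _to_raw(config, z)
    ages = rng.uniform(*config.fracture_ref_age_range, n)
    return CohortTable(
        records=_records("F", ages, por, den, "fracture_reference", fracture=np.ones(n, bool)),
        label="synthetic fracture derivation cohort",
    )


def generate_postmenopausal(
    config: GeneratorConfig,
    seed: Optional[int] = None,
    n: Optional[int] = None,
    cohort: str = "evaluation",
) -> CohortTable:
    """Draw a postmenopausal cohort with age-dependent axis drift.

    Each subject is a premenopausal-style draw displaced by
    ``drift_per_decade · (age − 50)/10 + N(0, drift_sd)`` standardized units
    along the true deterioration axis plus orthogonal noise. Fracture status
    is left unset (all False for the evaluation label's validity) until
    :func:`assign_fracture` is applied.
    """
    rng = np.random.Generator(np.random.PCG64(config.seed if seed is None else seed))
    n = config.n_cases + config.n_controls if n is None else n
    ages = rng.uniform(*config.age_range, n)
    u, u_perp = _axis_vectors(config.axis_slope_true)
    t = config.aging_drift_per_decade * (ages - 50.0) / 10.0 + rng.normal(0, config.drift_sd, n)
    w = rng.normal(0.0, config.orthogonal_noise_sd, n)
    shift = t[:, None] * u + w[:, None] * u_perp
    z = _draw_premeno_z(config, n, rng)
    z = _truncate_redraw(config, z, rng, extra_shift=shift)
    por, den = _to_raw(config, z)
    return CohortTable(
        records=_records("E", ages, por, den, cohort, fracture=np.zeros(n, bool)),
        label="synthetic postmenopausal cohort",
    )


def assign_fracture(
    cohort: CohortTable,
    frame: ReferenceFrame,
    config: GeneratorConfig,
    seed: Optional[int] = None,
) -> CohortTable:
    """Assign fracture flags by a logistic model on the fragility score.

    ``fracture ~ Bernoulli(logistic(intercept + beta · SFS))`` with SFS
    computed under ``frame``.
    """
    rng = np.random.Generator(np.random.PCG64(config.seed if seed is None else seed))
    scores = score_cohort(cohort, frame)
    sfs = np.array([scores[r.subject_id].sfs for r in cohort.records])
    prob = 1.0 / (1.0 + np.exp(-(config.fracture_intercept + config.fracture_beta * sfs)))
    flags = rng.random(len(cohort)) < prob
    recs = [
        replace(rec, fracture=bool(flag))
        for rec, flag in zip(cohort.records, flags)
    ]
    return CohortTable(records=recs, label=cohort.label)


def generate_case_control(config: GeneratorConfig, max_batches: int = 50) -> CohortBundle:
    """Generate the full three-cohort bundle.

    Fits a reference frame on the generated premenopausal and
    fracture-derivation cohorts, then draws postmenopausal subjects in
    batches, assigns fracture status, and samples (without replacement, in
    draw order) to the configured case/control quotas.
    """
    rngs = np.random.SeedSequence(config.seed).spawn(4)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in rngs]
    premeno = generate_premenopausal(config, seed=seeds[0])
    fracture_ref = generate_fracture_reference(config, seed=seeds[1])
    frame = fit_frame(premeno, fracture_ref)

    cases: list[SubjectRecord] = []
    controls: list[SubjectRecord] = []
    batch = 4 * (config.n_cases + config.n_controls)
    pool_seq = np.random.SeedSequence(seeds[2]).spawn(max_batches)
    assign_seq = np.random.SeedSequence(seeds[3]).spawn(max_batches)
    for b in range(max_batches):
        pool = generate_postmenopausal(
            config, seed=int(pool_seq[b].generate_state(1)[0] % (2**31)), n=batch
        )
        pool = assign_fracture(
            config=config,
            cohort=pool,
            frame=frame,
            seed=int(assign_seq[b].generate_state(1)[0] % (2**31)),
        )
        for rec in pool.records:
            if rec.fracture and len(cases) < config.n_cases:
                cases.append(rec)
            elif not rec.fracture and len(controls) < config.n_controls:
                controls.append(rec)
        if len(cases) >= config.n_cases and len(controls) >= config.n_controls:
            break
    else:
        raise SimulationError(
            f"case/control quotas ({config.n_cases}/{config.n_controls}) not met "
            f"after {max_batches} batches; fracture model yields too few of one arm"
        )

    # stable unique ids across the merged evaluation set
    merged = [
        replace(rec, subject_id=f"E{i + 1:05d}")
        for i, rec in enumerate(cases + controls)
    ]
    evaluation = CohortTable(records=merged, label="synthetic case-control evaluation")
    truth = {
        "config": config.to_dict(),
        "frame": {
            "o_x": frame.o_x,
            "o_y": frame.o_y,
            "s_x": frame.s_x,
            "s_y": frame.s_y,
            "slope": frame.slope,
            "ell_z": frame.ell_z,
            "scale": frame.scale,
        },
    }
    return CohortBundle(
        premeno=premeno, fracture_ref=fracture_ref, evaluation=evaluation, truth=truth
    )
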