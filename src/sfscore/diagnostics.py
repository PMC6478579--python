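"""Threshold-based diagnostic evaluation.

Implements the statistical battery used to validate the fragility score
against prevalent fractures in a case–control cohort:

* percentile thresholds on a reference sample (90th-centile porosity,
  5th-centile density, −2.5 SD femoral-neck BMD T-score, 90th-centile SFS);
* 2×2 contingency tables, either counted from a scored cohort or
  reconstructed from published sensitivity/specificity and group sizes;
* sensitivity/specificity with exact (Clopper–Pearson) 95% CIs;
* odds ratios with Woolf (log-normal) 95% CIs and two-sided Wald p-values;
* unconditional logistic regression (IRLS) for covariate-adjusted ORs;
* replicate-precision RMS-CV.

Directionality: high porosity, low trabecular density, low T-score and high
SFS are the at-risk ("positive") directions; boundary equality counts as
positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import ValidationError

Z_95 = 1.959963984540054  # standard-normal 97.5% quantile

TRAITS = ("porosity", "density", "bmd", "sfs")

_TRAIT_COLUMNS = {
    "porosity": "cortical_porosity",
    "density": "trabecular_density",
    "bmd": "fn_bmd_tscore",
    "sfs": "sfs",
}


class StatisticsError(ValueError):
    """A statistic is undefined for the given counts or data."""


class SeparationError(StatisticsError):
    """Logistic regression is non-identifiable (complete separation)."""


# ---------------------------------------------------------------------------
# thresholds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Thresholds:
    """Positivity cut-offs per trait.

    A subject is positive (at risk) when porosity >= porosity_cut,
    density <= density_cut, T-score <= bmd_cut, or SFS >= sfs_cut. Any cut
    may be None, in which case the trait cannot be evaluated.
    """

    porosity_cut: Optional[float] = None
    density_cut: Optional[float] = None
    bmd_cut: Optional[float] = None
    sfs_cut: Optional[float] = None

    def cut(self, trait: str) -> float:
        value = {
            "porosity": self.porosity_cut,
            "density": self.density_cut,
            "bmd": self.bmd_cut,
            "sfs": self.sfs_cut,
        }[trait]
        if value is None:
            raise StatisticsError(f"no threshold configured for trait {trait!r}")
        if not math.isfinite(value):
            raise StatisticsError(f"threshold for {trait!r} is not finite: {value}")
        return float(value)


def percentile_threshold(values: Iterable[float], p: float) -> float:
    """Linear-interpolation percentile of a sample.

    Uses the convention that the p-th percentile sits at fractional order
    statistic ``p/100 * (n - 1)`` of the sorted sample, with linear
    interpolation between neighbours (numpy's ``linear`` quantile method).
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise StatisticsError(f"need at least 2 values for a percentile, got {arr.size}")
    if not 0.0 < p < 100.0:
        raise StatisticsError(f"percentile must lie in (0, 100), got {p}")
    return float(np.quantile(arr, p / 100.0, method="linear"))


def reference_thresholds(
    porosity: Iterable[float],
    density: Iterable[float],
    sfs: Iterable[float],
    *,
    porosity_percentile: float = 90.0,
    density_percentile: float = 5.0,
    bmd_cut: float = -2.5,
    sfs_percentile: float = 90.0,
) -> Thresholds:
    """Default thresholds from the premenopausal reference cohort.

    90th-centile porosity, 5th-centile density and 90th-centile SFS of the
    reference sample, plus the conventional osteoporosis cut of −2.5 SD on
    the femoral-neck BMD T-score (an absolute cut, not reference-derived).
    """
    return Thresholds(
        porosity_cut=percentile_threshold(porosity, porosity_percentile),
        density_cut=percentile_threshold(density, density_percentile),
        bmd_cut=bmd_cut,
        sfs_cut=percentile_threshold(sfs, sfs_percentile),
    )


# ---------------------------------------------------------------------------
# 2x2 tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable:
    """Counts of a binary test against fracture status."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            if getattr(self, name) < 0:
                raise StatisticsError(f"negative cell count {name}={getattr(self, name)}")
        if self.n_cases < 1 or self.n_controls < 1:
            raise StatisticsError(
                f"need at least one case and one control, got "
                f"{self.n_cases} cases / {self.n_controls} controls"
            )

    @property
    def n_cases(self) -> int:
        return self.tp + self.fn

    @property
    def n_controls(self) -> int:
        return self.fp + self.tn

    def swapped(self) -> "ContingencyTable":
        """Table with case/control labels exchanged."""
        return ContingencyTable(tp=self.fp, fn=self.tn, fp=self.tp, tn=self.fn)


def positive_mask(df: pd.DataFrame, trait: str, thresholds: Thresholds) -> np.ndarray:
    """Boolean at-risk indicator for one trait over a scored cohort table."""
    if trait not in _TRAIT_COLUMNS:
        raise StatisticsError(f"unknown trait {trait!r}; expected one of {TRAITS}")
    col = _TRAIT_COLUMNS[trait]
    if col not in df.columns:
        raise StatisticsError(f"scored cohort lacks column {col!r} for trait {trait!r}")
    values = pd.to_numeric(df[col])
    if values.isna().any():
        sid = df.loc[values.isna(), "subject_id"].iloc[0]
        raise ValidationError(f"subject {sid!r}: missing value for trait {trait!r}")
    cut = thresholds.cut(trait)
    vals = values.to_numpy(dtype=float)
    if trait in ("porosity", "sfs"):
        return vals >= cut
    return vals <= cut


def _fracture_mask(df: pd.DataFrame) -> np.ndarray:
    frac = df["fracture"]
    if frac.isna().any():
        sid = df.loc[frac.isna(), "subject_id"].iloc[0]
        raise ValidationError(f"subject {sid!r}: missing fracture status")
    return frac.astype(bool).to_numpy()


def build_table(df: pd.DataFrame, trait: str, thresholds: Thresholds) -> ContingencyTable:
    """Count the 2×2 table of trait positivity against fracture status."""
    pos = positive_mask(df, trait, thresholds)
    case = _fracture_mask(df)
    return ContingencyTable(
        tp=int((pos & case).sum()),
        fn=int((~pos & case).sum()),
        fp=int((pos & ~case).sum()),
        tn=int((~pos & ~case).sum()),
    )


def reclassified_table(
    df: pd.DataFrame, index_trait: str, accounted_trait: str, thresholds: Thresholds
) -> ContingencyTable:
    """2×2 table for ``index_trait`` after accounting for ``accounted_trait``.

    A subject positive on the accounted-for trait is removed from the index
    trait's positives (positive = index-positive AND accounted-negative), so
    the table isolates the index trait's contribution beyond the other
    predictor.
    """
    pos = positive_mask(df, index_trait, thresholds) & ~positive_mask(
        df, accounted_trait, thresholds
    )
    case = _fracture_mask(df)
    return ContingencyTable(
        tp=int((pos & case).sum()),
        fn=int((~pos & case).sum()),
        fp=int((pos & ~case).sum()),
        tn=int((~pos & ~case).sum()),
    )


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def reconstruct_table(
    sensitivity: float, specificity: float, n_cases: int, n_controls: int
) -> ContingencyTable:
    """Rebuild a 2×2 table from published sensitivity/specificity.

    ``tp = round(sens · n_cases)``, ``tn = round(spec · n_controls)`` with
    half rounded away from zero; the complements fill fn and fp. This lets
    published odds ratios be recomputed exactly from a results table that
    prints only proportions and group sizes.
    """
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= specificity <= 1.0):
        raise StatisticsError("sensitivity and specificity must lie in [0, 1]")
    if n_cases < 1 or n_controls < 1:
        raise StatisticsError("group sizes must be >= 1")
    tp = _round_half_away(sensitivity * n_cases)
    tn = _round_half_away(specificity * n_controls)
    return ContingencyTable(tp=tp, fn=n_cases - tp, fp=n_controls - tn, tn=tn)


# ---------------------------------------------------------------------------
# interval estimates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProportionCI:
    estimate: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not self.ci_low <= self.estimate <= self.ci_high:
            raise StatisticsError(
                f"interval ({self.ci_low}, {self.ci_high}) does not bracket "
                f"estimate {self.estimate}"
            )


@dataclass(frozen=True)
class OddsRatioResult:
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass(frozen=True)
class DiagnosticSummary:
    sensitivity: ProportionCI
    specificity: ProportionCI
    odds_ratio: OddsRatioResult


def clopper_pearson(successes: int, n: int, level: float = 0.95) -> ProportionCI:
    """Exact binomial CI via beta quantiles.

    Lower bound is exactly 0 when ``successes == 0`` and the upper exactly 1
    when ``successes == n``.
    """
    if n < 1 or not 0 <= successes <= n:
        raise StatisticsError(f"invalid binomial counts {successes}/{n}")
    alpha = 1.0 - level
    lo = 0.0 if successes == 0 else float(stats.beta.ppf(alpha / 2, successes, n - successes + 1))
    hi = 1.0 if successes == n else float(stats.beta.ppf(1 - alpha / 2, successes + 1, n - successes))
    return ProportionCI(estimate=successes / n, ci_low=lo, ci_high=hi)


def sens_spec(table: ContingencyTable) -> tuple[ProportionCI, ProportionCI]:
    """Sensitivity and specificity with 95% Clopper–Pearson intervals."""
    return (
        clopper_pearson(table.tp, table.n_cases),
        clopper_pearson(table.tn, table.n_controls),
    )


def odds_ratio(table: ContingencyTable, zero_cell_correction: bool = False) -> OddsRatioResult:
    """Cross-product odds ratio with Woolf 95% CI and two-sided Wald p.

    ``OR = tp·tn / (fn·fp)``; ``SE = √(1/tp + 1/fn + 1/fp + 1/tn)`` on the
    log scale. With ``zero_cell_correction`` the Haldane–Anscombe 0.5 is
    added to every cell; without it a zero cell is an error.
    """
    cells = [float(table.tp), float(table.fn), float(table.fp), float(table.tn)]
    if any(c == 0 for c in cells):
        if not zero_cell_correction:
            raise StatisticsError(
                "zero cell in 2x2 table; enable zero_cell_correction "
                "(Haldane-Anscombe) or collect more data"
            )
        cells = [c + 0.5 for c in cells]
    tp, fn, fp, tn = cells
    or_ = (tp * tn) / (fn * fp)
    se = math.sqrt(1 / tp + 1 / fn + 1 / fp + 1 / tn)
    log_or = math.log(or_)
    z = log_or / se
    return OddsRatioResult(
        estimate=or_,
        ci_low=math.exp(log_or - Z_95 * se),
        ci_high=math.exp(log_or + Z_95 * se),
        p_value=float(2.0 * stats.norm.sf(abs(z))),
    )


def diagnostic_summary(
    table: ContingencyTable, zero_cell_correction: bool = False
) -> DiagnosticSummary:
    sens, spec = sens_spec(table)
    return DiagnosticSummary(
        sensitivity=sens,
        specificity=spec,
        odds_ratio=odds_ratio(table, zero_cell_correction=zero_cell_correction),
    )


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood logistic fit with Wald inference per coefficient."""

    names: tuple[str, ...]
    coef: np.ndarray
    se: np.ndarray
    n_iter: int
    converged: bool
    odds_ratios: dict[str, OddsRatioResult] = field(default_factory=dict)


def logistic_fit(
    outcomes: Sequence[bool] | np.ndarray,
    predictors: pd.DataFrame | np.ndarray,
    names: Optional[Sequence[str]] = None,
    *,
    tol: float = 1e-8,
    max_iter: int = 100,
    separation_bound: float = 15.0,
) -> LogisticFit:
    """Fit a logistic regression by iteratively reweighted least squares.

    An intercept is always included. Convergence is declared when the
    maximum absolute score (gradient of the log-likelihood) drops below
    ``tol``. A coefficient drifting beyond ``separation_bound`` on the
    log-odds scale is treated as complete separation and raises
    :class:`SeparationError`.
    """
    y = np.asarray(outcomes, dtype=float)
    if isinstance(predictors, pd.DataFrame):
        if names is None:
            names = list(predictors.columns)
        X = predictors.to_numpy(dtype=float)
    else:
        X = np.asarray(predictors, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if names is None:
            names = [f"x{i}" for i in range(X.shape[1])]
    if y.size != X.shape[0]:
        raise StatisticsError("outcomes and predictors have different lengths")
    n_events = int(y.sum())
    if n_events == 0 or n_events == y.size:
        raise StatisticsError("need at least one event and one non-event")
    for j in range(X.shape[1]):
        if np.ptp(X[:, j]) == 0:
            raise StatisticsError(f"predictor {names[j]!r} is constant")

    Xd = np.column_stack([np.ones_like(y), X])
    beta = np.zeros(Xd.shape[1])
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = Xd @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        score_vec = Xd.T @ (y - mu)
        if np.max(np.abs(score_vec)) < tol:
            converged = True
            break
        w = mu * (1.0 - mu)
        info = Xd.T @ (Xd * w[:, None])
        try:
            step = np.linalg.solve(info, score_vec)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                "singular information matrix; model is non-identifiable"
            ) from exc
        beta = beta + step
        if np.max(np.abs(beta[1:])) > separation_bound:
            raise SeparationError(
                "complete separation detected (a log-odds coefficient exceeded "
                f"{separation_bound}); the odds ratio is not identifiable"
            )
    eta = Xd @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    info = Xd.T @ (Xd * w[:, None])
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    all_names = ("intercept", *names)
    ors = {}
    for j, nm in enumerate(all_names):
        if nm == "intercept":
            continue
        z = beta[j] / se[j]
        ors[nm] = OddsRatioResult(
            estimate=math.exp(beta[j]),
            ci_low=math.exp(beta[j] - Z_95 * se[j]),
            ci_high=math.exp(beta[j] + Z_95 * se[j]),
            p_value=float(2.0 * stats.norm.sf(abs(z))),
        )
    return LogisticFit(
        names=all_names,
        coef=beta,
        se=se,
        n_iter=it,
        converged=converged,
        odds_ratios=ors,
    )


# ---------------------------------------------------------------------------
# replicate precision
# ---------------------------------------------------------------------------

def rms_cv(replicates: Iterable[Sequence[float]]) -> float:
    """Root-mean-square coefficient of variation across subjects, in percent.

    Each subject contributes ``cv_i = sd_i / mean_i`` (sample SD, n−1) over
    ≥2 replicate measurements; the result is ``√(mean(cv_i²)) × 100``.
    """
    cvs = []
    for i, reps in enumerate(replicates):
        arr = np.asarray(list(reps), dtype=float)
        if arr.size < 2:
            raise StatisticsError(f"subject index {i}: need >= 2 replicates, got {arr.size}")
        mean = arr.mean()
        if mean <= 0:
            raise StatisticsError(f"subject index {i}: non-positive replicate mean {mean}")
        cvs.append(arr.std(ddof=1) / mean)
    if not cvs:
        raise StatisticsError("no subjects supplied")
    return float(math.sqrt(np.mean(np.square(cvs))) * 100.0)


# ---------------------------------------------------------------------------
# full evaluation report
# ---------------------------------------------------------------------------

def _summary_dict(table: ContingencyTable, zero_cell_correction: bool) -> dict:
    summ = diagnostic_summary(table, zero_cell_correction=zero_cell_correction)
    return {
        "table": {"tp": table.tp, "fn": table.fn, "fp": table.fp, "tn": table.tn},
        "sensitivity": {
            "est": summ.sensitivity.estimate,
            "lo": summ.sensitivity.ci_low,
            "hi": summ.sensitivity.ci_high,
        },
        "specificity": {
            "est": summ.specificity.estimate,
            "lo": summ.specificity.ci_low,
            "hi": summ.specificity.ci_high,
        },
        "or": {
            "est": summ.odds_ratio.estimate,
            "lo": summ.odds_ratio.ci_low,
            "hi": summ.odds_ratio.ci_high,
            "p": summ.odds_ratio.p_value,
        },
    }


def evaluate(
    df: pd.DataFrame,
    thresholds: Thresholds,
    traits: Sequence[str] = TRAITS,
    adjust_pairs: Sequence[tuple[str, str]] = (("bmd", "sfs"), ("sfs", "bmd")),
    zero_cell_correction: bool = False,
) -> dict:
    """Full threshold-based report over a scored case–control cohort.

    For each trait: the threshold used, 2×2 counts, sensitivity/specificity
    with exact CIs, and the OR with Woolf CI and Wald p. For each
    (index, accounted) pair two adjusted variants are reported: the
    reclassification table (index-positive minus accounted-positives) and the
    index trait's OR from a joint logistic model on both binary indicators.
    """
    report: dict = {"thresholds": {t: thresholds.cut(t) for t in traits}, "traits": {}}
    for trait in traits:
        entry = _summary_dict(build_table(df, trait, thresholds), zero_cell_correction)
        entry["threshold"] = thresholds.cut(trait)
        report["traits"][trait] = entry
    for index_trait, accounted in adjust_pairs:
        adj = _summary_dict(
            reclassified_table(df, index_trait, accounted, thresholds),
            zero_cell_correction,
        )
        adj["method"] = "reclassification"
        indicators = pd.DataFrame(
            {
                index_trait: positive_mask(df, index_trait, thresholds).astype(float),
                accounted: positive_mask(df, accounted, thresholds).astype(float),
            }
        )
        try:
            fit = logistic_fit(_fracture_mask(df), indicators)
            joint = fit.odds_ratios[index_trait]
            adj["joint_logistic"] = {
                "est": joint.estimate,
                "lo": joint.ci_low,
                "hi": joint.ci_high,
                "p": joint.p_value,
            }
        except StatisticsError as exc:
            adj["joint_logistic"] = {"error": str(exc)}
        report["traits"][index_trait][f"after_{accounted}"] = adj
    return report
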