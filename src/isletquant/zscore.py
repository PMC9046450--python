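"""Conditional OXPHOS Z-scores against a resampled control population.

The central statistic.  A reference ("control") pool is drawn by sampling an
equal number of islet ROIs from each reference mouse (the minimum per-mouse
count, so no mouse dominates).  On that pool:

* log-TOMM20 gets a location/scale model (sample mean, sample SD, n-1);
* each OXPHOS subunit (NDUFB8 for complex I, MTCO1 for complex IV) gets an
  ordinary least-squares regression of log-subunit on log-TOMM20, with the
  residual SD — the standard error of estimate, SEE = sqrt(RSS / (n-2)) —
  as the conditional scale;
* log-insulin gets a location/scale model like TOMM20.

Every ROI is then scored: ``Tomm20_Z = (x - mu_T) / sigma_T`` and, per
subunit, ``Z = (y - (intercept + slope * x)) / SEE``, so a negative subunit
Z means less of the protein than its mitochondrial mass predicts.  Residual
normality of the control regression is checked (Shapiro-Wilk, warn-only).
Deficiency categories at Z < -3 (deficient) and Z < -2 (low) are
configurable conveniences, not a calibrated clinical rule.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml
from scipy import stats

from ._rng import child_rng
from .errors import ConfigurationError, DataError

__all__ = [
    "SubunitFit",
    "ControlModel",
    "build_control_pool",
    "fit_control_model",
    "validate_residuals",
    "compute_z",
    "classify_deficiency",
    "score_cohort",
]

log = logging.getLogger(__name__)

SUBUNITS = ("ndufb8", "mtco1")
MIN_POOL_SIZE = 10


@dataclass(frozen=True)
class SubunitFit:
    intercept: float
    slope: float
    see: float
    residual_normality_p: float = float("nan")


@dataclass(frozen=True)
class ControlModel:
    """Reference-population parameters for scoring."""

    mu_T: float
    sigma_T: float
    mu_ins: float
    sigma_ins: float
    subunits: dict[str, SubunitFit]
    n_ref: int
    reference_selector: str = ""
    seed: int | None = None

    def to_yaml(self, path: str | Path) -> None:
        payload = asdict(self)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ControlModel":
        payload = yaml.safe_load(Path(path).read_text())
        payload["subunits"] = {
            k: SubunitFit(**v) for k, v in payload["subunits"].items()
        }
        return cls(**payload)


def build_control_pool(
    table: pd.DataFrame, reference_selector: str, seed: int = 0
) -> pd.DataFrame:
    """Sample the reference pool: equal ROI counts per reference mouse.

    ``reference_selector`` is a pandas query expression (e.g.
    ``"genotype == 'WT' and age == '12w'"``).  From each selected mouse,
    ``m`` ROIs are drawn without replacement, where ``m`` is the minimum
    per-mouse ROI count across reference mice; sampling is seeded.
    """
    ref = table.query(reference_selector)
    if ref.empty:
        raise DataError(f"reference selector {reference_selector!r} selects no ROIs")
    counts = ref.groupby("mouse_id").size()
    if len(counts) == 1:
        log.warning(
            "single reference mouse %s: pool = all its %d ROIs", counts.index[0], counts.iloc[0]
        )
        pool = ref.copy()
    else:
        m = int(counts.min())
        if m == 0:
            raise DataError("a reference mouse contributes zero ROIs")
        rng = child_rng(seed, "control_pool")
        parts = []
        for mouse_id, grp in ref.groupby("mouse_id", sort=True):
            idx = rng.choice(len(grp), size=m, replace=False)
            parts.append(grp.iloc[np.sort(idx)])
        pool = pd.concat(parts)
    pool = pool.copy()
    pool["reference_selector"] = reference_selector
    return pool


def fit_control_model(
    pool: pd.DataFrame,
    *,
    reference_selector: str = "",
    seed: int | None = None,
    min_pool_size: int = MIN_POOL_SIZE,
) -> ControlModel:
    """Fit location/scale and per-subunit OLS models on the reference pool.

    Uses columns ``tomm20_log``, ``ndufb8_log``, ``mtco1_log``,
    ``insulin_log``.  SEE uses the n-2 residual degrees of freedom; location
    scales use the n-1 sample SD.  A perfect fit (SEE = 0) is refused rather
    than allowed to emit infinite Z-scores downstream.
    """
    n = len(pool)
    if n < min_pool_size:
        raise DataError(f"reference pool size {n} below floor {min_pool_size}")
    x = pool["tomm20_log"].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise DataError("reference pool contains excluded TOMM20 values")
    sigma_T = float(np.std(x, ddof=1))
    if sigma_T == 0:
        raise DataError("zero variance of log-TOMM20 in reference pool")

    subunits: dict[str, SubunitFit] = {}
    X = sm.add_constant(x)
    for sub in SUBUNITS:
        y = pool[f"{sub}_log"].to_numpy(dtype=float)
        res = sm.OLS(y, X).fit()
        see = float(np.sqrt(res.ssr / (n - 2)))
        if see <= 1e-10 * max(1.0, float(np.std(y, ddof=1))):
            raise DataError(f"perfect {sub} fit (SEE = 0); conditional Z undefined")
        p = float(stats.shapiro(res.resid).pvalue) if n >= 3 else float("nan")
        subunits[sub] = SubunitFit(
            intercept=float(res.params[0]),
            slope=float(res.params[1]),
            see=see,
            residual_normality_p=p,
        )

    y_ins = pool["insulin_log"].to_numpy(dtype=float)
    return ControlModel(
        mu_T=float(x.mean()),
        sigma_T=sigma_T,
        mu_ins=float(y_ins.mean()),
        sigma_ins=float(np.std(y_ins, ddof=1)),
        subunits=subunits,
        n_ref=n,
        reference_selector=reference_selector,
        seed=seed,
    )


def validate_residuals(
    model: ControlModel, pool: pd.DataFrame, alpha: float = 0.01
) -> dict[str, float]:
    """Shapiro-Wilk residual-normality p-values per subunit; warn-only.

    A p-value below ``alpha`` logs a warning that the SEE-based conditional
    Z-scores assume Gaussian residuals; the pipeline continues.
    """
    report: dict[str, float] = {}
    x = pool["tomm20_log"].to_numpy(dtype=float)
    for sub, fit in model.subunits.items():
        resid = pool[f"{sub}_log"].to_numpy(dtype=float) - (fit.intercept + fit.slope * x)
        p = float(stats.shapiro(resid).pvalue)
        report[sub] = p
        if p < alpha:
            log.warning(
                "control regression residuals for %s fail normality (Shapiro-Wilk "
                "p = %.2g < %.2g); conditional Z-scores assume Gaussian residuals",
                sub,
                p,
                alpha,
            )
    return report


def compute_z(records: pd.DataFrame, model: ControlModel) -> pd.DataFrame:
    """Score every record against the control model.

    Adds ``tomm20_z``, ``ndufb8_z``, ``mtco1_z``, ``insulin_z``.  Records
    whose TOMM20 channel is excluded get missing conditional scores with a
    ``z_missing_reason`` annotation, since the conditional prediction needs
    the mitochondrial-mass covariate.
    """
    out = records.copy()
    x = out["tomm20_log"]
    out["tomm20_z"] = (x - model.mu_T) / model.sigma_T
    for sub, fit in model.subunits.items():
        out[f"{sub}_z"] = (out[f"{sub}_log"] - (fit.intercept + fit.slope * x)) / fit.see
    out["insulin_z"] = (out["insulin_log"] - model.mu_ins) / model.sigma_ins
    missing_t = x.isna()
    if missing_t.any():
        out.loc[missing_t, "z_missing_reason"] = "tomm20 excluded"
    return out


def classify_deficiency(
    z: pd.Series | np.ndarray, thresholds: tuple[float, float] = (-2.0, -3.0)
) -> pd.Series:
    """Categorise a subunit Z-score column: normal / low / deficient.

    ``thresholds = (low, deficient)`` with low > deficient; defaults (-2, -3)
    follow the convention of SD-based deficiency calling and are
    configurable.
    """
    low, deficient = thresholds
    if not low > deficient:
        raise ConfigurationError(
            f"thresholds must satisfy low > deficient, got {thresholds}"
        )
    z = pd.Series(np.asarray(z, dtype=float))
    cat = pd.Series("normal", index=z.index, dtype=object)
    cat[z < low] = "low"
    cat[z < deficient] = "deficient"
    cat[z.isna()] = pd.NA
    return cat


def score_cohort(
    table: pd.DataFrame,
    reference_selector: str,
    seed: int = 0,
    thresholds: tuple[float, float] = (-2.0, -3.0),
) -> tuple[pd.DataFrame, ControlModel]:
    """End-to-end scoring: pool -> fit -> validate -> Z for every ROI.

    All ROIs (reference and test, islet or cell-population strata) are scored
    against the one model fitted on the reference pool.
    """
    pool = build_control_pool(table, reference_selector, seed=seed)
    model = fit_control_model(pool, reference_selector=reference_selector, seed=seed)
    validate_residuals(model, pool)
    scored = compute_z(table, model)
    for sub in SUBUNITS:
        scored[f"{sub}_cat"] = classify_deficiency(scored[f"{sub}_z"], thresholds)
    return scored, model
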