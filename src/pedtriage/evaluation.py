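"""Cross-validated discrimination, bootstrap uncertainty and calibration.

Discrimination is summarized by the rank (Mann-Whitney) AUROC of pooled
out-of-fold predictions from stratified k-fold cross-validation: each row
receives exactly one predicted risk from a model fitted without that row's
fold. Threshold metrics (sensitivity, specificity, predictive values,
likelihood ratios) get percentile bootstrap confidence intervals.
Calibration is assessed with equal-count risk bins, a logistic
recalibration fit (slope/intercept), and a bootstrap optimism correction of
the binned curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import logit as _logit
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .errors import ConfigError, DataError
from .preprocess import OUTCOME_COL

__all__ = [
    "EvalConfig",
    "cross_validated_predictions",
    "auroc",
    "threshold_metrics",
    "bootstrap_metric_ci",
    "calibration_curve",
    "CalibrationResult",
    "evaluate_model",
]


@dataclass
class EvalConfig:
    """Evaluation settings.

    ``n_folds`` stratified folds pool out-of-fold predictions (primary
    mode); ``test_fraction`` sizes the optional repeated Monte-Carlo
    holdout mode exposed by :func:`holdout_auroc`.
    """

    test_fraction: float = 0.20
    n_folds: int = 10
    n_bootstrap_metrics: int = 2000
    n_bootstrap_calibration: int = 1000
    seed: int = 0
    stratified: bool = True

    def validate(self) -> None:
        if not (0 < self.test_fraction < 1):
            raise ConfigError("test_fraction must lie in (0, 1)")
        if self.n_folds < 2:
            raise ConfigError("n_folds must be >= 2")


def _fit_predict(train: pd.DataFrame, test: pd.DataFrame, predictors, outcome_col):
    import warnings

    y = train[outcome_col].to_numpy(dtype=float)
    X = sm.add_constant(train[predictors].to_numpy(dtype=float))
    Xt = sm.add_constant(test[predictors].to_numpy(dtype=float), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, method="newton", maxiter=100)
            if res.mle_retvals.get("converged", False) and np.all(
                np.isfinite(res.params)
            ):
                return res.predict(Xt)
        except Exception:
            pass
        # separation: ridge-penalized fallback keeps the fold usable
        pen = sm.GLM(y, X, family=sm.families.Binomial()).fit_regularized(
            alpha=1e-4, L1_wt=0.0
        )
        eta = np.clip(Xt @ np.asarray(pen.params), -500, 500)
        return 1.0 / (1.0 + np.exp(-eta))


def cross_validated_predictions(
    cohort: pd.DataFrame,
    predictors: list[str],
    config: EvalConfig = EvalConfig(),
    outcome_col: str = OUTCOME_COL,
) -> np.ndarray:
    """Out-of-fold predicted risk per row from stratified k-fold CV."""
    config.validate()
    y = cohort[outcome_col].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise DataError("outcome has a single class")
    if min(np.bincount(y)) < config.n_folds:
        raise DataError(
            "too few members of the minority class for stratified folds; "
            "use a larger cohort or fewer folds"
        )
    splitter = StratifiedKFold(
        n_splits=config.n_folds, shuffle=True, random_state=config.seed
    )
    oof = np.full(len(cohort), np.nan)
    for train_idx, test_idx in splitter.split(np.zeros(len(y)), y):
        oof[test_idx] = _fit_predict(
            cohort.iloc[train_idx], cohort.iloc[test_idx], predictors, outcome_col
        )
    return oof


def holdout_auroc(
    cohort: pd.DataFrame,
    predictors: list[str],
    config: EvalConfig = EvalConfig(),
    n_repeats: int = 20,
    outcome_col: str = OUTCOME_COL,
) -> dict:
    """Repeated Monte-Carlo 80/20 split AUROC (secondary mode)."""
    from sklearn.model_selection import train_test_split

    config.validate()
    y = cohort[outcome_col].to_numpy(dtype=int)
    aucs = []
    for r in range(n_repeats):
        tr, te = train_test_split(
            np.arange(len(y)),
            test_size=config.test_fraction,
            stratify=y if config.stratified else None,
            random_state=config.seed + r,
        )
        risks = _fit_predict(
            cohort.iloc[tr], cohort.iloc[te], predictors, outcome_col
        )
        aucs.append(auroc(risks, y[te]))
    return {"mean_auroc": float(np.mean(aucs)), "per_repeat": [float(a) for a in aucs]}


def auroc(risks, outcomes) -> float:
    """Rank (Mann-Whitney) AUROC with ties counted one half.

    The probability that a randomly chosen positive outranks a randomly
    chosen negative.
    """
    risks = np.asarray(risks, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise DataError("AUROC undefined with a single outcome class")
    ranks = rankdata(risks)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


_METRICS = ("sensitivity", "specificity", "ppv", "npv", "lr_pos", "lr_neg")


def threshold_metrics(risks, outcomes, threshold: float) -> dict[str, float]:
    """Confusion-matrix metrics with ``risk > threshold`` as test-positive."""
    risks = np.asarray(risks, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    pos = risks > threshold
    tp = int(np.sum(pos & (y == 1)))
    fp = int(np.sum(pos & (y == 0)))
    fn = int(np.sum(~pos & (y == 1)))
    tn = int(np.sum(~pos & (y == 0)))
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "tn": tn,
        "sensitivity": sens,
        "specificity": spec,
        "ppv": tp / (tp + fp) if tp + fp else np.nan,
        "npv": tn / (tn + fn) if tn + fn else np.nan,
        "lr_pos": sens / (1 - spec) if spec is not np.nan and spec < 1 else np.nan,
        "lr_neg": (1 - sens) / spec if spec is not np.nan and spec > 0 else np.nan,
    }


def bootstrap_metric_ci(
    risks,
    outcomes,
    metric: str,
    threshold: float,
    n_bootstrap: int = 2000,
    seed: int = 0,
) -> dict:
    """Percentile 95% CI and SE of a threshold metric over seeded resamples.

    ``metric`` may be any of sensitivity, specificity, ppv, npv, lr_pos,
    lr_neg, or ``auroc`` (threshold ignored). Resamples on which the metric
    is undefined (an empty class) are skipped and counted.
    """
    if metric != "auroc" and metric not in _METRICS:
        raise ConfigError(f"unknown metric {metric!r}")
    if n_bootstrap < 100:
        raise ConfigError("n_bootstrap must be >= 100 for CI output")
    risks = np.asarray(risks, dtype=float)
    y = np.asarray(outcomes, dtype=int)

    def compute(r, o):
        if metric == "auroc":
            return auroc(r, o)
        return threshold_metrics(r, o, threshold)[metric]

    point = compute(risks, y)
    rng = np.random.default_rng(seed)
    stats = []
    n_skipped = 0
    n = len(y)
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n, n)
        try:
            v = compute(risks[idx], y[idx])
        except DataError:
            n_skipped += 1
            continue
        if np.isnan(v):
            n_skipped += 1
            continue
        stats.append(v)
    stats = np.asarray(stats)
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return {
        "point": float(point),
        "low": float(lo),
        "high": float(hi),
        "se": float(stats.std(ddof=1)),
        "n_skipped": n_skipped,
    }


@dataclass
class CalibrationResult:
    """Binned calibration curve with recalibration slope and intercept."""

    bins: pd.DataFrame  # bin_mid (mean predicted), observed, corrected, n
    slope: float
    intercept: float
    n_bins_requested: int
    n_bins_effective: int
    notes: str = ""


def _recalibration_fit(risks, y):
    """Logistic fit of the outcome on logit(risk); slope 1, intercept 0 is
    perfect calibration."""
    eps = 1e-12
    lp = _logit(np.clip(risks, eps, 1 - eps))
    X = sm.add_constant(lp)
    res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    return float(res.params[1]), float(res.params[0]), res


def calibration_curve(
    risks,
    outcomes,
    n_bins: int = 10,
    n_bootstrap: int = 0,
    seed: int = 0,
) -> CalibrationResult:
    """Equal-count calibration bins with optional bootstrap bias correction.

    Bins with duplicate quantile edges (e.g. near-constant risk) are merged
    and noted. The bias-corrected observed frequency shifts each bin by the
    average optimism of a recalibration map refit on resamples and evaluated
    at the original bin means.
    """
    if n_bins < 2:
        raise ConfigError("n_bins must be >= 2")
    risks = np.asarray(risks, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    notes = ""

    edges = np.unique(np.quantile(risks, np.linspace(0, 1, n_bins + 1)))
    if len(edges) < 3:  # near-constant risks: single effective bin
        bins = pd.DataFrame(
            {
                "bin_mid": [float(risks.mean())],
                "observed": [float(y.mean())],
                "corrected": [float(y.mean())],
                "n": [len(y)],
            }
        )
        slope, intercept = np.nan, np.nan
        if risks.std() > 0:
            slope, intercept, _ = _recalibration_fit(risks, y)
        return CalibrationResult(
            bins, slope, intercept, n_bins, 1, notes="risks nearly constant; single bin"
        )
    which = np.clip(np.searchsorted(edges, risks, side="right") - 1, 0, len(edges) - 2)
    eff = len(edges) - 1
    if eff < n_bins:
        notes = f"{n_bins - eff} empty/duplicate bins merged"

    mids = np.array([risks[which == b].mean() for b in range(eff)])
    obs = np.array([y[which == b].mean() for b in range(eff)])
    ns = np.array([(which == b).sum() for b in range(eff)])
    slope, intercept, res = _recalibration_fit(risks, y)

    corrected = obs.copy()
    if n_bootstrap > 0:
        eps = 1e-12
        grid = sm.add_constant(_logit(np.clip(mids, eps, 1 - eps)))
        f_orig = np.asarray(res.predict(grid))
        rng = np.random.default_rng(seed)
        optimism = np.zeros(eff)
        n_ok = 0
        for _ in range(n_bootstrap):
            idx = rng.integers(0, len(y), len(y))
            if len(np.unique(y[idx])) < 2:
                continue
            try:
                _, _, rb = _recalibration_fit(risks[idx], y[idx])
            except Exception:
                continue
            optimism += np.asarray(rb.predict(grid)) - f_orig
            n_ok += 1
        if n_ok:
            corrected = obs - optimism / n_ok
    bins = pd.DataFrame({"bin_mid": mids, "observed": obs, "corrected": corrected, "n": ns})
    return CalibrationResult(bins, slope, intercept, n_bins, eff, notes)


def evaluate_model(
    cohort: pd.DataFrame,
    predictors: list[str],
    config: EvalConfig = EvalConfig(),
    thresholds: tuple[float, float] | None = None,
    outcome_col: str = OUTCOME_COL,
    n_calibration_bins: int = 10,
) -> dict:
    """Full evaluation report: pooled CV AUROC with bootstrap CI, per-fold
    AUROCs, threshold metrics with CIs, and the calibration curve."""
    config.validate()
    y = cohort[outcome_col].to_numpy(dtype=int)
    oof = cross_validated_predictions(cohort, predictors, config, outcome_col)

    splitter = StratifiedKFold(
        n_splits=config.n_folds, shuffle=True, random_state=config.seed
    )
    per_fold = [
        auroc(oof[test], y[test])
        for _, test in splitter.split(np.zeros(len(y)), y)
    ]
    pooled = bootstrap_metric_ci(
        oof, y, "auroc", 0.5, max(config.n_bootstrap_metrics, 100), config.seed
    )
    report = {
        "n": int(len(y)),
        "n_positive": int(y.sum()),
        "pooled_auroc": pooled,
        "per_fold_auroc": [float(a) for a in per_fold],
        "threshold_metrics": {},
        "calibration": None,
    }
    for t in thresholds or ():
        entry = {}
        for m in _METRICS:
            entry[m] = bootstrap_metric_ci(
                oof, y, m, t, max(config.n_bootstrap_metrics, 100), config.seed
            )
        report["threshold_metrics"][f"{t:g}"] = entry
    cal = calibration_curve(
        oof, y, n_calibration_bins, config.n_bootstrap_calibration, config.seed
    )
    report["calibration"] = {
        "slope": cal.slope,
        "intercept": cal.intercept,
        "bins": cal.bins.to_dict(orient="list"),
        "n_bins_effective": cal.n_bins_effective,
        "notes": cal.notes,
    }
    return report
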