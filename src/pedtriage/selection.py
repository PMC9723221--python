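"""Bootstrap-stepwise AIC consensus variable selection and the final fit.

The selection engine repeats a stepwise AIC search on bootstrap resamples of
the cohort and retains the predictors present in at least a threshold
fraction (default 80%) of the converged replicate models. Stepwise search
starts from the intercept-only model and at each step makes the single
addition or removal that lowers AIC the most; ties are broken toward the
smaller model, then lexicographically, so the procedure is deterministic
given the data.

All logistic fits go through statsmodels. Replicates whose resample contains
a single outcome class, or whose fit fails to converge, are skipped and
counted; inclusion frequencies use converged replicates as denominator. The
final consensus model is a maximum-likelihood fit on the full cohort, with a
small ridge penalty as a flagged fallback under separation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ConfigError, DataError
from .model import TriageModel
from .preprocess import OUTCOME_COL

__all__ = [
    "SelectionConfig",
    "SelectionResult",
    "stepwise_aic",
    "bootstrap_consensus",
    "fit_final",
]


@dataclass
class SelectionConfig:
    """Settings of the bootstrap consensus selection."""

    n_bootstrap: int = 2000
    inclusion_threshold: float = 0.80
    direction: str = "both"  # both | forward | backward
    seed: int = 0
    max_steps: int = 50

    def validate(self) -> None:
        if self.n_bootstrap < 1:
            raise ConfigError("n_bootstrap must be >= 1")
        if not (0 < self.inclusion_threshold <= 1):
            raise ConfigError("inclusion_threshold must lie in (0, 1]")
        if self.direction not in ("both", "forward", "backward"):
            raise ConfigError("direction must be both, forward or backward")
        if self.max_steps < 1:
            raise ConfigError("max_steps must be >= 1")


@dataclass
class SelectionResult:
    """Per-predictor bootstrap inclusion frequencies and the consensus set."""

    inclusion_frequency: dict[str, float]
    consensus_set: list[str]
    n_converged_replicates: int
    n_skipped_replicates: int = 0
    threshold: float = 0.80
    per_replicate_models: list[tuple[str, ...]] | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"predictor": p, "frequency": f, "selected": p in set(self.consensus_set)}
            for p, f in sorted(
                self.inclusion_frequency.items(), key=lambda kv: (-kv[1], kv[0])
            )
        ]
        return pd.DataFrame(rows)


def _fit_logit(y: np.ndarray, X: np.ndarray):
    """One MLE logistic fit; returns the results object or None on failure."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, method="newton", maxiter=100)
        except Exception:
            return None
    if not res.mle_retvals.get("converged", False):
        return None
    if not np.all(np.isfinite(res.params)):
        return None
    return res


def _design(cohort_values: np.ndarray, cols: tuple[int, ...]) -> np.ndarray:
    n = cohort_values.shape[0]
    return np.column_stack([np.ones(n)] + [cohort_values[:, j] for j in cols])


def _penalized_aic(y, X, alpha=1e-4) -> float:
    """AIC proxy from a small-ridge fit, for separated/non-convergent moves."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            pen = sm.GLM(y, X, family=sm.families.Binomial()).fit_regularized(
                alpha=alpha, L1_wt=0.0
            )
            eta = X @ np.asarray(pen.params)
            eta = np.clip(eta, -30, 30)
            p = 1.0 / (1.0 + np.exp(-eta))
            ll = np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))
        except Exception:
            return np.inf
    return float(-2 * ll + 2 * X.shape[1])


def _aic_of(y, values, cols, cache) -> float:
    if cols in cache:
        return cache[cols]
    X = _design(values, cols)
    res = _fit_logit(y, X)
    # separation makes the MLE diverge; a ridge-penalized AIC proxy keeps a
    # perfectly predictive candidate eligible instead of silently skipping it
    aic = _penalized_aic(y, X) if res is None else res.aic
    cache[cols] = aic
    return aic


def stepwise_aic(
    cohort: pd.DataFrame,
    candidates: list[str],
    direction: str = "both",
    max_steps: int = 50,
    outcome_col: str = OUTCOME_COL,
    start: list[str] | None = None,
) -> list[str]:
    """Stepwise AIC-minimizing logistic predictor search.

    Starting from ``start`` (default: intercept-only), repeatedly applies
    the single addition (``forward``), removal (``backward``) or either
    (``both``) that lowers AIC, until no move improves it. AIC ties prefer
    the smaller model, then the lexicographically smaller predictor set.
    Non-convergent candidate moves are skipped. Returns predictors in
    ``candidates`` order.
    """
    if not candidates:
        return []
    y = cohort[outcome_col].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise DataError("outcome has a single class; stepwise selection undefined")
    values = cohort[candidates].to_numpy(dtype=float)
    order = {name: j for j, name in enumerate(candidates)}

    current: tuple[int, ...] = tuple(sorted(order[s] for s in (start or [])))
    cache: dict[tuple[int, ...], float] = {}
    current_aic = _aic_of(y, values, current, cache)

    for _ in range(max_steps):
        moves = []  # (aic, size, cols)
        if direction in ("both", "forward"):
            for j in range(len(candidates)):
                if j not in current:
                    cols = tuple(sorted(current + (j,)))
                    moves.append((_aic_of(y, values, cols, cache), len(cols), cols))
        if direction in ("both", "backward"):
            for j in current:
                cols = tuple(k for k in current if k != j)
                moves.append((_aic_of(y, values, cols, cache), len(cols), cols))
        if not moves:
            break
        best = min(moves, key=lambda m: (m[0], m[1], m[2]))
        if best[0] < current_aic - 1e-10:
            current, current_aic = best[2], best[0]
        else:
            break
    return [candidates[j] for j in sorted(current)]


def bootstrap_consensus(
    cohort: pd.DataFrame,
    candidates: list[str],
    config: SelectionConfig = SelectionConfig(),
    outcome_col: str = OUTCOME_COL,
    keep_replicate_models: bool = False,
) -> SelectionResult:
    """Bootstrap the stepwise search and form the consensus predictor set.

    Each replicate resamples the cohort rows with replacement (seeded from a
    per-replicate seed sequence spawned off ``config.seed``), reruns
    :func:`stepwise_aic`, and records the selected set. A replicate whose
    resample holds a single outcome class is skipped and counted as
    non-converged. The consensus set applies the ``>= threshold`` rule to
    the inclusion frequencies.
    """
    config.validate()
    n = len(cohort)
    counts = {p: 0 for p in candidates}
    replicate_models: list[tuple[str, ...]] = []
    n_ok = 0
    n_skip = 0
    children = np.random.SeedSequence(config.seed).spawn(config.n_bootstrap)
    y_all = cohort[outcome_col].to_numpy()
    for ss in children:
        rng = np.random.default_rng(ss)
        idx = rng.integers(0, n, n)
        if len(np.unique(y_all[idx])) < 2:
            n_skip += 1
            continue
        boot = cohort.iloc[idx]
        try:
            selected = stepwise_aic(
                boot, candidates, config.direction, config.max_steps, outcome_col
            )
        except DataError:
            n_skip += 1
            continue
        n_ok += 1
        for p in selected:
            counts[p] += 1
        if keep_replicate_models:
            replicate_models.append(tuple(selected))
    if n_ok == 0:
        raise DataError("no bootstrap replicate converged; cohort too degenerate")
    freq = {p: counts[p] / n_ok for p in candidates}
    consensus = [p for p in candidates if freq[p] >= config.inclusion_threshold]
    return SelectionResult(
        inclusion_frequency=freq,
        consensus_set=consensus,
        n_converged_replicates=n_ok,
        n_skipped_replicates=n_skip,
        threshold=config.inclusion_threshold,
        per_replicate_models=replicate_models if keep_replicate_models else None,
    )


def fit_final(
    cohort: pd.DataFrame,
    consensus_set: list[str],
    outcome_col: str = OUTCOME_COL,
    ridge_alpha: float = 1e-4,
) -> TriageModel:
    """Maximum-likelihood logistic fit of the consensus model on the cohort.

    Reports coefficients, Wald standard errors, 95% CIs on the odds-ratio
    scale, AIC and n. Under separation or non-convergence the model is refit
    with a small ridge penalty; the fallback is flagged in ``notes`` and no
    standard errors are reported in that case.
    """
    if not consensus_set:
        raise ConfigError("consensus_set must be nonempty")
    y = cohort[outcome_col].to_numpy(dtype=float)
    X = sm.add_constant(cohort[list(consensus_set)].to_numpy(dtype=float))
    res = _fit_logit(y, X)
    if res is not None:
        params = res.params
        ses = res.bse
        ci = res.conf_int()
        return TriageModel(
            intercept=float(params[0]),
            coefficients={p: float(b) for p, b in zip(consensus_set, params[1:])},
            standard_errors={p: float(s) for p, s in zip(consensus_set, ses[1:])},
            odds_ratio_ci={
                p: (float(np.exp(b)), float(np.exp(lo)), float(np.exp(hi)))
                for p, b, (lo, hi) in zip(consensus_set, params[1:], ci[1:])
            },
            n_obs=int(len(y)),
            aic=float(res.aic),
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pen = sm.GLM(y, X, family=sm.families.Binomial()).fit_regularized(
            alpha=ridge_alpha, L1_wt=0.0
        )
    params = np.asarray(pen.params)
    return TriageModel(
        intercept=float(params[0]),
        coefficients={p: float(b) for p, b in zip(consensus_set, params[1:])},
        n_obs=int(len(y)),
        notes=f"ridge fallback (alpha={ridge_alpha}): MLE did not converge "
        "(likely separation); standard errors unavailable",
    )
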