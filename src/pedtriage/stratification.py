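"""Dual-threshold risk stratification into three triage categories.

A low threshold targets at least 90% sensitivity (few missed admissions
among children labelled non-urgent) and a high threshold targets at least
90% specificity (few false alarms among children labelled emergency). A
risk at or below the low threshold is *non-urgent*; above the high
threshold, *emergency*; in between, *priority* (boundaries inclusive on the
left). Test-positivity at a boundary means ``risk > boundary``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .evaluation import bootstrap_metric_ci, threshold_metrics
from .preprocess import OUTCOME_COL

__all__ = [
    "ThresholdPair",
    "CATEGORIES",
    "select_thresholds",
    "categorize",
    "build_report",
    "StratificationReport",
]

CATEGORIES = ("non-urgent", "priority", "emergency")


@dataclass(frozen=True)
class ThresholdPair:
    """Low (non-urgent) and high (emergency) risk boundaries."""

    low: float
    high: float
    target_sensitivity: float = 0.90
    target_specificity: float = 0.90
    degenerate: bool = False

    def __post_init__(self):
        if not self.degenerate and not (0 < self.low < self.high < 1):
            raise ConfigError("thresholds must satisfy 0 < low < high < 1")


def select_thresholds(
    risks,
    outcomes,
    target_sensitivity: float = 0.90,
    target_specificity: float = 0.90,
) -> ThresholdPair:
    """Pick the dual thresholds from predicted risks and outcomes.

    Scanning the sorted unique risks as candidate boundaries (positive means
    ``risk > t``): the low threshold is the largest candidate keeping
    sensitivity at or above its target (maximizing specificity subject to
    the sensitivity floor); the high threshold is the smallest candidate
    reaching the specificity target (maximizing sensitivity subject to the
    specificity floor). If the two cross, a degenerate two-category pair is
    returned with a warning.

    Raises
    ------
    DataError
        If a target is unattainable at every candidate; the message states
        the achievable maximum.
    """
    if not (0 < target_sensitivity < 1) or not (0 < target_specificity < 1):
        raise ConfigError("targets must lie in (0, 1)")
    risks = np.asarray(risks, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    if y.min() == y.max():
        raise DataError("both outcome classes required to select thresholds")

    cand = np.unique(risks)
    n_pos = y.sum()
    n_neg = len(y) - n_pos
    # counts with risk > t for each candidate t, via cumulative sums
    order = np.argsort(risks, kind="mergesort")
    r_sorted = risks[order]
    y_sorted = y[order]
    pos_upto = np.cumsum(y_sorted)  # positives with risk <= position
    idx_last = np.searchsorted(r_sorted, cand, side="right") - 1
    tp = n_pos - pos_upto[idx_last]  # positives with risk > t
    fp = n_neg - (idx_last + 1 - pos_upto[idx_last])
    sens = tp / n_pos
    spec = (n_neg - fp) / n_neg

    ok_sens = sens >= target_sensitivity
    if not ok_sens.any():
        raise DataError(
            f"sensitivity target {target_sensitivity:.2f} unattainable; "
            f"achievable maximum {sens.max():.3f}"
        )
    low = float(cand[np.flatnonzero(ok_sens)[-1]])

    ok_spec = spec >= target_specificity
    if not ok_spec.any():
        raise DataError(
            f"specificity target {target_specificity:.2f} unattainable; "
            f"achievable maximum {spec.max():.3f}"
        )
    high = float(cand[np.flatnonzero(ok_spec)[0]])

    if low >= high:
        warnings.warn(
            "low and high thresholds cross; reporting a degenerate "
            "two-category stratification"
        )
        return ThresholdPair(
            low, low, target_sensitivity, target_specificity, degenerate=True
        )
    return ThresholdPair(low, high, target_sensitivity, target_specificity)


def categorize(risk, thresholds: ThresholdPair):
    """Triage category per risk: ``<= low`` non-urgent, ``<= high`` priority,
    otherwise emergency. Scalar in, scalar out; array in, array out."""
    r = np.asarray(risk, dtype=float)
    if np.any((r < 0) | (r > 1)):
        raise ConfigError("risks must lie in [0, 1]")
    out = np.where(
        r <= thresholds.low,
        CATEGORIES[0],
        np.where(r <= thresholds.high, CATEGORIES[1], CATEGORIES[2]),
    )
    return out.item() if np.isscalar(risk) else out


@dataclass
class StratificationReport:
    """Per-category tallies and per-boundary performance metrics."""

    thresholds: ThresholdPair
    categories: pd.DataFrame  # one row per category
    boundary_metrics: dict[str, dict]  # "low"/"high" -> metric dict
    n: int
    n_positive: int
    notes: str = ""

    def to_dict(self) -> dict:
        return {
            "thresholds": {
                "low": self.thresholds.low,
                "high": self.thresholds.high,
                "degenerate": self.thresholds.degenerate,
            },
            "n": self.n,
            "n_positive": self.n_positive,
            "categories": self.categories.to_dict(orient="records"),
            "boundary_metrics": self.boundary_metrics,
            "notes": self.notes,
        }

    def to_text(self) -> str:
        lines = [
            "Risk stratification into three triage categories",
            f"thresholds: low={self.thresholds.low:.4f} "
            f"high={self.thresholds.high:.4f}"
            + ("  [degenerate]" if self.thresholds.degenerate else ""),
            "",
            f"{'':28s}" + "".join(f"{c:>14s}" for c in self.categories["category"]),
        ]

        def row(label, key, fmt="{:d}"):
            vals = "".join(
                f"{fmt.format(v):>14s}" for v in self.categories[key]
            )
            lines.append(f"{label:28s}{vals}")

        row("participants", "n_participants")
        row("participants (%)", "pct_participants", "{:.1f}")
        row("positive outcomes", "n_positive")
        row("positive outcomes (%)", "pct_positive", "{:.1f}")
        row("admitted", "n_admitted")
        row("stay < 24 h", "n_stay_lt_24")
        row("stay 24-48 h", "n_stay_24_48")
        row("stay > 48 h", "n_stay_gt_48")
        row("readmitted within 48 h", "n_readmitted_48h")
        lines.append("")
        for name in ("low", "high"):
            m = self.boundary_metrics.get(name)
            if not m:
                continue
            lines.append(
                f"{name} boundary ({m['threshold']:.4f}): "
                f"sens={m['sensitivity']:.3f} spec={m['specificity']:.3f} "
                f"ppv={m['ppv']:.3f} npv={m['npv']:.3f} "
                f"LR+={m['lr_pos']:.2f} LR-={m['lr_neg']:.2f} "
                f"TP:FP={m['tp']}:{m['fp']}"
            )
        if self.notes:
            lines += ["", self.notes]
        return "\n".join(lines)


def build_report(
    cohort: pd.DataFrame,
    risks,
    thresholds: ThresholdPair,
    outcome_col: str = OUTCOME_COL,
    n_bootstrap_ci: int = 0,
    seed: int = 0,
) -> StratificationReport:
    """Tally the three categories and compute boundary metrics.

    ``n_bootstrap_ci > 0`` adds percentile bootstrap CIs to each boundary
    metric. Category counts always sum to the cohort size and positive
    counts to the total positives (partition property).
    """
    risks = np.asarray(risks, dtype=float)
    if len(risks) != len(cohort):
        raise DataError("risks must align with cohort rows")
    y = cohort[outcome_col].to_numpy(dtype=int)
    cats = categorize(risks, thresholds)

    admitted = cohort["admitted"].to_numpy(dtype=float)
    stay = cohort["length_of_stay_hours"].to_numpy(dtype=float)
    readmit = cohort["readmitted_within_48h"].to_numpy(dtype=float)

    rows = []
    for c in CATEGORIES:
        mask = cats == c
        nm = int(mask.sum())
        adm = (admitted == 1) & mask
        rows.append(
            {
                "category": c,
                "n_participants": nm,
                "pct_participants": 100 * nm / len(cohort),
                "n_positive": int(y[mask].sum()),
                "pct_positive": 100 * y[mask].mean() if nm else 0.0,
                "n_admitted": int(adm.sum()),
                "n_stay_lt_24": int(np.nansum(adm & (stay < 24))),
                "n_stay_24_48": int(np.nansum(adm & (stay >= 24) & (stay <= 48))),
                "n_stay_gt_48": int(np.nansum(adm & (stay > 48))),
                "n_readmitted_48h": int(np.nansum((readmit == 1) & mask)),
            }
        )
    categories = pd.DataFrame(rows)

    boundary_metrics = {}
    for name, t in (("low", thresholds.low), ("high", thresholds.high)):
        m = threshold_metrics(risks, y, t)
        m["threshold"] = float(t)
        m["tp_fp_ratio"] = (m["tp"], m["fp"])
        if n_bootstrap_ci > 0:
            for metric in ("sensitivity", "specificity", "ppv", "npv", "lr_pos", "lr_neg"):
                m[f"{metric}_ci"] = bootstrap_metric_ci(
                    risks, y, metric, t, max(n_bootstrap_ci, 100), seed
                )
        boundary_metrics[name] = m

    notes = ""
    if thresholds.degenerate:
        notes = "degenerate thresholds: priority category is empty"
    return StratificationReport(
        thresholds=thresholds,
        categories=categories,
        boundary_metrics=boundary_metrics,
        n=int(len(cohort)),
        n_positive=int(y.sum()),
        notes=notes,
    )
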