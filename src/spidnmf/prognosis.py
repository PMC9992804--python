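"""Survival screening and the linear risk-score model over module genes.

The workflow downstream of module extraction: keep patients surviving
past a minimum follow-up (90 days by default), screen each candidate
gene/miRNA with a univariate proportional-hazards fit and keep those
with p below a cutoff (0.05, uncorrected, by default), fit a
multivariate Cox model on the retained features, and summarize each
patient with the linear risk score

    risk = sum_n coef_n * x_n

where coef_n are the Cox coefficients and x_n the expression values.
Patients are split into high- and low-risk groups at the
training-cohort median risk score.  Cox fitting itself is delegated to
lifelines; this module owns the bespoke arithmetic (filters, score,
split rule).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

from .datamodel import OmicsView, SurvivalTable

logger = logging.getLogger(__name__)

__all__ = [
    "RiskModel",
    "filter_survival",
    "univariate_screen",
    "risk_score",
    "assign_risk_groups",
    "fit_risk_model",
]


@dataclass(frozen=True)
class RiskModel:
    """Linear risk score: feature IDs, Cox coefficients, median cutoff."""

    feature_ids: tuple[str, ...]
    coefficients: tuple[float, ...]
    cutoff: float = 0.0

    def __post_init__(self) -> None:
        if len(self.feature_ids) != len(self.coefficients):
            raise ValueError(
                f"{len(self.feature_ids)} features but "
                f"{len(self.coefficients)} coefficients"
            )
        if len(self.feature_ids) == 0:
            raise ValueError("risk model needs at least one feature")


def filter_survival(table: SurvivalTable, min_days: float = 90.0) -> SurvivalTable:
    """Keep patients with survival time strictly greater than ``min_days``.

    Very short follow-up times mostly reflect perioperative or
    unrelated mortality; the default drops everyone at or below 90
    days.  An empty result is allowed but logged.
    """
    keep = table.time > min_days
    if not keep.any():
        logger.warning("filter_survival: no samples remain after %g-day filter", min_days)
    ids = tuple(s for s, k in zip(table.sample_ids, keep) if k)
    return SurvivalTable(
        sample_ids=ids, time=table.time[keep], event=table.event[keep]
    )


def _align(expression: OmicsView, survival: SurvivalTable) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    common = sorted(set(expression.sample_ids) & set(survival.sample_ids))
    epos = {s: i for i, s in enumerate(expression.sample_ids)}
    spos = {s: i for i, s in enumerate(survival.sample_ids)}
    x = expression.matrix[[epos[s] for s in common]]
    t = survival.time[[spos[s] for s in common]]
    e = survival.event[[spos[s] for s in common]]
    return x, t, e, common


def univariate_screen(
    expression: OmicsView,
    survival: SurvivalTable,
    p_cutoff: float = 0.05,
    min_overlap: int = 10,
    adjust: str = "none",
) -> pd.DataFrame:
    """Per-feature univariate Cox screen; keep features with p < cutoff.

    Returns a frame indexed by feature ID with columns ``coef``, ``HR``,
    ``HR.95L``, ``HR.95H`` and ``p`` for the retained features.  No
    multiple-testing correction is applied by default (the screen is a
    deliberate raw p < 0.05 filter feeding a multivariate model);
    ``adjust="bh"`` filters on Benjamini-Hochberg-adjusted p-values
    instead.  Constant or non-convergent features are skipped and
    logged.
    """
    if adjust not in ("none", "bh"):
        raise ValueError(f"adjust must be 'none' or 'bh', got {adjust!r}")
    x, t, e, common = _align(expression, survival)
    if len(common) < min_overlap:
        raise ValueError(
            f"only {len(common)} samples shared between expression and survival; "
            f"need at least {min_overlap}"
        )
    rows = []
    for j, fid in enumerate(expression.feature_ids):
        col = x[:, j]
        if col.std() == 0:
            logger.info("univariate_screen: skipping constant feature %s", fid)
            continue
        df = pd.DataFrame({"time": t, "event": e, "x": col})
        cph = CoxPHFitter()
        try:
            cph.fit(df, duration_col="time", event_col="event")
        except (ConvergenceError, ValueError) as exc:
            logger.warning("univariate_screen: feature %s failed to fit: %s", fid, exc)
            continue
        s = cph.summary.loc["x"]
        rows.append(
            {
                "feature_id": fid,
                "coef": float(s["coef"]),
                "HR": float(s["exp(coef)"]),
                "HR.95L": float(np.exp(s["coef lower 95%"])),
                "HR.95H": float(np.exp(s["coef upper 95%"])),
                "p": float(s["p"]),
            }
        )
    result = pd.DataFrame(
        rows, columns=["feature_id", "coef", "HR", "HR.95L", "HR.95H", "p"]
    ).set_index("feature_id")
    if adjust == "bh" and len(result):
        from statsmodels.stats.multitest import multipletests

        result = result.assign(
            p_adjusted=multipletests(result["p"], method="fdr_bh")[1]
        )
        return result[result["p_adjusted"] < p_cutoff]
    return result[result["p"] < p_cutoff]


def risk_score(model: RiskModel, expression_row: Mapping[str, float]) -> float:
    """Linear risk score sum_n coef_n * x_n for one sample."""
    total = 0.0
    for fid, coef in zip(model.feature_ids, model.coefficients):
        if fid not in expression_row:
            raise KeyError(f"expression value missing for model feature {fid!r}")
        total += coef * float(expression_row[fid])
    return total


def assign_risk_groups(
    scores: Sequence[float] | np.ndarray, cutoff: float
) -> list[str]:
    """Median-style split: score > cutoff -> 'high', score <= cutoff -> 'low'."""
    if not np.isfinite(cutoff):
        raise ValueError(f"cutoff must be finite, got {cutoff}")
    return ["high" if s > cutoff else "low" for s in np.asarray(scores, dtype=float)]


def fit_risk_model(
    expression: OmicsView,
    survival: SurvivalTable,
    feature_ids: Sequence[str],
) -> RiskModel:
    """Multivariate Cox fit on the given features; cutoff = median risk.

    The coefficient estimation is routine proportional-hazards
    regression and is delegated to lifelines; the returned model holds
    only what the risk score needs.
    """
    feature_ids = [str(f) for f in feature_ids]
    missing = [f for f in feature_ids if f not in expression.feature_ids]
    if missing:
        raise KeyError(f"features not in expression view: {missing}")
    x, t, e, common = _align(expression, survival)
    pos = {f: j for j, f in enumerate(expression.feature_ids)}
    cols = [pos[f] for f in feature_ids]
    df = pd.DataFrame(x[:, cols], columns=feature_ids)
    df["time"] = t
    df["event"] = e
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    coefs = tuple(float(cph.params_[f]) for f in feature_ids)
    interim = RiskModel(feature_ids=tuple(feature_ids), coefficients=coefs)
    scores = [
        risk_score(interim, dict(zip(feature_ids, row))) for row in x[:, cols]
    ]
    return RiskModel(
        feature_ids=tuple(feature_ids),
        coefficients=coefs,
        cutoff=float(np.median(scores)),
    )
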