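"""Hyperparameter grid search over the five regularization weights.

The tunables are (lambda1, lambda2, beta, gamma1, gamma2) in that fixed
order; k is held fixed during a sweep (it is tied to sample size, not
swept jointly with the weights).  Each combination is fitted with
per-fit early stopping and ranked by the relative reconstruction
error; ties break to the lowest combination index, so sweeps are fully
deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from itertools import product
from typing import Sequence

import pandas as pd

from .datamodel import MultiViewDataset
from .factorization import Hyperparameters, fit
from .priors import CrossModalPrior, SampleGraph

logger = logging.getLogger(__name__)

__all__ = ["GridSpec", "GridResult", "enumerate_grid", "grid_search", "TUNABLES"]

TUNABLES = ("lambda1", "lambda2", "beta", "gamma1", "gamma2")

#: Candidate values used in the reference four-point sweep.
DEFAULT_CANDIDATES = (0.001, 0.01, 0.1, 1.0)


@dataclass(frozen=True)
class GridSpec:
    """Candidate values per tunable weight plus the fixed remainder.

    ``values`` maps each of lambda1, lambda2, beta, gamma1, gamma2 to a
    non-empty sequence of non-negative candidates.  ``fixed`` supplies
    k, alpha, iteration controls and so on.
    """

    fixed: Hyperparameters
    values: dict[str, tuple[float, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = dict(self.values)
        for name in TUNABLES:
            vals = tuple(values.get(name, DEFAULT_CANDIDATES))
            if len(vals) == 0:
                raise ValueError(f"empty candidate list for {name}")
            if any(v < 0 for v in vals):
                raise ValueError(f"negative candidate for {name}: {vals}")
            values[name] = vals
        unknown = set(values) - set(TUNABLES)
        if unknown:
            raise ValueError(f"unknown tunables: {sorted(unknown)}")
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class GridResult:
    combination_index: int
    hyperparameters: Hyperparameters
    relative_error: float
    iterations_run: int


def enumerate_grid(spec: GridSpec) -> list[Hyperparameters]:
    """Full Cartesian product in deterministic odometer order.

    Parameters cycle in the fixed tunable order with the last (gamma2)
    fastest; length is the product of the per-parameter counts — e.g.
    four candidates for each of the five weights give 4**5 = 1024
    combinations.
    """
    combos = []
    for values in product(*(spec.values[name] for name in TUNABLES)):
        combos.append(replace(spec.fixed, **dict(zip(TUNABLES, values))))
    return combos


def grid_search(
    dataset: MultiViewDataset,
    graph: SampleGraph | None,
    prior: CrossModalPrior | None,
    spec: GridSpec,
    early_stop_patience: int = 5,
    method: str = "spid",
) -> tuple[GridResult, list[GridResult]]:
    """Fit every combination; return (best, all results).

    Best = argmin of relative error, ties broken by the lowest
    combination index.  A fit that fails is logged and recorded with
    relative_error = inf rather than aborting the sweep.
    """
    results: list[GridResult] = []
    for idx, hp in enumerate(enumerate_grid(spec)):
        try:
            model, report = fit(
                dataset,
                hp,
                method=method,
                graph=graph,
                prior=prior,
                early_stop_patience=early_stop_patience,
            )
            err = report.relative_error_trajectory[-1] if report.iterations_run else float("inf")
            results.append(
                GridResult(
                    combination_index=idx,
                    hyperparameters=hp,
                    relative_error=err,
                    iterations_run=report.iterations_run,
                )
            )
        except (FloatingPointError, ValueError) as exc:
            logger.warning("combination %d failed: %s", idx, exc)
    if not results:
        raise RuntimeError("every grid combination failed")
    best = min(results, key=lambda r: (r.relative_error, r.combination_index))
    return best, results


def results_table(results: Sequence[GridResult]) -> pd.DataFrame:
    """Long-format sweep table: index, five weights, error, iterations."""
    rows = []
    for r in results:
        row = {"combination_index": r.combination_index}
        for name in TUNABLES:
            row[name] = getattr(r.hyperparameters, name)
        row["relative_error"] = r.relative_error
        row["iterations_run"] = r.iterations_run
        rows.append(row)
    return pd.DataFrame(rows)
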