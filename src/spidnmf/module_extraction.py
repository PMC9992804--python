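"""Co-expression module extraction and correlation scoring.

Each factor of a fitted joint NMF induces one module: the features of
every view whose coefficient in that factor's row of H_l stands out
from the row's distribution.  Membership uses the per-row z-score rule
standard in the joint-NMF module literature: feature j belongs to
factor i's module in view l iff

    H_l[i, j] > mean(H_l[i, :]) + z * sd(H_l[i, :])

with z = 2.0 by default.  Modules are scored by the |Pearson| between
the original and reconstructed submatrices restricted to member
columns, averaged over the views that contributed members; the module
with the highest mean correlation is the primary candidate for
downstream interpretation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._utils import abs_flat_pearson
from .datamodel import MultiViewDataset
from .factorization import FactorModel

logger = logging.getLogger(__name__)

__all__ = [
    "CoexpressionModule",
    "extract_modules",
    "score_module",
    "select_top_module",
    "modules_table",
]


@dataclass(frozen=True)
class CoexpressionModule:
    """Per-factor feature memberships across views, with |Pearson| scores.

    ``factor_index`` is 1-based.  ``members`` maps view_id to the tuple
    of member feature IDs; ``per_view_correlation`` is filled by
    :func:`score_module` for views with at least one member.
    """

    factor_index: int
    members: dict[str, tuple[str, ...]]
    per_view_correlation: dict[str, float] | None = None
    mean_correlation: float | None = None

    @property
    def is_scored(self) -> bool:
        return self.mean_correlation is not None


def extract_modules(
    model: FactorModel, dataset: MultiViewDataset, z_threshold: float = 2.0
) -> list[CoexpressionModule]:
    """One module per factor via the per-row z-score membership rule.

    A zero-variance row (constant coefficients) contributes no members
    for that view and is logged: no feature stands out from a flat row.
    Returns exactly k unscored modules.
    """
    k = model.hyperparameters.k
    modules = []
    for i in range(k):
        members: dict[str, tuple[str, ...]] = {}
        for view, h in zip(dataset.views, model.H):
            row = h[i]
            sd = row.std()
            if sd == 0:
                logger.info(
                    "factor %d: constant coefficient row in view %s, no members",
                    i + 1,
                    view.view_id,
                )
                members[view.view_id] = ()
                continue
            mask = row > row.mean() + z_threshold * sd
            members[view.view_id] = tuple(
                f for f, m in zip(view.feature_ids, mask) if m
            )
        modules.append(CoexpressionModule(factor_index=i + 1, members=members))
    return modules


def score_module(
    module: CoexpressionModule, model: FactorModel, dataset: MultiViewDataset
) -> CoexpressionModule:
    """Fill per-view and mean |Pearson| between X_l and W H_l on members.

    Per view, both the original and the reconstructed matrix are
    restricted to the module's member columns and flattened before the
    correlation; the mean is over views with at least one member.
    """
    if all(len(m) == 0 for m in module.members.values()):
        raise ValueError(
            f"module {module.factor_index} has no members in any view; "
            "score undefined"
        )
    per_view: dict[str, float] = {}
    for view, h in zip(dataset.views, model.H):
        member_ids = module.members.get(view.view_id, ())
        if not member_ids:
            continue
        pos = {f: j for j, f in enumerate(view.feature_ids)}
        cols = [pos[f] for f in member_ids]
        recon = model.W @ h[:, cols]
        per_view[view.view_id] = abs_flat_pearson(view.matrix[:, cols], recon)
    mean = float(np.mean(list(per_view.values())))
    return replace(module, per_view_correlation=per_view, mean_correlation=mean)


def select_top_module(modules: list[CoexpressionModule]) -> CoexpressionModule:
    """Module with maximal mean correlation; ties to the lowest factor."""
    scored = [m for m in modules if m.is_scored]
    if not scored:
        raise ValueError("no scored modules to select from")
    return max(scored, key=lambda m: (m.mean_correlation, -m.factor_index))


def modules_table(modules: list[CoexpressionModule]) -> pd.DataFrame:
    """Long-format membership table (factor_index, view, feature_id)."""
    rows = [
        {"factor_index": m.factor_index, "view": view_id, "feature_id": f}
        for m in modules
        for view_id, feats in m.members.items()
        for f in feats
    ]
    return pd.DataFrame(rows, columns=["factor_index", "view", "feature_id"])


def scores_table(modules: list[CoexpressionModule]) -> pd.DataFrame:
    """Per-module score table mirroring the membership output."""
    rows = []
    for m in modules:
        row: dict[str, float | int | None] = {"factor_index": m.factor_index}
        if m.per_view_correlation:
            for view_id, r in m.per_view_correlation.items():
                row[f"corr_{view_id}"] = r
        row["mean_correlation"] = m.mean_correlation
        rows.append(row)
    return pd.DataFrame(rows)
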