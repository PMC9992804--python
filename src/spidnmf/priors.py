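"""Stage-label sample graph and cross-modal absolute-Pearson priors.

The sample graph connects two samples iff they carry the same clinical
stage label; its Laplacian L = D - A turns into the smoothing penalty
beta * Tr(W^T L W) = (beta/2) * sum_ij A_ij ||w_i - w_j||^2 pulling
same-stage rows of the basis matrix together.  The cross-modal priors
are |Pearson r| matrices between the feature columns of two views,
rewarded through trace coupling terms on the coefficient matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datamodel import OmicsView

logger = logging.getLogger(__name__)

__all__ = [
    "SampleGraph",
    "CrossModalPrior",
    "build_sample_adjacency",
    "build_laplacian",
    "build_cross_modal_prior",
]


@dataclass(frozen=True)
class SampleGraph:
    """Binary same-stage adjacency A with degree D and Laplacian L = D - A."""

    adjacency: np.ndarray
    degree: np.ndarray
    laplacian: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=float)
        object.__setattr__(self, "adjacency", a)
        object.__setattr__(self, "degree", np.asarray(self.degree, dtype=float))
        object.__setattr__(self, "laplacian", np.asarray(self.laplacian, dtype=float))

    @property
    def n_samples(self) -> int:
        return self.adjacency.shape[0]


@dataclass(frozen=True)
class CrossModalPrior:
    """|Pearson| feature-coupling matrices between the image view and each
    genomic view: ``a1`` couples WSI to miRNA (p1 x p2), ``a2`` couples
    WSI to mRNA (p1 x p3).  Either may be None when the corresponding
    view is absent."""

    a1: np.ndarray | None = None
    a2: np.ndarray | None = None


def build_sample_adjacency(stage_labels: Sequence[str]) -> np.ndarray:
    """Binary adjacency: A_ij = 1 iff samples i and j share a stage label.

    The diagonal is all ones (a sample shares its own group).  Self
    loops are penalty-neutral in L = D - A, so this convention costs
    nothing while keeping the membership reading literal.
    """
    labels = [str(s) for s in stage_labels]
    if len(labels) < 2:
        raise ValueError(f"need at least 2 labels, got {len(labels)}")
    for i, lab in enumerate(labels):
        if lab.strip() == "" or lab.lower() == "nan":
            raise ValueError(f"missing stage label at position {i}")
    arr = np.asarray(labels, dtype=object)
    return (arr[:, None] == arr[None, :]).astype(float)


def build_laplacian(adjacency: np.ndarray) -> SampleGraph:
    """Degree and unnormalized Laplacian L = D - A of a binary adjacency."""
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {a.shape}")
    if not np.array_equal(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if not np.isin(a, (0.0, 1.0)).all():
        raise ValueError("adjacency entries must be 0 or 1")
    degree = np.diag(a.sum(axis=1))
    return SampleGraph(adjacency=a, degree=degree, laplacian=degree - a)


def build_cross_modal_prior(view_a: OmicsView, view_b: OmicsView) -> np.ndarray:
    """Absolute Pearson correlation between every feature pair of two views.

    Entry (i, j) = |corr over samples(column i of view_a, column j of
    view_b)|.  Pairs involving a constant column are set to 0 (no prior
    coupling) and counted in a warning: correlation is undefined there.
    """
    if view_a.sample_ids != view_b.sample_ids:
        raise ValueError(
            f"views {view_a.view_id!r} and {view_b.view_id!r} are not sample-aligned"
        )
    n = view_a.n_samples
    if n < 3:
        raise ValueError(f"need at least 3 samples for Pearson priors, got {n}")
    za, const_a = _standardize(view_a.matrix)
    zb, const_b = _standardize(view_b.matrix)
    prior = np.abs(za.T @ zb) / n
    if const_a.any() or const_b.any():
        n_pairs = int(
            const_a.sum() * zb.shape[1]
            + const_b.sum() * za.shape[1]
            - const_a.sum() * const_b.sum()
        )
        logger.warning(
            "constant columns in cross-modal prior: %d feature pairs set to 0",
            n_pairs,
        )
        prior[const_a, :] = 0.0
        prior[:, const_b] = 0.0
    # guard against rounding slightly above 1
    np.clip(prior, 0.0, 1.0, out=prior)
    return prior


def _standardize(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center and scale columns to unit population sd; flag constant ones."""
    centered = x - x.mean(axis=0)
    sd = centered.std(axis=0)
    const = sd == 0
    z = centered / np.where(const, 1.0, sd)
    return z, const
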