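"""Joint NMF solvers: objective, SVD initialization, multiplicative updates.

Three nested methods share one update engine:

``jnmf``
    min sum_l ||X_l - W H_l||_F^2 over W, H_l >= 0 — plain joint NMF
    with a shared sample basis W and view-specific coefficients H_l.
``mdjnmf``
    adds an orthogonality penalty alpha * ||H_l H_l^T - I||_F^2, an
    entry-sum sparsity penalty gamma2 * sum_ij H_l,ij, a basis norm
    penalty gamma1 * ||W||_F^2, and cross-modal coupling rewards
    -lambda1 * Tr(H1 A1 H2^T) - lambda2 * Tr(H1 A2 H3^T) where A1, A2
    are |Pearson| feature-coupling priors.
``spid``
    adds the clinical-stage sample-graph penalty beta * Tr(W^T L W)
    with L = D - A the Laplacian of the binary same-stage adjacency.

Each method's iterates are bit-identical to the next-simpler method's
when its extra weights are zero, so the nesting is exact.

Update rules are multiplicative (numerator / denominator ratios keep
factors non-negative).  The Laplacian enters the W update split as
``+ beta A W`` in the numerator and ``+ beta D W`` in the denominator:
this is the standard graph-regularized NMF split of the gradient
2 beta (D - A) W, and the only arrangement that is both dimensionally
consistent (W is n x k, L is n x n, so LW not WL) and sign-safe for a
multiplicative scheme (L has negative off-diagonal entries).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ._utils import abs_flat_pearson
from .datamodel import MultiViewDataset
from .priors import CrossModalPrior, SampleGraph

__all__ = [
    "Hyperparameters",
    "FactorModel",
    "FitReport",
    "initialize_factors",
    "objective",
    "update_step",
    "relative_error",
    "fit",
    "compare_methods",
]

METHODS = ("jnmf", "mdjnmf", "spid")


@dataclass(frozen=True)
class Hyperparameters:
    """Weights and controls of the factorization.

    Parameters
    ----------
    k:
        Factorization rank = number of co-expression modules.
    alpha:
        Orthogonality weight on each H_l (redundancy control).
    lambda1, lambda2:
        Cross-modal coupling weights for the image-miRNA (A1) and
        image-mRNA (A2) priors.
    beta:
        Sample-graph Laplacian weight (stage smoothing of W rows).
    gamma1:
        Frobenius penalty on W.
    gamma2:
        Entry-sum sparsity penalty on the H_l.
    max_iter, tol:
        Stop when |change in relative error| < tol, or at max_iter.
    eps:
        Floor applied to update denominators.
    init_floor:
        Zeros in the SVD initialization are raised to this value so
        multiplicative updates can move them.
    """

    k: int
    alpha: float = 0.01
    lambda1: float = 0.0
    lambda2: float = 0.0
    beta: float = 0.0
    gamma1: float = 0.0
    gamma2: float = 0.0
    max_iter: int = 200
    tol: float = 1e-5
    seed: int = 0
    eps: float = 1e-10
    init_floor: float = 1e-6

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be a positive integer, got {self.k}")
        for name in ("alpha", "lambda1", "lambda2", "beta", "gamma1", "gamma2"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.max_iter < 0:
            raise ValueError("max_iter must be >= 0")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")


@dataclass(frozen=True)
class FactorModel:
    """Shared basis W (n x k) and per-view coefficients H_l (k x p_l)."""

    W: np.ndarray
    H: tuple[np.ndarray, ...]
    hyperparameters: Hyperparameters
    method: str = "spid"

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        W = np.asarray(self.W, dtype=float)
        H = tuple(np.asarray(h, dtype=float) for h in self.H)
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "H", H)
        k = self.hyperparameters.k
        if W.ndim != 2 or W.shape[1] != k:
            raise ValueError(f"W must be n x k={k}, got shape {W.shape}")
        for i, h in enumerate(H):
            if h.ndim != 2 or h.shape[0] != k:
                raise ValueError(f"H[{i}] must be k={k} x p, got shape {h.shape}")
        if (W < 0).any() or any((h < 0).any() for h in H):
            raise ValueError("factors must be non-negative")

    def reconstruct(self, view_index: int) -> np.ndarray:
        return self.W @ self.H[view_index]


@dataclass(frozen=True)
class FitReport:
    objective_trajectory: tuple[float, ...]
    relative_error_trajectory: tuple[float, ...]
    iterations_run: int
    converged: bool
    stop_reason: str  # "tol" | "max_iter" | "early_stop"


def _effective_weights(hp: Hyperparameters, method: str) -> Hyperparameters:
    """Zero out the weights a simpler method does not use.

    This makes the reduction chain exact: spid with beta=0 runs the
    same arithmetic as mdjnmf, and mdjnmf with all extras zero runs the
    same arithmetic as jnmf.
    """
    if method == "jnmf":
        return replace(
            hp, alpha=0.0, lambda1=0.0, lambda2=0.0, beta=0.0, gamma1=0.0, gamma2=0.0
        )
    if method == "mdjnmf":
        return replace(hp, beta=0.0)
    return hp


def _check_inputs(
    method: str,
    hp: Hyperparameters,
    n_views: int,
    graph: SampleGraph | None,
    prior: CrossModalPrior | None,
) -> None:
    if method == "spid" and hp.beta > 0 and graph is None:
        raise ValueError("method 'spid' with beta > 0 requires a sample graph")
    if hp.lambda1 > 0 and (prior is None or prior.a1 is None):
        raise ValueError("lambda1 > 0 requires the A1 cross-modal prior")
    if hp.lambda2 > 0 and (prior is None or prior.a2 is None):
        raise ValueError("lambda2 > 0 requires the A2 cross-modal prior")
    if (hp.lambda1 > 0 and n_views < 2) or (hp.lambda2 > 0 and n_views < 3):
        raise ValueError("coupling weights require the corresponding views")


# ---------------------------------------------------------------------------
# Initialization: non-negative double SVD (NNDSVD)
# ---------------------------------------------------------------------------


def initialize_factors(
    dataset: MultiViewDataset,
    k: int,
    seed: int = 0,
    hyperparameters: Hyperparameters | None = None,
    method: str = "spid",
) -> FactorModel:
    """Deterministic SVD-based initialization of W and the H_l.

    Runs non-negative double SVD (positive/negative part splitting of
    the top-k singular triplets) on the column-concatenated data
    matrix, then splits the coefficient block back into per-view H_l.
    Zeros are floored at ``init_floor`` so multiplicative updates can
    move every entry.  The same dataset and k always yield bit-identical
    factors; ``seed`` is accepted for interface uniformity but the
    scheme involves no randomness.
    """
    hp = hyperparameters or Hyperparameters(k=k, seed=seed)
    if hp.k != k:
        hp = replace(hp, k=k)
    x_cat = dataset.concatenated()
    n, p_total = x_cat.shape
    if k > min(n, p_total):
        raise ValueError(f"k={k} exceeds min(n={n}, total features={p_total})")
    w, h_cat = _nndsvd(x_cat, k)
    floor = hp.init_floor
    w = np.maximum(w, floor)
    h_cat = np.maximum(h_cat, floor)
    h_list: list[np.ndarray] = []
    start = 0
    for v in dataset.views:
        h_list.append(h_cat[:, start : start + v.n_features])
        start += v.n_features
    return FactorModel(W=w, H=tuple(h_list), hyperparameters=hp, method=method)


def _nndsvd(x: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Boutsidis-Gallopoulos NNDSVD from the top-k singular triplets."""
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    u, s, vt = u[:, :k], s[:k], vt[:k]
    n, p = x.shape
    w = np.zeros((n, k))
    h = np.zeros((k, p))
    # leading triplet of a non-negative matrix is sign-fixable to non-negative
    w[:, 0] = np.sqrt(s[0]) * np.abs(u[:, 0])
    h[0] = np.sqrt(s[0]) * np.abs(vt[0])
    for j in range(1, k):
        uj, vj = u[:, j], vt[j]
        up, un = np.maximum(uj, 0), np.maximum(-uj, 0)
        vp, vn = np.maximum(vj, 0), np.maximum(-vj, 0)
        nup, nun = np.linalg.norm(up), np.linalg.norm(un)
        nvp, nvn = np.linalg.norm(vp), np.linalg.norm(vn)
        mp, mn = nup * nvp, nun * nvn
        if mp >= mn:
            uu = up / nup if nup > 0 else up
            vv = vp / nvp if nvp > 0 else vp
            sigma = mp
        else:
            uu = un / nun if nun > 0 else un
            vv = vn / nvn if nvn > 0 else vn
            sigma = mn
        w[:, j] = np.sqrt(s[j] * sigma) * uu
        h[j] = np.sqrt(s[j] * sigma) * vv
    return w, h


# ---------------------------------------------------------------------------
# Objective, updates, convergence
# ---------------------------------------------------------------------------


def objective(
    model: FactorModel,
    dataset: MultiViewDataset,
    graph: SampleGraph | None = None,
    prior: CrossModalPrior | None = None,
) -> float:
    """Penalized reconstruction objective for the model's method.

    jnmf keeps only the Frobenius reconstruction sum; mdjnmf adds
    orthogonality, sparsity, W-norm and coupling terms; spid adds the
    Laplacian term beta * Tr(W^T L W).  Coupling rewards enter with a
    minus sign, so the objective can be negative for large lambdas.
    """
    hp = _effective_weights(model.hyperparameters, model.method)
    _check_inputs(model.method, hp, len(dataset.views), graph, prior)
    w = model.W
    total = 0.0
    for x, h in zip(dataset.matrices, model.H):
        r = x - w @ h
        total += float(np.sum(r * r))
    if hp.alpha > 0:
        k = hp.k
        eye = np.eye(k)
        for h in model.H:
            g = h @ h.T - eye
            total += hp.alpha * float(np.sum(g * g))
    if hp.gamma2 > 0:
        total += hp.gamma2 * float(sum(h.sum() for h in model.H))
    if hp.lambda1 > 0:
        total -= hp.lambda1 * float(np.trace(model.H[0] @ prior.a1 @ model.H[1].T))
    if hp.lambda2 > 0:
        total -= hp.lambda2 * float(np.trace(model.H[0] @ prior.a2 @ model.H[2].T))
    if hp.beta > 0:
        total += hp.beta * float(np.trace(w.T @ graph.laplacian @ w))
    if hp.gamma1 > 0:
        total += hp.gamma1 * float(np.sum(w * w))
    return total


def update_step(
    model: FactorModel,
    dataset: MultiViewDataset,
    graph: SampleGraph | None = None,
    prior: CrossModalPrior | None = None,
) -> FactorModel:
    """One multiplicative update sweep: W first, then H1, H2, H3.

    Each factor update uses the freshest available co-factors
    (Gauss-Seidel order).  Denominators are floored at ``eps`` so the
    ratios stay finite; non-negativity is preserved by construction.
    """
    hp = _effective_weights(model.hyperparameters, model.method)
    _check_inputs(model.method, hp, len(dataset.views), graph, prior)
    xs = dataset.matrices
    w = model.W
    hs = [h.copy() for h in model.H]

    num = sum(x @ h.T for x, h in zip(xs, hs))
    den = sum(w @ (h @ h.T) for h in hs)
    if hp.gamma1 > 0:
        den = den + hp.gamma1 * w
    if hp.beta > 0:
        num = num + hp.beta * (graph.adjacency @ w)
        den = den + hp.beta * (np.diag(graph.degree)[:, None] * w)
    w = w * num / np.maximum(den, hp.eps)

    wtw = w.T @ w
    for l, (x, h) in enumerate(zip(xs, hs)):
        num = w.T @ x
        den = wtw @ h
        if hp.alpha > 0:
            num = num + 2.0 * hp.alpha * h
            den = den + 2.0 * hp.alpha * (h @ h.T @ h)
        if hp.gamma2 > 0:
            den = den + 0.5 * hp.gamma2
        if l == 0:
            if hp.lambda1 > 0:
                num = num + 0.5 * hp.lambda1 * (hs[1] @ prior.a1.T)
            if hp.lambda2 > 0:
                num = num + 0.5 * hp.lambda2 * (hs[2] @ prior.a2.T)
        elif l == 1 and hp.lambda1 > 0:
            num = num + 0.5 * hp.lambda1 * (hs[0] @ prior.a1)
        elif l == 2 and hp.lambda2 > 0:
            num = num + 0.5 * hp.lambda2 * (hs[0] @ prior.a2)
        hs[l] = h * num / np.maximum(den, hp.eps)

    return FactorModel(
        W=w, H=tuple(hs), hyperparameters=model.hyperparameters, method=model.method
    )


def relative_error(
    model: FactorModel, dataset: MultiViewDataset, squared: bool = False
) -> float:
    """Scale-free reconstruction error ||X - WH||_F / ||X||_F.

    X and H are the column-concatenations over views.  The normalized
    ratio form is used for convergence checks and model selection;
    ``squared=True`` returns the raw squared norm ||X - WH||_F^2
    instead.
    """
    x_cat = dataset.concatenated()
    h_cat = np.hstack(model.H)
    resid = x_cat - model.W @ h_cat
    sq = float(np.sum(resid * resid))
    if squared:
        return sq
    norm_x = float(np.linalg.norm(x_cat))
    if norm_x == 0:
        raise ValueError("dataset is all zeros; relative error undefined")
    return float(np.sqrt(sq)) / norm_x


def fit(
    dataset: MultiViewDataset,
    hyperparameters: Hyperparameters,
    method: str = "spid",
    graph: SampleGraph | None = None,
    prior: CrossModalPrior | None = None,
    early_stop_patience: int | None = None,
) -> tuple[FactorModel, FitReport]:
    """Iterate multiplicative updates from the SVD initialization.

    Stops when the change in relative error drops below ``tol``
    (converged), when ``max_iter`` is reached, or — if
    ``early_stop_patience`` is given — when the relative error has
    failed to improve by ``tol`` for that many consecutive iterations.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    hp = hyperparameters
    _check_inputs(method, _effective_weights(hp, method), len(dataset.views), graph, prior)
    model = initialize_factors(
        dataset, hp.k, seed=hp.seed, hyperparameters=hp, method=method
    )
    obj_traj: list[float] = []
    err_traj: list[float] = []
    prev_err = relative_error(model, dataset)
    best_err = prev_err
    stale = 0
    converged = False
    stop_reason = "max_iter"
    iterations = 0
    for it in range(1, hp.max_iter + 1):
        model = update_step(model, dataset, graph=graph, prior=prior)
        if not np.isfinite(model.W).all() or not all(
            np.isfinite(h).all() for h in model.H
        ):
            raise FloatingPointError(
                f"non-finite factor entries at iteration {it}"
            )
        err = relative_error(model, dataset)
        obj_traj.append(objective(model, dataset, graph=graph, prior=prior))
        err_traj.append(err)
        iterations = it
        if abs(prev_err - err) < hp.tol:
            converged = True
            stop_reason = "tol"
            break
        if early_stop_patience is not None:
            if best_err - err > hp.tol:
                best_err = err
                stale = 0
            else:
                stale += 1
                if stale >= early_stop_patience:
                    stop_reason = "early_stop"
                    break
        prev_err = err
    report = FitReport(
        objective_trajectory=tuple(obj_traj),
        relative_error_trajectory=tuple(err_traj),
        iterations_run=iterations,
        converged=converged,
        stop_reason=stop_reason,
    )
    return model, report


def compare_methods(
    dataset: MultiViewDataset,
    graph: SampleGraph | None,
    prior: CrossModalPrior | None,
    hyperparameters: Hyperparameters,
) -> pd.DataFrame:
    """Fit jnmf, mdjnmf and spid at identical k; tabulate error and fit.

    One row per method with the relative reconstruction error and the
    per-view |Pearson| between each X_l and its reconstruction W H_l
    (matrices flattened), mirroring the usual algorithm-comparison
    table for this family of factorizations.
    """
    rows = []
    for method in METHODS:
        model, _ = fit(
            dataset, hyperparameters, method=method, graph=graph, prior=prior
        )
        row: dict[str, float | str] = {"method": method}
        for view, h in zip(dataset.views, model.H):
            row[f"corr_{view.view_id}"] = abs_flat_pearson(view.matrix, model.W @ h)
        row["relative_error"] = relative_error(model, dataset)
        rows.append(row)
    return pd.DataFrame(rows).set_index("method")
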