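"""Synthetic multi-view generator with planted factors and outcomes.

Emulates the statistical structure the joint factorization assumes: a
shared non-negative sample-factor matrix W_true, view-specific
block-sparse loadings H_true with disjoint active feature blocks per
factor (the planted co-expression modules), clinical-stage labels
correlated with the dominant factor of each sample, and additive
non-negative noise.  Optionally, exponential survival times whose
log-hazard is driven by one planted factor.

What it does NOT emulate: count-like marginal distributions of real
sequencing data, correlated noise across features, batch effects, or
real histology feature statistics.  Recovery results on this generator
demonstrate algorithmic correctness, not performance on real cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datamodel import MultiViewDataset, OmicsView, SurvivalTable

__all__ = ["SyntheticTruth", "generate_multiview", "generate_survival"]

_VIEW_IDS = ("wsi", "mirna", "mrna")

#: Roman-numeral stage names used for labels.
_STAGES = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth behind a generated dataset.

    ``planted_modules`` maps view_id to a list of per-factor feature-ID
    tuples (the active block of each factor); blocks are disjoint
    across factors within a view.
    """

    W_true: np.ndarray
    H_true: tuple[np.ndarray, ...]
    planted_modules: dict[str, list[tuple[str, ...]]]
    stage_labels: tuple[str, ...]
    noise_sigma: float
    seed: int


def generate_multiview(
    n: int = 60,
    p: Sequence[int] = (50, 80, 100),
    k: int = 4,
    n_stages: int = 3,
    noise_sigma: float = 0.05,
    stage_strength: float = 1.0,
    module_fraction: float = 0.1,
    seed: int = 0,
) -> tuple[MultiViewDataset, SyntheticTruth]:
    """Generate 1-3 sample-aligned views from a shared factor matrix.

    Stages are assigned round-robin (balanced group sizes).  Each
    sample's factor row is uniform background plus ``stage_strength``
    added to the factor indexed by its stage (mod k), so stage and
    factor structure are correlated; ``stage_strength = 0`` removes the
    association.  Per view, factor i loads uniformly on a narrow
    contiguous block of roughly ``module_fraction`` of the features
    (at least 2, at most p_l // k so blocks stay disjoint); features
    outside every block carry no signal, only noise.  The blocks are
    kept sparse deliberately: a module is a *minority* of features
    standing out from a factor's coefficient row, which is what makes
    the downstream z-score membership rule well-posed.
    X_l = W_true @ H_true_l plus additive truncated-at-zero Gaussian
    noise with standard deviation ``noise_sigma``.  Everything is
    reproducible from ``seed``.
    """
    p = tuple(int(q) for q in p)
    if not 1 <= len(p) <= 3:
        raise ValueError(f"need 1-3 views, got {len(p)}")
    if any(q < k for q in p):
        raise ValueError(f"every view needs at least k={k} features, got p={p}")
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    if n_stages < 1:
        raise ValueError("n_stages must be >= 1")
    if n_stages > len(_STAGES):
        raise ValueError(f"at most {len(_STAGES)} stages supported")
    rng = np.random.default_rng(seed)

    stage_idx = np.arange(n) % n_stages
    stage_labels = tuple(_STAGES[s] for s in stage_idx)

    w = rng.uniform(0.1, 0.5, size=(n, k))
    w[np.arange(n), stage_idx % k] += stage_strength

    views: list[OmicsView] = []
    hs: list[np.ndarray] = []
    planted: dict[str, list[tuple[str, ...]]] = {}
    sample_ids = tuple(f"s{i:04d}" for i in range(n))
    for v, p_l in enumerate(p):
        view_id = _VIEW_IDS[v]
        feature_ids = tuple(f"{view_id}_f{j:04d}" for j in range(p_l))
        stride = p_l // k
        width = min(stride, max(2, round(module_fraction * p_l)))
        h = np.zeros((k, p_l))
        blocks: list[tuple[str, ...]] = []
        for i in range(k):
            lo = i * stride
            hi = lo + width
            # active loadings bounded away from zero so modules are
            # separable from the zero background
            h[i, lo:hi] = rng.uniform(1.0, 2.0, size=hi - lo)
            blocks.append(feature_ids[lo:hi])
        noise = np.maximum(rng.normal(0.0, noise_sigma, size=(n, p_l)), 0.0)
        x = w @ h + noise
        views.append(
            OmicsView(
                view_id=view_id,
                matrix=x,
                sample_ids=sample_ids,
                feature_ids=feature_ids,
            )
        )
        hs.append(h)
        planted[view_id] = blocks

    dataset = MultiViewDataset(views=tuple(views), stage_labels=stage_labels)
    truth = SyntheticTruth(
        W_true=w,
        H_true=tuple(hs),
        planted_modules=planted,
        stage_labels=stage_labels,
        noise_sigma=noise_sigma,
        seed=seed,
    )
    return dataset, truth


def generate_survival(
    W_true: np.ndarray,
    effect_factor: int = 0,
    effect_size: float = 0.0,
    censor_rate: float = 0.0,
    baseline_hazard: float = 1.0 / 365.0,
    seed: int = 0,
    sample_ids: Sequence[str] | None = None,
) -> SurvivalTable:
    """Exponential survival times driven by one planted factor.

    Event time T_i ~ Exponential(rate = baseline_hazard *
    exp(effect_size * W_true[i, effect_factor])), i.e. the chosen
    factor acts with log-hazard slope ``effect_size``.  With
    probability ``censor_rate`` a sample is censored at a uniform
    fraction of its event time.  Times are in days; the default
    baseline gives a one-year mean at zero effect.
    """
    w = np.asarray(W_true, dtype=float)
    n, k = w.shape
    if not 0 <= effect_factor < k:
        raise ValueError(f"effect_factor {effect_factor} out of range for k={k}")
    if not 0 <= censor_rate <= 1:
        raise ValueError("censor_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rate = baseline_hazard * np.exp(effect_size * w[:, effect_factor])
    time = rng.exponential(1.0 / rate)
    event = (rng.uniform(size=n) >= censor_rate).astype(int)
    censor_frac = rng.uniform(size=n)
    time = np.where(event == 1, time, time * censor_frac)
    time = np.maximum(time, 1e-3)  # keep times strictly positive
    if sample_ids is None:
        sample_ids = tuple(f"s{i:04d}" for i in range(n))
    return SurvivalTable(sample_ids=tuple(sample_ids), time=time, event=event)
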