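"""Aggregate per-nucleus cell features into patient-level image vectors.

Nuclear segmentation of whole-slide images (an upstream image-analysis
step) yields, per nucleus, ten cell-level features: nuclear area, long
and short axis lengths and their ratio, mean pixel value in each RGB
channel, and the mean / max / min distance to neighbouring nuclei.  A
patient is summarized by, per cell-level feature, a 10-bin histogram
(fractions of nuclei per bin, bin1 = smallest values through bin10 =
largest, outermost bins open-ended) plus five summary statistics
(mean, sd, median, min, max): 15 aggregates x 10 features = 150
patient-level features, named ``<feature>_<agg>`` (area_bin1 ...
area_max).  Default bin edges are per-feature deciles of the input
cohort; a fixed edge set can be supplied for cross-cohort
comparability.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CELL_FEATURES",
    "N_BINS",
    "default_bin_edges",
    "aggregate_cell_features",
    "aggregate_cohort",
]

CELL_FEATURES = (
    "area",
    "major",
    "minor",
    "ratio",
    "rMean",
    "gMean",
    "bMean",
    "distMean",
    "distMax",
    "distMin",
)

N_BINS = 10
_STATS = ("mean", "sd", "median", "min", "max")

#: features required to be strictly positive (lengths and distances)
_POSITIVE = ("area", "major", "minor", "distMean", "distMax", "distMin")


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CELL_FEATURES if c not in table.columns]
    if missing:
        raise ValueError(f"cell table missing feature columns: {missing}")
    if len(table) == 0:
        raise ValueError("cell table is empty")
    values = table[list(CELL_FEATURES)].to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("cell table contains non-finite feature values")
    for feat in _POSITIVE:
        if (table[feat].to_numpy(dtype=float) <= 0).any():
            raise ValueError(f"feature {feat!r} must be strictly positive")
    return table


def default_bin_edges(
    table: pd.DataFrame, n_bins: int = N_BINS
) -> dict[str, np.ndarray]:
    """Per-feature decile bin boundaries (n_bins - 1 internal cut points).

    The outermost bins are open-ended, so only internal boundaries are
    needed; values tied to a boundary fall in the lower bin.
    """
    _validate(table)
    quantiles = np.linspace(0, 1, n_bins + 1)[1:-1]
    return {
        feat: np.quantile(table[feat].to_numpy(dtype=float), quantiles)
        for feat in CELL_FEATURES
    }


def aggregate_cell_features(
    table: pd.DataFrame,
    bin_edges: Mapping[str, np.ndarray] | None = None,
) -> pd.Series:
    """Collapse one patient's nuclei into the 150-feature vector.

    ``bin_edges`` maps each cell-level feature to its monotone internal
    bin boundaries (9 values for 10 bins); by default they are the
    deciles of this patient's own nuclei.  Histogram fractions per
    feature sum to 1.  A single-nucleus table is valid (sd = 0).
    """
    _validate(table)
    if bin_edges is None:
        bin_edges = default_bin_edges(table)
    out: dict[str, float] = {}
    n = len(table)
    for feat in CELL_FEATURES:
        values = table[feat].to_numpy(dtype=float)
        edges = np.asarray(bin_edges[feat], dtype=float)
        if edges.shape != (N_BINS - 1,):
            raise ValueError(
                f"bin edges for {feat!r} must have {N_BINS - 1} internal "
                f"boundaries, got shape {edges.shape}"
            )
        if np.any(np.diff(edges) < 0):
            raise ValueError(f"bin edges for {feat!r} are not monotone")
        # value == boundary -> lower bin; outer bins open-ended
        bins = np.searchsorted(edges, values, side="left")
        counts = np.bincount(bins, minlength=N_BINS)
        for b in range(N_BINS):
            out[f"{feat}_bin{b + 1}"] = counts[b] / n
        out[f"{feat}_mean"] = float(values.mean())
        out[f"{feat}_sd"] = float(values.std())
        out[f"{feat}_median"] = float(np.median(values))
        out[f"{feat}_min"] = float(values.min())
        out[f"{feat}_max"] = float(values.max())
    return pd.Series(out)


def aggregate_cohort(
    table: pd.DataFrame,
    patient_column: str = "patient_id",
    bin_edges: Mapping[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Aggregate a multi-patient nucleus table into a patients x 150 frame.

    Bin edges default to the deciles of the pooled cohort so that
    histogram features are comparable across patients.
    """
    if patient_column not in table.columns:
        raise ValueError(f"cell table missing {patient_column!r} column")
    _validate(table)
    if bin_edges is None:
        bin_edges = default_bin_edges(table)
    rows = {
        str(pid): aggregate_cell_features(group, bin_edges=bin_edges)
        for pid, group in table.groupby(patient_column, sort=True)
    }
    return pd.DataFrame.from_dict(rows, orient="index")
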