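"""Domain types and delimited-file I/O for sample-aligned omics views.

All matrices are stored samples x features with explicit sample and
feature identifiers.  Non-negativity is enforced at construction time:
NMF is only defined on non-negative data, so a negative entry anywhere
is a hard error that names the offending cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OmicsView",
    "MultiViewDataset",
    "SurvivalTable",
    "read_view",
    "write_view",
    "read_labels",
    "read_survival",
    "write_survival",
    "assemble_dataset",
    "scale_features",
]


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} ID: {i!r}")
        seen.add(i)


@dataclass(frozen=True)
class OmicsView:
    """A single data view: non-negative matrix of samples x features.

    Parameters
    ----------
    view_id:
        One of ``wsi``, ``mirna``, ``mrna`` or ``other``; identifies the
        modality for cross-modal priors and file naming.
    matrix:
        Non-negative, finite float array of shape (n_samples, n_features).
    sample_ids, feature_ids:
        Ordered, unique row and column identifiers.
    """

    view_id: str
    matrix: np.ndarray
    sample_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]

    _VIEW_IDS = ("wsi", "mirna", "mrna", "other")

    def __post_init__(self) -> None:
        if self.view_id not in self._VIEW_IDS:
            raise ValueError(
                f"view_id must be one of {self._VIEW_IDS}, got {self.view_id!r}"
            )
        matrix = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", matrix)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "feature_ids", tuple(str(f) for f in self.feature_ids))
        if matrix.ndim != 2:
            raise ValueError(f"matrix must be 2-D, got shape {matrix.shape}")
        n, p = matrix.shape
        if n != len(self.sample_ids):
            raise ValueError(
                f"{n} matrix rows but {len(self.sample_ids)} sample IDs"
            )
        if p != len(self.feature_ids):
            raise ValueError(
                f"{p} matrix columns but {len(self.feature_ids)} feature IDs"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.feature_ids, "feature")
        bad = ~np.isfinite(matrix)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-finite entry at sample {self.sample_ids[i]!r}, "
                f"feature {self.feature_ids[j]!r}"
            )
        neg = matrix < 0
        if neg.any():
            i, j = np.argwhere(neg)[0]
            raise ValueError(
                f"negative entry {matrix[i, j]} at sample {self.sample_ids[i]!r}, "
                f"feature {self.feature_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix, index=list(self.sample_ids), columns=list(self.feature_ids)
        )

    def select_samples(self, sample_ids: Sequence[str]) -> "OmicsView":
        """Return a copy restricted to ``sample_ids``, in that order."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            idx = [pos[s] for s in sample_ids]
        except KeyError as exc:  # pragma: no cover - guarded by callers
            raise KeyError(f"sample {exc.args[0]!r} not in view {self.view_id}")
        return OmicsView(
            view_id=self.view_id,
            matrix=self.matrix[idx],
            sample_ids=tuple(sample_ids),
            feature_ids=self.feature_ids,
        )


@dataclass(frozen=True)
class MultiViewDataset:
    """One to three sample-aligned views plus per-sample stage labels.

    Every view must carry the identical sample IDs in the identical
    order; the shared basis matrix W of the joint factorization is only
    meaningful under this row correspondence.
    """

    views: tuple[OmicsView, ...]
    stage_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        views = tuple(self.views)
        object.__setattr__(self, "views", views)
        object.__setattr__(
            self, "stage_labels", tuple(str(s) for s in self.stage_labels)
        )
        if not 1 <= len(views) <= 3:
            raise ValueError(f"need 1-3 views, got {len(views)}")
        ref = views[0].sample_ids
        if len(ref) < 2:
            raise ValueError("need at least 2 samples")
        for v in views[1:]:
            if v.sample_ids != ref:
                raise ValueError(
                    f"view {v.view_id!r} sample order differs from "
                    f"view {views[0].view_id!r}"
                )
        if len(self.stage_labels) != len(ref):
            raise ValueError(
                f"{len(self.stage_labels)} stage labels for {len(ref)} samples"
            )

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return self.views[0].sample_ids

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def matrices(self) -> list[np.ndarray]:
        return [v.matrix for v in self.views]

    def concatenated(self) -> np.ndarray:
        """Column-concatenation of all view matrices (n x sum p_l)."""
        return np.hstack(self.matrices)


@dataclass(frozen=True)
class SurvivalTable:
    """Per-sample overall-survival outcomes: time in days, event flag."""

    sample_ids: tuple[str, ...]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        time = np.asarray(self.time, dtype=float)
        event = np.asarray(self.event, dtype=int)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", event)
        n = len(self.sample_ids)
        if time.shape != (n,) or event.shape != (n,):
            raise ValueError("time and event must be 1-D, one entry per sample")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(time)) or np.any(time <= 0):
            raise ValueError("survival times must be positive and finite")
        if not np.isin(event, (0, 1)).all():
            raise ValueError("event indicators must be 0 or 1")

    def __len__(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.time, "event": self.event}, index=list(self.sample_ids)
        )


# ---------------------------------------------------------------------------
# File I/O: delimited text, comma or tab auto-detected from the header line.
# ---------------------------------------------------------------------------


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    if not header:
        raise ValueError(f"{path} is empty")
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_view(path: str | Path, view_id: str = "other") -> OmicsView:
    """Read a samples x features matrix from a delimited text file.

    The first row holds feature IDs, the first column sample IDs.
    Separator (tab or comma) is auto-detected from the header line.
    Negative or non-finite entries are rejected with the cell named.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"view file not found: {path}")
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    try:
        matrix = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric entry in {path}: {exc}") from exc
    return OmicsView(
        view_id=view_id,
        matrix=matrix,
        sample_ids=tuple(str(s) for s in df.index),
        feature_ids=tuple(str(f) for f in df.columns),
    )


def write_view(view: OmicsView, path: str | Path, sep: str = "\t") -> None:
    """Write a view as delimited text at full float precision."""
    view.to_frame().to_csv(Path(path), sep=sep, float_format="%.17g")


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column (sample_id, stage) delimited file into a map."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"label file not found: {path}")
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"label file {path} needs 2 columns (sample_id, stage)")
    out: dict[str, str] = {}
    for sid, stage in zip(df.iloc[:, 0], df.iloc[:, 1]):
        if pd.isna(stage) or str(stage).strip() == "":
            raise ValueError(f"missing stage label for sample {sid!r}")
        out[str(sid)] = str(stage)
    return out


def read_survival(path: str | Path) -> SurvivalTable:
    """Read a three-column (sample_id, time_days, event) delimited file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"survival file not found: {path}")
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 3:
        raise ValueError(
            f"survival file {path} needs 3 columns (sample_id, time_days, event)"
        )
    return SurvivalTable(
        sample_ids=tuple(str(s) for s in df.iloc[:, 0]),
        time=df.iloc[:, 1].to_numpy(dtype=float),
        event=df.iloc[:, 2].to_numpy(dtype=int),
    )


def write_survival(table: SurvivalTable, path: str | Path, sep: str = "\t") -> None:
    df = table.to_frame().reset_index(names="sample_id")
    df.to_csv(Path(path), sep=sep, index=False)


# ---------------------------------------------------------------------------
# Assembly and scaling
# ---------------------------------------------------------------------------


def assemble_dataset(
    views: Iterable[OmicsView], labels: Mapping[str, str]
) -> MultiViewDataset:
    """Restrict views and labels to their common samples and align rows.

    The output is restricted to the intersection of the views' sample
    sets and the label map's keys, with rows reordered to a single
    canonical order (lexicographic by sample ID) across all views.
    """
    views = list(views)
    if not views:
        raise ValueError("need at least one view")
    common = set(views[0].sample_ids)
    for v in views[1:]:
        common &= set(v.sample_ids)
    common &= set(labels)
    if not common:
        raise ValueError("empty sample intersection across views and labels")
    order = sorted(common)
    aligned = tuple(v.select_samples(order) for v in views)
    return MultiViewDataset(
        views=aligned, stage_labels=tuple(labels[s] for s in order)
    )


def scale_features(view: OmicsView, mode: str = "minmax") -> OmicsView:
    """Rescale each feature column; ``minmax`` maps columns to [0, 1].

    Heterogeneous modalities (histogram fractions vs expression counts)
    live on wildly different scales; without per-feature rescaling one
    view dominates the joint Frobenius objective.  Constant columns map
    to all zeros.  ``none`` is the identity.
    """
    if mode == "none":
        return view
    if mode != "minmax":
        raise ValueError(f"unknown scaling mode {mode!r}")
    x = view.matrix
    lo = x.min(axis=0)
    span = x.max(axis=0) - lo
    span_safe = np.where(span > 0, span, 1.0)
    scaled = (x - lo) / span_safe
    scaled[:, span == 0] = 0.0
    return OmicsView(
        view_id=view.view_id,
        matrix=scaled,
        sample_ids=view.sample_ids,
        feature_ids=view.feature_ids,
    )
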