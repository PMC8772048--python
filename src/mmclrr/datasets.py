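"""In-memory containers for multi-view (multi-omics) sample data."""

from __future__ import annotations

import dataclasses
from typing import Iterator, Sequence

import numpy as np

__all__ = ["ViewMatrix", "MultiViewDataset"]


@dataclasses.dataclass
class ViewMatrix:
    """One data view: a features x samples matrix with feature identifiers."""

    data: np.ndarray  # (n_features, n_samples)
    feature_ids: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("view data must be a 2-D features x samples matrix")
        if self.data.shape[0] < 1:
            raise ValueError("a view must have at least one feature")
        if len(self.feature_ids) != self.data.shape[0]:
            raise ValueError(
                f"feature_ids length {len(self.feature_ids)} does not match "
                f"{self.data.shape[0]} rows"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("view contains non-finite entries (NaN or inf)")

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclasses.dataclass
class MultiViewDataset:
    """An ordered collection of views over one shared sample axis.

    Every view has exactly ``len(sample_ids)`` columns, in identical sample
    order; there is at least one view.
    """

    views: list[ViewMatrix]
    sample_ids: list[str]
    view_names: list[str]

    def __post_init__(self) -> None:
        if len(self.views) < 1:
            raise ValueError("a dataset needs at least one view")
        if len(self.view_names) != len(self.views):
            raise ValueError("view_names length must match the number of views")
        n = len(self.sample_ids)
        for name, view in zip(self.view_names, self.views):
            if view.n_samples != n:
                raise ValueError(
                    f"view {name!r} has {view.n_samples} samples, expected {n}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_views(self) -> int:
        return len(self.views)

    def matrices(self) -> list[np.ndarray]:
        """The raw per-view arrays, in view order."""
        return [v.data for v in self.views]

    def __iter__(self) -> Iterator[ViewMatrix]:
        return iter(self.views)


def as_view_matrices(views: "MultiViewDataset | Sequence[np.ndarray]") -> list[np.ndarray]:
    """Coerce a dataset or a plain sequence of arrays to a list of 2-D arrays."""
    if isinstance(views, MultiViewDataset):
        return views.matrices()
    mats = [np.asarray(v, dtype=float) for v in views]
    if not mats:
        raise ValueError("need at least one view")
    n = mats[0].shape[1]
    for i, m in enumerate(mats):
        if m.ndim != 2:
            raise ValueError(f"view {i} is not 2-D")
        if m.shape[1] != n:
            raise ValueError(f"view {i} has {m.shape[1]} samples, expected {n}")
        if not np.all(np.isfinite(m)):
            raise ValueError(f"view {i} contains non-finite entries")
    return mats
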