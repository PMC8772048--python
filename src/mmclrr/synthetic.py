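"""Synthetic multi-view data with union-of-subspaces structure.

Each cluster occupies its own low-dimensional linear subspace in every
view; cluster membership is shared across views.  Clean samples are
``B @ C`` with an orthonormal basis ``B`` (features x d) and standard
normal coefficients ``C`` (d x n_j), plus isotropic Gaussian noise.  An
optional fraction of sample columns — the same columns in every view,
modelling sample-level artifacts — is replaced by large-magnitude noise,
which is what the column-sparse (l2,1) error term of the solver absorbs.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .datasets import MultiViewDataset, ViewMatrix

__all__ = ["SyntheticSpec", "generate", "default_fixture"]

_CORRUPT_AMPLITUDE = 5.0


@dataclasses.dataclass
class SyntheticSpec:
    """Recipe for one synthetic multi-view dataset."""

    n_clusters: int = 3
    samples_per_cluster: tuple[int, ...] = (20, 20, 20)
    view_dims: tuple[int, ...] = (50, 60, 40)
    subspace_dim: int = 4
    noise_sigma: float = 0.01
    corrupt_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if len(self.samples_per_cluster) != self.n_clusters:
            raise ValueError("samples_per_cluster must list one size per cluster")
        if any(n < 1 for n in self.samples_per_cluster):
            raise ValueError("every cluster needs at least one sample")
        if any(d < 1 for d in self.view_dims):
            raise ValueError("every view needs at least one feature")
        if not 1 <= self.subspace_dim < min(self.view_dims):
            raise ValueError("subspace_dim must satisfy 1 <= d < min(view_dims)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if not 0 <= self.corrupt_fraction <= 1:
            raise ValueError("corrupt_fraction must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return sum(self.samples_per_cluster)

    @property
    def n_views(self) -> int:
        return len(self.view_dims)


def _orthonormal_basis(rng: np.random.Generator, m: int, d: int) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((m, d)))
    return q * np.sign(np.diag(r))  # sign-fix for a deterministic QR


def generate(spec: SyntheticSpec) -> tuple[MultiViewDataset, np.ndarray]:
    """Draw one dataset according to ``spec``; reproducible from its seed.

    Returns the dataset and the shared ground-truth labels (1..c).  All
    randomness flows from ``spec.seed`` through independently spawned
    per-view streams plus one stream for the corruption pattern, so any
    one view's draw is unchanged by the presence of the others.
    """
    root = np.random.SeedSequence(spec.seed)
    view_seeds = root.spawn(spec.n_views)
    corrupt_rng = np.random.default_rng(root.spawn(1)[0])

    n = spec.n_samples
    labels = np.repeat(np.arange(1, spec.n_clusters + 1), spec.samples_per_cluster)

    n_corrupt = int(np.floor(spec.corrupt_fraction * n))
    corrupt_cols = (
        np.sort(corrupt_rng.choice(n, size=n_corrupt, replace=False))
        if n_corrupt
        else np.empty(0, dtype=int)
    )

    views: list[ViewMatrix] = []
    view_names: list[str] = []
    for v, (m_v, vseed) in enumerate(zip(spec.view_dims, view_seeds), start=1):
        rng = np.random.default_rng(vseed)
        x = np.empty((m_v, n))
        col = 0
        for n_j in spec.samples_per_cluster:
            basis = _orthonormal_basis(rng, m_v, spec.subspace_dim)
            coeff = rng.standard_normal((spec.subspace_dim, n_j))
            x[:, col : col + n_j] = basis @ coeff
            col += n_j
        if spec.noise_sigma > 0:
            x += spec.noise_sigma * rng.standard_normal((m_v, n))
        if n_corrupt:
            x[:, corrupt_cols] = _CORRUPT_AMPLITUDE * rng.standard_normal(
                (m_v, n_corrupt)
            )
        views.append(
            ViewMatrix(
                data=x,
                feature_ids=[f"view{v}_f{i + 1:04d}" for i in range(m_v)],
            )
        )
        view_names.append(f"view{v}")

    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    return MultiViewDataset(views=views, sample_ids=sample_ids, view_names=view_names), labels


def default_fixture() -> tuple[MultiViewDataset, np.ndarray]:
    """A small imbalanced two-class dataset (48 samples: 40 + 8, 3 views).

    The 40/8 split mirrors the strong cancer/normal imbalance of TCGA
    cohorts while staying cheap enough for routine testing.
    """
    spec = SyntheticSpec(
        n_clusters=2,
        samples_per_cluster=(40, 8),
        view_dims=(60, 80, 50),
        subspace_dim=3,
        noise_sigma=0.02,
        corrupt_fraction=0.0,
        seed=0,
    )
    return generate(spec)
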