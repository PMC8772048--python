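"""Pipeline configuration: regularization weights, graph, solver and
clustering settings, plus the published per-dataset presets."""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any

import yaml

__all__ = ["PipelineConfig", "PRESETS", "load_config"]


@dataclasses.dataclass
class PipelineConfig:
    """All knobs of the end-to-end clustering pipeline.

    Parameters
    ----------
    gamma1 : float
        Weight of the elementwise sparsity (l1) penalty on the representation.
    gamma2 : float
        Weight of the column-sparse (l2,1) penalty on the error matrix.
    gamma3 : float
        Weight of the manifold (graph Laplacian trace) penalty.
    gamma_view : float
        Weight of the cross-view consistency penalty, shared by all views.
    k_neighbors : int
        Neighbour count of the per-view kNN graph.
    kernel_t : float or "auto"
        Heat-kernel width; "auto" uses the mean retained kNN distance.
    mu0, mu_max, rho : float
        Initial penalty, cap and growth factor of the adaptive-penalty scheme.
    tol : float
        Convergence tolerance on the maximum relative constraint residual.
    max_iter : int
        Iteration cap of the solver.
    w_damping : float
        Spectral shift of the inertial dictionary update; stabilizes the
        otherwise ill-conditioned orthogonal Procrustes step.
    n_clusters : int
        Number of clusters requested from normalized cuts.
    seed : int
        Seed for the spectral clustering k-means restarts.
    normalize_columns : bool
        Scale every sample column of every view to unit Euclidean norm
        before any computation (standard low-rank-representation practice).
    """

    gamma1: float = 0.1
    gamma2: float = 10.0
    gamma3: float = 0.1
    gamma_view: float = 1.0
    k_neighbors: int = 5
    kernel_t: float | str = "auto"
    mu0: float = 1e-2
    mu_max: float = 1e6
    rho: float = 1.1
    tol: float = 1e-6
    max_iter: int = 500
    w_damping: float = 0.0
    n_clusters: int = 2
    seed: int = 0
    normalize_columns: bool = True

    def __post_init__(self) -> None:
        for name in ("gamma1", "gamma2", "gamma3", "gamma_view"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.rho < 1:
            raise ValueError("rho must be >= 1")
        if not 0 < self.mu0 <= self.mu_max:
            raise ValueError("need 0 < mu0 <= mu_max")
        if self.w_damping < 0:
            raise ValueError("w_damping must be nonnegative")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be a positive integer")
        if self.kernel_t != "auto" and float(self.kernel_t) <= 0:
            raise ValueError('kernel_t must be positive or "auto"')
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")


# Grid-searched regularization weights reported for the three TCGA
# datasets: (gamma1, gamma2, gamma3, gamma_view).
PRESETS: dict[str, PipelineConfig] = {
    "hnsc": PipelineConfig(gamma1=1e-1, gamma2=1e4, gamma3=1e-1, gamma_view=1e0),
    "coad": PipelineConfig(gamma1=1e-1, gamma2=1e-1, gamma3=1e-1, gamma_view=1e2),
    "esca": PipelineConfig(gamma1=1e0, gamma2=1e-1, gamma3=1e2, gamma_view=1e2),
}


def load_config(path: str | Path | None = None, preset: str | None = None,
                **overrides: Any) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file and/or a preset.

    Precedence: keyword overrides > YAML keys > preset values > defaults.
    YAML keys must exactly match the dataclass field names.
    """
    base: dict[str, Any] = {}
    if preset is not None:
        if preset not in PRESETS:
            raise KeyError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
        base.update(dataclasses.asdict(PRESETS[preset]))
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a YAML mapping")
        known = {f.name for f in dataclasses.fields(PipelineConfig)}
        unknown = set(loaded) - known
        if unknown:
            raise ValueError(f"unknown config keys in {path}: {sorted(unknown)}")
        base.update(loaded)
    base.update(overrides)
    return PipelineConfig(**base)
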