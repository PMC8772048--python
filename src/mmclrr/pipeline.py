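"""End-to-end clustering: normalize -> per-view graphs -> LADMAP solver ->
affinity fusion -> normalized cuts -> (optional) evaluation."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .clustering import ClusterAssignment, NCutsClustering, symmetrize_affinity
from .config import PipelineConfig
from .datasets import MultiViewDataset, as_view_matrices
from .graph import view_laplacian
from .io import write_assignment, write_matrix_tsv
from .metrics import MetricsReport, evaluate_clustering
from .solver import MmCLRR

__all__ = ["MmCLRRClustering", "normalize_columns", "run_pipeline", "PipelineResult"]


def normalize_columns(x: np.ndarray) -> np.ndarray:
    """Scale every sample column to unit Euclidean norm (zero columns kept)."""
    x = np.asarray(x, dtype=float)
    norms = np.linalg.norm(x, axis=0)
    return x / np.maximum(norms, np.finfo(float).tiny)


class MmCLRRClustering(ClusterMixin, BaseEstimator):
    """Cluster samples shared by several feature views.

    The one-stop scikit-learn estimator: ``fit`` takes a list of per-view
    features x samples matrices (or a :class:`~mmclrr.datasets.MultiViewDataset`),
    learns the fused low-rank representation and clusters it with
    normalized cuts; ``labels_`` holds the assignment (1..n_clusters).

    See :class:`~mmclrr.solver.MmCLRR` for the representation model and its
    parameters, which this class forwards unchanged.
    """

    def __init__(
        self,
        n_clusters: int = 2,
        gamma1: float = 0.1,
        gamma2: float = 10.0,
        gamma3: float = 0.1,
        gamma_view: float = 1.0,
        k_neighbors: int = 5,
        kernel_t: float | str = "auto",
        mu0: float = 1e-2,
        mu_max: float = 1e6,
        rho: float = 1.1,
        tol: float = 1e-6,
        max_iter: int = 500,
        w_damping: float = 0.0,
        normalize: bool = True,
        random_state: int = 0,
    ):
        self.n_clusters = n_clusters
        self.gamma1 = gamma1
        self.gamma2 = gamma2
        self.gamma3 = gamma3
        self.gamma_view = gamma_view
        self.k_neighbors = k_neighbors
        self.kernel_t = kernel_t
        self.mu0 = mu0
        self.mu_max = mu_max
        self.rho = rho
        self.tol = tol
        self.max_iter = max_iter
        self.w_damping = w_damping
        self.normalize = normalize
        self.random_state = random_state

    @classmethod
    def from_config(cls, config: PipelineConfig) -> "MmCLRRClustering":
        return cls(
            n_clusters=config.n_clusters,
            gamma1=config.gamma1,
            gamma2=config.gamma2,
            gamma3=config.gamma3,
            gamma_view=config.gamma_view,
            k_neighbors=config.k_neighbors,
            kernel_t=config.kernel_t,
            mu0=config.mu0,
            mu_max=config.mu_max,
            rho=config.rho,
            tol=config.tol,
            max_iter=config.max_iter,
            w_damping=config.w_damping,
            normalize=config.normalize_columns,
            random_state=config.seed,
        )

    def fit(self, X: "MultiViewDataset | Sequence[np.ndarray]", y: None = None):
        mats = as_view_matrices(X)
        if self.normalize:
            mats = [normalize_columns(m) for m in mats]
        laplacians = [
            view_laplacian(m, k=self.k_neighbors, t=self.kernel_t) for m in mats
        ]
        solver = MmCLRR(
            gamma1=self.gamma1,
            gamma2=self.gamma2,
            gamma3=self.gamma3,
            gamma_view=self.gamma_view,
            mu0=self.mu0,
            mu_max=self.mu_max,
            rho=self.rho,
            tol=self.tol,
            max_iter=self.max_iter,
            w_damping=self.w_damping,
        )
        solver.fit(mats, laplacians=laplacians)
        clusterer = NCutsClustering(
            n_clusters=self.n_clusters, random_state=self.random_state
        ).fit(solver.Z_star_)

        self.solver_ = solver
        self.Z_star_ = solver.Z_star_
        self.affinity_ = clusterer.affinity_
        self.assignment_ = clusterer.assignment_
        self.labels_ = clusterer.labels_
        self.n_iter_ = solver.n_iter_
        self.converged_ = solver.converged_
        return self

    def fit_predict(self, X, y: None = None) -> np.ndarray:
        return self.fit(X).labels_


@dataclasses.dataclass
class PipelineResult:
    assignment: ClusterAssignment
    metrics: MetricsReport | None
    estimator: MmCLRRClustering


def run_pipeline(
    config: PipelineConfig,
    dataset: MultiViewDataset,
    labels: np.ndarray | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full pipeline and optionally write artifacts to ``out_dir``.

    Artifacts: the assignment TSV, fused affinity and per-view
    representation TSVs, a JSON residual-history log, and (when ground
    truth labels are given) a JSON metrics report.  Non-convergence at
    ``max_iter`` is recorded in the log, not raised.
    """
    est = MmCLRRClustering.from_config(config).fit(dataset)
    metrics = evaluate_clustering(labels, est.labels_) if labels is not None else None
    result = PipelineResult(assignment=est.assignment_, metrics=metrics, estimator=est)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_assignment(est.labels_, dataset.sample_ids, out / "assignment.tsv")
        write_matrix_tsv(
            est.affinity_, out / "fused_affinity.tsv",
            dataset.sample_ids, dataset.sample_ids,
        )
        for name, z in zip(dataset.view_names, est.solver_.Z_):
            write_matrix_tsv(
                z, out / f"Z_{name}.tsv", dataset.sample_ids, dataset.sample_ids
            )
        log = {
            "config": dataclasses.asdict(config),
            "n_views": dataset.n_views,
            "n_samples": dataset.n_samples,
            **est.solver_.diagnostics_.to_dict(),
        }
        (out / "run_log.json").write_text(json.dumps(log, indent=2))
        if metrics is not None:
            (out / "metrics.json").write_text(json.dumps(metrics.to_dict(), indent=2))
    return result
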