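"""Vertex-wise GLM and Monte-Carlo cluster-extent inference on a mesh.

A desk-scale analogue of whole-cortex cluster correction: per-vertex OLS of
subject connectivity maps on the SNP x phenotype interaction (with main
effects and covariates), thresholding of the vertex-wise p-map at a
cluster-forming threshold, connected-component clustering on the mesh
graph (positive and negative statistics clustered separately), and
cluster-wise p-values from the Monte-Carlo null distribution of the
maximum cluster size under smooth Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from scipy.sparse.csgraph import connected_components as _cc

from .association import DEFAULT_COVARIATES
from .containers import GenotypeMatrix


@dataclass
class SurfaceMesh:
    """Undirected triangle/grid mesh reduced to its vertex adjacency graph.

    ``edges`` is an (E, 2) integer array of undirected vertex pairs; the
    graph must be simple (no self-loops, no duplicate edges).  ``area`` is
    an optional per-vertex area used as the cluster-size metric.
    """

    n_vertices: int
    edges: np.ndarray
    area: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=np.intp).reshape(-1, 2)
        if self.edges.size:
            if self.edges.min() < 0 or self.edges.max() >= self.n_vertices:
                raise ValueError("edge endpoint outside vertex range")
            if (self.edges[:, 0] == self.edges[:, 1]).any():
                raise ValueError("self-edges not allowed")
            canon = np.sort(self.edges, axis=1)
            if len(np.unique(canon, axis=0)) != len(canon):
                raise ValueError("duplicate edges not allowed")
            self.edges = canon
        if self.area is not None:
            self.area = np.asarray(self.area, dtype=float)
            if self.area.shape != (self.n_vertices,):
                raise ValueError("area must have one value per vertex")

    @cached_property
    def adjacency(self) -> sp.csr_matrix:
        i, j = self.edges[:, 0], self.edges[:, 1]
        data = np.ones(2 * len(self.edges))
        return sp.csr_matrix(
            (data, (np.r_[i, j], np.r_[j, i])),
            shape=(self.n_vertices, self.n_vertices),
        )

    @cached_property
    def is_connected(self) -> bool:
        if self.n_vertices <= 1:
            return True
        ncomp, _ = _cc(self.adjacency, directed=False)
        return ncomp == 1

    @cached_property
    def smoothing_operator(self) -> sp.csr_matrix:
        """Row-stochastic one-step graph smoother: mean of self + neighbours."""
        A = self.adjacency + sp.eye(self.n_vertices, format="csr")
        deg = np.asarray(A.sum(axis=1)).ravel()
        return sp.diags(1.0 / deg) @ A


def grid_mesh(rows: int, cols: int) -> SurfaceMesh:
    """Rectangular 4-connected grid graph with ``rows * cols`` vertices."""
    idx = np.arange(rows * cols).reshape(rows, cols)
    horiz = np.column_stack([idx[:, :-1].ravel(), idx[:, 1:].ravel()])
    vert = np.column_stack([idx[:-1, :].ravel(), idx[1:, :].ravel()])
    return SurfaceMesh(rows * cols, np.vstack([horiz, vert]))


@dataclass
class ClusterResult:
    """A contiguous suprathreshold patch of one statistic sign."""

    cluster_id: int
    vertices: np.ndarray
    size: float
    peak_t: float
    sign: int
    p_cluster: float | None = None


# ----------------------------------------------------------------------
# Graph utilities


def components_of(mesh: SurfaceMesh, vertex_mask: np.ndarray) -> list[np.ndarray]:
    """Connected components of the subgraph induced by ``vertex_mask``."""
    verts = np.flatnonzero(vertex_mask)
    if verts.size == 0:
        return []
    sub = mesh.adjacency[verts][:, verts]
    ncomp, labels = _cc(sub, directed=False)
    return [verts[labels == k] for k in range(ncomp)]


def smooth_noise_maps(
    mesh: SurfaceMesh, n_subjects: int, smoothing_steps: int, rng: np.random.Generator
) -> np.ndarray:
    """IID per-subject Gaussian vertex maps, graph-smoothed in place.

    Each smoothing step replaces every vertex value by the mean over the
    vertex and its neighbours, inducing spatial autocorrelation with range
    growing in the number of steps.  Returns (n_subjects, n_vertices).
    """
    if smoothing_steps < 0:
        raise ValueError("smoothing_steps must be >= 0")
    maps = rng.standard_normal((n_subjects, mesh.n_vertices))
    if smoothing_steps:
        S = mesh.smoothing_operator
        for _ in range(smoothing_steps):
            maps = maps @ S.T
    return np.asarray(maps)


# ----------------------------------------------------------------------
# Vertex-wise GLM


def _interaction_design(
    geno: GenotypeMatrix,
    cohort: pd.DataFrame,
    snp_id: str,
    phenotype: str,
    covariates: tuple[str, ...],
) -> tuple[np.ndarray, list[str]]:
    n = len(cohort)
    g = geno.imputed()[:, geno.snp_ids.index(snp_id)]
    pheno = cohort[phenotype].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(n)]
        + [cohort[c].to_numpy(dtype=float) for c in covariates]
        + [pheno, g, g * pheno]
    )
    names = ["const", *covariates, phenotype, f"snp[{snp_id}]", f"snp[{snp_id}]:{phenotype}"]
    return X, names


def vertexwise_glm(
    maps: np.ndarray,
    geno: GenotypeMatrix,
    cohort: pd.DataFrame,
    snp_id: str,
    phenotype: str = "severity",
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-vertex interaction t- and p-maps.

    ``maps`` is (n_subjects, n_vertices); at each vertex the map value is
    regressed on covariates, phenotype, SNP dosage and the dosage x
    phenotype interaction, and the interaction's two-tailed t statistic is
    returned with its p-value.  Identical in model to the scalar block-3
    fit of the association module, vectorised across vertices.
    """
    from ._ols import check_full_rank

    X, names = _interaction_design(geno, cohort, snp_id, phenotype, covariates)
    check_full_rank(X, names)
    n, p = X.shape
    if maps.shape[0] != n:
        raise ValueError("maps not aligned with cohort rows")
    pinv = np.linalg.pinv(X)
    beta = pinv @ maps  # (p, V)
    resid = maps - X @ beta
    df = n - p
    sigma2 = np.einsum("nv,nv->v", resid, resid) / df
    XtX_inv_last = (pinv @ pinv.T)[-1, -1]
    se = np.sqrt(sigma2 * XtX_inv_last)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[-1] / se, 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    return t, pvals


# ----------------------------------------------------------------------
# Clustering and correction


def cluster_threshold(
    p_map: np.ndarray,
    t_map: np.ndarray,
    mesh: SurfaceMesh,
    vertex_p: float = 0.05,
) -> list[ClusterResult]:
    """Sign-split suprathreshold clusters, sorted by size descending.

    Vertices with ``p < vertex_p`` are partitioned by the sign of their
    statistic; connected components are formed within each sign so that
    adjacent opposite-direction effects remain distinct clusters.
    """
    p_map = np.asarray(p_map, dtype=float)
    t_map = np.asarray(t_map, dtype=float)
    supra = p_map < vertex_p
    clusters: list[ClusterResult] = []
    for sign in (1, -1):
        mask = supra & ((t_map > 0) if sign > 0 else (t_map < 0))
        for verts in components_of(mesh, mask):
            size = (
                float(mesh.area[verts].sum())
                if mesh.area is not None
                else float(len(verts))
            )
            peak = t_map[verts][np.argmax(np.abs(t_map[verts]))]
            clusters.append(
                ClusterResult(0, verts, size, float(peak), sign)
            )
    clusters.sort(key=lambda c: -c.size)
    for i, c in enumerate(clusters):
        c.cluster_id = i + 1
    return clusters


@dataclass
class ClusterNull:
    """Null distribution of the maximum cluster size under smooth noise."""

    max_sizes: np.ndarray
    vertex_p: float
    smoothing_steps: int

    def assign_p(self, clusters: list[ClusterResult]) -> list[ClusterResult]:
        """Attach add-one Monte-Carlo cluster-wise p-values in place."""
        B = len(self.max_sizes)
        for c in clusters:
            exceed = int(np.sum(self.max_sizes >= c.size))
            c.p_cluster = (1 + exceed) / (B + 1)
        return clusters


def monte_carlo_cluster_correction(
    mesh: SurfaceMesh,
    geno: GenotypeMatrix,
    cohort: pd.DataFrame,
    snp_id: str,
    rng: np.random.Generator,
    phenotype: str = "severity",
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    vertex_p: float = 0.05,
    smoothing_steps: int = 0,
    B: int = 1_000,
) -> ClusterNull:
    """Simulate the null max-cluster-size distribution for a fixed design.

    Each replicate draws smooth Gaussian noise maps for the same subjects,
    runs the identical vertex-wise GLM and sign-split clustering, and
    records the largest cluster size (zero when nothing survives the
    cluster-forming threshold).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    max_sizes = np.empty(B)
    for b in range(B):
        noise = smooth_noise_maps(mesh, len(cohort), smoothing_steps, rng)
        t, p = vertexwise_glm(noise, geno, cohort, snp_id, phenotype, covariates)
        clusters = cluster_threshold(p, t, mesh, vertex_p)
        max_sizes[b] = clusters[0].size if clusters else 0.0
    return ClusterNull(max_sizes, vertex_p, smoothing_steps)


def clusters_to_frame(clusters: list[ClusterResult]) -> pd.DataFrame:
    rows = [
        dict(
            cluster_id=c.cluster_id,
            n_vertices=len(c.vertices),
            size=c.size,
            peak_t=c.peak_t,
            sign=c.sign,
            p_cluster=c.p_cluster,
        )
        for c in clusters
    ]
    return pd.DataFrame(
        rows,
        columns=["cluster_id", "n_vertices", "size", "peak_t", "sign", "p_cluster"],
    )
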