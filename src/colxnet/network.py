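"""Signed weighted co-expression network construction and module detection.

The network follows the WGCNA-style signed convention: adjacency
``a_ij = ((1 + cor(x_i, x_j)) / 2) ** beta`` with a soft-thresholding power
``beta`` chosen for approximate scale-free topology, smoothed into the
topological overlap measure (TOM)

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

with connectivity ``k_i = sum_{u != i} a_iu``. Genes are clustered by
average-linkage hierarchical clustering of 1 - TOM and modules are obtained
by a static cut of the dendrogram with a minimum module size; the cut height
is a quantile of the merge heights indexed by a deep-split level (a
documented simplification of the dynamic hybrid tree cut). Modules are
numbered 1..K in descending size, 0 marking unassigned genes. Each module is
summarized by its eigengene: the first principal component of the
row-standardized member submatrix, unit variance, oriented to correlate
positively with the mean member expression profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .io import ExpressionMatrix

logger = logging.getLogger("colxnet")

__all__ = [
    "NetworkConfig",
    "ModulePartition",
    "select_soft_power",
    "signed_adjacency",
    "topological_overlap",
    "detect_modules",
    "module_eigengene",
    "extract_anchor_module",
]

# deep-split level -> how many steps below the coarsest optimal cut to take
# (larger level = finer cut with tighter module cores)
DEEP_SPLIT_TIE_OFFSET = {0: 0, 1: 0, 2: 0, 3: 1, 4: 2}


@dataclass
class NetworkConfig:
    candidate_powers: tuple[float, ...] = tuple(range(1, 21))
    fit_r2_target: float = 0.85
    min_module_size: int = 30
    deep_split_level: int = 2
    correlation: str = "pearson"  # or "spearman"
    max_genes: int = 20000

    def __post_init__(self) -> None:
        if any(p <= 0 for p in self.candidate_powers):
            raise ValueError("candidate powers must be positive")
        if not (0 < self.fit_r2_target < 1):
            raise ValueError("fit_r2_target must be in (0,1)")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        if self.deep_split_level not in DEEP_SPLIT_TIE_OFFSET:
            raise ValueError("deep_split_level must be in 0..4")
        if self.correlation not in ("pearson", "spearman"):
            raise ValueError("correlation must be pearson or spearman")


@dataclass
class ModulePartition:
    """Gene -> module label (1..K by descending size; 0 unassigned) + eigengenes."""

    labels: dict[str, int]
    eigengenes: pd.DataFrame          # samples x modules, columns "ME<k>"
    explained_variance: dict[int, float]
    anchor_module: int | None = None

    def module_genes(self, module_id: int) -> list[str]:
        return [g for g, l in self.labels.items() if l == module_id]

    @property
    def module_ids(self) -> list[int]:
        return sorted({l for l in self.labels.values() if l != 0})


def _correlation_matrix(X: ExpressionMatrix, method: str = "pearson") -> np.ndarray:
    vals = X.values
    sds = vals.std(axis=1)
    if np.any(sds == 0):
        bad = [g for g, s in zip(X.gene_ids, sds) if s == 0]
        raise ValueError(f"constant gene(s), correlation undefined: {bad[:10]}")
    if method == "spearman":
        vals = np.apply_along_axis(rankdata, 1, vals)
    R = np.corrcoef(vals)
    return np.clip(R, -1.0, 1.0)


def signed_adjacency(X: ExpressionMatrix, beta: float,
                     correlation: str = "pearson",
                     _cor: np.ndarray | None = None) -> np.ndarray:
    """Signed adjacency ((1 + cor)/2)^beta with unit diagonal."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    R = _correlation_matrix(X, correlation) if _cor is None else _cor
    A = ((1.0 + R) / 2.0) ** beta
    np.fill_diagonal(A, 1.0)
    return A


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of log10(freq) vs log10(k) over connectivity bins.

    Returns R^2 when the fitted slope is negative, else -R^2, mirroring the
    sign convention of scale-free topology fit indices.
    """
    k = k[k > 0]
    if k.size < n_bins:
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    if edges[0] == edges[-1]:
        return 0.0
    idx = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, n_bins - 1)
    log_k, log_f = [], []
    for b in range(n_bins):
        members = k[idx == b]
        if members.size == 0:
            continue
        log_k.append(np.log10(members.mean()))
        log_f.append(np.log10(members.size / k.size))
    log_k, log_f = np.asarray(log_k), np.asarray(log_f)
    if log_k.size < 3 or np.allclose(log_k, log_k[0]):
        return 0.0
    slope, intercept = np.polyfit(log_k, log_f, 1)
    resid = log_f - (slope * log_k + intercept)
    ss_tot = np.sum((log_f - log_f.mean()) ** 2)
    r2 = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else 0.0
    return float(r2 if slope < 0 else -r2)


def select_soft_power(X: ExpressionMatrix, config: NetworkConfig
                      ) -> tuple[float, pd.DataFrame]:
    """Choose the soft-thresholding power for approximate scale-free topology.

    Returns the smallest candidate power whose signed scale-free fit R^2
    reaches ``fit_r2_target`` (with negative slope); if none does, the power
    maximizing the signed R^2, with a logged note. The fit table reports the
    signed R^2 and mean connectivity per candidate.
    """
    if X.n_genes < 20:
        raise ValueError("scale-free fit undefined below 20 genes")
    R = _correlation_matrix(X, config.correlation)
    rows = []
    for beta in config.candidate_powers:
        A = ((1.0 + R) / 2.0) ** beta
        np.fill_diagonal(A, 0.0)
        k = A.sum(axis=1)
        rows.append({"power": beta, "sft_r2": _scale_free_fit(k),
                     "mean_k": float(k.mean())})
    fit_table = pd.DataFrame(rows)
    # powers that empty the network (mean connectivity < 1) produce spuriously
    # good fits on a degenerate degree distribution; exclude them unless
    # nothing else is available
    viable = fit_table[fit_table["mean_k"] >= 1.0]
    if viable.empty:
        viable = fit_table
    ok = viable[viable["sft_r2"] >= config.fit_r2_target]
    if len(ok):
        beta = float(ok["power"].iloc[0])
    else:
        beta = float(viable.loc[viable["sft_r2"].idxmax(), "power"])
        logger.warning(
            "no candidate power reached scale-free R^2 target %.2f; "
            "falling back to max-R^2 power %g", config.fit_r2_target, beta)
    return beta, fit_table


def topological_overlap(A: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a symmetric adjacency with unit diagonal."""
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    off = A - np.diag(np.diag(A))
    k = off.sum(axis=1)
    # off has zero diagonal, so (off @ off)_ij already sums shared neighbors
    # over u != i, j only
    numer = off @ off + off
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - off
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(denom > 0, numer / denom, 0.0)
    np.fill_diagonal(tom, 1.0)
    return tom


def _best_static_cut(Z: np.ndarray, min_module_size: int,
                     deep_split_level: int, n_gaps: int = 12) -> float:
    """Static cut height chosen at a wide merge-height gap.

    Candidate cuts are the midpoints of the ``n_gaps`` widest gaps between
    consecutive merge heights — natural separations between tight clusters
    and the diffuse upper tree. Among candidates the cut maximizing the
    number of clusters of at least ``min_module_size`` genes wins; among
    ties the coarsest (highest) cut is taken, stepped down for deep-split
    levels above 2 (finer cuts keep tighter module cores).
    """
    heights = Z[:, 2]
    if heights.size == 0:
        return 0.0
    gaps = np.diff(heights)
    order = np.argsort(gaps)[::-1][:n_gaps]
    cands = sorted((heights[i] + heights[i + 1]) / 2.0
                   for i in order if gaps[i] > 0)
    if not cands:
        return float(heights[-1] + 1e-6)
    counts = []
    for c in cands:
        _, sizes = np.unique(fcluster(Z, t=c, criterion="distance"),
                             return_counts=True)
        counts.append(int((sizes >= min_module_size).sum()))
    max_big = max(counts)
    ties = [c for c, k in zip(cands, counts) if k == max_big]
    offset = DEEP_SPLIT_TIE_OFFSET[deep_split_level]
    return float(ties[max(0, len(ties) - 1 - offset)])


def _order_labels_by_size(raw: np.ndarray) -> np.ndarray:
    """Relabel cluster ids 1..K by descending size; 0 stays 0."""
    out = np.zeros_like(raw)
    ids, counts = np.unique(raw[raw > 0], return_counts=True)
    order = ids[np.argsort(-counts, kind="stable")]
    for new, old in enumerate(order, start=1):
        out[raw == old] = new
    return out


def detect_modules(tom: np.ndarray, X: ExpressionMatrix,
                   config: NetworkConfig) -> ModulePartition:
    """Cluster 1 - TOM by average linkage and cut statically into modules.

    The dendrogram is cut at a single height chosen by scanning all merge
    heights for the cut that maximizes the number of clusters of at least
    ``min_module_size`` genes; among tied heights, the deep-split level picks
    the position (higher level = finer cut). Clusters below
    ``min_module_size`` are unassigned (label 0); surviving clusters are
    renumbered by descending size and summarized by their eigengenes.
    """
    n = tom.shape[0]
    if n != X.n_genes:
        raise ValueError("TOM size does not match expression matrix")
    if n > config.max_genes:
        raise ValueError(f"{n} genes exceeds the max_genes guard ({config.max_genes})")
    diss = 1.0 - tom
    np.fill_diagonal(diss, 0.0)
    diss = (diss + diss.T) / 2.0
    np.clip(diss, 0.0, None, out=diss)
    Z = average(squareform(diss, checks=False))
    cut_height = _best_static_cut(Z, config.min_module_size,
                                  config.deep_split_level)
    raw = fcluster(Z, t=cut_height, criterion="distance")
    ids, counts = np.unique(raw, return_counts=True)
    small = set(ids[counts < config.min_module_size].tolist())
    raw = np.where(np.isin(raw, list(small)), 0, raw)
    labels_arr = _order_labels_by_size(raw)
    labels = dict(zip(X.gene_ids, labels_arr.tolist()))
    if labels_arr.max() == 0:
        logger.warning("no module survived the minimum size filter")
        return ModulePartition(labels, pd.DataFrame(index=X.sample_ids), {})
    me_cols, expl = {}, {}
    for mid in range(1, int(labels_arr.max()) + 1):
        genes = [g for g, l in labels.items() if l == mid]
        me, ev = module_eigengene(X, genes)
        me_cols[f"ME{mid}"] = me
        expl[mid] = ev
    eigengenes = pd.DataFrame(me_cols, index=X.sample_ids)
    return ModulePartition(labels, eigengenes, expl)


def module_eigengene(X: ExpressionMatrix, member_genes: list[str]
                     ) -> tuple[np.ndarray, float]:
    """First PC of the row-standardized member submatrix.

    Unit variance; sign oriented so the eigengene correlates non-negatively
    with the mean standardized member expression. Returns (eigengene over
    samples, fraction of variance explained).
    """
    if len(member_genes) < 2:
        raise ValueError("need >= 2 member genes")
    pos = {g: i for i, g in enumerate(X.gene_ids)}
    missing = [g for g in member_genes if g not in pos]
    if missing:
        raise KeyError(f"member genes absent from matrix: {missing[:10]}")
    sub = X.values[[pos[g] for g in member_genes], :]
    sds = sub.std(axis=1)
    if np.any(sds == 0):
        raise ValueError("constant member gene; eigengene undefined")
    std = (sub - sub.mean(axis=1, keepdims=True)) / sds[:, None]
    # SVD of genes x samples standardized matrix: right singular vector = PC scores
    _, s, vt = np.linalg.svd(std, full_matrices=False)
    me = vt[0]
    explained = float(s[0] ** 2 / np.sum(s ** 2))
    mean_profile = std.mean(axis=0)
    if np.dot(me, mean_profile) < 0:
        me = -me
    me = me / me.std()
    return me, explained


def extract_anchor_module(partition: ModulePartition, anchor_gene: str,
                          X: ExpressionMatrix | None = None
                          ) -> tuple[int | None, list[str], str]:
    """Return the anchor gene's module id, member list and status.

    Status is "assigned" (module id + full member list, anchor included) or
    "unassigned" (label 0: empty list). The anchor must be a gene of the
    partition (and of ``X`` when supplied).
    """
    if X is not None and anchor_gene not in set(X.gene_ids):
        raise KeyError(f"anchor gene {anchor_gene!r} not a row of the expression matrix")
    if anchor_gene not in partition.labels:
        raise KeyError(f"anchor gene {anchor_gene!r} absent from the partition")
    mid = partition.labels[anchor_gene]
    if mid == 0:
        return None, [], "unassigned"
    return mid, partition.module_genes(mid), "assigned"
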