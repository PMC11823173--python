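"""Permutation Z statistics for module preservation across cohorts.

A module discovered in a reference cohort is evaluated in a test cohort with
four statistics — two density statistics (mean off-diagonal intramodular
correlation and mean signed adjacency in the test cohort) and two
connectivity statistics (correlation across member genes of reference-vs-test
intramodular connectivity, and correlation of the vectorized intramodular
correlation matrices). Each observed statistic is standardized against a
permutation null of random same-size gene sets drawn from the shared gene
universe (module genes excluded). Z_density and Z_connectivity are the
medians of their groups' Z scores and Z_summary is their mean; Z_summary > 10
is the conventional threshold for strong preservation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import ExpressionMatrix

logger = logging.getLogger("colxnet")

__all__ = ["PreservationResult", "preservation_observed", "z_summary"]

DENSITY_STATS = ("mean_intramodular_cor", "mean_adjacency")
CONNECTIVITY_STATS = ("cor_kIM", "cor_cor")


@dataclass
class PreservationResult:
    module_genes: list[str]
    observed: dict[str, float]
    z_scores: dict[str, float]
    z_density: float
    z_connectivity: float
    z_summary: float
    n_permutations: int
    seed: int
    notes: list[str] = field(default_factory=list)


def _module_stats(rows_ref: np.ndarray, rows_test: np.ndarray, beta: float
                  ) -> dict[str, float]:
    m = rows_ref.shape[0]
    iu = np.triu_indices(m, k=1)
    R_test = np.corrcoef(rows_test)
    R_ref = np.corrcoef(rows_ref)
    A_test = ((1.0 + R_test) / 2.0) ** beta
    k_test = A_test.sum(axis=1) - np.diag(A_test)
    A_ref = ((1.0 + R_ref) / 2.0) ** beta
    k_ref = A_ref.sum(axis=1) - np.diag(A_ref)
    return {
        "mean_intramodular_cor": float(R_test[iu].mean()),
        "mean_adjacency": float(A_test[iu].mean()),
        "cor_kIM": float(np.corrcoef(k_ref, k_test)[0, 1]),
        "cor_cor": float(np.corrcoef(R_ref[iu], R_test[iu])[0, 1]),
    }


def _aligned_rows(module_genes: list[str], X_ref: ExpressionMatrix,
                  X_test: ExpressionMatrix) -> tuple[list[str], np.ndarray, np.ndarray]:
    ref_genes = set(X_ref.gene_ids)
    test_genes = set(X_test.gene_ids)
    shared = [g for g in module_genes if g in ref_genes and g in test_genes]
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} module genes shared between cohorts; need >= 3")
    frac = len(shared) / len(module_genes)
    if frac < 1.0:
        logger.info("preservation: %.0f%% of module genes shared across cohorts",
                    100 * frac)
    rows_ref = X_ref.subset_genes(shared).values
    rows_test = X_test.subset_genes(shared).values
    for name, rows in (("reference", rows_ref), ("test", rows_test)):
        if np.any(rows.std(axis=1) == 0):
            raise ValueError(f"constant gene inside module in {name} cohort")
    return shared, rows_ref, rows_test


def preservation_observed(module_genes: list[str], X_ref: ExpressionMatrix,
                          X_test: ExpressionMatrix, beta: float) -> dict[str, float]:
    """Observed density/connectivity preservation statistics for one module."""
    _, rows_ref, rows_test = _aligned_rows(module_genes, X_ref, X_test)
    return _module_stats(rows_ref, rows_test, beta)


def z_summary(module_genes: list[str], X_ref: ExpressionMatrix,
              X_test: ExpressionMatrix, beta: float, n_perm: int = 200,
              seed: int = 0) -> PreservationResult:
    """Permutation Z_summary for a module evaluated in a test cohort."""
    if n_perm < 50:
        raise ValueError("n_perm must be >= 50")
    shared, rows_ref, rows_test = _aligned_rows(module_genes, X_ref, X_test)
    observed = _module_stats(rows_ref, rows_test, beta)

    universe = [g for g in X_ref.gene_ids
                if g in set(X_test.gene_ids) and g not in set(shared)]
    m = len(shared)
    if len(universe) < m:
        raise ValueError("gene universe too small for same-size permutation draws")
    ref_all = X_ref.subset_genes(universe).values
    test_all = X_test.subset_genes(universe).values
    ok = (ref_all.std(axis=1) > 0) & (test_all.std(axis=1) > 0)
    ref_all, test_all = ref_all[ok], test_all[ok]

    rng = np.random.default_rng(seed)
    null: dict[str, list[float]] = {s: [] for s in observed}
    for _ in range(n_perm):
        idx = rng.choice(ref_all.shape[0], size=m, replace=False)
        stats = _module_stats(ref_all[idx], test_all[idx], beta)
        for s, v in stats.items():
            null[s].append(v)

    notes: list[str] = []
    z_scores: dict[str, float] = {}
    for s, v in observed.items():
        arr = np.asarray(null[s])
        sd = arr.std(ddof=1)
        if sd == 0:
            z_scores[s] = float(np.inf) if v > arr.mean() else float(-np.inf)
            notes.append(f"null sd of {s} is zero; Z reported as +/-inf")
            logger.warning("preservation: %s", notes[-1])
        else:
            z_scores[s] = float((v - arr.mean()) / sd)
    z_density = float(np.median([z_scores[s] for s in DENSITY_STATS]))
    z_connectivity = float(np.median([z_scores[s] for s in CONNECTIVITY_STATS]))
    return PreservationResult(
        module_genes=shared, observed=observed, z_scores=z_scores,
        z_density=z_density, z_connectivity=z_connectivity,
        z_summary=float((z_density + z_connectivity) / 2.0),
        n_permutations=n_perm, seed=seed, notes=notes,
    )
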