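"""Low-expression filters, probe collapsing, normalization and log transform.

Three platform-specific low-expression rules are implemented verbatim from
their stated inequalities:

* RSEM (RNA-Seq): removed iff value < 1 in >= 50% of samples AND mean < 50
  (the rule is conjunctive).
* raw counts: removed iff count < ``min_count`` in >= ``frac`` of samples.
* log intensity (microarray): removed iff below the supplied threshold in
  strictly more than ``frac`` of samples. The intensity threshold is dataset
  specific and has no default.

Count normalization is median-of-ratios (DESeq-style size factors computed
over zero-free reference genes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ExpressionMatrix, Unit

__all__ = [
    "FilterReport",
    "filter_low_expression_rsem",
    "filter_low_expression_counts",
    "filter_low_intensity",
    "collapse_probes",
    "median_of_ratios_normalize",
    "log_transform",
]


@dataclass
class FilterReport:
    rule: str
    genes_removed: list[str] = field(default_factory=list)
    genes_kept_count: int = 0
    params: dict = field(default_factory=dict)


def _apply_removal(X: ExpressionMatrix, remove_mask: np.ndarray, rule: str,
                   params: dict) -> tuple[ExpressionMatrix, FilterReport]:
    if X.n_genes == 0:
        raise ValueError("empty expression matrix")
    keep = ~remove_mask
    kept_genes = [g for g, k in zip(X.gene_ids, keep) if k]
    removed = [g for g, k in zip(X.gene_ids, keep) if not k]
    filtered = ExpressionMatrix(kept_genes, list(X.sample_ids), X.values[keep, :],
                                X.unit, X.cohort_label)
    report = FilterReport(rule=rule, genes_removed=removed,
                          genes_kept_count=len(kept_genes), params=params)
    return filtered, report


def filter_low_expression_rsem(X: ExpressionMatrix) -> tuple[ExpressionMatrix, FilterReport]:
    """Remove genes with RSEM < 1 in >= 50% of samples and overall mean < 50."""
    if X.unit != Unit.RSEM:
        raise ValueError(f"expected rsem unit, got {X.unit.value}")
    if X.n_genes == 0:
        raise ValueError("empty expression matrix")
    frac_below_1 = (X.values < 1).mean(axis=1)
    mean_val = X.values.mean(axis=1)
    remove = (frac_below_1 >= 0.5) & (mean_val < 50)
    return _apply_removal(X, remove, "low_expression_rsem",
                          {"value_lt": 1, "frac_ge": 0.5, "mean_lt": 50})


def filter_low_expression_counts(X: ExpressionMatrix, min_count: int = 5,
                                 frac: float = 0.90) -> tuple[ExpressionMatrix, FilterReport]:
    """Remove genes with fewer than ``min_count`` counts in >= ``frac`` of samples."""
    if X.unit != Unit.COUNTS:
        raise ValueError(f"expected counts unit, got {X.unit.value}")
    if X.n_genes == 0:
        raise ValueError("empty expression matrix")
    frac_below = (X.values < min_count).mean(axis=1)
    remove = frac_below >= frac
    return _apply_removal(X, remove, "low_expression_counts",
                          {"min_count": min_count, "frac_ge": frac})


def filter_low_intensity(X: ExpressionMatrix, threshold: float,
                         frac: float = 0.80) -> tuple[ExpressionMatrix, FilterReport]:
    """Remove genes below ``threshold`` in strictly more than ``frac`` of samples."""
    if X.unit != Unit.LOG_INTENSITY:
        raise ValueError(f"expected log_intensity unit, got {X.unit.value}")
    if X.n_genes == 0:
        raise ValueError("empty expression matrix")
    frac_below = (X.values < threshold).mean(axis=1)
    remove = frac_below > frac
    return _apply_removal(X, remove, "low_intensity",
                          {"threshold": threshold, "frac_gt": frac})


def collapse_probes(P: ExpressionMatrix, probe_to_gene: dict[str, str | list[str]]
                    ) -> tuple[ExpressionMatrix, FilterReport]:
    """Collapse probe rows to gene rows.

    Unmapped and multi-mapping probes are dropped (and reported). Among probes
    of a single gene, the probe with the highest mean intensity represents the
    gene (max-mean consolidation rule).
    """
    if not probe_to_gene:
        raise ValueError("empty probe-to-gene mapping")
    dropped: list[str] = []
    per_gene: dict[str, list[int]] = {}
    for i, probe in enumerate(P.gene_ids):
        target = probe_to_gene.get(probe)
        if target is None:
            dropped.append(probe)
            continue
        if isinstance(target, (list, tuple, set)):
            targets = list(target)
            if len(targets) != 1:
                dropped.append(probe)
                continue
            target = targets[0]
        per_gene.setdefault(str(target), []).append(i)
    genes, rows = [], []
    means = P.values.mean(axis=1)
    for gene, idxs in per_gene.items():
        best = max(idxs, key=lambda i: means[i])
        genes.append(gene)
        rows.append(best)
    collapsed = ExpressionMatrix(genes, list(P.sample_ids), P.values[rows, :],
                                 P.unit, P.cohort_label)
    report = FilterReport(rule="collapse_probes", genes_removed=dropped,
                          genes_kept_count=len(genes),
                          params={"consolidation": "max_mean_probe"})
    return collapsed, report


def median_of_ratios_normalize(X: ExpressionMatrix
                               ) -> tuple[ExpressionMatrix, np.ndarray]:
    """Median-of-ratios size-factor normalization of raw counts.

    The reference per gene is the geometric mean of its counts across samples,
    computed over genes with no zero count. Each sample's size factor is the
    median over reference genes of count/reference; normalized values are
    counts divided by the size factor.
    """
    if X.unit != Unit.COUNTS:
        raise ValueError(f"expected counts unit, got {X.unit.value}")
    if X.n_samples < 2:
        raise ValueError("need at least 2 samples")
    counts = X.values
    zero_free = np.all(counts > 0, axis=1)
    if not zero_free.any():
        raise ValueError(
            "no gene with all-positive counts; supply a pseudo-reference or "
            "pre-filter more aggressively"
        )
    ref = counts[zero_free, :]
    log_geomean = np.log(ref).mean(axis=1)
    size_factors = np.exp(np.median(np.log(ref) - log_geomean[:, None], axis=0))
    normalized = counts / size_factors[None, :]
    out = ExpressionMatrix(list(X.gene_ids), list(X.sample_ids), normalized,
                           unit=Unit.RSEM, cohort_label=X.cohort_label)
    return out, size_factors


def log_transform(X: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(x + pseudocount); input values must be non-negative."""
    if np.any(X.values < 0):
        raise ValueError("log transform requires non-negative values")
    return ExpressionMatrix(list(X.gene_ids), list(X.sample_ids),
                            np.log2(X.values + pseudocount), unit=Unit.LOG2,
                            cohort_label=X.cohort_label)
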