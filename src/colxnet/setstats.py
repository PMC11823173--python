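"""Gene-set overlap enrichment and correlation-aware differential activity.

Overlap enrichment is a one-sided Fisher exact test of a gene set against a
module within a declared gene universe, BH-adjusted across the collection,
with significance requiring p.adj below the mode's alpha (0.05 standard,
0.10 for TF-target candidate discovery) and odds ratio > 1.

Differential set activity between high and low strata is quantified as the
mean log2 fold change of set genes relative to the background mean ("mean
activity relative to background"). Because set genes are correlated, the
variance of the set mean is inflated by VIF = 1 + (m - 1) * rho_bar, with
rho_bar the mean pairwise correlation of the set genes across all samples
(floored at 0 so VIF >= 1); the test statistic is t-distributed with
Welch-combined degrees of freedom. A set is called significant when its BH
p.adj < 0.05 AND its enrichment magnitude reaches at least 25% of the anchor
module's own activity magnitude in the same comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger("colxnet")

__all__ = [
    "EnrichmentRow",
    "ActivityRow",
    "fisher_overlap",
    "bh_adjust",
    "enrichment_screen",
    "set_activity",
    "activity_screen",
]

MODE_ALPHA = {"standard": 0.05, "tft_discovery": 0.10}


@dataclass
class EnrichmentRow:
    set_name: str
    overlap: int
    overlap_genes: list[str]
    odds_ratio: float
    p: float
    p_adj: float = float("nan")
    significant: bool = False


@dataclass
class ActivityRow:
    set_name: str
    enrichment: float          # mean log2FC of set genes relative to background
    vif: float
    p: float
    p_adj: float = float("nan")
    significant: bool = False
    reference_activity: float = float("nan")


def fisher_overlap(set_genes, module_genes, universe) -> tuple[float, float, int]:
    """One-sided (upper tail) Fisher test of set x module overlap in a universe.

    Returns (odds_ratio, p, overlap). The odds ratio is the sample estimate
    a*d / (b*c), +inf when b*c = 0 with a > 0.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    s = set(set_genes) & universe
    m = set(module_genes)
    if not m <= universe:
        raise ValueError("module must be a subset of the universe")
    a = len(s & m)
    b = len(m) - a
    c = len(s) - a
    d = len(universe) - a - b - c
    # upper-tail hypergeometric: P(overlap >= a)
    p = float(sps.hypergeom.sf(a - 1, len(universe), len(s), len(m)))
    if b * c == 0:
        odds = float("inf") if a > 0 else float("nan")
    else:
        odds = a * d / (b * c)
    return odds, min(p, 1.0), a


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrichment_screen(collection: GeneSetCollection, module_genes, universe,
                      mode: str = "standard") -> list[EnrichmentRow]:
    """Fisher overlap per set, BH across the collection, mode-specific gates."""
    if mode not in MODE_ALPHA:
        raise ValueError(f"mode must be one of {sorted(MODE_ALPHA)}")
    if not collection.sets:
        raise ValueError("empty gene-set collection")
    universe = set(universe)
    module = set(module_genes)
    rows = []
    for name, members in collection.sets.items():
        odds, p, a = fisher_overlap(members, module, universe)
        rows.append(EnrichmentRow(
            set_name=name, overlap=a,
            overlap_genes=sorted(set(members) & module & universe),
            odds_ratio=odds, p=p))
    adj = bh_adjust([r.p for r in rows])
    alpha = MODE_ALPHA[mode]
    for r, pa in zip(rows, adj):
        r.p_adj = float(pa)
        r.significant = bool(pa < alpha and r.odds_ratio > 1)
    return rows


def _group_masks(X: ExpressionMatrix, groups: dict[str, list[str]]
                 ) -> tuple[np.ndarray, np.ndarray]:
    idx = {s: j for j, s in enumerate(X.sample_ids)}
    hi = np.array([idx[s] for s in groups["high"]], dtype=int)
    lo = np.array([idx[s] for s in groups["low"]], dtype=int)
    if hi.size < 3 or lo.size < 3:
        raise ValueError("each stratum needs >= 3 samples")
    return hi, lo


def set_activity(X_log2: ExpressionMatrix, groups: dict[str, list[str]],
                 set_genes, background_genes) -> ActivityRow:
    """VIF-corrected differential activity of one gene set (high vs low).

    Enrichment is the set-mean log2 difference minus the background-mean log2
    difference; since the background contains the set, this equals
    (1 - m/N) * (set mean - non-set mean). Its variance combines the
    VIF-inflated set-mean variance (VIF = 1 + (m-1)*rho_bar from per-gene
    Welch variances) with the non-set mean's variance (genes treated as
    independent), both scaled by (1 - m/N)^2; degrees of freedom are the mean
    per-gene Welch-Satterthwaite df of the set genes.
    """
    background = list(dict.fromkeys(background_genes))
    set_genes = list(dict.fromkeys(set_genes))
    if not set(set_genes) <= set(background):
        raise ValueError("set genes must be contained in the background")
    hi, lo = _group_masks(X_log2, groups)
    bg = X_log2.subset_genes(background)
    d_bg = bg.values[:, hi].mean(axis=1) - bg.values[:, lo].mean(axis=1)
    pos = {g: i for i, g in enumerate(bg.gene_ids)}
    sel = np.array([pos[g] for g in set_genes], dtype=int)
    d_set = d_bg[sel]
    enrichment = float(d_set.mean() - d_bg.mean())

    sub = bg.values[sel]
    m = sel.size
    N = len(background)
    v_hi = sub[:, hi].var(axis=1, ddof=1)
    v_lo = sub[:, lo].var(axis=1, ddof=1)
    per_gene_var = v_hi / hi.size + v_lo / lo.size
    nonset = np.setdiff1d(np.arange(N), sel)
    if nonset.size:
        vb_hi = bg.values[nonset][:, hi].var(axis=1, ddof=1)
        vb_lo = bg.values[nonset][:, lo].var(axis=1, ddof=1)
        nonset_mean_var = float((vb_hi / hi.size + vb_lo / lo.size).sum()
                                / nonset.size ** 2)
    else:
        nonset_mean_var = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        df_g = per_gene_var ** 2 / (
            (v_hi / hi.size) ** 2 / (hi.size - 1)
            + (v_lo / lo.size) ** 2 / (lo.size - 1))
    df = float(np.nanmean(df_g)) if np.isfinite(df_g).any() else hi.size + lo.size - 2

    if m > 1:
        R = np.corrcoef((sub - sub.mean(axis=1, keepdims=True))
                        / np.where(sub.std(axis=1) == 0, 1, sub.std(axis=1))[:, None])
        iu = np.triu_indices(m, k=1)
        rho_bar = max(float(np.nanmean(R[iu])), 0.0)
    else:
        rho_bar = 0.0
    vif = 1.0 + (m - 1) * rho_bar
    shrink = 1.0 - m / N  # enrichment = (1 - m/N) * (set mean - non-set mean)
    set_mean_var = vif * per_gene_var.sum() / m ** 2
    se = float(shrink * np.sqrt(set_mean_var + nonset_mean_var)) if shrink > 0 else 0.0
    if se == 0:
        p = 1.0 if enrichment == 0 else 0.0
    else:
        p = float(2.0 * sps.t.sf(abs(enrichment) / se, df))
    return ActivityRow(set_name="", enrichment=enrichment, vif=float(vif), p=p)


def activity_screen(collection: GeneSetCollection, X_log2: ExpressionMatrix,
                    groups: dict[str, list[str]], anchor_module_genes,
                    background_genes) -> list[ActivityRow]:
    """Screen a collection for differential activity between strata.

    BH across the collection; significance requires p.adj < 0.05 and
    |enrichment| >= 25% of the anchor module's activity magnitude. When the
    anchor activity is exactly 0 the magnitude gate degenerates and the
    p.adj gate alone applies, with a warning.
    """
    if not collection.sets:
        raise ValueError("empty gene-set collection")
    reference = set_activity(X_log2, groups, anchor_module_genes, background_genes)
    ref_mag = abs(reference.enrichment)
    if ref_mag == 0:
        logger.warning("anchor-module activity is 0; the 25%%-magnitude gate "
                       "degenerates, applying the p.adj gate alone")
    rows = []
    bg = set(background_genes)
    for name, members in collection.sets.items():
        members_in_bg = [g for g in members if g in bg]
        if len(members_in_bg) == 0:
            logger.warning("set %r has no genes in the background; skipped", name)
            continue
        row = set_activity(X_log2, groups, members_in_bg, background_genes)
        row.set_name = name
        row.reference_activity = reference.enrichment
        rows.append(row)
    adj = bh_adjust([r.p for r in rows])
    for r, pa in zip(rows, adj):
        r.p_adj = float(pa)
        gate = True if ref_mag == 0 else abs(r.enrichment) >= 0.25 * ref_mag
        r.significant = bool(pa < 0.05 and gate)
    return rows
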