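"""Cell-type markers, signature matrix, and bulk fraction deconvolution.

Markers follow the "tissue-enriched" four-fold rule: a gene is a marker of
cell type t iff, against EVERY other type, its log2 fold change (pseudocount
1 on normalized means) is >= 2 AND its BH-adjusted p-value is < 0.05. The
per-contrast test is a moderated two-sample t on log2(normalized+1)
replicate values: per-gene pooled variances are shrunk toward the
across-gene distribution with an empirical-Bayes prior (the moderation that
makes 2-3-replicate designs testable), adding the estimated prior degrees of
freedom to the residual df. Markers build a
reduced signature matrix of per-type mean normalized expression; per-sample
cell-type abundances are imputed by non-negative least squares of the bulk
marker-gene vector on the signature columns (absolute scores), rescaled to
per-sample relative fractions. Fractions are related to %G.A.M.E. by
Spearman correlation with Bonferroni correction across cell types.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import nnls

from .io import ExpressionMatrix
from .setstats import bh_adjust

__all__ = [
    "MarkerTable",
    "define_celltype_markers",
    "build_signature_matrix",
    "impute_fractions",
    "correlate_fractions_with_game",
]

LOG2FC_MIN = 2.0
P_ADJ_MAX = 0.05


@dataclass
class MarkerTable:
    contrasts: pd.DataFrame   # gene, celltype, other, log2fc, p, p_adj
    markers: dict[str, list[str]]  # celltype -> marker genes

    def is_marker(self, gene: str, celltype: str) -> bool:
        return gene in self.markers.get(celltype, [])


def _fit_prior_df(s2: np.ndarray, df_resid: int) -> tuple[float, float]:
    """Empirical-Bayes prior (df0, s0^2) for gene variances.

    Moment estimation on log variances: a scaled chi^2_df variance s^2 has
    E[log s^2] = log(sigma^2) + psi(df/2) - log(df/2) and Var[log s^2] =
    psi'(df/2); the excess spread of log s^2 beyond psi'(df_resid/2)
    identifies the prior df.
    """
    from scipy.special import polygamma, digamma
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 10:
        return np.inf, float(np.mean(s2)) if s2.size else 1.0
    z = np.log(s2)
    e = z - digamma(df_resid / 2.0) + np.log(df_resid / 2.0)
    evar = z.var(ddof=1) - float(polygamma(1, df_resid / 2.0))
    if evar <= 0:
        # variances more concentrated than chi^2 sampling alone: infinite prior
        return np.inf, float(np.exp(e.mean()))
    from scipy.optimize import brentq
    f = lambda d0: float(polygamma(1, d0 / 2.0)) - evar
    if f(1e-2) < 0:
        df0 = 1e-2
    elif f(1e6) > 0:
        df0 = np.inf
    else:
        df0 = brentq(f, 1e-2, 1e6)
    if np.isfinite(df0):
        s0 = float(np.exp(e.mean() + digamma(df0 / 2.0) - np.log(df0 / 2.0)))
    else:
        s0 = float(np.exp(e.mean()))
    return float(df0), s0


def define_celltype_markers(norm_counts: ExpressionMatrix, labels: list[str]
                            ) -> MarkerTable:
    """Four-fold rule markers from replicated normalized count profiles."""
    if len(labels) != norm_counts.n_samples:
        raise ValueError("labels must match samples")
    types = list(dict.fromkeys(labels))
    lab = np.asarray(labels)
    for t in types:
        if (lab == t).sum() < 2:
            raise ValueError(f"cell type {t!r} has < 2 replicates")
    vals = norm_counts.values
    logv = np.log2(vals + 1.0)
    means = {t: vals[:, lab == t].mean(axis=1) for t in types}
    rows = []
    for t in types:
        for o in types:
            if o == t:
                continue
            a, b = logv[:, lab == t], logv[:, lab == o]
            na, nb = a.shape[1], b.shape[1]
            df_resid = na + nb - 2
            s2 = (a.var(axis=1, ddof=1) * (na - 1)
                  + b.var(axis=1, ddof=1) * (nb - 1)) / df_resid
            df0, s0 = _fit_prior_df(s2, df_resid)
            if np.isfinite(df0):
                s2_mod = (df0 * s0 + df_resid * s2) / (df0 + df_resid)
                df_mod = df0 + df_resid
            else:
                s2_mod = np.full_like(s2, s0)
                df_mod = np.inf
            se = np.sqrt(s2_mod * (1.0 / na + 1.0 / nb))
            tstat = np.where(se > 0, (a.mean(axis=1) - b.mean(axis=1)) / se, 0.0)
            if np.isfinite(df_mod):
                p = 2.0 * sps.t.sf(np.abs(tstat), df_mod)
            else:
                p = 2.0 * sps.norm.sf(np.abs(tstat))
            l2fc = np.log2((means[t] + 1.0) / (means[o] + 1.0))
            for g, fc, pv in zip(norm_counts.gene_ids, l2fc, p):
                rows.append((g, t, o, float(fc), float(pv)))
    df = pd.DataFrame(rows, columns=["gene", "celltype", "other", "log2fc", "p"])
    df["p"] = df["p"].fillna(1.0)
    df["p_adj"] = bh_adjust(df["p"].to_numpy())
    passed = (df["log2fc"] >= LOG2FC_MIN) & (df["p_adj"] < P_ADJ_MAX)
    df["pass"] = passed
    markers: dict[str, list[str]] = {t: [] for t in types}
    by_gene_type = df.groupby(["gene", "celltype"])["pass"].all()
    for (g, t), ok in by_gene_type.items():
        if ok:
            markers[t].append(g)
    for t in markers:
        markers[t].sort()
    return MarkerTable(contrasts=df.drop(columns=["pass"]), markers=markers)


def build_signature_matrix(norm_counts: ExpressionMatrix, labels: list[str],
                           markers: dict[str, list[str]],
                           max_genes: int | None = None) -> pd.DataFrame:
    """Signature of mean normalized expression: marker genes x cell types.

    With ``max_genes`` set, each type keeps at most max_genes/k markers,
    ranked by descending minimum pairwise log2 fold change (most specific
    first).
    """
    types = list(dict.fromkeys(labels))
    lab = np.asarray(labels)
    for t in types:
        if not markers.get(t):
            raise ValueError(f"cell type {t!r} has no markers")
    vals = norm_counts.values
    gene_idx = {g: i for i, g in enumerate(norm_counts.gene_ids)}
    means = {t: vals[:, lab == t].mean(axis=1) for t in types}

    selected: dict[str, list[str]] = {}
    cap = None if max_genes is None else max(1, max_genes // len(types))
    claimed: set[str] = set()
    for t in types:
        genes = [g for g in markers[t] if g in gene_idx]
        if claimed & set(genes):
            raise AssertionError("a gene is claimed as marker of two types")
        claimed |= set(genes)
        if cap is not None and len(genes) > cap:
            def min_fc(g: str) -> float:
                i = gene_idx[g]
                return min(np.log2((means[t][i] + 1) / (means[o][i] + 1))
                           for o in types if o != t)
            genes = sorted(genes, key=min_fc, reverse=True)[:cap]
            genes = sorted(genes)
        selected[t] = genes
    rows = [g for t in types for g in selected[t]]
    sig = pd.DataFrame(
        {t: [means[t][gene_idx[g]] for g in rows] for t in types}, index=rows)
    return sig


def impute_fractions(signature: pd.DataFrame, X_bulk: ExpressionMatrix
                     ) -> pd.DataFrame:
    """Per-sample NNLS abundances on the signature; absolute and relative.

    Returns a frame indexed by sample with one column per cell type
    (absolute scores) plus ``<type>_rel`` relative fractions (NaN when a
    sample's absolute scores sum to 0).
    """
    shared = [g for g in signature.index if g in set(X_bulk.gene_ids)]
    if not shared:
        raise ValueError("no signature genes shared with the bulk matrix")
    if len(shared) < signature.shape[1]:
        raise ValueError("fewer shared signature genes than cell types")
    S = signature.loc[shared].to_numpy(dtype=float)
    B = X_bulk.subset_genes(shared).values
    types = list(signature.columns)
    abs_scores = np.zeros((X_bulk.n_samples, len(types)))
    for j in range(X_bulk.n_samples):
        coef, _ = nnls(S, B[:, j])
        abs_scores[j] = coef
    out = pd.DataFrame(abs_scores, index=X_bulk.sample_ids, columns=types)
    totals = abs_scores.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(totals[:, None] > 0, abs_scores / totals[:, None], np.nan)
    for i, t in enumerate(types):
        out[f"{t}_rel"] = rel[:, i]
    return out


def correlate_fractions_with_game(fractions: pd.DataFrame, game_values: pd.Series,
                                  relative: bool = False) -> pd.DataFrame:
    """Spearman correlation of per-type fractions with %G.A.M.E.

    Bonferroni correction multiplies raw p by the number of cell types. Run
    with ``relative=False`` for absolute scores and ``relative=True`` for
    relative fractions.
    """
    shared = [s for s in fractions.index if s in set(game_values.index)]
    if len(shared) < 3:
        raise ValueError("need >= 3 matched samples")
    types = [c for c in fractions.columns if not c.endswith("_rel")]
    cols = [f"{t}_rel" for t in types] if relative else types
    g = game_values.loc[shared].to_numpy(dtype=float)
    rows = []
    for t, c in zip(types, cols):
        f = fractions.loc[shared, c].to_numpy(dtype=float)
        ok = np.isfinite(f)
        rho, p = sps.spearmanr(f[ok], g[ok])
        rows.append({"celltype": t, "rho": float(rho), "p": float(p),
                     "p_bonf": float(min(1.0, p * len(types)))})
    return pd.DataFrame(rows)
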