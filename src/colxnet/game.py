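"""%G.A.M.E. sample scoring and Jenks natural-breaks stratification.

%G.A.M.E. (percentage of Genes Above-Median Expression) scores sample s on a
module M as the fraction of module genes whose expression in s is strictly
above that gene's median across the whole cohort. The score lives in [0, 1],
is invariant to any strictly increasing per-gene transformation, and turns a
unimodal module-eigengene distribution into a bimodal one that clusters
cleanly. Samples are split into low/medium/high groups at the Jenks natural
breaks (the optimal 1-D classification minimizing within-class sums of
squared deviations), and binarized for Kaplan-Meier comparison as low vs all
others.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

__all__ = [
    "SampleStrata",
    "game_score",
    "jenks_breaks",
    "assign_game_groups",
    "binarize_for_km",
    "stratify_samples",
]


@dataclass
class SampleStrata:
    table: pd.DataFrame          # index sample_id; columns game, group, km_label
    breaks: tuple[float, float]
    gene_medians: dict[str, float]

    @property
    def game(self) -> pd.Series:
        return self.table["game"]


def game_score(X: ExpressionMatrix, module_genes: list[str]) -> pd.Series:
    """Fraction of module genes strictly above their cohort-wide median.

    Medians are the usual interpolated sample medians per gene. Ties at the
    median do not count (a constant gene contributes 0 to every sample).
    """
    if not module_genes:
        raise ValueError("empty module")
    sub = X.subset_genes(list(module_genes))
    medians = np.median(sub.values, axis=1)
    above = sub.values > medians[:, None]
    return pd.Series(above.mean(axis=0), index=X.sample_ids, name="game")


def _ssd_prefix(v: np.ndarray):
    c1 = np.concatenate([[0.0], np.cumsum(v)])
    c2 = np.concatenate([[0.0], np.cumsum(v * v)])

    def ssd(i: int, j: int) -> float:
        # within-class sum of squared deviations of v[i..j] inclusive
        n = j - i + 1
        s = c1[j + 1] - c1[i]
        return (c2[j + 1] - c2[i]) - s * s / n

    return ssd


def jenks_breaks(values, k: int = 3) -> tuple[float, ...]:
    """Fisher-Jenks optimal classification of 1-D values into k classes.

    Dynamic-programming minimization of the total within-class sum of squared
    deviations over contiguous partitions of the sorted values. Returns the
    k-1 upper boundaries (class maxima) of the lower classes.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if np.unique(v).size < k:
        raise ValueError(f"need at least {k} distinct values")
    ssd = _ssd_prefix(v)
    # cost[c][j]: minimal SSD of splitting v[0..j] into c+1 classes
    cost = np.full((k, n), np.inf)
    split = np.zeros((k, n), dtype=int)
    for j in range(n):
        cost[0][j] = ssd(0, j)
    for c in range(1, k):
        for j in range(c, n):
            best, best_i = np.inf, c
            for i in range(c, j + 1):
                cand = cost[c - 1][i - 1] + ssd(i, j)
                if cand < best:
                    best, best_i = cand, i
            cost[c][j] = best
            split[c][j] = best_i
    # backtrack class boundaries
    bounds = []
    j = n - 1
    for c in range(k - 1, 0, -1):
        i = split[c][j]
        bounds.append(v[i - 1])  # class maximum of the lower class
        j = i - 1
    return tuple(float(b) for b in reversed(bounds))


def assign_game_groups(game_values, breaks) -> list[str]:
    """Label values as low/medium/high: value <= b1 -> low, <= b2 -> medium, else high."""
    b1, b2 = tuple(breaks)
    out = []
    for v in np.asarray(game_values, dtype=float):
        if v <= b1:
            out.append("low")
        elif v <= b2:
            out.append("medium")
        else:
            out.append("high")
    return out


def binarize_for_km(groups) -> list[str]:
    """Collapse low/medium/high to the Kaplan-Meier grouping low vs high."""
    return ["low" if g == "low" else "high" for g in groups]


def stratify_samples(X: ExpressionMatrix, module_genes: list[str],
                     k: int = 3) -> SampleStrata:
    """Score, break and label all samples in one call."""
    game = game_score(X, module_genes)
    breaks = jenks_breaks(game.to_numpy(), k=k)
    groups = assign_game_groups(game.to_numpy(), breaks)
    km = binarize_for_km(groups)
    sub = X.subset_genes(list(module_genes))
    medians = dict(zip(sub.gene_ids, np.median(sub.values, axis=1).tolist()))
    table = pd.DataFrame({"game": game, "group": groups, "km_label": km})
    return SampleStrata(table=table, breaks=(breaks[0], breaks[-1]),
                        gene_medians=medians)
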