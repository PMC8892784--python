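"""Time-agnostic differential expression screen across the three groups.

All 18 fpkm values per group are pooled without regard to collection time and
compared with a Kruskal-Wallis omnibus test per gene, BH-adjusted across
genes.  Genes with q <= alpha get all three pairwise Mann-Whitney post-hoc
tests, a compact letter display (groups sharing a letter are not
significantly different), and a pattern category; the dominant patterns in
this design are WRF up (or down) versus both C and W.

Post-hoc Mann-Whitney p-values are intentionally not multiplicity-adjusted —
only the omnibus test is — and letters derive from raw post-hoc p < 0.05.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .ensemble import bh_adjust
from .io import ExpressionMatrix

logger = logging.getLogger("circaheart")

__all__ = [
    "filter_expressed",
    "kruskal_wallis_test",
    "mann_whitney_test",
    "assign_letter_groups",
    "differential_expression_screen",
]

CATEGORIES = ("WRF_up_vs_C_and_W", "WRF_down_vs_C_and_W", "W_different", "other", "none")


def filter_expressed(matrix: ExpressionMatrix, threshold: float = 1.0,
                     min_samples: int = 18) -> ExpressionMatrix:
    """Keep genes with expression strictly above ``threshold`` in at least
    ``min_samples`` samples (default: fpkm > 1 in >= 18 of 54)."""
    n_above = (matrix.values > threshold).sum(axis=1)
    keep = n_above >= min_samples
    kept = matrix.data.loc[keep]
    logger.info("expression filter: kept %d/%d genes (>%g in >=%d samples)",
                kept.shape[0], matrix.data.shape[0], threshold, min_samples)
    return ExpressionMatrix(kept, list(matrix.samples))


def kruskal_wallis_test(values: Sequence[float], group_labels: Sequence) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    Identical values across all groups give (H=0, p=1).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    groups = [values[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    if np.ptp(values) == 0.0:
        return 0.0, 1.0
    res = _stats.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def mann_whitney_test(a: Sequence[float], b: Sequence[float],
                      continuity: bool = True) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact enumeration when n_a + n_b <= 12 and the pooled data are untied,
    otherwise the normal approximation with tie correction (and continuity
    correction unless disabled).  Returns (U of sample a, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    untied = len(np.unique(pooled)) == pooled.size
    if np.ptp(pooled) == 0.0:
        return float(a.size * b.size / 2.0), 1.0
    if untied and (a.size + b.size) <= 12:
        method = "exact"
    else:
        method = "asymptotic"
    res = _stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                              use_continuity=continuity)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def assign_letter_groups(pairwise_significant: Mapping[tuple[str, str], bool],
                         group_order: Sequence[str]) -> dict[str, str]:
    """Compact letter display: groups share a letter iff not significantly
    different.

    Uses the insert-and-absorb clique cover of the "not different" graph:
    start from one clique of all groups, split every clique containing a
    significantly different pair, drop subsets, and letter the surviving
    cliques in the fixed group order.
    """
    order = list(group_order)
    sig = {frozenset(pair) for pair, s in pairwise_significant.items() if s}
    cliques: list[set[str]] = [set(order)]
    for pair in sorted(sig, key=lambda fs: tuple(sorted(fs, key=order.index))):
        u, v = sorted(pair, key=order.index)
        new: list[set[str]] = []
        for cl in cliques:
            if u in cl and v in cl:
                new.extend([cl - {u}, cl - {v}])
            else:
                new.append(cl)
        # drop empty cliques and subsets of other cliques
        new = [cl for cl in new if cl]
        cliques = [cl for i, cl in enumerate(new)
                   if not any(cl < other or (cl == other and i > j)
                              for j, other in enumerate(new))]
    # letter cliques by their earliest member in the fixed order
    cliques.sort(key=lambda cl: min(order.index(g) for g in cl))
    letters = {g: "" for g in order}
    for i, cl in enumerate(cliques):
        letter = chr(ord("a") + i)
        for g in cl:
            letters[g] += letter
    return letters


def _categorize(letters: Mapping[str, str], medians: Mapping[str, float]) -> str:
    lc, lw, lwrf = set(letters["C"]), set(letters["W"]), set(letters["WRF"])
    wrf_distinct = not (lwrf & lc) and not (lwrf & lw)
    if wrf_distinct and medians["WRF"] > medians["C"] and medians["WRF"] > medians["W"]:
        return "WRF_up_vs_C_and_W"
    if wrf_distinct and medians["WRF"] < medians["C"] and medians["WRF"] < medians["W"]:
        return "WRF_down_vs_C_and_W"
    if not (lw & lc) and not (lw & lwrf):
        return "W_different"
    return "other"


def differential_expression_screen(matrix: ExpressionMatrix, alpha: float = 0.05,
                                   posthoc_alpha: float = 0.05,
                                   continuity: bool = True) -> pd.DataFrame:
    """Kruskal-Wallis screen with Mann-Whitney post hoc and letter groups.

    Expects an expression-filtered matrix containing groups C, W, and WRF.
    Returns one row per gene with H, p, q, the three pairwise p-values,
    letters per group, the pattern category, and group medians.  Genes with
    q > alpha are categorized ``none`` and skip the post hoc stage.
    """
    groups = ("C", "W", "WRF")
    cols = {g: matrix.group_columns(g) for g in groups}  # raises if absent
    values = matrix.values
    gene_ids = matrix.gene_ids
    n = len(gene_ids)
    H = np.empty(n)
    p_kw = np.empty(n)
    for i in range(n):
        samples = [values[i, cols[g]] for g in groups]
        if np.ptp(np.concatenate(samples)) == 0.0:
            H[i], p_kw[i] = 0.0, 1.0
        else:
            res = _stats.kruskal(*samples)
            H[i], p_kw[i] = res.statistic, res.pvalue
    q_kw = bh_adjust(p_kw)

    pairs = [("C", "W"), ("C", "WRF"), ("W", "WRF")]
    pair_cols = {pair: f"p_{pair[0]}_{pair[1]}" for pair in pairs}
    records = []
    for i in range(n):
        medians = {g: float(np.median(values[i, cols[g]])) for g in groups}
        rec = {
            "gene_id": gene_ids[i],
            "H": float(H[i]),
            "p_kw": float(p_kw[i]),
            "q_kw": float(q_kw[i]),
            **{f"median_{g}": medians[g] for g in groups},
        }
        if q_kw[i] <= alpha:
            pw = {}
            for ga, gb in pairs:
                _, p = mann_whitney_test(values[i, cols[ga]], values[i, cols[gb]],
                                         continuity=continuity)
                pw[(ga, gb)] = p
                rec[pair_cols[(ga, gb)]] = p
            sig = {pair: p < posthoc_alpha for pair, p in pw.items()}
            letters = assign_letter_groups(sig, groups)
            rec.update({f"letters_{g}": letters[g] for g in groups})
            rec["category"] = _categorize(letters, medians)
        else:
            for pair in pairs:
                rec[pair_cols[pair]] = np.nan
            rec.update({f"letters_{g}": "" for g in groups})
            rec["category"] = "none"
        records.append(rec)
    out = pd.DataFrame.from_records(records)
    n_sig = int((out["category"] != "none").sum())
    logger.info("DE screen: %d/%d genes significant at q <= %g", n_sig, n, alpha)
    return out
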