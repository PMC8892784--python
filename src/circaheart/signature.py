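"""Score misregulated genes against disease gene modules.

Three complementary views of how a perturbed transcriptome relates to
cardiac-hypertrophy gene programs and cardiomyopathy signatures:

* percent-of-module-upregulated enrichment, tested per module against the
  null module M0 with a one-sided Fisher's exact test;
* per-module distributions of log2 expression ratios (e.g. WRF/C medians),
  each compared to M0 with a Kruskal-Wallis test;
* cumulative-distribution shift of a disease gene set's ratios against all
  genes, compared by a two-sample Kolmogorov-Smirnov test after normalizing
  both distributions to 500 quantiles (removing raw-size sensitivity).

Modules are cross-referenced with the expressed-gene universe first and only
modules keeping at least 50 genes are analyzed.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .io import ExpressionMatrix, ModuleSet

logger = logging.getLogger("circaheart")

__all__ = [
    "filter_modules",
    "module_enrichment",
    "module_expression_shift",
    "quantile_normalize_distribution",
    "ks_shift_test",
]


def filter_modules(modules: ModuleSet, universe: Iterable[str],
                   min_size: int = 50) -> ModuleSet:
    """Cross-reference modules with the expressed universe, then drop modules
    under ``min_size`` genes.  The null module is always retained but must
    itself stay at or above ``min_size``."""
    uni = frozenset(universe)
    crossed = {mid: genes & uni for mid, genes in modules.modules.items()}
    null_id = modules.null_module_id
    if len(crossed[null_id]) < min_size:
        raise ValueError(
            f"null module {null_id!r} keeps only {len(crossed[null_id])} universe "
            f"genes (< {min_size}); reference unusable"
        )
    kept = {mid: genes for mid, genes in crossed.items()
            if len(genes) >= min_size or mid == null_id}
    logger.info("module filter: kept %d/%d modules at >= %d universe genes",
                len(kept), len(crossed), min_size)
    return ModuleSet(kept, null_module_id=null_id)


def module_enrichment(up_set: Iterable[str], modules: ModuleSet,
                      universe: Iterable[str], alpha: float = 0.05,
                      alternative: str = "greater") -> pd.DataFrame:
    """Per-module enrichment of ``up_set`` members versus the null module.

    Each module M != M0 is scored with a 2x2 Fisher's exact test contrasting
    membership (M vs M0) against up-set membership, one-sided for enrichment
    by default.  Returns module size, n_up, percent_up, the p-value and a
    flagged column (p < alpha).
    """
    uni = frozenset(universe)
    up = frozenset(up_set) & uni
    null_id = modules.null_module_id
    m0 = modules[null_id] & uni
    m0_up = len(m0 & up)
    rows = []
    for mid in modules.module_ids:
        genes = modules[mid] & uni
        n_up = len(genes & up)
        size = len(genes)
        pct = 100.0 * n_up / size if size else 0.0
        if mid == null_id:
            rows.append({"module_id": mid, "size_in_universe": size, "n_up": n_up,
                         "percent_up": pct, "fisher_p": np.nan, "flagged": False})
            continue
        if len(up) == 0:
            p = 1.0
        else:
            table = [[n_up, size - n_up], [m0_up, len(m0) - m0_up]]
            p = float(_stats.fisher_exact(table, alternative=alternative)[1])
        rows.append({"module_id": mid, "size_in_universe": size, "n_up": n_up,
                     "percent_up": pct, "fisher_p": p, "flagged": p < alpha})
    return pd.DataFrame(rows)


def module_expression_shift(matrix: ExpressionMatrix, modules: ModuleSet,
                            group_a: str = "WRF", group_b: str = "C",
                            alpha: float = 0.05) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene log2 median ratios between two groups, summarized per module.

    The ratio for each gene is log2(median(group_a) / median(group_b)) over
    that group's samples; genes with a zero median in either group are
    excluded (no pseudocount) and counted in the log.  Each module's ratio
    distribution is compared to M0's with a Kruskal-Wallis test; the returned
    stats include the median, the module IQR, M0's interquartile band, and a
    flagged column (p < alpha).

    Returns (per-gene ratio table, per-module stats table).
    """
    cols_a = matrix.group_columns(group_a)
    cols_b = matrix.group_columns(group_b)
    med_a = np.median(matrix.values[:, cols_a], axis=1)
    med_b = np.median(matrix.values[:, cols_b], axis=1)
    ok = (med_a > 0) & (med_b > 0)
    n_excluded = int(np.sum(~ok))
    if n_excluded:
        logger.info("expression shift: excluded %d genes with a zero group median",
                    n_excluded)
    gene_ids = np.asarray(matrix.gene_ids)
    ratios = pd.DataFrame({
        "gene_id": gene_ids[ok],
        "log2_ratio": np.log2(med_a[ok] / med_b[ok]),
    })
    ratio_of = dict(zip(ratios["gene_id"], ratios["log2_ratio"]))
    null_id = modules.null_module_id
    m0_ratios = np.array([ratio_of[g] for g in modules[null_id] if g in ratio_of])
    if m0_ratios.size < 2:
        raise ValueError("null module has fewer than 2 usable ratio values")
    m0_q1, m0_q3 = np.percentile(m0_ratios, [25, 75])
    rows = []
    for mid in modules.module_ids:
        vals = np.array([ratio_of[g] for g in modules[mid] if g in ratio_of])
        rec = {
            "module_id": mid,
            "n_genes": int(vals.size),
            "median_log2_ratio": float(np.median(vals)) if vals.size else np.nan,
            "iqr_low": float(np.percentile(vals, 25)) if vals.size else np.nan,
            "iqr_high": float(np.percentile(vals, 75)) if vals.size else np.nan,
            "m0_iqr_low": float(m0_q1),
            "m0_iqr_high": float(m0_q3),
        }
        if mid == null_id or vals.size < 2:
            rec.update({"kw_p_vs_M0": np.nan, "flagged": False})
        elif np.ptp(np.concatenate([vals, m0_ratios])) == 0.0:
            rec.update({"kw_p_vs_M0": 1.0, "flagged": False})
        else:
            p = float(_stats.kruskal(vals, m0_ratios).pvalue)
            rec.update({"kw_p_vs_M0": p, "flagged": p < alpha})
        rows.append(rec)
    return ratios, pd.DataFrame(rows)


def quantile_normalize_distribution(values: Sequence[float], n: int = 500) -> np.ndarray:
    """Summarize a distribution by ``n`` quantiles at probabilities
    (i - 0.5)/n, using linear interpolation of the empirical quantile
    function (Hazen plotting positions); the output is nondecreasing."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 2:
        raise ValueError("need at least 2 finite values")
    probs = (np.arange(1, n + 1) - 0.5) / n
    return np.quantile(values, probs, method="hazen")


def ks_shift_test(all_gene_ratios: Sequence[float], subset_ratios: Sequence[float],
                  n_quantiles: int = 500, label: str = "") -> pd.DataFrame:
    """Two-sample KS test between a gene subset's ratio distribution and the
    all-genes background, both normalized to ``n_quantiles`` quantiles first.

    Returns a one-row table with D, the asymptotic p (effective n =
    ``n_quantiles`` per side), the subset size, and the median shift.
    """
    subset = np.asarray(subset_ratios, dtype=float)
    if subset.size < 2:
        raise ValueError("subset must contain at least 2 values")
    qa = quantile_normalize_distribution(all_gene_ratios, n=n_quantiles)
    qs = quantile_normalize_distribution(subset, n=n_quantiles)
    res = _stats.ks_2samp(qs, qa, alternative="two-sided", method="asymp")
    return pd.DataFrame([{
        "label": label,
        "n_genes": int(subset.size),
        "D": float(res.statistic),
        "ks_p": float(res.pvalue),
        "median_shift": float(np.median(qs) - np.median(qa)),
    }])
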