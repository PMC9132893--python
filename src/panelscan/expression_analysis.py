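"""Tumor-vs-normal differential expression, tissue specificity, correlation ranking.

Differential expression follows the cohort rule used for bulk FPKM panels:
only cancer types with more than ``min_normals`` normal samples are tested;
per gene the two-sided Wilcoxon rank-sum test is applied to log-transformed
values, p-values are BH-adjusted within the cancer type, and a gene is
called up-regulated when log2FC > 1 and adjusted p < 0.05 (down-regulation
symmetric). The fold change is log2(mean tumor FPKM + 1) - log2(mean normal
FPKM + 1) by default; a mean-of-logs variant is available.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import InputError, OmicsMatrix

DE_COLUMNS = ["gene", "cancer_type", "log2_fold_change", "p_value", "adjusted_p", "direction"]


class CohortSkipped(Exception):
    """Raised when a cancer type fails the normal-sample requirement."""

    def __init__(self, cancer_type: str, n_normals: int, min_normals: int):
        self.cancer_type = cancer_type
        self.n_normals = n_normals
        super().__init__(f"{cancer_type}: {n_normals} normals < required > {min_normals}")


def differential_expression(expr: OmicsMatrix, cancer_type: str, min_normals: int = 5,
                            lfc_threshold: float = 1.0, alpha: float = 0.05,
                            pseudocount: float = 1.0, fc_mode: str = "log_of_means") -> pd.DataFrame:
    """Per-gene tumor-vs-normal DE within one cancer type.

    Raises :class:`CohortSkipped` when the cancer type has ``min_normals``
    or fewer normal samples (the cohort rule requires strictly more).
    """
    if fc_mode not in ("log_of_means", "mean_of_logs"):
        raise InputError(f"unknown fc_mode {fc_mode!r}")
    meta = expr.col_meta
    if meta is None:
        raise InputError("expression matrix lacks sample metadata")
    cols = meta.index[meta["cancer_type"] == cancer_type]
    is_tumor = meta.loc[cols, "is_tumor"].astype(bool)
    tumor_cols, normal_cols = cols[is_tumor], cols[~is_tumor]
    if len(normal_cols) <= min_normals:
        raise CohortSkipped(cancer_type, len(normal_cols), min_normals)
    if len(tumor_cols) == 0:
        raise InputError(f"{cancer_type}: no tumor samples")

    fpkm_t = expr.values[tumor_cols].to_numpy(dtype=float)
    fpkm_n = expr.values[normal_cols].to_numpy(dtype=float)
    log_t = np.log2(fpkm_t + pseudocount)
    log_n = np.log2(fpkm_n + pseudocount)
    res = stats.mannwhitneyu(log_t, log_n, axis=1, alternative="two-sided", method="asymptotic")
    pvals = np.asarray(res.pvalue, dtype=float)
    if fc_mode == "log_of_means":
        lfc = np.log2(fpkm_t.mean(axis=1) + pseudocount) - np.log2(fpkm_n.mean(axis=1) + pseudocount)
    else:
        lfc = log_t.mean(axis=1) - log_n.mean(axis=1)
    adj = multipletests(pvals, method="fdr_bh")[1]
    direction = np.where(
        (lfc > lfc_threshold) & (adj < alpha), "up",
        np.where((lfc < -lfc_threshold) & (adj < alpha), "down", "ns"),
    )
    return pd.DataFrame(
        {
            "gene": expr.features,
            "cancer_type": cancer_type,
            "log2_fold_change": lfc,
            "p_value": pvals,
            "adjusted_p": adj,
            "direction": direction,
        },
        columns=DE_COLUMNS,
    ).reset_index(drop=True)


def differential_expression_all(expr: OmicsMatrix, min_normals: int = 5, **kwargs
                                ) -> tuple[pd.DataFrame, list[dict]]:
    """DE across every cancer type in the cohort; skipped cohorts are logged."""
    meta = expr.col_meta
    if meta is None:
        raise InputError("expression matrix lacks sample metadata")
    results, skipped = [], []
    for ct in sorted(meta["cancer_type"].unique()):
        try:
            results.append(differential_expression(expr, ct, min_normals=min_normals, **kwargs))
        except CohortSkipped as exc:
            skipped.append({"cancer_type": ct, "n_normals": exc.n_normals, "status": "skipped"})
    out = pd.concat(results, ignore_index=True) if results else pd.DataFrame(columns=DE_COLUMNS)
    return out, skipped


def tissue_specificity_classify(expr_by_tissue: pd.DataFrame, fold: float = 4.0,
                                group_min: int = 2, group_max: int = 7) -> pd.Series:
    """HPA-style expression specificity classes from a gene x tissue mean matrix.

    Classes, checked in order:
    * ``tissue enriched`` — one tissue at least ``fold`` x every other tissue;
    * ``group enriched`` — a group of ``group_min``..``group_max`` tissues,
      each at least ``fold`` x the mean of all remaining tissues;
    * ``tissue enhanced`` — some tissue at least ``fold`` x the mean across
      all tissues;
    * ``low specificity`` otherwise.
    """
    if expr_by_tissue.shape[1] < 3:
        raise InputError("at least 3 tissues required")
    if (expr_by_tissue.to_numpy() < 0).any():
        raise InputError("negative expression values")
    classes = {}
    arr = expr_by_tissue.to_numpy(dtype=float)
    for i, gene in enumerate(expr_by_tissue.index):
        x = arr[i]
        order = np.argsort(x)[::-1]
        xs = x[order]
        label = "low specificity"
        if xs[0] >= fold * xs[1] and xs[0] > 0:
            label = "tissue enriched"
        else:
            # for fixed group size g the top-g tissues dominate every other group
            for g in range(group_min, min(group_max, len(xs) - 1) + 1):
                rest_mean = xs[g:].mean()
                if xs[g - 1] >= fold * rest_mean and xs[g - 1] > 0:
                    label = "group enriched"
                    break
            if label == "low specificity" and xs[0] >= fold * x.mean() and xs[0] > 0:
                label = "tissue enhanced"
        classes[gene] = label
    return pd.Series(classes, name="specificity_class")


def tissue_mean_matrix(expr: OmicsMatrix, normals_only: bool = True) -> pd.DataFrame:
    """Gene x tissue mean FPKM from cohort columns (normal samples by default)."""
    meta = expr.col_meta
    if meta is None:
        raise InputError("expression matrix lacks sample metadata")
    cols = meta.index if not normals_only else meta.index[~meta["is_tumor"].astype(bool)]
    if len(cols) == 0:
        raise InputError("no samples available for tissue means")
    tissues = meta.loc[cols, "tissue"]
    return expr.values[cols].T.groupby(tissues).mean().T


def rank_by_correlation(expr: OmicsMatrix | pd.DataFrame, anchor_gene: str) -> pd.DataFrame:
    """Spearman correlation of every gene with the anchor, sorted descending.

    Ties get average ranks. Genes with zero variance get NaN rho, are placed
    last and flagged (``defined = False``). The anchor itself is excluded.
    """
    values = expr.values if isinstance(expr, OmicsMatrix) else expr
    if anchor_gene not in values.index:
        raise InputError(f"anchor gene {anchor_gene!r} not in matrix")
    arr = values.to_numpy(dtype=float)
    ranks = stats.rankdata(arr, axis=1)
    sd = ranks.std(axis=1)
    anchor_idx = values.index.get_loc(anchor_gene)
    if sd[anchor_idx] == 0:
        raise InputError("anchor gene is constant across samples")
    a = ranks[anchor_idx]
    a = (a - a.mean())
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    denom = np.sqrt((centered**2).sum(axis=1) * (a**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = centered @ a / denom
    rho[sd == 0] = np.nan
    out = pd.DataFrame({"gene": values.index, "rho": rho})
    out = out[out["gene"] != anchor_gene]
    out["defined"] = out["rho"].notna()
    out = out.sort_values(["defined", "rho"], ascending=[False, False], kind="mergesort")
    return out.reset_index(drop=True)
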