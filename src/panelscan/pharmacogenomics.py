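"""Drug-sensitivity preprocessing and rank-correlation screens.

``prepare_ic50`` reproduces the preprocessing contract of the classic
row-wise KNN imputation (impute.knn): drugs (rows) missing IC50 in more than
``na_limit`` of cell lines are removed outright; remaining missing entries
are imputed from the ``k`` nearest rows by Euclidean distance over mutually
observed columns; rows missing more than ``rowmax`` fall back to column
means; any column missing more than ``colmax`` aborts. The ``maxp``
recursive-partitioning path (and hence the random seed) only engages above
``maxp`` rows; desk-scale matrices never take it, so imputation here is
deterministic regardless of the seed.

``correlation_screen`` computes Spearman correlations (average-rank ties)
between every row of one matrix and every row of another over their shared
columns, with t-approximation p-values (exact permutation enumeration for
n <= 9), BH adjustment across all tested pairs, and a significance rule of
|SCC| > threshold AND adjusted p < 0.05. One function serves the four
screens (drug IC50 at 0.15; actionable genes, essentiality profiles and the
MKI67 proliferation marker at 0.2).
"""

from __future__ import annotations

import math
from itertools import permutations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import InputError, OmicsMatrix

SCREEN_COLUMNS = ["left_id", "right_id", "scc", "p_value", "adjusted_p", "n_pairs",
                  "threshold", "significant", "defined"]


def prepare_ic50(ic50: OmicsMatrix | pd.DataFrame, na_limit: float = 0.30, k: int = 5,
                 rowmax: float = 0.5, colmax: float = 0.8, maxp: int = 1500,
                 seed: int = 362436069) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter high-NA drugs and KNN-impute the rest (see module docstring).

    Returns ``(complete_matrix, removal_log)``; the removal log has one row
    per dropped drug with its missing fraction.
    """
    df = (ic50.values if isinstance(ic50, OmicsMatrix) else ic50).astype(float)
    na_frac = df.isna().mean(axis=1)
    removed = df.index[na_frac > na_limit]
    removal_log = pd.DataFrame(
        {"drug": removed, "missing_fraction": na_frac[removed].to_numpy(),
         "reason": f"missing in more than {na_limit:.0%} of cell lines"}
    )
    df = df.drop(index=removed)
    if df.empty:
        return df, removal_log
    col_na = df.isna().mean(axis=0)
    bad_cols = col_na[col_na > colmax]
    if len(bad_cols):
        raise InputError(f"cell line(s) exceed colmax missingness: {', '.join(bad_cols.index[:5])}")
    arr = df.to_numpy()
    miss = np.isnan(arr)
    if not miss.any():
        return df, removal_log
    col_means = np.nanmean(arr, axis=0)
    row_na = miss.mean(axis=1)
    out = arr.copy()
    # rowmax fallback: rows too sparse for neighbour search use column means
    for i in np.where(row_na > rowmax)[0]:
        out[i, miss[i]] = col_means[miss[i]]
    knn_rows = np.where(miss.any(axis=1) & (row_na <= rowmax))[0]
    for i in knn_rows:
        shared = ~miss[i] & ~miss  # per candidate row: columns observed in both
        diffs = arr - arr[i]
        with np.errstate(invalid="ignore"):
            sq = np.where(shared, diffs**2, 0.0)
        counts = shared.sum(axis=1)
        dist = np.full(len(arr), np.inf)
        ok = counts > 0
        dist[ok] = np.sqrt(sq[ok].sum(axis=1) / counts[ok])
        dist[i] = np.inf
        for j in np.where(miss[i])[0]:
            have = ~miss[:, j]
            have[i] = False
            cand = np.where(have & np.isfinite(dist))[0]
            if len(cand) == 0:
                out[i, j] = col_means[j]
                continue
            nearest = cand[np.argsort(dist[cand], kind="mergesort")[:k]]
            out[i, j] = arr[nearest, j].mean()
    return pd.DataFrame(out, index=df.index, columns=df.columns), removal_log


def _exact_spearman_pvalue(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman rho (small n)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx_c = rx - rx.mean()
    denom_x = math.sqrt((rx_c**2).sum())
    hits = total = 0
    for perm in permutations(ry):
        ry_c = np.asarray(perm) - ry.mean()
        denom = denom_x * math.sqrt((ry_c**2).sum())
        rho = float(rx_c @ ry_c / denom) if denom > 0 else 0.0
        total += 1
        if abs(rho) >= abs(rho_obs) - 1e-9:
            hits += 1
    return hits / total


def correlation_screen(expr: OmicsMatrix | pd.DataFrame, response: OmicsMatrix | pd.DataFrame,
                       scc_threshold: float = 0.15, adjust: str = "BH",
                       alpha: float = 0.05) -> pd.DataFrame:
    """All-pairs Spearman screen between two matrices over shared columns.

    Pairs with a constant profile on either side are reported with undefined
    rho and excluded from the BH family. The significance flag requires both
    |SCC| > ``scc_threshold`` and adjusted p < ``alpha``.
    """
    left = (expr.values if isinstance(expr, OmicsMatrix) else expr).astype(float)
    right = (response.values if isinstance(response, OmicsMatrix) else response).astype(float)
    shared = left.columns.intersection(right.columns)
    n = len(shared)
    if n < 3:
        raise InputError(f"need >= 3 shared samples, found {n}")
    if left.loc[:, shared].isna().any().any() or right.loc[:, shared].isna().any().any():
        raise InputError("matrices must be complete over shared columns (impute first)")
    lx = left[shared].to_numpy()
    rx = right[shared].to_numpy()
    lr = stats.rankdata(lx, axis=1)
    rr = stats.rankdata(rx, axis=1)
    l_sd = lr.std(axis=1)
    r_sd = rr.std(axis=1)
    lc = lr - lr.mean(axis=1, keepdims=True)
    rc = rr - rr.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (lc @ rc.T) / np.sqrt(np.outer((lc**2).sum(axis=1), (rc**2).sum(axis=1)))
    rho[l_sd == 0, :] = np.nan
    rho[:, r_sd == 0] = np.nan
    rho = np.clip(rho, -1.0, 1.0)
    if n <= 9:
        pvals = np.full(rho.shape, np.nan)
        for i in range(rho.shape[0]):
            for j in range(rho.shape[1]):
                if np.isfinite(rho[i, j]):
                    pvals[i, j] = _exact_spearman_pvalue(lx[i], rx[j], rho[i, j])
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            t = rho * np.sqrt((n - 2) / np.maximum(1e-300, 1 - rho**2))
        pvals = 2 * stats.t.sf(np.abs(t), df=n - 2)
        pvals = np.where(np.isclose(np.abs(rho), 1.0), 0.0, pvals)
    out = pd.DataFrame(
        {
            "left_id": np.repeat(left.index.to_numpy(), rho.shape[1]),
            "right_id": np.tile(right.index.to_numpy(), rho.shape[0]),
            "scc": rho.ravel(),
            "p_value": pvals.ravel(),
            "n_pairs": n,
            "threshold": scc_threshold,
        }
    )
    out["defined"] = out["scc"].notna()
    adj = np.full(len(out), np.nan)
    defined = out["defined"].to_numpy()
    if defined.any():
        if adjust.upper() != "BH":
            raise InputError(f"unsupported adjustment {adjust!r}")
        adj[defined] = multipletests(out.loc[defined, "p_value"], method="fdr_bh")[1]
    out["adjusted_p"] = adj
    out["significant"] = defined & (out["scc"].abs() > scc_threshold) & (out["adjusted_p"] < alpha)
    return out[SCREEN_COLUMNS]


def knn_vs_column_mean_rmse(complete: pd.DataFrame, missing_fraction: float = 0.10,
                            seed: int = 0, **knn_kwargs) -> dict:
    """Mask entries MCAR, impute with KNN and with column means, compare RMSE."""
    rng = np.random.default_rng(seed)
    arr = complete.to_numpy(dtype=float)
    mask = rng.random(arr.shape) < missing_fraction
    # keep at least one observed value per row and column
    mask &= ~(mask.all(axis=1, keepdims=True))
    holey = arr.copy()
    holey[mask] = np.nan
    df = pd.DataFrame(holey, index=complete.index, columns=complete.columns)
    imputed, _ = prepare_ic50(df, na_limit=1.0, **knn_kwargs)
    knn_rmse = float(np.sqrt(np.mean((imputed.to_numpy()[mask] - arr[mask]) ** 2)))
    col_means = np.nanmean(holey, axis=0)
    col_filled = np.where(np.isnan(holey), col_means[None, :], holey)
    mean_rmse = float(np.sqrt(np.mean((col_filled[mask] - arr[mask]) ** 2)))
    return {"knn_rmse": knn_rmse, "column_mean_rmse": mean_rmse,
            "n_masked": int(mask.sum())}
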