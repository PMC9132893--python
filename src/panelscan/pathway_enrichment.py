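"""Preranked GSEA on co-expression rankings of panel genes.

For each anchor gene, all other genes are ranked by their Spearman
correlation with the anchor, and each gene set's enrichment score (ES) is
the signed maximum deviation of the weighted Kolmogorov-Smirnov running sum:
walking down the ranked list, a hit increments by |score|^weight (normalized
so hits sum to 1) and a miss decrements by 1/(N - N_hit). The null
distribution is obtained by permuting set membership (random sets of the
same size drawn from the ranked list); NES is the ES divided by the mean
|null ES| of matching sign, the permutation p-value is two-sided with the
+1 correction (so its floor is 1/(n_perm + 1)), and BH adjustment is applied
across sets within each anchor.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .containers import InputError, OmicsMatrix
from .expression_analysis import rank_by_correlation

GSEA_COLUMNS = ["anchor_gene", "set_name", "es", "nes", "p_value", "adjusted_p",
                "n_overlap", "leading_edge", "status"]


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set file (name, description, genes...)."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise InputError(f"malformed GMT line: {line[:80]!r}")
        name, genes = parts[0], [g for g in parts[2:] if g]
        if not genes:
            raise InputError(f"empty gene set {name!r}")
        if len(set(genes)) != len(genes):
            genes = list(dict.fromkeys(genes))
        sets[name] = genes
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path, description: str = "") -> None:
    lines = [f"{name}\t{description}\t" + "\t".join(genes) for name, genes in sets.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def _es_core(weights: np.ndarray, hit_positions: np.ndarray, n_total: int) -> tuple[float, np.ndarray]:
    """ES and full running-sum profile for one ranked list and one hit set.

    ``weights`` are |score|^weight over the whole ranked list (length N);
    ``hit_positions`` are 0-based indices of set members in the list.
    """
    n_hit = len(hit_positions)
    hit_w = weights[hit_positions]
    total = hit_w.sum()
    if total <= 0:
        # all hit scores are zero: equal steps (unweighted KS)
        hit_w = np.ones(n_hit)
        total = float(n_hit)
    steps = np.full(n_total, -1.0 / (n_total - n_hit))
    steps[hit_positions] = hit_w / total
    profile = np.cumsum(steps)
    es = float(profile[np.argmax(np.abs(profile))])
    return es, profile


def preranked_es(ranked_list: Sequence[tuple[str, float]], gene_set: Sequence[str],
                 weight: float = 1.0) -> tuple[float, np.ndarray]:
    """Weighted KS enrichment score for one gene set on a ranked (gene, score) list.

    The list must be ordered (descending score); the set must intersect the
    list and must not cover it entirely (the miss decrement would be
    undefined).
    """
    genes = [g for g, _ in ranked_list]
    scores = np.asarray([s for _, s in ranked_list], dtype=float)
    members = set(gene_set)
    hit_positions = np.array([i for i, g in enumerate(genes) if g in members], dtype=int)
    if len(hit_positions) == 0:
        raise InputError("gene set does not intersect the ranked list")
    if len(hit_positions) == len(genes):
        raise InputError("gene set covers the entire ranked list")
    weights = np.abs(scores) ** weight
    return _es_core(weights, hit_positions, len(genes))


def _es_batch(weights: np.ndarray, pos_matrix: np.ndarray, n_total: int) -> np.ndarray:
    """Vectorized ES for many hit-position sets of equal size.

    The running-sum extremes can only occur immediately after a hit (local
    maxima) or immediately before a hit (local minima), so only 2m points
    per permutation are evaluated.
    """
    B, m = pos_matrix.shape
    pos = np.sort(pos_matrix, axis=1)
    hw = weights[pos]
    totals = hw.sum(axis=1, keepdims=True)
    zero_rows = (totals[:, 0] <= 0)
    if zero_rows.any():
        hw[zero_rows] = 1.0
        totals = hw.sum(axis=1, keepdims=True)
    cum = np.cumsum(hw, axis=1) / totals
    miss = 1.0 / (n_total - m)
    j = np.arange(1, m + 1)
    after = cum - (pos + 1 - j) * miss
    before = np.concatenate([np.zeros((B, 1)), cum[:, :-1]], axis=1) - (pos - (j - 1)) * miss
    cand = np.concatenate([after, before], axis=1)
    idx = np.argmax(np.abs(cand), axis=1)
    return cand[np.arange(B), idx]


def _null_positions(rng: np.random.Generator, n_perm: int, m: int, n_total: int) -> np.ndarray:
    """n_perm random hit-position sets of size m (membership permutation)."""
    u = rng.random((n_perm, n_total))
    return np.argpartition(u, m - 1, axis=1)[:, :m]


def gsea_screen(expr: OmicsMatrix | pd.DataFrame, panel_genes: Sequence[str],
                collection: Mapping[str, Sequence[str]], n_perm: int = 1000,
                seed: int = 0, weight: float = 1.0, min_overlap: int = 5) -> pd.DataFrame:
    """Preranked GSEA of every gene set against each anchor's co-expression ranking.

    Returns one row per (anchor, set); sets overlapping the ranked list in
    fewer than ``min_overlap`` genes are reported with status ``skipped``.
    Permutation draws are seeded per anchor from ``seed``, so results are
    reproducible bit-for-bit.
    """
    values = expr.values if isinstance(expr, OmicsMatrix) else expr
    if values.shape[1] < 10:
        raise InputError("at least 10 samples required")
    if not collection:
        raise InputError("empty gene-set collection")
    rows = []
    for a_i, anchor in enumerate(panel_genes):
        if anchor not in values.index:
            continue
        ranked = rank_by_correlation(values, anchor)
        ranked = ranked[ranked["defined"]]
        genes = ranked["gene"].tolist()
        scores = ranked["rho"].to_numpy(dtype=float)
        n_total = len(genes)
        pos_of = {g: i for i, g in enumerate(genes)}
        weights = np.abs(scores) ** weight
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), a_i]))
        anchor_rows = []
        null_cache: dict[int, np.ndarray] = {}
        for set_name, members in collection.items():
            hit_positions = np.array(sorted(pos_of[g] for g in set(members) if g in pos_of), dtype=int)
            m = len(hit_positions)
            if m < min_overlap or m >= n_total:
                anchor_rows.append({"anchor_gene": anchor, "set_name": set_name, "es": np.nan,
                                    "nes": np.nan, "p_value": np.nan, "n_overlap": m,
                                    "leading_edge": "", "status": "skipped"})
                continue
            es, profile = _es_core(weights, hit_positions, n_total)
            if m not in null_cache:
                null_cache[m] = _null_positions(rng, n_perm, m, n_total)
            null_es = _es_batch(weights, null_cache[m], n_total)
            same_sign = null_es[np.sign(null_es) == np.sign(es)] if es != 0 else null_es
            denom = np.abs(same_sign).mean() if len(same_sign) else np.abs(null_es).mean()
            nes = float(es / denom) if denom > 0 else np.nan
            p = float((1 + np.sum(np.abs(null_es) >= abs(es))) / (n_perm + 1))
            peak = int(np.argmax(np.abs(profile)))
            if es >= 0:
                leading = [genes[i] for i in hit_positions if i <= peak]
            else:
                leading = [genes[i] for i in hit_positions if i >= peak]
            anchor_rows.append({"anchor_gene": anchor, "set_name": set_name, "es": es,
                                "nes": nes, "p_value": p, "n_overlap": m,
                                "leading_edge": ",".join(leading), "status": "ok"})
        sub = pd.DataFrame(anchor_rows)
        tested = sub["status"].eq("ok")
        adj = np.full(len(sub), np.nan)
        if tested.any():
            adj[tested.to_numpy()] = multipletests(sub.loc[tested, "p_value"], method="fdr_bh")[1]
        sub["adjusted_p"] = adj
        rows.append(sub)
    if not rows:
        return pd.DataFrame(columns=GSEA_COLUMNS)
    return pd.concat(rows, ignore_index=True)[GSEA_COLUMNS]
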