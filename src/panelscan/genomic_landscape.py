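"""Somatic mutation and CNV landscape statistics for a gene panel.

The centerpiece is the transmembrane-region (TM) enrichment test: for each
gene with N observed mutations of which k fall inside TM intervals, the
number of TM mutations under the no-enrichment null is Binomial(N, p_ri)
with p_ri = L_TR / L_g (both lengths in amino-acid residues). The reported
p-value is the upper tail P(X >= k), evaluated with the numerically stable
binomial survival function, and the enrichment ratio is

    E = k / (N * L_TR / L_g),

the observed TM mutation count over its null expectation. A gene is called
enriched when E > e_threshold (default 1.3) and p < p_threshold (default
0.05); raw p-values are reported alongside a BH-adjusted column.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import InputError, OmicsMatrix
from .panel import GenePanel

ENRICHMENT_COLUMNS = ["gene", "k", "N", "p_ri", "E", "p_value", "adjusted_p", "enriched", "scored"]


def _positioned(muts: pd.DataFrame) -> pd.DataFrame:
    """Mutations usable for region analyses: a valid protein position."""
    pos = pd.to_numeric(muts["protein_pos"], errors="coerce")
    return muts.loc[pos.notna() & (pos >= 1)]


def mutation_frequency_matrix(muts: pd.DataFrame, cohort_sizes: Mapping[str, int],
                              panel: GenePanel) -> pd.DataFrame:
    """Gene x cancer-type mutation frequency.

    Entry = (# distinct samples of that cancer type with >= 1 mutation in
    the gene) / cohort size; values in [0, 1].
    """
    for ct, n in cohort_sizes.items():
        if n < 1:
            raise InputError(f"cohort size for {ct} must be >= 1")
    out = pd.DataFrame(0.0, index=panel.symbols, columns=list(cohort_sizes))
    if len(muts) == 0:
        return out
    unknown = set(muts["cancer_type"]) - set(cohort_sizes)
    if unknown:
        raise InputError(f"mutations reference cancer types without cohort sizes: {sorted(unknown)}")
    counts = (
        muts[muts["gene"].isin(panel.symbols)]
        .groupby(["gene", "cancer_type"], observed=True)["sample"]
        .nunique()
    )
    for (gene, ct), c in counts.items():
        out.at[gene, ct] = c / cohort_sizes[ct]
    return out


def compute_tmb(muts: pd.DataFrame, samples: Sequence[str]) -> pd.Series:
    """Tumor mutation burden: nonsynonymous mutation count per sample (0 if absent)."""
    nonsyn = muts[muts["variant_class"] == "nonsynonymous"]
    counts = nonsyn.groupby("sample").size()
    return counts.reindex(pd.Index(samples, name="sample"), fill_value=0).astype(int).rename("tmb")


def tm_region_enrichment(muts: pd.DataFrame, panel: GenePanel,
                         e_threshold: float = 1.3, p_threshold: float = 0.05) -> pd.DataFrame:
    """Binomial upper-tail TM-region enrichment per gene (see module docstring).

    Genes with no positioned mutations or with L_TR = 0 are reported with
    ``scored = False``. Splice/intronic records without a protein position
    are excluded here (they still count for frequency and TMB).
    """
    muts = _positioned(muts)
    rows = []
    for sym in panel.symbols:
        L_g = panel.length(sym)
        L_tm = panel.tm_length(sym)
        sub = muts[muts["gene"] == sym]
        N = len(sub)
        if N == 0 or L_tm == 0:
            rows.append({"gene": sym, "k": 0, "N": N, "p_ri": L_tm / L_g, "E": np.nan,
                         "p_value": np.nan, "enriched": False, "scored": False})
            continue
        pos = sub["protein_pos"].astype(int)
        if (pos > L_g).any():
            raise InputError(f"mutation position beyond protein length for {sym}")
        k = int(sum(panel.in_tm(sym, p) for p in pos))
        if k > N:
            raise InputError(f"internal inconsistency: k > N for {sym}")
        p_ri = L_tm / L_g
        p_value = float(stats.binom.sf(k - 1, N, p_ri))  # P(X >= k)
        E = k / (N * p_ri)
        rows.append({"gene": sym, "k": k, "N": N, "p_ri": p_ri, "E": E,
                     "p_value": p_value, "enriched": bool(E > e_threshold and p_value < p_threshold),
                     "scored": True})
    out = pd.DataFrame(rows)
    scored = out["scored"].to_numpy()
    adj = np.full(len(out), np.nan)
    if scored.any():
        adj[scored] = multipletests(out.loc[scored, "p_value"], method="fdr_bh")[1]
    out["adjusted_p"] = adj
    return out[ENRICHMENT_COLUMNS]


def mutation_density_by_region(muts: pd.DataFrame, panel: GenePanel, per_gene: bool = True
                               ) -> dict[str, np.ndarray]:
    """Mutation densities (mutations per residue) in TM vs. other regions.

    ``per_gene=True`` returns one density per gene and region (genes with
    both regions annotated and >= 1 positioned mutation); ``False`` pools
    counts and lengths across genes into a single density per region.
    """
    muts = _positioned(muts)
    tm_d, other_d = [], []
    tm_counts = other_counts = tm_len = other_len = 0
    for sym in panel.symbols:
        L_g, L_tm = panel.length(sym), panel.tm_length(sym)
        sub = muts[muts["gene"] == sym]
        if len(sub) == 0:
            continue
        k = int(sum(panel.in_tm(sym, p) for p in sub["protein_pos"].astype(int)))
        n_other = len(sub) - k
        if per_gene:
            if L_tm > 0 and L_g - L_tm > 0:
                tm_d.append(k / L_tm)
                other_d.append(n_other / (L_g - L_tm))
        else:
            tm_counts += k
            other_counts += n_other
            tm_len += L_tm
            other_len += L_g - L_tm
    if per_gene:
        return {"TM": np.asarray(tm_d, dtype=float), "other": np.asarray(other_d, dtype=float)}
    return {
        "TM": np.array([tm_counts / tm_len]) if tm_len else np.array([]),
        "other": np.array([other_counts / other_len]) if other_len else np.array([]),
    }


def _exact_ranksum_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p by enumerating all group assignments.

    Average ranks handle ties; the p-value is the probability, over all
    C(n, n_x) equally likely assignments of the pooled values to the two
    group sizes, of a rank sum at least as far from its mean as observed.
    """
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n, nx = len(pooled), len(x)
    obs = ranks[:nx].sum()
    mu = nx * (n + 1) / 2.0
    dev = abs(obs - mu) - 1e-9
    hits = total = 0
    for idx in combinations(range(n), nx):
        total += 1
        if abs(ranks[list(idx)].sum() - mu) >= dev:
            hits += 1
    return hits / total


def region_value_compare(values_by_region: Mapping[str, Sequence[float]],
                         exact_max_n: int = 20) -> dict:
    """Compare per-region score distributions (densities or CADD scores).

    Exact enumeration rank-sum for combined n <= ``exact_max_n``; otherwise
    the normal approximation with tie and continuity corrections
    (Mann-Whitney U). Returns the two-sided p, the method used and the
    median difference (TM minus other) as a location-shift summary.
    """
    try:
        x = np.asarray(values_by_region["TM"], dtype=float)
        y = np.asarray(values_by_region["other"], dtype=float)
    except KeyError as exc:
        raise InputError("values_by_region must contain 'TM' and 'other'") from exc
    if len(x) == 0 or len(y) == 0:
        raise InputError("both regions must have at least one value")
    if len(x) + len(y) <= exact_max_n:
        p = _exact_ranksum_pvalue(x, y)
        method = "exact"
        u_stat = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").statistic
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic", use_continuity=True)
        p, u_stat, method = float(res.pvalue), float(res.statistic), "normal_approx"
    return {
        "p_value": float(p),
        "statistic": float(u_stat),
        "method": method,
        "median_shift": float(np.median(x) - np.median(y)),
        "n_tm": int(len(x)),
        "n_other": int(len(y)),
    }


def deleterious_region_association(muts: pd.DataFrame, panel: GenePanel) -> dict:
    """2x2 Fisher test: region (TM / other) vs deleterious-or-damaging status.

    A mutation counts as deleterious/damaging when SIFT labels it
    deleterious OR PolyPhen labels it damaging; records lacking both labels
    (NA) are excluded. The two-sided p comes from the hypergeometric
    enumeration of Fisher's exact test; the odds ratio is the conditional
    maximum-likelihood estimate.
    """
    muts = _positioned(muts)
    muts = muts[muts["gene"].isin(panel.symbols)]
    labeled = muts[(muts["sift"] != "NA") | (muts["polyphen"] != "NA")]
    if len(labeled) == 0:
        raise InputError("no mutation carries a SIFT or PolyPhen label")
    deleterious = (labeled["sift"] == "deleterious") | (labeled["polyphen"] == "damaging")
    in_tm = np.array(
        [panel.in_tm(g, int(p)) for g, p in zip(labeled["gene"], labeled["protein_pos"])]
    )
    table = np.array(
        [
            [int((in_tm & deleterious).sum()), int((in_tm & ~deleterious).sum())],
            [int((~in_tm & deleterious).sum()), int((~in_tm & ~deleterious).sum())],
        ]
    )
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    try:
        cond_or = float(stats.contingency.odds_ratio(table, kind="conditional").statistic)
    except ValueError:
        cond_or = float("nan")
    return {"table": table, "p_value": float(p), "odds_ratio": cond_or, "sample_odds_ratio": float(odds)}


def cnv_frequency_matrix(cnv: OmicsMatrix, panel: GenePanel, high_level_only: bool = False
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gain and loss frequency matrices (gene x cancer type).

    Inclusive mode (default) counts thresholded values {1, 2} as gain and
    {-1, -2} as loss; ``high_level_only`` restricts to |value| = 2.
    """
    vals = cnv.values
    arr = vals.to_numpy()
    if not np.isin(arr, [-2, -1, 0, 1, 2]).all():
        raise InputError("cnv entries must be integers in {-2,-1,0,1,2}")
    cancer = cnv.meta("cancer_type")
    genes = [g for g in panel.symbols if g in vals.index]
    gain_cut, loss_cut = (2, -2) if high_level_only else (1, -1)
    gain = {}
    loss = {}
    for ct, cols in cancer.groupby(cancer).groups.items():
        sub = vals.loc[genes, cols]
        gain[ct] = (sub >= gain_cut).mean(axis=1)
        loss[ct] = (sub <= loss_cut).mean(axis=1)
    return pd.DataFrame(gain), pd.DataFrame(loss)
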