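"""Alteration-status grouping, clinical-feature comparisons and survival analysis.

Survival associations follow the per-gene recipe common to pan-cancer panel
studies: tumors are dichotomized at the expression cutpoint maximizing the
standardized two-group log-rank statistic (a maximally selected rank
statistic; the post-selection p-value is flagged as selection-biased), then
a univariate Cox proportional-hazards model (Efron tie handling, via
lifelines) yields the hazard ratio with Wald 95% CI. Genes with zero
expression in more than half of tumors are skipped. HR > 1 with p < 0.05 is
classified risky; HR < 1 with p < 0.05 protective.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import InputError, OmicsMatrix, SurvivalFit
from .panel import GenePanel

ORDINAL_ORDERS = {
    "stage": ["I", "II", "III", "IV"],
    "grade": ["G1", "G2", "G3", "G4"],
}


def alteration_status(muts: pd.DataFrame, cnv: OmicsMatrix | None, panel: GenePanel,
                      patients: Sequence[str], cnv_mode: str = "high") -> pd.Series:
    """Patient -> altered/unaltered for the panel.

    Default criterion (cBioPortal-style): altered iff the patient carries a
    nonsynonymous mutation in any panel gene OR a high-level CNV event
    (|value| = 2) in any panel gene. ``cnv_mode='any'`` widens the CNV
    criterion to |value| >= 1.
    """
    patients = pd.Index(patients)
    if len(patients) == 0:
        raise InputError("empty patient universe")
    if cnv_mode not in ("high", "any"):
        raise InputError(f"unknown cnv_mode {cnv_mode!r}")
    altered = pd.Series(False, index=patients)
    if len(muts):
        hits = muts[(muts["variant_class"] == "nonsynonymous") & muts["gene"].isin(panel.symbols)]
        altered[altered.index.intersection(hits["sample"].unique())] = True
    if cnv is not None:
        genes = [g for g in panel.symbols if g in cnv.values.index]
        cut = 2 if cnv_mode == "high" else 1
        hit_cols = cnv.values.loc[genes].abs().ge(cut).any(axis=0)
        hit_samples = hit_cols.index[hit_cols]
        altered[altered.index.intersection(hit_samples)] = True
    return altered.rename("altered")


def compare_clinical_features(clinical: pd.DataFrame, status: pd.Series,
                              features: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-feature altered-vs-unaltered tests with BH adjustment across features.

    Categorical features use the chi-square test, or Fisher's exact test
    when a 2x2 table has an expected cell below 5; continuous and ordinal
    features use the two-sided Wilcoxon rank-sum test (ordinals on their
    category codes). Entirely missing features are reported as untested.
    """
    status = status.reindex(clinical.index)
    if status.isna().any():
        raise InputError("alteration status missing for some patients")
    groups = status.astype(bool)
    if groups.all() or (~groups).all():
        raise InputError("both altered and unaltered groups must be nonempty")
    if features is None:
        features = ["sex", "ethnicity", "weight", "hypoxia_score", "tmb", "stage", "grade"]
    rows = []
    for feat in features:
        if feat not in clinical.columns or clinical[feat].isna().all():
            rows.append({"feature": feat, "kind": "missing", "test": "untested",
                         "statistic": np.nan, "p_value": np.nan})
            continue
        col = clinical[feat]
        if feat in ORDINAL_ORDERS:
            codes = pd.Categorical(col, categories=ORDINAL_ORDERS[feat], ordered=True).codes.astype(float)
            codes[codes < 0] = np.nan
            x, y = codes[groups.to_numpy()], codes[~groups.to_numpy()]
            x, y = x[~np.isnan(x)], y[~np.isnan(y)]
            res = stats.mannwhitneyu(x, y, alternative="two-sided")
            rows.append({"feature": feat, "kind": "ordinal", "test": "ranksum",
                         "statistic": float(res.statistic), "p_value": float(res.pvalue)})
        elif pd.api.types.is_numeric_dtype(col):
            x = col[groups].dropna().to_numpy(dtype=float)
            y = col[~groups].dropna().to_numpy(dtype=float)
            res = stats.mannwhitneyu(x, y, alternative="two-sided")
            rows.append({"feature": feat, "kind": "continuous", "test": "ranksum",
                         "statistic": float(res.statistic), "p_value": float(res.pvalue)})
        else:
            table = pd.crosstab(col, groups)
            expected = stats.contingency.expected_freq(table.to_numpy())
            if table.shape == (2, 2) and (expected < 5).any():
                _, p = stats.fisher_exact(table.to_numpy())
                rows.append({"feature": feat, "kind": "categorical", "test": "fisher",
                             "statistic": np.nan, "p_value": float(p)})
            else:
                chi2, p, _, _ = stats.chi2_contingency(table.to_numpy())
                rows.append({"feature": feat, "kind": "categorical", "test": "chi2",
                             "statistic": float(chi2), "p_value": float(p)})
    out = pd.DataFrame(rows)
    tested = out["p_value"].notna()
    adj = np.full(len(out), np.nan)
    if tested.any():
        adj[tested] = multipletests(out.loc[tested, "p_value"], method="fdr_bh")[1]
    out["adjusted_p"] = adj
    return out


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

def _logrank_chi2(times: np.ndarray, events: np.ndarray, in_group1: np.ndarray) -> float:
    """Two-group log-rank chi-square via observed-minus-expected tabulation."""
    order = np.argsort(times, kind="mergesort")
    t, e, g = times[order], events[order].astype(bool), in_group1[order].astype(bool)
    n = len(t)
    event_times = np.unique(t[e])
    o_minus_e = 0.0
    var = 0.0
    # counts at risk just before each event time
    for et in event_times:
        at_risk = t >= et
        n_tot = int(at_risk.sum())
        n1 = int((at_risk & g).sum())
        d = int((e & (t == et)).sum())
        d1 = int((e & (t == et) & g).sum())
        if n_tot <= 1:
            continue
        exp1 = d * n1 / n_tot
        v = d * (n1 / n_tot) * (1 - n1 / n_tot) * (n_tot - d) / (n_tot - 1)
        o_minus_e += d1 - exp1
        var += v
    if var <= 0:
        return 0.0
    return float(o_minus_e**2 / var)


def logrank_test(times: Sequence[float], events: Sequence[int], groups: Sequence) -> tuple[float, float]:
    """Standard two-group log-rank test; returns (chi2, p) on 1 df."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise InputError(f"exactly 2 groups required, got {len(labels)}")
    if events.sum() == 0:
        raise InputError("no events observed; log-rank test undefined")
    chi2 = _logrank_chi2(times, events, groups == labels[0])
    return chi2, float(stats.chi2.sf(chi2, df=1))


def optimal_cutpoint(expression_values: Sequence[float], times: Sequence[float],
                     events: Sequence[int], minprop: float = 0.1) -> dict:
    """Maximally selected log-rank cutpoint over all order-statistic midpoints.

    Scans every midpoint between consecutive distinct expression values that
    leaves at least ``minprop`` of patients in each group, and returns the
    cutpoint maximizing the standardized log-rank statistic. Ties keep the
    lowest cutpoint. The associated p-value is selection-biased (flagged).
    """
    x = np.asarray(expression_values, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n = len(x)
    if n < 10:
        raise InputError("at least 10 patients required for cutpoint selection")
    if np.unique(x).size < 2:
        raise InputError("expression constant across patients")
    if events.sum() == 0:
        raise InputError("no events observed")
    distinct = np.unique(x)
    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    min_count = int(np.ceil(minprop * n))
    best = None
    for c in candidates:
        high = x > c
        if high.sum() < min_count or (~high).sum() < min_count:
            continue
        stat = np.sqrt(_logrank_chi2(times, events, high))
        if best is None or stat > best[1] + 1e-12:
            best = (c, stat)
    if best is None:
        raise InputError("no cutpoint satisfies the minprop constraint")
    cut, stat = best
    return {
        "cutpoint": float(cut),
        "statistic": float(stat),
        "groups": pd.Series(np.where(x > cut, "high", "low")),
        "selection_biased_p": True,
    }


def hazard_ratio(expression_or_group, times: Sequence[float], events: Sequence[int],
                 label: str = "gene", zero_fraction_limit: float = 0.5,
                 minprop: float = 0.1, alpha: float = 0.05) -> SurvivalFit:
    """Univariate Cox PH fit (Efron ties) on a dichotomized expression profile.

    Continuous input is first checked against the zero-expression filter
    (more than ``zero_fraction_limit`` zeros -> skipped), then dichotomized
    at the optimal log-rank cutpoint. Two-level group input is used as-is.
    The fit is by Newton iteration on the Cox partial likelihood (lifelines);
    non-convergence returns a flagged fit rather than raising.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    x = np.asarray(expression_or_group)
    cutpoint = None
    biased = False
    if np.issubdtype(x.dtype, np.number) and len(pd.unique(x)) > 2:
        zero_frac = float((x == 0).mean())
        if zero_frac > zero_fraction_limit:
            return SurvivalFit(label=label, skipped="zero-expression filter")
        try:
            cp = optimal_cutpoint(x, times, events, minprop=minprop)
        except InputError as exc:
            return SurvivalFit(label=label, skipped=str(exc))
        indicator = (x > cp["cutpoint"]).astype(float)
        cutpoint = cp["cutpoint"]
        biased = True
    else:
        labels = pd.unique(x)
        if len(labels) != 2:
            return SurvivalFit(label=label, skipped="grouping is not two-level")
        # HR is the exposure group's hazard relative to the reference group;
        # exposure = True/1 for indicator input, else 'altered'/'high' (which
        # sort first as strings)
        if set(labels) <= {True, False, 0, 1}:
            exposure = max(labels)
        else:
            exposure = sorted(labels, key=str)[0]
        indicator = (x == exposure).astype(float)
    for grp in (0.0, 1.0):
        if events[indicator == grp].sum() < 1:
            return SurvivalFit(label=label, skipped="a group has no events")
    df = pd.DataFrame({"t": times, "e": events, "x": indicator})
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="t", event_col="e")
    except ConvergenceError:
        return SurvivalFit(label=label, converged=False, skipped=None,
                           cutpoint=cutpoint, classification="ns")
    coef = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    p = float(cph.summary.loc["x", "p"])
    z = stats.norm.ppf(1 - alpha / 2)
    hr = float(np.exp(coef))
    chi2, _ = logrank_test(times, events, indicator)
    classification = "risky" if (hr > 1 and p < alpha) else ("protective" if (hr < 1 and p < alpha) else "ns")
    return SurvivalFit(
        label=label,
        hr=hr,
        ci_low=float(np.exp(coef - z * se)),
        ci_high=float(np.exp(coef + z * se)),
        logrank_chi2=chi2,
        p_value=p,
        cutpoint=cutpoint,
        classification=classification,
        selection_biased_p=biased,
    )


def survival_screen(expr: OmicsMatrix, clinical: pd.DataFrame, genes: Sequence[str] | None = None,
                    time_col: str = "os_time", event_col: str = "os_event",
                    zero_fraction_limit: float = 0.5, minprop: float = 0.1) -> pd.DataFrame:
    """Per-gene survival fits over the tumors shared with the clinical table."""
    meta = expr.col_meta
    tumor_cols = expr.samples if meta is None else meta.index[meta["is_tumor"].astype(bool)]
    shared = pd.Index(tumor_cols).intersection(clinical.index)
    if len(shared) == 0:
        raise InputError("no shared patients between expression and clinical tables")
    times = clinical.loc[shared, time_col].to_numpy(dtype=float)
    events = clinical.loc[shared, event_col].to_numpy(dtype=int)
    genes = list(expr.features) if genes is None else [g for g in genes if g in expr.values.index]
    fits = []
    for g in genes:
        fit = hazard_ratio(expr.values.loc[g, shared].to_numpy(dtype=float), times, events,
                           label=g, zero_fraction_limit=zero_fraction_limit, minprop=minprop)
        fits.append(fit.as_dict())
    out = pd.DataFrame(fits)
    tested = out["skipped"].eq("") & out["p_value"].notna()
    adj = np.full(len(out), np.nan)
    if tested.any():
        adj[tested] = multipletests(out.loc[tested, "p_value"], method="fdr_bh")[1]
    out["adjusted_p"] = adj
    return out
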