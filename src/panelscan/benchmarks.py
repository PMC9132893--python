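"""Planted-truth recovery studies on synthetic cohorts.

Each function generates a cohort whose ground truth is known, runs the
corresponding analysis, and reports recovery metrics (sensitivity,
false-discovery proportion, estimation error, calibration). They are used
by both the test suite and the acceptance script; the study conditions
(sample sizes, effect sizes, rates) are fixed by the generator defaults and
stated in docs/methods.md.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import clinical_relevance as cr
from . import expression_analysis as ea
from . import genomic_landscape as gl
from . import pathway_enrichment as pe
from . import pharmacogenomics as ph
from .containers import OmicsMatrix
from .synthetic_data import (
    CoexpressionModule,
    SimulationConfig,
    gen_drug_response,
    gen_expression_cohort,
    gen_gene_panel,
    gen_mutation_table,
)


def tm_enrichment_recovery(seed: int = 0, n_genes: int = 200, n_enriched: int = 20,
                           multiplier: float = 3.0, mutation_rate: float = 0.05) -> dict:
    """Recovery of planted TM-enriched genes (default: 20/200 at x3, ~50 mut/gene)."""
    genes = [f"G{i:04d}" for i in range(1, n_genes + 1)]
    config = SimulationConfig(
        seed=seed, n_genes=n_genes, background_mutation_rate=mutation_rate,
        tm_enrichment_genes={g: multiplier for g in genes[:n_enriched]},
    )
    panel = gen_gene_panel(config)
    muts = gen_mutation_table(panel, config)
    res = gl.tm_region_enrichment(muts, panel)
    called = set(res.loc[res["enriched"], "gene"])
    truth = set(genes[:n_enriched])
    tp = len(called & truth)
    fp = len(called - truth)
    return {
        "sensitivity": tp / len(truth),
        "fdp": fp / max(1, len(called)),
        "n_called": len(called),
        "n_genes": n_genes,
        "mean_mutations_per_gene": float(res["N"].mean()),
    }


def de_recovery(seed: int = 0, n_tumor: int = 50, n_normal: int = 50, effect: float = 2.0,
                n_de: int = 20) -> dict:
    """Sensitivity/specificity of the DE rule on one planted cohort plus a null cohort."""
    genes = [f"G{i:04d}" for i in range(1, 201)]
    de = {g: effect for g in genes[:n_de // 2]}
    de.update({g: -effect for g in genes[n_de // 2:n_de]})
    config = SimulationConfig(seed=seed, n_genes=200, n_cancer_types=1,
                              n_tumor=n_tumor, n_normal=n_normal, de_genes=de)
    panel = gen_gene_panel(config)
    expr = gen_expression_cohort(panel, config)
    res = ea.differential_expression(expr, "C1")
    res = res[res["gene"] != config.proliferation_marker]
    truth_up = set(genes[:n_de // 2])
    truth_dn = set(genes[n_de // 2:n_de])
    called_up = set(res.loc[res["direction"] == "up", "gene"])
    called_dn = set(res.loc[res["direction"] == "down", "gene"])
    tp = len(called_up & truth_up) + len(called_dn & truth_dn)
    flagged = res["direction"].ne("ns")
    null_genes = ~res["gene"].isin(truth_up | truth_dn)
    fp = int((flagged & null_genes).sum())

    null_config = SimulationConfig(seed=seed + 1, n_genes=200, n_cancer_types=1,
                                   n_tumor=n_tumor, n_normal=n_normal, de_genes={})
    null_expr = gen_expression_cohort(gen_gene_panel(null_config), null_config)
    null_res = ea.differential_expression(null_expr, "C1")
    return {
        "sensitivity": tp / n_de,
        "specificity": 1 - fp / int(null_genes.sum()),
        "null_flag_rate": float(null_res["direction"].ne("ns").mean()),
        "n_tumor": n_tumor,
        "n_normal": n_normal,
    }


def survival_recovery(seed: int = 0, n_per_arm: int = 200, true_hr: float = 2.0,
                      n_seeds: int = 30) -> dict:
    """Median estimated HR and log-rank power over seeded exponential two-arm cohorts."""
    hrs, logrank_sig = [], []
    for rep in range(n_seeds):
        config = SimulationConfig(seed=seed + rep, hazard_multiplier_altered=true_hr)
        patients = pd.Index([f"P{i:04d}" for i in range(1, 2 * n_per_arm + 1)])
        status = pd.Series([True] * n_per_arm + [False] * n_per_arm, index=patients)
        from .synthetic_data import gen_clinical

        clin = gen_clinical(patients, status, config)
        fit = cr.hazard_ratio(np.where(status, "altered", "unaltered"),
                              clin["os_time"], clin["os_event"], label="arm")
        hrs.append(fit.hr)
        _, p = cr.logrank_test(clin["os_time"], clin["os_event"], status)
        logrank_sig.append(p < 0.01)
    return {
        "median_hr": float(np.median(hrs)),
        "logrank_power": float(np.mean(logrank_sig)),
        "n_per_arm": n_per_arm,
        "n_seeds": n_seeds,
    }


def cutpoint_oracle_agreement(seed: int = 0, n_instances: int = 5, n: int = 120) -> float:
    """Fraction of random instances where the scan matches a brute-force oracle.

    The oracle evaluates the log-rank statistic at every admissible midpoint
    with lifelines and takes the argmax, independently of the package's scan.
    """
    from lifelines.statistics import logrank_test as ll_logrank

    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_instances):
        x = rng.normal(size=n)
        risk = np.exp(0.5 * (x > 0))
        t = rng.exponential(1.0 / risk)
        c = rng.uniform(0, 3, size=n)
        times = np.minimum(t, c)
        events = (t <= c).astype(int)
        got = cr.optimal_cutpoint(x, times, events, minprop=0.1)["cutpoint"]
        distinct = np.unique(x)
        best = None
        min_count = int(np.ceil(0.1 * n))
        for cand in (distinct[:-1] + distinct[1:]) / 2:
            high = x > cand
            if high.sum() < min_count or (~high).sum() < min_count:
                continue
            res = ll_logrank(times[high], times[~high], events[high], events[~high])
            stat = np.sqrt(res.test_statistic)
            if best is None or stat > best[1] + 1e-12:
                best = (cand, stat)
        agree += int(np.isclose(got, best[0]))
    return agree / n_instances


def gsea_planted_module_recovery(seed: int = 0, module_size: int = 30, loading: float = 0.8,
                                 n_perm: int = 999) -> dict:
    """Adjusted p of the planted co-expression module set at its anchor."""
    genes = [f"G{i:04d}" for i in range(1, 301)]
    module = CoexpressionModule(name="PLANTED", anchor=genes[0],
                                members=genes[1:module_size + 1], loading=loading)
    config = SimulationConfig(seed=seed, n_genes=300, n_cancer_types=1,
                              n_tumor=100, n_normal=10, modules=[module])
    panel = gen_gene_panel(config)
    expr = gen_expression_cohort(panel, config)
    tumor_cols = expr.col_meta.index[expr.col_meta["is_tumor"]]
    rng = np.random.default_rng(seed)
    collection = {"PLANTED": module.members}
    universe = np.array(genes[module_size + 1:])
    for i in range(1, 20):
        collection[f"RANDOM_{i:02d}"] = list(rng.choice(universe, size=module_size, replace=False))
    res = pe.gsea_screen(expr.values[tumor_cols], [genes[0]], collection,
                         n_perm=n_perm, seed=seed)
    row = res[res["set_name"] == "PLANTED"].iloc[0]
    return {"adjusted_p": float(row["adjusted_p"]), "nes": float(row["nes"]),
            "es": float(row["es"]), "n_perm": n_perm}


def gsea_null_calibration(seed: int = 0, n_anchors: int = 8, n_sets: int = 100,
                          n_genes: int = 300, n_samples: int = 80, n_perm: int = 999,
                          alpha: float = 0.05) -> dict:
    """Fraction of null (anchor, set) pairs with permutation p below alpha.

    Expression is unstructured noise and sets are random, so raw p-values
    should be uniform; the flag rate should sit near alpha.
    """
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(1, n_genes + 1)]
    expr = pd.DataFrame(rng.normal(size=(n_genes, n_samples)), index=genes,
                        columns=[f"S{i:03d}" for i in range(n_samples)])
    collection = {}
    for i in range(n_sets):
        size = int(rng.integers(10, 41))
        collection[f"NULL_{i:03d}"] = list(rng.choice(genes, size=size, replace=False))
    res = pe.gsea_screen(expr, genes[:n_anchors], collection, n_perm=n_perm, seed=seed)
    ok = res[res["status"] == "ok"]
    return {"flag_rate": float((ok["p_value"] < alpha).mean()), "n_tests": len(ok),
            "n_perm": n_perm}


def pharmaco_recovery(seed: int = 0, n_cell_lines: int = 300, rho: float = 0.6,
                      n_pairs: int = 10) -> dict:
    """Recovery of planted gene-drug correlations through the full screen."""
    genes = [f"G{i:04d}" for i in range(1, 101)]
    pairs = [(genes[i], f"D{i + 1:03d}", rho) for i in range(n_pairs)]
    config = SimulationConfig(seed=seed, n_genes=100, n_cell_lines=n_cell_lines,
                              n_drugs=40, planted_drug_pairs=pairs, missing_fraction=0.10)
    panel = gen_gene_panel(config)
    ic50, cl_expr = gen_drug_response(panel, config)
    complete, removed = ph.prepare_ic50(ic50)
    screen = ph.correlation_screen(cl_expr.values.loc[genes], complete, scc_threshold=0.15)
    truth = {(g, d) for g, d, _ in pairs}
    sig = screen[screen["significant"]]
    called = set(zip(sig["left_id"], sig["right_id"]))
    tp = len(called & truth)
    null_tested = screen[~screen.apply(lambda r: (r["left_id"], r["right_id"]) in truth, axis=1)]
    fp_rate = float(null_tested["significant"].mean())
    return {
        "sensitivity": tp / n_pairs,
        "false_positive_rate": fp_rate,
        "n_removed_drugs": len(removed),
        "n_cell_lines": n_cell_lines,
    }


def knn_imputation_benchmark(seed: int = 0, missing_fraction: float = 0.10) -> dict:
    """KNN vs column-mean imputation RMSE on a complete synthetic IC50 matrix."""
    config = SimulationConfig(seed=seed, n_genes=50, n_drugs=40, n_cell_lines=200,
                              missing_fraction=0.0)
    panel = gen_gene_panel(config)
    ic50, _ = gen_drug_response(panel, config)
    return ph.knn_vs_column_mean_rmse(ic50.values, missing_fraction=missing_fraction, seed=seed)
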