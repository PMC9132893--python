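"""End-to-end pipeline: landscape -> expression -> clinical -> pathways -> pharmaco.

Each stage reads its input tables, runs the corresponding module and writes
result TSVs into ``outdir``. Stages whose inputs are absent are skipped and
logged; a malformed input fails its stage (and the stages depending on it)
while independent stages still run. A run manifest records the config hash,
seed, package version and every threshold actually applied, so a run is
reconstructible from its manifest. No timestamps are written, so two runs
with identical config and seed produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import InputError, PanelscanError
from .io import read_clinical, read_matrix, read_mutations, write_table
from .panel import GenePanel

logger = logging.getLogger("panelscan")

_CONVENTIONS = "coordinates 1-based inclusive; frequencies in [0,1]; p-values two-sided; BH-adjusted columns named adjusted_p"


@dataclass
class PipelineConfig:
    """Input paths, thresholds and seed for one pipeline run."""

    outdir: str = "panelscan_out"
    seed: int = 0
    # input paths (None -> stage skipped)
    mutations: str | None = None
    cnv: str | None = None
    expression: str | None = None
    sample_meta: str | None = None
    clinical: str | None = None
    gene_sets: str | None = None
    ic50: str | None = None
    cell_line_expression: str | None = None
    actionable_genes: str | None = None
    panel: str | None = None
    tm_intervals: str | None = None
    # thresholds
    e_threshold: float = 1.3
    p_threshold: float = 0.05
    min_normals: int = 5
    lfc_threshold: float = 1.0
    alpha: float = 0.05
    minprop: float = 0.1
    zero_fraction_limit: float = 0.5
    na_limit: float = 0.30
    knn_k: int = 5
    knn_rowmax: float = 0.5
    knn_colmax: float = 0.8
    knn_maxp: int = 1500
    knn_seed: int = 362436069
    scc_threshold_drug: float = 0.15
    scc_threshold_actionable: float = 0.2
    gsea_n_perm: int = 200
    gsea_min_overlap: int = 5
    panel_genes: list[str] = field(default_factory=list)
    cnv_mode: str = "high"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        canon = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def validate(self) -> None:
        for name in ("mutations", "cnv", "expression", "sample_meta", "clinical",
                     "gene_sets", "ic50", "cell_line_expression", "actionable_genes",
                     "panel", "tm_intervals"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise InputError(f"configured input {name} does not exist: {p}")
        if not (0 < self.minprop < 0.5):
            raise InputError("minprop must be in (0, 0.5)")
        if not (0 <= self.na_limit < 1):
            raise InputError("na_limit must be in [0, 1)")


def _load_panel(config: PipelineConfig) -> GenePanel:
    if config.panel is None:
        raise InputError("panel path is required")
    return GenePanel.from_tables(config.panel, config.tm_intervals)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns a report dict {stage: status, outputs: {...}}."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "outputs": {}, "thresholds": {}}

    panel = _load_panel(config)
    panel_genes = config.panel_genes or panel.symbols

    def _done(stage: str, outputs: dict[str, Path]) -> None:
        report["stages"][stage] = "ok"
        report["outputs"].update({k: str(v) for k, v in outputs.items()})
        logger.info("stage %s complete (%d tables)", stage, len(outputs))

    def _skip(stage: str, why: str) -> None:
        report["stages"][stage] = f"skipped: {why}"
        logger.info("stage %s skipped: %s", stage, why)

    def _fail(stage: str, exc: Exception) -> None:
        report["stages"][stage] = f"error: {exc}"
        logger.error("stage %s failed: %s", stage, exc)

    # ---------------- landscape ----------------
    muts = None
    if config.mutations is None:
        _skip("landscape", "no mutation table configured")
    else:
        try:
            from . import genomic_landscape as gl

            muts = read_mutations(config.mutations)
            outputs = {}
            meta = pd.read_csv(config.sample_meta, sep="\t", comment="#", index_col=0) if config.sample_meta else None
            if meta is not None:
                tumors = meta[meta["is_tumor"].astype(bool)]
                cohort_sizes = tumors.groupby("cancer_type").size().to_dict()
                freq = gl.mutation_frequency_matrix(muts, cohort_sizes, panel)
                outputs["mutation_frequency"] = write_table(
                    freq, outdir / "mutation_frequency.tsv", _CONVENTIONS, index=True, index_label="gene")
                tmb = gl.compute_tmb(muts, tumors.index)
                outputs["tmb"] = write_table(tmb.reset_index(), outdir / "tmb.tsv",
                                             "TMB = nonsynonymous mutation count per sample")
            enr = gl.tm_region_enrichment(muts, panel, e_threshold=config.e_threshold,
                                          p_threshold=config.p_threshold)
            outputs["tm_enrichment"] = write_table(
                enr, outdir / "tm_enrichment.tsv",
                f"{_CONVENTIONS}; enriched iff E > {config.e_threshold} and p < {config.p_threshold}")
            dens = gl.mutation_density_by_region(muts, panel, per_gene=True)
            if len(dens["TM"]) and len(dens["other"]):
                cmp_density = gl.region_value_compare(dens)
                tm_mask = np.array([panel.in_tm(g, int(p)) for g, p in
                                    zip(muts["gene"], pd.to_numeric(muts["protein_pos"], errors="coerce").fillna(-1))])
                cadd = {"TM": muts.loc[tm_mask, "cadd"].dropna().to_numpy(),
                        "other": muts.loc[~tm_mask, "cadd"].dropna().to_numpy()}
                cmp_cadd = gl.region_value_compare(cadd) if len(cadd["TM"]) and len(cadd["other"]) else None
                fisher = gl.deleterious_region_association(muts, panel)
                summary = pd.DataFrame([
                    {"comparison": "mutation_density", **{k: v for k, v in cmp_density.items()}},
                    *([{"comparison": "cadd_scores", **{k: v for k, v in cmp_cadd.items()}}] if cmp_cadd else []),
                    {"comparison": "deleterious_fraction_fisher", "p_value": fisher["p_value"],
                     "statistic": fisher["odds_ratio"], "method": "fisher_exact",
                     "median_shift": np.nan, "n_tm": int(fisher["table"][0].sum()),
                     "n_other": int(fisher["table"][1].sum())},
                ])
                outputs["region_comparisons"] = write_table(
                    summary, outdir / "region_comparisons.tsv", _CONVENTIONS)
            if config.cnv is not None:
                cnv = read_matrix(config.cnv, role="cnv", meta_path=config.sample_meta)
                gain, loss = gl.cnv_frequency_matrix(cnv, panel)
                outputs["cnv_gain_frequency"] = write_table(
                    gain, outdir / "cnv_gain_frequency.tsv", _CONVENTIONS, index=True, index_label="gene")
                outputs["cnv_loss_frequency"] = write_table(
                    loss, outdir / "cnv_loss_frequency.tsv", _CONVENTIONS, index=True, index_label="gene")
            _done("landscape", outputs)
        except PanelscanError as exc:
            _fail("landscape", exc)

    # ---------------- expression ----------------
    expr = None
    if config.expression is None or config.sample_meta is None:
        _skip("expression", "expression matrix or sample metadata not configured")
    else:
        try:
            from . import expression_analysis as ea

            expr = read_matrix(config.expression, role="expression", meta_path=config.sample_meta)
            de, skipped = ea.differential_expression_all(
                expr, min_normals=config.min_normals, lfc_threshold=config.lfc_threshold,
                alpha=config.alpha)
            outputs = {"differential_expression": write_table(
                de, outdir / "differential_expression.tsv",
                f"{_CONVENTIONS}; up iff log2FC > {config.lfc_threshold} and adjusted_p < {config.alpha}")}
            if skipped:
                outputs["de_skipped_cohorts"] = write_table(
                    pd.DataFrame(skipped), outdir / "de_skipped_cohorts.tsv", _CONVENTIONS)
            tissue_means = ea.tissue_mean_matrix(expr)
            if tissue_means.shape[1] >= 3:
                classes = ea.tissue_specificity_classify(tissue_means)
                outputs["tissue_specificity"] = write_table(
                    classes.rename_axis("gene").reset_index(), outdir / "tissue_specificity.tsv",
                    "HPA-style classes at 4x threshold, groups of 2-7 tissues")
            _done("expression", outputs)
        except PanelscanError as exc:
            _fail("expression", exc)
            expr = None

    # ---------------- clinical ----------------
    if config.clinical is None:
        _skip("clinical", "no clinical table configured")
    else:
        try:
            from . import clinical_relevance as cr

            clinical = read_clinical(config.clinical)
            outputs = {}
            if muts is not None:
                cnv_m = read_matrix(config.cnv, role="cnv", meta_path=config.sample_meta) if config.cnv else None
                status = cr.alteration_status(muts, cnv_m, panel.subset([g for g in panel_genes if g in panel]),
                                              patients=clinical.index, cnv_mode=config.cnv_mode)
                if status.any() and not status.all():
                    features = cr.compare_clinical_features(clinical, status)
                    outputs["clinical_features"] = write_table(
                        features, outdir / "clinical_features.tsv", _CONVENTIONS)
                    chi2, p = cr.logrank_test(clinical["os_time"], clinical["os_event"], status)
                    group_fit = cr.hazard_ratio(status.map({True: "altered", False: "unaltered"}).to_numpy(),
                                                clinical["os_time"], clinical["os_event"],
                                                label="panel_alteration")
                    km = pd.DataFrame([{**group_fit.as_dict(), "logrank_chi2": chi2, "logrank_p": p}])
                    outputs["alteration_survival"] = write_table(
                        km, outdir / "alteration_survival.tsv", _CONVENTIONS)
            if expr is not None:
                fits = cr.survival_screen(
                    expr, clinical, genes=[g for g in panel_genes if g in expr.values.index],
                    zero_fraction_limit=config.zero_fraction_limit, minprop=config.minprop)
                outputs["survival_fits"] = write_table(
                    fits, outdir / "survival_fits.tsv",
                    f"{_CONVENTIONS}; risky iff HR > 1 and p < {config.alpha}; cutpoint p-values are selection-biased")
            _done("clinical", outputs)
        except PanelscanError as exc:
            _fail("clinical", exc)

    # ---------------- pathways ----------------
    if config.gene_sets is None or expr is None:
        _skip("pathways", "gene sets or expression unavailable")
    else:
        try:
            from . import pathway_enrichment as pe

            collection = pe.read_gmt(config.gene_sets)
            tumor_cols = expr.col_meta.index[expr.col_meta["is_tumor"].astype(bool)]
            tumor_expr = expr.values[tumor_cols]
            anchors = [g for g in panel_genes if g in tumor_expr.index]
            gsea = pe.gsea_screen(tumor_expr, anchors, collection, n_perm=config.gsea_n_perm,
                                  seed=config.seed, min_overlap=config.gsea_min_overlap)
            outputs = {"gsea": write_table(
                gsea, outdir / "gsea.tsv",
                f"{_CONVENTIONS}; NES sign-matched normalization; permutation p floor 1/(n_perm+1), n_perm={config.gsea_n_perm}")}
            _done("pathways", outputs)
        except PanelscanError as exc:
            _fail("pathways", exc)

    # ---------------- pharmacogenomics ----------------
    if config.ic50 is None or config.cell_line_expression is None:
        _skip("pharmaco", "IC50 or cell-line expression not configured")
    else:
        try:
            from . import pharmacogenomics as ph

            ic50 = read_matrix(config.ic50, role="ic50")
            cl_expr = read_matrix(config.cell_line_expression, role="expression")
            complete, removal_log = ph.prepare_ic50(
                ic50, na_limit=config.na_limit, k=config.knn_k, rowmax=config.knn_rowmax,
                colmax=config.knn_colmax, maxp=config.knn_maxp, seed=config.knn_seed)
            outputs = {}
            if len(removal_log):
                outputs["ic50_removed_drugs"] = write_table(
                    removal_log, outdir / "ic50_removed_drugs.tsv", _CONVENTIONS)
            panel_expr = cl_expr.values.loc[[g for g in panel_genes if g in cl_expr.values.index]]
            drug_screen = ph.correlation_screen(panel_expr, complete,
                                                scc_threshold=config.scc_threshold_drug, alpha=config.alpha)
            outputs["drug_correlations"] = write_table(
                drug_screen, outdir / "drug_correlations.tsv",
                f"{_CONVENTIONS}; significant iff |SCC| > {config.scc_threshold_drug} and adjusted_p < {config.alpha}")
            if config.actionable_genes is not None:
                actionable = pd.read_csv(config.actionable_genes, sep="\t", comment="#")["gene"].tolist()
                act_expr = cl_expr.values.loc[[g for g in actionable if g in cl_expr.values.index]]
                if len(act_expr):
                    act_screen = ph.correlation_screen(panel_expr, act_expr,
                                                       scc_threshold=config.scc_threshold_actionable,
                                                       alpha=config.alpha)
                    outputs["actionable_correlations"] = write_table(
                        act_screen, outdir / "actionable_correlations.tsv",
                        f"{_CONVENTIONS}; significant iff |SCC| > {config.scc_threshold_actionable} and adjusted_p < {config.alpha}")
            _done("pharmaco", outputs)
        except PanelscanError as exc:
            _fail("pharmaco", exc)

    # ---------------- manifest ----------------
    report["thresholds"] = {
        "e_threshold": config.e_threshold, "p_threshold": config.p_threshold,
        "min_normals": config.min_normals, "lfc_threshold": config.lfc_threshold,
        "alpha": config.alpha, "minprop": config.minprop,
        "zero_fraction_limit": config.zero_fraction_limit, "na_limit": config.na_limit,
        "knn": {"k": config.knn_k, "rowmax": config.knn_rowmax, "colmax": config.knn_colmax,
                "maxp": config.knn_maxp, "seed": config.knn_seed},
        "scc_threshold_drug": config.scc_threshold_drug,
        "scc_threshold_actionable": config.scc_threshold_actionable,
        "gsea_n_perm": config.gsea_n_perm,
    }
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "stages": report["stages"],
        "thresholds": report["thresholds"],
        "outputs": sorted(Path(p).name for p in report["outputs"].values()),
    }
    (outdir / "run_manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    report["manifest"] = str(outdir / "run_manifest.yaml")
    return report
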