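"""Synthetic pan-cancer cohorts with the statistical structure the pipeline assumes.

Every generator draws from its own pseudo-random stream, seeded from
``SimulationConfig.seed`` plus an op-specific offset, so adding one generator
never perturbs another's draws and the same config is byte-reproducible.

What is emulated
----------------
* per-gene somatic mutation counts (Poisson at a configurable per-residue
  rate) with optional rate multipliers inside transmembrane intervals;
* GISTIC-thresholded CNV calls in {-2,-1,0,1,2} at configured gain/loss
  probabilities;
* log-normal FPKM expression with planted tumor/normal log2 effects,
  latent-factor co-expression modules and a proliferation marker;
* exponential survival with a hazard multiplier for genetically altered
  patients, plus shifted hypoxia/TMB/stage/grade distributions;
* drug IC50 across cell lines with planted gene-drug Spearman correlations
  (Gaussian copula) and MCAR missingness.

All planted parameters are recorded in a :class:`~panelscan.containers.Manifest`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ConfigurationError, InputError, Manifest, OmicsMatrix
from .panel import GenePanel, trp_channel_panel

# op-specific seed offsets (fixed; see module docstring)
_OFF_PANEL = 11
_OFF_MUT = 23
_OFF_CNV = 37
_OFF_EXPR = 53
_OFF_CLIN = 71
_OFF_DRUG = 97
_OFF_SETS = 113


@dataclass
class CoexpressionModule:
    """A gene set sharing one latent factor with an anchor gene."""

    name: str
    anchor: str
    members: list[str]
    loading: float = 0.8


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort in one place.

    Defaults are the study conditions of the recovery experiments: a
    200-gene universe with 20 genes mutation-enriched (x3) in TM regions at
    ~50 mutations/gene, 20 differentially expressed genes at |log2FC| = 2,
    an altered-vs-unaltered hazard ratio of 2, one 30-gene co-expression
    module, and ten planted gene-drug pairs at Spearman rho 0.6 with 10%
    MCAR missingness in the IC50 matrix.
    """

    seed: int = 0
    n_genes: int = 200
    n_cancer_types: int = 3
    n_tumor: int = 60
    n_normal: int = 20

    # mutations
    background_mutation_rate: float = 0.05  # mutations per residue per cohort
    tm_enrichment_genes: dict[str, float] = field(default_factory=dict)
    nonsyn_prob: float = 0.75
    p_deleterious_tm: float = 0.5
    p_deleterious_other: float = 0.25
    p_label_na: float = 0.05
    cadd_mean_tm: float = 22.0
    cadd_mean_other: float = 15.0
    cadd_sd: float = 6.0

    # CNV
    gain_prob: float = 0.05
    loss_prob: float = 0.05
    high_level_fraction: float = 0.2  # of gain/loss events that are +/-2

    # expression
    de_genes: dict[str, float] = field(default_factory=dict)  # gene -> log2 effect in tumors
    base_log2_mean: float = 3.0
    base_log2_mean_sd: float = 1.5
    expr_noise_sd: float = 1.0
    modules: list[CoexpressionModule] = field(default_factory=list)
    proliferation_marker: str = "MKI67"
    proliferation_loading: float = 0.9

    # clinical
    hazard_multiplier_altered: float = 2.0
    baseline_hazard: float = math.log(2) / 1000.0  # per day; median ~1000 d unaltered
    censoring_horizon: float = 3000.0  # days, uniform independent censoring
    hypoxia_shift: float = 0.8  # SD units, placeholder effect size (not stated upstream)
    tmb_lambda: float = 10.0
    tmb_multiplier_altered: float = 1.5  # placeholder effect size
    stage_log_odds_shift: float = 0.5  # placeholder effect size
    weight_mean: float = 75.0
    weight_sd: float = 12.0

    # drugs / cell lines
    n_drugs: int = 40
    n_cell_lines: int = 300
    planted_drug_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    missing_fraction: float = 0.10
    drug_offset_sd: float = 2.0
    line_factor_loading: float = 0.6

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_cancer_types", "n_tumor", "n_normal", "n_drugs", "n_cell_lines"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be a positive integer")
        if self.background_mutation_rate < 0:
            raise ConfigurationError("background_mutation_rate must be >= 0")
        for g, m in self.tm_enrichment_genes.items():
            if m < 0:
                raise ConfigurationError(f"rate multiplier for {g} must be >= 0")
        if not (0 <= self.missing_fraction < 1):
            raise ConfigurationError("missing_fraction must be in [0,1)")
        for g, d, rho in self.planted_drug_pairs:
            if abs(rho) >= 1:
                raise ConfigurationError(f"planted rho for ({g},{d}) must satisfy |rho| < 1")
        if self.hazard_multiplier_altered <= 0:
            raise ConfigurationError("hazard_multiplier_altered must be > 0")
        if self.expr_noise_sd <= 0:
            raise ConfigurationError("expression dispersion must be positive")
        if not (0 <= self.gain_prob <= 1 and 0 <= self.loss_prob <= 1):
            raise ConfigurationError("gain/loss probabilities must be in [0,1]")
        if self.gain_prob + self.loss_prob > 1:
            raise ConfigurationError("gain_prob + loss_prob must not exceed 1")

    @classmethod
    def default_study(cls, seed: int = 0) -> "SimulationConfig":
        """The default recovery-study configuration (see class docstring)."""
        genes = [f"G{i:04d}" for i in range(1, 201)]
        de = {g: 2.0 for g in genes[20:30]}
        de.update({g: -2.0 for g in genes[30:40]})
        module = CoexpressionModule(name="MODULE_G0001", anchor=genes[0], members=genes[40:70], loading=0.8)
        pairs = [(genes[i], f"D{i + 1:03d}", 0.6) for i in range(10)]
        return cls(
            seed=seed,
            tm_enrichment_genes={g: 3.0 for g in genes[:20]},
            de_genes=de,
            modules=[module],
            planted_drug_pairs=pairs,
        )


def _rng(config: SimulationConfig, offset: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), int(offset)]))


def _gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(1, n + 1)]


def _cancer_types(n: int) -> list[str]:
    return [f"C{i}" for i in range(1, n + 1)]


# ---------------------------------------------------------------------------
# gene panel
# ---------------------------------------------------------------------------

def gen_gene_panel(config: SimulationConfig, fixture: bool = False) -> GenePanel:
    """Synthesize a gene panel, or return the shipped 28-gene TRP fixture.

    Synthetic genes have protein lengths uniform on [500, 1500] residues and
    0-8 non-overlapping 21-residue TM helices; genes named in
    ``tm_enrichment_genes`` are guaranteed at least four helices so the
    planted enrichment has a region to land in.
    """
    if fixture:
        return trp_channel_panel()
    rng = _rng(config, _OFF_PANEL)
    names = _gene_names(config.n_genes)
    families = [f"F{(i % 6) + 1}" for i in range(config.n_genes)]
    lengths = rng.integers(500, 1501, size=config.n_genes)
    intervals: dict[str, tuple[tuple[int, int], ...]] = {}
    helix_len = 21
    for name, length in zip(names, lengths):
        n_tm = int(rng.integers(0, 9))
        if name in config.tm_enrichment_genes and n_tm < 4:
            n_tm = 4 + int(rng.integers(0, 5))
        if n_tm == 0:
            intervals[name] = ()
            continue
        block = int(length) // n_tm
        if block < helix_len:
            raise ConfigurationError("requested TM intervals exceed protein length")
        ivs = []
        for i in range(n_tm):
            lo = i * block + 1
            start = int(rng.integers(lo, lo + block - helix_len + 1))
            ivs.append((start, start + helix_len - 1))
        intervals[name] = tuple(ivs)
    genes = pd.DataFrame({"symbol": names, "family": families, "length": lengths}).set_index("symbol")
    return GenePanel(genes=genes, tm_intervals=intervals)


# ---------------------------------------------------------------------------
# samples
# ---------------------------------------------------------------------------

def sample_frame(config: SimulationConfig) -> pd.DataFrame:
    """Sample metadata for the cohort: tumors and normals per cancer type."""
    rows = []
    for ct in _cancer_types(config.n_cancer_types):
        for i in range(1, config.n_tumor + 1):
            rows.append({"sample_id": f"{ct}-T{i:03d}", "cancer_type": ct, "is_tumor": True, "tissue": f"tissue_{ct}"})
        for i in range(1, config.n_normal + 1):
            rows.append({"sample_id": f"{ct}-N{i:03d}", "cancer_type": ct, "is_tumor": False, "tissue": f"tissue_{ct}"})
    return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# mutations
# ---------------------------------------------------------------------------

def gen_mutation_table(panel: GenePanel, config: SimulationConfig, manifest: Manifest | None = None) -> pd.DataFrame:
    """MAF-like somatic mutation records in protein coordinates.

    Per gene, the mutation count is Poisson with mean
    ``rate * (L_other + multiplier * L_TR)``; positions are uniform within
    their region, so the planted TM fraction is
    ``m*L_TR / (m*L_TR + L_other)``. SIFT/PolyPhen labels and CADD scores
    are drawn from region-specific distributions.
    """
    if len(panel) == 0:
        raise InputError("empty gene panel")
    rng = _rng(config, _OFF_MUT)
    samples = sample_frame(config)
    tumor_ids = samples.index[samples["is_tumor"]].to_numpy()
    records: list[dict] = []
    for sym in panel.symbols:
        L_g = panel.length(sym)
        if L_g <= 0:
            raise InputError(f"zero-length protein for {sym}")
        L_tm = panel.tm_length(sym)
        L_other = L_g - L_tm
        mult = config.tm_enrichment_genes.get(sym, 1.0)
        lam = config.background_mutation_rate * (L_other + mult * L_tm)
        n_mut = int(rng.poisson(lam))
        if n_mut == 0:
            continue
        p_tm = (mult * L_tm) / (mult * L_tm + L_other) if (mult * L_tm + L_other) > 0 else 0.0
        in_tm = rng.random(n_mut) < p_tm
        tm_residues = np.concatenate(
            [np.arange(a, b + 1) for a, b in panel.tm_intervals.get(sym, ())]
        ) if L_tm else np.array([], dtype=int)
        other_residues = np.setdiff1d(np.arange(1, L_g + 1), tm_residues, assume_unique=True)
        positions = np.empty(n_mut, dtype=int)
        if in_tm.any():
            positions[in_tm] = rng.choice(tm_residues, size=int(in_tm.sum()))
        if (~in_tm).any():
            positions[~in_tm] = rng.choice(other_residues, size=int((~in_tm).sum()))
        chosen = rng.choice(tumor_ids, size=n_mut)
        nonsyn = rng.random(n_mut) < config.nonsyn_prob
        p_del = np.where(in_tm, config.p_deleterious_tm, config.p_deleterious_other)
        na_mask = rng.random(n_mut) < config.p_label_na
        sift = np.where(rng.random(n_mut) < p_del, "deleterious", "tolerated")
        polyphen = np.where(rng.random(n_mut) < p_del, "damaging", "benign")
        sift = np.where(na_mask, "NA", sift)
        polyphen = np.where(na_mask, "NA", polyphen)
        cadd = rng.normal(np.where(in_tm, config.cadd_mean_tm, config.cadd_mean_other), config.cadd_sd)
        for j in range(n_mut):
            records.append(
                {
                    "sample": chosen[j],
                    "cancer_type": samples.at[chosen[j], "cancer_type"],
                    "gene": sym,
                    "protein_pos": int(positions[j]),
                    "variant_class": "nonsynonymous" if nonsyn[j] else "silent",
                    "sift": sift[j],
                    "polyphen": polyphen[j],
                    "cadd": float(cadd[j]),
                }
            )
    cols = ["sample", "cancer_type", "gene", "protein_pos", "variant_class", "sift", "polyphen", "cadd"]
    out = pd.DataFrame(records, columns=cols)
    if manifest is not None:
        manifest.record("tm_enrichment_genes", sorted(config.tm_enrichment_genes))
        manifest.record("tm_enrichment_multipliers", dict(sorted(config.tm_enrichment_genes.items())))
        manifest.record("background_mutation_rate", config.background_mutation_rate)
    return out


# ---------------------------------------------------------------------------
# CNV
# ---------------------------------------------------------------------------

def gen_cnv_matrix(panel: GenePanel, config: SimulationConfig, manifest: Manifest | None = None) -> OmicsMatrix:
    """GISTIC-thresholded CNV calls over tumor samples."""
    rng = _rng(config, _OFF_CNV)
    samples = sample_frame(config)
    tumors = samples[samples["is_tumor"]]
    n = len(tumors)
    values = np.zeros((len(panel), n), dtype=int)
    u = rng.random((len(panel), n))
    high = rng.random((len(panel), n)) < config.high_level_fraction
    gain = u < config.gain_prob
    loss = (u >= config.gain_prob) & (u < config.gain_prob + config.loss_prob)
    values[gain] = np.where(high[gain], 2, 1)
    values[loss] = np.where(high[loss], -2, -1)
    df = pd.DataFrame(values, index=panel.symbols, columns=tumors.index)
    if manifest is not None:
        manifest.record("cnv_gain_prob", config.gain_prob)
        manifest.record("cnv_loss_prob", config.loss_prob)
    return OmicsMatrix(values=df, role="cnv", col_meta=tumors)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def gen_expression_cohort(panel: GenePanel, config: SimulationConfig, manifest: Manifest | None = None,
                          cell_lines: bool = False) -> OmicsMatrix:
    """Log-normal FPKM cohort with planted DE effects and co-expression modules.

    With ``cell_lines=True`` the columns are cell lines (no tumor/normal
    split); the same latent-module structure applies, which is what the
    pharmacogenomic screens correlate against.
    """
    rng = _rng(config, _OFF_EXPR + (1 if cell_lines else 0))
    genes = list(panel.symbols)
    if config.proliferation_marker not in genes:
        genes = genes + [config.proliferation_marker]
    if cell_lines:
        meta = pd.DataFrame(
            {
                "cancer_type": ["CL"] * config.n_cell_lines,
                "is_tumor": [True] * config.n_cell_lines,
                "tissue": ["cell_line"] * config.n_cell_lines,
            },
            index=pd.Index([f"L{i:04d}" for i in range(1, config.n_cell_lines + 1)], name="sample_id"),
        )
    else:
        meta = sample_frame(config)
    n_samples = len(meta)
    mu = rng.normal(config.base_log2_mean, config.base_log2_mean_sd, size=len(genes))
    log2x = mu[:, None] + rng.normal(0.0, config.expr_noise_sd, size=(len(genes), n_samples))

    gene_idx = {g: i for i, g in enumerate(genes)}
    # latent-factor co-expression modules (anchor + members share one factor)
    for module in config.modules:
        z = rng.normal(0.0, 1.0, size=n_samples)
        lam = float(module.loading)
        for g in [module.anchor, *module.members]:
            if g in gene_idx:
                i = gene_idx[g]
                noise = rng.normal(0.0, 1.0, size=n_samples)
                log2x[i] = mu[i] + config.expr_noise_sd * (lam * z + math.sqrt(1 - lam**2) * noise)
    # proliferation factor drives the marker gene
    prolif = rng.normal(0.0, 1.0, size=n_samples)
    pm = gene_idx[config.proliferation_marker]
    lam = config.proliferation_loading
    log2x[pm] = mu[pm] + config.expr_noise_sd * (
        lam * prolif + math.sqrt(1 - lam**2) * rng.normal(0.0, 1.0, size=n_samples)
    )
    # planted tumor/normal shifts
    if not cell_lines:
        tumor_mask = meta["is_tumor"].to_numpy()
        for g, effect in config.de_genes.items():
            if g in gene_idx:
                log2x[gene_idx[g], tumor_mask] += float(effect)
    fpkm = np.power(2.0, log2x)
    df = pd.DataFrame(fpkm, index=genes, columns=meta.index)
    if manifest is not None and not cell_lines:
        manifest.record("de_genes", dict(sorted(config.de_genes.items())))
        manifest.record("modules", {m.name: {"anchor": m.anchor, "size": len(m.members), "loading": m.loading} for m in config.modules})
        manifest.record("proliferation_marker", config.proliferation_marker)
    return OmicsMatrix(values=df, role="expression", col_meta=meta)


# ---------------------------------------------------------------------------
# clinical
# ---------------------------------------------------------------------------

_STAGES = ["I", "II", "III", "IV"]
_GRADES = ["G1", "G2", "G3", "G4"]
_STAGE_BASE = np.array([0.30, 0.30, 0.25, 0.15])
_GRADE_BASE = np.array([0.25, 0.35, 0.25, 0.15])


def _shift_ordinal(base: np.ndarray, log_odds: float) -> np.ndarray:
    """Tilt an ordinal pmf toward higher categories by a log-odds factor."""
    w = base * np.exp(log_odds * np.arange(len(base)))
    return w / w.sum()


def gen_clinical(samples: pd.Index | list[str], alteration_status: pd.Series | dict,
                 config: SimulationConfig, manifest: Manifest | None = None) -> pd.DataFrame:
    """Per-patient clinical table with alteration-linked hazards and covariates.

    Survival is exponential: hazard = baseline_hazard * multiplier for
    altered patients; censoring is independent, uniform on
    [0, censoring_horizon]. Hypoxia scores, TMB, stage and grade receive the
    configured shifts in the altered group; sex, ethnicity and weight do not
    differ by construction.
    """
    rng = _rng(config, _OFF_CLIN)
    patients = pd.Index(samples)
    status = pd.Series(alteration_status).reindex(patients)
    if status.isna().any():
        raise InputError("alteration status missing for some patients")
    altered = status.astype(bool).to_numpy()
    n = len(patients)
    hazard = config.baseline_hazard * np.where(altered, config.hazard_multiplier_altered, 1.0)
    t_event = rng.exponential(1.0 / hazard)
    t_cens = rng.uniform(0.0, config.censoring_horizon, size=n)
    os_time = np.minimum(t_event, t_cens)
    os_event = (t_event <= t_cens).astype(int)
    # disease-free survival: same structure, modestly higher hazard
    t_event2 = rng.exponential(1.0 / (1.3 * hazard))
    t_cens2 = rng.uniform(0.0, config.censoring_horizon, size=n)
    dfs_time = np.minimum(t_event2, t_cens2)
    dfs_event = (t_event2 <= t_cens2).astype(int)

    hypoxia = rng.normal(0.0, 1.0, size=n) + config.hypoxia_shift * altered
    tmb = rng.poisson(config.tmb_lambda * np.where(altered, config.tmb_multiplier_altered, 1.0))
    stage = np.array(
        [rng.choice(_STAGES, p=_shift_ordinal(_STAGE_BASE, config.stage_log_odds_shift if a else 0.0)) for a in altered]
    )
    grade = np.array(
        [rng.choice(_GRADES, p=_shift_ordinal(_GRADE_BASE, config.stage_log_odds_shift if a else 0.0)) for a in altered]
    )
    sex = rng.choice(["female", "male"], size=n)
    ethnicity = rng.choice(["groupA", "groupB", "groupC"], size=n, p=[0.6, 0.3, 0.1])
    weight = rng.normal(config.weight_mean, config.weight_sd, size=n)

    out = pd.DataFrame(
        {
            "patient_id": patients,
            "os_time": os_time,
            "os_event": os_event,
            "dfs_time": dfs_time,
            "dfs_event": dfs_event,
            "stage": stage,
            "grade": grade,
            "sex": sex,
            "ethnicity": ethnicity,
            "weight": weight,
            "hypoxia_score": hypoxia,
            "tmb": tmb,
            "altered": altered,
        }
    ).set_index("patient_id")
    if manifest is not None:
        manifest.record("hazard_multiplier_altered", config.hazard_multiplier_altered)
        manifest.record("hypoxia_shift", config.hypoxia_shift)
        manifest.record("tmb_multiplier_altered", config.tmb_multiplier_altered)
    return out


# ---------------------------------------------------------------------------
# drug response
# ---------------------------------------------------------------------------

def _pearson_for_spearman(rho_s: float) -> float:
    """Bivariate-normal Pearson correlation giving a target Spearman rho."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def gen_drug_response(panel: GenePanel, config: SimulationConfig, manifest: Manifest | None = None
                      ) -> tuple[OmicsMatrix, OmicsMatrix]:
    """IC50 matrix (drugs x cell lines) plus matching cell-line expression.

    Planted (gene, drug, rho) triples use a Gaussian copula against the
    gene's standardized log2 expression so the population Spearman
    correlation equals the stated rho. Unplanted drugs carry a drug-level
    offset and a shared cell-line sensitivity factor, so rows are mutually
    informative (the structure KNN imputation exploits). Missingness is MCAR
    at ``missing_fraction``. IC50 values are on natural-log scale.
    """
    if config.n_cell_lines < 10:
        raise ConfigurationError("n_cell_lines must be >= 10")
    expr = gen_expression_cohort(panel, config, cell_lines=True)
    rng = _rng(config, _OFF_DRUG)
    lines = expr.samples
    n = len(lines)
    drugs = [f"D{i:03d}" for i in range(1, config.n_drugs + 1)]
    offsets = rng.normal(0.0, config.drug_offset_sd, size=len(drugs))
    line_factor = rng.normal(0.0, 1.0, size=n)
    ic50 = (
        offsets[:, None]
        + config.line_factor_loading * line_factor[None, :]
        + math.sqrt(max(0.0, 1 - config.line_factor_loading**2)) * rng.normal(0.0, 1.0, size=(len(drugs), n))
    )
    drug_idx = {d: i for i, d in enumerate(drugs)}
    log2x = np.log2(expr.values.to_numpy())
    gene_pos = {g: i for i, g in enumerate(expr.features)}
    for gene, drug, rho_s in config.planted_drug_pairs:
        if drug not in drug_idx:
            raise ConfigurationError(f"planted drug {drug} not among generated drugs")
        if gene not in gene_pos:
            raise ConfigurationError(f"planted gene {gene} not in panel expression")
        z = log2x[gene_pos[gene]]
        z = (z - z.mean()) / z.std()
        r = _pearson_for_spearman(rho_s)
        i = drug_idx[drug]
        ic50[i] = offsets[i] + r * z + math.sqrt(1 - r**2) * rng.normal(0.0, 1.0, size=n)
    if config.missing_fraction > 0:
        mask = rng.random(ic50.shape) < config.missing_fraction
        ic50 = np.where(mask, np.nan, ic50)
    df = pd.DataFrame(ic50, index=drugs, columns=lines)
    out = OmicsMatrix(values=df, role="ic50", col_meta=expr.col_meta)
    if manifest is not None:
        manifest.record("planted_drug_pairs", [(g, d, r) for g, d, r in config.planted_drug_pairs])
        manifest.record("missing_fraction", config.missing_fraction)
    return out, expr


# ---------------------------------------------------------------------------
# gene sets (for the pathway stage)
# ---------------------------------------------------------------------------

def gen_gene_sets(panel: GenePanel, config: SimulationConfig, n_random_sets: int = 30,
                  size_range: tuple[int, int] = (15, 40)) -> dict[str, list[str]]:
    """Planted-module sets plus random sets over the gene universe."""
    rng = _rng(config, _OFF_SETS)
    universe = np.array(panel.symbols)
    sets: dict[str, list[str]] = {}
    for module in config.modules:
        sets[module.name] = [g for g in module.members if g in set(universe)]
    for i in range(1, n_random_sets + 1):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        sets[f"RANDOM_{i:02d}"] = sorted(rng.choice(universe, size=size, replace=False).tolist())
    return sets


# ---------------------------------------------------------------------------
# write everything to disk
# ---------------------------------------------------------------------------

def simulate_all(config: SimulationConfig, outdir: str | Path, fixture_panel: bool = False) -> dict[str, Path]:
    """Generate the full synthetic study and write every input table as TSV.

    Returns a mapping of logical names to written paths. The alteration
    status fed to the clinical generator is derived from the generated
    mutations/CNV (nonsynonymous panel mutation or |CNV| = 2), so the
    planted survival effect is attached to the observable alteration groups.
    """
    from .clinical_relevance import alteration_status  # local import to avoid a cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = Manifest()
    manifest.record("seed", config.seed)

    panel = gen_gene_panel(config, fixture=fixture_panel)
    muts = gen_mutation_table(panel, config, manifest)
    cnv = gen_cnv_matrix(panel, config, manifest)
    expr = gen_expression_cohort(panel, config, manifest)
    tumors = expr.col_meta.index[expr.col_meta["is_tumor"]]
    status = alteration_status(muts, cnv, panel, patients=tumors)
    clinical = gen_clinical(tumors, status, config, manifest)
    ic50, cl_expr = gen_drug_response(panel, config, manifest)
    sets = gen_gene_sets(panel, config)

    paths: dict[str, Path] = {}

    def _write(df: pd.DataFrame, name: str, index_label: str | None = None) -> None:
        p = outdir / f"{name}.tsv"
        df.to_csv(p, sep="\t", float_format="%.10g", lineterminator="\n", index_label=index_label)
        paths[name] = p

    panel.to_tables(outdir / "panel.tsv", outdir / "tm_intervals.tsv")
    paths["panel"] = outdir / "panel.tsv"
    paths["tm_intervals"] = outdir / "tm_intervals.tsv"
    muts.to_csv(outdir / "mutations.tsv", sep="\t", float_format="%.10g", lineterminator="\n", index=False)
    paths["mutations"] = outdir / "mutations.tsv"
    _write(cnv.values, "cnv", index_label="gene")
    _write(expr.values, "expression", index_label="gene")
    _write(expr.col_meta, "sample_meta", index_label="sample_id")
    _write(clinical, "clinical", index_label="patient_id")
    _write(ic50.values, "ic50", index_label="drug")
    _write(cl_expr.values, "cell_line_expression", index_label="gene")
    # a small 'actionable gene' list: genes with cell-line expression, outside the planted pairs
    actionable = [g for g in panel.symbols if g not in {p[0] for p in config.planted_drug_pairs}][:10]
    pd.DataFrame({"gene": actionable}).to_csv(outdir / "actionable_genes.tsv", sep="\t", index=False, lineterminator="\n")
    paths["actionable_genes"] = outdir / "actionable_genes.tsv"
    from .pathway_enrichment import write_gmt

    write_gmt(sets, outdir / "gene_sets.gmt", description="synthetic")
    paths["gene_sets"] = outdir / "gene_sets.gmt"
    (outdir / "manifest.txt").write_text(manifest.to_text())
    paths["manifest"] = outdir / "manifest.txt"
    return paths
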