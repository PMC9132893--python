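import numpy as np
import pandas as pd
import pytest

from panelscan.containers import ConfigurationError
from panelscan.panel import GenePanel
from panelscan.synthetic_data import (
    SimulationConfig,
    gen_clinical,
    gen_cnv_matrix,
    gen_drug_response,
    gen_expression_cohort,
    gen_gene_panel,
    gen_mutation_table,
)


def big_gene_panel(length=1000, tm=((1, 200),)):
    genes = pd.DataFrame({"symbol": ["GX"], "family": ["F1"], "length": [length]}).set_index("symbol")
    return GenePanel(genes=genes, tm_intervals={"GX": tm})


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_genes": 0},
            {"background_mutation_rate": -0.1},
            {"missing_fraction": 1.0},
            {"planted_drug_pairs": [("G0001", "D001", 1.0)]},
            {"hazard_multiplier_altered": 0.0},
            {"expr_noise_sd": 0.0},
            {"gain_prob": 0.7, "loss_prob": 0.6},
            {"tm_enrichment_genes": {"G0001": -1.0}},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SimulationConfig(**kwargs)


class TestMutationGenerator:
    def test_zero_rate_gives_empty_table(self):
        config = SimulationConfig(seed=1, n_genes=5, background_mutation_rate=0.0)
        muts = gen_mutation_table(gen_gene_panel(config), config)
        assert len(muts) == 0

    def test_uniform_null_density_ratio_near_one(self):
        # multiplier 1 everywhere: TM density / other density ~ 1 over ~1e4 mutations
        panel = big_gene_panel(length=1000, tm=((1, 200),))
        config = SimulationConfig(seed=2, background_mutation_rate=10.0)
        muts = gen_mutation_table(panel, config)
        assert len(muts) > 5000
        in_tm = muts["protein_pos"] <= 200
        tm_density = in_tm.sum() / 200
        other_density = (~in_tm).sum() / 800
        assert tm_density / other_density == pytest.approx(1.0, abs=0.1)

    def test_planted_multiplier_gives_mixture_fraction(self):
        # m=3, L_TR/L_g=0.2 -> TM fraction 3*0.2/(3*0.2+0.8) = 0.4286
        panel = big_gene_panel(length=1000, tm=((1, 200),))
        config = SimulationConfig(seed=3, background_mutation_rate=1.0,
                                  tm_enrichment_genes={"GX": 3.0})
        muts = gen_mutation_table(panel, config)
        frac = (muts["protein_pos"] <= 200).mean()
        assert frac == pytest.approx(3 * 0.2 / (3 * 0.2 + 0.8), abs=0.03)

    def test_positions_within_protein_and_determinism(self):
        config = SimulationConfig(seed=4, n_genes=10, background_mutation_rate=0.02)
        panel = gen_gene_panel(config)
        m1 = gen_mutation_table(panel, config)
        m2 = gen_mutation_table(panel, config)
        pd.testing.assert_frame_equal(m1, m2)
        for _, row in m1.iterrows():
            assert 1 <= row["protein_pos"] <= panel.length(row["gene"])


class TestCnvGenerator:
    def test_zero_gain_prob_no_positive_entries(self):
        config = SimulationConfig(seed=5, n_genes=10, gain_prob=0.0, loss_prob=0.2)
        cnv = gen_cnv_matrix(gen_gene_panel(config), config)
        assert (cnv.values.to_numpy() <= 0).all()

    def test_gain_frequency_recovered_within_binomial_error(self):
        config = SimulationConfig(seed=6, n_genes=5, n_cancer_types=1, n_tumor=1000,
                                  gain_prob=0.3, loss_prob=0.1)
        cnv = gen_cnv_matrix(gen_gene_panel(config), config)
        gain_freq = (cnv.values.to_numpy() >= 1).mean(axis=1)
        assert np.all(np.abs(gain_freq - 0.3) < 0.05)

    def test_determinism(self):
        config = SimulationConfig(seed=7, n_genes=8)
        a = gen_cnv_matrix(gen_gene_panel(config), config)
        b = gen_cnv_matrix(gen_gene_panel(config), config)
        pd.testing.assert_frame_equal(a.values, b.values)


class TestExpressionGenerator:
    def test_no_effect_means_equal_within_error(self):
        config = SimulationConfig(seed=8, n_genes=30, n_cancer_types=1,
                                  n_tumor=200, n_normal=200, de_genes={})
        expr = gen_expression_cohort(gen_gene_panel(config), config)
        log2x = np.log2(expr.values)
        tumor = expr.col_meta["is_tumor"].to_numpy()
        diff = log2x.loc[:, tumor].mean(axis=1) - log2x.loc[:, ~tumor].mean(axis=1)
        assert np.abs(diff).max() < 0.35

    def test_planted_log2_effect_recovered(self):
        config = SimulationConfig(seed=9, n_genes=30, n_cancer_types=1,
                                  n_tumor=50, n_normal=50, de_genes={"G0005": 2.0})
        expr = gen_expression_cohort(gen_gene_panel(config), config)
        log2x = np.log2(expr.values)
        tumor = expr.col_meta["is_tumor"].to_numpy()
        lfc = log2x.loc["G0005", tumor].mean() - log2x.loc["G0005", ~tumor].mean()
        assert lfc == pytest.approx(2.0, abs=0.6)

    def test_module_members_co_correlated(self):
        from panelscan.synthetic_data import CoexpressionModule
        from scipy.stats import spearmanr

        members = [f"G{i:04d}" for i in range(2, 10)]
        module = CoexpressionModule(name="M", anchor="G0001", members=members, loading=0.8)
        config = SimulationConfig(seed=10, n_genes=30, n_cancer_types=1,
                                  n_tumor=300, n_normal=1, modules=[module])
        expr = gen_expression_cohort(gen_gene_panel(config), config)
        rhos = [
            spearmanr(expr.values.loc["G0001"], expr.values.loc[m]).statistic for m in members
        ]
        # factor model: expected pairwise correlation = loading^2 = 0.64
        assert np.mean(rhos) > 0.4


class TestClinicalGenerator:
    def _status(self, n_alt=100, n_unalt=100):
        ids = [f"P{i}" for i in range(n_alt + n_unalt)]
        return pd.Series([True] * n_alt + [False] * n_unalt, index=ids)

    def test_null_config_groups_similar(self):
        status = self._status(300, 300)
        config = SimulationConfig(seed=11, hazard_multiplier_altered=1.0,
                                  hypoxia_shift=0.0, tmb_multiplier_altered=1.0,
                                  stage_log_odds_shift=0.0)
        clin = gen_clinical(status.index, status, config)
        alt = clin[clin["altered"]]
        unalt = clin[~clin["altered"]]
        assert abs(alt["hypoxia_score"].mean() - unalt["hypoxia_score"].mean()) < 0.25
        assert abs(alt["os_event"].mean() - unalt["os_event"].mean()) < 0.1

    def test_hazard_multiplier_shortens_survival(self):
        status = self._status(200, 200)
        config = SimulationConfig(seed=12, hazard_multiplier_altered=2.0)
        clin = gen_clinical(status.index, status, config)
        assert clin.loc[clin["altered"], "os_time"].median() < clin.loc[~clin["altered"], "os_time"].median()

    def test_determinism(self):
        status = self._status(20, 20)
        config = SimulationConfig(seed=13)
        a = gen_clinical(status.index, status, config)
        b = gen_clinical(status.index, status, config)
        pd.testing.assert_frame_equal(a, b)


class TestDrugResponseGenerator:
    def test_planted_rho_recovered_at_large_n(self):
        from scipy.stats import spearmanr

        config = SimulationConfig(seed=14, n_genes=20, n_cell_lines=500, n_drugs=10,
                                  planted_drug_pairs=[("G0003", "D002", 0.6)],
                                  missing_fraction=0.0)
        ic50, expr = gen_drug_response(gen_gene_panel(config), config)
        rho = spearmanr(expr.values.loc["G0003"], ic50.values.loc["D002"]).statistic
        assert rho == pytest.approx(0.6, abs=0.1)

    def test_zero_missing_fraction_complete(self):
        config = SimulationConfig(seed=15, n_genes=10, n_cell_lines=50, missing_fraction=0.0)
        ic50, _ = gen_drug_response(gen_gene_panel(config), config)
        assert not ic50.values.isna().any().any()

    def test_missingness_near_configured_rate(self):
        config = SimulationConfig(seed=16, n_genes=10, n_cell_lines=200, n_drugs=30,
                                  missing_fraction=0.2)
        ic50, _ = gen_drug_response(gen_gene_panel(config), config)
        assert ic50.values.isna().to_numpy().mean() == pytest.approx(0.2, abs=0.02)
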