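import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from panelscan import genomic_landscape as gl
from panelscan.containers import InputError, OmicsMatrix
from panelscan.panel import GenePanel
from tests.conftest import make_mutations


def exact_binomial_upper_tail(k: int, N: int, p: float) -> float:
    """Direct summation oracle: P(X >= k) = sum_{x=k}^{N} C(N,x) p^x (1-p)^(N-x)."""
    return sum(math.comb(N, x) * p**x * (1 - p) ** (N - x) for x in range(k, N + 1))


class TestTmRegionEnrichment:
    def test_worked_example_E_and_p(self, one_gene_panel):
        # N=10 mutations, k=5 in a region of p_ri=0.2: E=2.5, p=0.0327935
        muts = make_mutations([1, 2, 3, 4, 5, 30, 40, 50, 60, 70])
        res = gl.tm_region_enrichment(muts, one_gene_panel).iloc[0]
        assert res["k"] == 5 and res["N"] == 10
        assert res["E"] == pytest.approx(2.5)
        assert res["p_value"] == pytest.approx(0.0327935, abs=1e-7)
        assert res["p_value"] == pytest.approx(exact_binomial_upper_tail(5, 10, 0.2), abs=1e-12)

    def test_k_zero_gives_p_one(self, one_gene_panel):
        muts = make_mutations([30, 40, 50])
        res = gl.tm_region_enrichment(muts, one_gene_panel).iloc[0]
        assert res["k"] == 0
        assert res["p_value"] == pytest.approx(1.0)

    def test_saturated_region_never_enriched(self):
        genes = pd.DataFrame({"symbol": ["GS"], "family": ["F"], "length": [50]}).set_index("symbol")
        panel = GenePanel(genes=genes, tm_intervals={"GS": ((1, 50),)})
        muts = make_mutations([1, 10, 20], gene="GS")
        res = gl.tm_region_enrichment(muts, panel).iloc[0]
        assert res["p_ri"] == 1.0
        assert res["p_value"] == pytest.approx(1.0)
        assert res["E"] == pytest.approx(1.0)
        assert not res["enriched"]

    def test_matches_exact_summation_on_grid(self, one_gene_panel):
        # stable sf formulation vs direct summation, N <= 60 across a p_ri grid
        for p_ri in (0.05, 0.2, 0.5, 0.9):
            for N in (1, 7, 23, 60):
                for k in range(0, N + 1, max(1, N // 6)):
                    expected = exact_binomial_upper_tail(k, N, p_ri)
                    got = float(stats.binom.sf(k - 1, N, p_ri))
                    assert got == pytest.approx(expected, abs=1e-10)

    def test_monotonicity_in_k(self):
        # E increases and p decreases as k grows at fixed N, p_ri
        N, p_ri = 30, 0.25
        E = [k / (N * p_ri) for k in range(N + 1)]
        p = [stats.binom.sf(k - 1, N, p_ri) for k in range(N + 1)]
        assert all(a < b for a, b in zip(E, E[1:]))
        assert all(a >= b for a, b in zip(p, p[1:]))

    def test_gene_without_tm_annotation_unscored(self):
        genes = pd.DataFrame({"symbol": ["GN"], "family": ["F"], "length": [100]}).set_index("symbol")
        panel = GenePanel(genes=genes, tm_intervals={})
        res = gl.tm_region_enrichment(make_mutations([5, 6], gene="GN"), panel).iloc[0]
        assert not res["scored"] and not res["enriched"]


class TestFrequencyAndTmb:
    def test_frequency_definitional(self, one_gene_panel):
        muts = make_mutations([5], sample=["s1"])
        freq = gl.mutation_frequency_matrix(muts, {"C1": 4}, one_gene_panel)
        assert freq.at["GX", "C1"] == 0.25

    def test_empty_table_all_zero(self, one_gene_panel):
        empty = make_mutations([]).iloc[:0]
        freq = gl.mutation_frequency_matrix(empty, {"C1": 10}, one_gene_panel)
        assert (freq.to_numpy() == 0).all()

    def test_distinct_samples_counted_once(self, one_gene_panel):
        muts = make_mutations([5, 6], sample=["s1", "s1"])
        freq = gl.mutation_frequency_matrix(muts, {"C1": 4}, one_gene_panel)
        assert freq.at["GX", "C1"] == 0.25

    def test_unknown_cancer_type_rejected(self, one_gene_panel):
        muts = make_mutations([5], cancer_type="C9")
        with pytest.raises(InputError):
            gl.mutation_frequency_matrix(muts, {"C1": 4}, one_gene_panel)

    def test_tmb_counts_nonsynonymous_only(self):
        muts = pd.concat([
            make_mutations([1, 2, 3], sample=["sA"] * 3, variant_class="nonsynonymous"),
            make_mutations([4, 5], sample=["sA"] * 2, variant_class="silent"),
        ])
        tmb = gl.compute_tmb(muts, ["sA", "sB"])
        assert tmb["sA"] == 3
        assert tmb["sB"] == 0

    def test_tmb_mean_matches_poisson_generator(self):
        from panelscan.synthetic_data import SimulationConfig, gen_gene_panel, gen_mutation_table

        # one cancer type, 1000 tumors; nonsynonymous rate tuned by nonsyn_prob
        config = SimulationConfig(seed=21, n_genes=50, n_cancer_types=1, n_tumor=1000,
                                  background_mutation_rate=0.2, nonsyn_prob=1.0)
        panel = gen_gene_panel(config)
        muts = gen_mutation_table(panel, config)
        tmb = gl.compute_tmb(muts, sorted(muts["sample"].unique()))
        expected = len(muts) / 1000
        assert tmb.mean() == pytest.approx(expected, rel=0.05)


class TestRegionValueCompare:
    def test_identical_multisets_p_one(self):
        res = gl.region_value_compare({"TM": [1, 2, 3], "other": [1, 2, 3]})
        assert res["method"] == "exact"
        assert res["p_value"] == 1.0

    def test_small_instance_matches_enumeration(self):
        # TM={5,6,7}, other={1,2,3}: 2 extreme assignments out of C(6,3)=20
        res = gl.region_value_compare({"TM": [5, 6, 7], "other": [1, 2, 3]})
        assert res["p_value"] == pytest.approx(2 / 20)

    def test_large_shift_tiny_p(self):
        rng = np.random.default_rng(0)
        x = rng.normal(3.0, 1.0, 100)
        y = rng.normal(0.0, 1.0, 100)
        res = gl.region_value_compare({"TM": x, "other": y})
        assert res["method"] == "normal_approx"
        assert res["p_value"] < 1e-6
        assert res["median_shift"] == pytest.approx(3.0, abs=0.5)

    def test_empty_group_rejected(self):
        with pytest.raises(InputError):
            gl.region_value_compare({"TM": [], "other": [1.0]})

    def test_density_modes(self, one_gene_panel):
        muts = make_mutations([1, 2, 30, 40, 50, 60])
        per_gene = gl.mutation_density_by_region(muts, one_gene_panel, per_gene=True)
        pooled = gl.mutation_density_by_region(muts, one_gene_panel, per_gene=False)
        assert per_gene["TM"][0] == pytest.approx(2 / 20)
        assert pooled["other"][0] == pytest.approx(4 / 80)


def fisher_two_sided_oracle(table) -> float:
    """Hypergeometric enumeration: sum of P(tables) no more probable than observed."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    p_obs = stats.hypergeom.pmf(a, n, col1, row1)
    total = 0.0
    for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        p = stats.hypergeom.pmf(x, n, col1, row1)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(1.0, total)


class TestDeleteriousRegionAssociation:
    def test_perfect_separation_table(self, one_gene_panel):
        muts = make_mutations(
            [1, 2, 3, 30, 40, 50],
            sift=["deleterious"] * 3 + ["tolerated"] * 3,
            polyphen=["damaging"] * 3 + ["benign"] * 3,
        )
        res = gl.deleterious_region_association(muts, one_gene_panel)
        assert res["table"].tolist() == [[3, 0], [0, 3]]
        assert res["p_value"] == pytest.approx(0.1)
        assert res["p_value"] == pytest.approx(fisher_two_sided_oracle(res["table"]), abs=1e-12)

    def test_no_association_table(self, one_gene_panel):
        muts = make_mutations(
            list(range(1, 11)) + list(range(30, 40)),
            sift=(["deleterious"] * 5 + ["tolerated"] * 5) * 2,
            polyphen=["benign"] * 20,
        )
        res = gl.deleterious_region_association(muts, one_gene_panel)
        assert res["table"].tolist() == [[5, 5], [5, 5]]
        assert res["p_value"] == pytest.approx(1.0)
        assert res["odds_ratio"] == pytest.approx(1.0)

    def test_na_labeled_mutations_excluded(self, one_gene_panel):
        muts = make_mutations(
            [1, 2, 30, 40],
            sift=["deleterious", "NA", "tolerated", "NA"],
            polyphen=["damaging", "NA", "benign", "NA"],
        )
        res = gl.deleterious_region_association(muts, one_gene_panel)
        assert res["table"].sum() == 2

    def test_all_na_rejected(self, one_gene_panel):
        muts = make_mutations([1, 2])
        with pytest.raises(InputError):
            gl.deleterious_region_association(muts, one_gene_panel)

    def test_matches_hypergeometric_enumeration_small_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            table = rng.integers(0, 11, size=(2, 2))
            if table.sum() == 0 or table.sum() > 40:
                continue
            _, p = stats.fisher_exact(table)
            assert p == pytest.approx(fisher_two_sided_oracle(table), abs=1e-10)


class TestCnvFrequency:
    def _matrix(self, data, samples, cancer_types):
        meta = pd.DataFrame({"cancer_type": cancer_types}, index=samples)
        return OmicsMatrix(values=pd.DataFrame(data, index=["GX"], columns=samples),
                           role="cnv", col_meta=meta)

    def test_definitional_frequencies(self, one_gene_panel):
        cnv = self._matrix([[2, 1, 0, -1]], [f"s{i}" for i in range(4)], ["C1"] * 4)
        gain, loss = gl.cnv_frequency_matrix(cnv, one_gene_panel)
        assert gain.at["GX", "C1"] == 0.5
        assert loss.at["GX", "C1"] == 0.25

    def test_high_level_only_mode(self, one_gene_panel):
        cnv = self._matrix([[2, 1, 0, -1]], [f"s{i}" for i in range(4)], ["C1"] * 4)
        gain, loss = gl.cnv_frequency_matrix(cnv, one_gene_panel, high_level_only=True)
        assert gain.at["GX", "C1"] == 0.25
        assert loss.at["GX", "C1"] == 0.0

    def test_all_zero_matrix(self, one_gene_panel):
        cnv = self._matrix([[0, 0, 0]], ["a", "b", "c"], ["C1"] * 3)
        gain, loss = gl.cnv_frequency_matrix(cnv, one_gene_panel)
        assert (gain.to_numpy() == 0).all() and (loss.to_numpy() == 0).all()

    def test_generator_round_trip(self):
        from panelscan.synthetic_data import SimulationConfig, gen_cnv_matrix, gen_gene_panel

        config = SimulationConfig(seed=22, n_genes=5, n_cancer_types=1, n_tumor=1000,
                                  gain_prob=0.3, loss_prob=0.1)
        panel = gen_gene_panel(config)
        gain, _ = gl.cnv_frequency_matrix(gen_cnv_matrix(panel, config), panel)
        assert np.all(np.abs(gain.to_numpy() - 0.3) < 0.05)
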