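"""Association statistics: Fisher, RVT1 boundary likelihood, scans, power."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from extremevar.association import (ContingencyTable, GeneBurdenResult,
                                    MultipleTestingConfig, allele_burden_test,
                                    bonferroni_threshold, burden_scan,
                                    fisher_exact, logistic_lrt,
                                    min_detectable_carriers_gene,
                                    min_detectable_carriers_variant,
                                    recessive_scan, rvt1_test,
                                    variant_enrichment_scan)
from extremevar.cohort_io import NOCALL, FrequencyPanel, VariantKey
from tests.conftest import make_cohort


def enum_fisher(a, b, c, d, sided):
    """Independent oracle: integer enumeration of all tables at fixed margins."""
    r1, c1, n = a + b, a + c, a + b + c + d
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        return 1.0
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    nums = {x: math.comb(c1, x) * math.comb(n - c1, r1 - x)
            for x in range(lo, hi + 1)}
    den = math.comb(n, r1)
    if sided == "one_greater":
        return sum(v for x, v in nums.items() if x >= a) / den
    gate = nums[a] + nums[a] // 10**9
    return sum(v for v in nums.values() if v <= gate) / den


class TestFisherExact:
    @pytest.mark.parametrize("table,sided,expected", [
        # 4 of 13 case carriers vs 0 of 379 panel: C(13,4)/C(392,4)
        ((4, 9, 0, 379), "one_greater", 7.379726228258153e-07),
        # 3 of 13 vs 0 of 379: C(13,3)/C(392,3)
        ((3, 10, 0, 379), "one_greater", 2.8707135027924214e-05),
        ((0, 13, 0, 379), "one_greater", 1.0),
        ((0, 13, 0, 379), "two", 1.0),
        # 3 of 13 cases vs 0 of 34 controls: C(13,3)/C(47,3) = 286/16215
        ((3, 10, 0, 34), "one_greater", 286 / 16215),
    ])
    def test_frozen_values(self, table, sided, expected):
        p = fisher_exact(ContingencyTable(*table), sided)
        assert p == pytest.approx(expected, rel=1e-9)
        assert p == pytest.approx(enum_fisher(*table, sided), rel=1e-9)

    @given(st.tuples(st.integers(0, 25), st.integers(0, 25),
                     st.integers(0, 25), st.integers(0, 25)))
    @settings(max_examples=300, deadline=None)
    def test_matches_scipy_cross_check(self, table):
        """Independent library cross-check on random tables."""
        ours_two = fisher_exact(ContingencyTable(*table), "two")
        ours_gt = fisher_exact(ContingencyTable(*table), "one_greater")
        arr = [[table[0], table[1]], [table[2], table[3]]]
        assert ours_two == pytest.approx(
            float(sps.fisher_exact(arr, "two-sided")[1]), rel=1e-6, abs=1e-12)
        assert ours_gt == pytest.approx(
            float(sps.fisher_exact(arr, "greater")[1]), rel=1e-6, abs=1e-12)

    def test_one_sided_monotone_in_case_carriers(self):
        n_cases, n_panel = 13, 379
        last = 1.1
        for a in range(0, n_cases + 1):
            p = fisher_exact(ContingencyTable(a, n_cases - a, 0, n_panel),
                             "one_greater")
            assert 0 < p <= 1
            assert p < last or (a == 0 and p == 1.0)
            last = p

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 1, 1, 1)


class TestBonferroni:
    def test_thresholds(self):
        assert bonferroni_threshold(MultipleTestingConfig(0.05, 13892)) \
            == pytest.approx(3.599193780593147e-06)
        assert bonferroni_threshold(MultipleTestingConfig(0.05, 10508)) \
            == pytest.approx(4.758279406166731e-06)
        assert bonferroni_threshold(MultipleTestingConfig(0.05, 1)) == 0.05

    def test_validation(self):
        with pytest.raises(ValueError):
            MultipleTestingConfig(0.05, 0)


def boundary_lrt_oracle(k, n_cases=13, n_controls=34):
    """Closed-form group deviance at the separation boundary: k case
    carriers at distinct sites, zero control carriers."""
    n = n_cases + n_controls
    m = n_cases - k + n_controls
    ll1 = 0.0
    if n_cases - k:
        ll1 += (n_cases - k) * math.log((n_cases - k) / m)
    ll1 += n_controls * math.log(n_controls / m)
    ll0 = n_cases * math.log(n_cases / n) + n_controls * math.log(n_controls / n)
    return 2 * (ll1 - ll0)


class TestRvt1:
    def test_no_variation_gives_p_one(self):
        res = rvt1_test([0.0] * 13 + [0.0] * 34, [True] * 13 + [False] * 34)
        assert res.p_value == 1.0 and res.lrt_statistic == 0.0

    @pytest.mark.parametrize("k,lrt,p", [
        (7, 21.61594856836731, 3.3307074955525593e-06),
        (6, 17.955023883766692, 2.261866290087317e-05),
    ])
    def test_boundary_lrt_matches_closed_form(self, k, lrt, p):
        """k of 13 cases carrying one distinct site each, 0 of 34 controls:
        the fit separates and the LRT equals the group deviance."""
        x = [1 / k] * k + [0.0] * (13 - k) + [0.0] * 34
        labels = [True] * 13 + [False] * 34
        res = rvt1_test(x, labels, gene_symbol="G", n_rare_sites=k)
        assert res.separation
        assert res.lrt_statistic == pytest.approx(lrt, rel=1e-9)
        assert res.p_value == pytest.approx(p, rel=1e-9)
        assert res.lrt_statistic == pytest.approx(boundary_lrt_oracle(k), rel=1e-12)
        assert res.carriers_cases == k and res.carriers_controls == 0

    def test_capped_iterative_fit_approaches_boundary(self):
        """Cross-check: maximizing the logistic likelihood numerically with
        a large coefficient cap approaches the analytic boundary LRT."""
        from scipy.optimize import minimize
        k = 7
        x = np.array([1 / k] * k + [0.0] * 6 + [0.0] * 34)
        y = np.array([1.0] * 13 + [0.0] * 34)

        def nll(params):
            eta = params[0] + params[1] * x
            return float(np.sum(np.log1p(np.exp(eta)) - y * eta))

        fit = minimize(nll, x0=[0.0, 0.0], method="L-BFGS-B",
                       bounds=[(-50, 50), (-4000, 4000)])
        ll0 = 13 * math.log(13 / 47) + 34 * math.log(34 / 47)
        lrt_capped = 2 * (-fit.fun - ll0)
        assert lrt_capped == pytest.approx(boundary_lrt_oracle(7), rel=1e-3)

    def test_non_separated_fit_matches_direct_optimizer(self):
        """For an overlapping dataset the LRT equals a direct numerical
        maximization of the logistic likelihood."""
        from scipy.optimize import minimize
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.uniform(0, 0.5, 13) + 0.2, rng.uniform(0, 0.5, 34)])
        y = np.array([1.0] * 13 + [0.0] * 34)
        lrt, sep = logistic_lrt(x, y)
        assert not sep

        def nll(params):
            eta = params[0] + params[1] * x
            return float(np.sum(np.log1p(np.exp(eta)) - y * eta))

        fit = minimize(nll, x0=[0.0, 0.0], method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12})
        ll0 = 13 * math.log(13 / 47) + 34 * math.log(34 / 47)
        assert lrt == pytest.approx(2 * (-fit.fun - ll0), abs=1e-5)

    @pytest.mark.parametrize("scale", [0.01, 1.0, 250.0])
    def test_scale_invariance(self, scale):
        """Rescaling all proportions by a positive constant leaves the
        statistic unchanged, separated or not."""
        labels = [True] * 13 + [False] * 34
        x_sep = np.array([1 / 7] * 7 + [0.0] * 40)
        x_mix = np.array([0.3, 0.2, 0.2, 0.1] + [0.0] * 9 + [0.1] * 5 + [0.0] * 29)
        for x in (x_sep, x_mix):
            base = rvt1_test(x, labels).lrt_statistic
            scaled = rvt1_test(x * scale, labels).lrt_statistic
            assert scaled == pytest.approx(base, rel=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            logistic_lrt(np.array([0.1, 0.2]), np.array([1.0, 1.0]))

    def test_type_one_error_on_null_genes(self):
        """On 500 null genes the RVT1 rejection rate at alpha 0.05 stays
        within (or below) the binomial 99% envelope of 0.05 — the test is
        conservative for sparse carrier counts."""
        rng = np.random.default_rng(11)
        labels = [True] * 13 + [False] * 34
        hits = 0
        for _ in range(500):
            freq = rng.uniform(0.01, 0.2)
            carriers = rng.random(47) < freq
            x = np.where(carriers, 1.0 / rng.integers(1, 6), 0.0)
            if np.ptp(x) == 0:
                continue
            res = rvt1_test(x, labels)
            hits += res.p_value < 0.05
        upper = 0.05 + 2.576 * math.sqrt(0.05 * 0.95 / 500)
        assert hits / 500 <= upper


class TestVariantScan:
    def make_scan_cohort(self, carrier_counts):
        n = len(carrier_counts)
        variants = [VariantKey("chr1", 100 + j, "A", "G") for j in range(n)]
        case = np.zeros((13, n), dtype=np.int8)
        for j, k in enumerate(carrier_counts):
            case[:k, j] = 1
        cohort = make_cohort(case, np.zeros((34, n)), variants=variants)
        return cohort, variants

    def test_four_carriers_vs_empty_panel(self):
        cohort, variants = self.make_scan_cohort([4])
        panel = FrequencyPanel({}, 379)
        results = variant_enrichment_scan(variants, cohort, panel)
        r = results[0]
        assert (r.case_carriers, r.n_cases, r.panel_carriers, r.n_panel) \
            == (4, 13, 0, 379)
        assert r.p_value == pytest.approx(7.379726228258153e-07, rel=1e-9)
        assert r.p_value < MultipleTestingConfig(0.05, 13892).threshold

    def test_empty_input(self):
        cohort, _ = self.make_scan_cohort([1])
        assert variant_enrichment_scan([], cohort, FrequencyPanel({}, 379)) == []

    def test_results_sorted_by_p(self):
        cohort, variants = self.make_scan_cohort([1, 4, 2])
        results = variant_enrichment_scan(variants, cohort, FrequencyPanel({}, 379))
        assert [r.case_carriers for r in results] == [4, 2, 1]


class TestBurdenScan:
    def test_spiked_gene_ranks_first(self, sim_bundle):
        from extremevar.consequence import annotate_cohort, protein_altering_by_gene
        from extremevar.filters import BURDEN_TEST_STAGES, FilterConfig, run_cascade
        b = sim_bundle
        cohort, genome = b["cohort"], b["genome"]
        calls = annotate_cohort(cohort, genome.models, genome.sequences)
        index = protein_altering_by_gene(calls)
        platform = cohort.subset_samples(
            cohort.samples_with_label("platform_control"))
        pa = sorted({v for vs in index.values() for v in vs})
        retained, _ = run_cascade(pa, cohort, b["panel"], b["known"], platform,
                                  FilterConfig(), stages=BURDEN_TEST_STAGES)
        rset = set(retained)
        gene_sites = {g: sorted(vs & rset) for g, vs in index.items() if vs & rset}
        results = burden_scan(cohort, gene_sites)
        assert results[0].gene_symbol == "GENE0010"
        assert results[0].carriers_cases == 7
        assert results[0].p_value == pytest.approx(3.3307074955525593e-06, rel=1e-6)

    def test_empty(self):
        cohort, _ = TestVariantScan().make_scan_cohort([1])
        assert burden_scan(cohort, {}) == []


class TestRecessiveScan:
    def make(self, per_sample_counts):
        """One gene, two sites; per_sample_counts rows are (site1, site2)."""
        case_rows, ctrl_rows = per_sample_counts
        variants = [VariantKey("chr1", 100, "A", "G"),
                    VariantKey("chr1", 200, "C", "T")]
        cohort = make_cohort(case_rows, ctrl_rows, variants=variants)
        return cohort, {"G": variants}

    def test_no_two_plus_gives_p_one(self):
        cohort, gs = self.make((np.zeros((13, 2)), np.zeros((34, 2))))
        res = recessive_scan(cohort, gs)[0]
        assert res.p_value == 1.0

    def test_three_cases_hypergeometric(self):
        case = np.zeros((13, 2));  case[:3] = 1  # compound het: 1 + 1
        cohort, gs = self.make((case, np.zeros((34, 2))))
        res = recessive_scan(cohort, gs)[0]
        assert (res.cases_with_two_plus, res.controls_with_two_plus) == (3, 0)
        assert res.p_value == pytest.approx(286 / 16215, rel=1e-9)

    def test_homozygote_counts_as_two(self):
        case = np.zeros((13, 2));  case[0, 0] = 2
        cohort, gs = self.make((case, np.zeros((34, 2))))
        res = recessive_scan(cohort, gs)[0]
        assert res.cases_with_two_plus == 1

    def test_nocall_contributes_zero(self):
        case = np.zeros((13, 2));  case[0, 0] = 1;  case[0, 1] = NOCALL
        cohort, gs = self.make((case, np.zeros((34, 2))))
        res = recessive_scan(cohort, gs)[0]
        assert res.cases_with_two_plus == 0


class TestAlleleBurdenTest:
    def test_followup_comparison(self):
        """8 carrier alleles of 198 vs 213 of 8600: P = 0.17 to 2 d.p."""
        p = allele_burden_test(8, 198, 213, 8600)
        assert p == pytest.approx(0.1691710054, rel=1e-6)
        assert round(p, 2) == 0.17

    def test_equal_frequencies_give_one(self):
        assert allele_burden_test(5, 100, 50, 1000) == pytest.approx(1.0)

    def test_small_table_enumeration(self):
        p = allele_burden_test(2, 20, 0, 20)
        assert p == pytest.approx(enum_fisher(2, 20, 0, 20, "two"), rel=1e-9)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            allele_burden_test(0, 0, 1, 10)


class TestPowerCalculators:
    def test_variant_level(self):
        thr = MultipleTestingConfig(0.05, 13892).threshold
        assert min_detectable_carriers_variant(13, 379, thr) == 4
        assert min_detectable_carriers_variant(13, 379, 1.0) == 1
        # boundary around the k=3 p-value of 2.87e-5
        assert min_detectable_carriers_variant(13, 379, 2.8e-5) == 4
        assert min_detectable_carriers_variant(13, 379, 2.9e-5) == 3

    def test_gene_level(self):
        thr = MultipleTestingConfig(0.05, 10508).threshold
        assert min_detectable_carriers_gene(13, 34, thr) == 7
        assert min_detectable_carriers_gene(13, 34, 1.0) == 1
        # the k=6 boundary p is 2.26e-5, so thresholds below it require 7
        assert min_detectable_carriers_gene(13, 34, 2e-5) == 7
        assert min_detectable_carriers_gene(13, 34, 2.3e-5) == 6

    def test_unattainable_reported(self):
        assert min_detectable_carriers_variant(2, 10, 1e-9) is None

    def test_power_prediction_matches_simulation(self):
        """Spiked cohorts at the predicted minimum detectable carrier
        count are detected in every replicate (the boundary LRT is
        deterministic given carrier counts)."""
        from extremevar.synthetic_data import (SimulationConfig, generate_genome,
                                               simulate_cohort, simulate_panel)
        from extremevar.consequence import annotate_cohort, protein_altering_by_gene
        thr = MultipleTestingConfig(0.05, 10508).threshold
        k = min_detectable_carriers_gene(13, 34, thr)
        detected = 0
        n_rep = 5
        for seed in range(n_rep):
            # the power statement is conditional on zero control carriers,
            # so every non-spiked site is left novel (monomorphic)
            cfg = SimulationConfig(seed=100 + seed, n_genes=8,
                                   spike=(("GENE0003", k, 0),),
                                   nocall_site_fraction=0.0,
                                   false_rare_call_rate=0.0,
                                   common_known_fraction=0.0,
                                   novel_rare_fraction=1.0)
            genome = generate_genome(cfg)
            panel, known, site_truth = simulate_panel(cfg, genome)
            cohort, _ = simulate_cohort(cfg, panel, genome, site_truth)
            calls = annotate_cohort(cohort, genome.models, genome.sequences)
            index = protein_altering_by_gene(calls)
            rare = {g: sorted(v for v in vs if panel.frequency(v) < 0.015)
                    for g, vs in index.items()}
            rare = {g: vs for g, vs in rare.items() if vs}
            results = burden_scan(cohort, rare, threshold=thr)
            top = results[0]
            detected += (top.gene_symbol == "GENE0003" and top.p_value < thr)
        assert detected == n_rep
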