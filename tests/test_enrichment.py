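"""De novo burden: depth correction, Poisson test, FDR, PPV, sextiles, CIs."""

import math

import numpy as np
import pandas as pd
import pytest

from splicesel import (
    compute_ppv, depth_factor, diagnostic_proportion, enrichment_table,
    expected_dnms, fdr_adjust, pli_sextile_enrichment, poisson_burden_test,
    poisson_exact_ci, ppv_diagnosis_correlation, wilson_ci_cc,
)


class TestDepthFactor:
    @pytest.mark.parametrize("d,expected", [
        (0.5, 0.119),
        (0.0, 0.119),
        (math.e, 0.119 + 0.204),
        (49.999, 0.119 + 0.204 * math.log(49.999)),
        (50.0, 1.0),
        (60.0, 1.0),
        (1.0, 0.119),  # log branch, continuous with the flat branch
    ])
    def test_branch_values(self, d, expected):
        assert depth_factor(d) == pytest.approx(expected, abs=1e-12)

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            depth_factor(-0.1)

    def test_factor_in_unit_interval_and_monotone(self):
        grid = np.linspace(0, 80, 4001)
        f = np.array([depth_factor(d) for d in grid])
        assert ((f > 0) & (f <= 1)).all()
        assert (np.diff(f) >= -1e-15).all()


class TestExpectedDnms:
    def _changes(self, depth):
        return pd.DataFrame({"context": ["ACA"], "alt": ["T"], "depth": [depth]})

    def test_well_covered_site_arithmetic(self, rates):
        df = self._changes(60.0)
        r = rates.rate("ACA", "T")
        out = expected_dnms(df, rates, n_trios=7833)
        assert out["expected"].iloc[0] == pytest.approx(2 * 7833 * r, rel=1e-12)

    def test_low_coverage_applies_flat_factor(self, rates):
        r = rates.rate("ACA", "T")
        out = expected_dnms(self._changes(0.5), rates, n_trios=7833)
        assert out["expected"].iloc[0] == pytest.approx(2 * 7833 * r * 0.119, rel=1e-12)

    def test_expectation_is_additive_over_classes(self, study):
        total = study.expected["expected"].sum()
        by_class = study.expected.groupby("class")["expected"].sum().sum()
        assert by_class == pytest.approx(total, rel=1e-12)

    def test_missing_context_is_an_error(self, rates):
        df = pd.DataFrame({"context": ["NNN"], "alt": ["T"], "depth": [60.0]})
        with pytest.raises(KeyError):
            expected_dnms(df, rates, n_trios=10)


def poisson_two_sided_oracle(observed, lam):
    """Independent pmf-enumeration oracle using the multiplicative recurrence."""
    terms = []
    p = math.exp(-lam)
    k = 0
    while k <= max(observed, lam) + 20 * math.sqrt(lam) + 100:
        terms.append(p)
        k += 1
        p = p * lam / k
    p_obs = terms[observed]
    return min(1.0, sum(t for t in terms if t <= p_obs * (1 + 1e-10)))


class TestPoissonBurden:
    def test_observed_at_mode_gives_p_one(self):
        assert poisson_burden_test(3, 3.5) == 1.0

    def test_five_observed_one_expected(self):
        # all k >= 5 qualify and no k <= 4 does: p = 1 - CDF(4; 1)
        assert poisson_burden_test(5, 1.0) == pytest.approx(3.6598e-3, rel=1e-3)

    def test_zero_observed_tiny_expectation_tends_to_one(self):
        assert poisson_burden_test(0, 1e-12) == pytest.approx(1.0, abs=1e-9)

    def test_matches_enumeration_oracle(self):
        for lam in [0.1, 0.5, 1.0, 3.5, 7.0, 15.0, 30.0]:
            for obs in [0, 1, 2, 3, 5, 8, 13, 21, 40, 100]:
                assert poisson_burden_test(obs, lam) == pytest.approx(
                    poisson_two_sided_oracle(obs, lam), abs=1e-12
                ), (obs, lam)

    def test_nonpositive_expectation_rejected(self):
        with pytest.raises(ValueError):
            poisson_burden_test(1, 0.0)


def bh_stepup_oracle(p):
    """Brute-force Benjamini-Hochberg step-up."""
    p = list(p)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adj = [None] * n
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


class TestFdr:
    def test_single_p_unchanged(self):
        assert fdr_adjust([0.2])[0] == 0.2

    def test_hand_example(self):
        np.testing.assert_allclose(fdr_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_ones_stay_ones(self):
        np.testing.assert_allclose(fdr_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_matches_brute_force_stepup(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            p = rng.random(rng.integers(1, 51))
            np.testing.assert_allclose(fdr_adjust(p), bh_stepup_oracle(p), atol=1e-12)

    def test_adjusted_at_least_raw_and_order_preserving(self):
        rng = np.random.default_rng(5)
        p = rng.random(40)
        adj = fdr_adjust(p)
        assert (adj >= p - 1e-15).all()
        assert (np.diff(adj[np.argsort(p)]) >= -1e-15).all()


class TestPpv:
    @pytest.mark.parametrize("fold,expected", [
        (9.29, 0.89), (10.0, 0.90), (3.46, 0.71), (1.86, 0.46),
    ])
    def test_printed_fold_enrichments(self, fold, expected):
        assert round(compute_ppv(fold, 1.0), 2) == pytest.approx(expected)

    def test_observed_below_expected_clamps_to_zero(self):
        assert compute_ppv(3, 5.0) == 0.0

    def test_zero_observed_is_undefined(self):
        assert math.isnan(compute_ppv(0, 1.0))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            compute_ppv(1, 0.0)
        with pytest.raises(ValueError):
            compute_ppv(-1, 1.0)


class TestEnrichmentTable:
    def test_aggregation_and_family_wide_fdr(self, study):
        tab = enrichment_table(study.dnms, study.expected)
        assert tab["observed"].sum() == len(study.dnms)
        assert tab["expected"].sum() == pytest.approx(study.expected["expected"].sum())
        assert (tab["p_fdr"] >= tab["p_raw"] - 1e-15).all()

    def test_fold_recovery_in_enriched_cells(self, study):
        """Cells given a strong fold in the generator show fold estimates
        above the null cells' (a smoke-level parameter-recovery check)."""
        tab = enrichment_table(study.dnms, study.expected).set_index(["class", "geneset"])
        css_dom = tab.loc[("CSS", "dominant")]
        assert css_dom["observed"] >= 1


class TestSextiles:
    def _per_exon(self, n, rng):
        return pd.DataFrame({
            "gene": [f"G{i}" for i in range(n)],
            "observed": rng.poisson(1.0, n),
            "expected": np.full(n, 1.0),
        })

    def test_partition_sizes_differ_by_at_most_one(self):
        rng = np.random.default_rng(0)
        for n in [97, 100, 6, 61]:
            per_exon = self._per_exon(n, rng)
            gi = pd.DataFrame({"gene": per_exon["gene"], "pLI": rng.random(n)})
            out = pli_sextile_enrichment(per_exon, gi)
            assert out["n_exons"].sum() == n
            assert out["n_exons"].max() - out["n_exons"].min() <= 1

    def test_enrichment_confined_to_high_pli_lands_in_top_sextile(self):
        rng = np.random.default_rng(1)
        n = 300
        gi = pd.DataFrame({"gene": [f"G{i}" for i in range(n)],
                           "pLI": np.linspace(0, 1, n)})
        obs = np.where(gi["pLI"] > 0.9, rng.poisson(8.0, n), rng.poisson(1.0, n))
        per_exon = pd.DataFrame({"gene": gi["gene"], "observed": obs,
                                 "expected": 1.0})
        out = pli_sextile_enrichment(per_exon, gi)
        assert out.iloc[5]["ratio"] > out.iloc[0]["ratio"]

    def test_sextile_boundaries_are_deterministic_under_ties(self):
        per_exon = pd.DataFrame({"gene": [f"G{i}" for i in range(12)],
                                 "observed": 1, "expected": 1.0})
        gi = pd.DataFrame({"gene": per_exon["gene"], "pLI": 0.5})
        a = pli_sextile_enrichment(per_exon, gi)
        b = pli_sextile_enrichment(per_exon.sample(frac=1, random_state=0), gi)
        pd.testing.assert_frame_equal(a, b)


class TestDiagnosticProportion:
    def test_cohort_split_point_estimates(self):
        r = diagnostic_proportion(48, 18)
        assert r["css_percent"] == 73
        assert r["noncss_percent"] == 27

    def test_symmetric_counts(self):
        r = diagnostic_proportion(10, 10)
        assert r["css_percent"] == 50

    def test_ci_matches_r_prop_test(self):
        # frozen from R: prop.test(48, 66) and prop.test(18, 66)
        r = diagnostic_proportion(48, 18)
        assert r["css_ci"][0] == pytest.approx(0.6015854, abs=1e-6)
        assert r["css_ci"][1] == pytest.approx(0.8262571, abs=1e-6)
        assert r["noncss_ci"][0] == pytest.approx(0.1737429, abs=1e-6)
        assert r["noncss_ci"][1] == pytest.approx(0.3984146, abs=1e-6)

    def test_wilson_cc_matches_r_for_clinical_review_counts(self):
        # frozen from R: prop.test(18, 38)
        lo, hi = wilson_ci_cc(18, 38)
        assert lo == pytest.approx(0.3130791, abs=1e-6)
        assert hi == pytest.approx(0.6395032, abs=1e-6)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            diagnostic_proportion(0, 0)
        r = diagnostic_proportion(5, 0)
        assert r["css_ci"][1] == 1.0


class TestPoissonExactCi:
    def test_zero_count_lower_bound_is_zero(self):
        lo, hi = poisson_exact_ci(0)
        assert lo == 0.0
        assert hi == pytest.approx(3.688879, abs=1e-5)  # -ln(0.025) * ... chi2

    def test_interval_covers_count(self):
        for k in [1, 5, 20]:
            lo, hi = poisson_exact_ci(k)
            assert lo < k < hi


class TestCorrelation:
    def test_perfectly_linear(self):
        r, p = ppv_diagnosis_correlation([0.1, 0.5, 0.9], [0.2, 1.0, 1.8])
        assert r == pytest.approx(1.0)

    def test_anti_linear(self):
        r, _ = ppv_diagnosis_correlation([0.1, 0.5, 0.9], [3, 2, 1])
        assert r == pytest.approx(-1.0)

    def test_matches_covariance_oracle(self):
        x = np.array([0.1, 0.3, 0.45, 0.7, 0.95])
        y = np.array([0.05, 0.4, 0.3, 0.8, 0.75])
        r, _ = ppv_diagnosis_correlation(x, y)
        manual = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert r == pytest.approx(manual, abs=1e-12)

    def test_too_few_classes_rejected(self):
        with pytest.raises(ValueError):
            ppv_diagnosis_correlation([0.1, 0.2], [0.3, 0.4])
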