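"""QC gate, normality-gated paired tests, linear models, reference intervals."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from osmoscan.cohort import CohortConfig, simulate_fractions, DonorRecord, simulate_cohort
from osmoscan.errors import CollinearityError, InsufficientDataError, SchemaError
from osmoscan.stats import (
    choose_paired_test,
    fit_index_model,
    paired_compare,
    qc_filter,
    reference_interval,
)


class TestQCFilter:
    def test_threshold_is_five_percent(self):
        df = pd.DataFrame({"donor_id": ["a", "b", "c"], "hypochromic_pct": [2.0, 4.9, 5.1]})
        kept, flags = qc_filter(df)
        assert len(kept) == 2 and flags == ["c"]

    def test_clean_table_passes_unchanged(self):
        df = pd.DataFrame({"hypochromic_pct": [1.0, 2.0]})
        kept, flags = qc_filter(df)
        assert kept.equals(df) and flags == []

    def test_empty_table(self):
        kept, flags = qc_filter(pd.DataFrame({"hypochromic_pct": []}))
        assert len(kept) == 0 and flags == []

    def test_missing_column_is_schema_error(self):
        with pytest.raises(SchemaError):
            qc_filter(pd.DataFrame({"age": [30]}))


class TestNormalityGate:
    def test_normal_differences_select_t(self):
        d = np.random.default_rng(11).normal(size=20)
        assert sps.shapiro(d).pvalue >= 0.05  # independent oracle for this draw
        assert choose_paired_test(d, np.zeros(20)) == "paired_t"

    def test_heavy_tailed_differences_select_wilcoxon(self):
        d = sps.cauchy.rvs(size=50, random_state=np.random.default_rng(11))
        assert sps.shapiro(d).pvalue < 0.05
        assert choose_paired_test(d, np.zeros(50)) == "wilcoxon_signed_rank"

    def test_constant_differences_fall_back_with_warning(self):
        x = np.arange(10.0)
        with pytest.warns(UserWarning):
            assert choose_paired_test(x + 1.0, x) == "wilcoxon_signed_rank"

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            choose_paired_test([1.0, 2.0], [2.0, 1.0])


class TestPairedCompare:
    def test_identical_samples_convention(self):
        x = np.arange(10.0)
        res = paired_compare(x, x.copy())
        assert res.estimate == 0.0 and res.p_value == 1.0

    def test_exact_shift_oriented_x_minus_y(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = paired_compare(x, x + 2.0, test="paired_t")
        assert res.test_name == "paired_t"
        assert res.estimate == pytest.approx(-2.0) and res.p_value < 0.01
        assert res.ci_lo <= res.estimate <= res.ci_hi

    def test_power_to_separate_density_fractions(self):
        """L vs H O_hyper at default offsets rejects for nearly every 13-donor panel."""
        rng = np.random.default_rng(0)
        cfg = CohortConfig()
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            l, h = [], []
            for i in range(13):
                d = DonorRecord(f"D{i}", rng.uniform(20, 60), "F", 137, 41, 89.6, 334, 13.2, 2.0, 0.65)
                s = {x.fraction: x for x in simulate_fractions(d, cfg, rng)}
                l.append(s["L"].indices.o_hyper)
                h.append(s["H"].indices.o_hyper)
            rejections += paired_compare(np.array(l), np.array(h)).p_value < 0.05
        assert rejections / n_rep >= 0.90


class TestFitIndexModel:
    def test_perfect_linear_fit(self):
        df = pd.DataFrame({"age": np.arange(20.0, 60.0), "gender": ["F", "M"] * 20})
        df["o_hyper"] = 2.0 * df.age
        coefs, overall = fit_index_model(df, "o_hyper")
        slope = next(c for c in coefs if c.term == "age")
        assert slope.estimate == pytest.approx(2.0, abs=1e-8) and slope.p_value < 1e-12
        assert overall.test_name == "anova_F"

    def test_rank_deficiency_reported(self):
        df = pd.DataFrame({"age": [30.0] * 10, "age2": [30.0] * 10, "o_hyper": np.arange(10.0)})
        with pytest.raises(CollinearityError):
            fit_index_model(df, "o_hyper", covariates=("age", "age2"))

    def test_missing_column_is_schema_error(self):
        with pytest.raises(SchemaError):
            fit_index_model(pd.DataFrame({"age": [1.0] * 10}), "o_hyper")

    def test_slope_ci_covers_generating_value(self):
        """95% CI coverage of the age slope across simulated cohorts."""
        cover = 0
        n_rep = 60
        for rep in range(n_rep):
            df = simulate_cohort(CohortConfig(n_female=250, n_male=250, beta_age=0.5, seed=1000 + rep))
            coefs, _ = fit_index_model(df, "o_hyper")
            slope = next(c for c in coefs if c.term == "age")
            cover += slope.ci_lo <= 0.5 <= slope.ci_hi
        assert 0.85 <= cover / n_rep <= 1.0

    def test_power_to_detect_strong_age_effect_at_pilot_size(self):
        """When the age effect spans at least twice the residual sd across the
        cohort age range, the pilot-sized model detects it in well over half
        of simulated cohorts."""
        cfg = dict(beta_age=0.5, sigma_ohyper=8.0)  # 0.5 * 43 y >> 2 * 8
        hits = 0
        n_rep = 60
        for rep in range(n_rep):
            df = simulate_cohort(CohortConfig(seed=300 + rep, **cfg))
            coefs, _ = fit_index_model(df, "o_hyper")
            hits += next(c for c in coefs if c.term == "age").p_value < 0.05
        assert hits / n_rep > 0.5


class TestReferenceInterval:
    def test_quantile_rule_on_1_to_100(self):
        ris = reference_interval(np.arange(1.0, 101.0), np.zeros(100))
        assert ris[0].lo == pytest.approx(3.475) and ris[0].hi == pytest.approx(97.525)
        assert ris[0].n == 100 and ris[0].flag is None

    def test_small_stratum_flagged_undefined(self):
        ris = reference_interval(np.arange(5.0), np.zeros(5), min_n=20)
        assert ris[0].lo is None and ris[0].hi is None and ris[0].flag == "LOW_N"

    def test_stratum_means_order_interval_midpoints(self, rng):
        v1 = rng.normal(440.0, 8.0, 200)
        v2 = rng.normal(460.0, 8.0, 200)
        ris = reference_interval(
            np.concatenate([v1, v2]), np.array(["lo"] * 200 + ["hi"] * 200)
        )
        mid = {r.stratum: (r.lo + r.hi) / 2 for r in ris}
        assert mid["lo"] < mid["hi"]

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(a=st.floats(0.1, 50.0), b=st.floats(-100.0, 100.0))
    def test_affine_equivariance(self, a, b):
        values = np.linspace(400.0, 480.0, 60)
        base = reference_interval(values, np.zeros(60))[0]
        scaled = reference_interval(a * values + b, np.zeros(60))[0]
        assert scaled.lo == pytest.approx(a * base.lo + b, rel=1e-9, abs=1e-7)
        assert scaled.hi == pytest.approx(a * base.hi + b, rel=1e-9, abs=1e-7)
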