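import math
from dataclasses import replace

import numpy as np
import pytest

from tropref.errors import ConfigurationError, DomainError
from tropref.quantiles import percentile_point
from tropref.synthetic import (
    AGE_GROUPS,
    GeneratorParams,
    TroponinKnot,
    _CAL_MEDIAN,
    _troponin_mu_sigma,
    generate_cohort,
    stratum_params,
    true_stratum_quantile,
)


def degenerate_params(mu=math.log(10.0), n=500):
    """Single knot, zero noise, no disease, no renal coupling."""
    knot = (TroponinKnot(age=50.0, mu_log=mu, sigma_log=0.0),)
    return GeneratorParams(
        n_subjects=n,
        troponin_knots={"F": knot, "M": knot},
        cardiac_disease_prevalence=0.0,
        renal_troponin_coupling=0.0,
        seed=7,
    )


class TestGenerateCohort:
    def test_degenerate_noise_gives_constant(self):
        cohort = generate_cohort(degenerate_params())
        np.testing.assert_allclose(cohort["troponin_ngL"], 10.0, rtol=1e-12)

    def test_determinism(self, default_params):
        a = generate_cohort(replace(default_params, n_subjects=800))
        b = generate_cohort(replace(default_params, n_subjects=800))
        assert a.equals(b)
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_row_count_and_schema(self, default_cohort, default_params):
        assert len(default_cohort) == default_params.n_subjects
        assert default_cohort["sex"].isin(["F", "M"]).all()
        assert (default_cohort["age"].between(20, 80)).all()
        assert (default_cohort["creatinine_umolL"] > 0).all()
        assert (default_cohort["ntprobnp_ngL"] >= 0).all()
        assert (default_cohort["hba1c_mmolmol"] > 0).all()

    def test_floor_invariant(self, default_cohort, default_params):
        assert default_cohort["troponin_ngL"].min() >= default_params.detection_floor

    def test_floor_dominated_female_median(self, default_params):
        params = stratum_params(default_params, "F", 20, 40, n=2000, seed=3)
        cohort = generate_cohort(params)
        assert percentile_point(cohort["troponin_ngL"], 50) == 3.0

    def test_invalid_params_name_field(self):
        with pytest.raises(ConfigurationError, match="female_fraction"):
            GeneratorParams(female_fraction=1.5)
        with pytest.raises(ConfigurationError, match="age_group_weights"):
            GeneratorParams(age_group_weights=(0.5, 0.5, 0.1, 0.0, 0.0))
        with pytest.raises(ConfigurationError, match="detection_floor"):
            GeneratorParams(detection_floor=0)
        with pytest.raises(ConfigurationError, match="troponin_knots"):
            GeneratorParams(
                troponin_knots={
                    "F": (TroponinKnot(50, 1.0, -0.1),),
                    "M": (TroponinKnot(50, 1.0, 0.1),),
                }
            )


class TestTrueStratumQuantile:
    def test_degenerate_any_percentile(self):
        params = degenerate_params()
        for p in (1, 50, 99):
            for sex in ("F", "M"):
                assert true_stratum_quantile(params, sex, 20, 80, p) == pytest.approx(
                    10.0, abs=1e-6
                )

    def test_floor_dominated_median_is_floor(self, default_params):
        assert true_stratum_quantile(default_params, "F", 20, 40, 50) == 3.0

    def test_empty_age_range(self, default_params):
        with pytest.raises(DomainError):
            true_stratum_quantile(default_params, "F", 50, 50, 50)

    def test_monte_carlo_oracle_male_71_80_p99(self, default_params):
        analytic = true_stratum_quantile(default_params, "M", 70, 80, 99)
        rng = np.random.default_rng(42)
        n = 10_000_000
        ages = rng.uniform(70, 80, n)  # single group: restricted density uniform
        mu, sg = _troponin_mu_sigma(default_params, "M", ages)
        log_tnt = (
            mu
            + sg * rng.standard_normal(n)
            + default_params.renal_troponin_coupling * rng.standard_normal(n)
        )
        sample = np.maximum(np.exp(log_tnt), default_params.detection_floor)
        mc = np.percentile(sample, 99)
        assert analytic == pytest.approx(mc, rel=0.005)

    def test_stochastic_ordering_in_mu(self, default_params):
        bumped = {
            sex: tuple(
                TroponinKnot(k.age, k.mu_log + 0.15, k.sigma_log) for k in knots
            )
            for sex, knots in default_params.troponin_knots.items()
        }
        higher = replace(default_params, troponin_knots=bumped)
        for sex in ("F", "M"):
            for lo, hi in AGE_GROUPS:
                for p in (25, 50, 99):
                    assert true_stratum_quantile(
                        higher, sex, lo, hi, p
                    ) >= true_stratum_quantile(default_params, sex, lo, hi, p)

    def test_invalid_percentile(self, default_params):
        with pytest.raises(DomainError):
            true_stratum_quantile(default_params, "M", 20, 80, 0)
        with pytest.raises(DomainError):
            true_stratum_quantile(default_params, "M", 20, 80, 100)


class TestCalibration:
    def test_stratum_medians_match_targets(self, filtered_cohorts):
        """Per-sex per-age-group sample medians at the full cohort scale stay
        within 0.5 ng/L of the calibration targets."""
        cohort1, _, _ = filtered_cohorts
        tnt = np.maximum(cohort1["troponin_ngL"].to_numpy(), 3.0)
        ages = cohort1["age"].to_numpy()
        sexes = cohort1["sex"].to_numpy()
        for sex in ("F", "M"):
            for (lo, hi), target in zip(AGE_GROUPS, _CAL_MEDIAN[sex]):
                mask = (sexes == sex) & (ages > lo) & (ages <= hi)
                med = percentile_point(tnt[mask], 50)
                assert med == pytest.approx(target, abs=0.5), (sex, lo, hi)

    def test_cohort1_scale(self, filtered_cohorts):
        _, _, report = filtered_cohorts
        assert 5000 <= report.n_cohort1 <= 5900
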