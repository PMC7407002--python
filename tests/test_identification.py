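"""Free-active rescaling, MAP estimation, population sampling, fixtures."""

import numpy as np
import pytest
from scipy import stats

from basalsim.identification import (
    CLAMP_GRID_MIN,
    FREE_LLOQ,
    POPULATION_MEDIANS,
    ClampDataset,
    EfficacyInputs,
    FitResult,
    PriorSpec,
    day8_concentrations,
    efficacy_ratio,
    generate_clamp_fixtures,
    map_fit,
    population_log_sd,
    read_clamp_datasets,
    rescale_total_to_free,
    sample_population,
    weighted_residuals,
    write_clamp_datasets,
)

#: point-mass "population": every sampled subject is exactly this vector.
#: m1 and CL sit at the prior means so the MAP penalty is centred on truth.
POINT_TRUTH = {"F": (0.69, 1e-9), "kd": (0.0056, 1e-9), "ka": (0.0007, 1e-9),
               "m1": (0.18, 1e-9), "CL": (1.11, 1e-9)}


class TestRescaling:
    def test_free_fraction_product(self):
        assert rescale_total_to_free(100.0) == pytest.approx(2.85)

    def test_identity_at_fraction_one(self):
        assert rescale_total_to_free(37.5, free_fraction=1.0) == 37.5

    def test_lloq_maps_to_free_scale(self):
        assert rescale_total_to_free(12.0) == pytest.approx(0.342)
        assert FREE_LLOQ == pytest.approx(0.342)

    @pytest.mark.parametrize("frac", [0.0, -0.1, 1.2])
    def test_bad_fraction_raises(self, frac):
        with pytest.raises(ValueError):
            rescale_total_to_free(10.0, free_fraction=frac)


class TestEfficacyRatio:
    def test_equal_normalised_efficacy_is_one(self):
        inp = EfficacyInputs(gir_auc_deg=2000.0, gir_auc_gla=1000.0,
                             ins_auc_deg=50.0, ins_auc_gla=25.0)
        assert efficacy_ratio(inp) == pytest.approx(1.0)

    def test_doubling_exposure_halves_ratio(self):
        base = EfficacyInputs(1000.0, 1000.0, 20.0, 20.0)
        doubled = EfficacyInputs(1000.0, 1000.0, 40.0, 20.0)
        assert efficacy_ratio(doubled) == pytest.approx(efficacy_ratio(base) / 2)

    def test_reciprocal_symmetry(self, rng):
        for _ in range(20):
            g1, g2, i1, i2 = rng.uniform(0.1, 100.0, size=4)
            fwd = efficacy_ratio(EfficacyInputs(g1, g2, i1, i2))
            rev = efficacy_ratio(EfficacyInputs(g2, g1, i2, i1))
            assert fwd * rev == pytest.approx(1.0, rel=1e-12)

    def test_nonpositive_auc_rejected(self):
        with pytest.raises(ValueError):
            EfficacyInputs(0.0, 1.0, 1.0, 1.0)


class TestMapFit:
    def test_noise_free_self_consistency(self):
        """Noise-free data generated at a known vector is recovered to <1%."""
        ds = generate_clamp_fixtures(1, truth=POINT_TRUTH, dose_U_per_kg=0.4,
                                     error_cv=0.0, seed=3)[0]
        fit = map_fit(ds, n_starts=6, seed=0)
        assert fit.converged
        for name, (value, _) in POINT_TRUTH.items():
            assert fit.estimates[name] == pytest.approx(value, rel=0.01), name

    def test_tight_priors_pin_penalised_parameters(self):
        """With near-degenerate prior dispersion, m1 and CL collapse onto the
        prior means regardless of the data."""
        truth = dict(POINT_TRUTH, m1=(0.16, 1e-9), CL=(1.00, 1e-9))
        ds = generate_clamp_fixtures(1, truth=truth, dose_U_per_kg=0.4,
                                     error_cv=0.0, seed=3)[0]
        priors = PriorSpec(log_sd={"m1": 1e-4, "CL": 1e-4})
        fit = map_fit(ds, priors=priors, n_starts=4, seed=0)
        assert fit.estimates["m1"] == pytest.approx(0.18, rel=1e-3)
        assert fit.estimates["CL"] == pytest.approx(1.11, rel=1e-3)

    def test_all_censored_raises(self):
        times = np.asarray(CLAMP_GRID_MIN)
        ds = ClampDataset("S1", 0.4, times, np.full(times.size, 0.1),
                          np.full(times.size, 0.02))
        with pytest.raises(ValueError):
            map_fit(ds)

    def test_precision_reported(self):
        ds = generate_clamp_fixtures(1, truth=POINT_TRUTH, dose_U_per_kg=0.4,
                                     error_cv=0.06, seed=9)[0]
        fit = map_fit(ds, n_starts=6, seed=0)
        assert set(fit.cv_percent) == {"F", "kd", "ka", "m1", "CL"}
        assert all(v >= 0 or np.isnan(v) for v in fit.cv_percent.values())


class TestWeightedResiduals:
    def test_perfect_fit_gives_zeros(self):
        ds = generate_clamp_fixtures(1, truth=POINT_TRUTH, error_cv=0.0,
                                     seed=3)[0]
        fit = map_fit(ds, n_starts=6, seed=0)
        r = weighted_residuals(ds, fit)
        assert np.max(np.abs(r)) < 0.05

    def test_one_sigma_offset_gives_plus_one(self):
        """Data lying exactly sigma above the model prediction."""
        truth = {k: (v, 1e-9) for k, v in POPULATION_MEDIANS.items()}
        ds = generate_clamp_fixtures(1, truth=truth, error_cv=0.0, seed=3)[0]
        fit = FitResult(estimates=dict(POPULATION_MEDIANS), cv_percent={},
                        objective=0.0, converged=True, n_used=ds.conc.size)
        shifted = ClampDataset(ds.subject_id, ds.dose_U_per_kg, ds.times_min,
                               ds.conc + ds.sd, ds.sd)
        r = weighted_residuals(shifted, fit)
        np.testing.assert_allclose(r, 1.0, atol=1e-9)

    def test_unit_noise_residual_statistics(self):
        """Residuals of data at truth with known noise behave standard-normal."""
        truth = {k: (v, 1e-9) for k, v in POPULATION_MEDIANS.items()}
        ds = generate_clamp_fixtures(1, truth=truth, error_cv=0.06, seed=21)[0]
        fit = FitResult(estimates=dict(POPULATION_MEDIANS), cv_percent={},
                        objective=0.0, converged=True, n_used=ds.conc.size)
        r = weighted_residuals(ds, fit)
        assert abs(r.mean()) < 0.5
        assert 0.5 < r.std(ddof=1) < 1.5


class TestPopulationSampling:
    def test_determinism(self):
        a = sample_population(50, seed=42)
        b = sample_population(50, seed=42)
        assert all(x == y for x, y in zip(a, b))

    def test_median_recovery_large_sample(self):
        pop = sample_population(10000, seed=8)
        f_median = np.median([p.F for p in pop])
        assert f_median == pytest.approx(0.69, rel=0.02)

    def test_marginals_are_lognormal(self):
        pop = sample_population(2000, seed=8)
        log_sd = population_log_sd()
        for name in ("F", "kd", "ka"):
            z = np.log([getattr(p, name) for p in pop])
            z = (z - np.log(POPULATION_MEDIANS[name])) / log_sd[name]
            assert stats.kstest(z, "norm").pvalue > 0.01

    def test_invalid_correlation_rejected(self):
        bad = np.eye(5)
        bad[0, 1] = bad[1, 0] = 2.0  # not PSD
        with pytest.raises(ValueError):
            sample_population(10, correlation=bad, seed=0)


class TestClampFixtures:
    def test_zero_error_equals_prediction(self, median_pk):
        truth = {k: (v, 1e-9) for k, v in POPULATION_MEDIANS.items()}
        ds = generate_clamp_fixtures(1, truth=truth, dose_U_per_kg=0.4,
                                     error_cv=0.0, seed=5)[0]
        expected = day8_concentrations(median_pk, 400.0, ds.times_min)
        # truth marginals carry a vanishing but nonzero dispersion
        np.testing.assert_allclose(ds.conc, expected, rtol=1e-6)

    def test_dose_linearity(self):
        truth = {k: (v, 1e-9) for k, v in POPULATION_MEDIANS.items()}
        lo = generate_clamp_fixtures(1, truth=truth, dose_U_per_kg=0.4,
                                     error_cv=0.0, seed=5)[0]
        hi = generate_clamp_fixtures(1, truth=truth, dose_U_per_kg=0.8,
                                     error_cv=0.0, seed=5)[0]
        np.testing.assert_allclose(hi.conc, 2.0 * lo.conc, rtol=1e-9)

    def test_peak_sample_near_expected_timepoints(self):
        """The day-8 profile peaks around the 8-10 h protocol samples."""
        truth = {k: (v, 1e-9) for k, v in POPULATION_MEDIANS.items()}
        ds = generate_clamp_fixtures(1, truth=truth, dose_U_per_kg=0.4,
                                     error_cv=0.0, seed=5)[0]
        t_peak = ds.times_min[np.argmax(ds.conc)]
        assert t_peak in (480.0, 600.0)

    def test_round_trip_io(self, tmp_path):
        datasets = generate_clamp_fixtures(3, dose_U_per_kg=0.4,
                                           error_cv=0.06, seed=13)
        path = tmp_path / "clamp.csv"
        write_clamp_datasets(path, datasets)
        back = read_clamp_datasets(path)
        assert len(back) == 3
        for a, b in zip(datasets, back):
            assert a.subject_id == b.subject_id
            np.testing.assert_allclose(a.conc, b.conc)
            np.testing.assert_allclose(a.sd, b.sd)
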