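import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import screenlight as sl
from screenlight.gsd import (GSDFitError, GrainMeasurementSet, read_weighted,
                             stats_report, write_diameters, read_diameters)
from screenlight.samples import SAMPLES, Activator


def mset(diams):
    return GrainMeasurementSet("UKL65/UF-R1", Activator.TB, np.asarray(diams, float))


class TestDescriptiveStats:
    def test_constant_sample(self):
        st_ = sl.compute_descriptive_stats(mset([2, 2, 2, 2]))
        assert st_.mean_um == 2.0
        assert st_.sd_um == 0.0
        assert st_.mode_um == 2.0

    def test_symmetric_no_repeats(self):
        st_ = sl.compute_descriptive_stats(mset([1, 2, 3]))
        assert st_.mean_um == 2.0
        assert st_.median_um == 2.0
        assert st_.range_um == 2.0
        assert st_.mode_um is None

    def test_identities(self):
        rng = np.random.default_rng(5)
        st_ = sl.compute_descriptive_stats(mset(rng.lognormal(0.3, 0.4, 50)))
        assert st_.range_um == pytest.approx(st_.max_um - st_.min_um)
        assert st_.standard_error_um == pytest.approx(st_.sd_um / np.sqrt(st_.n))
        assert st_.variance_um2 == pytest.approx(st_.sd_um**2)
        assert st_.min_um <= st_.median_um <= st_.max_um

    def test_spreadsheet_moment_convention(self):
        # n-corrected skewness/kurtosis as in common spreadsheet software
        d = np.array([1.0, 1.2, 1.3, 1.9, 3.5])
        st_ = sl.compute_descriptive_stats(mset(d))
        n, mean, s = 5, d.mean(), d.std(ddof=1)
        z = (d - mean) / s
        skew = n / ((n - 1) * (n - 2)) * np.sum(z**3)
        kurt = (n * (n + 1) / ((n - 1) * (n - 2) * (n - 3)) * np.sum(z**4)
                - 3 * (n - 1) ** 2 / ((n - 2) * (n - 3)))
        assert st_.skewness == pytest.approx(skew)
        assert st_.kurtosis == pytest.approx(kurt)

    def test_rejects_insufficient_or_invalid(self):
        with pytest.raises(ValueError):
            mset([1.0])
        with pytest.raises(ValueError):
            mset([1.0, -2.0])

    def test_synthetic_sample_matches_published_stats(self):
        rng = np.random.default_rng(11)
        ms = sl.generate_sample_measurements("UKL65/UF-R1", 100_000, rng)
        st_ = sl.compute_descriptive_stats(ms)
        assert st_.mean_um == pytest.approx(1.232, rel=0.02)
        assert st_.sd_um == pytest.approx(0.424, rel=0.10)


class TestFit:
    def test_small_grain_tb_target(self):
        g = sl.fit_truncated_lognormal(SAMPLES["UKL65/UF-R1"])
        assert 1.220 <= g.mean() <= 1.244
        assert g.sd() == pytest.approx(0.424, rel=0.05)

    def test_zero_sd_gives_spike(self):
        class T:
            mean_um, sd_um, min_um, max_um = 2.0, 0.0, 1.0, 3.0
        g = sl.fit_truncated_lognormal(T())
        assert g.kind == "empirical"
        assert float(g.ppf(0.5)) == 2.0

    def test_round_trip_all_samples(self):
        # sample 1e5 diameters from each fit and recompute the stats
        for sid, rec in SAMPLES.items():
            g = sl.fit_sample(sid)
            d = g.sample(100_000, np.random.default_rng(3))
            assert d.mean() == pytest.approx(rec.mean_um, rel=0.02), sid
            assert d.std(ddof=1) == pytest.approx(rec.sd_um, rel=0.10), sid
            assert d.min() >= rec.min_um and d.max() <= rec.max_um, sid

    def test_infeasible_sd_reports_best(self):
        class T:
            mean_um, sd_um, min_um, max_um = 2.0, 5.0, 1.9, 2.1
        with pytest.raises(GSDFitError, match="best achievable"):
            sl.fit_truncated_lognormal(T())


class TestSampling:
    def test_spike_always_returns_atom(self, spike_gsd):
        rng = np.random.default_rng(0)
        assert all(sl.sample_diameter(spike_gsd, rng) == 3.0 for _ in range(20))

    def test_empirical_two_atoms_mean(self):
        g = sl.GrainSizeDistribution(kind="empirical",
                                     support_um=np.array([1.0, 3.0]),
                                     weights=np.array([0.5, 0.5]))
        d = g.sample(100_000, np.random.default_rng(1))
        se = 1.0 / np.sqrt(100_000)  # atoms are +-1 from the mean
        assert abs(d.mean() - 2.0) < 3 * se

    def test_fitted_large_eu_mean(self):
        g = sl.fit_sample("UKL63/N-R1")
        d = g.sample(100_000, np.random.default_rng(2))
        se = 1.170 / np.sqrt(100_000)
        assert abs(d.mean() - 3.644) < 3 * se

    def test_reproducible_from_seed(self, tb_small_gsd):
        a = tb_small_gsd.sample(1000, np.random.default_rng(42))
        b = tb_small_gsd.sample(1000, np.random.default_rng(42))
        np.testing.assert_array_equal(a, b)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(mu=st.floats(-0.5, 1.5), sigma=st.floats(0.05, 1.0),
           q=st.floats(0, 1))
    def test_parametric_ppf_respects_truncation(self, mu, sigma, q):
        g = sl.GrainSizeDistribution(kind="truncated_lognormal", mu=mu,
                                     sigma=sigma, lower_um=0.5, upper_um=6.0)
        assert 0.5 <= float(g.ppf(q)) <= 6.0


class TestGenerateMeasurements:
    def test_counted_grain_fixture(self):
        ms = sl.generate_sample_measurements("UKL65/UF-R1", rng=np.random.default_rng(0))
        assert ms.n == 83
        assert ms.diameters_um.min() >= 0.566
        assert ms.diameters_um.max() <= 3.492

    def test_minimal_n(self):
        assert sl.generate_sample_measurements(
            "UKL65/UF-R1", 2, np.random.default_rng(0)).n == 2

    def test_positive_skew_of_fitted_surrogate(self):
        ms = sl.generate_sample_measurements("UKL59CF/S-R1", 10_000,
                                             np.random.default_rng(4))
        assert sl.compute_descriptive_stats(ms).skewness > 0

    def test_unknown_code_lists_valid(self):
        with pytest.raises(KeyError, match="UKL65/UF-R1"):
            sl.generate_sample_measurements("nope", 10, np.random.default_rng(0))


class TestIO:
    def test_diameter_file_round_trip(self, tmp_path):
        d = np.array([1.25, 2.5, 0.75])
        p = tmp_path / "d.txt"
        write_diameters(p, d)
        np.testing.assert_allclose(read_diameters(p), d, atol=1e-6)

    def test_weighted_csv(self, tmp_path):
        p = tmp_path / "w.csv"
        p.write_text("1.0,2\n3.0,2\n")
        g = read_weighted(p)
        assert g.mean() == pytest.approx(2.0)

    def test_stats_report_layout(self):
        ms = sl.generate_sample_measurements("UKL65/UF-R1", 50,
                                             np.random.default_rng(0))
        rep = stats_report({"UKL65/UF-R1": sl.compute_descriptive_stats(ms)})
        assert rep.shape == (12, 1)
        assert rep.index[0] == "Mean grain size (um)"
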