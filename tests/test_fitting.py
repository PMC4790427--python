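"""Estimation: self-consistency of the fit, weighting, distribution
summaries, correlations, Monte Carlo plumbing and sensitivity scans."""

import numpy as np
import pytest
from scipy import stats

from cumoflux.fitting import (
    _Objective,
    correlation_matrix,
    fit,
    monte_carlo,
    sensitivity_scan,
    summarize_distribution,
)
from cumoflux.network import FREE_FLUXES, FluxSet
from cumoflux.synth import AcquisitionSpec, generate_dataset


@pytest.fixture(scope="module")
def clean_bonded(truth):
    spec = AcquisitionSpec(noise_sd_total=0.0, noise_sd_multiplet=0.0)
    return generate_dataset(truth, spec, "bonded")


@pytest.fixture(scope="module")
def base_fit(clean_bonded):
    return fit(clean_bonded, "bonded")


def max_relative_error(estimates, truth):
    return max(abs(getattr(estimates, n) - getattr(truth, n)) / getattr(truth, n)
               for n in FREE_FLUXES)


class TestFit:
    def test_zero_noise_recovers_truth(self, base_fit, truth):
        assert base_fit.success
        assert max_relative_error(base_fit.estimates, truth) < 0.01
        assert base_fit.residual < 1e-6

    def test_positional_variant_uses_six_curves(self, clean_bonded, truth):
        r = fit(clean_bonded, "positional")
        assert r.n_curves == 6
        assert max_relative_error(r.estimates, truth) < 0.01

    def test_perturbed_init_reaches_same_optimum(self, clean_bonded, base_fit, truth):
        init = FluxSet.from_values([v * 1.5 for v in truth.free_values()])
        r = fit(clean_bonded, "bonded", init=init)
        assert max_relative_error(r.estimates, base_fit.estimates) < 0.005

    def test_missing_curves_rejected(self, truth):
        spec = AcquisitionSpec(noise_sd_total=0.0, noise_sd_multiplet=0.0)
        positional_ds = generate_dataset(truth, spec, "positional")
        with pytest.raises(ValueError, match="lacks curves"):
            fit(positional_ds, "bonded")

    def test_fixed_flux_out_of_bounds_rejected(self, clean_bonded):
        with pytest.raises(ValueError, match="bounds"):
            fit(clean_bonded, "bonded", fixed={"vnt": 9.0})


class TestWeighting:
    def test_doubling_sd_halves_residuals(self, truth):
        ds = generate_dataset(truth, AcquisitionSpec(seed=4), "bonded")
        obj = _Objective(ds, "bonded")
        f = FluxSet(0.5, 0.15, 0.05, 0.4, 0.12, 0.25, 0.2)
        r1 = obj.residuals(f)
        obj.sd = obj.sd * 2.0
        r2 = obj.residuals(f)
        assert np.allclose(r2, r1 / 2.0, rtol=1e-12)


class TestDistributionSummary:
    def test_gamma_shape_recovery(self):
        rng = np.random.default_rng(0)
        samples = stats.gamma.rvs(100.0, scale=0.003, size=4000, random_state=rng)
        summ = summarize_distribution(samples)
        assert summ["shape"] == pytest.approx(100.0, rel=0.10)

    def test_fwhm_normal_limit(self):
        """For large shape the gamma is near-Gaussian: FWHM ~ 2.355 sigma."""
        rng = np.random.default_rng(1)
        samples = stats.gamma.rvs(100.0, scale=0.003, size=4000, random_state=rng)
        summ = summarize_distribution(samples)
        assert summ["fwhm"] == pytest.approx(2.3548 * samples.std(), rel=0.05)

    @pytest.mark.parametrize("samples", [
        np.full(100, 0.3),                      # constant -> degenerate
        np.concatenate([[-0.1], np.ones(99)]),  # non-positive
        np.ones(10),                            # too few
    ])
    def test_invalid_samples_rejected(self, samples):
        with pytest.raises(ValueError):
            summarize_distribution(samples)


class TestCorrelationMatrix:
    def test_structure(self):
        rng = np.random.default_rng(2)
        corr = correlation_matrix(rng.normal(1.0, 0.1, size=(200, 7)))
        values = corr.to_numpy()
        assert np.allclose(np.diag(values), 1.0)
        assert np.allclose(values, values.T)
        assert np.all(np.abs(values) <= 1.0 + 1e-12)

    def test_independent_columns_near_zero(self):
        n = 400
        rng = np.random.default_rng(3)
        corr = correlation_matrix(rng.normal(1.0, 0.1, size=(n, 7))).to_numpy()
        off = corr[~np.eye(7, dtype=bool)]
        assert np.all(np.abs(off) < 3 / np.sqrt(n))

    def test_zero_variance_rejected(self):
        x = np.random.default_rng(4).normal(1, 0.1, size=(100, 7))
        x[:, 2] = 0.5
        with pytest.raises(ValueError, match="zero-variance"):
            correlation_matrix(x)


class TestMonteCarlo:
    def test_seed_reproducibility(self, truth):
        ds = generate_dataset(truth, AcquisitionSpec(seed=6), "positional")
        a = monte_carlo(ds, "positional", n_mc=4, seed=9)
        b = monte_carlo(ds, "positional", n_mc=4, seed=9)
        assert np.array_equal(a.samples.to_numpy(), b.samples.to_numpy())
        assert a.n_failed == b.n_failed == 0

    def test_tiny_noise_gives_tiny_spread(self, truth):
        spec = AcquisitionSpec(noise_sd_total=1e-4, noise_sd_multiplet=1e-4, seed=6)
        ds = generate_dataset(truth, spec, "positional", add_noise=False)
        mc = monte_carlo(ds, "positional", n_mc=4, seed=1)
        assert float(mc.sd.max()) < 5e-3


class TestSensitivityScan:
    def test_scan_on_clean_data(self, clean_bonded, base_fit, truth):
        scan = sensitivity_scan(clean_bonded, "bonded", "vnt",
                                init=base_fit.estimates)
        assert scan.grid == (0.07, 0.10, 0.20)
        assert all(scan.converged)
        # the grid contains the truth: there the refit matches the
        # unconstrained optimum
        i_truth = scan.grid.index(0.10)
        assert scan.fits[i_truth].residual <= base_fit.residual + 1e-6
        assert max_relative_error(scan.fits[i_truth].estimates, truth) < 0.01
        # constrained away from the truth the fit degrades
        assert scan.fits[0].residual > scan.fits[i_truth].residual

    def test_glnc4_singlet_doublet_move_oppositely_with_vnt(
            self, clean_bonded, base_fit):
        """Raising the constrained neurotransmission flux pushes the GlnC4
        doublet up (more neuron-derived C4-C3 pairs) and the singlet down."""
        scan = sensitivity_scan(clean_bonded, "bonded", "vnt",
                                init=base_fit.estimates)
        late = slice(-4, None)  # steady-state part of the curves
        s = [c[("gln", 4, "S")][late].mean() for c in scan.curves]
        d = [c[("gln", 4, "D43")][late].mean() for c in scan.curves]
        assert s[0] > s[1] > s[2]
        assert d[0] < d[1] < d[2]

    def test_grid_validation(self, clean_bonded):
        with pytest.raises(ValueError, match="increasing"):
            sensitivity_scan(clean_bonded, "bonded", "vnt", grid=[0.2, 0.1])
        with pytest.raises(ValueError, match="unknown free flux"):
            sensitivity_scan(clean_bonded, "bonded", "vxx")
        with pytest.raises(ValueError, match="no default grid"):
            sensitivity_scan(clean_bonded, "bonded", "vpc")
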