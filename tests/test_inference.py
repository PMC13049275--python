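"""Bayesian fitting: posterior density, sampler, summaries, bootstrap."""

import numpy as np
import pytest

from ivimflow.inference import (
    PARAM_NAMES,
    PRIOR_BOUNDS,
    ProtocolModel,
    bootstrap_median_ci,
    fit_map,
    fit_voxel,
    fit_voxels,
    log_posterior,
)
from ivimflow.synthetic import (
    SyntheticDataset,
    default_protocol,
    noisefree_dataset,
    regime_params,
)


@pytest.fixture(scope="module")
def clean_signal(brain_params, protocol):
    return noisefree_dataset(brain_params, protocol)


def theta_of(p):
    return np.array([p.D, p.f, p.v, p.tau, p.S0])


class TestLogPosterior:
    def test_outside_any_bound_is_minus_inf(self, clean_signal, protocol, brain_params):
        base = theta_of(brain_params)
        for k, bad in [(0, 3.5), (1, 1.2), (2, 5.5), (3, 1500.0), (4, 2.5)]:
            theta = base.copy()
            theta[k] = bad
            assert log_posterior(theta, clean_signal, protocol) == -np.inf

    def test_truth_beats_perturbations(self, clean_signal, protocol, brain_params):
        lp0 = log_posterior(theta_of(brain_params), clean_signal, protocol)
        rng = np.random.default_rng(1)
        for _ in range(10):
            theta = theta_of(brain_params) * (1 + 0.05 * rng.standard_normal(5))
            assert lp0 > log_posterior(theta, clean_signal, protocol)

    def test_batch_matches_scalar_reevaluation(self, clean_signal, protocol, brain_params):
        rng = np.random.default_rng(2)
        thetas = theta_of(brain_params) * (1 + 0.1 * rng.standard_normal((8, 5)))
        batch = log_posterior(thetas, clean_signal, protocol)
        singles = np.array(
            [log_posterior(t, clean_signal, protocol) for t in thetas]
        )
        np.testing.assert_allclose(batch, singles, rtol=1e-12, atol=1e-12)

    def test_rician_needs_sigma_and_mismatch_rejected(self, clean_signal, protocol, brain_params):
        with pytest.raises(ValueError, match="sigma"):
            log_posterior(theta_of(brain_params), clean_signal, protocol, noise_model="rician")
        with pytest.raises(ValueError, match="length"):
            log_posterior(theta_of(brain_params), clean_signal[:-3], protocol)


class TestValidation:
    def test_degenerate_data_rejected(self, protocol):
        with pytest.raises(ValueError, match="all-zero"):
            fit_voxel(np.zeros(len(protocol)), protocol, n_samples=10)
        bad = np.ones(len(protocol))
        bad[3] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            fit_voxel(bad, protocol, n_samples=10)

    def test_insufficient_protocols_rejected(self):
        single_T = default_protocol(encoding_times=(50.0,))
        data = np.ones(len(single_T))
        with pytest.raises(ValueError, match="encoding time"):
            fit_voxel(data, single_T, n_samples=10)


class TestRecovery:
    def test_noise_free_recovery(self, clean_signal, protocol, brain_params):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # noise-free Rhat flags are expected
            s = fit_voxel(clean_signal, protocol, n_samples=800, seed=3)
        assert s.median["D"] == pytest.approx(brain_params.D, rel=0.02)
        assert s.median["f"] == pytest.approx(brain_params.f, rel=0.02)
        assert s.median["S0"] == pytest.approx(brain_params.S0, rel=0.02)
        assert s.median["v"] == pytest.approx(brain_params.v, rel=0.05)
        assert s.median["tau"] == pytest.approx(brain_params.tau, rel=0.05)

    def test_posterior_width_shrinks_with_sweeps_on_clean_data(
        self, clean_signal, protocol
    ):
        import warnings

        widths = []
        for n in (30, 120, 600):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                s = fit_voxel(clean_signal, protocol, n_samples=n, seed=4)
            widths.append(s.ci_high["f"] - s.ci_low["f"])
        assert widths[0] > widths[1] > widths[2]

    def test_prior_containment_and_determinism(self, protocol, brain_params):
        ds = SyntheticDataset.generate(brain_params, protocol, n_voxels=2, snr=50, seed=5)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s1, samples = fit_voxels(
                ds.signals, protocol, n_samples=300, seed=6, return_samples=True
            )
            s2 = fit_voxels(ds.signals, protocol, n_samples=300, seed=6)
        flat = samples.reshape(-1, 5)
        for k, name in enumerate(PARAM_NAMES[:-1]):
            lo, hi = PRIOR_BOUNDS[name]
            assert flat[:, k].min() >= lo and flat[:, k].max() <= hi
        assert flat[:, 4].min() >= 0.0
        assert np.all(flat[:, 4] <= 2.0 * ds.signals.max(axis=1).max())
        # identical seeds give identical summaries
        for a, b in zip(s1, s2):
            assert a.median == b.median and a.rhat == b.rhat

    def test_ensemble_agrees_with_emcee(self, protocol, brain_params):
        """Dual-route check of the posterior: stretch-move vs emcee."""
        emcee = pytest.importorskip("emcee")
        ds = SyntheticDataset.generate(brain_params, protocol, n_voxels=1, snr=200, seed=7)
        data = ds.signals[0]
        pm = ProtocolModel(protocol)

        def lp(x):
            th = x.copy()
            th[3] = np.exp(x[3])
            val = log_posterior(th, data, protocol, model=pm)
            return val + x[3] if np.isfinite(val) else -np.inf

        rng = np.random.default_rng(8)
        p0 = np.array([0.9, 0.05, 1.5, np.log(130.0), 1.0]) + 0.02 * rng.standard_normal((32, 5))
        sampler = emcee.EnsembleSampler(32, 5, lp)
        sampler.run_mcmc(p0, 2500, progress=False)
        ch = sampler.get_chain(discard=1250, flat=True)
        ref = np.median(ch, axis=0)
        ref[3] = np.exp(ref[3])

        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = fit_voxel(data, protocol, n_samples=2500, seed=9)
        ours = np.array([s.median[k] for k in PARAM_NAMES])
        # posterior medians from two independent samplers agree
        assert ours[0] == pytest.approx(ref[0], rel=0.05)  # D
        assert ours[1] == pytest.approx(ref[1], abs=0.01)  # f
        assert ours[2] == pytest.approx(ref[2], rel=0.25)  # v
        assert ours[3] == pytest.approx(ref[3], rel=0.25)  # tau
        assert ours[4] == pytest.approx(ref[4], rel=0.01)  # S0


class TestFitMap:
    def test_single_voxel_map_reduces_to_fit_voxel(self, protocol, brain_params):
        ds = SyntheticDataset.generate(brain_params, protocol, n_voxels=1, snr=100, seed=10)
        vol = ds.signals.reshape(1, 1, 1, -1)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            maps = fit_map(vol, protocol, n_samples=200, seed=11)
            ref = fit_voxel(ds.signals[0], protocol, n_samples=200, seed=11)
        for name in PARAM_NAMES:
            assert maps[name][0, 0, 0] == pytest.approx(ref.median[name], rel=1e-12)

    def test_mask_and_calibration(self, protocol, brain_params):
        ds = SyntheticDataset.generate(brain_params, protocol, n_voxels=4, snr=100, seed=12)
        vol = ds.signals.reshape(2, 2, 1, -1)
        mask = np.array([[True, True], [True, False]])[:, :, None]
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            maps = fit_map(vol, protocol, mask=mask, n_samples=400, seed=13)
        assert np.isnan(maps["f"][1, 1, 0])
        fitted = maps["f"][mask]
        widths = maps["f_ci_width"][mask]
        # spatial scatter of identical-parameter voxels stays within the
        # per-voxel posterior spread
        assert fitted.std(ddof=1) < widths.mean()

    def test_shape_mismatch(self, protocol):
        with pytest.raises(ValueError, match="volume"):
            fit_map(np.ones((2, 2, 1, 10)), protocol, n_samples=10)


class TestBootstrap:
    def test_constant_vector(self):
        med, (lo, hi) = bootstrap_median_ci(np.full(20, 3.3), n_boot=200, seed=0)
        assert med == 3.3 and lo == 3.3 and hi == 3.3

    def test_symmetric_sample(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(2001)
        med, (lo, hi) = bootstrap_median_ci(x, n_boot=2000, seed=2)
        assert abs((hi - med) - (med - lo)) < 0.05

    def test_reproducible_and_validated(self):
        x = np.arange(10.0)
        assert bootstrap_median_ci(x, 100, seed=3) == bootstrap_median_ci(x, 100, seed=3)
        with pytest.raises(ValueError):
            bootstrap_median_ci(np.array([]), 100, seed=0)
        with pytest.raises(ValueError):
            bootstrap_median_ci(np.array([1.0]), 100, seed=0)

    def test_coverage_of_true_median(self):
        # nominal 95% CI covers the true median of a standard normal in
        # about 95% of repeated experiments
        rng = np.random.default_rng(4)
        hits = 0
        n_rep = 400
        for k in range(n_rep):
            x = rng.standard_normal(100)
            _, (lo, hi) = bootstrap_median_ci(x, n_boot=800, seed=1000 + k)
            hits += lo <= 0.0 <= hi
        p_hat = hits / n_rep
        se = np.sqrt(0.95 * 0.05 / n_rep)
        assert abs(p_hat - 0.95) < 3 * se + 0.01
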