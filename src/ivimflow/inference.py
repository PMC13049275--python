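"""Voxel-wise Bayesian estimation of IVIM flow parameters.

Estimates theta = (D, f, v, tau, S0) per voxel from FC/NC multi-T
signal data under the closed-form DDE model, by random-walk Metropolis
MCMC. Priors are uniform: D in [0, 3] um^2/ms, f in [0, 1], v in
[0, 5] mm/s, tau in [1, 1000] ms and S0 in [0, 2 Smax] (Smax = largest
measured signal); the blood diffusion coefficient is fixed at
D_b = 1.75 um^2/ms. Separating v and tau requires data at two or more
encoding times with both FC and NC acquisitions, which `fit_voxel`
enforces.

Likelihood: Gaussian on magnitude signals with the per-voxel noise SD
marginalized under a Jeffreys prior (log L = -n/2 log RSS), a standard
choice at SNR >= 20 where the Rice distribution is close to Gaussian; a
Rician likelihood with known noise SD is available as an option.

Sampling runs in log(tau) with the Jacobian correction keeping the
prior uniform on tau, and uses an affine-invariant ensemble (stretch
move) sampler: the posterior is a curved ridge in (f, v, tau) along
which single-chain random-walk proposals mix very slowly, while the
stretch move adapts to the local ridge geometry automatically.
Proposals outside the prior box are rejected. Voxels are fitted
independently; the walker ensembles of many voxels advance in lockstep
as vectorized numpy operations. Convergence is monitored by split-Rhat
across walkers, warning above 1.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import B_TIMES_D, MS_TO_S, MM_PER_S_TO_M_PER_S
from .model import DEFAULT_D_BLOOD, _bracket
from .synthetic import AcquisitionProtocol

__all__ = [
    "PARAM_NAMES",
    "PRIOR_BOUNDS",
    "ProtocolModel",
    "PosteriorSummary",
    "log_posterior",
    "fit_voxel",
    "fit_voxels",
    "fit_map",
    "bootstrap_median_ci",
]

PARAM_NAMES = ("D", "f", "v", "tau", "S0")

#: Uniform prior bounds; S0's upper bound is 2*Smax, resolved per voxel.
PRIOR_BOUNDS = {
    "D": (0.0, 3.0),
    "f": (0.0, 1.0),
    "v": (0.0, 5.0),
    "tau": (1.0, 1000.0),
}


class ProtocolModel:
    """Closed-form signal predictor compiled for a fixed protocol.

    Precomputes, per protocol entry, the factor turning the
    phase-variance bracket into the F_P exponent (gamma^2 G^2 follows
    from the b-value via b = 2 gamma^2 G^2 delta^2 (Delta - delta/3)),
    and groups entries by unique (T, m) so the bracket is evaluated once
    per group per parameter vector.
    """

    def __init__(self, protocol: AcquisitionProtocol, D_b: float = DEFAULT_D_BLOOD):
        self.protocol = protocol
        self.D_b = D_b
        self.b = protocol.b
        d_s = protocol.delta * MS_TO_S
        D_s = protocol.Delta * MS_TO_S
        self._delta_s, self._Delta_s = d_s, D_s
        b_si = self.b * 1e6
        #: gamma^2 G^2 per entry, s^-2 m^-2... (rad^2 m^-2 s^-2)
        self.g2 = b_si / (2.0 * d_s**2 * (D_s - d_s / 3.0))
        tm = np.stack([protocol.T, protocol.m], axis=1)
        uniq, inv = np.unique(tm, axis=0, return_inverse=True)
        self._T_u = uniq[:, 0] * MS_TO_S
        self._m_u = uniq[:, 1].astype(int)
        self._inv = inv
        self._exp_bD = np.exp(-self.b * B_TIMES_D)  # per unit D

    def predict(self, D, f, v, tau, S0):
        """Signals, shape (n_theta, n_entries); scalar inputs allowed."""
        D, f, v, tau, S0 = np.atleast_1d(
            *(np.asarray(x, dtype=float) for x in (D, f, v, tau, S0))
        )
        tau_s = tau * MS_TO_S
        br = _bracket(
            tau_s[:, None], self._delta_s, self._Delta_s, self._T_u[None, :], self._m_u[None, :]
        )  # (n_theta, n_unique)
        v2_si = (v * MM_PER_S_TO_M_PER_S) ** 2
        expo = self.g2[None, :] * (v2_si / 3.0)[:, None] * br[:, self._inv]
        fp = np.exp(-expo)
        tissue = self._exp_bD[None, :] ** D[:, None]
        blood = fp * self._exp_bD[None, :] ** self.D_b
        return S0[:, None] * ((1.0 - f)[:, None] * tissue + f[:, None] * blood)


def _log_likelihood_gaussian_marginal(pred, data):
    """log p(data | theta) with noise SD integrated out (Jeffreys prior)."""
    rss = np.sum((pred - data) ** 2, axis=-1)
    n = data.shape[-1]
    return -0.5 * n * np.log(np.maximum(rss, 1e-300))

def _log_likelihood_rician(pred, data, sigma):
    """Rician log-likelihood at known noise SD."""
    from scipy.stats import rice

    s = np.maximum(pred, 1e-12) / sigma
    return np.sum(rice.logpdf(data / sigma, s) - np.log(sigma), axis=-1)


def _in_bounds(theta, s0_max):
    """Boolean mask of theta rows inside the prior box. theta: (..., 5)."""
    D, f, v, tau, S0 = (theta[..., i] for i in range(5))
    ok = (
        (D >= PRIOR_BOUNDS["D"][0]) & (D <= PRIOR_BOUNDS["D"][1])
        & (f >= PRIOR_BOUNDS["f"][0]) & (f <= PRIOR_BOUNDS["f"][1])
        & (v >= PRIOR_BOUNDS["v"][0]) & (v <= PRIOR_BOUNDS["v"][1])
        & (tau >= PRIOR_BOUNDS["tau"][0]) & (tau <= PRIOR_BOUNDS["tau"][1])
        & (S0 >= 0.0) & (S0 <= 2.0 * s0_max)
    )
    return ok


def log_posterior(
    theta,
    data,
    protocol: AcquisitionProtocol,
    noise_model: str = "gaussian",
    sigma: float | None = None,
    model: ProtocolModel | None = None,
):
    """Unnormalized log posterior density of theta = (D, f, v, tau, S0).

    Uniform priors (zero log-density inside the box, -inf outside);
    ``noise_model`` is 'gaussian' (noise SD marginalized) or 'rician'
    (requires ``sigma``). ``theta`` may be a single 5-vector or an
    array (..., 5) evaluated in batch.
    """
    theta = np.asarray(theta, dtype=float)
    data = np.asarray(data, dtype=float)
    if theta.shape[-1] != 5:
        raise ValueError("theta must have 5 components (D, f, v, tau, S0)")
    if data.ndim != 1 or len(data) != len(protocol):
        raise ValueError("data length does not match the protocol")
    if model is None:
        model = ProtocolModel(protocol)
    scalar = theta.ndim == 1
    th = np.atleast_2d(theta)
    out = np.full(th.shape[0], -np.inf)
    ok = _in_bounds(th, float(np.max(data)))
    # guard the model against nonsensical proposals before evaluating
    if np.any(ok):
        pred = model.predict(*(th[ok, i] for i in range(5)))
        if noise_model == "gaussian":
            ll = _log_likelihood_gaussian_marginal(pred, data)
        elif noise_model == "rician":
            if sigma is None:
                raise ValueError("rician noise model requires sigma")
            ll = _log_likelihood_rician(pred, data, sigma)
        else:
            raise ValueError(f"unknown noise model {noise_model!r}")
        out[ok] = ll
    return float(out[0]) if scalar else out.reshape(theta.shape[:-1])


@dataclass(frozen=True)
class PosteriorSummary:
    """Per-voxel posterior summary of an MCMC fit."""

    median: dict
    ci_low: dict
    ci_high: dict
    acceptance_rate: float
    n_samples: int
    burn_in: int
    seed: int
    rhat: dict

    @property
    def converged(self) -> bool:
        return all(r <= 1.05 for r in self.rhat.values())


def _validate_voxel_data(data, protocol):
    data = np.asarray(data, dtype=float)
    if data.ndim != 1 or len(data) != len(protocol):
        raise ValueError("data length does not match the protocol")
    if np.any(~np.isfinite(data)):
        raise ValueError("data contains NaN/inf")
    if np.all(data == 0):
        raise ValueError("degenerate all-zero voxel")
    if len(data) < 10:
        raise ValueError("need at least 10 data points")
    if len(np.unique(protocol.T)) < 2:
        raise ValueError("tau and v are not separable from a single encoding time")
    if len(np.unique(protocol.m)) < 2:
        raise ValueError("need both FC and NC acquisitions")
    return data


def _initial_theta(data, protocol):
    """Crude data-driven start: log-linear diffusion fit on NC entries."""
    nc = protocol.m == +1
    b, s = protocol.b[nc], np.maximum(np.asarray(data)[nc], 1e-12)
    s0 = float(np.mean(np.asarray(data)[protocol.b == 0]))
    slope, icept = np.polyfit(b, np.log(s), 1)
    D0 = np.clip(-slope / B_TIMES_D, 0.05, 2.95)
    f0 = np.clip(1.0 - np.exp(icept) / max(s0, 1e-12), 0.01, 0.5)
    return np.array([D0, f0, 1.5, 100.0, max(s0, 1e-12)])


def _split_rhat(chain):
    """Split-Rhat per parameter from an ensemble chain.

    chain shape (n_steps, n_vox, n_walkers, 5); every walker is split in
    half, giving 2 * n_walkers chains per voxel. Returns (n_vox, 5).
    """
    n = chain.shape[0] // 2
    # (2*n_walkers, n, n_vox, 5)
    chains = np.concatenate([chain[:n], chain[n : 2 * n]], axis=2).transpose(2, 0, 1, 3)
    means = chains.mean(axis=1)
    vars_ = chains.var(axis=1, ddof=1)
    W = vars_.mean(axis=0)
    B = n * means.var(axis=0, ddof=1)
    var_plus = (n - 1) / n * W + B / n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_plus / W)
    return np.where(np.isfinite(rhat), rhat, 1.0)


#: Walkers per voxel ensemble (even; two half-ensembles).
N_WALKERS = 16
#: Stretch-move scale parameter.
STRETCH_A = 2.0


def _init_walkers(data2d, protocol, n_vox, rng):
    """Overdispersed walker starts around a crude data-driven center."""
    center = np.stack([_initial_theta(d, protocol) for d in data2d])  # (n_vox, 5)
    K = N_WALKERS
    x0 = np.empty((n_vox, K, 5))
    x0[..., 0] = np.clip(
        center[:, None, 0] + 0.3 * rng.standard_normal((n_vox, K)), 0.02, 2.98
    )
    x0[..., 1] = rng.uniform(0.005, 0.25, (n_vox, K))
    x0[..., 2] = rng.uniform(0.2, 4.0, (n_vox, K))
    x0[..., 3] = rng.uniform(np.log(2.0), np.log(900.0), (n_vox, K))
    x0[..., 4] = center[:, None, 4] * (1.0 + 0.03 * rng.standard_normal((n_vox, K)))
    return x0


def _ensemble_mcmc(data2d, protocol, n_samples, burn_in, seed, noise_model, sigma):
    """Vectorized affine-invariant ensemble sampler over independent voxels.

    data2d : (n_vox, n_entries). Runs ``burn_in + n_samples`` ensemble
    sweeps of N_WALKERS walkers per voxel in the coordinates
    (D, f, v, log tau, S0); the +log(tau) Jacobian keeps the prior
    uniform on tau. Post-burn-in sweeps are thinned so that at most
    ~500 are stored (each sweep contributes N_WALKERS draws).

    Returns (samples (n_kept, n_vox, n_walkers, 5) with tau on its
    natural scale, mean acceptance rate per voxel).
    """
    n_vox = data2d.shape[0]
    K = N_WALKERS
    model = ProtocolModel(protocol)
    rng = np.random.default_rng(seed)
    s0_max = data2d.max(axis=1)

    def logpost(xs):
        """xs: (n_vox, W, 5) in sampling coordinates -> (n_vox, W)."""
        W = xs.shape[1]
        th = xs.reshape(-1, 5).copy()
        th[:, 3] = np.exp(th[:, 3])
        lp = np.full(n_vox * W, -np.inf)
        ok = _in_bounds(th, np.repeat(s0_max, W))
        if np.any(ok):
            vox_idx = np.nonzero(ok)[0] // W
            pred = model.predict(*(th[ok, i] for i in range(5)))
            if noise_model == "gaussian":
                ll = _log_likelihood_gaussian_marginal(pred, data2d[vox_idx])
            else:
                ll = _log_likelihood_rician(pred, data2d[vox_idx], sigma)
            lp[ok] = ll + xs.reshape(-1, 5)[ok, 3]  # Jacobian of tau = exp(x3)
        return lp.reshape(n_vox, W)

    x = _init_walkers(data2d, protocol, n_vox, rng)
    lp = logpost(x)
    half = K // 2
    a = STRETCH_A

    thin = max(1, n_samples // 500)
    kept = []
    acc_sum = np.zeros(n_vox)
    for step in range(burn_in + n_samples):
        for lo, hi, plo, phi in ((0, half, half, K), (half, K, 0, half)):
            movers = x[:, lo:hi]
            partners_pool = x[:, plo:phi]
            j = rng.integers(0, half, size=(n_vox, half))
            partners = np.take_along_axis(partners_pool, j[..., None], axis=1)
            u = rng.random((n_vox, half))
            z = ((a - 1.0) * u + 1.0) ** 2 / a
            prop = partners + z[..., None] * (movers - partners)
            lp_prop = logpost(prop)
            with np.errstate(invalid="ignore"):
                log_ratio = (5 - 1) * np.log(z) + lp_prop - lp[:, lo:hi]
                accept = np.log(rng.random((n_vox, half))) < log_ratio
            x[:, lo:hi][accept] = prop[accept]
            lp[:, lo:hi][accept] = lp_prop[accept]
            if step >= burn_in:
                acc_sum += accept.mean(axis=1)
        if step >= burn_in and (step - burn_in) % thin == 0:
            th = x.copy()
            th[..., 3] = np.exp(th[..., 3])
            kept.append(th)
    samples = np.stack(kept)  # (n_kept, n_vox, K, 5)
    return samples, acc_sum / (2 * n_samples)


def fit_voxels(
    data,
    protocol: AcquisitionProtocol,
    n_samples: int = 1000,
    burn_in: int | None = None,
    seed: int = 0,
    noise_model: str = "gaussian",
    sigma: float | None = None,
    return_samples: bool = False,
):
    """Fit many voxels at once; see :func:`fit_voxel` for the contract.

    ``data`` has shape (n_voxels, n_entries). ``n_samples`` counts
    post-burn-in ensemble sweeps; each sweep contributes N_WALKERS
    posterior draws per voxel. ``burn_in`` defaults to ``n_samples``.
    Returns a list of :class:`PosteriorSummary` (plus the raw sample
    array, shape (n_kept, n_vox, n_walkers, 5), if ``return_samples``).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("expected (n_voxels, n_entries) data")
    for row in data:
        _validate_voxel_data(row, protocol)
    if burn_in is None:
        burn_in = n_samples
    samples, acc = _ensemble_mcmc(
        data, protocol, n_samples, burn_in, seed, noise_model, sigma
    )
    rhat = _split_rhat(samples)  # (n_vox, 5)
    med = np.median(samples, axis=(0, 2))
    lo = np.percentile(samples, 2.5, axis=(0, 2))
    hi = np.percentile(samples, 97.5, axis=(0, 2))
    summaries = []
    for i in range(data.shape[0]):
        rh = dict(zip(PARAM_NAMES, rhat[i]))
        if any(r > 1.05 for r in rh.values()):
            warnings.warn(
                f"voxel {i}: split-Rhat > 1.05 for "
                f"{[k for k, r in rh.items() if r > 1.05]}; chain may not have converged",
                stacklevel=2,
            )
        summaries.append(
            PosteriorSummary(
                median=dict(zip(PARAM_NAMES, med[i])),
                ci_low=dict(zip(PARAM_NAMES, lo[i])),
                ci_high=dict(zip(PARAM_NAMES, hi[i])),
                acceptance_rate=float(acc[i]),
                n_samples=n_samples,
                burn_in=burn_in,
                seed=seed,
                rhat=rh,
            )
        )
    if return_samples:
        return summaries, samples
    return summaries


def fit_voxel(
    data,
    protocol: AcquisitionProtocol,
    n_samples: int = 1000,
    seed: int = 0,
    burn_in: int | None = None,
    noise_model: str = "gaussian",
    sigma: float | None = None,
) -> PosteriorSummary:
    """MCMC fit of one voxel.

    Requires >= 10 points spanning >= 2 encoding times and both FC and
    NC acquisitions; rejects degenerate (all-zero or non-finite) data.
    Returns posterior medians, 2.5/97.5 percentiles, acceptance rate and
    split-Rhat per parameter (warning when Rhat > 1.05).
    """
    data = _validate_voxel_data(data, protocol)
    return fit_voxels(
        data[None, :],
        protocol,
        n_samples=n_samples,
        burn_in=burn_in,
        seed=seed,
        noise_model=noise_model,
        sigma=sigma,
    )[0]


def fit_map(
    volume,
    protocol: AcquisitionProtocol,
    mask=None,
    n_samples: int = 1000,
    seed: int = 0,
    **kw,
):
    """Parameter maps from a 4-D volume (x, y, z, entries).

    Masked-out voxels receive NaN and are never fitted. Returns a dict
    of 3-D maps: the posterior median per parameter plus ``<name>_iqr``
    uncertainty maps (interquartile-like 95% CI width).
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 4 or volume.shape[-1] != len(protocol):
        raise ValueError("expected (x, y, z, n_entries) volume matching the protocol")
    spatial = volume.shape[:3]
    if mask is None:
        mask = np.ones(spatial, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != spatial:
        raise ValueError("mask shape mismatch")
    flat = volume[mask]
    summaries = fit_voxels(flat, protocol, n_samples=n_samples, seed=seed, **kw)
    maps = {}
    for name in PARAM_NAMES:
        med = np.full(spatial, np.nan)
        width = np.full(spatial, np.nan)
        med[mask] = [s.median[name] for s in summaries]
        width[mask] = [s.ci_high[name] - s.ci_low[name] for s in summaries]
        maps[name] = med
        maps[f"{name}_ci_width"] = width
    return maps


def bootstrap_median_ci(values, n_boot: int = 10000, seed: int = 0, ci: float = 95.0):
    """Percentile bootstrap confidence interval of the median.

    Returns ``(median, (lo, hi))``; reproducible by seed.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    if values.size < 2:
        raise ValueError("need at least two values")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    meds = np.median(values[idx], axis=1)
    half = (100.0 - ci) / 2.0
    lo, hi = np.percentile(meds, [half, 100.0 - half])
    return float(np.median(values)), (float(lo), float(hi))
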