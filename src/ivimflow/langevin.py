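"""Monte-Carlo simulation of intravoxel blood flow (Langevin dynamics).

Blood velocity along the dephasing direction is simulated as an
Ornstein-Uhlenbeck process via the Euler-Maruyama update

    v(t + dt) = v(t) (1 - dt/tau) + sqrt(2 sigma_v^2 dt / tau) * xi

with xi a standard normal draw, producing velocities that are Gaussian
with stationary variance sigma_v^2 and exponentially correlated on the
timescale tau. Each walker accrues phase phi = -int q(t) v(t) dt under
a dephasing waveform, and the ensemble signal is the modulus of the
complex mean F_P = |<exp(i phi)>|, mirroring magnitude MRI.

Only the 1-D velocity component along the encoding direction is
simulated: for linear encoding the signal depends on nothing else. For
isotropic d-dimensional flow the analytic model's mean squared speed
maps as v2bar = d * sigma_v^2. Three independent components can be run
for trajectory visualization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .waveforms import GradientWaveform, QFactor, dephasing
from .constants import MS_TO_S, MM_PER_S_TO_M_PER_S

__all__ = ["WalkerEnsemble", "step_velocity", "simulate_phases", "ensemble_signal"]

#: Largest allowed dt/tau before automatic refinement (discretization bias control).
MAX_DT_OVER_TAU = 1.0 / 20.0


@dataclass(frozen=True)
class WalkerEnsemble:
    """Phases (and optionally velocity traces) of simulated walkers.

    phases : rad, shape (n_walkers,).
    velocities : mm/s, shape (n_walkers, n_steps + 1) if kept, else None.
    dt : time step actually used, ms (may be refined below the request).
    """

    phases: np.ndarray
    dt: float
    tau: float
    sigma_v: float
    seed: int
    velocities: np.ndarray | None = None

    @property
    def n_walkers(self) -> int:
        return len(self.phases)


def step_velocity(v, tau: float, sigma_v: float, dt: float, xi):
    """One Euler-Maruyama update of the Langevin velocity.

    ``v`` and ``sigma_v`` in mm/s, ``tau`` and ``dt`` in ms (only the
    ratio dt/tau matters), ``xi`` standard normal. Requires dt < tau
    (the explicit scheme is unstable otherwise).
    """
    if dt >= tau:
        raise ValueError(f"dt={dt} ms must be smaller than tau={tau} ms")
    return v * (1.0 - dt / tau) + np.sqrt(2.0 * sigma_v**2 * dt / tau) * np.asarray(xi)


def _q_step_integrals(q: QFactor, t_grid_s: np.ndarray) -> np.ndarray:
    """Exact integral of the piecewise-linear q over each [t_i, t_{i+1}]."""
    # refine the grid with q's breakpoints so each sub-interval is linear
    knots = np.union1d(t_grid_s, q.times)
    knots = knots[(knots >= t_grid_s[0]) & (knots <= t_grid_s[-1])]
    qk = q(knots)
    seg = 0.5 * (qk[:-1] + qk[1:]) * np.diff(knots)  # exact trapezoid per sub-piece
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    at = np.searchsorted(knots, t_grid_s)
    return np.diff(cum[at])


def simulate_phases(
    w: GradientWaveform,
    tau: float,
    sigma_v: float,
    n_walkers: int = 20000,
    dt: float = 0.1,
    seed: int = 0,
    keep_velocities: bool = False,
) -> WalkerEnsemble:
    """Simulate walker phases under a dephasing waveform.

    Parameters
    ----------
    w : GradientWaveform
    tau : float
        Velocity correlation time, ms.
    sigma_v : float
        Per-component velocity SD, mm/s.
    n_walkers, dt, seed
        Ensemble size, time step (ms) and RNG seed. If dt > tau/20 the
        step is refined automatically (with a warning) to control
        Euler-Maruyama bias.
    keep_velocities : bool
        Store the full velocity traces (memory: n_walkers * n_steps).

    Initial velocities are drawn from the stationary distribution
    N(0, sigma_v^2), so no burn-in is needed. The per-step phase
    increment uses the exact integral of q over the step, with the
    walker velocity held at its value at the step start.
    """
    if n_walkers < 1:
        raise ValueError("need at least one walker")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt > tau * MAX_DT_OVER_TAU:
        dt_new = tau * MAX_DT_OVER_TAU
        warnings.warn(
            f"dt={dt} ms too coarse for tau={tau} ms; refined to dt={dt_new:g} ms",
            stacklevel=2,
        )
        dt = dt_new

    TE = w.TE
    n_steps = int(np.ceil(TE / dt - 1e-12))
    t_grid_s = np.linspace(0.0, n_steps * dt, n_steps + 1) * MS_TO_S
    q = dephasing(w)
    # q vanishes beyond TE; clamp the last edge to TE
    t_grid_s[-1] = TE * MS_TO_S
    q_int = _q_step_integrals(q, t_grid_s)  # rad*s/m per step

    rng = np.random.default_rng(seed)
    v = rng.standard_normal(n_walkers) * sigma_v  # mm/s
    phases = np.zeros(n_walkers)
    traces = np.empty((n_walkers, n_steps + 1)) if keep_velocities else None
    if keep_velocities:
        traces[:, 0] = v
    decay = 1.0 - dt / tau
    kick = np.sqrt(2.0 * sigma_v**2 * dt / tau)
    for i in range(n_steps):
        phases -= q_int[i] * (v * MM_PER_S_TO_M_PER_S)
        v = v * decay + kick * rng.standard_normal(n_walkers)
        if keep_velocities:
            traces[:, i + 1] = v
    return WalkerEnsemble(
        phases=phases,
        dt=dt,
        tau=tau,
        sigma_v=sigma_v,
        seed=seed,
        velocities=traces,
    )


def ensemble_signal(e: WalkerEnsemble, n_jackknife: int = 20):
    """Ensemble attenuation F_P = |mean exp(i phi)| with jackknife SE.

    Returns
    -------
    (fp, se) : tuple of float
        The modulus of the complex ensemble mean and its Monte-Carlo
        standard error estimated by ``n_jackknife``-fold delete-one-group
        jackknife over walkers.
    """
    z = np.exp(1j * e.phases)
    fp = float(np.abs(z.mean()))
    n = len(z)
    k = min(n_jackknife, n)
    groups = np.array_split(z, k)
    total = z.sum()
    fps = np.array([np.abs((total - g.sum()) / (n - len(g))) for g in groups])
    se = float(np.sqrt((k - 1) / k * np.sum((fps - fps.mean()) ** 2)))
    return fp, se
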