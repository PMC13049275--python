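"""Closed-form IVIM signal model for FC/NC double diffusion encoding.

The perfusion compartment is modeled as blood moving with exponentially
correlated velocities (Ornstein-Uhlenbeck / Langevin flow): the velocity
autocorrelation is <v(t) v(t')> = (v2bar / d) exp(-|t - t'| / tau) per
component, where ``v2bar`` is the mean squared speed, ``tau`` the
velocity correlation time and ``d`` the flow dimensionality. Under the
Gaussian phase approximation the perfusion attenuation for an FC/NC DDE
waveform has the closed form

    F_P = exp(-gamma^2 G^2 (v2bar/d) * [tau^4 (Psi + Omega)
            - 4 delta tau^3 + 2 delta^2 (Delta - delta/3) tau])

with

    Psi   = 2 exp(-(Delta+delta)/tau) (exp(delta/tau) - 1)
              * (2 exp(Delta/tau) + exp(delta/tau) - 1)
    Omega = m exp(-T/tau) (exp(Delta/tau) - 1)^2 (exp(delta/tau) - 1)^2

and m = +1 for NC, m = -1 for FC. The implementation below evaluates
Psi and Omega in an algebraically identical form containing only
decaying exponentials, so it is overflow-free for every tau > 0
(including tau far below the lobe duration). The form above is derived
by the symbolic engine in :mod:`ivimflow.derivation` and locked in by a
regression test against the numeric double-quadrature of the phase
variance.

Limiting regimes:

* ``T/tau >> 1`` (diffusive / pseudodiffusion): F_P -> exp(-b D*) with
  D* = v2bar tau / d, independent of flow compensation.
* ``T/tau << 1`` (ballistic): F_P -> exp(-c^2 v2bar / (2 d)) for NC and
  -> 1 for FC, with c the flow-weighting factor.

The two-compartment IVIM signal is
``S = S0 [(1 - f) exp(-b D) + f F_P exp(-b D_b)]``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .constants import (
    B_TIMES_D,
    GAMMA,
    MM_PER_S_TO_M_PER_S,
    MS_TO_S,
    MT_PER_M_TO_T_PER_M,
)
from .waveforms import strength_for_b

__all__ = [
    "IVIMParams",
    "psi",
    "omega",
    "fp_closed_form",
    "fp_diffusive",
    "fp_ballistic",
    "ivim_signal",
]

#: Default blood diffusion coefficient, um^2/ms.
DEFAULT_D_BLOOD = 1.75


@dataclass(frozen=True)
class IVIMParams:
    """Two-compartment IVIM parameter set.

    Attributes
    ----------
    f : float
        Perfusion (blood signal) fraction, in [0, 1].
    D : float
        Tissue diffusion coefficient, um^2/ms.
    v : float
        Blood speed sqrt(v2bar), mm/s.
    tau : float
        Velocity correlation time, ms.
    S0 : float
        Unattenuated signal (arbitrary units).
    D_b : float
        Blood diffusion coefficient, um^2/ms (default 1.75).
    d : int
        Flow dimensionality (default 3, isotropic flow).
    """

    f: float
    D: float
    v: float
    tau: float
    S0: float = 1.0
    D_b: float = DEFAULT_D_BLOOD
    d: int = 3

    def __post_init__(self):
        if not 0.0 <= self.f <= 1.0:
            raise ValueError("perfusion fraction f must be in [0, 1]")
        for name in ("D", "v", "tau", "S0", "D_b"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.d not in (1, 2, 3):
            raise ValueError("flow dimensionality d must be 1, 2 or 3")

    @property
    def v2bar(self) -> float:
        """Mean squared blood speed, mm^2/s^2."""
        return self.v**2

    @property
    def sigma_v(self) -> float:
        """Per-component velocity standard deviation, mm/s (v2bar = d sigma_v^2)."""
        return self.v / np.sqrt(self.d)

    @property
    def Dstar(self) -> float:
        """Pseudodiffusion coefficient D* = v2bar tau / d, um^2/ms."""
        # mm^2/s^2 * ms -> um^2/ms: 1 mm^2/s^2 * 1 ms = 1e-3 mm^2/s = 1 um^2/ms
        return self.v2bar * self.tau * 1e-3 / self.d * 1e3  # = v2bar*tau/d in um^2/ms

    def regime(self, T: float) -> float:
        """Regime descriptor T/tau for an encoding time T (ms)."""
        return T / self.tau

    def with_(self, **kw) -> "IVIMParams":
        return replace(self, **kw)


def psi(tau, delta, Delta):
    """Intra-pair term Psi of the DDE phase-variance closed form.

    Algebraically equal to
    ``2 exp(-(Delta+delta)/tau) (exp(delta/tau)-1) (2 exp(Delta/tau) + exp(delta/tau) - 1)``
    but evaluated with decaying exponentials only:

    ``Psi = 4 - 4 e^{-delta/tau} - 4 e^{-Delta/tau} + 2 e^{-(Delta-delta)/tau}
    + 2 e^{-(Delta+delta)/tau}``.

    All arguments in the same time unit; requires ``0 < delta <= Delta``.
    Vectorized over tau.
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(tau <= 0):
        raise ValueError("tau must be positive")
    if not 0 < delta <= Delta:
        raise ValueError("need 0 < delta <= Delta")
    return (
        4.0
        - 4.0 * np.exp(-delta / tau)
        - 4.0 * np.exp(-Delta / tau)
        + 2.0 * np.exp(-(Delta - delta) / tau)
        + 2.0 * np.exp(-(Delta + delta) / tau)
    )


def omega(tau, delta, Delta, T, m):
    """Cross-pair term Omega of the DDE phase-variance closed form.

    Algebraically equal to
    ``m exp(-T/tau) (exp(Delta/tau)-1)^2 (exp(delta/tau)-1)^2`` and
    evaluated as
    ``m (1-e^{-Delta/tau})^2 (1-e^{-delta/tau})^2 e^{-(T-2Delta-2delta)/tau}``,
    which is bounded for all tau > 0 because T >= 2(Delta+delta).

    Omega carries the polarity flag m (+1 NC, -1 FC) and vanishes as
    T/tau -> infinity. Vectorized over tau and T.
    """
    tau = np.asarray(tau, dtype=float)
    T = np.asarray(T, dtype=float)
    if np.any(tau <= 0):
        raise ValueError("tau must be positive")
    m_arr = np.asarray(m)
    if not np.all(np.isin(m_arr, (-1, 1))):
        raise ValueError("polarity flag m must be +1 (NC) or -1 (FC)")
    if np.any(T < 2 * (Delta + delta) - 1e-9):
        raise ValueError("need T >= 2*(Delta + delta)")
    core = (
        (-np.expm1(-Delta / tau)) ** 2
        * (-np.expm1(-delta / tau)) ** 2
        * np.exp(-(T - 2.0 * Delta - 2.0 * delta) / tau)
    )
    return m_arr * core


#: tau/T ratio above which the bracket switches to its large-tau series.
#: At the switch point the two branches agree to ~1e-10 relative.
_SERIES_SWITCH = 2.0


def _bracket_direct(tau, delta, Delta, T, m):
    """tau^4 (Psi+Omega) - 4 delta tau^3 + 2 delta^2 (Delta - delta/3) tau."""
    return (
        tau**4 * (psi(tau, delta, Delta) + omega(tau, delta, Delta, T, m))
        - 4.0 * delta * tau**3
        + 2.0 * delta**2 * (Delta - delta / 3.0) * tau
    )


def _bracket_series(tau, delta, Delta, T, m, n_max=40):
    """Large-tau evaluation of the bracket by series expansion in 1/tau.

    The direct form cancels the leading tau^4..tau^1 orders between
    Psi, Omega and the polynomial terms, which loses all precision once
    tau >> T. Expanding every exponential exp(-x/tau) in powers of
    x/tau, the orders n = 0..3 cancel identically and the bracket is

        tau^4 * sum_{n>=4} (-1)^n / n! * sum_k a_k (x_k/tau)^n

    over the exponential terms of Psi (offsets delta, Delta, Delta-delta,
    Delta+delta) and Omega (offsets T - i - j with binomial weights).
    Converges geometrically for tau > T.
    """
    tau = np.asarray(tau, dtype=float)
    T = np.asarray(T, dtype=float)
    m = np.asarray(m)
    # exponential offsets and coefficients; Omega offsets depend on T
    psi_x = np.array([delta, Delta, Delta - delta, Delta + delta])
    psi_a = np.array([-4.0, -4.0, 2.0, 2.0])
    pair_x = np.array([0.0, Delta, 2 * Delta])
    pair_aD = np.array([1.0, -2.0, 1.0])
    pair_d = np.array([0.0, delta, 2 * delta])
    om_x = (T[..., None] - (pair_x[:, None] + pair_d[None, :]).ravel())  # (..., 9)
    om_a = np.broadcast_to(
        m[..., None], om_x.shape
    ) * np.outer(pair_aD, pair_aD).ravel()
    x = np.concatenate(
        [np.broadcast_to(psi_x, T.shape + (4,)), om_x], axis=-1
    )
    a = np.concatenate(
        [np.broadcast_to(psi_a, T.shape + (4,)), om_a], axis=-1
    )
    r = x / tau[..., None]  # all |r| <= T/tau < 1 on the series branch
    # fixed-order summation: at tau >= 2T every |r| <= 0.5, so the n_max
    # tail is ~1e-60 relative — no data-dependent early exit (for the FC
    # waveform the leading n = 4 term cancels exactly, so a "first term
    # negligible" shortcut would be wrong)
    total = np.zeros(np.broadcast_shapes(tau.shape, T.shape))
    rn = r**4
    fact = 24.0
    for n in range(4, n_max + 1):
        term = np.sum(a * rn, axis=-1) / fact
        if n % 2 == 1:
            term = -term
        total = total + term
        rn = rn * r
        fact *= n + 1
    return tau**4 * total


def _bracket(tau, delta, Delta, T, m):
    """Phase-variance bracket with automatic series branch at large tau.

    All times in the same unit; result has units time^3 (times the
    implicit gamma^2 G^2 v2bar/d prefactor it becomes phi2/2).
    """
    tau, T, m = np.broadcast_arrays(
        np.asarray(tau, dtype=float), np.asarray(T, dtype=float), np.asarray(m)
    )
    out = np.array(_bracket_direct(tau, delta, Delta, T, m), dtype=float, ndmin=0)
    big = tau > _SERIES_SWITCH * T
    if np.any(big):
        vals = _bracket_series(tau[big], delta, Delta, T[big], m[big])
        if out.ndim == 0:
            out = vals.reshape(())
        else:
            out[big] = vals
    return out


def _fp_exponent(v, tau, d, G, delta, Delta, T, m):
    """Exponent of F_P (= phi2/2), dimensionless, in SI internally."""
    tau_s = np.asarray(tau, dtype=float) * MS_TO_S
    d_s = delta * MS_TO_S
    D_s = Delta * MS_TO_S
    T_s = np.asarray(T, dtype=float) * MS_TO_S
    g_si = np.asarray(G, dtype=float) * MT_PER_M_TO_T_PER_M
    v2_si = (np.asarray(v, dtype=float) * MM_PER_S_TO_M_PER_S) ** 2
    return GAMMA**2 * g_si**2 * (v2_si / d) * _bracket(tau_s, d_s, D_s, T_s, m)


def fp_closed_form(p: IVIMParams, G, delta, Delta, T, m):
    """Perfusion attenuation F_P for an FC/NC DDE waveform.

    Parameters
    ----------
    p : IVIMParams
        Only ``v``, ``tau`` and ``d`` are used.
    G : array_like
        Gradient amplitude, mT/m.
    delta, Delta : float
        Lobe duration / separation, ms.
    T : array_like
        Encoding time, ms.
    m : array_like
        +1 for NC, -1 for FC.

    Returns
    -------
    ndarray or float
        F_P in (0, 1], broadcast over (G, T, m).
    """
    return np.exp(-_fp_exponent(p.v, p.tau, p.d, G, delta, Delta, T, m))


def fp_diffusive(p: IVIMParams, b):
    """Pseudodiffusive-limit attenuation exp(-b D*), b in s/mm^2."""
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("b must be nonnegative")
    return np.exp(-b * p.Dstar * B_TIMES_D)


def fp_ballistic(p: IVIMParams, c):
    """Ballistic-limit attenuation exp(-c^2 v2bar / (2 d)), c in s/mm.

    For a flow-compensated waveform c = 0 and the attenuation is exactly 1.
    """
    c = np.asarray(c, dtype=float)
    return np.exp(-(c**2) * p.v2bar / (2.0 * p.d))


def ivim_signal(p: IVIMParams, b, T, m, delta, Delta, G=None):
    """Two-compartment IVIM signal for protocol entries.

    ``S = S0 [(1 - f) exp(-b D) + f F_P exp(-b D_b)]`` with F_P from the
    closed-form DDE model. If ``G`` is omitted it is computed from the
    b-value via the DDE relation b = 2 gamma^2 G^2 delta^2 (Delta - delta/3).

    All of b (s/mm^2), T (ms) and m broadcast together.
    """
    b = np.asarray(b, dtype=float)
    if G is None:
        G = np.sqrt(b) * strength_for_b(1.0, delta, Delta)
    fp = fp_closed_form(p, G, delta, Delta, T, m)
    tissue = (1.0 - p.f) * np.exp(-b * p.D * B_TIMES_D)
    blood = p.f * fp * np.exp(-b * p.D_b * B_TIMES_D)
    return p.S0 * (tissue + blood)
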