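"""Diffusion-encoding gradient waveforms and their moments.

Waveforms are represented as piecewise-constant *effective* gradients
G(t): the sign flip imposed by the 180-degree refocusing pulse of a
single-refocused sequence is absorbed into the stored amplitudes, so a
valid diffusion waveform integrates to zero directly and the dephasing
factor q(t) = gamma * int_0^t G dt' is a plain integral.

The central constructor is :func:`make_dde`, building the double
diffusion encoding (DDE) waveform used for flow-compensated (FC) and
non-flow-compensated (NC) acquisitions: two bipolar gradient pairs of
lobe duration ``delta`` and lobe separation ``Delta``; the encoding time
``T`` runs from the start of the first pair to the end of the second.
Toggling flow compensation inverts the polarity of the second pair. Any
dead time for T > 2*(Delta+delta) is placed between the two pairs,
symmetric about the refocusing pulse.

Sign convention: the stored effective amplitudes are chosen such that
the flow-weighting factor c = -int q dt is nonnegative for the NC
waveform (c = 2*gamma*G*delta*Delta); only |c| carries physics.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np

from .constants import (
    GAMMA,
    MS_TO_S,
    MT_PER_M_TO_T_PER_M,
    S_PER_M2_TO_S_PER_MM2,
    S_PER_M_TO_S_PER_MM,
)

__all__ = [
    "GradientWaveform",
    "QFactor",
    "make_dde",
    "dephasing",
    "bvalue",
    "cvalue",
    "strength_for_b",
    "save_waveform",
    "load_waveform",
]


@dataclass(frozen=True)
class GradientWaveform:
    """Piecewise-constant effective gradient waveform.

    Parameters
    ----------
    breakpoints : ndarray
        Ordered times in ms partitioning [0, TE]; length ``n + 1``.
    amplitudes : ndarray
        Effective gradient per interval in mT/m (signed); length ``n``.
    delta : float
        Gradient lobe duration in ms.
    Delta : float
        Lobe separation (leading edge to leading edge) in ms.
    T : float
        Encoding time in ms, from the start of the first bipolar pair to
        the end of the second.
    m : int
        Polarity flag: +1 for NC, -1 for FC.
    label : str
        Free-text description.
    """

    breakpoints: np.ndarray
    amplitudes: np.ndarray
    delta: float
    Delta: float
    T: float
    m: int
    label: str = ""

    def __post_init__(self):
        bp = np.asarray(self.breakpoints, dtype=float)
        amp = np.asarray(self.amplitudes, dtype=float)
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "amplitudes", amp)
        if bp.ndim != 1 or amp.ndim != 1 or len(bp) != len(amp) + 1:
            raise ValueError("need n+1 breakpoints for n amplitude segments")
        if not np.all(np.diff(bp) > 0):
            raise ValueError("breakpoints must be strictly increasing")
        if not np.all(np.isfinite(amp)):
            raise ValueError("amplitudes must be finite")
        gmax = float(np.max(np.abs(amp)))
        moment0 = float(np.sum(amp * np.diff(bp)))
        if gmax > 0 and abs(moment0) > 1e-12 * gmax * self.delta:
            raise ValueError(
                f"rephasing condition violated: int G dt = {moment0:g} mT/m*ms"
            )

    @property
    def TE(self) -> float:
        """Duration of the stored waveform in ms."""
        return float(self.breakpoints[-1])

    @property
    def G(self) -> float:
        """Peak gradient amplitude in mT/m."""
        return float(np.max(np.abs(self.amplitudes)))

    @property
    def flow_compensated(self) -> bool:
        return self.m == -1


@dataclass(frozen=True)
class QFactor:
    """Continuous piecewise-linear dephasing factor q(t).

    ``times`` are breakpoints in seconds, ``values`` the corresponding
    q in rad/m. q is linear on each interval; integrals of q and q^2 are
    therefore exact (trapezoid / quadratic Simpson-free closed forms).
    """

    times: np.ndarray  # s
    values: np.ndarray  # rad/m

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    def __call__(self, t):
        return np.interp(t, self.times, self.values)

    @property
    def slopes(self) -> np.ndarray:
        """Per-interval slope dq/dt in rad/(m*s) (equals gamma*G)."""
        return np.diff(self.values) / np.diff(self.times)

    def max_abs(self) -> float:
        """max |q(t)|; attained at a breakpoint since q is piecewise linear."""
        return float(np.max(np.abs(self.values)))

    def integral(self) -> float:
        """int q dt in rad*s/m (exact trapezoid)."""
        return float(np.trapezoid(self.values, self.times))

    def integral_sq(self) -> float:
        """int q^2 dt in rad^2*s/m^2 (exact for piecewise-linear q)."""
        q0, q1 = self.values[:-1], self.values[1:]
        dt = np.diff(self.times)
        return float(np.sum(dt * (q0 * q0 + q0 * q1 + q1 * q1) / 3.0))


def make_dde(
    G: float,
    delta: float,
    Delta: float,
    T: float,
    flow_compensated: bool = False,
    label: str = "",
) -> GradientWaveform:
    """Construct an FC or NC double-diffusion-encoding waveform.

    Parameters
    ----------
    G : float
        Gradient lobe amplitude in mT/m (G >= 0).
    delta, Delta : float
        Lobe duration and separation in ms, delta <= Delta.
    T : float
        Encoding time in ms; must satisfy T >= 2*(Delta + delta).
    flow_compensated : bool
        If True, the polarity of the second bipolar pair is inverted
        (first gradient moment nulled; m = -1).

    Returns
    -------
    GradientWaveform
        First pair on [0, Delta+delta], second pair ending at T; any
        slack time sits between the pairs.
    """
    if G < 0:
        raise ValueError("gradient amplitude must be nonnegative")
    if delta <= 0 or Delta <= 0:
        raise ValueError("delta and Delta must be positive")
    if delta > Delta:
        raise ValueError(f"lobe duration delta={delta} ms exceeds separation Delta={Delta} ms")
    pair = Delta + delta
    if T < 2 * pair - 1e-12:
        raise ValueError(
            f"encoding time T={T} ms too short for two bipolar pairs; need T >= {2 * pair} ms"
        )
    m = -1 if flow_compensated else +1
    s = T - pair  # start of the second pair
    # effective amplitudes; overall sign fixed so that c(NC) >= 0
    edges = [
        (delta, -G),
        (Delta, 0.0),  # zero length when delta == Delta
        (pair, +G),
        (s, 0.0),  # gap; zero length when T == 2*(Delta+delta)
        (s + delta, -m * G),
        (s + Delta, 0.0),
        (T, m * G),
    ]
    bp, amp = [0.0], []
    for edge, g in edges:
        if edge > bp[-1] + 1e-12:
            bp.append(edge)
            amp.append(g)
    if not label:
        label = f"DDE {'FC' if flow_compensated else 'NC'} G={G:g} d={delta:g} D={Delta:g} T={T:g}"
    return GradientWaveform(
        breakpoints=np.array(bp),
        amplitudes=np.array(amp),
        delta=delta,
        Delta=Delta,
        T=T,
        m=m,
        label=label,
    )


def dephasing(w: GradientWaveform) -> QFactor:
    """Dephasing factor q(t) = gamma * int_0^t G(t') dt' of a waveform.

    Returns a piecewise-linear :class:`QFactor` in SI units (rad/m vs
    seconds). q(0) = 0, and q(TE) = 0 by the rephasing condition.
    """
    t_s = w.breakpoints * MS_TO_S
    g_si = w.amplitudes * MT_PER_M_TO_T_PER_M
    q = np.concatenate([[0.0], np.cumsum(GAMMA * g_si * np.diff(t_s))])
    # pin the final value: rephasing guarantees it is zero up to rounding
    q[-1] = 0.0
    return QFactor(times=t_s, values=q)


def bvalue(w: GradientWaveform) -> float:
    """Diffusion weighting b = int q(t)^2 dt, in s/mm^2.

    For the DDE constructor this equals 2 gamma^2 G^2 delta^2 (Delta - delta/3)
    and is identical for FC and NC.
    """
    return dephasing(w).integral_sq() * S_PER_M2_TO_S_PER_MM2


def cvalue(w: GradientWaveform) -> float:
    """Flow-weighting factor c = -int q(t) dt, in s/mm.

    Zero for flow-compensated waveforms; 2 gamma G delta Delta for NC DDE.
    """
    return -dephasing(w).integral() * S_PER_M_TO_S_PER_MM


def strength_for_b(b: float, delta: float, Delta: float) -> float:
    """Gradient amplitude (mT/m) giving b-value ``b`` (s/mm^2) for a DDE.

    Inverts b = 2 gamma^2 G^2 delta^2 (Delta - delta/3).
    """
    if b < 0:
        raise ValueError("b must be nonnegative")
    if delta <= 0 or Delta <= 0 or Delta - delta / 3.0 <= 0:
        raise ValueError("nonpositive effective timing")
    d_s = delta * MS_TO_S
    D_s = Delta * MS_TO_S
    b_si = b * 1e6  # s/m^2
    g_si = np.sqrt(b_si / (2.0 * GAMMA**2 * d_s**2 * (D_s - d_s / 3.0)))
    return float(g_si / MT_PER_M_TO_T_PER_M)


# ---------------------------------------------------------------------------
# serialization: JSON header in '#' comments + two-column table
# ---------------------------------------------------------------------------

def save_waveform(w: GradientWaveform, path) -> None:
    """Write a waveform as plain text: JSON header + (time_ms, G_mT_per_m)."""
    header = {
        "delta": w.delta,
        "Delta": w.Delta,
        "T": w.T,
        "m": int(w.m),
        "G": w.G,
        "label": w.label,
    }
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(header) + "\n")
        fh.write("# time_ms\tgradient_mT_per_m\n")
        for i, amp in enumerate(w.amplitudes):
            fh.write(f"{w.breakpoints[i]:.9g}\t{amp:.9g}\n")
        fh.write(f"{w.breakpoints[-1]:.9g}\t0\n")


def load_waveform(path) -> GradientWaveform:
    """Read a waveform written by :func:`save_waveform`."""
    with open(path) as fh:
        text = fh.read()
    header = None
    times, amps = [], []
    for line in io.StringIO(text):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("# ")
            if header is None and body.startswith("{"):
                header = json.loads(body)
            continue
        t_str, g_str = line.split()
        times.append(float(t_str))
        amps.append(float(g_str))
    if header is None:
        raise ValueError("missing JSON header line")
    return GradientWaveform(
        breakpoints=np.array(times),
        amplitudes=np.array(amps[:-1]),
        delta=header["delta"],
        Delta=header["Delta"],
        T=header["T"],
        m=header["m"],
        label=header.get("label", ""),
    )
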