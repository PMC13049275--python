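"""Gradient waveform construction, moments and serialization."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import brentq

from ivimflow.constants import GAMMA
from ivimflow.waveforms import (
    GradientWaveform,
    make_dde,
    dephasing,
    bvalue,
    cvalue,
    strength_for_b,
    save_waveform,
    load_waveform,
)

from conftest import DELTA, BIG_DELTA


def dde_b_closed_form(G, delta, Delta):
    """2 gamma^2 G^2 delta^2 (Delta - delta/3), SI in, s/mm^2 out."""
    g, d, D = G * 1e-3, delta * 1e-3, Delta * 1e-3
    return 2.0 * GAMMA**2 * g**2 * d**2 * (D - d / 3.0) * 1e-6


@pytest.mark.parametrize("fc", [False, True])
@pytest.mark.parametrize(
    "delta,Delta,T", [(8.6, 10.0, 50.0), (8.6, 10.0, 37.2), (3.0, 15.0, 100.0), (5.0, 5.0, 40.0)]
)
def test_rephasing_and_layout(delta, Delta, T, fc):
    w = make_dde(40.0, delta, Delta, T, fc)
    moment0 = np.sum(w.amplitudes * np.diff(w.breakpoints))
    assert abs(moment0) < 1e-12 * 40.0 * delta
    assert w.breakpoints[0] == 0.0
    assert w.breakpoints[-1] == pytest.approx(T)
    assert w.m == (-1 if fc else +1)


def test_dde_timing_validation():
    with pytest.raises(ValueError, match="too short"):
        make_dde(40.0, 8.6, 10.0, 36.0, False)
    with pytest.raises(ValueError, match="exceeds separation"):
        make_dde(40.0, 12.0, 10.0, 60.0, False)
    with pytest.raises(ValueError, match="nonnegative"):
        make_dde(-1.0, 8.6, 10.0, 50.0, False)
    # zero gap between the pairs is a valid boundary case
    make_dde(40.0, 8.6, 10.0, 2 * (10.0 + 8.6), False)


def test_fc_negates_second_pair_only():
    nc = make_dde(40.0, DELTA, BIG_DELTA, 50.0, False)
    fc = make_dde(40.0, DELTA, BIG_DELTA, 50.0, True)
    assert np.array_equal(nc.breakpoints, fc.breakpoints)
    mid = 0.5 * (nc.breakpoints[:-1] + nc.breakpoints[1:])
    first_pair = mid <= BIG_DELTA + DELTA
    assert np.array_equal(nc.amplitudes[first_pair], fc.amplitudes[first_pair])
    second = ~first_pair & (nc.amplitudes != 0)
    assert np.array_equal(nc.amplitudes[second], -fc.amplitudes[second])


def test_invalid_waveform_rejected():
    with pytest.raises(ValueError, match="rephasing"):
        GradientWaveform(
            breakpoints=np.array([0.0, 1.0, 2.0]),
            amplitudes=np.array([10.0, 10.0]),
            delta=1.0,
            Delta=1.0,
            T=2.0,
            m=1,
        )
    with pytest.raises(ValueError, match="increasing"):
        GradientWaveform(
            breakpoints=np.array([0.0, 2.0, 1.0]),
            amplitudes=np.array([10.0, -20.0]),
            delta=1.0,
            Delta=1.0,
            T=1.0,
            m=1,
        )


def test_dephasing_shape_and_ends():
    w = make_dde(40.0, DELTA, BIG_DELTA, 50.0, False)
    q = dephasing(w)
    assert q.values[0] == 0.0
    assert q.values[-1] == 0.0
    # NC: two identical lobes in q (second pair same effective polarity)
    t_probe = np.linspace(0, BIG_DELTA + DELTA, 50)
    shift = 50.0 - (BIG_DELTA + DELTA)
    np.testing.assert_allclose(q(t_probe * 1e-3), q((t_probe + shift) * 1e-3), atol=1e-9)
    # piecewise-linear extrema sit at breakpoints
    dense = np.linspace(q.times[0], q.times[-1], 20001)
    assert q.max_abs() >= np.max(np.abs(q(dense))) - 1e-12


def test_zero_gradient_gives_zero_everything():
    w = make_dde(0.0, DELTA, BIG_DELTA, 50.0, False)
    q = dephasing(w)
    assert q.max_abs() == 0.0
    assert bvalue(w) == 0.0
    assert cvalue(w) == 0.0


@pytest.mark.parametrize("delta,Delta", [(3.0, 5.0), (5.0, 12.0), (8.6, 10.0), (8.6, 20.0)])
@pytest.mark.parametrize("fc", [False, True])
def test_bvalue_closed_form_grid(delta, Delta, fc):
    G = 35.0
    w = make_dde(G, delta, Delta, 2 * (Delta + delta) + 11.0, fc)
    assert bvalue(w) == pytest.approx(dde_b_closed_form(G, delta, Delta), rel=1e-10)


def test_bvalue_quadratic_in_G_and_fc_equivalence():
    b1 = bvalue(make_dde(20.0, DELTA, BIG_DELTA, 50.0, False))
    b2 = bvalue(make_dde(40.0, DELTA, BIG_DELTA, 50.0, False))
    assert b2 == pytest.approx(4.0 * b1, rel=1e-12)
    assert bvalue(make_dde(40.0, DELTA, BIG_DELTA, 50.0, True)) == pytest.approx(
        b2, rel=1e-12
    )


def test_bvalue_against_numeric_quadrature():
    w = make_dde(51.463, DELTA, BIG_DELTA, 50.0, False)
    q = dephasing(w)
    num = sum(
        quad(lambda t: q(t) ** 2, a, b, limit=200)[0]
        for a, b in zip(q.times[:-1], q.times[1:])
    )
    assert bvalue(w) == pytest.approx(num * 1e-6, rel=1e-10)


def test_cvalue_conventions():
    G = 40.0
    nc = make_dde(G, DELTA, BIG_DELTA, 50.0, False)
    fc = make_dde(G, DELTA, BIG_DELTA, 50.0, True)
    # analytic 2 gamma G delta Delta, converted to s/mm
    expected = 2.0 * GAMMA * (G * 1e-3) * (DELTA * 1e-3) * (BIG_DELTA * 1e-3) * 1e-3
    assert cvalue(nc) == pytest.approx(expected, rel=1e-10)
    assert cvalue(nc) > 0  # nonnegative by convention
    assert abs(cvalue(fc)) < 1e-12 * expected
    # quadrature oracle
    q = dephasing(nc)
    num = sum(
        quad(lambda t: q(t), a, b, limit=200)[0]
        for a, b in zip(q.times[:-1], q.times[1:])
    )
    assert cvalue(nc) == pytest.approx(-num * 1e-3, rel=1e-10)


def test_strength_for_b_roundtrip_and_oracle():
    assert strength_for_b(0.0, DELTA, BIG_DELTA) == 0.0
    G = strength_for_b(200.0, DELTA, BIG_DELTA)
    assert bvalue(make_dde(G, DELTA, BIG_DELTA, 50.0, False)) == pytest.approx(
        200.0, rel=1e-10
    )
    # independent root-finding oracle on the numeric b-value
    G_root = brentq(
        lambda g: bvalue(make_dde(g, DELTA, BIG_DELTA, 50.0, False)) - 200.0,
        1.0,
        200.0,
        xtol=1e-10,
    )
    assert G == pytest.approx(G_root, rel=1e-8)
    with pytest.raises(ValueError):
        strength_for_b(100.0, -1.0, BIG_DELTA)
    with pytest.raises(ValueError):
        strength_for_b(-5.0, DELTA, BIG_DELTA)


try:
    from hypothesis import given, settings, strategies as st

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        G=st.floats(0.5, 80.0),
        delta=st.floats(1.0, 12.0),
        gap=st.floats(0.0, 10.0),
        slack=st.floats(0.0, 60.0),
        fc=st.booleans(),
    )
    def test_dde_properties_hold_for_random_timings(G, delta, gap, slack, fc):
        """Rephasing, b-value closed form and c-value conventions for
        arbitrary valid (G, delta, Delta, T) combinations."""
        Delta = delta + gap
        T = 2 * (Delta + delta) + slack
        w = make_dde(G, delta, Delta, T, fc)
        assert abs(np.sum(w.amplitudes * np.diff(w.breakpoints))) < 1e-12 * G * delta
        assert bvalue(w) == pytest.approx(dde_b_closed_form(G, delta, Delta), rel=1e-9)
        c = cvalue(w)
        c_scale = 2.0 * GAMMA * (G * 1e-3) * (delta * 1e-3) * (Delta * 1e-3) * 1e-3
        if fc:
            assert abs(c) < 1e-12 * c_scale
        else:
            assert c == pytest.approx(c_scale, rel=1e-9)
        q = dephasing(w)
        assert q.values[0] == 0.0 and q.values[-1] == 0.0

except ImportError:  # pragma: no cover - hypothesis is an optional test dep
    pass


def test_waveform_serialization_roundtrip(tmp_path):
    w = make_dde(51.4, DELTA, BIG_DELTA, 60.0, True, label="fc test")
    path = tmp_path / "wf.txt"
    save_waveform(w, path)
    w2 = load_waveform(path)
    np.testing.assert_allclose(w2.breakpoints, w.breakpoints)
    np.testing.assert_allclose(w2.amplitudes, w.amplitudes)
    assert (w2.delta, w2.Delta, w2.T, w2.m) == (w.delta, w.Delta, w.T, w.m)
    assert w2.label == "fc test"
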