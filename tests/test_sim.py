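"""0D Windkessel simulator: stepper accuracy, flow splits, convergence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from carotidwk.sim import (Waveform, WindkesselBC, multi_outlet_split,
                           periodic_convergence, rcr_outlet_pressure,
                           resistive_divider_splits, synth_inflow)


def sinusoid_pressure_exact(t, bc, q0, amp, omega):
    """Integrating-factor (impedance phasor) solution for Q = q0 + amp*sin."""
    z = bc.proximal_resistance + bc.distal_resistance / (
        1 + 1j * omega * bc.distal_resistance * bc.compliance
    )
    return (bc.distal_pressure + q0 * bc.total_resistance
            + np.real(z * (-1j * amp) * np.exp(1j * omega * t)))


def constant_waveform(period=0.55, q=5.35e-6, samples=64):
    t = np.linspace(0.0, period, samples + 1)
    return Waveform(period=period, time=t, flow=np.full(samples + 1, q))


ICA_BC = WindkesselBC(4.80e6, 3.79e-14, 5.89e7)
ECA_BC = WindkesselBC(1.11e7, 3.89e-13, 3.19e7)


def test_constant_inflow_reaches_ohmic_steady_state():
    bc = WindkesselBC(4.80e6, 2e-10, 5.89e7, distal_pressure=1333.0)
    res = rcr_outlet_pressure(constant_waveform(), bc)
    expected = 1333.0 + 5.35e-6 * bc.total_resistance
    assert res.pressure[-1] == pytest.approx(expected, rel=1e-12)
    assert res.converged


def test_zero_flow_decays_exponentially_with_rd_c():
    bc = WindkesselBC(1e7, 5e-10, 5e7)
    tau = bc.time_constant
    period = 0.55
    t = np.linspace(0.0, period, 65)
    w = Waveform(period=period, time=t, flow=np.zeros(65))
    p0 = 1e4
    res = rcr_outlet_pressure(w, bc, dt=period / 8000, max_cycles=1,
                              p_init=p0, tol=1e-12)
    expected = p0 * np.exp(-res.time / tau)
    assert np.max(np.abs(res.pressure - expected)) / p0 < 2e-3


def test_sinusoidal_forcing_matches_integrating_factor_solution():
    period = 0.55
    omega = 2 * np.pi / period
    bc = WindkesselBC(4.80e6, 2e-10, 5.89e7)
    t = np.linspace(0.0, period, 513)
    q0, amp = 5.35e-6, 2e-6
    w = Waveform(period=period, time=t, flow=q0 + amp * np.sin(omega * t))
    res = rcr_outlet_pressure(w, bc, dt=period / 4000, max_cycles=40, tol=1e-10)
    assert res.converged
    steps = 4000
    tl = res.time[-(steps + 1):]
    exact = sinusoid_pressure_exact(tl, bc, q0, amp, omega)
    err = np.max(np.abs(res.pressure[-(steps + 1):] - exact))
    assert err / np.max(np.abs(exact)) < 0.005


def test_stepper_is_first_order():
    period = 0.55
    omega = 2 * np.pi / period
    bc = WindkesselBC(4.80e6, 2e-10, 5.89e7)
    t = np.linspace(0.0, period, 513)
    q0, amp = 5.35e-6, 2e-6
    w = Waveform(period=period, time=t, flow=q0 + amp * np.sin(omega * t))

    def max_err(dt_frac):
        res = rcr_outlet_pressure(w, bc, dt=period / dt_frac, max_cycles=60,
                                  tol=1e-12)
        steps = dt_frac
        tl = res.time[-(steps + 1):]
        exact = sinusoid_pressure_exact(tl, bc, q0, amp, omega)
        return np.max(np.abs(res.pressure[-(steps + 1):] - exact))

    ratio = max_err(256) / max_err(512)
    assert 1.5 < ratio < 3.0  # halving dt roughly halves the error


def test_divergence_and_grid_validation_errors():
    with pytest.raises(ValueError, match="dt"):
        rcr_outlet_pressure(constant_waveform(), ICA_BC, dt=0.55 / 10)
    t = np.linspace(0.0, 0.55, 65)
    q = np.linspace(1e-6, 2e-6, 65)  # open at the seam
    with pytest.raises(ValueError, match="non-periodic"):
        Waveform(period=0.55, time=t, flow=q).flow_at(0.1)
    with pytest.raises(ValueError, match="16 samples"):
        Waveform(period=0.55, time=np.linspace(0, 0.55, 8),
                 flow=np.zeros(8))


def test_multi_outlet_conserves_flow_and_matches_divider():
    inflow = synth_inflow(period=0.55, mean_flow=5.35e-6)
    res = multi_outlet_split(inflow, {"ICA": ICA_BC, "ECA": ECA_BC},
                             max_cycles=30, tol=1e-7)
    assert res.converged
    assert res.flow_balance_error < 1e-12 * 5.35e-6
    divider = resistive_divider_splits({"ICA": ICA_BC, "ECA": ECA_BC})
    assert res.mean_splits["ICA"] == pytest.approx(divider["ICA"], rel=0.005)
    assert divider["ICA"] == pytest.approx(0.403, abs=0.001)
    assert sum(res.mean_splits.values()) == pytest.approx(1.0, rel=1e-12)


@given(
    rps=st.lists(st.floats(min_value=2e6, max_value=3e7), min_size=2, max_size=4),
    rds=st.lists(st.floats(min_value=2e7, max_value=2e8), min_size=2, max_size=4),
    cs=st.lists(st.floats(min_value=5e-11, max_value=2e-9), min_size=2, max_size=4),
)
@settings(max_examples=10, deadline=None, derandomize=True)
def test_mean_split_theorem_randomized(rps, rds, cs):
    n = min(len(rps), len(rds), len(cs))
    bcs = [WindkesselBC(rps[i], cs[i], rds[i]) for i in range(n)]
    if n < 2:
        return
    inflow = synth_inflow(period=0.55, mean_flow=5.35e-6)
    res = multi_outlet_split(inflow, bcs, max_cycles=40, tol=1e-7)
    divider = resistive_divider_splits(bcs)
    for name, share in divider.items():
        assert res.mean_splits[name] == pytest.approx(share, rel=0.005)


def test_compliance_shifts_shape_not_mean_split():
    inflow = synth_inflow(period=0.55, mean_flow=5.35e-6)
    # compliances large enough that Rd*C is a visible fraction of the beat
    pair = [WindkesselBC(4.80e6, 1e-10, 5.89e7),
            WindkesselBC(1.11e7, 2e-10, 3.19e7)]
    scaled = [WindkesselBC(b.proximal_resistance, 10 * b.compliance,
                           b.distal_resistance) for b in pair]
    base = multi_outlet_split(inflow, pair, max_cycles=40, tol=1e-7)
    tenfold = multi_outlet_split(inflow, scaled, max_cycles=40, tol=1e-7)
    assert tenfold.mean_splits["outlet1"] == pytest.approx(
        base.mean_splits["outlet1"], rel=0.005)
    # but the waveform shape does change
    q_base = base.flows["outlet1"][-500:]
    q_ten = tenfold.flows["outlet1"][-500:]
    assert np.max(np.abs(q_base - q_ten)) > 0.01 * np.max(np.abs(q_base))


def test_pressure_bounded_and_finite_for_bounded_inflow():
    inflow = synth_inflow(period=0.55, mean_flow=5.35e-6)
    res = multi_outlet_split(inflow, [ICA_BC, ECA_BC], max_cycles=10)
    assert np.all(np.isfinite(res.pressure))
    q_peak = np.max(inflow.flow)
    r_max = max(b.total_resistance for b in (ICA_BC, ECA_BC))
    assert np.max(np.abs(res.pressure)) < 2 * q_peak * r_max


def test_synth_inflow_mean_and_positivity():
    w = synth_inflow(period=0.55, mean_flow=5.35e-6)
    assert w.mean() == pytest.approx(5.35e-6, rel=1e-12)
    assert np.min(w.flow) > 0
    const = synth_inflow(period=0.753, mean_flow=1e-6, harmonics=[])
    assert np.allclose(const.flow, 1e-6)
    with pytest.raises(ValueError, match="non-positive"):
        synth_inflow(harmonics=[1.5], phases=[0.0])
    # explicit opt-in permits negative excursions
    w2 = synth_inflow(harmonics=[1.5], phases=[0.0], allow_negative=True)
    assert np.min(w2.flow) < 0


def test_periodic_convergence_detector():
    rows = [[1.0, 2.0], [1.0, 2.0], [1.0, 2.0]]
    assert periodic_convergence(rows, tol=1e-4) == 2
    ramp = [[1.0], [2.0], [2.2], [2.2001], [2.20011]]
    assert periodic_convergence(ramp, tol=1e-3) == 4
    with pytest.raises(ValueError):
        periodic_convergence([[1.0]])
    with pytest.warns(UserWarning):
        assert periodic_convergence([[1.0], [2.0], [4.0]], tol=1e-6) == -1


def test_fast_relaxation_converges_within_seven_cycles():
    # Rd*C much smaller than the period: transients die within a beat
    bcs = [WindkesselBC(5e6, 1e-10, 6e7), WindkesselBC(1e7, 1e-10, 3e7)]
    inflow = synth_inflow(period=0.55, mean_flow=5.35e-6)
    res = multi_outlet_split(inflow, bcs, max_cycles=7, tol=1e-3)
    assert res.converged and res.converged_cycle <= 7
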