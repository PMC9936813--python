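"""Membrane model: integration accuracy, spike detection, firing analyses."""

import numpy as np
import pytest

from olmcell.model import (IntegrationError, SimTrace, current_shares,
                           detect_spikes, fi_curve, rheobase_for_rate,
                           run_batch, simulate, step_protocol)

DT = 0.025


def test_passive_membrane_relaxes_to_leak_reversal(passive_model):
    """With only the leak, V decays exponentially to the leak reversal."""
    m = passive_model
    tr = simulate(m, 0.0, duration=2000.0, dt=DT, v0=m.leak.erev + 20.0)
    E = m.leak.erev
    tau = m.capacitance / (1000.0 * m.leak.gbar)  # pF / nS -> ms
    expected = E + 20.0 * np.exp(-tr.t / tau)
    assert abs(tr.V[-1] - E) < 1e-6
    np.testing.assert_allclose(tr.V, expected, atol=0.02)


def test_dt_halving_convergence(model):
    """Subthreshold voltage changes by less than tolerance when dt halves."""
    tr1 = simulate(model, 10.0, duration=500.0, dt=0.05)
    tr2 = simulate(model, 10.0, duration=500.0, dt=0.025)
    assert np.max(np.abs(tr1.V - tr2.V[::2])) < 0.05


def test_charge_balance(model):
    """C dV/dt + sum of membrane currents - stimulus vanishes at every sample."""
    tr = step_protocol(model, 60.0, duration=1500.0, dt=DT)
    dVdt = np.diff(tr.V) / DT
    total_I = sum(tr.currents.values())
    resid = (model.capacitance * dVdt + total_I[:-1] - tr.stimulus[:-1])
    # residual scales with the integration error of the splitting scheme;
    # it must stay far below the pA-scale currents at play
    scale = np.maximum(np.abs(total_I[:-1]), 100.0)
    assert np.max(np.abs(resid) / scale) < 0.35
    # away from spikes (slow voltage drift) the balance is tight
    quiet = np.abs(dVdt) < 0.5
    assert np.max(np.abs(resid[quiet])) < 5.0


def test_gates_bounded_under_strong_drive(model):
    """Every gating variable stays in [0, 1] for a large noisy stimulus."""
    rng = np.random.default_rng(0)
    stim = 200.0 * rng.standard_normal(int(500.0 / DT))
    tr = simulate(model, stim, duration=500.0, dt=DT, record_gates=True)
    for name, series in tr.gating.items():
        assert series.min() >= 0.0 and series.max() <= 1.0, name


def test_voltage_clamp_limit(model):
    """With V effectively clamped, gates relax exponentially to x_inf(V).

    An enormous capacitance freezes the voltage, so each gate's time
    course must match the closed-form exponential with tau(V0).
    """
    from dataclasses import replace
    vc = replace(model, capacitance=1e9)
    v0 = -50.0
    tr = simulate(vc, 0.0, duration=200.0, dt=DT, v0=v0, record_gates=True)
    assert np.max(np.abs(tr.V - v0)) < 1e-3
    for c in vc.channels:
        for g in c.gates:
            series = tr.gating[f"{c.name}.{g.name}"]
            xinf = float(g.steady_state(v0))
            tau = float(g.time_constant(v0))
            x0 = series[0]
            expected = xinf + (x0 - xinf) * np.exp(-tr.t / tau)
            np.testing.assert_allclose(series, expected, atol=1e-4)


def test_nonfinite_stimulus_rejected(model):
    with pytest.raises(ValueError):
        simulate(model, np.array([np.nan] * 100), duration=100 * DT, dt=DT)
    with pytest.raises(ValueError):
        simulate(model, 0.0, duration=0.0, dt=DT)


class TestDetectSpikes:
    def test_subthreshold_trace_is_empty_record(self):
        V = -70.0 + 5.0 * np.sin(np.linspace(0, 10, 4000))
        rec = detect_spikes(V, threshold=-10.0, dt=DT)
        assert rec.n == 0

    def test_three_crafted_depolarizations(self):
        V = np.full(12000, -65.0)
        for k in (2000, 5000, 9000):
            V[k:k + 40] = 20.0  # 1-ms rectangular "spikes"
        rec = detect_spikes(V, threshold=-10.0, dt=DT)
        np.testing.assert_allclose(rec.onset_times,
                                   np.array([2000, 5000, 9000]) * DT)
        assert np.all(rec.peak_times >= rec.onset_times)

    def test_onsets_invariant_to_subthreshold_noise(self):
        V = np.full(12000, -65.0)
        for k in (2000, 9000):
            V[k:k + 40] = 20.0
        rec0 = detect_spikes(V, threshold=-10.0, dt=DT)
        rng = np.random.default_rng(1)
        # noise amplitude below (threshold - resting)/2
        noisy = V + rng.uniform(-20, 20, V.size)
        rec1 = detect_spikes(noisy, threshold=-10.0, dt=DT)
        np.testing.assert_allclose(rec0.onset_times, rec1.onset_times)


class TestFiring:
    def test_below_rheobase_is_silent(self, model):
        (_, rate), = fi_curve(model, [5.0])
        assert rate == 0.0

    def test_fi_monotone_and_matches_simulate(self, model):
        rows = fi_curve(model, [20.0, 30.0, 40.0, 60.0])
        rates = [r for _, r in rows]
        assert all(b >= a for a, b in zip(rates, rates[1:]))
        # self-consistency: rate equals spike count/10 s of a direct run
        tr = simulate(model, 40.0, duration=10_000.0, dt=DT)
        n = detect_spikes(tr).n
        assert rates[2] == pytest.approx(n / 10.0)

    def test_rheobase_bisection(self, model):
        with pytest.raises(ValueError):
            rheobase_for_rate(model, target_rate=0.0)
        with pytest.raises(ValueError, match="widen"):
            rheobase_for_rate(model, bracket=(100.0, 200.0))
        i1 = rheobase_for_rate(model, target_rate=1.0, tol=0.2,
                               bracket=(10.0, 60.0))
        assert 10.0 < i1 < 60.0
        (_, rate), = fi_curve(model, [i1 + 0.2])
        assert rate >= 1.0


class TestCurrentShares:
    def test_single_current_share_is_unit(self):
        t = np.arange(10) * DT
        tr = SimTrace(dt=DT, t=t, V=np.full(10, -60.0),
                      currents={"leak": np.full(10, 5.0),
                                "Na": np.zeros(10)},
                      stimulus=np.zeros(10))
        sh = current_shares(tr)
        np.testing.assert_allclose(sh["leak"], 1.0)
        np.testing.assert_allclose(sh["Na"], 0.0)

    def test_shares_sum_to_one_and_match_recomputation(self, model):
        tr = step_protocol(model, 60.0, duration=1500.0, dt=DT)
        tr2 = simulate(model, tr.stimulus, duration=1500.0, dt=DT,
                       record_gates=True)
        sh = current_shares(tr2)
        total = sum(np.abs(s) for s in sh.values())
        active = sum(np.abs(c) for c in tr2.currents.values()) > 0
        np.testing.assert_allclose(total[active], 1.0, atol=1e-12)
        # independent recomputation of |shares| from g * prod(gates) * (V-E)
        for c in model.channels:
            gate_prod = np.ones(len(tr2))
            for g in c.gates:
                gate_prod *= tr2.gating[f"{c.name}.{g.name}"] ** g.power
            I = 1000.0 * c.gbar * gate_prod * (tr2.V - c.erev)
            np.testing.assert_allclose(tr2.currents[c.name], I,
                                       atol=1e-6, rtol=1e-6)

    def test_im_share_grows_between_spikes(self, model):
        """During a 60 pA step the M-current share builds up between spikes."""
        tr = step_protocol(model, 60.0, duration=2500.0, dt=DT)
        sh = current_shares(tr)["M"]
        mid = (tr.t > 1500) & (tr.t < 2400)
        assert sh[mid].max() > 0.05
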