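"""Low-level batched integrator for single-compartment conductance models.

The kernel advances ``B`` independent membranes in lock-step over a shared
time grid.  Gates use exponential-Euler updates against their
voltage-dependent steady state; the voltage update is also exponential-Euler
on the membrane equation with gates frozen over the step (the equation is
linear in V once the gates are held), which keeps the scheme stable for
Hodgkin-Huxley-type stiffness at dt = 0.025 ms.

Units: mV, ms, pA, uS, pF.  A conductance g (uS) times a driving force (mV)
is a current in nA, hence the factor 1000 converting to pA.

Gating functional forms are encoded as small integer codes plus parameter
rows so that arbitrary channel definitions loaded from JSON can run through
one compiled kernel:

steady state (code ``inf`` is always a Boltzmann)::

    x_inf(V) = 1 / (1 + exp((V - vhalf) / k))   # k < 0: activation

time constant forms (``tau_form``)::

    0: tau = p0                                  (constant)
    1: tau = p0 + p1 * exp(-((V - p2) / p3)^2)   (Gaussian bell)
    2: tau = p0 + p1 / (exp((V - p2)/p3) + exp(-(V - p2)/p4))
"""

from __future__ import annotations

import numpy as np
from numba import njit

TAU_CONSTANT = 0
TAU_GAUSS = 1
TAU_BELL = 2


@njit(cache=False)
def gate_inf(v, vhalf, k):
    return 1.0 / (1.0 + np.exp((v - vhalf) / k))


@njit(cache=False)
def gate_tau(v, form, p):
    if form == TAU_CONSTANT:
        return p[0]
    elif form == TAU_GAUSS:
        z = (v - p[2]) / p[3]
        return p[0] + p[1] * np.exp(-z * z)
    else:
        return p[0] + p[1] / (np.exp((v - p[2]) / p[3]) + np.exp(-(v - p[2]) / p[4]))


@njit(cache=False)
def integrate(V, gates, gbar, erev,
              gate_chan, gate_pow, inf_vh, inf_k, tau_form, tau_p,
              cap, dt,
              istim, ioffset, ge, gi, Ee, Ei,
              out_V, out_cur, rec_cur, out_gates, rec_gates):
    """Advance the batch over the full stimulus, recording along the way.

    V : (B,) initial voltages, overwritten in place with the final state.
    gates : (B, G) gating variables, in place.
    gbar : (B, C) maximal conductances in uS (per-batch so that parameter
        filters can propagate sigma points with distinct conductances).
    istim : (T,) shared injected current (pA); ioffset : (B,) per-batch
        constant addend (used for f-I batches and holding currents).
    ge, gi : (B, Te)/(B, Ti) synaptic conductance series (uS); pass a
        (B, 1) zero array when unused.  Negative excursions are clipped.
    out_V : (B, T) voltage record; out_cur : (B, C + 1, T) per-channel and
        synaptic current record (pA, outward positive) when rec_cur.
    Returns -1 on success, else the sample index where the state went
    non-finite.
    """
    B, G = gates.shape
    C = gbar.shape[1]
    T = istim.shape[0]
    chan_open = np.empty(C)
    for b in range(B):
        ge_var = ge.shape[1] > 1
        gi_var = gi.shape[1] > 1
        for k in range(T):
            v = V[b]
            for c in range(C):
                chan_open[c] = 1.0
            for g in range(G):
                x = gates[b, g]
                p = gate_pow[g]
                xp = x
                for _ in range(p - 1):
                    xp *= x
                chan_open[gate_chan[g]] *= xp
            gtot = 0.0
            gE = 0.0
            for c in range(C):
                gc = gbar[b, c] * chan_open[c]
                gtot += gc
                gE += gc * erev[c]
                if rec_cur:
                    out_cur[b, c, k] = 1000.0 * gc * (v - erev[c])
            gec = ge[b, k] if ge_var else ge[b, 0]
            gic = gi[b, k] if gi_var else gi[b, 0]
            if gec < 0.0:
                gec = 0.0
            if gic < 0.0:
                gic = 0.0
            gtot += gec + gic
            gE += gec * Ee + gic * Ei
            if rec_cur:
                out_cur[b, C, k] = 1000.0 * (gec * (v - Ee) + gic * (v - Ei))
            iin = istim[k] + ioffset[b]
            out_V[b, k] = v
            if rec_gates:
                for g in range(G):
                    out_gates[b, g, k] = gates[b, g]
            # gates: exponential Euler toward steady state at the current V
            for g in range(G):
                xi = gate_inf(v, inf_vh[g], inf_k[g])
                tau = gate_tau(v, tau_form[g], tau_p[g])
                gates[b, g] = xi + (gates[b, g] - xi) * np.exp(-dt / tau)
                if gates[b, g] < 0.0:
                    gates[b, g] = 0.0
                elif gates[b, g] > 1.0:
                    gates[b, g] = 1.0
            # voltage: exponential Euler on C dV/dt = iin - 1000*(gtot*v - gE)
            if gtot > 1e-12:
                vinf = (iin / 1000.0 + gE) / gtot
                V[b] = vinf + (v - vinf) * np.exp(-dt * 1000.0 * gtot / cap)
            else:
                V[b] = v + dt * iin / cap
            if not np.isfinite(V[b]):
                return k
    return -1


@njit(cache=False)
def step_batch(V, gates, gbar, erev,
               gate_chan, gate_pow, inf_vh, inf_k, tau_form, tau_p,
               cap, dt, iin):
    """Single integration step for a batch with per-batch conductances.

    Used by the unscented filter to push sigma points (each carrying its
    own conductance vector) through one observation interval.  Same update
    rule as :func:`integrate`.  In-place on V and gates.
    """
    B, G = gates.shape
    C = gbar.shape[1]
    chan_open = np.empty(C)
    for b in range(B):
        v = V[b]
        for c in range(C):
            chan_open[c] = 1.0
        for g in range(G):
            x = gates[b, g]
            xp = x
            for _ in range(gate_pow[g] - 1):
                xp *= x
            chan_open[gate_chan[g]] *= xp
        gtot = 0.0
        gE = 0.0
        for c in range(C):
            gc = gbar[b, c] * chan_open[c]
            if gc < 0.0:
                gc = 0.0
            gtot += gc
            gE += gc * erev[c]
        for g in range(G):
            xi = gate_inf(v, inf_vh[g], inf_k[g])
            tau = gate_tau(v, tau_form[g], tau_p[g])
            gates[b, g] = xi + (gates[b, g] - xi) * np.exp(-dt / tau)
            if gates[b, g] < 0.0:
                gates[b, g] = 0.0
            elif gates[b, g] > 1.0:
                gates[b, g] = 1.0
        if gtot > 1e-12:
            vinf = (iin / 1000.0 + gE) / gtot
            V[b] = vinf + (v - vinf) * np.exp(-dt * 1000.0 * gtot / cap)
        else:
            V[b] = v + dt * iin / cap
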