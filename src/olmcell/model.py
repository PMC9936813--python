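"""Single-compartment conductance-based OLM interneuron model.

The reduced model carries five active currents -- transient sodium (INa),
fast delayed-rectifier potassium (IKdrf), A-type potassium (IKa),
muscarinic-type slow potassium (IM) and the hyperpolarization-activated
cation current (Ih) -- plus an ohmic leak, in one isopotential compartment:

    C dV/dt = I_inj - sum_x gbar_x * prod(gates^p) * (V - E_x) - I_syn

Gating variables follow first-order kinetics dx/dt = (x_inf(V) - x)/tau_x(V)
with Boltzmann steady states and parameterized time-constant curves.  The
kinetics are data, not code: they are loaded from a JSON channel definition
(see :mod:`olmcell.io`), so alternative channel fits can be swapped in
without touching the integrator.

Units throughout: mV, ms, pA, uS, pF.  Currents are reported outward
positive (potassium currents positive above their reversal, sodium
negative), matching the sign convention of current-share plots.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from . import _kernel


class IntegrationError(RuntimeError):
    """Raised when the membrane state becomes non-finite during a run."""


# ---------------------------------------------------------------------------
# gating functional forms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Boltzmann:
    """Steady-state curve 1 / (1 + exp((V - vhalf)/k)); k < 0 activates."""
    vhalf: float
    k: float

    def __call__(self, v):
        return 1.0 / (1.0 + np.exp((np.asarray(v, dtype=float) - self.vhalf) / self.k))


@dataclass(frozen=True)
class TauConstant:
    tau: float

    code = _kernel.TAU_CONSTANT

    def params(self):
        return [self.tau, 0.0, 0.0, 1.0, 1.0]

    def __call__(self, v):
        return np.full_like(np.asarray(v, dtype=float), self.tau)


@dataclass(frozen=True)
class TauGauss:
    """tau(V) = base + amp * exp(-((V - vpeak)/sigma)^2), in ms."""
    base: float
    amp: float
    vpeak: float
    sigma: float

    code = _kernel.TAU_GAUSS

    def params(self):
        return [self.base, self.amp, self.vpeak, self.sigma, 1.0]

    def __call__(self, v):
        z = (np.asarray(v, dtype=float) - self.vpeak) / self.sigma
        return self.base + self.amp * np.exp(-z * z)


@dataclass(frozen=True)
class TauBell:
    """tau(V) = base + amp / (exp((V-vhalf)/k1) + exp(-(V-vhalf)/k2))."""
    base: float
    amp: float
    vhalf: float
    k1: float
    k2: float

    code = _kernel.TAU_BELL

    def params(self):
        return [self.base, self.amp, self.vhalf, self.k1, self.k2]

    def __call__(self, v):
        v = np.asarray(v, dtype=float)
        return self.base + self.amp / (
            np.exp((v - self.vhalf) / self.k1) + np.exp(-(v - self.vhalf) / self.k2)
        )


@dataclass(frozen=True)
class GatingSpec:
    name: str
    power: int
    steady_state: Boltzmann
    time_constant: TauConstant | TauGauss | TauBell

    def __post_init__(self):
        if self.power < 0:
            raise ValueError("gate power must be a non-negative integer")


@dataclass(frozen=True)
class ChannelSpec:
    """One membrane conductance: maximal conductance, reversal, gates.

    ``gbar`` is the total conductance of the compartment in uS (the
    published channel densities in S/cm^2 times the compartment area).
    """
    name: str
    gbar: float
    erev: float
    gates: tuple[GatingSpec, ...] = ()

    def __post_init__(self):
        if self.gbar < 0:
            raise ValueError(f"gbar must be >= 0 (channel {self.name})")

    def open_fraction(self, gating: dict[str, float]) -> float:
        out = 1.0
        for g in self.gates:
            out *= gating[g.name] ** g.power
        return out


@dataclass
class MembraneModel:
    """Isopotential compartment with a leak and a set of gated channels."""
    capacitance: float                 # pF
    channels: tuple[ChannelSpec, ...]
    bias_current: float = 4.0          # pA, default holding used by protocols
    area_cm2: float | None = None      # for converting gbar <-> density
    name: str = "model"

    def __post_init__(self):
        if self.capacitance <= 0:
            raise ValueError("capacitance must be positive")
        leaks = [c for c in self.channels if not c.gates]
        if len(leaks) != 1:
            raise ValueError("model must contain exactly one gateless (leak) channel")
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ValueError("duplicate channel names")

    @property
    def leak(self) -> ChannelSpec:
        return next(c for c in self.channels if not c.gates)

    def channel(self, name: str) -> ChannelSpec:
        for c in self.channels:
            if c.name == name:
                return c
        raise KeyError(name)

    def with_gbar(self, updates: dict[str, float]) -> "MembraneModel":
        """Copy of the model with some maximal conductances replaced."""
        chans = tuple(
            replace(c, gbar=updates.get(c.name, c.gbar)) for c in self.channels
        )
        return replace(self, channels=chans)

    def gate_names(self) -> list[str]:
        out = []
        for c in self.channels:
            for g in c.gates:
                out.append(f"{c.name}.{g.name}")
        return out

    # -- kernel packing -----------------------------------------------------

    def pack(self) -> dict:
        """Flatten channel/gate definitions into kernel arrays."""
        gate_chan, gate_pow, inf_vh, inf_k, tau_form, tau_p = [], [], [], [], [], []
        for ci, c in enumerate(self.channels):
            for g in c.gates:
                gate_chan.append(ci)
                gate_pow.append(g.power)
                inf_vh.append(g.steady_state.vhalf)
                inf_k.append(g.steady_state.k)
                tau_form.append(g.time_constant.code)
                tau_p.append(g.time_constant.params())
        return {
            "gbar": np.array([c.gbar for c in self.channels], dtype=float),
            "erev": np.array([c.erev for c in self.channels], dtype=float),
            "gate_chan": np.array(gate_chan, dtype=np.int64),
            "gate_pow": np.array(gate_pow, dtype=np.int64),
            "inf_vh": np.array(inf_vh, dtype=float),
            "inf_k": np.array(inf_k, dtype=float),
            "tau_form": np.array(tau_form, dtype=np.int64),
            "tau_p": np.array(tau_p, dtype=float).reshape(len(gate_chan), 5),
        }

    def steady_gates(self, v: float) -> np.ndarray:
        out = []
        for c in self.channels:
            for g in c.gates:
                out.append(float(g.steady_state(v)))
        return np.array(out, dtype=float)


# ---------------------------------------------------------------------------
# traces and spikes
# ---------------------------------------------------------------------------

@dataclass
class SimTrace:
    """A simulated recording on a uniform time grid.

    ``currents`` maps channel name -> pA series (outward positive); the key
    ``"syn"`` holds the synaptic current when a synaptic drive was present.
    ``stimulus`` is the injected current actually applied (pA).
    """
    dt: float
    t: np.ndarray
    V: np.ndarray
    currents: dict[str, np.ndarray]
    stimulus: np.ndarray
    gating: dict[str, np.ndarray] = field(default_factory=dict)
    seed: int | None = None

    @property
    def duration(self) -> float:
        return self.t.size * self.dt

    def __len__(self):
        return self.t.size


@dataclass
class SpikeRecord:
    onset_times: np.ndarray   # ms, strictly increasing
    peak_times: np.ndarray    # ms
    detection_threshold: float

    @property
    def n(self) -> int:
        return self.onset_times.size

    def isis(self) -> np.ndarray:
        return np.diff(self.onset_times)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _as_stim_array(stimulus, n: int, dt: float) -> np.ndarray:
    if stimulus is None:
        return np.zeros(n)
    if np.isscalar(stimulus):
        return np.full(n, float(stimulus))
    arr = np.asarray(stimulus, dtype=float)
    if arr.size != n:
        raise ValueError(f"stimulus length {arr.size} != {n} samples")
    if not np.all(np.isfinite(arr)):
        raise ValueError("stimulus contains non-finite values")
    return arr


def run_batch(model: MembraneModel,
              istim: np.ndarray,
              duration: float,
              dt: float,
              *,
              ioffset: np.ndarray | None = None,
              ge: np.ndarray | None = None,
              gi: np.ndarray | None = None,
              Ee: float = 0.0,
              Ei: float = -75.0,
              v0: float | None = None,
              record_currents: bool = False,
              record_gates: bool = False,
              n_batch: int | None = None):
    """Integrate a batch of membranes sharing the model and base stimulus.

    Returns (V, currents, gates, final_state) where V has shape (B, T).
    ``istim`` is the shared injected current (T,), ``ioffset`` a per-batch
    constant addend, ``ge``/``gi`` optional per-batch synaptic conductance
    series in uS, shape (B, T) or (B, 1).
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    T = int(round(duration / dt))
    istim = _as_stim_array(istim, T, dt)
    if n_batch is None:
        n_batch = 1
        for arr in (ioffset, ge, gi):
            if arr is not None:
                n_batch = max(n_batch, np.asarray(arr).shape[0])
    B = n_batch
    if ioffset is None:
        ioffset = np.zeros(B)
    else:
        ioffset = np.asarray(ioffset, dtype=float)
    ge = np.zeros((B, 1)) if ge is None else np.ascontiguousarray(ge, dtype=float)
    gi = np.zeros((B, 1)) if gi is None else np.ascontiguousarray(gi, dtype=float)

    pk = model.pack()
    C = pk["gbar"].size
    G = pk["gate_chan"].size
    if v0 is None:
        v0 = model.leak.erev
    V = np.full(B, float(v0))
    gates = np.tile(model.steady_gates(v0), (B, 1))
    gbar = np.tile(pk["gbar"], (B, 1))

    out_V = np.empty((B, T))
    out_cur = np.empty((B, C + 1, T)) if record_currents else np.empty((1, 1, 1))
    out_gates = np.empty((B, G, T)) if record_gates else np.empty((1, 1, 1))
    fail = _kernel.integrate(
        V, gates, gbar, pk["erev"],
        pk["gate_chan"], pk["gate_pow"], pk["inf_vh"], pk["inf_k"],
        pk["tau_form"], pk["tau_p"],
        model.capacitance, dt,
        istim, ioffset, ge, gi, Ee, Ei,
        out_V, out_cur, record_currents, out_gates, record_gates)
    if fail >= 0:
        raise IntegrationError(
            f"non-finite membrane state at t = {fail * dt:.3f} ms")
    return out_V, (out_cur if record_currents else None), \
        (out_gates if record_gates else None), (V, gates)


def simulate(model: MembraneModel,
             stimulus,
             duration: float,
             dt: float = 0.025,
             seed: int | None = None,
             *,
             ge: np.ndarray | None = None,
             gi: np.ndarray | None = None,
             Ee: float = 0.0,
             Ei: float = -75.0,
             v0: float | None = None,
             record_gates: bool = False) -> SimTrace:
    """Simulate the model under an injected-current stimulus.

    ``stimulus`` may be a scalar (constant pA), an array of per-sample pA
    values covering [0, duration), or None (zero current).  Optional
    ``ge``/``gi`` arrays add a synaptic conductance drive with reversal
    potentials ``Ee``/``Ei``.  Deterministic given (model, stimulus, seed);
    the seed is metadata here -- stochastic stimuli are built upstream (see
    :mod:`olmcell.stimuli`).
    """
    T = int(round(duration / dt))
    istim = _as_stim_array(stimulus, T, dt)
    if T == 0:
        raise ValueError("zero-length stimulus")
    _ge = ge.reshape(1, -1) if ge is not None else None
    _gi = gi.reshape(1, -1) if gi is not None else None
    out_V, out_cur, out_gates, _ = run_batch(
        model, istim, duration, dt, ge=_ge, gi=_gi, Ee=Ee, Ei=Ei, v0=v0,
        record_currents=True, record_gates=record_gates)
    t = np.arange(T) * dt
    names = [c.name for c in model.channels]
    currents = {nm: out_cur[0, i] for i, nm in enumerate(names)}
    if ge is not None or gi is not None:
        currents["syn"] = out_cur[0, -1]
    gating = {}
    if record_gates:
        gating = {nm: out_gates[0, i] for i, nm in enumerate(model.gate_names())}
    return SimTrace(dt=dt, t=t, V=out_V[0], currents=currents,
                    stimulus=istim, gating=gating, seed=seed)


def step_protocol(model: MembraneModel, step_pA: float,
                  t_on: float = 1000.0, t_off: float = 3000.0,
                  duration: float = 4000.0, dt: float = 0.025,
                  holding: float | None = None) -> SimTrace:
    """Holding current plus a rectangular current step (classic step test)."""
    T = int(round(duration / dt))
    hold = model.bias_current if holding is None else holding
    stim = np.full(T, hold)
    k0, k1 = int(round(t_on / dt)), int(round(t_off / dt))
    stim[k0:k1] += step_pA
    return simulate(model, stim, duration, dt)


# ---------------------------------------------------------------------------
# spike detection and firing analyses
# ---------------------------------------------------------------------------

def detect_spikes(trace_or_V, threshold: float = -10.0,
                  dt: float | None = None) -> SpikeRecord:
    """Detect spike onsets as upward crossings of ``threshold``.

    Accepts a :class:`SimTrace` or a raw voltage array (then ``dt`` is
    required).  The onset time is the first sample at or above threshold;
    the peak is the local voltage maximum within 3 ms after onset.  An
    empty record is a valid result for subthreshold traces.
    """
    if isinstance(trace_or_V, SimTrace):
        V = trace_or_V.V
        dt = trace_or_V.dt
    else:
        V = np.asarray(trace_or_V, dtype=float)
        if dt is None:
            raise ValueError("dt required when passing a raw voltage array")
    if V.size == 0:
        raise ValueError("empty trace")
    above = V >= threshold
    onsets = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above[0]:
        onsets = np.concatenate(([0], onsets))
    w = max(1, int(round(3.0 / dt)))
    peaks = np.array([k + int(np.argmax(V[k:k + w + 1])) for k in onsets],
                     dtype=float)
    return SpikeRecord(onset_times=onsets * dt, peak_times=peaks * dt,
                       detection_threshold=threshold)


def spike_onsets_batch(V: np.ndarray, dt: float,
                       threshold: float = -10.0) -> list[np.ndarray]:
    """Per-row spike onset times (ms) for a (B, T) voltage batch."""
    above = V >= threshold
    out = []
    for b in range(V.shape[0]):
        ons = np.flatnonzero(above[b, 1:] & ~above[b, :-1]) + 1
        if above[b, 0]:
            ons = np.concatenate(([0], ons))
        out.append(ons * dt)
    return out


def fi_curve(model: MembraneModel, currents: Sequence[float],
             duration: float = 10_000.0, dt: float = 0.025,
             threshold: float = -10.0) -> list[tuple[float, float]]:
    """Firing rate versus injected current, rates counted over ``duration``.

    Each current is the full constant injection (holding included); rates
    are spike counts divided by the interval, so a 10 s run resolves
    0.1 Hz.
    """
    if duration < 10_000.0:
        raise ValueError("rate estimates need >= 10 s of simulation")
    cur = np.asarray(list(currents), dtype=float)
    out_V, _, _, _ = run_batch(model, np.zeros(int(round(duration / dt))),
                               duration, dt, ioffset=cur)
    onsets = spike_onsets_batch(out_V, dt, threshold)
    return [(float(c), len(o) / (duration / 1000.0))
            for c, o in zip(cur, onsets)]


def rheobase_for_rate(model: MembraneModel, target_rate: float = 1.0,
                      tol: float = 0.05,
                      bracket: tuple[float, float] = (0.0, 200.0),
                      duration: float = 10_000.0, dt: float = 0.025) -> float:
    """Bisect for the constant current giving the target sustained rate.

    Finds the smallest current whose 10-s spike count reaches
    ``target_rate`` (counting resolution 0.1 Hz for 10 s runs).  Raises if
    the bracket does not straddle the target.
    """
    if target_rate <= 0:
        raise ValueError("target rate must be positive (0 Hz is not bracketable)")

    def rate(i):
        return fi_curve(model, [i], duration, dt)[0][1]

    lo, hi = bracket
    r_lo, r_hi = rate(lo), rate(hi)
    if r_lo >= target_rate or r_hi < target_rate:
        raise ValueError(
            f"bracket ({lo}, {hi}) pA does not straddle {target_rate} Hz: "
            f"rates ({r_lo}, {r_hi}); widen the interval")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if rate(mid) >= target_rate:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def current_shares(trace: SimTrace,
                   include_syn: bool = False) -> dict[str, np.ndarray]:
    """Signed fractional contribution of each current per timepoint.

    Each share is I_x / sum|I_y| so that sum of |shares| is 1 wherever the
    total absolute current is nonzero (shares are 0 at all-zero
    timepoints).  Inward currents give negative shares, outward positive.
    The stimulus is not a membrane current and is excluded; the synaptic
    current is excluded unless requested, matching current-share plots of
    the intrinsic biophysical currents.
    """
    if not trace.currents:
        raise ValueError("trace has no per-channel currents")
    names = [n for n in trace.currents if include_syn or n != "syn"]
    stack = np.vstack([trace.currents[n] for n in names])
    denom = np.abs(stack).sum(axis=0)
    safe = np.where(denom > 0, denom, 1.0)
    shares = stack / safe
    shares[:, denom == 0] = 0.0
    return {n: shares[i] for i, n in enumerate(names)}
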