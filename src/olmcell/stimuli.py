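"""Stimulus generators: OU background conductances, synaptic perturbation
events, current steps and the noisy step train used for filter estimation.

The in-vivo-like background follows the point-conductance model: the
excitatory and inhibitory synaptic conductances are independent
Ornstein-Uhlenbeck processes

    dg/dt = -(g - g0)/tau + D * N(t)

with white noise N(t), giving a synaptic current
I_syn = ge(t) (V - Ee) + gi(t) (V - Ei).  The discrete update uses the
exact OU transition, so the stationary mean is g0 and the stationary
variance D^2 * tau / 2 at any dt.  Negative conductance excursions are
clipped to zero at use time (inside the integrator), never inside the
generator, so the recorded process keeps its exact moments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter


@dataclass(frozen=True)
class OUBackground:
    """Point-conductance background parameters (one IVL candidate).

    Means g0 and noise parameters D are in uS, time constants in ms,
    reversals in mV.  The stationary sd of each process is
    D * sqrt(tau / 2).
    """
    ge0: float
    gi0: float
    De: float
    Di: float
    tau_e: float = 3.0
    tau_i: float = 7.5
    Ee: float = 0.0
    Ei: float = -86.0

    def __post_init__(self):
        if self.tau_e <= 0 or self.tau_i <= 0:
            raise ValueError("OU time constants must be positive")
        if min(self.ge0, self.gi0, self.De, self.Di) < 0:
            raise ValueError("OU conductance parameters must be non-negative")


def _ou_path(g0: float, D: float, tau: float, n: int, dt: float,
             rng: np.random.Generator) -> np.ndarray:
    """Exact-discretization OU path started at its stationary distribution."""
    phi = np.exp(-dt / tau)
    sd_stat = D * np.sqrt(tau / 2.0)
    if D == 0:
        return np.full(n, g0)
    innov_sd = sd_stat * np.sqrt(1.0 - phi * phi)
    z = rng.standard_normal(n)
    x0 = sd_stat * z[0]
    # AR(1) on the deviation from g0: x_k = phi x_{k-1} + innov_sd * z_k
    x = np.empty(n)
    x[0] = x0
    if n > 1:
        x[1:] = lfilter([1.0], [1.0, -phi], innov_sd * z[1:], zi=[phi * x0])[0]
    return g0 + x


def ou_conductances(bg: OUBackground, duration: float, dt: float,
                    seed: int | np.random.Generator | None = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Sample the excitatory and inhibitory OU conductance paths.

    Deterministic given the seed.  Paths start from the stationary
    distribution so long-run sample moments match g0 and D^2 tau / 2
    without a burn-in.
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    n = int(round(duration / dt))
    ge = _ou_path(bg.ge0, bg.De, bg.tau_e, n, dt, rng)
    gi = _ou_path(bg.gi0, bg.Di, bg.tau_i, n, dt, rng)
    return ge, gi


def synaptic_current(ge, gi, V, Ee: float = 0.0, Ei: float = -75.0) -> np.ndarray:
    """I_syn = ge (V - Ee) + gi (V - Ei), in pA for uS and mV inputs."""
    ge = np.asarray(ge, dtype=float)
    gi = np.asarray(gi, dtype=float)
    V = np.asarray(V, dtype=float)
    return 1000.0 * (ge * (V - Ee) + gi * (V - Ei))


# ---------------------------------------------------------------------------
# synaptic perturbation events
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynapticKinetics:
    """Double-exponential synaptic event: g(t) ~ exp(-t/decay) - exp(-t/rise).

    ``weight`` is the single-synapse peak conductance in uS; perturbations
    scale it by a multiplicity factor standing in for a population of
    synchronously active synapses.
    """
    weight: float
    rise: float
    decay: float
    erev: float
    polarity: str  # "excitatory" | "inhibitory"

    def __post_init__(self):
        if not (self.decay > self.rise > 0):
            raise ValueError("require decay > rise > 0")
        if self.weight < 0:
            raise ValueError("weight must be >= 0")
        if self.polarity not in ("excitatory", "inhibitory"):
            raise ValueError("polarity must be excitatory or inhibitory")


#: Reference synaptic weights (uS): 30 synchronous synapses are collapsed
#: into one somatic event of 30x the single-synapse weight.
EXC_KINETICS = SynapticKinetics(weight=0.006, rise=0.5, decay=3.0,
                                erev=0.0, polarity="excitatory")
INH_KINETICS = SynapticKinetics(weight=0.0054, rise=1.0, decay=8.0,
                                erev=-86.0, polarity="inhibitory")
PERTURBATION_SCALE = 30.0


def synaptic_kinetics(polarity: str) -> SynapticKinetics:
    return EXC_KINETICS if polarity == "excitatory" else INH_KINETICS


@dataclass(frozen=True)
class PerturbationSpec:
    """Periodic synaptic perturbation at frequency ``frequency`` Hz."""
    frequency: float
    polarity: str
    onset_phase: float = 0.0   # ms, time of the first event
    duration: float | None = None

    def __post_init__(self):
        if self.frequency <= 0:
            raise ValueError("perturbation frequency must be positive")


def event_waveform(kin: SynapticKinetics, duration: float, dt: float,
                   scale: float = PERTURBATION_SCALE) -> np.ndarray:
    """Peak-normalized double-exponential event of amplitude scale*weight."""
    t = np.arange(int(round(duration / dt))) * dt
    raw = np.exp(-t / kin.decay) - np.exp(-t / kin.rise)
    tp = (np.log(kin.decay) - np.log(kin.rise)) / (1 / kin.rise - 1 / kin.decay)
    peak = np.exp(-tp / kin.decay) - np.exp(-tp / kin.rise)
    return scale * kin.weight * raw / peak


def perturbation_conductance(spec: PerturbationSpec, kin: SynapticKinetics,
                             duration: float, dt: float,
                             scale: float = PERTURBATION_SCALE) -> np.ndarray:
    """Conductance series of periodic double-exponential events (uS).

    One event of peak ``scale * weight`` per period 1/frequency, first
    event at ``onset_phase``; overlapping tails superpose additively.
    """
    n = int(round(duration / dt))
    g = np.zeros(n)
    period = 1000.0 / spec.frequency
    # event tail truncated once it decays to < 1e-6 of peak
    tail = int(round(min(duration, kin.decay * 14.0) / dt))
    wave = event_waveform(kin, tail * dt, dt, scale)
    t0 = spec.onset_phase
    if period > duration - t0:
        import warnings
        warnings.warn("perturbation period exceeds the stimulus window; "
                      "only a single event fits")
    while t0 < duration:
        k0 = int(round(t0 / dt))
        k1 = min(n, k0 + wave.size)
        if k0 < n:
            g[k0:k1] += wave[:k1 - k0]
        t0 += period
    return g


# ---------------------------------------------------------------------------
# noisy step train for parameter estimation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RAUKFTrain:
    """Noisy multi-step current protocol exposing the model's dynamic range.

    After ``lead_in`` ms of zero mean current, the injected current steps
    through ``step_levels`` (each ``step_length`` ms), the whole sequence
    repeated ``repeats`` times; Gaussian white noise of mean
    ``noise_mean`` and sd ``noise_sd`` pA is added throughout (the noise
    mean reproduces the model's characterized bias current).
    """
    step_levels: tuple[float, ...] = (30.0, 60.0, 90.0, 0.0, -30.0, -60.0, -90.0)
    step_length: float = 196.0
    lead_in: float = 500.0
    repeats: int = 4
    noise_mean: float = 4.0
    noise_sd: float = 5.0

    @property
    def total_duration(self) -> float:
        return self.lead_in + self.repeats * len(self.step_levels) * self.step_length


def raukf_train(cfg: RAUKFTrain, dt: float,
                seed: int | np.random.Generator | None = None) -> np.ndarray:
    """Sample the noisy step train as a per-sample pA series."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    n = int(round(cfg.total_duration / dt))
    stim = np.zeros(n)
    k = int(round(cfg.lead_in / dt))
    per = int(round(cfg.step_length / dt))
    for _ in range(cfg.repeats):
        for level in cfg.step_levels:
            stim[k:k + per] = level
            k += per
    stim += cfg.noise_mean
    if cfg.noise_sd > 0:
        stim += cfg.noise_sd * rng.standard_normal(n)
    return stim
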