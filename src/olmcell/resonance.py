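"""Spiking resonance and phase-response analyses.

Spiking resonance is measured by entrainment of the spike train to a
periodic synaptic perturbation: each voltage trace is reduced to a binary
spike train (1 at spike onset, 0 elsewhere), its power spectral density
estimated by Welch's method, and the perturbation's effectiveness at
frequency f_i quantified by the baseline ratio

    dPSD(f_i) = PSD_perturbed(f_i) / PSD_baseline(f_i)

where the baseline run shares the OU background seed and differs only by
the absent perturbation.  dPSD = 1 means no effect; the resonant
frequency f_r is the perturbation frequency with the largest dPSD.

The phase response curve (PRC) measures how a single synaptic
perturbation delivered at a given phase of the firing cycle advances or
delays the next spike; alongside it, the per-current change measure
compares each biophysical current's maximum amplitude around the
perturbation with the preceding unperturbed cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import welch

from .model import (MembraneModel, current_shares, detect_spikes, run_batch,
                    spike_onsets_batch)
from .stimuli import (PerturbationSpec, event_waveform, ou_conductances,
                      perturbation_conductance, synaptic_kinetics)

#: Perturbation-frequency set used for the expanded resonance analyses:
#: 0.5 Hz, every integer from 1 to 25, and 30 Hz.
FREQUENCY_SET = (0.5,) + tuple(float(i) for i in range(1, 26)) + (30.0,)

#: Spike trains are binned at 1 ms before the Welch estimate so that the
#: frequency grid resolves 1-Hz-spaced perturbation frequencies.
PSD_BIN_MS = 1.0
PSD_NPERSEG = 20_000


def spike_train_signal(onset_times, duration: float,
                       bin_ms: float = PSD_BIN_MS) -> np.ndarray:
    """Binary spike-onset indicator binned on a bin_ms grid."""
    n = int(round(duration / bin_ms))
    train = np.zeros(n)
    idx = np.floor(np.asarray(onset_times, dtype=float) / bin_ms).astype(int)
    train[idx[(idx >= 0) & (idx < n)]] = 1.0
    return train


def spike_psd(train: np.ndarray, fs: float = 1000.0 / PSD_BIN_MS,
              nperseg: int | None = None):
    """Welch power spectral density of a spike train.

    ``nperseg`` defaults to min(20000, len(train)); passing one larger
    than the train is an error rather than a silent shortening.
    """
    train = np.asarray(train, dtype=float)
    if nperseg is None:
        nperseg = min(PSD_NPERSEG, train.size)
    if train.size < nperseg:
        raise ValueError(f"train length {train.size} < nperseg {nperseg}")
    return welch(train, fs=fs, scaling="density", nperseg=nperseg)


def psd_at(f: np.ndarray, Pxx: np.ndarray, f_i: float) -> float:
    """Density at the grid frequency nearest f_i."""
    return float(Pxx[int(np.argmin(np.abs(f - f_i)))])


def delta_psd(perturbed_onsets, baseline_onsets, duration: float,
              f_i: float, bin_ms: float = PSD_BIN_MS,
              nperseg: int | None = None) -> float:
    """Baseline ratio dPSD at f_i; nan when the baseline density is zero."""
    f, Pp = spike_psd(spike_train_signal(perturbed_onsets, duration, bin_ms),
                      fs=1000.0 / bin_ms, nperseg=nperseg)
    _, Pb = spike_psd(spike_train_signal(baseline_onsets, duration, bin_ms),
                      fs=1000.0 / bin_ms, nperseg=nperseg)
    base = psd_at(f, Pb, f_i)
    if base == 0.0:
        return float("nan")
    return psd_at(f, Pp, f_i) / base


@dataclass
class ResonanceResult:
    freqs: tuple[float, ...]
    delta_psd: np.ndarray          # one value per frequency (may contain nan)
    f_r: float                     # argmax frequency (ties -> lowest)
    f_B: float                     # baseline firing rate, Hz
    baseline_onsets: np.ndarray = field(repr=False, default=None)
    perturbed_onsets: list = field(repr=False, default=None)


def _argmax_lowest(freqs, values) -> float:
    """Argmax over the finite entries; ties resolved to the lowest frequency."""
    best_f, best_v = None, -np.inf
    for f, v in sorted(zip(freqs, values)):
        if np.isfinite(v) and v > best_v:
            best_f, best_v = f, v
    if best_f is None:
        raise ValueError("dPSD undefined at every frequency "
                         "(no baseline power / no spikes)")
    return best_f


def resonant_frequency(model: MembraneModel,
                       background=None,
                       holding: float | None = None,
                       freqs=FREQUENCY_SET,
                       polarity: str = "inhibitory",
                       seed: int | None = 0,
                       duration: float = 10_000.0,
                       dt: float = 0.025,
                       settle: float = 1_000.0,
                       nperseg: int | None = None) -> ResonanceResult:
    """Resonant frequency of one state over a perturbation-frequency set.

    Two modes: in-vitro (``holding`` pA constant current, no background)
    and in-vivo-like (``background`` an OUBackground; the OU seed is
    shared between the baseline and every perturbed run so the ratio
    isolates the perturbation).  One 10-s run per frequency plus one
    baseline, all integrated as a single batch.
    """
    if not freqs:
        raise ValueError("frequency set is empty")
    if (background is None) == (holding is None):
        raise ValueError("exactly one of background/holding must be given")
    freqs = tuple(freqs)
    kin = synaptic_kinetics(polarity)
    B = len(freqs) + 1               # row 0 = baseline
    total = duration + settle
    n = int(round(total / dt))
    if background is not None:
        ge0, gi0 = ou_conductances(background, total, dt, seed=seed)
        Ee, Ei = background.Ee, background.Ei
        ioff = model.bias_current
    else:
        ge0 = np.zeros(n)
        gi0 = np.zeros(n)
        Ee, Ei = 0.0, kin.erev if polarity == "inhibitory" else -86.0
        ioff = float(holding)
    ge = np.tile(ge0, (B, 1))
    gi = np.tile(gi0, (B, 1))
    for j, f_i in enumerate(freqs):
        spec = PerturbationSpec(frequency=f_i, polarity=polarity,
                                onset_phase=settle)
        gp = perturbation_conductance(spec, kin, total, dt)
        if polarity == "excitatory":
            ge[j + 1] += gp
        else:
            gi[j + 1] += gp
    V, _, _, _ = run_batch(model, np.zeros(n), total, dt,
                           ioffset=np.full(B, ioff), ge=ge, gi=gi,
                           Ee=Ee, Ei=Ei)
    k0 = int(round(settle / dt))
    onsets = spike_onsets_batch(V[:, k0:], dt)
    if all(o.size == 0 for o in onsets[1:]):
        raise ValueError("no spikes in any perturbed run")
    base_train = spike_train_signal(onsets[0], duration)
    f, Pb = spike_psd(base_train, nperseg=nperseg)
    dvals = np.empty(len(freqs))
    for j, f_i in enumerate(freqs):
        ptrain = spike_train_signal(onsets[j + 1], duration)
        _, Pp = spike_psd(ptrain, nperseg=nperseg)
        base = psd_at(f, Pb, f_i)
        dvals[j] = psd_at(f, Pp, f_i) / base if base > 0 else np.nan
    f_r = _argmax_lowest(freqs, dvals)
    return ResonanceResult(freqs=freqs, delta_psd=dvals, f_r=f_r,
                           f_B=onsets[0].size / (duration / 1000.0),
                           baseline_onsets=onsets[0],
                           perturbed_onsets=onsets[1:])


# ---------------------------------------------------------------------------
# phase response curve
# ---------------------------------------------------------------------------

@dataclass
class PRCResult:
    """Phase response of single perturbations across one firing cycle.

    ``delta_phi`` follows the advance-positive convention: positive values
    mean the perturbed ISI was shorter (spike advanced), negative values a
    prolonged ISI (delay).
    """
    phases: np.ndarray             # fraction of cycle in [0, 1)
    delta_phi: np.ndarray          # percent, positive = advance
    T0: float                      # baseline ISI, ms
    T1: np.ndarray                 # perturbed ISI per phase, ms
    t_pert: np.ndarray             # perturbation time per phase, ms
    holding: float
    delta_I: dict = field(default_factory=dict)


def prc(model: MembraneModel, holding: float, n_phases: int = 20,
        polarity: str = "inhibitory", dt: float = 0.025,
        scale: float = 30.0, stability_tol: float = 0.01,
        compute_delta_I: bool = False) -> PRCResult:
    """Phase response curve at a constant holding current.

    The baseline run must fire periodically (ISI sd/mean below
    ``stability_tol`` over the last 10 cycles); the perturbation is one
    double-exponential synaptic event placed at ``n_phases`` uniform
    phases of a late reference cycle.  With ``compute_delta_I`` the
    per-current maximum-amplitude change around the perturbation is also
    measured (positive = amplitude increase).
    """
    kin = synaptic_kinetics(polarity)
    # baseline: run long enough to see >= 14 spikes
    base_dur = 20_000.0
    V, _, _, _ = run_batch(model, np.zeros(int(round(base_dur / dt))),
                           base_dur, dt, ioffset=np.array([holding]))
    base_onsets = spike_onsets_batch(V, dt)[0]
    if base_onsets.size < 14:
        raise ValueError("baseline firing too slow/absent for PRC "
                         f"({base_onsets.size} spikes in {base_dur/1000:.0f} s)")
    isis = np.diff(base_onsets)
    tail = isis[-10:]
    if tail.std() / tail.mean() > stability_tol:
        raise ValueError("unstable baseline firing (ISI CV "
                         f"{tail.std()/tail.mean():.3f} over last 10 cycles)")
    T0 = float(tail.mean())
    ref_idx = base_onsets.size - 4          # reference cycle start
    t_ref = base_onsets[ref_idx]
    duration = t_ref + 4.0 * T0
    n = int(round(duration / dt))
    phases = np.arange(n_phases) / n_phases
    wave = event_waveform(kin, min(kin.decay * 14.0, duration), dt, scale)
    B = n_phases
    gp = np.zeros((B, n))
    t_pert = t_ref + phases * T0
    for b in range(B):
        k0 = int(round(t_pert[b] / dt))
        k1 = min(n, k0 + wave.size)
        gp[b, k0:k1] = wave[:k1 - k0]
    zeros = np.zeros((B, 1))
    ge, gi = (gp, zeros) if polarity == "excitatory" else (zeros, gp)
    rec = compute_delta_I
    Vp, cur, _, _ = run_batch(model, np.zeros(n), duration, dt,
                              ioffset=np.full(B, holding), ge=ge, gi=gi,
                              Ee=0.0, Ei=kin.erev, record_currents=rec)
    onsets = spike_onsets_batch(Vp, dt)
    T1 = np.empty(B)
    dI: dict[str, np.ndarray] = {}
    names = [c.name for c in model.channels]
    if rec:
        dI = {nm: np.full(B, np.nan) for nm in names}
    for b in range(B):
        ons = onsets[b]
        after = ons[ons > t_pert[b]]
        before = ons[ons <= t_pert[b]]
        if after.size < 2 or before.size < 2:
            T1[b] = np.nan
            continue
        T1[b] = after[0] - before[-1]
        if rec:
            k_pert = int(round(t_pert[b] / dt))
            k0 = int(round(before[-2] / dt))
            k1 = int(round(after[1] / dt))
            for ci, nm in enumerate(names):
                I = cur[b, ci]
                i0 = np.max(np.abs(I[k0:k_pert]))
                i1 = np.max(np.abs(I[k_pert:k1]))
                dI[nm][b] = (i1 - i0) / i0 * 100.0 if i0 > 0 else np.nan
    # advance-positive sign convention: shorter perturbed ISI -> positive
    delta_phi = (T0 - T1) / T0 * 100.0
    return PRCResult(phases=phases, delta_phi=delta_phi, T0=T0, T1=T1,
                     t_pert=t_pert, holding=holding, delta_I=dI)


def delta_I(result: PRCResult) -> dict[str, np.ndarray]:
    """Per-current percent change in maximum amplitude, per phase.

    Requires the PRC to have been run with ``compute_delta_I=True``;
    window conventions: the unperturbed reference spans from the
    second-last spike before the perturbation up to it, the perturbed
    window from the perturbation to the second following spike.
    """
    if not result.delta_I:
        raise ValueError("PRC was run without compute_delta_I=True")
    return result.delta_I
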