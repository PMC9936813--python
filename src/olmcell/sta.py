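"""Spike-triggered-average (STA) analyses of the biophysical currents.

For in-vivo-like states resonant at a target frequency, windows preceding
spikes with long (>= 200 ms) inter-spike intervals are harvested; each
window carries every current's signed share of the total absolute current
on t in [-195, -10] ms relative to spike onset.  Averages over windows
are organised per (resonant frequency, representative set), min-max
normalized across sets, and summarised by least-squares slopes of the
across-set mean (analysis range [-195, -25] ms, avoiding the pre-spike
curving) and by a spread measure: twice the across-set standard deviation
summed over the analysis timepoints.  Trends of slope and spread against
resonant frequency are fit with linear or parabolic least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .model import MembraneModel, current_shares, detect_spikes, simulate
from .resonance import FREQUENCY_SET, resonant_frequency
from .stimuli import (PerturbationSpec, ou_conductances,
                      perturbation_conductance, synaptic_kinetics)

#: Window preserved before each spike (ms before onset).
WINDOW_START = -195.0
WINDOW_END = -10.0
#: Analysis range for slope/spread (ms before onset).
ANALYSIS_END = -25.0
#: Minimum ISI for a window to qualify (ms).
MIN_ISI = 200.0


@dataclass
class STAWindow:
    proportions: dict[str, np.ndarray]   # per-current signed shares
    t: np.ndarray                        # ms relative to spike onset
    f_r: float
    set_id: int
    seed: int | None = None


@dataclass
class STAEnsemble:
    """Mean STA shares keyed by current name and (f_r, set_id)."""
    t: np.ndarray
    data: dict[str, dict[tuple[float, int], np.ndarray]]
    n_windows: dict[tuple[float, int], int] = field(default_factory=dict)

    def currents(self):
        return list(self.data)

    def keys(self):
        first = next(iter(self.data.values()))
        return list(first)


def windows_from_shares(shares: dict[str, np.ndarray], onsets: np.ndarray,
                        dt: float, f_r: float = np.nan, set_id: int = -1,
                        seed=None) -> list[STAWindow]:
    """Extract qualifying pre-spike windows from a trace's current shares.

    A spike qualifies when the preceding ISI is >= 200 ms (the first
    spike of a trace has no preceding ISI and never qualifies).
    """
    out = []
    nt = next(iter(shares.values())).size
    k_start = int(round(-WINDOW_START / dt))
    k_end = int(round(-WINDOW_END / dt))
    t_rel = np.arange(-k_start, -k_end + 1) * dt
    for i in range(1, onsets.size):
        if onsets[i] - onsets[i - 1] < MIN_ISI:
            continue
        k = int(round(onsets[i] / dt))
        a, b = k - k_start, k - k_end + 1
        if a < 0 or b > nt:
            continue
        out.append(STAWindow(
            proportions={nm: s[a:b].copy() for nm, s in shares.items()},
            t=t_rel, f_r=f_r, set_id=set_id, seed=seed))
    return out


def harvest_windows(model: MembraneModel, rep, f_r_target: float,
                    polarity: str = "inhibitory", n_windows: int = 50,
                    seeds=range(200), freqs=FREQUENCY_SET,
                    duration: float = 10_000.0, dt: float = 0.025,
                    settle: float = 1_000.0) -> list[STAWindow]:
    """Collect pre-spike windows from states resonant at ``f_r_target``.

    For each seed, the state's resonant frequency is measured over
    ``freqs``; only when it equals the target does the perturbed run at
    that frequency contribute windows (re-simulated with current
    recording).  Stops at ``n_windows``; a shorter result with a warning
    means the seed budget was exhausted.
    """
    bg = rep.bg if hasattr(rep, "bg") else rep
    set_id = getattr(rep, "set_id", -1)
    kin = synaptic_kinetics(polarity)
    out: list[STAWindow] = []
    for seed in seeds:
        if len(out) >= n_windows:
            break
        try:
            res = resonant_frequency(model, background=bg, freqs=freqs,
                                     polarity=polarity, seed=seed,
                                     duration=duration, dt=dt, settle=settle)
        except ValueError:
            continue
        if res.f_r != f_r_target:
            continue
        total = duration + settle
        ge, gi = ou_conductances(bg, total, dt, seed=seed)
        gp = perturbation_conductance(
            PerturbationSpec(frequency=f_r_target, polarity=polarity,
                             onset_phase=settle), kin, total, dt)
        if polarity == "excitatory":
            ge = ge + gp
        else:
            gi = gi + gp
        trace = simulate(model, np.full(int(round(total / dt)),
                                        model.bias_current),
                         total, dt, seed=seed, ge=ge, gi=gi,
                         Ee=bg.Ee, Ei=bg.Ei)
        k0 = int(round(settle / dt))
        sub_currents = {nm: s[k0:] for nm, s in trace.currents.items()
                        if nm != "syn"}
        V = trace.V[k0:]
        onsets = detect_spikes(V, dt=dt).onset_times
        shares = _shares_from_currents(sub_currents)
        wins = windows_from_shares(shares, onsets, dt, f_r=f_r_target,
                                   set_id=set_id, seed=seed)
        out.extend(wins[:n_windows - len(out)])
    if len(out) < n_windows:
        warnings.warn(f"seed budget exhausted: {len(out)}/{n_windows} "
                      f"windows for f_r={f_r_target}, set {set_id}")
    return out


def _shares_from_currents(currents: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    stack = np.vstack(list(currents.values()))
    denom = np.abs(stack).sum(axis=0)
    safe = np.where(denom > 0, denom, 1.0)
    shares = stack / safe
    shares[:, denom == 0] = 0.0
    return {nm: shares[i] for i, nm in enumerate(currents)}


def build_ensemble(windows: list[STAWindow]) -> STAEnsemble:
    """Average windows into per-(f_r, set) mean STAs."""
    if not windows:
        raise ValueError("empty window list")
    t = windows[0].t
    names = list(windows[0].proportions)
    buckets: dict[tuple[float, int], list] = {}
    for w in windows:
        buckets.setdefault((w.f_r, w.set_id), []).append(w)
    data = {nm: {} for nm in names}
    counts = {}
    for key, ws in buckets.items():
        counts[key] = len(ws)
        for nm in names:
            data[nm][key] = np.mean([w.proportions[nm] for w in ws], axis=0)
    return STAEnsemble(t=t, data=data, n_windows=counts)


def normalize_sta(ensemble: STAEnsemble) -> STAEnsemble:
    """Min-max normalize |mean STA| across representative sets.

    For each current and resonant frequency, the absolute mean STAs of
    all sets are jointly rescaled over sets and timepoints to [0, 1]; a
    degenerate min = max collapses to zeros with a warning.
    """
    keys = ensemble.keys()
    sets_per_fr: dict[float, list] = {}
    for f_r, sid in keys:
        sets_per_fr.setdefault(f_r, []).append(sid)
    if all(len(v) < 2 for v in sets_per_fr.values()):
        raise ValueError("normalization needs >= 2 sets per frequency")
    out = {nm: {} for nm in ensemble.data}
    for nm, perkey in ensemble.data.items():
        for f_r, sids in sets_per_fr.items():
            mats = {sid: np.abs(perkey[(f_r, sid)]) for sid in sids}
            lo = min(m.min() for m in mats.values())
            hi = max(m.max() for m in mats.values())
            if hi == lo:
                warnings.warn(f"degenerate normalization for {nm} at "
                              f"f_r={f_r}: min == max; returning zeros")
                for sid in sids:
                    out[nm][(f_r, sid)] = np.zeros_like(mats[sid])
            else:
                for sid in sids:
                    out[nm][(f_r, sid)] = (mats[sid] - lo) / (hi - lo)
    return STAEnsemble(t=ensemble.t, data=out,
                       n_windows=dict(ensemble.n_windows))


def _analysis_slice(t: np.ndarray):
    return (t >= WINDOW_START - 1e-9) & (t <= ANALYSIS_END + 1e-9)


def _collect(ensemble: STAEnsemble, currents, f_r: float) -> np.ndarray:
    """(n_sets, n_t) matrix for one current (or summed currents) at f_r."""
    if isinstance(currents, str):
        currents = [currents]
    sids = sorted(sid for (fr, sid) in ensemble.keys() if fr == f_r)
    if not sids:
        raise KeyError(f"no sets at f_r={f_r}")
    rows = []
    for sid in sids:
        acc = np.zeros_like(ensemble.t)
        for nm in currents:
            acc = acc + ensemble.data[nm][(f_r, sid)]
        rows.append(acc)
    return np.vstack(rows)


def slope_of_mean(ensemble: STAEnsemble, currents, f_r: float) -> float:
    """OLS slope (per ms) of the across-set mean on [-195, -25] ms.

    ``currents`` may be one name or a list (e.g. ["M", "h"]): combined
    currents are summed per set before averaging, then fit.
    """
    mat = _collect(ensemble, currents, f_r)
    sel = _analysis_slice(ensemble.t)
    y = mat.mean(axis=0)[sel]
    x = ensemble.t[sel]
    return float(np.polyfit(x, y, 1)[0])


def spread(ensemble: STAEnsemble, currents, f_r: float,
           ddof: int = 0) -> float:
    """Sum over analysis timepoints of twice the across-set sd.

    Combined currents are summed per set before the sd.  A single set
    gives 0 with a warning.
    """
    mat = _collect(ensemble, currents, f_r)
    if mat.shape[0] < 2:
        warnings.warn("spread over a single set is 0")
        return 0.0
    sel = _analysis_slice(ensemble.t)
    return float((2.0 * mat[:, sel].std(axis=0, ddof=ddof)).sum())


@dataclass
class TrendFit:
    family: str                 # "linear" | "parabolic"
    coef: np.ndarray            # ascending powers
    r2: float
    p_value: float              # F-test of the regression
    zero_crossing: float | None = None   # linear fit only, within range
    vertex: float | None = None          # parabolic fit only


def trend_fits(f_r_values, stats, family: str = "linear") -> TrendFit:
    """Least-squares trend of a per-frequency statistic against f_r."""
    x = np.asarray(f_r_values, dtype=float)
    y = np.asarray(stats, dtype=float)
    order = {"linear": 1, "parabolic": 2}[family]
    if x.size < order + 2:
        raise ValueError(f"need >= {order + 2} points for a {family} fit")
    X = np.column_stack([x ** p for p in range(order + 1)])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (degenerate f_r values)")
    res = sm.OLS(y, X).fit()
    coef = np.asarray(res.params)
    zero = None
    vertex = None
    if family == "linear":
        if coef[1] != 0:
            x0 = -coef[0] / coef[1]
            if x.min() <= x0 <= x.max():
                zero = float(x0)
    else:
        if coef[2] != 0:
            vertex = float(-coef[1] / (2.0 * coef[2]))
    return TrendFit(family=family, coef=coef, r2=float(res.rsquared),
                    p_value=float(res.f_pvalue), zero_crossing=zero,
                    vertex=vertex)
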