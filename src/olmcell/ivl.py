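"""In-vivo-like (IVL) state classification and OU parameter search.

A 10-s trace under OU synaptic bombardment counts as in-vivo-like when
four criteria on its statistics all hold (strict inequalities, evaluated
exactly as printed):

    mean subthreshold voltage  Vm > -70.588 mV
    subthreshold sd            sigma_Vm > 2.2 mV
    ISI coefficient of variation  ISICV > 0.8
    firing rate                3 Hz < f < 25 Hz

Subthreshold statistics exclude samples within 7 ms of each spike peak;
the rate is spike count divided by the 10-s window.  The constrained grid
search additionally bounds the subthreshold mean and variance to match
the multi-compartment antecedent (8 < sigma^2 < 10 mV^2,
-70 < Vm < -67.5 mV), applied once per parameter set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model import MembraneModel, SimTrace, run_batch, spike_onsets_batch
from .stimuli import OUBackground, ou_conductances

#: Criterion thresholds, as printed.
VM_MEAN_MIN = -70.588
VM_SD_MIN = 2.2
ISI_CV_MIN = 0.8
RATE_MIN = 3.0
RATE_MAX = 25.0

#: Extra comparability bounds used by the constrained search.
EXTRA_VAR_BOUNDS = (8.0, 10.0)
EXTRA_MEAN_BOUNDS = (-70.0, -67.5)

#: Half-width of the exclusion window around each spike peak (ms).
SPIKE_EXCLUSION = 7.0


@dataclass(frozen=True)
class SubthresholdStats:
    mean_V: float
    sd_V: float
    n_retained: int

    @property
    def variance_V(self) -> float:
        return self.sd_V ** 2


@dataclass(frozen=True)
class IVLResult:
    stats: SubthresholdStats
    isi_cv: float          # nan when fewer than 3 spikes
    rate: float            # Hz
    criteria: tuple[bool, bool, bool, bool]

    @property
    def score(self) -> int:
        return int(sum(self.criteria))

    @property
    def valid(self) -> bool:
        return self.score == 4


@dataclass(frozen=True)
class RepresentativeSet:
    set_id: int
    bg: OUBackground
    min_f: float
    max_f: float

    def __post_init__(self):
        if self.min_f > self.max_f:
            raise ValueError("min_f must be <= max_f")


def _exclusion_mask(n: int, dt: float, peak_times: np.ndarray,
                    half_width: float = SPIKE_EXCLUSION) -> np.ndarray:
    """True where a sample is kept (>= half_width from every spike peak).

    Overlapping windows merge naturally through the boolean paint.
    """
    keep = np.ones(n, dtype=bool)
    w = int(round(half_width / dt))
    for tp in peak_times:
        k = int(round(tp / dt))
        keep[max(0, k - w):k + w + 1] = False
    return keep


def subthreshold_stats(V: np.ndarray, dt: float,
                       peak_times: np.ndarray) -> SubthresholdStats:
    """Mean/sd of the membrane potential away from spikes.

    ``peak_times`` are spike peak times in ms; the window
    [peak - 7, peak + 7] ms around each is removed before computing the
    moments of the remaining samples.
    """
    keep = _exclusion_mask(V.size, dt, peak_times)
    if not keep.any():
        raise ValueError("no subthreshold samples remain after spike removal")
    sub = V[keep]
    return SubthresholdStats(mean_V=float(sub.mean()), sd_V=float(sub.std()),
                             n_retained=int(keep.sum()))


def isi_cv(onset_times: np.ndarray) -> float:
    """sd/mean of the inter-spike intervals; nan below 3 spikes."""
    onset_times = np.asarray(onset_times, dtype=float)
    if onset_times.size < 3:
        return float("nan")
    isis = np.diff(onset_times)
    return float(isis.std() / isis.mean())


def ivl_metric_from_values(stats: SubthresholdStats, cv: float,
                           rate: float) -> IVLResult:
    crit = (
        stats.mean_V > VM_MEAN_MIN,
        stats.sd_V > VM_SD_MIN,
        bool(cv > ISI_CV_MIN),        # False for nan
        RATE_MIN < rate < RATE_MAX,
    )
    return IVLResult(stats=stats, isi_cv=cv, rate=rate, criteria=crit)


def ivl_metric(trace: SimTrace, threshold: float = -10.0) -> IVLResult:
    """Score a trace against the four IVL criteria (see module docstring)."""
    if trace.duration < 10_000.0 - 1e-9:
        raise ValueError("IVL metric is defined on >= 10 s traces")
    from .model import detect_spikes
    spikes = detect_spikes(trace, threshold)
    stats = subthreshold_stats(trace.V, trace.dt, spikes.peak_times)
    rate = spikes.n / (trace.duration / 1000.0)
    return ivl_metric_from_values(stats, isi_cv(spikes.onset_times), rate)


# ---------------------------------------------------------------------------
# simulation under OU background
# ---------------------------------------------------------------------------

def run_ivl_batch(model: MembraneModel, bgs, seeds,
                  duration: float = 10_000.0, dt: float = 0.025,
                  settle: float = 1_000.0):
    """Simulate OU-driven membranes, one row per (bg, seed) pair.

    ``bgs`` and ``seeds`` are equal-length sequences defining the batch.
    A ``settle`` lead-in is simulated and discarded so the scored window
    starts from the stochastic steady state.  Returns the (B, T) voltage
    array for the scored window.
    """
    bgs = list(bgs)
    seeds = list(seeds)
    if len(bgs) != len(seeds):
        raise ValueError("bgs and seeds must align")
    B = len(bgs)
    total = duration + settle
    n = int(round(total / dt))
    ge = np.empty((B, n))
    gi = np.empty((B, n))
    Ee = bgs[0].Ee
    Ei = bgs[0].Ei
    for b, (bg, sd) in enumerate(zip(bgs, seeds)):
        if bg.Ee != Ee or bg.Ei != Ei:
            raise ValueError("all backgrounds in a batch must share reversals")
        ge[b], gi[b] = ou_conductances(bg, total, dt, seed=sd)
    V, _, _, _ = run_batch(model, np.zeros(n), total, dt,
                           ioffset=np.full(B, model.bias_current),
                           ge=ge, gi=gi, Ee=Ee, Ei=Ei)
    k0 = int(round(settle / dt))
    return V[:, k0:]


def evaluate_ivl(model: MembraneModel, bg: OUBackground, seed,
                 duration: float = 10_000.0, dt: float = 0.025,
                 threshold: float = -10.0) -> IVLResult:
    """One OU-driven run scored by the IVL metric."""
    return evaluate_ivl_batch(model, [bg], [seed], duration, dt, threshold)[0]


def evaluate_ivl_batch(model, bgs, seeds, duration=10_000.0, dt=0.025,
                       threshold=-10.0) -> list[IVLResult]:
    V = run_ivl_batch(model, bgs, seeds, duration, dt)
    out = []
    for b, onsets in enumerate(spike_onsets_batch(V, dt, threshold)):
        # peaks approximated by onsets + argmax within 3 ms, as in detect_spikes
        w = int(round(3.0 / dt))
        peaks = np.array([k + np.argmax(V[b, k:k + w + 1])
                          for k in (onsets / dt).astype(int)]) * dt
        stats = subthreshold_stats(V[b], dt, peaks)
        rate = onsets.size / (duration / 1000.0)
        out.append(ivl_metric_from_values(stats, isi_cv(onsets), rate))
    return out


# ---------------------------------------------------------------------------
# constrained grid search and representative selection
# ---------------------------------------------------------------------------

def grid(lo: float, hi: float, n: int) -> np.ndarray:
    """Inclusive linspace built by count (not accumulation)."""
    return np.linspace(lo, hi, n)


#: The published search grid: (lo, hi, n_points) per OU parameter.
DEFAULT_GRID = {
    "ge0": (0.003, 0.006, 16),
    "gi0": (0.008, 0.012, 16),
    "De": (0.0, 0.0016, 16),
    "Di": (0.0, 0.01, 16),
}


def constrained_search(model: MembraneModel,
                       grid_spec: dict | None = None,
                       extra_mean_bounds=EXTRA_MEAN_BOUNDS,
                       extra_var_bounds=EXTRA_VAR_BOUNDS,
                       duration: float = 10_000.0, dt: float = 0.025,
                       seed: int = 0, chunk: int = 32,
                       bg_kwargs: dict | None = None):
    """Brute-force OU parameter search for valid IVL states.

    Every grid combination is simulated once (a single seed, as the extra
    comparability constraint is "applied only once to every parameter
    set") and kept when the IVL metric scores 4/4 AND the subthreshold
    mean/variance fall inside the extra bounds.  Returns
    (list of passing OUBackground, records DataFrame-ready list of dicts).
    """
    gs = grid_spec or DEFAULT_GRID
    bg_kwargs = bg_kwargs or {}
    axes = {k: grid(*gs[k]) for k in ("ge0", "gi0", "De", "Di")}
    combos = [
        OUBackground(ge0=a, gi0=b, De=c, Di=d, **bg_kwargs)
        for a in axes["ge0"] for b in axes["gi0"]
        for c in axes["De"] for d in axes["Di"]
    ]
    passing, records = [], []
    for i0 in range(0, len(combos), chunk):
        part = combos[i0:i0 + chunk]
        results = evaluate_ivl_batch(model, part, [seed] * len(part),
                                     duration, dt)
        for bg, res in zip(part, results):
            ok_extra = (extra_mean_bounds[0] < res.stats.mean_V < extra_mean_bounds[1]
                        and extra_var_bounds[0] < res.stats.variance_V < extra_var_bounds[1])
            ok = res.valid and ok_extra
            records.append({
                "ge0": bg.ge0, "gi0": bg.gi0, "De": bg.De, "Di": bg.Di,
                "mean_V": res.stats.mean_V, "var_V": res.stats.variance_V,
                "isi_cv": res.isi_cv, "rate": res.rate,
                "score": res.score, "extra_ok": ok_extra, "valid": ok,
            })
            if ok:
                passing.append(bg)
    return passing, records


def rate_envelope(model: MembraneModel, bg: OUBackground, seeds,
                  duration: float = 10_000.0, dt: float = 0.025,
                  chunk: int = 50) -> tuple[float, float]:
    """(min, max) firing rate of one background over a set of seeds."""
    seeds = list(seeds)
    rates = []
    for i0 in range(0, len(seeds), chunk):
        part = seeds[i0:i0 + chunk]
        V = run_ivl_batch(model, [bg] * len(part), part, duration, dt)
        rates += [o.size / (duration / 1000.0)
                  for o in spike_onsets_batch(V, dt)]
    return float(min(rates)), float(max(rates))


def select_representatives(model: MembraneModel, valid_sets, n_seeds: int = 50,
                           n_out: int = 10, duration: float = 10_000.0,
                           dt: float = 0.025, seed_base: int = 0
                           ) -> list[RepresentativeSet]:
    """Pick parameter sets spanning the (min_f, max_f) firing-rate plane.

    The same ``n_seeds`` seeds are reused for every set.  Selection is
    deterministic greedy farthest-point sampling in the (min_f, max_f)
    plane, seeded with the lowest- and highest-rate sets so the chosen
    representatives sweep the rate range from bottom to top; for
    ``n_out == 1`` the set closest to the centroid is returned.  Output is
    ordered (and numbered) by mean rate.
    """
    valid_sets = list(valid_sets)
    seeds = [seed_base + i for i in range(n_seeds)]
    pts = np.array([rate_envelope(model, bg, seeds, duration, dt)
                    for bg in valid_sets])
    if len(valid_sets) < n_out:
        warnings.warn(f"only {len(valid_sets)} valid sets for n_out={n_out}; "
                      "returning all")
        chosen = list(range(len(valid_sets)))
    elif n_out == 1:
        centroid = pts.mean(axis=0)
        chosen = [int(np.argmin(((pts - centroid) ** 2).sum(axis=1)))]
    else:
        mean_rate = pts.mean(axis=1)
        chosen = [int(np.argmin(mean_rate)), int(np.argmax(mean_rate))]
        while len(chosen) < n_out:
            d = np.min(
                [((pts - pts[c]) ** 2).sum(axis=1) for c in chosen], axis=0)
            d[chosen] = -1.0
            chosen.append(int(np.argmax(d)))
    order = sorted(chosen, key=lambda i: pts[i].mean())
    return [RepresentativeSet(set_id=rank, bg=valid_sets[i],
                              min_f=pts[i, 0], max_f=pts[i, 1])
            for rank, i in enumerate(order)]


def packaged_representatives(bg_kwargs: dict | None = None
                             ) -> list[RepresentativeSet]:
    """The ten packaged representative OU parameter sets."""
    from .io import representative_sets
    bg_kwargs = bg_kwargs or {}
    out = []
    for row in representative_sets():
        bg = OUBackground(ge0=row["ge0"], gi0=row["gi0"],
                          De=row["De"], Di=row["Di"], **bg_kwargs)
        out.append(RepresentativeSet(set_id=row["set"], bg=bg,
                                     min_f=row["min_f"], max_f=row["max_f"]))
    return out
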