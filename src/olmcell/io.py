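"""Model and trace serialization.

Channel definitions are data: a JSON file describes the compartment
(capacitance, area, bias current) and each channel's maximal conductance,
reversal potential and gating functional forms.  This keeps the one
under-specified ingredient of the model -- the exact channel kinetics --
swappable without code changes.  Traces round-trip through a plain CSV
dialect with a JSON sidecar carrying provenance (model hash, dt, seed,
spike onsets).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (Boltzmann, ChannelSpec, GatingSpec, MembraneModel,
                    SimTrace, TauBell, TauConstant, TauGauss)

_TAU_FORMS = {"constant": TauConstant, "gauss": TauGauss, "bell": TauBell}
_TAU_NAMES = {v: k for k, v in _TAU_FORMS.items()}


class SchemaError(ValueError):
    """Model-file schema violation, reporting the offending field path."""


def _require(d: dict, key: str, path: str):
    if key not in d:
        raise SchemaError(f"missing field: {path}.{key}")
    return d[key]


def _gating_from_dict(d: dict, path: str) -> GatingSpec:
    ss = _require(d, "steady_state", path)
    if ss.get("form", "boltzmann") != "boltzmann":
        raise SchemaError(f"{path}.steady_state.form: unknown form {ss.get('form')!r}")
    tc = _require(d, "time_constant", path)
    form = _require(tc, "form", f"{path}.time_constant")
    if form not in _TAU_FORMS:
        raise SchemaError(f"{path}.time_constant.form: unknown form {form!r}")
    cls = _TAU_FORMS[form]
    kwargs = {k: v for k, v in tc.items() if k != "form"}
    try:
        tau = cls(**kwargs)
    except TypeError as e:
        raise SchemaError(f"{path}.time_constant: {e}") from None
    try:
        return GatingSpec(
            name=_require(d, "name", path),
            power=int(_require(d, "power", path)),
            steady_state=Boltzmann(vhalf=float(_require(ss, "vhalf", f"{path}.steady_state")),
                                   k=float(_require(ss, "k", f"{path}.steady_state"))),
            time_constant=tau)
    except ValueError as e:
        raise SchemaError(f"{path}: {e}") from None


def model_from_dict(d: dict) -> MembraneModel:
    chans = []
    for i, cd in enumerate(_require(d, "channels", "model")):
        path = f"model.channels[{i}]"
        gates = tuple(_gating_from_dict(g, f"{path}.gates[{j}]")
                      for j, g in enumerate(cd.get("gates", [])))
        try:
            chans.append(ChannelSpec(
                name=_require(cd, "name", path),
                gbar=float(_require(cd, "gbar_uS", path)),
                erev=float(_require(cd, "erev_mV", path)),
                gates=gates))
        except ValueError as e:
            raise SchemaError(f"{path}: {e}") from None
    try:
        return MembraneModel(
            capacitance=float(_require(d, "capacitance_pF", "model")),
            channels=tuple(chans),
            bias_current=float(d.get("bias_current_pA", 4.0)),
            area_cm2=d.get("area_cm2"),
            name=d.get("name", "model"))
    except ValueError as e:
        raise SchemaError(f"model: {e}") from None


def model_to_dict(model: MembraneModel) -> dict:
    out = {
        "name": model.name,
        "capacitance_pF": model.capacitance,
        "bias_current_pA": model.bias_current,
        "area_cm2": model.area_cm2,
        "channels": [],
    }
    for c in model.channels:
        cd = {"name": c.name, "gbar_uS": c.gbar, "erev_mV": c.erev, "gates": []}
        for g in c.gates:
            tc = {"form": _TAU_NAMES[type(g.time_constant)]}
            tc.update(asdict(g.time_constant))
            cd["gates"].append({
                "name": g.name,
                "power": g.power,
                "steady_state": {"form": "boltzmann",
                                 "vhalf": g.steady_state.vhalf,
                                 "k": g.steady_state.k},
                "time_constant": tc,
            })
        out["channels"].append(cd)
    return out


def load_model(path) -> MembraneModel:
    with open(path) as f:
        return model_from_dict(json.load(f))


def save_model(model: MembraneModel, path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1))


def model_hash(model: MembraneModel) -> str:
    payload = json.dumps(model_to_dict(model), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def reference_model() -> MembraneModel:
    """The packaged reduced OLM cell model (reference conductances)."""
    with resources.files("olmcell.data").joinpath("olm_single.json").open() as f:
        return model_from_dict(json.load(f))


def representative_sets() -> list[dict]:
    """Packaged representative in-vivo-like OU parameter sets."""
    with resources.files("olmcell.data").joinpath(
            "representative_sets.json").open() as f:
        return json.load(f)


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------

def trace_to_csv(trace: SimTrace, path, model: MembraneModel | None = None,
                 spike_onsets=None) -> None:
    cols = {"t_ms": trace.t, "V_mV": trace.V}
    for name, series in trace.currents.items():
        cols[f"I_{name}_pA"] = series
    cols["I_stim_pA"] = trace.stimulus
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.6g")
    sidecar = {
        "dt_ms": trace.dt,
        "seed": trace.seed,
        "model_hash": model_hash(model) if model is not None else None,
        "spike_onsets_ms": (list(map(float, spike_onsets))
                            if spike_onsets is not None else None),
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def trace_from_csv(path) -> SimTrace:
    df = pd.read_csv(path)
    t = df["t_ms"].to_numpy()
    dt = float(t[1] - t[0]) if t.size > 1 else 0.025
    currents = {}
    for col in df.columns:
        if col.startswith("I_") and col != "I_stim_pA":
            currents[col[2:-3]] = df[col].to_numpy()
    meta = Path(str(path) + ".json")
    seed = None
    if meta.exists():
        side = json.loads(meta.read_text())
        dt = side.get("dt_ms", dt)
        seed = side.get("seed")
    return SimTrace(dt=dt, t=t, V=df["V_mV"].to_numpy(), currents=currents,
                    stimulus=df["I_stim_pA"].to_numpy(), seed=seed)
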