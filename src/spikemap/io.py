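"""Network description files, allocation reports, raster/weight writers.

The network description is a human-readable YAML document with top-level
sections ``populations``, ``projections``, ``plasticity``, ``stimuli`` and
scalar simulation parameters (``dt``, ``duration``, ``max_rate``,
``seed``).  The schema mirrors the in-memory dataclasses one-to-one; see
``docs/methods.md`` for a commented example.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from typing import Optional

import yaml

from .mapping import CoreAllocation, VirtualCore
from .network import (BackgroundInputSpec, NetworkSpec, NeuronParams,
                      Population, Projection, Stimulus)
from .plasticity import PlasticityConfig
from .simcore import read_raster, write_raster  # re-exported  # noqa: F401


# ---------------------------------------------------------------------------
# NetworkSpec <-> dict <-> YAML
# ---------------------------------------------------------------------------

def _tuple_out(v):
    return list(v) if isinstance(v, tuple) else v


def _tuple_in(v):
    return tuple(v) if isinstance(v, list) else v


def spec_to_dict(spec: NetworkSpec) -> dict:
    doc: dict = {
        "dt": spec.dt, "duration": spec.duration, "max_rate": spec.max_rate,
        "seed": spec.seed, "max_delay": spec.max_delay,
        "populations": [], "projections": [],
    }
    for pop in spec.populations:
        d: dict = {"name": pop.name, "size": pop.size}
        if pop.is_source:
            d["source_rate"] = pop.source_rate
        else:
            d["params"] = asdict(pop.params)
        if pop.background is not None:
            d["background"] = asdict(pop.background)
        if pop.v_init is not None:
            d["v_init"] = _tuple_out(pop.v_init)
        doc["populations"].append(d)
    for proj in spec.projections:
        d = {"pre": proj.pre, "post": proj.post, "receptor": proj.receptor,
             "weight": _tuple_out(proj.weight), "delay": _tuple_out(proj.delay)}
        if proj.p is not None:
            d["p"] = proj.p
        if proj.pairs is not None:
            d["pairs"] = [list(x) for x in proj.pairs]
        if proj.plasticity is not None:
            d["plasticity"] = proj.plasticity
        if proj.allow_self:
            d["allow_self"] = True
        doc["projections"].append(d)
    if spec.plasticity_configs:
        doc["plasticity"] = {name: asdict(cfg)
                             for name, cfg in spec.plasticity_configs.items()}
    if spec.stimuli:
        doc["stimuli"] = [asdict(st) for st in spec.stimuli]
    return doc


def dict_to_spec(doc: dict) -> NetworkSpec:
    pops = []
    for d in doc.get("populations", []):
        params = None
        if "params" in d:
            params = NeuronParams(**d["params"])
        bg = None
        if "background" in d:
            bg = BackgroundInputSpec(**d["background"])
        pops.append(Population(
            name=d["name"], size=int(d["size"]), params=params, background=bg,
            source_rate=d.get("source_rate"),
            v_init=_tuple_in(d.get("v_init"))))
    projs = []
    for d in doc.get("projections", []):
        projs.append(Projection(
            pre=d["pre"], post=d["post"], p=d.get("p"),
            pairs=[tuple(x) for x in d["pairs"]] if "pairs" in d else None,
            weight=_tuple_in(d.get("weight", 1.0)),
            delay=_tuple_in(d.get("delay", 1)),
            receptor=d.get("receptor", "exc"),
            plasticity=d.get("plasticity"),
            allow_self=bool(d.get("allow_self", False))))
    cfgs = {name: PlasticityConfig(**c)
            for name, c in doc.get("plasticity", {}).items()}
    stimuli = [Stimulus(**s) for s in doc.get("stimuli", [])]
    return NetworkSpec(
        populations=pops, projections=projs, plasticity_configs=cfgs,
        dt=float(doc.get("dt", 1.0)), duration=float(doc.get("duration", 1000.0)),
        max_rate=float(doc.get("max_rate", 100.0)), seed=int(doc.get("seed", 0)),
        stimuli=stimuli, max_delay=int(doc.get("max_delay", 16)))


def save_spec(spec: NetworkSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec_to_dict(spec), fh, sort_keys=False)


def load_spec(path) -> NetworkSpec:
    with open(path) as fh:
        return dict_to_spec(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Allocation reports
# ---------------------------------------------------------------------------

def save_allocation(alloc: CoreAllocation, path) -> None:
    with open(path, "w") as fh:
        json.dump(alloc.to_dict(), fh, indent=1)


def load_allocation(path) -> CoreAllocation:
    with open(path) as fh:
        doc = json.load(fh)
    alloc = CoreAllocation(scheme=doc["scheme"], dt=doc["dt"])
    for c in doc["cores"]:
        c = dict(c)
        c["slice"] = tuple(c["slice"])
        c["sources"] = [tuple(s) for s in c.get("sources", [])]
        alloc.cores.append(VirtualCore(**c))
    return alloc


def allocation_table(alloc: CoreAllocation) -> str:
    """Human-readable per-core table of an allocation."""
    lines = [f"scheme: {alloc.scheme}   dt: {alloc.dt} ms",
             f"{'core':>4} {'role':<13} {'population':<12} {'slice':<14} "
             f"{'kind':<7} {'est cycles/step':>15}"]
    for i, c in enumerate(alloc.cores):
        lines.append(
            f"{i:>4} {c.role:<13} {c.population:<12} "
            f"{f'[{c.slice[0]},{c.slice[1]})':<14} {c.kind or '-':<7} "
            f"{c.est_cycles_per_step:>15.0f}")
    s = alloc.summary()
    lines.append(f"totals: {s['neuron_cores']} neuron + "
                 f"{s['synapse_cores']} synapse + "
                 f"{s['current_input_cores']} current-input = "
                 f"{s['total_cores']} cores")
    return "\n".join(lines)


def save_audit(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1)


def write_weights(weights: dict, path) -> None:
    """Write plastic weights as 'pre post weight' triplet lines."""
    with open(path, "w") as fh:
        fh.write("# projection pre_gid post_gid weight\n")
        for pi, trips in sorted(weights.items()):
            for pre, post, w in trips:
                fh.write(f"{pi} {pre} {post} {w:.9g}\n")
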