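"""Structured-text (YAML) serialization of models and protocols, and
tabular trajectory export."""

from __future__ import annotations

from pathlib import Path

import yaml

from .network import (
    ModelNetwork,
    ParameterSet,
    RateLaw,
    Reaction,
    Regulator,
    SpeciesDef,
)
from .protocols import Phase, StimulusProtocol
from .simulate import Trajectory


def network_to_dict(network: ModelNetwork, params: ParameterSet) -> dict:
    return {
        "metadata": {
            k: v for k, v in network.metadata.items()
            if k != "baseline_parameters"
        },
        "species": [
            {
                "id": s.id,
                "compartment": s.compartment,
                "initial_amount": float(s.initial_amount),
                "role_tags": sorted(s.role_tags),
            }
            for s in network.species
        ],
        "reactions": [
            {
                "id": r.id,
                "module": r.module,
                "reactants": [[sp, int(st)] for sp, st in r.reactants],
                "products": [[sp, int(st)] for sp, st in r.products],
                "rate_law": {
                    "kind": r.rate_law.kind,
                    "hill_K": r.rate_law.hill_K,
                    "hill_n": r.rate_law.hill_n,
                },
                "parameter_id": r.parameter_id,
                "regulators": [
                    {"species": g.species, "mode": g.mode, "K": g.K, "n": g.n}
                    for g in r.regulators
                ],
            }
            for r in network.reactions
        ],
        "parameters": {
            pid: {
                "value": float(v),
                "bounds": [float(x) for x in params.bounds[pid]]
                if pid in params.bounds
                else None,
            }
            for pid, v in sorted(params.values.items())
        },
    }


def network_from_dict(doc: dict) -> tuple[ModelNetwork, ParameterSet]:
    species = [
        SpeciesDef(
            d["id"], d.get("compartment", "cytosol"),
            float(d.get("initial_amount", 0.0)),
            frozenset(d.get("role_tags", [])),
        )
        for d in doc["species"]
    ]
    reactions = [
        Reaction(
            id=d["id"],
            reactants=[(sp, int(st)) for sp, st in d.get("reactants", [])],
            products=[(sp, int(st)) for sp, st in d.get("products", [])],
            regulators=[
                Regulator(g["species"], g["mode"], g.get("K"), g.get("n", 1.0))
                for g in d.get("regulators", [])
            ],
            rate_law=RateLaw(
                kind=d["rate_law"]["kind"],
                hill_K=d["rate_law"].get("hill_K"),
                hill_n=d["rate_law"].get("hill_n", 1.0),
            ),
            parameter_id=d["parameter_id"],
            module=d.get("module", "environment"),
        )
        for d in doc["reactions"]
    ]
    values = {pid: d["value"] for pid, d in doc["parameters"].items()}
    bounds = {
        pid: tuple(d["bounds"])
        for pid, d in doc["parameters"].items()
        if d.get("bounds")
    }
    net = ModelNetwork(species, reactions, dict(doc.get("metadata", {})))
    return net, ParameterSet(values, bounds)


def save_model(path: str | Path, network: ModelNetwork, params: ParameterSet) -> None:
    Path(path).write_text(
        yaml.safe_dump(network_to_dict(network, params), sort_keys=False)
    )


def load_model(path: str | Path) -> tuple[ModelNetwork, ParameterSet]:
    return network_from_dict(yaml.safe_load(Path(path).read_text()))


def protocol_to_dict(protocol: StimulusProtocol) -> dict:
    return {
        "pre_equilibration": protocol.pre_equilibration,
        "phases": [
            {
                "label": p.label,
                "duration": p.duration,
                "environment": dict(p.environment),
                "ligand_doses": dict(p.ligand_doses),
            }
            for p in protocol.phases
        ],
    }


def protocol_from_dict(doc: dict) -> StimulusProtocol:
    return StimulusProtocol(
        [
            Phase(
                p["label"], float(p["duration"]),
                dict(p.get("environment", {})), dict(p.get("ligand_doses", {})),
            )
            for p in doc["phases"]
        ],
        float(doc.get("pre_equilibration", 24.0)),
    )


def save_trajectory(path: str | Path, traj: Trajectory) -> None:
    traj.to_frame().to_csv(path, index=False)
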