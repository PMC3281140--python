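"""YAML configuration round-tripping for the model parameter sets.

Keys mirror the dataclass field names, nested as

    binary: {n_pops, pop_size, beta, w_plus, w_inh, inputs, bias, ...}

for the binary network and

    architecture: {...}
    excitatory_neuron: {...}
    inhibitory_neuron: {...}
    synapses: {...}
    protocol: {...}
    dt, scale, seed

for the spiking network.  Unknown keys raise, so typos do not silently fall
back to defaults.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any, Type, TypeVar

import yaml

from .binary import BinaryNetworkParams
from .errors import InvalidParameterError
from .spiking import (
    EXC_NEURON,
    INH_NEURON,
    SYNAPSES,
    ArchitectureParams,
    NeuronParams,
    StimulusProtocol,
    SynapseParams,
)

__all__ = [
    "load_binary_params",
    "save_binary_params",
    "load_spiking_config",
    "save_spiking_config",
]

T = TypeVar("T")


def _from_dict(cls: Type[T], data: dict[str, Any], where: str) -> T:
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise InvalidParameterError(
            f"unknown keys {sorted(unknown)} in section {where!r}"
        )
    return cls(**data)


def load_binary_params(path: str | Path) -> BinaryNetworkParams:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    section = doc.get("binary", doc)
    return _from_dict(BinaryNetworkParams, section, "binary")


def save_binary_params(params: BinaryNetworkParams, path: str | Path) -> None:
    doc = {"binary": dataclasses.asdict(params)}
    doc["binary"]["inputs"] = list(params.inputs)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_spiking_config(path: str | Path) -> dict[str, Any]:
    """Load a full spiking-network configuration.

    Returns a dict with keys ``architecture``, ``excitatory_neuron``,
    ``inhibitory_neuron``, ``synapses``, ``protocol`` (dataclass instances)
    plus scalars ``dt``, ``scale`` and ``seed``.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    out: dict[str, Any] = {
        "architecture": _from_dict(ArchitectureParams,
                                   doc.get("architecture", {}), "architecture"),
        "excitatory_neuron": (_from_dict(NeuronParams, doc["excitatory_neuron"],
                                         "excitatory_neuron")
                              if "excitatory_neuron" in doc else EXC_NEURON),
        "inhibitory_neuron": (_from_dict(NeuronParams, doc["inhibitory_neuron"],
                                         "inhibitory_neuron")
                              if "inhibitory_neuron" in doc else INH_NEURON),
        "synapses": (_from_dict(SynapseParams, doc["synapses"], "synapses")
                     if "synapses" in doc else SYNAPSES),
        "protocol": _from_dict(StimulusProtocol, doc.get("protocol", {}),
                               "protocol"),
        "dt": float(doc.get("dt", 0.05)),
        "scale": float(doc.get("scale", 1.0)),
        "seed": int(doc.get("seed", 0)),
    }
    return out


def save_spiking_config(config: dict[str, Any], path: str | Path) -> None:
    doc: dict[str, Any] = {}
    for key in ("architecture", "excitatory_neuron", "inhibitory_neuron",
                "synapses", "protocol"):
        if key in config:
            doc[key] = dataclasses.asdict(config[key])
    for key in ("dt", "scale", "seed"):
        if key in config:
            doc[key] = config[key]
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
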