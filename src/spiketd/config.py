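"""Configuration and artifact I/O.

Circuit configurations are plain YAML documents with sections mirroring
the model description (architecture, neuron, synapse, stimulation, traces,
plasticity, simulation); spike rasters are two-column text files
(neuron_id, time_ms); weight snapshots are CSV tables suitable for
value-function and policy maps.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from .circuit import ArchitectureSpec, CircuitParams
from .lif import NeuronParams, Simulation
from .plasticity import PlasticityRates, TraceParams

__all__ = [
    "save_config",
    "load_config",
    "save_raster",
    "load_raster",
    "export_weight_snapshot",
]


def save_config(path, spec: ArchitectureSpec, params: CircuitParams) -> None:
    doc = {
        "architecture": asdict(spec),
        "neuron": asdict(params.neuron),
        "traces": asdict(params.traces),
        "plasticity": asdict(params.rates),
        "circuit": {
            k: v
            for k, v in asdict(params).items()
            if k not in ("neuron", "traces", "rates")
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_config(path) -> tuple[ArchitectureSpec, CircuitParams]:
    doc = yaml.safe_load(Path(path).read_text())
    spec = ArchitectureSpec(**doc["architecture"])
    params = CircuitParams(
        neuron=NeuronParams(**doc["neuron"]),
        traces=TraceParams(**doc["traces"]),
        rates=PlasticityRates(**doc["plasticity"]),
        **doc["circuit"],
    )
    return spec, params


def save_raster(sim: Simulation, path) -> None:
    """Two-column plain-text raster: neuron_id time_ms."""
    ids, times = sim.spike_record()
    with open(path, "w") as fh:
        fh.write("# neuron_id time_ms\n")
        for i, t in zip(ids, times):
            fh.write(f"{i} {t:.4f}\n")


def load_raster(path) -> tuple[np.ndarray, np.ndarray]:
    data = np.loadtxt(path, ndmin=2)
    if data.size == 0:
        return np.empty(0, dtype=int), np.empty(0)
    return data[:, 0].astype(int), data[:, 1]


def export_weight_snapshot(agent, path, t_ms: float | None = None) -> None:
    """CSV of per-state mean plastic weights: (state_id, target,
    mean_weight, time_ms)."""
    import pandas as pd

    t = agent.sim.t if t_ms is None else t_ms
    rows = []
    for s, w in enumerate(agent.state_value_weights()):
        rows.append((s, "striatum", float(w), t))
    for s in range(agent.spec.n_states):
        for a, w in enumerate(agent.actor_weights(s)):
            rows.append((s, f"actor_{a}", float(w), t))
    pd.DataFrame(rows, columns=["state_id", "target", "mean_weight",
                                "time_ms"]).to_csv(path, index=False)
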