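"""File formats: network JSON / edge lists, trace and curve CSVs."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from symptomnet.core_model import SimulationTrace, SymptomNetwork
from symptomnet.early_warning import EWSeries
from symptomnet.stress_protocol import HysteresisCurve


def write_network_json(net: SymptomNetwork, path: str | Path) -> None:
    """Serialize a network as JSON (labels, weights, thresholds)."""
    payload = {
        "labels": list(net.labels),
        "weights": net.weights.tolist(),
        "thresholds": net.thresholds.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_network_json(path: str | Path) -> SymptomNetwork:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"network file not found: {path}")
    payload = json.loads(path.read_text())
    return SymptomNetwork(
        labels=tuple(payload["labels"]),
        weights=np.asarray(payload["weights"], dtype=float),
        thresholds=np.asarray(payload["thresholds"], dtype=float),
    )


def write_network_edgelist(
    net: SymptomNetwork, edges_path: str | Path, thresholds_path: str | Path
) -> None:
    """Edge-list CSV (source,target,weight) plus thresholds CSV (label,threshold)."""
    iu, ju = np.triu_indices(net.J, k=1)
    mask = net.weights[iu, ju] != 0
    edges = pd.DataFrame(
        {
            "source": [net.labels[i] for i in iu[mask]],
            "target": [net.labels[j] for j in ju[mask]],
            "weight": net.weights[iu[mask], ju[mask]],
        }
    )
    edges.to_csv(edges_path, index=False)
    pd.DataFrame({"label": net.labels, "threshold": net.thresholds}).to_csv(
        thresholds_path, index=False
    )


def read_network_edgelist(
    edges_path: str | Path, thresholds_path: str | Path
) -> SymptomNetwork:
    thr = pd.read_csv(thresholds_path)
    labels = [str(x) for x in thr["label"]]
    index = {lab: i for i, lab in enumerate(labels)}
    J = len(labels)
    W = np.zeros((J, J))
    edges = pd.read_csv(edges_path)
    for _, row in edges.iterrows():
        try:
            i, j = index[str(row["source"])], index[str(row["target"])]
        except KeyError as err:
            raise ValueError(f"edge references unknown label {err}") from err
        W[i, j] = W[j, i] = float(row["weight"])
    return SymptomNetwork(
        labels=tuple(labels), weights=W, thresholds=thr["threshold"].to_numpy(float)
    )


def write_trace_csv(
    trace: SimulationTrace, path: str | Path, labels: Sequence[str] | None = None
) -> None:
    trace.to_frame(labels).to_csv(path, index=False)


def write_curve_csv(curve: HysteresisCurve, path: str | Path) -> None:
    curve.to_frame().to_csv(path, index=False)


def write_ew_csv(ew: EWSeries, path: str | Path, trace: SimulationTrace | None = None) -> None:
    ew.to_frame(trace).to_csv(path, index=False)
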