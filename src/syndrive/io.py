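"""Text-based input/output for networks, trajectories, and configs.

Networks are stored as JSON documents with keys ``AEE``, ``AEI``, ``AIE``,
``AII`` (row-major nested lists), ``lamE``, ``lamI``, ``BE``, ``BI``,
``vthE``, ``vthI``, and ``activation`` (an object with ``kind``, ``f_max``,
``gamma``).  Alternatively the four matrix keys may be replaced by a
``matrix_files`` object mapping each block name to a delimited-text (CSV)
file path, resolved relative to the document.  Trajectories are CSV with a
leading ``time`` column, state columns labeled ``E1..``/``I1..`` and, for
second-order models, derivative columns ``dE1..``/``dI1..``.  Configuration
files are YAML or JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .activations import ActivationSpec
from .network import NeuronalNetwork
from .simulate import Trajectory

_MATRIX_KEYS = ("AEE", "AEI", "AIE", "AII")
_VECTOR_KEYS = ("lamE", "lamI", "vthE", "vthI", "BE", "BI")


class SchemaError(ValueError):
    """A network/config document violates the expected schema."""


def write_network(net: NeuronalNetwork, path) -> None:
    if not net.constant_thresholds():
        raise ValueError("function-valued thresholds cannot be serialized")
    doc = {k: getattr(net, k).tolist() for k in _MATRIX_KEYS}
    doc |= {k: getattr(net, k).tolist() for k in _VECTOR_KEYS}
    doc["activation"] = {"kind": net.activation.kind,
                         "f_max": net.activation.f_max,
                         "gamma": net.activation.gamma}
    Path(path).write_text(json.dumps(doc, indent=1))


def read_network(path) -> NeuronalNetwork:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise SchemaError(f"{path}: not valid JSON: {e}") from e
    if not isinstance(doc, dict):
        raise SchemaError(f"{path}: top-level document must be an object")

    matrices = {}
    if "matrix_files" in doc:
        files = doc["matrix_files"]
        for k in _MATRIX_KEYS:
            if k not in files:
                raise SchemaError(f"{path}: matrix_files is missing key '{k}'")
            matrices[k] = np.loadtxt(path.parent / files[k], delimiter=",", ndmin=2)
    else:
        for k in _MATRIX_KEYS:
            if k not in doc:
                raise SchemaError(f"{path}: missing required key '{k}'")
            matrices[k] = np.asarray(doc[k], dtype=float)

    for k in ("lamE", "lamI", "vthE", "vthI"):
        if k not in doc:
            raise SchemaError(f"{path}: missing required key '{k}'")
    act = doc.get("activation")
    if not isinstance(act, dict) or "kind" not in act:
        raise SchemaError(f"{path}: missing or malformed key 'activation'")
    try:
        return NeuronalNetwork(
            **matrices,
            lamE=doc["lamE"], lamI=doc["lamI"],
            vthE=doc["vthE"], vthI=doc["vthI"],
            BE=doc.get("BE", 1.0), BI=doc.get("BI", 1.0),
            activation=ActivationSpec(kind=act["kind"],
                                      f_max=float(act.get("f_max", 1.0)),
                                      gamma=float(act.get("gamma", 1.0))))
    except ValueError as e:
        raise SchemaError(f"{path}: {e}") from e


def write_trajectory(traj: Trajectory, path) -> None:
    data = {"time": traj.times}
    for j, lab in enumerate(traj.labels):
        data[lab] = traj.S[:, j]
    if traj.Sdot is not None:
        for j, lab in enumerate(traj.labels):
            data[f"d{lab}"] = traj.Sdot[:, j]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def read_trajectory(path) -> Trajectory:
    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise SchemaError(f"{path}: trajectory CSV must have a 'time' column")
    state_cols = [c for c in df.columns if c != "time" and not c.startswith("d")]
    dcols = [f"d{c}" for c in state_cols]
    Sdot = df[dcols].to_numpy() if all(c in df.columns for c in dcols) and dcols else None
    return Trajectory(times=df["time"].to_numpy(),
                      S=df[state_cols].to_numpy(), Sdot=Sdot,
                      labels=state_cols)


def read_config(path) -> dict:
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    if not isinstance(doc, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    return doc
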