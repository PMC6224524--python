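"""File formats: CSV with a ``# key: value`` metadata header block for
records, curves and waveforms; JSON or nodes/edges CSV for vessel trees;
YAML/JSON for configuration."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .morphometry import VesselTree
from .pd_mechanics import PressureDiameterRecord, PressureStretchCurve
from .waveforms import PeriodicWaveform


def _write_csv_with_meta(path, df: pd.DataFrame, meta: dict) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)


def _read_csv_with_meta(path) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    meta: dict[str, str] = {}
    skip = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
            skip += 1
    df = pd.read_csv(path, skiprows=skip)
    return df, meta


def write_pd_record(path, record: PressureDiameterRecord) -> None:
    meta = {
        "vessel_id": record.vessel_id,
        "placenta_id": record.placenta_id,
        "group": record.group,
        "axial_stretch": record.axial_stretch,
        "initial_length_mm": record.initial_length,
    }
    df = pd.DataFrame({"t_s": record.t, "P_mmHg": record.P,
                       "D_outer_mm": record.D_outer})
    _write_csv_with_meta(path, df, meta)


def read_pd_record(path) -> PressureDiameterRecord:
    df, meta = _read_csv_with_meta(path)
    return PressureDiameterRecord(
        t=df["t_s"].to_numpy(), P=df["P_mmHg"].to_numpy(),
        D_outer=df["D_outer_mm"].to_numpy(),
        vessel_id=meta.get("vessel_id", "vessel"),
        placenta_id=meta.get("placenta_id", "placenta"),
        group=meta.get("group", "normal"),
        axial_stretch=float(meta.get("axial_stretch", 1.1)),
        initial_length=float(meta.get("initial_length_mm", 20.0)),
    )


def write_curve(path, curve: PressureStretchCurve, **extra_meta) -> None:
    meta = {"n_cycles_averaged": curve.n_cycles_averaged,
            "D0_mm": curve.D0, **extra_meta}
    df = pd.DataFrame({"P_mmHg": curve.P_grid, "lambda": curve.lam})
    _write_csv_with_meta(path, df, meta)


def read_curve(path) -> PressureStretchCurve:
    df, meta = _read_csv_with_meta(path)
    return PressureStretchCurve(
        P_grid=df["P_mmHg"].to_numpy(), lam=df["lambda"].to_numpy(),
        n_cycles_averaged=int(meta.get("n_cycles_averaged", 0)),
        D0=float(meta.get("D0_mm", "nan")),
    )


def write_waveform(path, wave: PeriodicWaveform, **extra_meta) -> None:
    meta = {"period_s": wave.period, **extra_meta}
    df = pd.DataFrame({"t_s": wave.t, "value": wave.v})
    _write_csv_with_meta(path, df, meta)


def read_waveform(path) -> PeriodicWaveform:
    df, meta = _read_csv_with_meta(path)
    return PeriodicWaveform(t=df["t_s"].to_numpy(),
                            v=df["value"].to_numpy(),
                            period=float(meta["period_s"]))


def write_tree_json(path, tree: VesselTree) -> None:
    doc = {
        "root_id": int(tree.root_id),
        "nodes": tree.nodes.to_dict(orient="records"),
        "edges": tree.edges.to_dict(orient="records"),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_tree_json(path) -> VesselTree:
    doc = json.loads(Path(path).read_text())
    return VesselTree(nodes=pd.DataFrame(doc["nodes"]),
                      edges=pd.DataFrame(doc["edges"]),
                      root_id=int(doc["root_id"]))


def write_tree_csv(nodes_path, edges_path, tree: VesselTree) -> None:
    tree.nodes.to_csv(nodes_path, index=False)
    tree.edges.to_csv(edges_path, index=False)


def read_tree_csv(nodes_path, edges_path, root_id: int | None = None) -> VesselTree:
    nodes = pd.read_csv(nodes_path)
    edges = pd.read_csv(edges_path)
    if root_id is None:
        roots = set(nodes["id"]) - set(edges["child"])
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {sorted(roots)}")
        root_id = roots.pop()
    return VesselTree(nodes=nodes, edges=edges, root_id=int(root_id))


def load_config(path) -> dict:
    """Read a YAML or JSON configuration file into a dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)
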