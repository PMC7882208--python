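"""File formats and configuration: atlas TSV, HDF5 epoch containers,
BrainNet Viewer .node/.edge files, YAML pipeline configuration."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .preprocess import EpochSet

logger = logging.getLogger(__name__)

ATLAS_COLUMNS = ["node_id", "label", "x_mm", "y_mm", "z_mm"]


def read_atlas(path) -> pd.DataFrame:
    """Read a node atlas TSV (node_id, label, x_mm, y_mm, z_mm).

    Row order defines matrix indexing for every downstream stage.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ATLAS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"atlas missing required column(s): {missing}")
    if len(df) == 0:
        raise ValueError("atlas contains no nodes")
    dup = df["label"][df["label"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate atlas label(s): {sorted(set(dup))}")
    if not np.all(np.isfinite(df[["x_mm", "y_mm", "z_mm"]].values)):
        raise ValueError("non-finite atlas coordinates")
    return df.reset_index(drop=True)


def make_demo_atlas(n_nodes: int) -> pd.DataFrame:
    """Deterministic toy atlas: nodes on a sphere of 80 mm radius."""
    i = np.arange(n_nodes)
    golden = np.pi * (3 - np.sqrt(5))
    z = 1 - 2 * (i + 0.5) / n_nodes
    r = np.sqrt(1 - z**2)
    return pd.DataFrame(
        {
            "node_id": i,
            "label": [f"node{k:03d}" for k in i],
            "x_mm": 80 * r * np.cos(golden * i),
            "y_mm": 80 * r * np.sin(golden * i),
            "z_mm": 80 * z,
        }
    )


def write_atlas(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BrainNet Viewer files


def write_brainnet(component, atlas: pd.DataFrame, node_path, edge_path, weights=None):
    """Write BrainNet-Viewer-compatible .node and .edge files.

    The .node file has whitespace-delimited rows ``x y z color size
    label`` for the component's nodes (color = 1, size = node degree
    within the component); the .edge file is the full square matrix with
    the component's edge weights (1.0 unless ``weights`` — a full node ×
    node matrix — is given) and zeros elsewhere.
    """
    edges = list(component.edges) if hasattr(component, "edges") else list(component)
    if not edges:
        raise ValueError("refusing to write an empty component")
    n = len(atlas)
    nodes = sorted({u for e in edges for u in e})
    if nodes[-1] >= n:
        raise ValueError(f"component node {nodes[-1]} missing from the {n}-node atlas")
    deg = {v: 0 for v in nodes}
    mat = np.zeros((n, n))
    for u, v in edges:
        w = 1.0 if weights is None else float(weights[u, v])
        mat[u, v] = mat[v, u] = w
        deg[u] += 1
        deg[v] += 1
    with open(node_path, "w") as f:
        for v in nodes:
            row = atlas.iloc[v]
            f.write(
                f"{row.x_mm:.3f}\t{row.y_mm:.3f}\t{row.z_mm:.3f}\t1\t{deg[v]}\t{row.label}\n"
            )
    np.savetxt(edge_path, mat, fmt="%.6g", delimiter="\t")


def read_brainnet_edge(path) -> np.ndarray:
    return np.loadtxt(path, delimiter="\t")


def read_brainnet_node(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None, names=["x_mm", "y_mm", "z_mm", "color", "size", "label"]
    )


# ---------------------------------------------------------------------------
# HDF5 containers


def save_subjects_h5(path, subjects, truth=None, meta: dict | None = None):
    """Write per-subject epochs (plus optional ground truth) to HDF5.

    Layout: /subjects/<id>/{epochs,times,conditions,kept,reasons}, attrs
    ``fs`` and ``group``; /truth/{edges,mixing,...}; /meta attrs.
    ``subjects`` may be any iterable of SubjectData (streamed).
    """
    with h5py.File(path, "w") as f:
        gsub = f.create_group("subjects")
        for s in subjects:
            g = gsub.create_group(s.subject_id)
            e = s.epochs
            g.create_dataset("epochs", data=e.data)
            g.create_dataset("times", data=e.times)
            g.create_dataset("conditions", data=np.array(e.conditions, dtype="S"))
            g.create_dataset("kept", data=e.kept)
            g.create_dataset("reasons", data=np.array(e.reasons, dtype="S"))
            g.attrs["fs"] = e.fs
            g.attrs["group"] = s.group
        if truth is not None:
            gt = f.create_group("truth")
            gt.create_dataset(
                "planted_edges", data=np.array(truth.planted_edges, dtype=int).reshape(-1, 2)
            )
            gt.create_dataset("mixing", data=truth.mixing)
            gt.attrs["seed"] = truth.seed
            gt.create_dataset("groups", data=np.array(truth.groups, dtype="S"))
            gr = gt.create_group("realized_coupling")
            for grp, d in truth.realized_coupling.items():
                arr = np.array([[e[0], e[1], r] for e, r in d.items()], dtype=float)
                gr.create_dataset(grp, data=arr.reshape(-1, 3))
        gm = f.create_group("meta")
        for k, v in (meta or {}).items():
            gm.attrs[k] = v


def load_subjects_h5(path):
    """Read subjects written by :func:`save_subjects_h5`.

    Returns (subjects, meta) where subjects is a list of SubjectData.
    """
    from .synthgen import SubjectData

    subjects, meta = [], {}
    with h5py.File(path, "r") as f:
        for sid in sorted(f["subjects"]):
            g = f["subjects"][sid]
            epochs = EpochSet(
                data=g["epochs"][()],
                times=g["times"][()],
                fs=float(g.attrs["fs"]),
                conditions=np.array([c.decode() for c in g["conditions"][()]], dtype=object),
                kept=g["kept"][()].astype(bool),
                reasons=np.array([c.decode() for c in g["reasons"][()]], dtype=object),
            )
            subjects.append(SubjectData(subject_id=sid, group=str(g.attrs["group"]), epochs=epochs))
        if "meta" in f:
            meta = dict(f["meta"].attrs)
    return subjects, meta


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """All pipeline parameters in one serialisable record.

    Every threshold the method fixes is a named field defaulting to its
    conventional value: 2500 fT amplitude ceiling, 10 mm motion ceiling,
    5% covariance regularization, strict t threshold 2.7 (the midpoint
    of the 2.5–3.0 range), 5000 permutations, canonical band edges and
    the −5..0 / 0–5 / 5–10 / 10–15 s windows.
    """

    n_nodes: int = 90
    n_subjects_per_group: int = 30
    n_trials: int = 22
    fs: float = 600.0
    band: str = "beta"
    bands: tuple = ("theta", "alpha", "beta", "gamma")
    planted_edges: tuple = ()
    coupling_by_group: dict = field(default_factory=lambda: {"A": 0.5, "B": 0.2})
    baseline_coupling: float = 0.0
    mixing_strength: float = 0.3
    artefact_rates: dict = field(default_factory=lambda: {"spike": 0.04, "motion": 0.04})
    amp_threshold_ft: float = 2500.0
    motion_threshold_mm: float = 10.0
    reg_fraction: float = 0.05
    tau: float = 2.7
    n_perm: int = 5000
    eps: float = 1e-3
    behaviour_slopes: dict = field(default_factory=lambda: {"A": -0.5, "B": 0.0})
    behaviour_noise_sd: float = 1.0
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bands"] = list(d["bands"])
        d["planted_edges"] = [list(e) for e in d["planted_edges"]]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        d = dict(d)
        if "bands" in d:
            d["bands"] = tuple(d["bands"])
        if "planted_edges" in d:
            d["planted_edges"] = tuple(tuple(e) for e in d["planted_edges"])
        return cls(**d)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def load_config(path) -> PipelineConfig:
    with open(path) as f:
        data = yaml.safe_load(f) or {}
    return PipelineConfig.from_dict(data)


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(config.to_dict(), f, sort_keys=True)


def derive_seeds(master: int, names) -> dict:
    """Deterministic named per-stage seeds (< 2**31) from a master seed."""
    ss = np.random.SeedSequence(master)
    children = ss.spawn(len(list(names)))
    return {
        n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)
    }
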