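"""Core data types for reaction path networks and their on-disk formats.

A network consists of equilibrium structures (EQs; local minima, the nodes)
and reaction paths (edges) whose transition state (TS) is the free-energy
maximum along the path.  Gibbs energies are stored in kJ/mol relative to an
arbitrary common reference — every downstream quantity depends on energy
differences only, so the choice of zero is immaterial.

On-disk formats:

* multi-structure XYZ for geometries (comment line may carry
  ``id=<label> G=<kJ/mol>`` tokens),
* two CSV tables (nodes: ``id,gibbs_kjmol[,structure_file,frame]``;
  edges: ``id,eq_a,eq_b,ts_gibbs_kjmol``),
* a single JSON document for provenance-carrying round trips.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .constants import ELEMENTS

logger = logging.getLogger(__name__)

__all__ = [
    "Structure",
    "PathEdge",
    "NetworkNode",
    "ReactionPathNetwork",
    "ParseError",
    "NetworkLoadError",
    "read_xyz_ensemble",
    "write_xyz_ensemble",
    "read_network",
    "write_network",
    "interatomic_distance",
    "apply_energy_overrides",
]


class ParseError(ValueError):
    """Malformed geometry file."""


class NetworkLoadError(ValueError):
    """Inconsistent or malformed network tables."""


@dataclass
class Structure:
    """A labelled Cartesian geometry of an EQ or TS.

    Parameters
    ----------
    id : str
        Opaque text label.
    elements : list of str
        Element symbols, length N.
    coords : (N, 3) ndarray
        Cartesian coordinates in Å.
    role : {"EQ", "TS"}
    gibbs_energy : float, optional
        Gibbs energy in kJ/mol relative to an arbitrary common zero.
    electronic_energy : float, optional
    """

    id: str
    elements: list[str]
    coords: np.ndarray
    role: str = "EQ"
    gibbs_energy: float | None = None
    electronic_energy: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must be (N, 3), got {self.coords.shape}")
        n = len(self.elements)
        if n < 1 or self.coords.shape[0] != n:
            raise ValueError(
                f"elements ({n}) and coords ({self.coords.shape[0]}) lengths differ"
            )
        if not np.isfinite(self.coords).all():
            raise ValueError(f"structure {self.id!r}: non-finite coordinate")
        if self.gibbs_energy is not None and not math.isfinite(self.gibbs_energy):
            raise ValueError(f"structure {self.id!r}: non-finite Gibbs energy")
        if self.role not in ("EQ", "TS"):
            raise ValueError(f"role must be 'EQ' or 'TS', got {self.role!r}")
        for sym in self.elements:
            if sym not in ELEMENTS:
                raise ValueError(f"structure {self.id!r}: unknown element {sym!r}")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)


def interatomic_distance(s: Structure, i: int, j: int) -> float:
    """Euclidean distance in Å between atoms ``i`` and ``j`` of ``s``."""
    n = s.n_atoms
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"atom index out of range (N={n}): {i}, {j}")
    if i == j:
        raise ValueError("i and j must differ")
    return float(np.linalg.norm(s.coords[i] - s.coords[j]))


@dataclass(frozen=True)
class PathEdge:
    """A reaction path between two EQs with its TS Gibbs energy (kJ/mol)."""

    id: str
    eq_a: str
    eq_b: str
    ts_gibbs: float
    ts_structure_ref: str | None = None

    def __post_init__(self) -> None:
        if self.eq_a == self.eq_b:
            raise ValueError(f"edge {self.id!r}: self-loop {self.eq_a!r}")
        if not math.isfinite(self.ts_gibbs):
            raise ValueError(f"edge {self.id!r}: non-finite TS energy")


@dataclass
class NetworkNode:
    gibbs: float
    structure_ref: str | None = None


@dataclass
class ReactionPathNetwork:
    """EQ nodes with Gibbs energies, reaction-path edges with TS energies.

    Parallel edges between a node pair are permitted (distinct conformational
    TS channels); their rates add in the rate matrix.  Node ids are opaque
    strings with no ordering semantics.
    """

    nodes: dict[str, NetworkNode]
    edges: list[PathEdge]
    temperature: float = 333.15
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError(f"temperature must be > 0, got {self.temperature}")
        for nid, node in self.nodes.items():
            if not math.isfinite(node.gibbs):
                raise ValueError(f"node {nid!r}: non-finite Gibbs energy")
        for e in self.edges:
            for end in (e.eq_a, e.eq_b):
                if end not in self.nodes:
                    raise NetworkLoadError(
                        f"edge {e.id!r} references unknown node {end!r}"
                    )

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node_order(self) -> list[str]:
        """Deterministic node ordering (lexicographic) for matrix indexing."""
        return sorted(self.nodes)

    def gibbs_vector(self, order: Iterable[str] | None = None) -> np.ndarray:
        order = list(order) if order is not None else self.node_order()
        return np.array([self.nodes[i].gibbs for i in order], dtype=float)

    def shifted(self, delta: float) -> "ReactionPathNetwork":
        """Copy with all node and TS energies shifted by ``delta`` kJ/mol."""
        nodes = {
            nid: NetworkNode(n.gibbs + delta, n.structure_ref)
            for nid, n in self.nodes.items()
        }
        edges = [
            PathEdge(e.id, e.eq_a, e.eq_b, e.ts_gibbs + delta, e.ts_structure_ref)
            for e in self.edges
        ]
        return ReactionPathNetwork(nodes, edges, self.temperature, dict(self.metadata))

    # ---- JSON round trip ------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "temperature": self.temperature,
            "metadata": self.metadata,
            "nodes": {
                nid: {"gibbs": n.gibbs, "structure_ref": n.structure_ref}
                for nid, n in self.nodes.items()
            },
            "edges": [
                {
                    "id": e.id,
                    "eq_a": e.eq_a,
                    "eq_b": e.eq_b,
                    "ts_gibbs": e.ts_gibbs,
                    "ts_structure_ref": e.ts_structure_ref,
                }
                for e in self.edges
            ],
        }
        text = json.dumps(doc, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ReactionPathNetwork":
        p = Path(source)
        text = p.read_text(encoding="utf-8") if p.exists() else str(source)
        doc = json.loads(text)
        nodes = {
            nid: NetworkNode(float(d["gibbs"]), d.get("structure_ref"))
            for nid, d in doc["nodes"].items()
        }
        edges = [
            PathEdge(
                d["id"], d["eq_a"], d["eq_b"], float(d["ts_gibbs"]),
                d.get("ts_structure_ref"),
            )
            for d in doc["edges"]
        ]
        return cls(nodes, edges, float(doc["temperature"]), doc.get("metadata", {}))


# ---- XYZ ensemble I/O ----------------------------------------------------


def _parse_comment_tokens(comment: str) -> dict[str, str]:
    out = {}
    for tok in comment.split():
        if "=" in tok:
            key, _, val = tok.partition("=")
            out[key] = val
    return out


def read_xyz_ensemble(path: str | Path, role: str = "EQ") -> list[Structure]:
    """Read a multi-structure XYZ file into a list of :class:`Structure`.

    The comment line of each frame may carry ``id=<label>`` and ``G=<value>``
    tokens; ``G`` is taken as the Gibbs energy in kJ/mol.  Frames without an
    ``id`` token are labelled ``frame<k>``.
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    structures: list[Structure] = []
    pos, frame = 0, 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            natoms = int(lines[pos].strip())
        except ValueError:
            raise ParseError(f"frame {frame}: bad atom-count line {lines[pos]!r}")
        if natoms < 1:
            raise ParseError(f"frame {frame}: bad atom count {natoms}")
        comment = lines[pos + 1] if pos + 1 < len(lines) else ""
        tokens = _parse_comment_tokens(comment)
        body = lines[pos + 2 : pos + 2 + natoms]
        if len(body) < natoms:
            raise ParseError(f"frame {frame}: expected {natoms} atoms, file truncated")
        elements, coords = [], []
        for k, line in enumerate(body):
            parts = line.split()
            if len(parts) < 4:
                raise ParseError(f"frame {frame}, atom {k}: malformed line {line!r}")
            sym = parts[0]
            if sym not in ELEMENTS:
                raise ParseError(f"frame {frame}, atom {k}: unknown element {sym!r}")
            try:
                xyz = [float(v) for v in parts[1:4]]
            except ValueError:
                raise ParseError(
                    f"frame {frame}, atom {k}: non-numeric coordinate in {line!r}"
                )
            elements.append(sym)
            coords.append(xyz)
        gibbs = float(tokens["G"]) if "G" in tokens else None
        sid = tokens.get("id", f"frame{frame}")
        try:
            structures.append(
                Structure(sid, elements, np.array(coords), role=role, gibbs_energy=gibbs)
            )
        except ValueError as exc:
            raise ParseError(f"frame {frame}: {exc}")
        pos += 2 + natoms
        frame += 1
    return structures


def write_xyz_ensemble(structures: Iterable[Structure], path: str | Path) -> None:
    """Write structures as multi-frame XYZ with ``id=``/``G=`` comment tokens."""
    chunks = []
    for s in structures:
        comment = f"id={s.id}"
        if s.gibbs_energy is not None:
            comment += f" G={s.gibbs_energy:.12g}"
        rows = "\n".join(
            f"{sym} {x:.10f} {y:.10f} {z:.10f}"
            for sym, (x, y, z) in zip(s.elements, s.coords)
        )
        chunks.append(f"{s.n_atoms}\n{comment}\n{rows}")
    Path(path).write_text("\n".join(chunks) + "\n", encoding="utf-8")


# ---- CSV table I/O -------------------------------------------------------


def read_network(
    nodes_table: str | Path,
    edges_table: str | Path,
    temperature: float = 333.15,
) -> ReactionPathNetwork:
    """Load a network from nodes/edges CSV tables.

    Self-loop edges (a path returning to the same EQ) carry no first-order
    kinetic information; they are dropped with a logged count.  Duplicate node
    ids and edges referencing unknown nodes are errors.
    """
    ndf = pd.read_csv(nodes_table, dtype={"id": str}, float_precision="round_trip")
    for col in ("id", "gibbs_kjmol"):
        if col not in ndf.columns:
            raise NetworkLoadError(f"nodes table missing column {col!r}")
    if ndf["id"].duplicated().any():
        dups = ndf.loc[ndf["id"].duplicated(), "id"].tolist()
        raise NetworkLoadError(f"duplicate node ids: {dups}")
    nodes = {}
    for _, row in ndf.iterrows():
        ref = row.get("structure_file")
        nodes[row["id"]] = NetworkNode(
            float(row["gibbs_kjmol"]),
            None if ref is None or (isinstance(ref, float) and math.isnan(ref)) else str(ref),
        )

    edf = pd.read_csv(
        edges_table, dtype={"id": str, "eq_a": str, "eq_b": str},
        float_precision="round_trip",
    )
    for col in ("id", "eq_a", "eq_b", "ts_gibbs_kjmol"):
        if col not in edf.columns:
            raise NetworkLoadError(f"edges table missing column {col!r}")
    edges, n_selfloops = [], 0
    for _, row in edf.iterrows():
        a, b = row["eq_a"], row["eq_b"]
        if a == b:
            n_selfloops += 1
            continue
        for end in (a, b):
            if end not in nodes:
                raise NetworkLoadError(
                    f"edge {row['id']!r} references unknown node {end!r}"
                )
        edges.append(PathEdge(row["id"], a, b, float(row["ts_gibbs_kjmol"])))
    if n_selfloops:
        logger.info("dropped %d self-loop path(s) at load", n_selfloops)
    meta = {"nodes_table": str(nodes_table), "edges_table": str(edges_table),
            "dropped_self_loops": n_selfloops}
    return ReactionPathNetwork(nodes, edges, temperature, meta)


def write_network(
    network: ReactionPathNetwork,
    nodes_table: str | Path,
    edges_table: str | Path,
) -> None:
    """Write the nodes/edges CSV tables (exact float round trip via repr)."""
    ndf = pd.DataFrame(
        {
            "id": list(network.nodes),
            "gibbs_kjmol": [n.gibbs for n in network.nodes.values()],
            "structure_file": [n.structure_ref for n in network.nodes.values()],
        }
    )
    edf = pd.DataFrame(
        {
            "id": [e.id for e in network.edges],
            "eq_a": [e.eq_a for e in network.edges],
            "eq_b": [e.eq_b for e in network.edges],
            "ts_gibbs_kjmol": [e.ts_gibbs for e in network.edges],
        }
    )
    ndf.to_csv(nodes_table, index=False)
    edf.to_csv(edges_table, index=False)


def apply_energy_overrides(
    network: ReactionPathNetwork,
    overrides: str | Path | pd.DataFrame,
) -> ReactionPathNetwork:
    """Return a copy of the network with selected energies replaced.

    ``overrides`` is a CSV (or DataFrame) with columns ``kind`` (``node`` or
    ``edge``), ``id`` and ``gibbs_kjmol``.  This supports curating a network
    by replacing the energies of individual EQs/TSs (e.g. to exclude spurious
    geometries from the kinetic analysis) without editing the master tables.
    """
    df = overrides if isinstance(overrides, pd.DataFrame) else pd.read_csv(overrides)
    nodes = {nid: NetworkNode(n.gibbs, n.structure_ref) for nid, n in network.nodes.items()}
    edges = {e.id: e for e in network.edges}
    for _, row in df.iterrows():
        kind, oid, g = row["kind"], str(row["id"]), float(row["gibbs_kjmol"])
        if kind == "node":
            if oid not in nodes:
                raise NetworkLoadError(f"override references unknown node {oid!r}")
            nodes[oid] = NetworkNode(g, nodes[oid].structure_ref)
        elif kind == "edge":
            if oid not in edges:
                raise NetworkLoadError(f"override references unknown edge {oid!r}")
            e = edges[oid]
            edges[oid] = PathEdge(e.id, e.eq_a, e.eq_b, g, e.ts_structure_ref)
        else:
            raise NetworkLoadError(f"override kind must be node|edge, got {kind!r}")
    out = ReactionPathNetwork(
        nodes, list(edges.values()), network.temperature, dict(network.metadata)
    )
    out.metadata["energy_overrides"] = int(len(df))
    return out
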