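"""Coarse-graining EQs by bonding pattern and reaction-site stereochemistry.

Tens of thousands of conformers collapse into a readable mechanism once EQs
are grouped by (i) their molecular graph — bonds perceived from a covalent
radius criterion and canonicalized by Morgan-style neighbourhood refinement —
and (ii) the absolute configuration (R/S) at the stereocenters of a
user-designated reaction-site region.  The coarse group network keeps, per
group, only the lowest-Gibbs-energy member and, per group pair, only the
lowest-energy connecting TS.
"""

from __future__ import annotations

import hashlib
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .constants import atomic_number, covalent_radius
from .network import ReactionPathNetwork, Structure

__all__ = [
    "BondPattern",
    "StereoDescriptor",
    "GroupAssignment",
    "GroupNetwork",
    "detect_bonds",
    "region_bond_pattern",
    "stereo_descriptor",
    "assign_groups",
    "build_group_network",
]


def _sha(text: str) -> str:
    return hashlib.sha1(text.encode()).hexdigest()[:16]


def _morgan_fingerprint(init_labels: Sequence[str], bonds: Iterable[tuple[int, int]]) -> str:
    """Canonical graph fingerprint by iterative neighbourhood refinement.

    Permutation-invariant: only the multiset of refined atom classes and the
    multiset of refined edge classes enter the hash.
    """
    n = len(init_labels)
    adj = defaultdict(list)
    for i, j in bonds:
        adj[i].append(j)
        adj[j].append(i)
    labels = [_sha(l) for l in init_labels]
    n_classes = len(set(labels))
    for _ in range(max(n, 1)):
        labels = [
            _sha(labels[i] + "|" + ",".join(sorted(labels[j] for j in adj[i])))
            for i in range(n)
        ]
        new_n = len(set(labels))
        if new_n == n_classes:
            break
        n_classes = new_n
    atom_part = ",".join(sorted(labels))
    edge_part = ";".join(sorted("-".join(sorted((labels[i], labels[j]))) for i, j in bonds))
    return _sha(atom_part + "#" + edge_part)


@dataclass(frozen=True)
class BondPattern:
    """Canonical bonding pattern of (part of) a structure.

    ``fingerprint`` is invariant under rigid motions, mirror reflection and
    permutation of identical atoms; ``bonds`` are atom-index pairs (i < j);
    ``element_pairs`` is the sorted multiset of bonded element pairs.
    """

    fingerprint: str
    bonds: tuple[tuple[int, int], ...]
    element_pairs: tuple[tuple[str, str], ...]

    def neighbors(self, i: int) -> list[int]:
        out = [b for a, b in self.bonds if a == i]
        out += [a for a, b in self.bonds if b == i]
        return sorted(out)


def _perceive_bonds(s: Structure, scale: float) -> list[tuple[int, int]]:
    if not (0.5 < scale < 2.0):
        raise ValueError(f"scale must lie in (0.5, 2.0), got {scale}")
    radii = np.array([covalent_radius(sym) for sym in s.elements])
    diff = s.coords[:, None, :] - s.coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    cut = scale * (radii[:, None] + radii[None, :])
    ii, jj = np.nonzero(np.triu(dist < cut, k=1))
    return [(int(i), int(j)) for i, j in zip(ii, jj)]


def detect_bonds(s: Structure, scale: float = 1.2) -> BondPattern:
    """Perceive bonds: i–j bonded iff d(i,j) < scale·(r_cov(i) + r_cov(j)).

    Uses published single-bond covalent radii; the default scale of 1.2 is a
    common perception margin and is configurable because "bonded" is a
    modelling choice, not an observable.
    """
    bonds = _perceive_bonds(s, scale)
    fp = _morgan_fingerprint(list(s.elements), bonds)
    pairs = tuple(
        sorted(tuple(sorted((s.elements[i], s.elements[j]))) for i, j in bonds)
    )
    return BondPattern(fp, tuple(bonds), pairs)


def region_bond_pattern(
    s: Structure, region: Iterable[int], scale: float = 1.2
) -> BondPattern:
    """Bond pattern of a reaction-site region plus its bonds to the rest.

    The subgraph contains the region atoms and their direct neighbours; only
    bonds with at least one endpoint in the region are kept.  Region
    membership enters the atom labels, so the same fragment inside and
    outside the region is distinguished.
    """
    region = set(region)
    n = s.n_atoms
    bad = [i for i in region if not (0 <= i < n)]
    if bad:
        raise IndexError(f"region atom indices out of range: {bad}")
    all_bonds = _perceive_bonds(s, scale)
    sub_bonds = [(i, j) for i, j in all_bonds if i in region or j in region]
    atoms = sorted(region | {a for b in sub_bonds for a in b})
    remap = {a: k for k, a in enumerate(atoms)}
    labels = [
        s.elements[a] + (":site" if a in region else ":env") for a in atoms
    ]
    mapped = [(remap[i], remap[j]) for i, j in sub_bonds]
    fp = _morgan_fingerprint(labels, mapped)
    pairs = tuple(
        sorted(tuple(sorted((s.elements[i], s.elements[j]))) for i, j in sub_bonds)
    )
    return BondPattern(fp, tuple(sub_bonds), pairs)


# ---------------------------------------------------------------------------
# stereodescriptors


@dataclass(frozen=True)
class StereoDescriptor:
    """R/S label at a tetra-coordinate centre from the signed tetrahedron volume.

    ``substituents`` lists the four neighbour atom indices in descending
    priority; ``signed_volume`` is det[v1−v4, v2−v4, v3−v4] in Å³.  Mirror
    reflection negates the volume and swaps R↔S.
    """

    label: str  # "R" | "S" | "none"
    center: int
    substituents: tuple[int, int, int, int]
    signed_volume: float


def _substituent_key(elements, adj, atom: int, parent: int, depth: int):
    z = atomic_number(elements[atom])
    if depth == 0:
        return (z,)
    subs = sorted(
        (
            _substituent_key(elements, adj, nb, atom, depth - 1)
            for nb in adj[atom]
            if nb != parent
        ),
        reverse=True,
    )
    return (z, tuple(subs))


def stereo_descriptor(
    s: Structure,
    center: int,
    pattern: BondPattern,
    planarity_tol: float = 0.1,
    depth: int = 3,
) -> StereoDescriptor:
    """Assign R/S at ``center`` using a simplified priority ranking.

    Substituents are ranked by atomic number with ties broken by the sorted
    atomic numbers of successive neighbour shells (to ``depth`` bonds; not
    full CIP — sufficient for stereocenters with chemically distinct
    substituents).  Viewing the top three priorities from the side opposite
    the lowest, a clockwise arrangement (negative signed volume under the
    right-hand convention) is R, counterclockwise is S.  Near-planar centres
    (|volume| < ``planarity_tol`` Å³) or exhausted ties give "none".
    """
    nbrs = pattern.neighbors(center)
    if len(nbrs) != 4:
        raise ValueError(
            f"stereocenter must have exactly 4 bonded neighbors, atom {center} has {len(nbrs)}"
        )
    adj = defaultdict(list)
    for i, j in pattern.bonds:
        adj[i].append(j)
        adj[j].append(i)
    keys = {nb: _substituent_key(s.elements, adj, nb, center, depth) for nb in nbrs}
    ranked = sorted(nbrs, key=lambda nb: keys[nb], reverse=True)
    tied = any(keys[ranked[k]] == keys[ranked[k + 1]] for k in range(3))
    v = [s.coords[a] - s.coords[ranked[3]] for a in ranked[:3]]
    vol = float(np.linalg.det(np.array(v)))
    if tied or abs(vol) < planarity_tol:
        label = "none"
    else:
        label = "R" if vol < 0 else "S"
    return StereoDescriptor(label, center, tuple(ranked), vol)


# ---------------------------------------------------------------------------
# group assignment


@dataclass
class GroupAssignment:
    """Partition of network nodes into (bond pattern × stereochemistry) groups.

    Group ids ``G1, G2, ...`` are assigned by ascending minimum Gibbs energy.
    """

    node_to_group: dict[str, str]
    group_key: dict[str, tuple]
    group_members: dict[str, list[str]]
    group_min: dict[str, tuple[float, str]]  # gid -> (min G, node id)
    region: tuple[int, ...]

    @property
    def n_groups(self) -> int:
        return len(self.group_key)

    def stereo_label(self, gid: str) -> str:
        """Concatenated stereo labels of a group's reaction-site centers."""
        _, stereo = self.group_key[gid]
        return ",".join(f"{c}:{l}" for c, l in stereo) or "none"

    def groups_with_label(self, label: str) -> list[str]:
        return [
            g
            for g, (_, stereo) in self.group_key.items()
            if any(l == label for _, l in stereo)
        ]

    def to_table(self) -> pd.DataFrame:
        rows = [
            (nid, gid, self.group_key[gid][0], self.stereo_label(gid))
            for nid, gid in sorted(self.node_to_group.items())
        ]
        return pd.DataFrame(
            rows, columns=["id", "group", "bond_fingerprint", "stereo"]
        )


def assign_groups(
    network: ReactionPathNetwork,
    structures: Mapping[str, Structure] | Iterable[Structure],
    region: Iterable[int],
    scale: float = 1.2,
    stereocenters: Sequence[int] | None = None,
    planarity_tol: float = 0.1,
) -> GroupAssignment:
    """Group every EQ by reaction-site bonding pattern and stereochemistry.

    The group key of a node is (region bond-pattern fingerprint, sorted
    (center, R/S label) pairs).  Stereocenters default to the region atoms
    with exactly four bonded neighbours; atom ordering must be consistent
    across all geometries.
    """
    if not isinstance(structures, Mapping):
        structures = {s.id: s for s in structures}
    region = tuple(sorted(set(region)))
    if not region:
        raise ValueError("region must contain at least one atom index")
    missing = [nid for nid in network.nodes if nid not in structures]
    if missing:
        raise ValueError(f"nodes without geometry: {missing[:5]}")
    counts = {structures[nid].n_atoms for nid in network.nodes}
    if len(counts) > 1:
        raise ValueError(f"inconsistent atom counts across structures: {sorted(counts)}")

    keys: dict[str, tuple] = {}
    for nid in network.nodes:
        s = structures[nid]
        rp = region_bond_pattern(s, region, scale)
        full = detect_bonds(s, scale)
        if stereocenters is None:
            centers = [a for a in region if len(full.neighbors(a)) == 4]
        else:
            centers = list(stereocenters)
        stereo = tuple(
            sorted(
                (c, stereo_descriptor(s, c, full, planarity_tol).label)
                for c in centers
            )
        )
        keys[nid] = (rp.fingerprint, stereo)

    by_key: dict[tuple, list[str]] = defaultdict(list)
    for nid, key in keys.items():
        by_key[key].append(nid)
    # sort groups by their minimum Gibbs energy, ties by representative id
    ranked = sorted(
        by_key.items(),
        key=lambda kv: (min(network.nodes[n].gibbs for n in kv[1]), min(kv[1])),
    )
    node_to_group, group_key, group_members, group_min = {}, {}, {}, {}
    for rank, (key, members) in enumerate(ranked, start=1):
        gid = f"G{rank}"
        group_key[gid] = key
        group_members[gid] = sorted(members)
        gmin = min(members, key=lambda n: (network.nodes[n].gibbs, n))
        group_min[gid] = (network.nodes[gmin].gibbs, gmin)
        for nid in members:
            node_to_group[nid] = gid
    return GroupAssignment(node_to_group, group_key, group_members, group_min, region)


@dataclass
class GroupNetwork:
    """Coarse network: one node per group, one edge per connected group pair.

    The group representative is its lowest-G EQ; the group-pair edge carries
    the minimum TS energy among all connecting paths, with a highlight flag
    for TSs strictly below the threshold.
    """

    groups: pd.DataFrame  # index group id: representative, min_gibbs, n_members, stereo
    edges: pd.DataFrame  # group_a, group_b, ts_gibbs, path_id, highlighted
    highlight_threshold: float

    def to_graphml(self, path: str | Path) -> None:
        g = nx.Graph()
        for gid, row in self.groups.iterrows():
            g.add_node(
                gid,
                representative=row["representative"],
                min_gibbs=float(row["min_gibbs"]),
                n_members=int(row["n_members"]),
                stereo=row["stereo"],
            )
        for _, row in self.edges.iterrows():
            g.add_edge(
                row["group_a"],
                row["group_b"],
                ts_gibbs=float(row["ts_gibbs"]),
                path_id=row["path_id"],
                highlighted=bool(row["highlighted"]),
            )
        nx.write_graphml(g, str(path))


def build_group_network(
    network: ReactionPathNetwork,
    assignment: GroupAssignment,
    highlight_threshold: float = 150.0,
) -> GroupNetwork:
    """Extract the lowest-energy inter-group routes.

    Highlighting is strict: a TS exactly at the threshold is not flagged.
    """
    rows = []
    for gid, members in assignment.group_members.items():
        g, rep = assignment.group_min[gid]
        rows.append((gid, rep, g, len(members), assignment.stereo_label(gid)))
    groups = (
        pd.DataFrame(
            rows, columns=["group", "representative", "min_gibbs", "n_members", "stereo"]
        )
        .set_index("group")
        .sort_values("min_gibbs")
    )

    best: dict[tuple[str, str], tuple[float, str]] = {}
    for e in network.edges:
        ga = assignment.node_to_group[e.eq_a]
        gb = assignment.node_to_group[e.eq_b]
        if ga == gb:
            continue
        pair = tuple(sorted((ga, gb)))
        if pair not in best or (e.ts_gibbs, e.id) < best[pair]:
            best[pair] = (e.ts_gibbs, e.id)
    edges = pd.DataFrame(
        [
            (a, b, ts, pid, ts < highlight_threshold)
            for (a, b), (ts, pid) in sorted(best.items())
        ],
        columns=["group_a", "group_b", "ts_gibbs", "path_id", "highlighted"],
    )
    return GroupNetwork(groups, edges, highlight_threshold)
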