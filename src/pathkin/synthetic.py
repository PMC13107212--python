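"""Synthetic reaction path networks and toy geometries with known ground truth.

The generator emulates the topology of a conformationally flexible
organocatalytic reaction: clusters of conformers per chemical species
(reactant, protonated reactant, a metastable carbocation-like intermediate,
off-path species, and enantiomeric S/R product wells), fully reversible
edges, and two competing product channels — a single-step ("concerted")
route straight from the reactant and a two-step ("stepwise") route through
the intermediate.  The free-energy gap between the S- and R-forming TS
ensembles is *programmed*: after random draws, all S-product-forming TS
energies are rigidly shifted so that the Boltzmann-ensemble gap
−RT·ln(Σ_S e^(−g/RT) / Σ_R e^(−g/RT)) equals ``programmed_ddg`` exactly.
In the pre-equilibrium regime the simulated enantiomer ratio must then
recover the programmed gap, which makes every downstream stage testable
without external data.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from pathlib import Path
import networkx as nx
import numpy as np

from .constants import rt_kj
from .network import NetworkNode, PathEdge, ReactionPathNetwork, Structure, write_network
from .selectivity import boltzmann_ts_ensemble_ratio, ddg_from_ratio

__all__ = [
    "GroupSpec",
    "ChannelSpec",
    "SyntheticNetworkSpec",
    "benchmark_spec",
    "generate_network",
    "generate_toy_geometries",
    "toy_grouping_set",
]

ROLES = {"reactant", "protonated-reactant", "intermediate", "product_S", "product_R", "offpath"}
MECHANISMS = {"concerted", "stepwise-leg"}


@dataclass
class GroupSpec:
    """One chemical species: a cluster of conformers around ``base_g`` kJ/mol."""

    label: str
    role: str
    base_g: float
    conformer_spread: float = 5.0

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.conformer_spread < 0:
            raise ValueError("conformer_spread must be >= 0")


@dataclass
class ChannelSpec:
    """A bundle of parallel TSs between two species.

    ``barrier_mean`` is the TS Gibbs energy on the common absolute scale
    (the reactant cluster sits near 0); individual TSs are drawn uniformly
    in [mean, mean + spread].
    """

    source: str
    target: str
    barrier_mean: float
    barrier_spread: float = 8.0
    n_ts: int = 3
    mechanism: str = "concerted"

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if self.n_ts < 1:
            raise ValueError("n_ts must be >= 1")
        if self.barrier_spread < 0:
            raise ValueError("barrier_spread must be >= 0")


@dataclass
class SyntheticNetworkSpec:
    groups: list[GroupSpec]
    channels: list[ChannelSpec]
    conformers_per_group: int = 8
    programmed_ddg: float = 11.6
    temperature: float = 333.15
    seed: int = 0
    intra_barrier: float = 15.0

    def __post_init__(self) -> None:
        if self.conformers_per_group < 1:
            raise ValueError("conformers_per_group must be >= 1")
        roles = [g.role for g in self.groups]
        if roles.count("reactant") != 1:
            raise ValueError("spec needs exactly one reactant group")
        if "product_S" not in roles or "product_R" not in roles:
            raise ValueError("spec needs at least one product_S and one product_R group")
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate group labels")
        for c in self.channels:
            for end in (c.source, c.target):
                if end not in labels:
                    raise ValueError(f"channel references unknown group {end!r}")
        g = nx.Graph()
        g.add_nodes_from(labels)
        g.add_edges_from((c.source, c.target) for c in self.channels)
        if not nx.is_connected(g):
            raise ValueError("channel topology does not connect all groups")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, doc: dict) -> "SyntheticNetworkSpec":
        doc = dict(doc)
        doc["groups"] = [GroupSpec(**g) for g in doc["groups"]]
        doc["channels"] = [ChannelSpec(**c) for c in doc["channels"]]
        return cls(**doc)


def benchmark_spec(
    programmed_ddg: float = 11.6,
    seed: int = 0,
    conformers_per_group: int = 8,
    conformer_spread: float = 5.0,
    barrier_spread: float = 8.0,
    product_base_g: float = -60.0,
    product_barrier: float = 95.0,
    intermediate_inbound_barrier: float = 70.0,
    temperature: float = 333.15,
) -> SyntheticNetworkSpec:
    """The default study conditions: a paper-like two-mechanism benchmark.

    Product wells 60 kJ/mol below the reactant make product formation
    effectively irreversible over two days at 333.15 K — even when the gap
    calibration pulls the S-forming TSs well below ``product_barrier`` —
    while conformer
    interconversion (15 kJ/mol barriers) and reactant protonation /
    carbocation formation (TSs at 60–70 kJ/mol) are fast against product
    formation (TSs near 95 kJ/mol): the Curtin–Hammett pre-equilibrium
    regime.  Raise ``product_base_g`` toward 0 to make product reversal
    competitive and break that regime.
    """
    groups = [
        GroupSpec("reactant", "reactant", 0.0, conformer_spread),
        GroupSpec("protonated", "protonated-reactant", 25.0, conformer_spread),
        GroupSpec("carbocation", "intermediate", 35.0, conformer_spread),
        GroupSpec("adduct", "offpath", 20.0, conformer_spread),
        GroupSpec("product_S", "product_S", product_base_g, conformer_spread),
        GroupSpec("product_R", "product_R", product_base_g, conformer_spread),
    ]
    channels = [
        ChannelSpec("reactant", "protonated", 60.0, barrier_spread, 3),
        ChannelSpec("protonated", "carbocation", intermediate_inbound_barrier,
                    barrier_spread, 3, "stepwise-leg"),
        ChannelSpec("carbocation", "adduct", 75.0, barrier_spread, 2),
        ChannelSpec("reactant", "product_S", product_barrier, barrier_spread, 3),
        ChannelSpec("reactant", "product_R", product_barrier, barrier_spread, 3),
        ChannelSpec("carbocation", "product_S", product_barrier, barrier_spread, 3,
                    "stepwise-leg"),
        ChannelSpec("carbocation", "product_R", product_barrier, barrier_spread, 3,
                    "stepwise-leg"),
    ]
    return SyntheticNetworkSpec(
        groups, channels, conformers_per_group, programmed_ddg, temperature, seed
    )


def generate_network(
    spec: SyntheticNetworkSpec,
) -> tuple[ReactionPathNetwork, dict]:
    """Generate a reversible network realizing the spec, plus its ground truth.

    Reproducible: the same spec (including seed) gives an identical network.
    The ground-truth record carries node/group maps, per-channel edge ids,
    the selectivity-determining TS ensembles and the expected er.
    """
    rng = np.random.default_rng(spec.seed)
    rt = rt_kj(spec.temperature)

    nodes: dict[str, NetworkNode] = {}
    group_nodes: dict[str, list[str]] = {}
    node_group: dict[str, str] = {}
    for g in spec.groups:
        ids = []
        for k in range(spec.conformers_per_group):
            nid = f"{g.label}_{k:02d}"
            gibbs = g.base_g + rng.uniform(0.0, g.conformer_spread)
            nodes[nid] = NetworkNode(float(gibbs))
            node_group[nid] = g.label
            ids.append(nid)
        group_nodes[g.label] = ids

    edges: list[PathEdge] = []
    counter = 0

    def add_edge(a: str, b: str, ts: float) -> str:
        nonlocal counter
        counter += 1
        eid = f"TS{counter:04d}"
        edges.append(PathEdge(eid, a, b, float(ts)))
        return eid

    # intra-group conformer interconversion: a ring keeps each cluster connected
    for g in spec.groups:
        ids = group_nodes[g.label]
        n = len(ids)
        pairs = [(ids[k], ids[k + 1]) for k in range(n - 1)]
        if n > 2:
            pairs.append((ids[0], ids[-1]))
        for a, b in pairs:
            ts = max(nodes[a].gibbs, nodes[b].gibbs) + spec.intra_barrier
            add_edge(a, b, ts)

    # inter-group channels
    channel_edges: dict[int, list[str]] = {}
    edge_ts: dict[str, float] = {}
    for ci, ch in enumerate(spec.channels):
        ids = []
        src, dst = group_nodes[ch.source], group_nodes[ch.target]
        for _ in range(ch.n_ts):
            a = src[int(rng.integers(len(src)))]
            b = dst[int(rng.integers(len(dst)))]
            ts = ch.barrier_mean + rng.uniform(0.0, ch.barrier_spread)
            ts = max(ts, nodes[a].gibbs + 1.0, nodes[b].gibbs + 1.0)
            eid = add_edge(a, b, ts)
            edge_ts[eid] = ts
            ids.append(eid)
        channel_edges[ci] = ids

    # calibrate the S/R TS-ensemble gap to programmed_ddg exactly
    product_role = {g.label: g.role for g in spec.groups}
    s_edges = [
        eid
        for ci, ch in enumerate(spec.channels)
        if product_role[ch.target] == "product_S"
        for eid in channel_edges[ci]
    ]
    r_edges = [
        eid
        for ci, ch in enumerate(spec.channels)
        if product_role[ch.target] == "product_R"
        for eid in channel_edges[ci]
    ]
    ts_s = [edge_ts[e] for e in s_edges]
    ts_r = [edge_ts[e] for e in r_edges]
    ratio_cur = boltzmann_ts_ensemble_ratio(ts_s, ts_r, spec.temperature)
    # lowering every S-forming TS by delta multiplies the S ensemble sum by
    # exp(delta/RT); choose delta so the realized gap equals programmed_ddg
    delta = spec.programmed_ddg - ddg_from_ratio(ratio_cur, spec.temperature)
    s_set = set(s_edges)
    edges = [
        PathEdge(e.id, e.eq_a, e.eq_b, e.ts_gibbs - delta if e.id in s_set else e.ts_gibbs)
        for e in edges
    ]
    ts_s = [g - delta for g in ts_s]

    network = ReactionPathNetwork(
        nodes,
        edges,
        spec.temperature,
        metadata={"generator": "pathkin.synthetic", "seed": spec.seed,
                  "programmed_ddg": spec.programmed_ddg},
    )
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from((e.eq_a, e.eq_b) for e in edges)
    if not nx.is_connected(g):  # pragma: no cover - guaranteed by spec check
        raise ValueError("generated network is disconnected")

    expected_ratio = math.exp(spec.programmed_ddg / rt)
    ground_truth = {
        "programmed_ddg": spec.programmed_ddg,
        "temperature": spec.temperature,
        "expected_sr_ratio": expected_ratio,
        "expected_fraction_s": 100.0 * expected_ratio / (1.0 + expected_ratio),
        "group_nodes": group_nodes,
        "node_group": node_group,
        "group_roles": product_role,
        "reactant_nodes": group_nodes[
            next(gr.label for gr in spec.groups if gr.role == "reactant")
        ],
        "product_s_groups": [gr.label for gr in spec.groups if gr.role == "product_S"],
        "product_r_groups": [gr.label for gr in spec.groups if gr.role == "product_R"],
        "channel_edges": {
            f"{ch.source}->{ch.target}": channel_edges[ci]
            for ci, ch in enumerate(spec.channels)
        },
        "channel_mechanism": {
            f"{ch.source}->{ch.target}": ch.mechanism for ch in spec.channels
        },
        "ts_energies_s": ts_s,
        "ts_energies_r": ts_r,
    }
    return network, ground_truth


def write_synthetic_network(
    spec: SyntheticNetworkSpec, out_dir: str | Path
) -> tuple[Path, Path]:
    """Generate and write the standard nodes/edges tables (exercises the loaders)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    network, _ = generate_network(spec)
    nodes_path, edges_path = out / "nodes.csv", out / "edges.csv"
    write_network(network, nodes_path, edges_path)
    return nodes_path, edges_path


# ---------------------------------------------------------------------------
# toy geometries for grouping/stereochemistry tests


_T = 1.0 / math.sqrt(3.0)
_TET = {
    "d1": np.array([_T, _T, _T]),
    "d2": np.array([_T, -_T, -_T]),
    "d3": np.array([-_T, _T, -_T]),
    "d4": np.array([-_T, -_T, _T]),
}


def _chfcl_oh(dihedral_deg: float, o_shift: float = 0.0, f_shift: float = 0.0,
              sid: str = "toy") -> Structure:
    """A 6-atom chiral scaffold: C bearing H, F, Cl and an O–H group.

    Substituent priorities at C are all distinct (Cl > O > F > H), so the
    centre is a genuine stereocenter.  ``o_shift``/``f_shift`` translate the
    O–H moiety / the F atom outward to break the corresponding bond while
    leaving everything else untouched.
    """
    d1, d2, d3, d4 = _TET["d1"], _TET["d2"], _TET["d3"], _TET["d4"]
    c = np.zeros(3)
    o = (1.43 + o_shift) * d1
    cl = 1.77 * d2
    f = (1.35 + f_shift) * d3
    h = 1.09 * d4
    # O-H with C-O-H angle 104.5 deg and a free dihedral
    xp = np.array([1.0, -1.0, 0.0]) / math.sqrt(2.0)
    yp = np.cross(d1, xp)
    phi = math.radians(dihedral_deg)
    oh_dir = 0.2504 * d1 + 0.9681 * (math.cos(phi) * xp + math.sin(phi) * yp)
    ho = o + 0.96 * oh_dir
    coords = np.array([c, h, f, cl, o, ho])
    return Structure(sid, ["C", "H", "F", "Cl", "O", "H"], coords)


def _mirror(s: Structure, sid: str) -> Structure:
    coords = s.coords.copy()
    coords[:, 2] *= -1.0
    return Structure(sid, list(s.elements), coords, role=s.role,
                     gibbs_energy=s.gibbs_energy)


def generate_toy_geometries(kind: str, seed: int = 0) -> list[Structure]:
    """Small geometries with analytically known bonds and handedness.

    kinds: ``chiral-center`` (one stereogenic molecule), ``mirror`` (the
    molecule and its z-negated enantiomer), ``conformer`` (two rotamers,
    identical bond pattern), ``bond-change`` (two geometries differing by
    exactly one broken C–O bond).  ``seed`` jitters the free dihedral only.
    """
    rng = np.random.default_rng(seed)
    base_phi = float(rng.uniform(0.0, 30.0))
    if kind == "chiral-center":
        return [_chfcl_oh(base_phi, sid="chiral")]
    if kind == "mirror":
        a = _chfcl_oh(base_phi, sid="chiral")
        return [a, _mirror(a, "chiral_mirror")]
    if kind == "conformer":
        return [
            _chfcl_oh(base_phi, sid="rotamer_a"),
            _chfcl_oh(base_phi + 120.0, sid="rotamer_b"),
        ]
    if kind == "bond-change":
        return [
            _chfcl_oh(base_phi, sid="bonded"),
            _chfcl_oh(base_phi, o_shift=2.5, sid="dissociated"),
        ]
    raise ValueError(f"unknown toy geometry kind {kind!r}")


def toy_grouping_set() -> list[Structure]:
    """Six 6-atom structures spanning exactly four groups.

    Three rotamers of the (S or R as built) scaffold merge into one group;
    the mirror image splits off; two rotamers of the C–O-dissociated form
    (achiral at C) merge; the C–F-dissociated form is its own group.
    """
    return [
        _chfcl_oh(0.0, sid="rot_a"),
        _chfcl_oh(120.0, sid="rot_b"),
        _mirror(_chfcl_oh(0.0, sid="x"), "mirror_a"),
        _chfcl_oh(0.0, o_shift=2.5, sid="ofar_a"),
        _chfcl_oh(120.0, o_shift=2.5, sid="ofar_b"),
        _chfcl_oh(0.0, f_shift=2.5, sid="ffar_a"),
    ]
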