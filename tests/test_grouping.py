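import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pathkin.grouping import (
    assign_groups,
    build_group_network,
    detect_bonds,
    region_bond_pattern,
    stereo_descriptor,
)
from pathkin.network import NetworkNode, PathEdge, ReactionPathNetwork, Structure
from pathkin.synthetic import generate_toy_geometries, toy_grouping_set


def _transformed(s, seed=0, mirror=False):
    rng = np.random.default_rng(seed)
    rot = Rotation.from_quat(rng.normal(size=4) / 2.0, scalar_first=False).as_matrix()
    coords = s.coords @ rot.T + rng.normal(size=3)
    if mirror:
        coords = coords * np.array([1.0, 1.0, -1.0])
    return Structure(s.id + "_t", list(s.elements), coords)


class TestBondPerception:
    def test_h2_bonded_at_074(self):
        s = Structure("h2", ["H", "H"], [[0, 0, 0], [0.74, 0, 0]])
        assert detect_bonds(s).bonds == ((0, 1),)

    def test_h2_unbonded_just_past_cutoff(self):
        # cutoff = 1.2 * (0.31 + 0.31) = 0.744
        s = Structure("h2", ["H", "H"], [[0, 0, 0], [0.745, 0, 0]])
        assert detect_bonds(s).bonds == ()

    def test_carbons_far_apart_not_bonded(self):
        s = Structure("cc", ["C", "C"], [[0, 0, 0], [3.0, 0, 0]])
        assert detect_bonds(s).bonds == ()

    def test_fingerprint_isometry_invariance(self):
        s = generate_toy_geometries("chiral-center")[0]
        fp = detect_bonds(s).fingerprint
        for seed in range(3):
            assert detect_bonds(_transformed(s, seed)).fingerprint == fp
        assert detect_bonds(_transformed(s, mirror=True)).fingerprint == fp

    def test_fingerprint_invariant_under_identical_atom_permutation(self):
        # methane-like: swapping two H atoms must not change the pattern
        d = 1.09 / np.sqrt(3)
        coords = np.array(
            [[0, 0, 0], [d, d, d], [d, -d, -d], [-d, d, -d], [-d, -d, d]]
        )
        s = Structure("ch4", ["C", "H", "H", "H", "H"], coords)
        perm = [0, 2, 1, 4, 3]
        sp = Structure("ch4p", ["C", "H", "H", "H", "H"], coords[perm])
        assert detect_bonds(s).fingerprint == detect_bonds(sp).fingerprint

    def test_unknown_element_and_bad_scale(self):
        with pytest.raises(ValueError):
            Structure("x", ["Uuq"], [[0, 0, 0]])
        s = Structure("h2", ["H", "H"], [[0, 0, 0], [0.74, 0, 0]])
        with pytest.raises(ValueError):
            detect_bonds(s, scale=2.5)

    def test_region_pattern_sees_bond_change(self):
        bonded, dissociated = generate_toy_geometries("bond-change")
        a = region_bond_pattern(bonded, [0, 4])
        b = region_bond_pattern(dissociated, [0, 4])
        assert a.fingerprint != b.fingerprint
        assert len(a.bonds) == len(b.bonds) + 1  # exactly the broken C-O bond


class TestStereoDescriptor:
    def test_mirror_flips_label_and_volume(self):
        a, b = generate_toy_geometries("mirror")
        da = stereo_descriptor(a, 0, detect_bonds(a))
        db = stereo_descriptor(b, 0, detect_bonds(b))
        assert {da.label, db.label} == {"R", "S"}
        assert da.signed_volume == pytest.approx(-db.signed_volume, rel=1e-12)

    def test_label_matches_signed_volume_oracle(self):
        s = generate_toy_geometries("chiral-center")[0]
        desc = stereo_descriptor(s, 0, detect_bonds(s))
        # independent oracle: priorities by atomic number Cl(17)>F(9)>O(8)>H(1)
        # at atom indices 3, 2, 4, 1; right-hand convention on the signed
        # volume of the top three viewed from opposite the lowest
        ranked = [3, 2, 4, 1]
        assert list(desc.substituents) == ranked
        v = np.array([s.coords[a] - s.coords[ranked[3]] for a in ranked[:3]])
        vol = float(np.linalg.det(v))
        assert desc.signed_volume == pytest.approx(vol, rel=1e-12)
        assert desc.label == ("R" if vol < 0 else "S")

    def test_equivalent_substituents_give_none(self):
        # CH2F2-like carbon: the two H trees tie exhaustively
        d = 1.2 / np.sqrt(3)
        coords = np.array(
            [[0, 0, 0], [d, d, d], [d, -d, -d], [-d, d, -d], [-d, -d, d]]
        )
        s = Structure("ch2f2", ["C", "H", "H", "F", "F"], coords)
        assert stereo_descriptor(s, 0, detect_bonds(s)).label == "none"

    def test_near_planar_center_gives_none(self):
        s = generate_toy_geometries("chiral-center")[0]
        desc = stereo_descriptor(s, 0, detect_bonds(s), planarity_tol=10.0)
        assert desc.label == "none"

    def test_non_tetracoordinate_center_rejected(self):
        s = Structure("h2o", ["O", "H", "H"],
                      [[0, 0, 0], [0.96, 0, 0], [-0.24, 0.93, 0]])
        with pytest.raises(ValueError):
            stereo_descriptor(s, 0, detect_bonds(s))


def _toy_network(structures):
    nodes = {s.id: NetworkNode(float(i)) for i, s in enumerate(structures)}
    ids = list(nodes)
    edges = [PathEdge(f"E{k}", ids[k], ids[k + 1], 60.0) for k in range(len(ids) - 1)]
    return ReactionPathNetwork(nodes, edges, 333.15)


class TestAssignGroups:
    def test_toy_set_partitions_into_four_groups(self):
        toys = toy_grouping_set()
        net = _toy_network(toys)
        asg = assign_groups(net, toys, region=range(6))
        assert asg.n_groups == 4
        g = asg.node_to_group
        assert g["rot_a"] == g["rot_b"]  # conformer pair merges
        assert g["ofar_a"] == g["ofar_b"]
        assert g["rot_a"] != g["mirror_a"]  # mirror pair splits
        assert g["rot_a"] != g["ofar_a"]  # bond change splits
        assert len({g["rot_a"], g["mirror_a"], g["ofar_a"], g["ffar_a"]}) == 4

    def test_group_ids_ordered_by_minimum_energy(self):
        toys = toy_grouping_set()
        net = _toy_network(toys)
        asg = assign_groups(net, toys, region=range(6))
        mins = [asg.group_min[f"G{k}"][0] for k in range(1, asg.n_groups + 1)]
        assert mins == sorted(mins)

    def test_rigid_motion_invariance_of_partition(self):
        toys = toy_grouping_set()
        net = _toy_network(toys)
        base = assign_groups(net, toys, region=range(6))
        moved = [
            Structure(s.id, list(s.elements), _transformed(s, seed=i).coords)
            for i, s in enumerate(toys)
        ]
        again = assign_groups(net, moved, region=range(6))
        assert base.node_to_group == again.node_to_group

    def test_global_mirror_swaps_r_and_s_labels(self):
        toys = toy_grouping_set()
        net = _toy_network(toys)
        base = assign_groups(net, toys, region=range(6))
        mirrored = [
            Structure(s.id, list(s.elements),
                      s.coords * np.array([1.0, 1.0, -1.0]))
            for s in toys
        ]
        flipped = assign_groups(net, mirrored, region=range(6))
        # same partition (as sets of member nodes) ...
        assert sorted(map(sorted, base.group_members.values())) == sorted(
            map(sorted, flipped.group_members.values())
        )
        # ... with R and S exchanged group-wise
        swap = {"R": "S", "S": "R", "none": "none"}
        for nid in base.node_to_group:
            _, stereo_a = base.group_key[base.node_to_group[nid]]
            _, stereo_b = flipped.group_key[flipped.node_to_group[nid]]
            assert [(c, swap[l]) for c, l in stereo_a] == list(stereo_b)

    def test_error_paths(self):
        toys = toy_grouping_set()
        net = _toy_network(toys)
        with pytest.raises(ValueError, match="region"):
            assign_groups(net, toys, region=[])
        with pytest.raises(ValueError, match="geometry"):
            assign_groups(net, toys[:-1], region=range(6))
        bad = toys[:-1] + [Structure("ffar_a", ["H", "H"],
                                     [[0, 0, 0], [0.7, 0, 0]])]
        with pytest.raises(ValueError, match="atom counts"):
            assign_groups(net, bad, region=range(6))


class TestGroupNetwork:
    def _setup(self, ts_ab=120.0, ts_ab2=90.0):
        toys = toy_grouping_set()
        nodes = {s.id: NetworkNode(g) for s, g in zip(toys, [10.0, 5.0, 7.0, 0.0, 2.0, 30.0])}
        edges = [
            PathEdge("P1", "rot_a", "mirror_a", ts_ab),
            PathEdge("P2", "rot_b", "mirror_a", ts_ab2),
            PathEdge("P3", "mirror_a", "ofar_a", 149.9),
            PathEdge("P4", "ofar_a", "ffar_a", 150.0),
            PathEdge("P5", "rot_a", "rot_b", 20.0),  # intra-group, not an edge
        ]
        net = ReactionPathNetwork(nodes, edges, 333.15)
        asg = assign_groups(net, toys, region=range(6))
        return net, asg

    def test_representative_is_group_minimum(self):
        net, asg = self._setup()
        gn = build_group_network(net, asg)
        grot = asg.node_to_group["rot_a"]
        row = gn.groups.loc[grot]
        assert row["representative"] == "rot_b" and row["min_gibbs"] == 5.0

    def test_group_pair_edge_takes_minimum_ts(self):
        net, asg = self._setup()
        gn = build_group_network(net, asg)
        pair = tuple(sorted((asg.node_to_group["rot_a"], asg.node_to_group["mirror_a"])))
        row = gn.edges[(gn.edges["group_a"] == pair[0]) & (gn.edges["group_b"] == pair[1])]
        assert row["ts_gibbs"].item() == 90.0 and row["path_id"].item() == "P2"

    def test_highlight_is_strictly_below_threshold(self):
        net, asg = self._setup()
        gn = build_group_network(net, asg, highlight_threshold=150.0)
        by_ts = gn.edges.set_index("ts_gibbs")["highlighted"]
        assert bool(by_ts[149.9]) is True
        assert bool(by_ts[150.0]) is False

    def test_edge_energy_monotone_in_underlying_ts(self):
        net1, asg = self._setup(ts_ab2=90.0)
        net2, _ = self._setup(ts_ab2=130.0)
        e1 = build_group_network(net1, asg).edges.set_index(["group_a", "group_b"])
        e2 = build_group_network(net2, asg).edges.set_index(["group_a", "group_b"])
        assert (e2["ts_gibbs"] >= e1["ts_gibbs"]).all()

    def test_graphml_export(self, tmp_path):
        net, asg = self._setup()
        gn = build_group_network(net, asg)
        out = tmp_path / "gn.graphml"
        gn.to_graphml(out)
        import networkx as nx

        g = nx.read_graphml(out)
        assert g.number_of_nodes() == asg.n_groups
        assert g.number_of_edges() == len(gn.edges)
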