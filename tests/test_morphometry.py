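"""Skeleton geometry: lengths, geodesics, branch counts, varicosity detection."""

import numpy as np
import networkx as nx
import pytest
from hypothesis import given, strategies as st

from axonstat import morphometry as mm
from axonstat import synthetic
from axonstat.types import AxonRecord, Skeleton, SkeletonNode, ValidationError, VoxelScale
from conftest import make_chain, random_tree


def nx_graph(skeleton):
    g = nx.Graph()
    for a, b in skeleton.edges:
        g.add_edge(a, b, weight=skeleton.edge_length_nm(a, b))
    g.add_nodes_from(skeleton.nodes)
    return g


class TestCableLength:
    def test_chain_of_six_nodes(self):
        skel = make_chain([(i * 100.0, 0, 0) for i in range(6)])
        assert mm.cable_length(skel) == pytest.approx(0.5)

    def test_single_node_is_zero(self):
        skel = Skeleton([SkeletonNode(1, 0, 0, 0)], [], VoxelScale(1, 1, 1))
        assert mm.cable_length(skel) == 0.0

    def test_empty_skeleton_errors(self):
        skel = Skeleton([], [], VoxelScale(1, 1, 1))
        with pytest.raises(ValidationError):
            mm.cable_length(skel)

    @given(seed=st.integers(0, 5000))
    def test_equals_per_edge_summation(self, seed):
        rng = np.random.default_rng(seed)
        skel = random_tree(rng, int(rng.integers(2, 50)))
        brute = sum(
            np.linalg.norm(
                skel.nodes[a].position_nm(skel.scale) - skel.nodes[b].position_nm(skel.scale)
            )
            for a, b in skel.edges
        )
        assert mm.cable_length(skel) == pytest.approx(brute / 1000.0)


class TestGeodesic:
    def test_same_node_is_zero(self):
        skel = make_chain([(0, 0, 0), (100, 0, 0)])
        assert mm.geodesic_distance(skel, 1, 1) == 0.0

    def test_path_additivity_across_branch(self):
        # chain A(1)-B(2)-C(3) with branch B-D(4), unit spacing
        skel = Skeleton(
            [
                SkeletonNode(1, 0, 0, 0),
                SkeletonNode(2, 1, 0, 0),
                SkeletonNode(3, 2, 0, 0),
                SkeletonNode(4, 1, 1, 0),
            ],
            [(1, 2), (2, 3), (2, 4)],
            VoxelScale(1, 1, 1),
        )
        assert mm.geodesic_distance(skel, 3, 4) == pytest.approx(2.0)

    def test_unknown_node_errors(self):
        skel = make_chain([(0, 0, 0), (100, 0, 0)])
        with pytest.raises(ValidationError):
            mm.geodesic_distance(skel, 1, 99)

    @given(seed=st.integers(0, 5000))
    def test_matches_weighted_shortest_path(self, seed):
        rng = np.random.default_rng(seed)
        skel = random_tree(rng, int(rng.integers(2, 50)))
        g = nx_graph(skel)
        ids = list(skel.nodes)
        for _ in range(5):
            a, b = rng.choice(ids, 2)
            expect = nx.shortest_path_length(g, int(a), int(b), weight="weight")
            assert mm.geodesic_distance(skel, int(a), int(b)) == pytest.approx(expect)


class TestCountBranches:
    @pytest.mark.parametrize(
        "edges,expected",
        [
            ([(1, 2), (2, 3), (3, 4)], 0),                    # chain
            ([(1, 2), (2, 3), (2, 4)], 1),                    # Y
            ([(1, 2), (2, 3), (2, 4), (2, 5)], 2),            # degree-4 node
            ([(1, 2), (2, 3), (2, 4), (4, 5), (4, 6)], 2),    # two degree-3 nodes
        ],
    )
    def test_degree_formula(self, edges, expected):
        n = max(max(e) for e in edges)
        skel = Skeleton(
            [SkeletonNode(i, float(i), 0, 0) for i in range(1, n + 1)],
            edges,
            VoxelScale(1, 1, 1),
        )
        assert mm.count_branches(skel) == expected


class TestDetectVaricosities:
    def profile(self, diams, spacing_nm=250.0):
        skel = make_chain(
            [(i * spacing_nm, 0, 0) for i in range(len(diams))],
            radii=[d / 2 for d in diams],
        )
        (prof,) = mm.path_profiles(skel)
        return prof

    def test_constant_profile_has_none(self):
        prof = self.profile([100.0] * 30)
        assert mm.detect_varicosities(prof) == []

    def test_single_plateau(self):
        diams = [100.0] * 10 + [300.0] * 3 + [100.0] * 10
        prof = self.profile(diams)
        hits = mm.detect_varicosities(prof, fold=2.0)
        assert len(hits) == 1
        assert hits[0][1] == 300.0

    def test_two_bumps_apart_are_separate(self):
        diams = [100.0] * 10 + [300.0] + [100.0] * 20 + [300.0] + [100.0] * 10
        prof = self.profile(diams)  # bumps ~5.25 µm apart
        assert len(mm.detect_varicosities(prof, min_separation_um=1.0)) == 2

    def test_close_bumps_merge(self):
        diams = [100.0] * 10 + [300.0, 100.0, 300.0] + [100.0] * 10
        prof = self.profile(diams)  # bumps 0.5 µm apart
        assert len(mm.detect_varicosities(prof, min_separation_um=1.0)) == 1

    def test_short_profile_warns_and_is_empty(self):
        prof = self.profile([100.0, 300.0])
        with pytest.warns(UserWarning):
            assert mm.detect_varicosities(prof) == []

    def test_recall_precision_on_synthetic_axons(self):
        """Fold-3 planted bumps are recovered by the fold-2 detector."""
        params = synthetic.study_defaults("saline")
        tp = fp = fn = 0
        for seed in range(8):
            rec, truth = synthetic.generate_axon(params, seed=seed)
            detected = {nid for nid, _ in mm.detect_varicosities_skeleton(rec.skeleton)}
            planted = set(truth.varicosity_node_ids)
            tp += len(detected & planted)
            fp += len(detected - planted)
            fn += len(planted - detected)
        assert tp / (tp + fn) >= 0.95
        assert tp / (tp + fp) >= 0.95


class TestMitoLength:
    def test_two_nodes(self):
        skel = make_chain([(0, 0, 0), (360.0, 0, 0)])
        assert mm.mito_length(skel, [1, 2]) == pytest.approx(0.36)

    def test_coiled_chain_equals_consecutive_sum(self):
        rng = np.random.default_rng(4)
        pts = np.cumsum(rng.normal(0, 100, (10, 3)), axis=0)
        skel = make_chain(pts)
        brute = sum(np.linalg.norm(pts[i + 1] - pts[i]) for i in range(9)) / 1000
        assert mm.mito_length(skel, list(range(1, 11))) == pytest.approx(brute)

    def test_duplicate_node_errors(self):
        skel = make_chain([(0, 0, 0), (100, 0, 0)])
        with pytest.raises(ValidationError, match="duplicate"):
            mm.mito_length(skel, [1, 2, 1])

    def test_short_chain_warns(self):
        skel = make_chain([(0, 0, 0), (100, 0, 0)])
        with pytest.warns(UserWarning):
            assert mm.mito_length(skel, [1]) == 0.0


class TestDendriteDiameter:
    def test_equal_chords(self):
        assert mm.dendrite_diameter((300.0, 300.0, 300.0)) == 300.0

    def test_mean(self):
        assert mm.dendrite_diameter((200.0, 300.0, 400.0)) == 300.0

    @given(st.permutations([211.0, 305.5, 417.0]))
    def test_permutation_invariant(self, chords):
        assert mm.dendrite_diameter(tuple(chords)) == pytest.approx(311.1666666667)

    def test_nonpositive_chord_errors(self):
        with pytest.raises(ValidationError):
            mm.dendrite_diameter((0.0, 300.0, 400.0))


class TestLinearDensity:
    def test_examples(self):
        assert mm.linear_density(4, 100.0) == pytest.approx(0.04)
        assert mm.linear_density(0, 50.0) == 0.0
        assert mm.linear_density(8, 200.0) == mm.linear_density(4, 100.0)

    def test_zero_length_errors(self):
        with pytest.raises(ValidationError):
            mm.linear_density(1, 0.0)


class TestIntervaricosityDistances:
    def axon_with_varics(self, positions_um, extra_edges=()):
        from axonstat.types import VaricosityRecord

        skel = make_chain([(p * 1000.0, 0, 0) for p in positions_um])
        rec = AxonRecord(skeleton=skel, axon_id="a")
        for i in range(len(positions_um)):
            rec.varicosities.append(
                VaricosityRecord(axon_id="a", index=i, node_id=i + 1)
            )
        return rec

    def test_chain_consecutive(self):
        rec = self.axon_with_varics([0.0, 2.0, 5.0])
        assert mm.intervaricosity_distances(rec) == pytest.approx([2000.0, 3000.0])

    def test_all_pairs_flag(self):
        rec = self.axon_with_varics([0.0, 2.0, 5.0])
        assert sorted(mm.intervaricosity_distances(rec, all_pairs=True)) == pytest.approx(
            [2000.0, 3000.0, 5000.0]
        )

    def test_single_varicosity_empty(self):
        rec = self.axon_with_varics([0.0])
        assert mm.intervaricosity_distances(rec) == []

    def test_straddling_a_branch_point_is_path_additive(self):
        from axonstat.types import VaricosityRecord

        skel = Skeleton(
            [
                SkeletonNode(1, 0, 0, 0),
                SkeletonNode(2, 1000.0, 0, 0),
                SkeletonNode(3, 2000.0, 0, 0),
                SkeletonNode(4, 1000.0, 1500.0, 0),
            ],
            [(1, 2), (2, 3), (2, 4)],
            VoxelScale(1, 1, 1),
        )
        rec = AxonRecord(skeleton=skel, axon_id="a")
        rec.varicosities = [
            VaricosityRecord("a", 0, node_id=3),
            VaricosityRecord("a", 1, node_id=4),
        ]
        assert mm.intervaricosity_distances(rec) == pytest.approx([2500.0])


class TestScaleCovariance:
    def test_doubling_scale_doubles_nm_outputs(self):
        rng = np.random.default_rng(9)
        skel1 = random_tree(rng, 30, scale=VoxelScale(10, 10, 20))
        skel2 = Skeleton(skel1.nodes.values(), skel1.edges, VoxelScale(20, 20, 40))
        assert mm.cable_length(skel2) == pytest.approx(2 * mm.cable_length(skel1))
        ids = list(skel1.nodes)
        assert mm.geodesic_distance(skel2, ids[0], ids[-1]) == pytest.approx(
            2 * mm.geodesic_distance(skel1, ids[0], ids[-1])
        )
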