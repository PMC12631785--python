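import numpy as np
import pytest

from conftest import _fresh_helix_chain, random_rotation, transform_chain
from mpbind.graph_features import (
    EDGE_FEATURE_DIM,
    GEOMETRIC_PAIRS,
    VIRTUAL_ATOM_ORDER,
    FeaturizationError,
    NodeFeatureConfig,
    StubEmbedder,
    assemble_edge_features,
    assemble_node_features,
    assign_secondary_structure,
    atomic_residue_features,
    build_graph,
    compute_frames,
    dssp_features,
    edge_directions,
    edge_distances,
    edge_orientation,
    featurize_chain,
    geometric_residue_features,
    load_graph,
    local_frame,
    positional_embedding,
    quaternion_to_rotation,
    rbf_encode,
    save_graph,
)
from mpbind.structure_io import Atom, Chain, Residue, compute_virtual_atoms


def _ca_chain(positions):
    residues = []
    for i, p in enumerate(positions):
        residues.append(Residue("GLY", "G", str(i + 1), i,
                                atoms=[Atom("CA", "C", p)]))
    return Chain("A", residues)


class TestBuildGraph:
    def test_boundary_inclusive(self):
        g = build_graph(_ca_chain([(0, 0, 0), (14.9, 0, 0)]))
        assert g.num_edges == 2
        g = build_graph(_ca_chain([(0, 0, 0), (15.1, 0, 0)]))
        assert g.num_edges == 0

    def test_straight_chain_neighbor_offsets(self):
        g = build_graph(_ca_chain([(3.8 * i, 0, 0) for i in range(10)]))
        offsets = {abs(int(i) - int(j)) for i, j in g.edges}
        assert offsets == {1, 2, 3}  # 3*3.8 = 11.4 <= 15 < 4*3.8

    def test_random_cloud_matches_bruteforce(self):
        rng = np.random.default_rng(0)
        pos = rng.uniform(0, 40, (50, 3))
        g = build_graph(_ca_chain(pos))
        brute = {
            (i, j)
            for i in range(50) for j in range(50)
            if i != j and np.linalg.norm(pos[i] - pos[j]) <= 15.0
        }
        assert {(int(i), int(j)) for i, j in g.edges} == brute

    def test_missing_ca_errors(self):
        chain = _ca_chain([(0, 0, 0)])
        chain.residues.append(Residue("GLY", "G", "2", 1,
                                      atoms=[Atom("N", "N", (1, 0, 0))]))
        with pytest.raises(FeaturizationError, match="2"):
            build_graph(chain)

    def test_no_self_edges_and_symmetric(self, featurized_graph):
        featurized_graph.validate()


class TestDSSP:
    def test_one_hot_rows_sum_to_one(self, helix_chain):
        f = dssp_features(helix_chain)
        np.testing.assert_allclose(f[:, :8].sum(axis=1), 1.0)
        assert f.shape == (len(helix_chain), 9)

    def test_ideal_helix_interior_is_H(self, helix_chain):
        ss = assign_secondary_structure(helix_chain)
        assert all(s == "H" for s in ss[2:-2])

    def test_extended_chain_has_no_H(self):
        chain = _fresh_helix_chain(20, geometry="extended")
        ss = assign_secondary_structure(chain)
        assert "H" not in ss

    def test_short_chain_all_coil(self):
        chain = _fresh_helix_chain(3)
        assert assign_secondary_structure(chain) == ["-", "-", "-"]

    def test_rsa_in_unit_interval(self, helix_chain):
        f = dssp_features(helix_chain)
        assert np.all(f[:, 8] >= 0) and np.all(f[:, 8] <= 1)

    def test_external_dssp_ingestion(self, helix_chain):
        external = [("E", 0.5)] * len(helix_chain)
        f = dssp_features(helix_chain, external=external)
        assert np.all(f[:, 2] == 1.0)
        np.testing.assert_allclose(f[:, 8], 0.5)


class TestGeometricResidueFeatures:
    def test_dimension(self, helix_chain):
        v = geometric_residue_features(helix_chain.residues[5])
        assert v.shape == (160,)

    def test_rigid_invariance(self, helix_chain):
        rng = np.random.default_rng(3)
        rot, trans = random_rotation(rng), rng.uniform(-30, 30, 3)
        moved = transform_chain(helix_chain, rot, trans)
        for i in (0, 7, 19):
            v0 = geometric_residue_features(helix_chain.residues[i])
            v1 = geometric_residue_features(moved.residues[i])
            np.testing.assert_allclose(v0, v1, atol=1e-6)

    def test_rbf_center_value_is_one(self):
        centers = np.linspace(0, 20, 16)
        enc = rbf_encode(np.array([centers[4]]))
        assert enc[0, 4] == pytest.approx(1.0)
        assert enc[0, 4] == enc.max()

    def test_closed_form_oracle(self, helix_chain):
        res = helix_chain.residues[9]
        va = res.virtual_atoms
        centers = np.linspace(0, 20, 16)
        sigma = centers[1] - centers[0]
        expected = []
        for a, b in GEOMETRIC_PAIRS:
            d = np.linalg.norm(va[a] - va[b])
            expected.extend(np.exp(-((d - centers) ** 2) / (2 * sigma ** 2)))
        np.testing.assert_allclose(
            geometric_residue_features(res), expected, atol=1e-12
        )

    def test_missing_virtual_atoms_errors(self):
        r = Residue("ALA", "A", "1", 0, atoms=[Atom("CA", "C", (0, 0, 0))])
        compute_virtual_atoms(r)
        with pytest.raises(FeaturizationError):
            geometric_residue_features(r)


class TestAtomicResidueFeatures:
    def _gly_with_oxt(self):
        return Residue("GLY", "G", "1", 0, atoms=[
            Atom("N", "N", (0, 0, 0)), Atom("CA", "C", (1.5, 0, 0)),
            Atom("C", "C", (2, 1.4, 0)), Atom("O", "O", (3, 1.5, 0)),
            Atom("OXT", "O", (1.6, 2.4, 0)),
        ])

    def test_gly_carbon_fraction(self):
        # 5 heavy atoms (N, CA, C, O, OXT), 2 carbons -> mean one-hot C = 2/5
        v = atomic_residue_features(self._gly_with_oxt())
        assert v.shape == (30,)
        assert v[0] == pytest.approx(2 / 5)

    def test_mean_pool_permutation_invariant(self):
        r = self._gly_with_oxt()
        v0 = atomic_residue_features(r)
        r.atoms = r.atoms[::-1]
        v1 = atomic_residue_features(r)
        np.testing.assert_allclose(v0, v1, atol=1e-12)

    def test_sum_pool_doubles_when_atoms_duplicated(self):
        r = self._gly_with_oxt()
        v0 = atomic_residue_features(r)
        r.atoms = r.atoms + [Atom(a.name, a.element, a.coords) for a in r.atoms]
        v1 = atomic_residue_features(r)
        np.testing.assert_allclose(v1[15:], 2 * v0[15:], atol=1e-12)
        np.testing.assert_allclose(v1[:15], v0[:15], atol=1e-12)

    def test_no_heavy_atoms_errors(self):
        r = Residue("GLY", "G", "1", 0, atoms=[Atom("H", "H", (0, 0, 0))])
        with pytest.raises(FeaturizationError):
            atomic_residue_features(r)


class TestStubEmbedder:
    def test_deterministic(self):
        e = StubEmbedder("prottrans")
        m1, m2 = e.embed("ACDEFG"), e.embed("ACDEFG")
        np.testing.assert_array_equal(m1, m2)

    def test_dim_is_1024(self):
        assert StubEmbedder("x").embed("AA").shape == (2, 1024)

    def test_locality_of_single_mutation(self):
        e = StubEmbedder("prottrans", window=2)
        seq1 = "AAAAAAAAAA"
        seq2 = "AAAAACAAAA"  # change at position 5
        m1, m2 = e.embed(seq1), e.embed(seq2)
        changed = [i for i in range(10) if not np.array_equal(m1[i], m2[i])]
        assert changed == [3, 4, 5, 6, 7]

    def test_providers_differ(self):
        m1 = StubEmbedder("prottrans").embed("ACD")
        m2 = StubEmbedder("prostt5_aa").embed("ACD")
        assert not np.array_equal(m1, m2)


class TestAssembleNodeFeatures:
    def test_default_width_2247(self, featurized_graph):
        assert featurized_graph.node_features.shape[1] == 2247

    def test_without_prostt5_width_1223(self, helix_chain):
        cfg = NodeFeatureConfig().without("prostt5_aa")
        assert cfg.total == 1223
        providers = {"prottrans": StubEmbedder("prottrans")}
        feats = assemble_node_features(helix_chain, cfg, providers)
        assert feats.shape == (len(helix_chain), 1223)

    def test_first_block_is_provider_output(self, helix_chain):
        from mpbind.structure_io import extract_sequence

        provider = StubEmbedder("prottrans")
        cfg = NodeFeatureConfig()
        feats = assemble_node_features(
            helix_chain, cfg,
            {"prottrans": provider, "prostt5_aa": StubEmbedder("prostt5_aa")},
        )
        np.testing.assert_array_equal(
            feats[:, :1024], provider.embed(extract_sequence(helix_chain))
        )

    def test_pure_function_bit_identical(self, helix_chain):
        providers = {"prottrans": StubEmbedder("prottrans"),
                     "prostt5_aa": StubEmbedder("prostt5_aa")}
        cfg = NodeFeatureConfig()
        f1 = assemble_node_features(helix_chain, cfg, providers)
        f2 = assemble_node_features(helix_chain, cfg, providers)
        np.testing.assert_array_equal(f1, f2)

    def test_missing_provider_errors(self, helix_chain):
        with pytest.raises(FeaturizationError):
            assemble_node_features(helix_chain, NodeFeatureConfig(), {})


class TestEdgeOrientation:
    def test_identity(self, helix_chain):
        f = local_frame(helix_chain.residues[3])
        np.testing.assert_allclose(edge_orientation(f, f), (1, 0, 0, 0), atol=1e-9)

    def test_90_degrees_about_z(self):
        from mpbind.graph_features import LocalFrame

        b1 = np.eye(3)
        c, s = 0.0, 1.0
        b2 = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        f1 = LocalFrame(origin=np.zeros(3), basis=b1)
        f2 = LocalFrame(origin=np.zeros(3), basis=b2)
        q = edge_orientation(f1, f2)
        np.testing.assert_allclose(q, (np.sqrt(2) / 2, 0, 0, np.sqrt(2) / 2),
                                   atol=1e-12)

    def test_roundtrip_oracle(self, helix_chain):
        frames = compute_frames(helix_chain)
        for i, j in ((0, 5), (3, 12), (19, 1)):
            q = edge_orientation(frames[i], frames[j])
            rel = frames[i].basis.T @ frames[j].basis
            np.testing.assert_allclose(quaternion_to_rotation(q), rel, atol=1e-9)
            assert q[0] >= 0

    def test_non_orthonormal_rejected(self):
        from mpbind.graph_features import LocalFrame

        bad = LocalFrame(origin=np.zeros(3), basis=np.ones((3, 3)))
        with pytest.raises(FeaturizationError):
            bad.validate()


class TestEdgeDirections:
    def test_unit_norms(self, helix_chain):
        frames = compute_frames(helix_chain)
        v = edge_directions(helix_chain.residues[2], helix_chain.residues[8],
                            frames[2], frames[8])
        for k in range(10):
            n = np.linalg.norm(v[3 * k:3 * k + 3])
            assert n == pytest.approx(1.0, abs=1e-9) or n == 0.0

    def test_rigid_invariance(self, helix_chain):
        rng = np.random.default_rng(5)
        rot, trans = random_rotation(rng), rng.uniform(-30, 30, 3)
        moved = transform_chain(helix_chain, rot, trans)
        f0, f1 = compute_frames(helix_chain), compute_frames(moved)
        v0 = edge_directions(helix_chain.residues[2], helix_chain.residues[8],
                             f0[2], f0[8])
        v1 = edge_directions(moved.residues[2], moved.residues[8], f1[2], f1[8])
        np.testing.assert_allclose(v0, v1, atol=1e-6)

    def test_hand_computed_fixture(self, helix_chain):
        # independent recomputation from the definition
        frames = compute_frames(helix_chain)
        i, j = 4, 9
        res_j = helix_chain.residues[j]
        v = edge_directions(helix_chain.residues[i], res_j, frames[i], frames[j])
        for k, name in enumerate(VIRTUAL_ATOM_ORDER):
            u = res_j.virtual_atoms[name] - frames[i].origin
            u = u / np.linalg.norm(u)
            expected = frames[i].basis.T @ u
            np.testing.assert_allclose(v[3 * k:3 * k + 3], expected, atol=1e-12)


class TestEdgeDistances:
    def test_superposed_residues(self, helix_chain):
        r = helix_chain.residues[3]
        v = edge_distances(r, r)
        assert v.shape == (400,)
        enc = v.reshape(25, 16)
        # distances 0 except cross pairs of distinct virtual atoms; the
        # diagonal pairs (same atom both sides) have d=0 -> first RBF maximal
        for k, (a, b) in enumerate(
            (a, b) for a in VIRTUAL_ATOM_ORDER for b in VIRTUAL_ATOM_ORDER
        ):
            if a == b:
                assert enc[k, 0] == pytest.approx(1.0)

    def test_rigid_invariance(self, helix_chain):
        rng = np.random.default_rng(6)
        rot, trans = random_rotation(rng), rng.uniform(-30, 30, 3)
        moved = transform_chain(helix_chain, rot, trans)
        v0 = edge_distances(helix_chain.residues[1], helix_chain.residues[6])
        v1 = edge_distances(moved.residues[1], moved.residues[6])
        np.testing.assert_allclose(v0, v1, atol=1e-6)

    def test_closed_form_oracle(self, helix_chain):
        ri, rj = helix_chain.residues[2], helix_chain.residues[11]
        centers = np.linspace(0, 20, 16)
        sigma = centers[1] - centers[0]
        expected = []
        for a in VIRTUAL_ATOM_ORDER:
            for b in VIRTUAL_ATOM_ORDER:
                d = np.linalg.norm(ri.virtual_atoms[a] - rj.virtual_atoms[b])
                expected.extend(np.exp(-((d - centers) ** 2) / (2 * sigma ** 2)))
        np.testing.assert_allclose(edge_distances(ri, rj), expected, atol=1e-12)


class TestPositionalEmbedding:
    def test_offset_zero(self):
        v = positional_embedding(5, 5)
        np.testing.assert_allclose(v[:8], 0.0)
        np.testing.assert_allclose(v[8:], 1.0)

    def test_parity(self):
        vp, vm = positional_embedding(0, 7), positional_embedding(7, 0)
        np.testing.assert_allclose(vp[8:], vm[8:], atol=1e-12)
        np.testing.assert_allclose(vp[:8], -vm[:8], atol=1e-12)

    def test_closed_form(self):
        d = 13
        v = positional_embedding(0, d)
        for k in range(8):
            angle = d / (10000.0 ** (2 * k / 16))
            assert v[k] == pytest.approx(np.sin(angle), abs=1e-12)
            assert v[8 + k] == pytest.approx(np.cos(angle), abs=1e-12)


class TestAssembleEdgeFeatures:
    def test_width_450(self, featurized_graph):
        assert featurized_graph.edge_features.shape[1] == 450

    def test_block_arithmetic(self):
        assert 400 + 30 + 4 + 16 == EDGE_FEATURE_DIM == 450

    def test_rigid_invariance_full_graph(self, helix_chain):
        g0 = featurize_chain(helix_chain)
        rng = np.random.default_rng(8)
        rot, trans = random_rotation(rng), rng.uniform(-30, 30, 3)
        g1 = featurize_chain(transform_chain(helix_chain, rot, trans))
        np.testing.assert_allclose(g0.edge_features, g1.edge_features, atol=1e-5)
        np.testing.assert_allclose(g0.node_features, g1.node_features, atol=1e-5)

    def test_edge_reversal_swaps_direction_blocks(self, helix_chain):
        frames = compute_frames(helix_chain)
        edges = np.array([[2, 9], [9, 2]])
        feats = assemble_edge_features(edges, helix_chain, frames)
        fwd, bwd = feats[0], feats[1]
        # distance block: reversal transposes the 5x5 pair grid
        d_f = fwd[:400].reshape(25, 16).reshape(5, 5, 16)
        d_b = bwd[:400].reshape(25, 16).reshape(5, 5, 16)
        np.testing.assert_allclose(d_f, np.swapaxes(d_b, 0, 1), atol=1e-12)
        # direction block halves swap
        np.testing.assert_allclose(fwd[400:415], bwd[415:430], atol=1e-12)
        np.testing.assert_allclose(fwd[415:430], bwd[400:415], atol=1e-12)
        # orientation quaternion conjugates (vector part negates up to sign)
        q_f, q_b = fwd[430:434], bwd[430:434]
        conj = np.array([q_f[0], -q_f[1], -q_f[2], -q_f[3]])
        if conj[0] < 0:
            conj = -conj
        np.testing.assert_allclose(q_b, conj, atol=1e-9)


class TestGraphSerialization:
    def test_save_load_roundtrip(self, tmp_path, featurized_graph):
        p = tmp_path / "graph.npz"
        save_graph(featurized_graph, p)
        g = load_graph(p)
        np.testing.assert_array_equal(g.edges, featurized_graph.edges)
        np.testing.assert_array_equal(g.node_features, featurized_graph.node_features)
        np.testing.assert_array_equal(g.edge_features, featurized_graph.edge_features)
        assert g.manifest["node_total"] == 2247
        assert g.manifest["edge_total"] == 450
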