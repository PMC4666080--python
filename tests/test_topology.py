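"""Secondary-structure parsing and elastic-network construction rules."""

import numpy as np
import pytest

import rnabd as rb
from rnabd.topology import (GeometryInconsistencyError, Helix,
                            InvalidTopologyError, ParseError,
                            SecondaryStructure, Spring,
                            UnsupportedFeatureError)


class TestParseDotBracket:
    def test_simple_hairpin(self):
        ss = rb.parse_dot_bracket("((((....))))")
        assert ss.n_residues == 12
        assert ss.n_helices == 1
        assert ss.helices[0].n_bp == 4
        assert ss.loops() == [(4, 7)]

    def test_unpaired_only(self):
        ss = rb.parse_dot_bracket("....")
        assert ss.n_helices == 0
        assert ss.loops() == [(0, 3)]

    def test_internal_loop_splits_helices(self):
        ss = rb.parse_dot_bracket("((..((...))..))")
        assert [h.n_bp for h in ss.helices] == [2, 2]
        kinds = {tuple(f["beads"]): f["kind"] for f in ss.loop_faces() if f["beads"]}
        assert kinds[(6, 7, 8)] == "hairpin"
        # both unpaired runs between the two helices form one internal face
        assert kinds[(2, 3, 11, 12)] == "internal"

    @pytest.mark.parametrize("bad", ["(((", "..)..", "(a)"])
    def test_malformed_input_rejected(self, bad):
        with pytest.raises(ParseError):
            rb.parse_dot_bracket(bad)

    def test_pseudoknot_rejected(self):
        with pytest.raises(UnsupportedFeatureError):
            rb.parse_dot_bracket("((..[[..))..]]")

    def test_pairing_involution_roundtrip(self):
        text = "((((....))))..((...))"
        ss = rb.parse_dot_bracket(text)
        pt = ss.pair_table()
        paired = pt >= 0
        assert np.array_equal(pt[pt[paired]], np.flatnonzero(paired))
        assert rb.parse_dot_bracket(ss.to_dot_bracket()).pair_table().tolist() \
            == pt.tolist()


def brute_force_duplex_pairs(n_bp):
    """Independent enumeration of the five helix connectivity rules for an
    isolated duplex (local indexing: 0..n-1 strand A, n..2n-1 partners)."""
    pairs = set()
    for k in range(n_bp):
        for dk in (1, 2, 3):  # rules a-c in both pieces
            if k + dk < n_bp:
                pairs.add((k, k + dk))
                pairs.add((n_bp + k, n_bp + k + dk))
        pairs.add((k, k + n_bp))  # rule d
        for dk in (-1, 1):        # rule e
            if 0 <= k + dk < n_bp:
                pairs.add(tuple(sorted((k, n_bp + k + dk))))
    return pairs


class TestSpringNetwork:
    @pytest.mark.parametrize("n_bp", [3, 4, 5, 6, 8])
    def test_isolated_duplex_count_matches_brute_force(self, n_bp):
        ss = SecondaryStructure(2 * n_bp, [Helix(1, n_bp, n_bp + 1, 2 * n_bp)])
        net = rb.build_spring_network(ss)
        assert len(net.springs) == len(brute_force_duplex_pairs(n_bp))
        assert len(net.springs) == 9 * n_bp - 14

    def test_duplex_pairs_match_rule_enumeration(self):
        n_bp = 5
        ss = SecondaryStructure(2 * n_bp, [Helix(1, n_bp, n_bp + 1, 2 * n_bp)])
        net = rb.build_spring_network(ss)
        # strand indices: A piece is 0..4; B piece residues 5..9 run
        # antiparallel, so local partner index n+k = strand 2n-1-k
        remap = {(i, j): tuple(sorted((
            i if i < n_bp else 3 * n_bp - 1 - i,
            j if j < n_bp else 3 * n_bp - 1 - j)))
            for i, j in brute_force_duplex_pairs(n_bp)}
        assert net.pair_set() == set(remap.values())

    def test_unpaired_chain_is_backbone_only(self):
        ss = rb.parse_dot_bracket("......")
        net = rb.build_spring_network(ss)
        assert net.pair_set() == {(k, k + 1) for k in range(5)}
        assert all(s.kind == "backbone" for s in net.springs)

    def test_strand_connectivity_and_single_component(self, trna):
        ss, _, ff, _ = trna
        net = ff.network
        pairs = net.pair_set()
        for k in range(ss.n_residues - 1):
            assert (k, k + 1) in pairs
        assert net.is_connected()
        touched = {i for s in net.springs for i in (s.i, s.j)}
        assert touched == set(range(ss.n_residues))

    def test_junction_stiffening_adds_hinge_springs_only(self):
        ss, _ = rb.load_fixture("trna_phe")
        stiff = rb.build_spring_network(ss, junction_stiffening=True)
        loose = rb.build_spring_network(ss, junction_stiffening=False)
        extra = stiff.pair_set() - loose.pair_set()
        hinge = {b for f in ss.loop_faces()
                 if f["kind"] in ("multiloop", "exterior") for b in f["beads"]}
        hairpin = {b for f in ss.loop_faces()
                   if f["kind"] == "hairpin" for b in f["beads"]}
        assert extra and all(i in hinge or j in hinge for i, j in extra)
        assert all(i not in hairpin and j not in hairpin for i, j in extra)

    def test_self_spring_rejected(self):
        with pytest.raises(InvalidTopologyError):
            Spring(3, 3, "backbone")

    def test_zero_bp_helix_rejected(self):
        with pytest.raises(InvalidTopologyError):
            Helix(5, 4, 8, 9)


class TestEquilibriumLengths:
    def test_helix_backbone_rest_length_is_a_form_chord(self, params):
        n_bp = 6
        ss = SecondaryStructure(2 * n_bp, [Helix(1, n_bp, n_bp + 1, 2 * n_bp)])
        net = rb.build_spring_network(ss)
        conf = rb.assemble_initial_conformation(ss, seed=0)
        net = rb.assign_equilibrium_lengths(net, conf.coords)
        bb = [s.l_e for s in net.springs if s.kind == "backbone"]
        assert np.allclose(bb, params.backbone_chord, atol=1e-6)
        assert abs(params.backbone_chord - 6.29) < 0.005
        assert abs(params.backbone_chord - params.l_e1) / params.l_e1 < 0.005

    def test_loop_backbone_rest_length_is_touching_beads(self, params):
        ss = rb.parse_dot_bracket("((((....))))")
        net = rb.build_spring_network(ss)
        conf = rb.assemble_initial_conformation(ss, seed=0)
        net = rb.assign_equilibrium_lengths(net, conf.coords)
        loop_bb = [s.l_e for s in net.springs
                   if s.kind == "backbone" and 4 <= s.i and s.j <= 7]
        assert np.allclose(loop_bb, params.l_e1, atol=1e-6)

    def test_inconsistent_reference_rejected(self, params):
        ss = rb.parse_dot_bracket("....")
        net = rb.build_spring_network(ss)
        bad = np.zeros((4, 3))
        bad[:, 0] = [0, 100, 200, 300]  # 100 A bonds > 5 l_e1
        with pytest.raises(GeometryInconsistencyError):
            rb.assign_equilibrium_lengths(net, bad)


def random_nested_structure(rng, n=40):
    """Random pseudoknot-free dot-bracket with hairpin loops >= 3 nt."""
    chars = ["."] * n
    spans = [(0, n - 1)]
    for _ in range(rng.integers(1, 6)):
        lo, hi = spans[rng.integers(len(spans))]
        if hi - lo < 9:
            continue
        a = int(rng.integers(lo, hi - 8))
        b = int(rng.integers(a + 8, hi + 1))
        if any(chars[k] != "." for k in (a, a + 1, b - 1, b)):
            continue
        chars[a] = chars[a + 1] = "("
        chars[b - 1] = chars[b] = ")"
        spans.append((a + 2, b - 2))
    return "".join(chars)


@pytest.mark.parametrize("seed", range(8))
def test_random_structures_build_valid_networks(seed):
    rng = np.random.default_rng(seed)
    text = random_nested_structure(rng)
    ss = rb.parse_dot_bracket(text)
    net = rb.build_spring_network(ss)
    assert net.is_connected()
    pairs = net.pair_set()
    assert all((k, k + 1) in pairs for k in range(ss.n_residues - 1))
    # export -> parse round trip preserves the pairing involution
    assert rb.parse_dot_bracket(ss.to_dot_bracket()).pair_table().tolist() == \
        ss.pair_table().tolist()


def test_helix_table_roundtrip(tmp_path):
    ss, _ = rb.load_fixture("trna_phe")
    path = tmp_path / "helices.tsv"
    rb.write_helix_table(ss, path)
    back = rb.read_helix_table(path)
    assert back.n_residues == ss.n_residues
    assert back.pair_table().tolist() == ss.pair_table().tolist()
    assert [h.name for h in back.helices][0] == "acceptor stem"
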