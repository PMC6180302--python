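"""Structure handling: desalting, circular fingerprints, Tanimoto, dedup."""

import hashlib

import pytest
from hypothesis import given, settings, strategies as st

from ccmscreen.compounds import (CompoundLibrary, Fingerprint, LibraryEntry,
                                 MolecularGraph, circular_fingerprint, deduplicate,
                                 desalt, parse_smiles, tanimoto)


def graph(atoms, bonds, cid="g"):
    return MolecularGraph(atoms=tuple(atoms), bonds=tuple(bonds), id=cid)


# ---------------------------------------------------------------------------
# desalt


class TestDesalt:
    def test_connected_graph_unchanged(self):
        g = graph([("C", 0)] * 5, [(i, i + 1, 1) for i in range(4)])
        assert desalt(g) is g

    def test_largest_component_kept(self):
        # 6-carbon ring plus a lone sodium counter-ion
        atoms = [("C", 0)] * 6 + [("Na", 1)]
        bonds = [(i, (i + 1) % 6, 1) for i in range(6)]
        d = desalt(graph(atoms, bonds))
        assert d.n_atoms == 6
        assert all(sym == "C" for sym, _q in d.atoms)

    def test_equal_size_tie_break_is_deterministic(self):
        # two 2-atom components with distinct elements: the tie-break keeps
        # the component with the lexicographically smallest canonical
        # feature multiset, independent of input order
        cc = graph([("C", 0), ("C", 0), ("N", 0), ("N", 0)],
                   [(0, 1, 1), (2, 3, 1)])
        nn_first = graph([("N", 0), ("N", 0), ("C", 0), ("C", 0)],
                         [(0, 1, 1), (2, 3, 1)])
        kept_a = sorted(sym for sym, _q in desalt(cc).atoms)
        kept_b = sorted(sym for sym, _q in desalt(nn_first).atoms)
        assert kept_a == kept_b  # same winner either way round
        # and the winner is the one whose feature multiset is smallest
        c_comp = graph([("C", 0), ("C", 0)], [(0, 1, 1)])
        n_comp = graph([("N", 0), ("N", 0)], [(0, 1, 1)])
        c_key = tuple(sorted(circular_fingerprint(c_comp).features))
        n_key = tuple(sorted(circular_fingerprint(n_comp).features))
        expected = "C" if c_key < n_key else "N"
        assert kept_a == [expected, expected]

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            desalt(graph([], []))


# ---------------------------------------------------------------------------
# circular fingerprints


class TestCircularFingerprint:
    def test_isolated_atom_has_one_feature(self):
        g = graph([("C", 0)], [])
        assert len(circular_fingerprint(g, radius=2).features) == 1

    def test_hand_traced_path_feature_count(self):
        # A-B-A path at radius 2, traced independently of the implementation:
        # iteration 0 gives 2 distinct atom ids (the two A atoms are
        # equivalent); each later iteration adds 2 more (terminal vs center),
        # with the terminal atoms staying equivalent forever => 6 features.
        def hand_trace():
            def h(*parts):
                d = hashlib.blake2b(repr(parts).encode(), digest_size=8)
                return int.from_bytes(d.digest(), "big")

            a0 = h("atom", "A", 1, 0)
            b0 = h("atom", "B", 2, 0)
            feats = {a0, b0}
            a1 = h("iter", a0, ((1, b0),))
            b1 = h("iter", b0, tuple(sorted([(1, a0), (1, a0)])))
            feats |= {a1, b1}
            a2 = h("iter", a1, ((1, b1),))
            b2 = h("iter", b1, tuple(sorted([(1, a1), (1, a1)])))
            feats |= {a2, b2}
            return feats

        g = graph([("A", 0), ("B", 0), ("A", 0)], [(0, 1, 1), (1, 2, 1)])
        got = circular_fingerprint(g, radius=2).features
        assert got == frozenset(hand_trace())
        assert len(got) == 6

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            circular_fingerprint(graph([("C", 0)], []), radius=-1)

    def test_folding_bounds_features(self):
        g = parse_smiles("CC(=O)OC1CCCCC1", "x")
        folded = circular_fingerprint(g, radius=2, nbits=64)
        assert all(f < 64 for f in folded.features)

    @settings(max_examples=50, deadline=None)
    @given(st.randoms(use_true_random=False), st.integers(2, 8))
    def test_invariant_under_atom_permutation(self, rnd, n):
        atoms = [(rnd.choice("CNOS"), 0) for _ in range(n)]
        bonds = [(i, i + 1, rnd.choice([1, 2])) for i in range(n - 1)]
        # add a random chord to vary topology
        if n > 3:
            i, j = sorted(rnd.sample(range(n), 2))
            if (i, j, 1) not in [(a, b, o) for a, b, o in bonds] and j != i + 1:
                bonds.append((i, j, 1))
        g = graph(atoms, bonds)
        perm = list(range(n))
        rnd.shuffle(perm)
        inv = {old: new for new, old in enumerate(perm)}
        g2 = graph([atoms[old] for old in perm],
                   [(inv[i], inv[j], o) for (i, j, o) in bonds])
        assert (circular_fingerprint(g, 2).features
                == circular_fingerprint(g2, 2).features)


# ---------------------------------------------------------------------------
# tanimoto


class TestTanimoto:
    def fp(self, *feats):
        return Fingerprint(frozenset(feats))

    def test_identity_is_one(self):
        a = self.fp(1, 5, 9)
        assert tanimoto(a, a) == 1.0

    def test_disjoint_is_zero(self):
        assert tanimoto(self.fp(1, 2), self.fp(3, 4)) == 0.0

    def test_half_overlap(self):
        assert tanimoto(self.fp(1, 2, 3), self.fp(2, 3, 4)) == 0.5

    def test_both_empty_undefined(self):
        with pytest.raises(ValueError):
            tanimoto(self.fp(), self.fp())

    def test_parameter_mismatch_rejected(self):
        with pytest.raises(ValueError):
            tanimoto(Fingerprint(frozenset({1}), radius=2),
                     Fingerprint(frozenset({1}), radius=3))

    @settings(max_examples=100, deadline=None)
    @given(st.frozensets(st.integers(0, 30), max_size=12),
           st.frozensets(st.integers(0, 30), max_size=12))
    def test_symmetry(self, a, b):
        if not a and not b:
            return
        assert tanimoto(self.fp(*a), self.fp(*b)) == tanimoto(self.fp(*b), self.fp(*a))


# ---------------------------------------------------------------------------
# dedup


def lib(feature_sets):
    return CompoundLibrary(entries=[
        LibraryEntry(f"m{i:02d}", Fingerprint(frozenset(fs)), "test")
        for i, fs in enumerate(feature_sets)
    ])


class TestDeduplicate:
    def test_all_distinct(self):
        out = deduplicate(lib([{1}, {2}, {3}, {4}]))
        assert out.n_groups() == 4

    def test_one_duplicate_pair(self):
        out = deduplicate(lib([{1, 2}, {3}, {1, 2}]))
        assert out.n_groups() == 2
        assert out.canonical["m02"] == "m00"

    def test_two_pairs_one_singleton(self):
        # hand Tanimoto matrix: m0=m2, m1=m4, m3 alone
        out = deduplicate(lib([{1, 2}, {3, 4}, {1, 2}, {5}, {3, 4}]))
        groups = {}
        for m, c in out.canonical.items():
            groups.setdefault(c, set()).add(m)
        assert groups == {"m00": {"m00", "m02"}, "m01": {"m01", "m04"},
                          "m03": {"m03"}}

    def test_idempotent(self):
        once = deduplicate(lib([{1}, {1}, {2, 3}, {2, 3}, {4}]))
        twice = deduplicate(once)
        assert once.canonical == twice.canonical

    def test_matches_brute_force_at_threshold_one(self):
        import random

        rnd = random.Random(11)
        sets = [frozenset(rnd.sample(range(8), rnd.randint(1, 4)))
                for _ in range(40)]
        out = deduplicate(lib(sets))
        for i in range(len(sets)):
            for j in range(len(sets)):
                same_group = out.canonical[f"m{i:02d}"] == out.canonical[f"m{j:02d}"]
                assert same_group == (sets[i] == sets[j])

    def test_mixed_parameters_rejected(self):
        bad = CompoundLibrary(entries=[
            LibraryEntry("a", Fingerprint(frozenset({1}), radius=2), "x"),
            LibraryEntry("b", Fingerprint(frozenset({1}), radius=3), "x"),
        ])
        with pytest.raises(ValueError):
            deduplicate(bad)


# ---------------------------------------------------------------------------
# SMILES subset


class TestParseSmiles:
    def test_linear_chain(self):
        g = parse_smiles("CCO", "ethanol")
        assert [s for s, _q in g.atoms] == ["C", "C", "O"]
        assert g.bonds == ((0, 1, 1), (1, 2, 1))

    def test_branches_rings_orders(self):
        g = parse_smiles("CC(=O)C1CC1", "x")
        assert len(g.atoms) == 6
        orders = sorted(o for _i, _j, o in g.bonds)
        assert orders.count(2) == 1
        # ring closure adds one bond: atoms 6, bonds 6 (tree would have 5)
        assert len(g.bonds) == 6

    def test_charges_and_disconnection(self):
        g = parse_smiles("[NH4+].[Cl-]", "salt")
        assert g.atoms == (("N", 1), ("Cl", -1))
        assert g.bonds == ()

    @pytest.mark.parametrize("bad", ["", "C(", "C1CC", "[Xx!]C", "C)"])
    def test_malformed_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_smiles(bad, "bad")
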