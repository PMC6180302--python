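"""Compound registry: structures, desalting, circular fingerprints, Tanimoto, dedup.

Compounds enter the pipeline either as connection tables / minimal SMILES
(parsed here into :class:`MolecularGraph`) or as precomputed feature-set
fingerprints read from TSV.  All similarity computation downstream runs on
:class:`Fingerprint` objects: sets of hashed substructure identifiers produced
by an iterative Morgan-style expansion (radius 2 corresponds to ECFP-4-like
fingerprints).  The hash is a seedless, platform-stable 64-bit digest of
canonical tuples, so fingerprints are bit-reproducible across machines;
fingerprints computed by an external chemistry toolkit can be substituted via
the TSV pass-through.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence


def _hash64(*parts) -> int:
    """Stable 64-bit hash of a tuple of primitives (ints, strings)."""
    h = hashlib.blake2b(repr(parts).encode("utf-8"), digest_size=8)
    return int.from_bytes(h.digest(), "big")


@dataclass(frozen=True)
class MolecularGraph:
    """Undirected molecular graph.

    atoms: tuple of (element symbol, formal charge); bonds: tuple of
    (i, j, order) with i < j, each bond stored once, no self-loops.
    """

    atoms: tuple
    bonds: tuple
    id: str = ""

    def __post_init__(self):
        n = len(self.atoms)
        seen = set()
        for (i, j, order) in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) references missing atom in {self.id!r}")
            if i == j:
                raise ValueError(f"self-loop on atom {i} in {self.id!r}")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate bond {key} in {self.id!r}")
            seen.add(key)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def adjacency(self) -> list:
        adj = [[] for _ in range(len(self.atoms))]
        for (i, j, order) in self.bonds:
            adj[i].append((j, order))
            adj[j].append((i, order))
        return adj

    def connected_components(self) -> list:
        """Atom-index components, each sorted ascending."""
        adj = self.adjacency()
        seen = [False] * len(self.atoms)
        comps = []
        for start in range(len(self.atoms)):
            if seen[start]:
                continue
            stack, comp = [start], []
            seen[start] = True
            while stack:
                a = stack.pop()
                comp.append(a)
                for (b, _o) in adj[a]:
                    if not seen[b]:
                        seen[b] = True
                        stack.append(b)
            comps.append(sorted(comp))
        return comps

    def subgraph(self, atom_indices: Sequence[int]) -> "MolecularGraph":
        index = {a: k for k, a in enumerate(atom_indices)}
        atoms = tuple(self.atoms[a] for a in atom_indices)
        bonds = tuple(
            (index[i], index[j], order)
            for (i, j, order) in self.bonds
            if i in index and j in index
        )
        return MolecularGraph(atoms=atoms, bonds=bonds, id=self.id)


@dataclass(frozen=True)
class Fingerprint:
    """Set-of-features circular fingerprint.

    ``features`` holds hashed substructure identifiers (folded modulo
    ``nbits`` when ``nbits`` is set).  ``radius`` records the expansion
    radius so fingerprints from different parameterisations are never
    silently compared.
    """

    features: frozenset
    radius: int = 2
    nbits: Optional[int] = None

    def __post_init__(self):
        if self.nbits is not None and any(f >= self.nbits for f in self.features):
            raise ValueError("folded fingerprint has features >= nbits")

    def same_params(self, other: "Fingerprint") -> bool:
        return self.radius == other.radius and self.nbits == other.nbits


def circular_fingerprint(graph: MolecularGraph, radius: int = 2,
                         nbits: Optional[int] = None) -> Fingerprint:
    """Morgan-style iterative fingerprint.

    Initial atom identifier hashes (element, heavy-atom degree, charge); each
    iteration re-hashes the previous identifier together with the sorted
    (bond order, neighbor identifier) pairs.  The feature set is the union of
    all atom identifiers over iterations 0..radius, invariant under atom
    reordering by construction.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    n = graph.n_atoms
    if n == 0:
        return Fingerprint(frozenset(), radius, nbits)
    adj = graph.adjacency()
    ids = [
        _hash64("atom", sym, len(adj[k]), charge)
        for k, (sym, charge) in enumerate(graph.atoms)
    ]
    feats = set(ids)
    for _ in range(radius):
        # an atom with no neighbors has a fixed environment: id repeats and
        # deduplicates instead of growing
        ids = [
            _hash64("iter", ids[k], tuple(sorted((order, ids[j]) for (j, order) in adj[k])))
            if adj[k] else ids[k]
            for k in range(n)
        ]
        feats.update(ids)
    if nbits is not None:
        feats = {f % nbits for f in feats}
    return Fingerprint(frozenset(feats), radius, nbits)


def _canonical_feature_multiset(graph: MolecularGraph) -> tuple:
    # all per-iteration atom identifiers, sorted: a canonical, order-free
    # description used only for deterministic tie-breaking
    return tuple(sorted(circular_fingerprint(graph, radius=2).features))


def desalt(graph: MolecularGraph) -> MolecularGraph:
    """Largest connected component by atom count.

    Ties are broken by the lexicographically smallest canonical feature
    multiset of the component, which is deterministic and independent of
    atom numbering.
    """
    if graph.n_atoms == 0:
        raise ValueError("cannot desalt an empty molecular graph")
    comps = graph.connected_components()
    if len(comps) == 1:
        return graph
    best = None
    best_key = None
    for comp in comps:
        sub = graph.subgraph(comp)
        key = (-len(comp), _canonical_feature_multiset(sub))
        if best_key is None or key < best_key:
            best_key = key
            best = sub
    return best


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|a∩b| / |a∪b| over feature sets; both-empty is undefined."""
    if not a.same_params(b):
        raise ValueError("fingerprints computed with different parameters")
    if not a.features and not b.features:
        raise ValueError("Tanimoto undefined for two empty fingerprints")
    inter = len(a.features & b.features)
    union = len(a.features | b.features)
    return inter / union


# ---------------------------------------------------------------------------
# libraries and deduplication


@dataclass(frozen=True)
class LibraryEntry:
    id: str
    fingerprint: Fingerprint
    source: str = ""


@dataclass
class CompoundLibrary:
    """Fingerprinted compound entries plus (after dedup) a canonical-id map."""

    entries: list = field(default_factory=list)
    canonical: dict = field(default_factory=dict)  # member id -> canonical id

    def __post_init__(self):
        seen = set()
        for e in self.entries:
            key = (e.source, e.id)
            if key in seen:
                raise ValueError(f"duplicate id {e.id!r} within source {e.source!r}")
            seen.add(key)

    @property
    def ids(self) -> list:
        return [e.id for e in self.entries]

    def fingerprints(self) -> dict:
        return {e.id: e.fingerprint for e in self.entries}

    def n_groups(self) -> int:
        return len(set(self.canonical.values())) if self.canonical else len(self.entries)


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def deduplicate(library: CompoundLibrary, threshold: float = 1.0) -> CompoundLibrary:
    """Collapse entries with pairwise Tanimoto >= threshold into groups.

    Grouping is the transitive closure of the threshold relation; the
    canonical id of a group is its lexicographically smallest member id.
    The default threshold 1.0 gives exact-duplicate semantics (set-equal
    feature sets).
    """
    entries = library.entries
    if not entries:
        return CompoundLibrary(entries=[], canonical={})
    first = entries[0].fingerprint
    for e in entries:
        if not e.fingerprint.same_params(first):
            raise ValueError("library mixes fingerprint parameters; re-fingerprint first")
    uf = _UnionFind([e.id for e in entries])
    if threshold >= 1.0:
        by_set = {}
        for e in entries:
            by_set.setdefault(e.fingerprint.features, []).append(e.id)
        for ids in by_set.values():
            for other in ids[1:]:
                uf.union(ids[0], other)
    else:
        for i in range(len(entries)):
            for j in range(i + 1, len(entries)):
                if tanimoto(entries[i].fingerprint, entries[j].fingerprint) >= threshold:
                    uf.union(entries[i].id, entries[j].id)
    groups = {}
    for e in entries:
        groups.setdefault(uf.find(e.id), []).append(e.id)
    canonical = {}
    for members in groups.values():
        canon = min(members)
        for m in members:
            canonical[m] = canon
    return CompoundLibrary(entries=list(entries), canonical=canonical)


# ---------------------------------------------------------------------------
# minimal SMILES subset parser

_ORGANIC = ("Cl", "Br", "B", "C", "N", "O", "P", "S", "F", "I")
_AROMATIC = {"b": "B", "c": "C", "n": "N", "o": "O", "p": "P", "s": "S"}
_BOND_ORDERS = {"-": 1, "=": 2, "#": 3, "/": 1, "\\": 1}

_BRACKET_RE = re.compile(
    r"^(?P<isotope>\d+)?(?P<elem>[A-Z][a-z]?|[a-z])(?P<chiral>@{1,2})?"
    r"(?P<hcount>H\d*)?(?P<charge>\+{1,3}|-{1,3}|\+\d+|-\d+)?$"
)


def parse_smiles(smiles: str, compound_id: str = "") -> MolecularGraph:
    """Parse a minimal SMILES subset into a MolecularGraph.

    Supported: organic-subset and bracket atoms with charges, single/double/
    triple bonds, branches, ring closures (including %nn), and dot
    disconnections.  Aromatic lowercase atoms are read as their element with
    single bonds (no aromaticity perception).  Anything else should come in
    through the precomputed-fingerprint TSV pass-through.
    """
    atoms = []  # (symbol, charge)
    bonds = []
    prev = None  # index of previous atom in current chain
    pending_order = None
    stack = []
    ring_open = {}  # ring number -> (atom index, order or None)
    i = 0
    s = smiles.strip()
    if not s:
        raise ValueError("empty SMILES string")

    def add_atom(symbol, charge):
        nonlocal prev, pending_order
        idx = len(atoms)
        atoms.append((symbol, charge))
        if prev is not None:
            order = pending_order if pending_order is not None else 1
            bonds.append((prev, idx, order))
        prev = idx
        pending_order = None

    def open_or_close_ring(num):
        nonlocal pending_order
        if prev is None:
            raise ValueError(f"ring closure {num} before any atom in {s!r}")
        if num in ring_open:
            other, order0 = ring_open.pop(num)
            order = pending_order if pending_order is not None else (order0 or 1)
            if other == prev:
                raise ValueError(f"ring closure {num} forms a self-loop in {s!r}")
            bonds.append((min(other, prev), max(other, prev), order))
            pending_order = None
        else:
            ring_open[num] = (prev, pending_order)
            pending_order = None

    while i < len(s):
        ch = s[i]
        if ch == "[":
            end = s.find("]", i)
            if end < 0:
                raise ValueError(f"unclosed bracket atom in {s!r}")
            body = s[i + 1:end]
            m = _BRACKET_RE.match(body)
            if not m:
                raise ValueError(f"unsupported bracket atom [{body}] in {s!r}")
            elem = m.group("elem")
            if elem in _AROMATIC:
                elem = _AROMATIC[elem]
            charge_tok = m.group("charge") or ""
            if charge_tok in ("",):
                charge = 0
            elif charge_tok.lstrip("+-").isdigit():
                charge = int(charge_tok[1:]) * (1 if charge_tok[0] == "+" else -1)
            else:
                charge = charge_tok.count("+") - charge_tok.count("-")
            add_atom(elem, charge)
            i = end + 1
        elif s.startswith(("Cl", "Br"), i):
            add_atom(s[i:i + 2], 0)
            i += 2
        elif ch in "BCNOPSFI":
            add_atom(ch, 0)
            i += 1
        elif ch in _AROMATIC:
            add_atom(_AROMATIC[ch], 0)
            i += 1
        elif ch in _BOND_ORDERS:
            pending_order = _BOND_ORDERS[ch]
            i += 1
        elif ch == "(":
            if prev is None:
                raise ValueError(f"branch before any atom in {s!r}")
            stack.append(prev)
            i += 1
        elif ch == ")":
            if not stack:
                raise ValueError(f"unmatched ')' in {s!r}")
            prev = stack.pop()
            i += 1
        elif ch.isdigit():
            open_or_close_ring(int(ch))
            i += 1
        elif ch == "%":
            if i + 2 >= len(s) or not s[i + 1:i + 3].isdigit():
                raise ValueError(f"malformed %ring closure in {s!r}")
            open_or_close_ring(int(s[i + 1:i + 3]))
            i += 3
        elif ch == ".":
            prev = None
            pending_order = None
            i += 1
        else:
            raise ValueError(f"unsupported SMILES token {ch!r} in {s!r}")
    if stack:
        raise ValueError(f"unmatched '(' in {s!r}")
    if ring_open:
        raise ValueError(f"unclosed ring bonds {sorted(ring_open)} in {s!r}")
    return MolecularGraph(atoms=tuple(atoms), bonds=tuple(bonds), id=compound_id)


# ---------------------------------------------------------------------------
# file I/O


def read_smiles_file(path, radius: int = 2, nbits: Optional[int] = None,
                     source: str = "", desalt_records: bool = True) -> CompoundLibrary:
    """One record per line: ``SMILES<whitespace>id``; '#' lines are comments."""
    entries = []
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"{path}:{line_no}: expected 'SMILES id'")
        smiles, cid = parts[0], parts[1]
        graph = parse_smiles(smiles, cid)
        if desalt_records:
            graph = desalt(graph)
        entries.append(LibraryEntry(cid, circular_fingerprint(graph, radius, nbits), source))
    return CompoundLibrary(entries=entries)


def read_fingerprint_tsv(path, radius: int = 2, nbits: Optional[int] = None,
                         source: str = "") -> CompoundLibrary:
    """Pass-through fingerprints: ``id<TAB>comma-separated integer features``."""
    entries = []
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{line_no}: expected 'id<TAB>features'")
        cid, feats = parts
        features = frozenset(int(x) for x in feats.split(",") if x != "")
        entries.append(LibraryEntry(cid, Fingerprint(features, radius, nbits), source))
    return CompoundLibrary(entries=entries)


def write_dedup_map(library: CompoundLibrary, path) -> None:
    """TSV of (member_id, canonical_id, group_size)."""
    if not library.canonical:
        raise ValueError("library has not been deduplicated")
    sizes = {}
    for canon in library.canonical.values():
        sizes[canon] = sizes.get(canon, 0) + 1
    with open(path, "w") as fh:
        fh.write("member_id\tcanonical_id\tgroup_size\n")
        for member in sorted(library.canonical):
            canon = library.canonical[member]
            fh.write(f"{member}\t{canon}\t{sizes[canon]}\n")
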