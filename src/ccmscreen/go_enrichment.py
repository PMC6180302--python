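"""GO biological-process enrichment with is_a annotation propagation.

Annotations are read from GAF-style files, propagated upward along is_a
edges only (part_of and other relations are deliberately ignored), and
tested for over-representation in a study set against a stated background
using the shared hypergeometric/BH kernel.  Background ids without any
propagated annotation are excluded from the universe by default, mirroring
analyses that count only background genes carrying at least one term.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import obonet
import pandas as pd

from .enrich import enrichment_table

logger = logging.getLogger(__name__)


@dataclass
class Ontology:
    """Term DAG with child -> parent is_a edges."""

    graph: nx.DiGraph                    # edge u -> v means "u is_a v"
    names: dict = field(default_factory=dict)
    namespaces: dict = field(default_factory=dict)

    @property
    def terms(self) -> set:
        return set(self.graph.nodes)

    def ancestors(self, term: str) -> set:
        """All is_a ancestors (parents, grandparents, ...)."""
        if term not in self.graph:
            raise KeyError(term)
        return nx.descendants(self.graph, term)  # descendants along child->parent

    def name(self, term: str) -> str:
        return self.names.get(term, "")

    def namespace(self, term: str) -> str:
        return self.namespaces.get(term, "")


def _check_acyclic(graph: nx.DiGraph) -> None:
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        member = cycle[0][0]
        raise ValueError(f"is_a graph contains a cycle through {member!r}")


def parse_obo(path) -> Ontology:
    """Parse an OBO file; only id, name, namespace and is_a are consumed.

    Obsolete terms are skipped (obonet drops them by default).  Non-BP
    namespaces are retained and can be filtered downstream.
    """
    multigraph = obonet.read_obo(str(path))
    graph = nx.DiGraph()
    graph.add_nodes_from(multigraph.nodes)
    for child, parent, key in multigraph.edges(keys=True):
        if key == "is_a":
            graph.add_edge(child, parent)
    _check_acyclic(graph)
    names = {t: data.get("name", "") for t, data in multigraph.nodes(data=True)}
    namespaces = {t: data.get("namespace", "")
                  for t, data in multigraph.nodes(data=True)}
    return Ontology(graph=graph, names=names, namespaces=namespaces)


def build_ontology(terms, is_a_edges, names=None, namespaces=None) -> Ontology:
    """Construct an Ontology directly (used by the synthetic generator)."""
    graph = nx.DiGraph()
    graph.add_nodes_from(terms)
    for child, parent in is_a_edges:
        if child not in graph or parent not in graph:
            raise ValueError(f"is_a edge ({child}, {parent}) references unknown term")
        graph.add_edge(child, parent)
    _check_acyclic(graph)
    return Ontology(graph=graph, names=dict(names or {}),
                    namespaces=dict(namespaces or {}))


@dataclass
class AnnotationMap:
    """Gene/protein id -> GO term sets, direct and (after propagation) closed."""

    direct: dict = field(default_factory=dict)   # id -> set of term ids
    closed: dict = field(default_factory=dict)   # id -> upward-closed set
    n_skipped: int = 0

    @property
    def is_propagated(self) -> bool:
        return bool(self.closed)


def parse_annotations(path, aspect: str = "P") -> AnnotationMap:
    """Read GAF-style (>= 15 columns) or simple 4-column annotation TSV.

    Simple dialect: object_id, qualifier, term, aspect.  Comment lines start
    with '!'.  Rows with a NOT qualifier are dropped; rows outside the
    requested aspect are dropped; malformed rows are logged, counted and
    skipped.
    """
    direct = {}
    n_skipped = 0
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line or line.startswith("!"):
            continue
        cols = line.split("\t")
        if len(cols) >= 15:           # GAF 2.x
            obj, qualifier, term, row_aspect = cols[1], cols[3], cols[4], cols[8]
        elif len(cols) == 4:          # simple dialect
            obj, qualifier, term, row_aspect = cols
        else:
            logger.warning("%s:%d: malformed annotation row skipped", path, line_no)
            n_skipped += 1
            continue
        if not obj or not term.startswith("GO:"):
            logger.warning("%s:%d: malformed annotation row skipped", path, line_no)
            n_skipped += 1
            continue
        if "NOT" in qualifier.split("|"):
            continue
        if aspect and row_aspect != aspect:
            continue
        direct.setdefault(obj, set()).add(term)
    if n_skipped:
        logger.info("%s: skipped %d malformed rows", path, n_skipped)
    return AnnotationMap(direct=direct, n_skipped=n_skipped)


def propagate(ann: AnnotationMap, ont: Ontology) -> AnnotationMap:
    """Close annotations upward along is_a edges; idempotent."""
    unknown = sorted(
        {t for terms in ann.direct.values() for t in terms} - ont.terms
    )
    if unknown:
        raise ValueError(f"annotations reference unknown terms: {unknown[:10]}")
    ancestor_cache = {}
    closed = {}
    for gene, terms in ann.direct.items():
        full = set(terms)
        for t in terms:
            if t not in ancestor_cache:
                ancestor_cache[t] = ont.ancestors(t)
            full |= ancestor_cache[t]
        closed[gene] = full
    return AnnotationMap(direct={g: set(ts) for g, ts in ann.direct.items()},
                         closed=closed, n_skipped=ann.n_skipped)


def go_enrich(study: set, background: set, ann: AnnotationMap,
              fdr: float = 0.10, min_count: int = 1,
              include_unannotated: bool = False) -> pd.DataFrame:
    """Per-term enrichment of the study set against the background.

    N = annotated background size (all of the background when
    ``include_unannotated``); K = background ids carrying the term after
    propagation; n = (annotated) study size; k = study ids with the term.
    """
    if not study:
        raise ValueError("empty study set")
    if not set(study) <= set(background):
        raise ValueError("study set must be a subset of the background")
    if not ann.is_propagated:
        raise ValueError("annotation map must be propagated before enrichment")
    closed = ann.closed
    if include_unannotated:
        bg = set(background)
        st = set(study)
    else:
        bg = {g for g in background if closed.get(g)}
        st = {g for g in study if closed.get(g)}
    if not st:
        raise ValueError("no annotated study ids; nothing to test")
    term_K = {}
    for g in bg:
        for t in closed.get(g, ()):
            term_K[t] = term_K.get(t, 0) + 1
    term_k = {}
    for g in st:
        for t in closed.get(g, ()):
            term_k[t] = term_k.get(t, 0) + 1
    counts = [
        (t, term_k.get(t, 0), K)
        for t, K in sorted(term_K.items())
        if K >= min_count
    ]
    return enrichment_table(counts, n=len(st), N=len(bg), fdr=fdr)


def attach_term_names(table: pd.DataFrame, ont: Ontology) -> pd.DataFrame:
    out = table.copy()
    out.insert(1, "name", [ont.name(t) for t in out["entity"]])
    return out


def read_id_list(path) -> set:
    """Plain-text id list, one id per line; '#' lines are comments."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out
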