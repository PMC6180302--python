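"""Seeded generators for every input the pipeline consumes.

The generators emulate the structure of a dual-organism suppression screen:
a compound library with binary structural features, a reference
compound→target association DB in which each target owns a planted feature
block, two screens over partially overlapping compound subsets whose
activity labels carry a planted excess of shared actives driven by
"disease-target" carriers, and a small is_a DAG ontology with a planted
enriched branch.  Feature sets stand in for real chemistry: Tanimoto
similarity over random feature sets preserves the statistical structure the
nearest-neighbor predictor exploits, without a chemistry engine.

Default dimensions are the study's screen dimensions scaled ~10x down
(160/475 compounds with 108 shared, ~8.4%/7.4% hit rates) so the full
pipeline runs in seconds; paper-scale runs only change the config.

Every generator is a pure function of (config, stage) — reruns are
bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .compounds import CompoundLibrary, Fingerprint, LibraryEntry
from .go_enrichment import AnnotationMap, Ontology, build_ontology
from .screens import ScreenResult
from .target_prediction import AssociationDB, DBCompound

_STAGE_CODES = {
    "library": 1,
    "association_db": 2,
    "dual_screen": 3,
    "ontology": 4,
    "labels": 5,
}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent stream per (run seed, stage name)."""
    return np.random.default_rng(np.random.SeedSequence((seed, _STAGE_CODES[stage])))


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    # library / chemistry
    n_compounds: int = 100
    n_features: int = 400
    feature_rate: float = 0.05          # per-feature inclusion probability
    duplicate_pairs: int = 0            # injected exact duplicates
    # association DB with planted feature->target signal
    n_db_compounds: int = 120
    n_targets: int = 24
    block_size: int = 8                 # features owned by each target
    association_strength: float = 0.9   # P(block feature | annotated compound)
    baseline_feature_rate: float = 0.02  # P(any feature | background)
    # dual screen
    n_screen_a: int = 160
    n_screen_b: int = 475
    n_shared: int = 108
    hit_rate_a: float = 0.084
    hit_rate_b: float = 0.074
    n_disease_targets: int = 1
    carrier_fraction: float = 0.15      # screened compounds carrying a disease target
    carrier_active_rate: float = 0.42   # ~5x the baseline hit rates
    # ontology
    onto_depth: int = 3
    onto_branching: int = 3
    diamond_rate: float = 0.15
    n_genes: int = 240
    max_terms_per_gene: int = 3
    study_size: int = 40
    planted_branch_factor: float = 3.0

    def __post_init__(self):
        if min(self.n_compounds, self.n_features, self.n_db_compounds,
               self.n_targets, self.block_size, self.n_screen_a,
               self.n_screen_b, self.n_genes) <= 0:
            raise ValueError("all counts must be positive")
        if self.n_shared > min(self.n_screen_a, self.n_screen_b):
            raise ValueError("overlap exceeds a screen size")
        for rate in (self.hit_rate_a, self.hit_rate_b):
            if not (0.0 < rate < 1.0):
                raise ValueError("hit rates must lie in (0, 1)")
        if self.n_targets * self.block_size > self.n_features:
            raise ValueError("more planted feature blocks than features")
        if self.n_disease_targets > self.n_targets:
            raise ValueError("more disease targets than targets")
        if not (0.0 <= self.carrier_active_rate <= 1.0):
            raise ValueError("carrier_active_rate must lie in [0, 1]")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


def _random_feature_set(rng, cfg: SimConfig, rate: float) -> frozenset:
    mask = rng.random(cfg.n_features) < rate
    feats = frozenset(np.flatnonzero(mask).tolist())
    if not feats:
        feats = frozenset({int(rng.integers(cfg.n_features))})
    return feats


def gen_library(cfg: SimConfig) -> CompoundLibrary:
    """Random feature-set library with optional injected exact duplicates."""
    rng = stage_rng(cfg.seed, "library")
    if cfg.feature_rate * cfg.n_features < 1:
        raise ValueError("feature universe too small for the per-compound rate")
    entries = []
    for i in range(cfg.n_compounds):
        fp = Fingerprint(_random_feature_set(rng, cfg, cfg.feature_rate), radius=2)
        entries.append(LibraryEntry(f"C{i:05d}", fp, "sim"))
    if cfg.duplicate_pairs > cfg.n_compounds:
        raise ValueError("more duplicate pairs than compounds")
    for d in range(cfg.duplicate_pairs):
        entries.append(LibraryEntry(f"D{d:05d}", entries[d].fingerprint, "sim"))
    return CompoundLibrary(entries=entries)


def target_block(cfg: SimConfig, target_index: int) -> frozenset:
    start = target_index * cfg.block_size
    return frozenset(range(start, start + cfg.block_size))


def target_ids(cfg: SimConfig) -> list:
    return [f"T{i:03d}" for i in range(cfg.n_targets)]


def disease_targets(cfg: SimConfig) -> list:
    return target_ids(cfg)[: cfg.n_disease_targets]


def _compound_features(rng, cfg: SimConfig, target_index) -> frozenset:
    """Block features at association_strength, all others at baseline."""
    feats = set(np.flatnonzero(
        rng.random(cfg.n_features) < cfg.baseline_feature_rate
    ).tolist())
    if target_index is not None:
        block = np.fromiter(target_block(cfg, target_index), dtype=int)
        feats -= set(block.tolist())
        feats |= set(block[rng.random(block.size) < cfg.association_strength].tolist())
    if not feats:
        feats = {int(rng.integers(cfg.n_features))}
    return frozenset(feats)


def gen_association_db(cfg: SimConfig) -> AssociationDB:
    """Reference DB where target t's compounds carry t's feature block."""
    rng = stage_rng(cfg.seed, "association_db")
    tids = target_ids(cfg)
    compounds = []
    for i in range(cfg.n_db_compounds):
        t_index = i % cfg.n_targets
        feats = _compound_features(rng, cfg, t_index)
        compounds.append(DBCompound(
            f"R{i:05d}", Fingerprint(feats, radius=2), frozenset({tids[t_index]})
        ))
    return AssociationDB(compounds, targets=set(tids))


@dataclass(frozen=True)
class ScreenTruth:
    """Ground truth recorded by the dual-screen generator."""

    planted_targets: tuple
    true_target: dict          # compound id -> target id (its latent target)
    carriers: frozenset        # compounds whose latent target is a disease target
    shared_ids: frozenset
    expected_shared_actives: float

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "planted_targets": list(self.planted_targets),
                "true_target": dict(sorted(self.true_target.items())),
                "carriers": sorted(self.carriers),
                "shared_ids": sorted(self.shared_ids),
                "expected_shared_actives": self.expected_shared_actives,
            }, fh, indent=1)


def gen_screen_compounds(cfg: SimConfig):
    """Fingerprints and latent targets for the union of both screens.

    Returns (fingerprints, true_target, ids_a, ids_b).  Screen A holds the
    first ``n_screen_a`` ids, screen B the last ``n_screen_b``; the middle
    ``n_shared`` ids belong to both.
    """
    rng = stage_rng(cfg.seed, "dual_screen")
    tids = target_ids(cfg)
    n_total = cfg.n_screen_a + cfg.n_screen_b - cfg.n_shared
    ids = [f"S{i:05d}" for i in range(n_total)]
    fingerprints = {}
    true_target = {}
    n_disease = cfg.n_disease_targets
    for cid in ids:
        if rng.random() < cfg.carrier_fraction:
            t_index = int(rng.integers(n_disease))
        else:
            t_index = int(rng.integers(n_disease, cfg.n_targets))
        true_target[cid] = tids[t_index]
        fingerprints[cid] = Fingerprint(
            _compound_features(rng, cfg, t_index), radius=2
        )
    ids_a = ids[: cfg.n_screen_a]
    ids_b = ids[cfg.n_screen_a - cfg.n_shared:]
    return fingerprints, true_target, ids_a, ids_b


def draw_labels(rng, ids, carriers, base_rate: float,
                carrier_rate: float) -> set:
    """Bernoulli activity labels: carrier_rate for carriers, base_rate else."""
    active = set()
    for cid in ids:
        rate = carrier_rate if cid in carriers else base_rate
        if rng.random() < rate:
            active.add(cid)
    return active


def gen_dual_screen(cfg: SimConfig, db: AssociationDB = None):
    """Two screens with planted target enrichment and shared-active excess.

    Compounds whose latent target is a disease target are active with
    ``carrier_active_rate`` in both screens (independently), producing both
    the per-screen target enrichment and the excess of shared actives; all
    other compounds are active at the baseline hit rates.  ``db`` is
    accepted for signature symmetry with the rest of the pipeline (screen
    compounds are generated against the same target set).
    """
    if cfg.carrier_active_rate < max(cfg.hit_rate_a, cfg.hit_rate_b):
        raise ValueError("planted overlap excess infeasible: carrier rate below baseline")
    fingerprints, true_target, ids_a, ids_b = gen_screen_compounds(cfg)
    planted = set(disease_targets(cfg))
    carriers = frozenset(c for c, t in true_target.items() if t in planted)
    rng = stage_rng(cfg.seed, "labels")
    active_a = draw_labels(rng, ids_a, carriers, cfg.hit_rate_a,
                           cfg.carrier_active_rate)
    active_b = draw_labels(rng, ids_b, carriers, cfg.hit_rate_b,
                           cfg.carrier_active_rate)
    shared = frozenset(ids_a) & frozenset(ids_b)
    exp = 0.0
    for cid in shared:
        if cid in carriers:
            exp += cfg.carrier_active_rate ** 2
        else:
            exp += cfg.hit_rate_a * cfg.hit_rate_b
    screen_a = ScreenResult("screen_a", {c: fingerprints[c] for c in ids_a}, active_a)
    screen_b = ScreenResult("screen_b", {c: fingerprints[c] for c in ids_b}, active_b)
    truth = ScreenTruth(
        planted_targets=tuple(sorted(planted)),
        true_target=true_target,
        carriers=carriers,
        shared_ids=shared,
        expected_shared_actives=exp,
    )
    return screen_a, screen_b, truth


# ---------------------------------------------------------------------------
# ontology


def gen_ontology(cfg: SimConfig):
    """Rooted is_a DAG with a planted enriched branch.

    A depth x branching tree (with optional extra "diamond" parents linking
    a node to a second parent one level up, keeping the graph acyclic);
    genes are annotated to leaves; a study set over-samples genes annotated
    under the first branch by ``planted_branch_factor``.

    Returns (Ontology, AnnotationMap (direct), planted term set, study set,
    background set).
    """
    if cfg.onto_depth < 1 or cfg.onto_branching < 1:
        raise ValueError("ontology depth and branching must be >= 1")
    rng = stage_rng(cfg.seed, "ontology")
    counter = [0]

    def new_term():
        counter[0] += 1
        return f"GO:{counter[0]:07d}"

    root = new_term()
    levels = [[root]]
    edges = []
    for _depth in range(cfg.onto_depth):
        level = []
        for parent in levels[-1]:
            for _ in range(cfg.onto_branching):
                child = new_term()
                edges.append((child, parent))
                level.append(child)
        levels.append(level)
    # diamonds: a second is_a parent one level up (strictly upward => acyclic)
    for d in range(2, len(levels)):
        for term in levels[d]:
            if len(levels[d - 1]) > 1 and rng.random() < cfg.diamond_rate:
                current = {p for (c, p) in edges if c == term}
                choices = [p for p in levels[d - 1] if p not in current]
                if choices:
                    edges.append((term, choices[int(rng.integers(len(choices)))]))
    terms = [t for level in levels for t in level]
    names = {t: f"synthetic process {t[3:].lstrip('0') or '0'}" for t in terms}
    namespaces = {t: "biological_process" for t in terms}
    ont = build_ontology(terms, edges, names=names, namespaces=namespaces)

    leaves = levels[-1]
    # planted branch: everything under the root's first child
    first_child = levels[1][0]
    planted = {first_child} | {
        t for t in ont.terms if first_child in (ont.ancestors(t) | {t}) and t != root
    }
    planted_leaves = [t for t in leaves if t in planted]
    direct = {}
    gene_in_branch = {}
    for i in range(cfg.n_genes):
        gene = f"G{i:05d}"
        n_terms = 1 + int(rng.integers(cfg.max_terms_per_gene))
        picks = rng.choice(len(leaves), size=min(n_terms, len(leaves)),
                           replace=False)
        direct[gene] = {leaves[int(k)] for k in picks}
        gene_in_branch[gene] = any(t in set(planted_leaves) for t in direct[gene])
    genes = sorted(direct)
    weights = np.array(
        [cfg.planted_branch_factor if gene_in_branch[g] else 1.0 for g in genes]
    )
    weights /= weights.sum()
    study_idx = rng.choice(len(genes), size=min(cfg.study_size, len(genes)),
                           replace=False, p=weights)
    study = {genes[int(k)] for k in study_idx}
    background = set(genes)
    return ont, AnnotationMap(direct=direct), planted, study, background


# ---------------------------------------------------------------------------
# bundle writer (all formats the pipeline reads)


def write_obo(ont: Ontology, path) -> None:
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: ccmscreen-synthetic\n")
        for t in sorted(ont.terms):
            fh.write(f"\n[Term]\nid: {t}\nname: {ont.name(t)}\n")
            ns = ont.namespace(t)
            if ns:
                fh.write(f"namespace: {ns}\n")
            for parent in sorted(ont.graph.successors(t)):
                fh.write(f"is_a: {parent} ! {ont.name(parent)}\n")


def write_gaf(ann: AnnotationMap, path, aspect: str = "P") -> None:
    """Simple 4-column annotation dialect (object, qualifier, term, aspect)."""
    with open(path, "w") as fh:
        fh.write("!gaf-like simple dialect: object\tqualifier\tterm\taspect\n")
        for gene in sorted(ann.direct):
            for term in sorted(ann.direct[gene]):
                fh.write(f"{gene}\t\t{term}\t{aspect}\n")


def write_library_tsv(library: CompoundLibrary, path) -> None:
    with open(path, "w") as fh:
        for e in library.entries:
            feats = ",".join(str(f) for f in sorted(e.fingerprint.features))
            fh.write(f"{e.id}\t{feats}\n")


def write_bundle(cfg: SimConfig, outdir) -> dict:
    """Write the full synthetic input bundle; returns the path manifest."""
    from .screens import write_screen_tsv
    from .target_prediction import write_association_db

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    library = gen_library(cfg)
    db = gen_association_db(cfg)
    screen_a, screen_b, truth = gen_dual_screen(cfg, db)
    ont, ann, planted, study, background = gen_ontology(cfg)
    paths = {
        "library": outdir / "library.tsv",
        "association_db": outdir / "association_db.tsv",
        "screen_a": outdir / "screen_a.tsv",
        "screen_b": outdir / "screen_b.tsv",
        "screen_fingerprints": outdir / "screen_fingerprints.tsv",
        "ontology": outdir / "ontology.obo",
        "annotations": outdir / "annotations.gaf",
        "study": outdir / "study_ids.txt",
        "background": outdir / "background_ids.txt",
        "truth": outdir / "truth.json",
    }
    write_library_tsv(library, paths["library"])
    write_association_db(db, paths["association_db"])
    write_screen_tsv(screen_a, paths["screen_a"])
    write_screen_tsv(screen_b, paths["screen_b"])
    merged = dict(screen_a.fingerprints)
    merged.update(screen_b.fingerprints)
    merged_lib = CompoundLibrary(entries=[
        LibraryEntry(cid, merged[cid], "sim-screen") for cid in sorted(merged)
    ])
    write_library_tsv(merged_lib, paths["screen_fingerprints"])
    write_obo(ont, paths["ontology"])
    write_gaf(ann, paths["annotations"])
    paths["study"].write_text("".join(f"{g}\n" for g in sorted(study)))
    paths["background"].write_text("".join(f"{g}\n" for g in sorted(background)))
    truth.to_json(paths["truth"])
    return {k: str(v) for k, v in paths.items()}
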