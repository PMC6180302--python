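"""Target deconvolution of a phenotypic screen (DePick-style).

Each screened compound is assigned the union of its known targets (exact
fingerprint matches in the reference DB) and its predicted targets above a
precision cutoff (default: strictly above 50%).  Highly promiscuous
compounds (more than 100 known-or-predicted targets) are discarded, as are
compounds with no target at all; the remaining compounds — actives and
inactives alike — form the universe of a one-sided hypergeometric
enrichment test per target, with BH FDR control at 10%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .enrich import enrichment_table
from .screens import ScreenResult
from .target_prediction import AssociationDB, CalibrationTable, predict_targets


@dataclass
class CompoundTargetMap:
    """compound id -> target set, with provenance per (compound, target)."""

    targets: dict = field(default_factory=dict)      # cid -> frozenset of targets
    provenance: dict = field(default_factory=dict)   # (cid, t) -> (kind, precision)
    n_promiscuous_dropped: int = 0
    n_targetless_dropped: int = 0

    @property
    def universe(self) -> set:
        return set(self.targets)

    def compounds_with(self, target: str) -> set:
        return {cid for cid, ts in self.targets.items() if target in ts}

    def all_targets(self) -> set:
        out = set()
        for ts in self.targets.values():
            out |= ts
        return out


def collect_targets(screen: ScreenResult, db: AssociationDB,
                    calib: CalibrationTable, precision_min: float = 0.5,
                    promiscuity_max: int = 100,
                    n_targets: int = 10) -> CompoundTargetMap:
    """Known ∪ predicted (precision strictly > precision_min) targets.

    Known targets are those of reference compounds with an identical feature
    set (precision 1.0 by convention).  Compounds whose union exceeds
    ``promiscuity_max`` targets are dropped entirely; compounds with no
    target leave the analysis universe.
    """
    some_fp = next(iter(screen.fingerprints.values()), None)
    if some_fp is not None and db.compounds:
        if not some_fp.same_params(db.compounds[0].fingerprint):
            raise ValueError("screen and DB fingerprint parameters differ")
    known_by_fp = db.by_fingerprint()
    out = CompoundTargetMap()
    for cid in sorted(screen.fingerprints):
        fp = screen.fingerprints[cid]
        prov = {}
        for t in known_by_fp.get(fp.features, frozenset()):
            prov[t] = ("known", 1.0)
        if fp.features:
            for pred in predict_targets(fp, db, calib, n_targets=n_targets):
                if pred.precision > precision_min and pred.target not in prov:
                    prov[pred.target] = ("predicted", pred.precision)
        if not prov:
            out.n_targetless_dropped += 1
            continue
        if len(prov) > promiscuity_max:
            out.n_promiscuous_dropped += 1
            continue
        out.targets[cid] = frozenset(prov)
        for t, tag in prov.items():
            out.provenance[(cid, t)] = tag
    return out


def enrich_targets(target_map: CompoundTargetMap, actives: set,
                   fdr: float = 0.10) -> pd.DataFrame:
    """Per-target enrichment among actives.

    Universe N = compounds in the map; K = compounds annotated to the
    target; n = actives within the map; k = active compounds annotated to
    the target.  One-sided (enrichment only); k = 0 targets are kept with
    p = 1 so the BH family is stable.
    """
    universe = set(target_map.targets)
    study = set(actives) & universe
    if not set(actives):
        raise ValueError("empty active set")
    if not study:
        raise ValueError("no active compound retained a target; nothing to test")
    N = len(universe)
    n = len(study)
    counts = []
    for t in sorted(target_map.all_targets()):
        carriers = target_map.compounds_with(t)
        counts.append((t, len(carriers & study), len(carriers)))
    return enrichment_table(counts, n=n, N=N, fdr=fdr)


def depick_summary(table: pd.DataFrame, fdr: float = 0.10) -> dict:
    return {
        "n_targets_tested": int(len(table)),
        "n_significant": int(table["significant"].sum()) if len(table) else 0,
        "fdr": fdr,
        "universe_size": int(table["N"].iloc[0]) if len(table) else 0,
        "n_actives": int(table["n"].iloc[0]) if len(table) else 0,
    }
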