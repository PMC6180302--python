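"""Ligand-based target prediction in the HitPickV2 style.

For a query fingerprint the predictor (i) finds the nearest reference
compounds by Tanimoto similarity until their annotations cover 10 distinct
protein targets (the "restricted target space"), (ii) scores each candidate
target with a Laplacian-corrected naive Bayes log-odds over the query's
features, and (iii) attaches an empirical precision estimated by
cross-validation, binned over (target occurrence in the space, rank, max
Tanimoto to an annotated neighbor).

The reference database is a plain collection of (fingerprint, target-set)
records; all "training" is counting.  All tie-breaks (similarity, score,
rank) fall back to ascending lexicographic ids so outputs are
bit-reproducible.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from .compounds import Fingerprint, parse_smiles, circular_fingerprint, desalt, tanimoto


@dataclass(frozen=True)
class DBCompound:
    id: str
    fingerprint: Fingerprint
    targets: frozenset


class AssociationDB:
    """Reference compound→target associations with count caches.

    Caches: ``feature_counts[f]`` = number of compounds containing feature f
    (A_f); ``feature_target_counts[t][f]`` = number of compounds annotated to
    target t containing f (A_{f,t}); ``target_counts[t]`` = compounds
    annotated to t, giving the prior P(t) = target_counts[t] / n_compounds.
    An explicit ``targets`` universe may extend beyond annotated targets
    (those extra targets score 0 for every query).
    """

    def __init__(self, compounds: Iterable[DBCompound], targets: Optional[set] = None):
        self.compounds = sorted(compounds, key=lambda c: c.id)
        if len(set(c.id for c in self.compounds)) != len(self.compounds):
            raise ValueError("duplicate compound ids in association DB")
        self.feature_counts = Counter()
        self.target_counts = Counter()
        self.feature_target_counts = {}
        n_assoc = 0
        for c in self.compounds:
            for f in c.fingerprint.features:
                self.feature_counts[f] += 1
            for t in c.targets:
                n_assoc += 1
                self.target_counts[t] += 1
                ftc = self.feature_target_counts.setdefault(t, Counter())
                for f in c.fingerprint.features:
                    ftc[f] += 1
        self.targets = set(self.target_counts)
        if targets is not None:
            self.targets |= set(targets)
        self.n_associations = n_assoc

    @property
    def n_compounds(self) -> int:
        return len(self.compounds)

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    def target_prior(self, target: str) -> float:
        if target not in self.targets:
            raise ValueError(f"unknown target id {target!r}")
        return self.target_counts.get(target, 0) / self.n_compounds

    def without(self, compound_id: str) -> "AssociationDB":
        """Copy with one compound removed (leave-one-out)."""
        return AssociationDB(
            [c for c in self.compounds if c.id != compound_id], targets=self.targets
        )

    def by_fingerprint(self) -> dict:
        """feature-set -> union of targets of compounds with that exact set."""
        out = {}
        for c in self.compounds:
            key = c.fingerprint.features
            out[key] = out.get(key, frozenset()) | c.targets
        return out


def nb_score(query: Fingerprint, target: str, db: AssociationDB) -> float:
    """Laplacian-corrected naive Bayes score (natural log scale).

    score = sum over features f in the query of
    ln[(A_{f,t} + 1) / (A_f * P(t) + 1)].  Features unseen in the DB
    contribute ln(1/1) = 0, as does any target with no annotated compounds.
    """
    if target not in db.targets:
        raise ValueError(f"unknown target id {target!r}")
    p_t = db.target_counts.get(target, 0) / db.n_compounds
    ftc = db.feature_target_counts.get(target, Counter())
    score = 0.0
    for f in query.features:
        a_f = db.feature_counts.get(f, 0)
        score += math.log((ftc.get(f, 0) + 1.0) / (a_f * p_t + 1.0))
    return score


def knn_target_space(query: Fingerprint, db: AssociationDB,
                     n_targets: int = 10) -> list:
    """Shortest similarity-ranked prefix of the DB covering n_targets targets.

    Returns a list of (DBCompound, tanimoto) sorted by descending similarity,
    ties broken by ascending compound id.  If the whole DB covers fewer than
    ``n_targets`` distinct targets the full ranked list is returned.
    """
    if db.n_compounds == 0:
        raise ValueError("association DB is empty")
    if not query.features:
        raise ValueError("query fingerprint is empty")
    ranked = sorted(
        ((c, tanimoto(query, c.fingerprint)) for c in db.compounds),
        key=lambda pair: (-pair[1], pair[0].id),
    )
    covered = set()
    space = []
    for c, sim in ranked:
        space.append((c, sim))
        covered |= c.targets
        if len(covered) >= n_targets:
            break
    return space


@dataclass(frozen=True)
class TargetPrediction:
    target: str
    nb_score: float
    occurrence: int
    rank: int
    max_tanimoto: float
    precision: float


# calibration bin edges (upper-inclusive final bins)
OCC_BINS = (1, 2, 3, 4)          # 1, 2, 3, >=4
RANK_BINS = (1, 2, 3, 4)         # 1, 2, 3, 4-10
TAN_EDGES = (0.4, 0.7)           # [0,0.4), [0.4,0.7), [0.7,1.0]


def _occ_bin(occ: int) -> int:
    return min(occ, 4)


def _rank_bin(rank: int) -> int:
    return min(rank, 4)


def _tan_bin(t: float) -> int:
    if t < TAN_EDGES[0]:
        return 0
    if t < TAN_EDGES[1]:
        return 1
    return 2


class CalibrationTable:
    """Binned empirical precision from cross-validated predictions.

    Bins: occurrence {1,2,3,>=4} x rank {1,2,3,4-10} x max Tanimoto
    {[0,0.4), [0.4,0.7), [0.7,1.0]}.  Cells with fewer than ``min_count``
    cross-validated predictions fall back to the marginal rank-bin precision,
    then to the global precision, then 0.
    """

    def __init__(self, min_count: int = 20, scheme: str = "loo", seed: int = 0):
        self.min_count = min_count
        self.scheme = scheme
        self.seed = seed
        self.counts = {}  # (occ_bin, rank_bin, tan_bin) -> [n, n_correct]

    def add(self, occurrence: int, rank: int, max_tanimoto: float, correct: bool):
        key = (_occ_bin(occurrence), _rank_bin(rank), _tan_bin(max_tanimoto))
        cell = self.counts.setdefault(key, [0, 0])
        cell[0] += 1
        cell[1] += int(correct)

    @property
    def n_predictions(self) -> int:
        return sum(n for n, _c in self.counts.values())

    def precision(self, occurrence: int, rank: int, max_tanimoto: float) -> float:
        key = (_occ_bin(occurrence), _rank_bin(rank), _tan_bin(max_tanimoto))
        cell = self.counts.get(key)
        if cell and cell[0] >= self.min_count:
            return cell[1] / cell[0]
        rb = _rank_bin(rank)
        n = c = 0
        for (ob, rbin, tb), (cn, cc) in self.counts.items():
            if rbin == rb:
                n += cn
                c += cc
        if n > 0:
            return c / n
        total = sum(n for n, _ in self.counts.values())
        correct = sum(c for _, c in self.counts.values())
        return correct / total if total else 0.0

    # ---- JSON round-trip -------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "min_count": self.min_count,
            "scheme": self.scheme,
            "seed": self.seed,
            "occ_bins": list(OCC_BINS),
            "rank_bins": list(RANK_BINS),
            "tanimoto_edges": list(TAN_EDGES),
            "cells": [
                {"occ": k[0], "rank": k[1], "tan": k[2], "n": v[0], "correct": v[1]}
                for k, v in sorted(self.counts.items())
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "CalibrationTable":
        payload = json.loads(Path(path).read_text())
        table = cls(min_count=payload["min_count"], scheme=payload["scheme"],
                    seed=payload["seed"])
        for cell in payload["cells"]:
            table.counts[(cell["occ"], cell["rank"], cell["tan"])] = [
                cell["n"], cell["correct"]
            ]
        return table


def predict_targets(query: Fingerprint, db: AssociationDB,
                    calib: Optional[CalibrationTable] = None,
                    n_targets: int = 10) -> list:
    """Predict up to ``n_targets`` targets for a query compound.

    Per candidate target in the k-NN space: occurrence = space compounds
    annotated to it; nb_score as in :func:`nb_score`; rank by descending
    score (ties by descending occurrence then ascending target id);
    max_tanimoto = similarity to the most similar annotated space compound;
    precision from the calibration table (0 when no table is given).
    """
    space = knn_target_space(query, db, n_targets=n_targets)
    occurrence = Counter()
    max_tan = {}
    for c, sim in space:
        for t in c.targets:
            occurrence[t] += 1
            if t not in max_tan or sim > max_tan[t]:
                max_tan[t] = sim
    scored = sorted(
        ((t, nb_score(query, t, db)) for t in occurrence),
        key=lambda pair: (-pair[1], -occurrence[pair[0]], pair[0]),
    )
    predictions = []
    for rank, (t, score) in enumerate(scored[:n_targets], start=1):
        prec = calib.precision(occurrence[t], rank, max_tan[t]) if calib else 0.0
        predictions.append(TargetPrediction(
            target=t, nb_score=score, occurrence=occurrence[t], rank=rank,
            max_tanimoto=max_tan[t], precision=prec,
        ))
    return predictions


def calibrate_precision(db: AssociationDB, folds: Optional[int] = None,
                        seed: int = 0, min_count: int = 20,
                        n_targets: int = 10) -> CalibrationTable:
    """Cross-validated precision calibration.

    Default is leave-one-out: each compound is removed from the counts and
    the neighbor search, re-predicted, and each prediction scored correct iff
    the predicted target belongs to the held-out compound's annotations.
    With ``folds`` >= 2, a seeded k-fold split is used instead.
    """
    if db.n_compounds < 2:
        raise ValueError("calibration requires at least 2 DB compounds")
    if folds is not None and folds < 2:
        raise ValueError("folds must be >= 2 (or None for leave-one-out)")
    table = CalibrationTable(
        min_count=min_count,
        scheme=f"{folds}-fold" if folds else "loo",
        seed=seed,
    )
    if folds is None:
        assignments = {c.id: i for i, c in enumerate(db.compounds)}
        n_folds = db.n_compounds
    else:
        import numpy as np

        rng = np.random.default_rng(seed)
        order = rng.permutation(db.n_compounds)
        assignments = {db.compounds[int(k)].id: int(i % folds)
                       for i, k in enumerate(order)}
        n_folds = folds
    for fold in range(n_folds):
        held = [c for c in db.compounds if assignments[c.id] == fold]
        if not held:
            continue
        rest = AssociationDB(
            [c for c in db.compounds if assignments[c.id] != fold],
            targets=db.targets,
        )
        if rest.n_compounds == 0:
            continue
        for c in held:
            if not c.fingerprint.features:
                continue
            for pred in predict_targets(c.fingerprint, rest, calib=None,
                                        n_targets=n_targets):
                table.add(pred.occurrence, pred.rank, pred.max_tanimoto,
                          pred.target in c.targets)
    return table


# ---------------------------------------------------------------------------
# file I/O


def read_association_db(path, radius: int = 2, nbits=None) -> AssociationDB:
    """TSV: compound_id TAB features-or-SMILES TAB semicolon-separated targets.

    The middle column is read as comma-separated integer features when it
    parses as such, otherwise as SMILES (desalted, then fingerprinted).
    """
    compounds = []
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"{path}:{line_no}: expected 3 tab-separated columns")
        cid, struct, targets = parts
        try:
            features = frozenset(int(x) for x in struct.split(","))
            fp = Fingerprint(features, radius, nbits)
        except ValueError:
            fp = circular_fingerprint(desalt(parse_smiles(struct, cid)), radius, nbits)
        tset = frozenset(t for t in targets.split(";") if t)
        compounds.append(DBCompound(cid, fp, tset))
    return AssociationDB(compounds)


def write_association_db(db: AssociationDB, path) -> None:
    with open(path, "w") as fh:
        for c in db.compounds:
            feats = ",".join(str(f) for f in sorted(c.fingerprint.features))
            fh.write(f"{c.id}\t{feats}\t{';'.join(sorted(c.targets))}\n")


def write_predictions(predictions_by_query: dict, path) -> None:
    """TSV: query_id, target, nb_score, occurrence, rank, max_tanimoto, precision."""
    with open(path, "w") as fh:
        fh.write("query_id\ttarget\tnb_score\toccurrence\trank\tmax_tanimoto\tprecision\n")
        for qid in sorted(predictions_by_query):
            for p in predictions_by_query[qid]:
                fh.write(
                    f"{qid}\t{p.target}\t{p.nb_score:.6f}\t{p.occurrence}\t"
                    f"{p.rank}\t{p.max_tanimoto:.6f}\t{p.precision:.6f}\n"
                )
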