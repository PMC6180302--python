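"""End-to-end orchestration: dedup -> calibrate -> predict -> enrichment ->
overlap -> GO -> summary.

``run_pipeline`` drives the whole analysis from a directory of input files
(such as one written by :func:`ccmscreen.synthetic_data.write_bundle`) and
writes TSV/JSON artifacts plus a manifest recording the config hash, seed
and per-stage row counts, so identical configs rerun byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .compounds import deduplicate, read_fingerprint_tsv, write_dedup_map
from .depick import collect_targets, depick_summary, enrich_targets
from .enrich import write_enrichment_tsv
from .go_enrichment import (attach_term_names, go_enrich, parse_annotations,
                            parse_obo, propagate, read_id_list)
from .overlap_stats import DualScreen, overlap_permutation_test
from .screens import read_screen_tsv
from .target_prediction import (CalibrationTable, calibrate_precision,
                                predict_targets, read_association_db,
                                write_predictions)


@dataclass(frozen=True)
class RunConfig:
    input_dir: str
    outdir: str
    seed: int = 0
    dedup_threshold: float = 1.0
    precision_min: float = 0.5
    promiscuity_max: int = 100
    fdr: float = 0.10
    n_perm: int = 1_000_000
    calib_folds: int = None          # None = leave-one-out
    go_aspect: str = "P"
    stages: tuple = ("dedup", "calibrate", "predict", "depick", "overlap",
                     "goenrich", "stats")

    def __post_init__(self):
        if not (0.0 < self.dedup_threshold <= 1.0):
            raise ValueError("dedup_threshold must lie in (0, 1]")
        if not (0.0 <= self.precision_min <= 1.0):
            raise ValueError("precision_min must lie in [0, 1]")
        if self.promiscuity_max < 1:
            raise ValueError("promiscuity_max must be >= 1")
        if not (0.0 < self.fdr < 1.0):
            raise ValueError("fdr must lie in (0, 1)")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")

    def config_hash(self) -> str:
        # analytic parameters only: the same analysis in a different
        # directory carries the same hash
        payload = dataclasses.asdict(self)
        payload.pop("input_dir")
        payload.pop("outdir")
        blob = json.dumps(payload, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise StageError(stage, f"missing input file {path}")
    return path


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the configured stages; returns (and writes) the run manifest."""
    indir = Path(cfg.input_dir)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "config": dataclasses.asdict(cfg),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stages": {},
    }
    header = f"ccmscreen {__version__} config_hash={cfg.config_hash()} seed={cfg.seed}"

    screen_fps = read_fingerprint_tsv(
        _require(indir / "screen_fingerprints.tsv", "load")
    ).fingerprints()
    screen_a = read_screen_tsv(_require(indir / "screen_a.tsv", "load"),
                               screen_fps, "screen_a")
    screen_b = read_screen_tsv(_require(indir / "screen_b.tsv", "load"),
                               screen_fps, "screen_b")
    db = read_association_db(_require(indir / "association_db.tsv", "load"))

    if "dedup" in cfg.stages:
        library = read_fingerprint_tsv(_require(indir / "library.tsv", "dedup"))
        deduped = deduplicate(library, threshold=cfg.dedup_threshold)
        write_dedup_map(deduped, outdir / "dedup_map.tsv")
        manifest["stages"]["dedup"] = {
            "n_entries": len(deduped.entries),
            "n_groups": deduped.n_groups(),
        }

    calib = None
    if "calibrate" in cfg.stages:
        calib = calibrate_precision(db, folds=cfg.calib_folds, seed=cfg.seed)
        calib.to_json(outdir / "calibration.json")
        manifest["stages"]["calibrate"] = {
            "scheme": calib.scheme,
            "n_predictions": calib.n_predictions,
        }
    elif (outdir / "calibration.json").exists():
        calib = CalibrationTable.from_json(outdir / "calibration.json")

    if "predict" in cfg.stages:
        if calib is None:
            raise StageError("predict", "no calibration table available")
        preds = {}
        for cid in sorted(screen_fps):
            fp = screen_fps[cid]
            if fp.features:
                preds[cid] = predict_targets(fp, db, calib)
        write_predictions(preds, outdir / "predictions.tsv")
        manifest["stages"]["predict"] = {
            "n_queries": len(preds),
            "n_predictions": sum(len(v) for v in preds.values()),
        }

    target_maps = {}
    if "depick" in cfg.stages:
        if calib is None:
            raise StageError("depick", "no calibration table available")
        for screen in (screen_a, screen_b):
            tmap = collect_targets(screen, db, calib,
                                   precision_min=cfg.precision_min,
                                   promiscuity_max=cfg.promiscuity_max)
            target_maps[screen.screen_id] = tmap
            table = enrich_targets(tmap, screen.active, fdr=cfg.fdr)
            write_enrichment_tsv(table, outdir / f"depick_{screen.screen_id}.tsv",
                                 header_comment=header)
            summary = depick_summary(table, fdr=cfg.fdr)
            summary["n_promiscuous_dropped"] = tmap.n_promiscuous_dropped
            summary["n_targetless_dropped"] = tmap.n_targetless_dropped
            (outdir / f"depick_{screen.screen_id}.json").write_text(
                json.dumps(summary, indent=1)
            )
            manifest["stages"][f"depick_{screen.screen_id}"] = summary

    if "overlap" in cfg.stages:
        ds = DualScreen(
            ids_a=frozenset(screen_a.ids), actives_a=frozenset(screen_a.active),
            ids_b=frozenset(screen_b.ids), actives_b=frozenset(screen_b.active),
        )
        result = overlap_permutation_test(ds, n_perm=cfg.n_perm, seed=cfg.seed)
        result.to_json(outdir / "overlap.json")
        manifest["stages"]["overlap"] = {
            "observed": result.observed,
            "empirical_p": result.empirical_p,
            "analytic_p": result.analytic_p,
        }

    if "goenrich" in cfg.stages:
        ont = parse_obo(_require(indir / "ontology.obo", "goenrich"))
        ann = parse_annotations(_require(indir / "annotations.gaf", "goenrich"),
                                aspect=cfg.go_aspect)
        ann = propagate(ann, ont)
        study = read_id_list(_require(indir / "study_ids.txt", "goenrich"))
        background = read_id_list(_require(indir / "background_ids.txt", "goenrich"))
        table = attach_term_names(
            go_enrich(study, background, ann, fdr=cfg.fdr), ont
        )
        write_enrichment_tsv(table, outdir / "go_enrichment.tsv",
                             header_comment=header)
        manifest["stages"]["goenrich"] = {
            "n_terms_tested": int(len(table)),
            "n_significant": int(table["significant"].sum()) if len(table) else 0,
        }

    if "stats" in cfg.stages:
        from .screen_stats import hit_rate

        manifest["stages"]["stats"] = {
            "hit_rate_a": hit_rate(screen_a.n_active, screen_a.n_compounds),
            "hit_rate_b": hit_rate(screen_b.n_active, screen_b.n_compounds),
            "n_screened_a": screen_a.n_compounds,
            "n_screened_b": screen_b.n_compounds,
        }

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
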