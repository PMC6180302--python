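#!/usr/bin/env python
"""Generate the synthetic input bundle for the downstream analyses.

Writes a compound library, a reference association DB with planted
feature->target signal, two overlapping screens with a planted excess of
shared actives, and a mini GO DAG with a planted enriched branch.  The
bundle is an intermediate (regenerated on demand), so it lands in scratch/.
"""

import json
from pathlib import Path

from ccmscreen.synthetic_data import SimConfig, write_bundle

OUTDIR = Path(__file__).resolve().parents[1] / "scratch" / "inputs"
SEED = 1

cfg = SimConfig(seed=SEED)
paths = write_bundle(cfg, OUTDIR)

truth = json.loads((OUTDIR / "truth.json").read_text())
print(f"wrote input bundle to {OUTDIR}")
print(f"  screens: {cfg.n_screen_a} + {cfg.n_screen_b} compounds, "
      f"{cfg.n_shared} shared")
print(f"  reference DB: {cfg.n_db_compounds} compounds over {cfg.n_targets} targets")
print(f"  planted disease target(s): {truth['planted_targets']} "
      f"({len(truth['carriers'])} carrier compounds)")
print(f"  expected shared actives under the planted model: "
      f"{truth['expected_shared_actives']:.2f}")
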