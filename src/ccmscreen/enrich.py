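"""Shared hypergeometric-enrichment kernel with BH FDR control.

Both the target-deconvolution stage and the GO term analysis reduce to the
same question — is an annotation over-represented in a study set drawn from
a finite universe? — so both call this single implementation.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    N: universe size; K: annotated in universe; n: study size; k: annotated
    in study.  k = 0 gives p = 1 (the certain event).
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(f"inconsistent hypergeometric counts k={k} N={N} K={K} n={n}")
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def enrichment_table(counts: Iterable, n: int, N: int,
                     fdr: float = 0.10) -> pd.DataFrame:
    """Build an enrichment table from per-entity counts.

    ``counts`` yields (entity id, k observed in study, K in universe).
    Returns a DataFrame with columns entity/k/K/n/N/p/q/significant, sorted
    by (q, p, entity).  Entities with k = 0 are kept (p = 1) so the BH family
    does not shrink with the draw.
    """
    rows = [(str(e), int(k), int(K)) for (e, k, K) in counts]
    if not rows:
        return pd.DataFrame(
            columns=["entity", "k", "K", "n", "N", "p", "q", "significant"]
        )
    p = np.array([hypergeom_upper_tail(k, N, K, n) for (_e, k, K) in rows])
    q = bh_adjust(p)
    df = pd.DataFrame({
        "entity": [e for (e, _k, _K) in rows],
        "k": [k for (_e, k, _K) in rows],
        "K": [K for (_e, _k, K) in rows],
        "n": n,
        "N": N,
        "p": p,
        "q": q,
    })
    df["significant"] = df["q"] < fdr
    return df.sort_values(["q", "p", "entity"], kind="mergesort").reset_index(drop=True)


def write_enrichment_tsv(df: pd.DataFrame, path, header_comment: str = "") -> None:
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
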