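"""Significance of the shared-active overlap between two screens.

The observed statistic is the number of compounds active in both screens
among the compounds tested in both.  Its null distribution is obtained by
uniformly re-assigning screen A's active labels over screen A's compounds
(screen B's labels stay fixed, matching how the original analysis shuffled
only one screen).  Under that shuffle the shared-active count of a single
permutation is exactly a hypergeometric draw — the number of B-active shared
compounds caught in a uniform sample of |activesA| of screen A's compounds —
so the default implementation samples the count directly; a literal
label-shuffling path is retained for cross-checking.  The exact
hypergeometric upper tail is always reported alongside as an analytic
oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import hypergeom


@dataclass(frozen=True)
class DualScreen:
    """Two screens over partially overlapping compound sets."""

    ids_a: frozenset
    actives_a: frozenset
    ids_b: frozenset
    actives_b: frozenset

    def __post_init__(self):
        if not self.actives_a <= self.ids_a:
            raise ValueError("screen A actives not a subset of screen A compounds")
        if not self.actives_b <= self.ids_b:
            raise ValueError("screen B actives not a subset of screen B compounds")

    @property
    def shared(self) -> frozenset:
        return self.ids_a & self.ids_b

    @property
    def observed_shared_actives(self) -> int:
        return len(self.actives_a & self.actives_b & self.shared)

    @property
    def n_b_active_shared(self) -> int:
        return len(self.actives_b & self.shared)


def proportional_b_actives(n_shared: int, n_active_b: int, n_b: int) -> int:
    """Shared compounds assumed B-active when only screen totals are known.

    When the identity of screen B's actives within the shared set is not
    recorded, assign round(n_shared * n_active_b / n_b) of the shared
    compounds as B-active (proportional assumption; override with real
    membership lists when available).
    """
    if n_b <= 0:
        raise ValueError("screen B size must be positive")
    return round(n_shared * n_active_b / n_b)


def dual_screen_from_counts(n_a: int, n_active_a: int, n_shared: int,
                            n_b_active_shared: int, observed: int,
                            n_b: Optional[int] = None) -> DualScreen:
    """Materialize a DualScreen from printed screen dimensions.

    Synthetic ids are laid out so that the first ``n_shared`` compounds of
    screen A are the shared ones, the first ``n_b_active_shared`` of those
    are B-active, and the observed co-actives sit inside that block.
    """
    if not (0 <= observed <= min(n_active_a, n_b_active_shared, n_shared)):
        raise ValueError("observed shared actives exceed a logical maximum")
    ids_a = [f"A{i:05d}" for i in range(n_a)]
    shared = ids_a[:n_shared]
    b_active = shared[:n_b_active_shared]
    # A-actives: the observed co-actives, then fill up outside the B-active block
    actives_a = list(b_active[:observed])
    pool = [c for c in ids_a if c not in set(b_active)]
    actives_a += pool[: n_active_a - observed]
    if len(actives_a) < n_active_a:
        raise ValueError("cannot place A-actives at the requested observed count")
    n_b = n_b if n_b is not None else n_shared
    ids_b = shared + [f"B{i:05d}" for i in range(n_b - n_shared)]
    return DualScreen(
        ids_a=frozenset(ids_a),
        actives_a=frozenset(actives_a),
        ids_b=frozenset(ids_b),
        actives_b=frozenset(b_active),
    )


@dataclass(frozen=True)
class OverlapResult:
    observed: int
    null_mean: float
    empirical_p: float
    analytic_p: float
    n_perm: int
    seed: int
    method: str

    def summary_text(self) -> str:
        p_txt = (f"< {1.0 / self.n_perm:g}" if self.empirical_p == 0.0
                 else f"{self.empirical_p:g}")
        return (
            f"observed shared actives = {self.observed}; null mean = "
            f"{self.null_mean:.3f}; empirical p {p_txt} "
            f"({self.n_perm} permutations); analytic p = {self.analytic_p:.3g}"
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "observed": self.observed,
                "null_mean": self.null_mean,
                "empirical_p": self.empirical_p,
                "empirical_p_text": ("< " + format(1.0 / self.n_perm, "g"))
                if self.empirical_p == 0.0 else format(self.empirical_p, "g"),
                "analytic_p": self.analytic_p,
                "n_perm": self.n_perm,
                "seed": self.seed,
                "method": self.method,
            }, fh, indent=1)


def overlap_permutation_test(ds: DualScreen, n_perm: int = 1_000_000,
                             seed: int = 0, method: str = "draw",
                             shuffle_both: bool = False) -> OverlapResult:
    """Permutation p-value for the shared-active overlap.

    ``method="draw"`` samples each permutation's shared-active count as the
    equivalent hypergeometric draw; ``method="shuffle"`` permutes the label
    vector literally (O(n_A) per permutation, for validation and small runs).
    ``shuffle_both`` additionally re-draws which shared compounds are
    B-active in each permutation (both margins random).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    N = len(ds.ids_a)
    n = len(ds.actives_a)
    K = ds.n_b_active_shared
    observed = ds.observed_shared_actives
    if observed > min(n, K):
        raise ValueError("observed count exceeds logical maximum")
    rng = np.random.default_rng(seed)
    if method == "draw" and not shuffle_both:
        counts = rng.hypergeometric(K, N - K, n, size=n_perm)
    elif method in ("draw", "shuffle"):
        ids = sorted(ds.ids_a)
        b_active_shared = np.array(
            [cid in (ds.actives_b & ds.shared) for cid in ids]
        )
        counts = np.empty(n_perm, dtype=np.int64)
        n_b_act = K
        for i in range(n_perm):
            perm = rng.permutation(N)
            active_mask = np.zeros(N, dtype=bool)
            active_mask[perm[:n]] = True
            if shuffle_both:
                shared_idx = np.flatnonzero(
                    np.array([cid in ds.shared for cid in ids])
                )
                b_mask = np.zeros(N, dtype=bool)
                b_mask[rng.choice(shared_idx, size=n_b_act, replace=False)] = True
                counts[i] = int((active_mask & b_mask).sum())
            else:
                counts[i] = int((active_mask & b_active_shared).sum())
    else:
        raise ValueError(f"unknown method {method!r}")
    empirical = float((counts >= observed).sum() / n_perm)
    analytic = float(hypergeom.sf(observed - 1, N, K, n))
    return OverlapResult(
        observed=observed,
        null_mean=float(counts.mean()),
        empirical_p=empirical,
        analytic_p=analytic,
        n_perm=n_perm,
        seed=seed,
        method=method,
    )
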