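"""Auxiliary quantitative computations around the screens.

Hit rates, mean/SEM, pooled two-sample t-tests and one-way ANOVA with
Tukey's HSD computed from group summaries (label, mean, sample SD, n),
comparative-Ct (2^-ΔΔCt) relative expression, summary statistics of
protein-interaction edge lists, and bucketing of compounds into the MeSH
D27 "Chemical Actions and Uses" branches.

The summary-statistic entry points exist because published methods tables
report groups only as (mean, SD, n); the pooled-variance t-test and the
equal-n Tukey test are exactly recoverable from those summaries.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy import stats


def hit_rate(n_active: int, n_screened: int) -> float:
    """Percent active, rounded half-even to 1 decimal."""
    if n_screened <= 0:
        raise ValueError("n_screened must be positive")
    if not (0 <= n_active <= n_screened):
        raise ValueError("n_active must lie in [0, n_screened]")
    return round(100.0 * n_active / n_screened, 1)


def mean_sem(values: Sequence[float]) -> tuple:
    """(arithmetic mean, sample SD / sqrt(n)); SEM is 0 for n = 1."""
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("mean_sem requires at least one value")
    if vals.size == 1:
        warnings.warn("SEM undefined for n=1; returning 0 by convention")
        return float(vals[0]), 0.0
    return float(vals.mean()), float(vals.std(ddof=1) / math.sqrt(vals.size))


@dataclass(frozen=True)
class GroupSummary:
    label: str
    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 1:
            raise ValueError("n must be >= 1")

    @classmethod
    def from_values(cls, label: str, values: Sequence[float]) -> "GroupSummary":
        vals = np.asarray(values, dtype=float)
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        return cls(label, float(vals.mean()), sd, int(vals.size))


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    degenerate: bool = False


def pooled_t_test_summary(a: GroupSummary, b: GroupSummary) -> TTestResult:
    """Pooled-variance (Student) two-tailed t-test from group summaries."""
    if a.n < 2 or b.n < 2:
        raise ValueError("pooled t-test requires n >= 2 per group")
    df = a.n + b.n - 2
    if a.sd == 0.0 and b.sd == 0.0:
        if a.mean == b.mean:
            return TTestResult(t=0.0, df=df, p=1.0, degenerate=True)
        return TTestResult(t=math.inf, df=df, p=0.0, degenerate=True)
    t, p = stats.ttest_ind_from_stats(a.mean, a.sd, a.n, b.mean, b.sd, b.n,
                                      equal_var=True)
    return TTestResult(t=float(t), df=df, p=float(p))


@dataclass(frozen=True)
class TukeyPair:
    label_a: str
    label_b: str
    q: float
    p_adjusted: float


@dataclass(frozen=True)
class AnovaTukeyResult:
    f: float
    p_f: float
    df_between: int
    df_error: int
    mse: float
    pairs: tuple  # of TukeyPair


def anova_tukey_summary(groups: Sequence[GroupSummary]) -> AnovaTukeyResult:
    """One-way ANOVA and Tukey HSD adjusted p-values from group summaries.

    MSE pools the within-group variances; for equal n the studentized range
    statistic is q = |m_i - m_j| / sqrt(MSE/n), and for unequal n the
    Tukey–Kramer form q = |m_i - m_j| / sqrt(MSE/2 * (1/n_i + 1/n_j)) is
    used.  Adjusted p is the upper tail of the studentized range
    distribution with k groups and the pooled error df.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.n < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    k = len(groups)
    df_error = sum(g.n - 1 for g in groups)
    mse = sum((g.n - 1) * g.sd ** 2 for g in groups) / df_error
    n_total = sum(g.n for g in groups)
    grand = sum(g.n * g.mean for g in groups) / n_total
    ss_between = sum(g.n * (g.mean - grand) ** 2 for g in groups)
    df_between = k - 1
    means_equal = all(g.mean == groups[0].mean for g in groups)
    if mse == 0.0:
        if not means_equal:
            raise ValueError("MSE is 0 with unequal means: statistic is infinite")
        f, p_f = 0.0, 1.0
    else:
        f = (ss_between / df_between) / mse
        p_f = float(stats.f.sf(f, df_between, df_error))
    pairs = []
    for ga, gb in combinations(groups, 2):
        diff = abs(ga.mean - gb.mean)
        if mse == 0.0:
            q = 0.0
            p_adj = 1.0
        else:
            se = math.sqrt(mse / 2.0 * (1.0 / ga.n + 1.0 / gb.n))
            q = diff / se
            p_adj = float(stats.studentized_range.sf(q, k, df_error))
        pairs.append(TukeyPair(ga.label, gb.label, q, p_adj))
    return AnovaTukeyResult(f=float(f), p_f=p_f, df_between=df_between,
                            df_error=df_error, mse=mse, pairs=tuple(pairs))


def ddct_fold_change(ct_target_sample: float, ct_refs_sample: Sequence[float],
                     ct_target_calibrator: float,
                     ct_refs_calibrator: Sequence[float]) -> float:
    """2^-ΔΔCt relative expression against a calibrator condition.

    ΔCt = Ct_target - mean(Ct_references) per condition; the arithmetic mean
    of reference Cts equals the geometric mean of reference quantities on
    the linear scale, which is the standard multi-reference normalization.
    """
    refs_s = np.asarray(ct_refs_sample, dtype=float)
    refs_c = np.asarray(ct_refs_calibrator, dtype=float)
    if refs_s.size == 0 or refs_c.size == 0:
        raise ValueError("at least one reference Ct is required per condition")
    values = np.concatenate([refs_s, refs_c, [ct_target_sample, ct_target_calibrator]])
    if not np.isfinite(values).all():
        raise ValueError("all Ct values must be finite")
    dct_sample = ct_target_sample - refs_s.mean()
    dct_calib = ct_target_calibrator - refs_c.mean()
    return float(2.0 ** -(dct_sample - dct_calib))


@dataclass(frozen=True)
class NetworkSummary:
    n_nodes: int
    n_edges: int
    avg_degree: float
    avg_local_clustering: float


def network_summary(edges: Iterable, nodes: Iterable = ()) -> NetworkSummary:
    """Node/edge counts, average degree 2E/N and mean local clustering.

    ``edges`` is an iterable of (u, v) pairs; duplicates and self-loops are
    rejected.  ``nodes`` may add isolated nodes.  The local clustering of a
    node with degree < 2 counts as 0.
    """
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for u, v in edges:
        if u == v:
            raise ValueError(f"self-loop on node {u!r}")
        if g.has_edge(u, v):
            raise ValueError(f"duplicate edge ({u!r}, {v!r})")
        g.add_edge(u, v)
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    n, m = g.number_of_nodes(), g.number_of_edges()
    return NetworkSummary(
        n_nodes=n,
        n_edges=m,
        avg_degree=2.0 * m / n,
        avg_local_clustering=float(nx.average_clustering(g, count_zeros=True)),
    )


def read_edge_list(path) -> list:
    """TSV edge list: node_a TAB node_b; '#' lines are comments."""
    edges = []
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{line_no}: expected two tab-separated nodes")
        edges.append((parts[0], parts[1]))
    return edges


# ---------------------------------------------------------------------------
# MeSH D27 bucketing

MESH_BRANCHES = {
    "D27.505.519": "Molecular Mechanisms of Pharmacological Action",
    "D27.505.696": "Physiological Effects of Drugs",
    "D27.505.954": "Therapeutic Uses",
}

_TREE_NUMBER_CHARS = set("0123456789.")


@dataclass
class MeshBucketCounts:
    branch_compounds: dict     # branch prefix -> set of compound ids
    subcategory_compounds: dict  # depth+1 prefix -> set of compound ids
    unclassified: dict         # compound id -> set of unmatched/malformed numbers

    def branch_counts(self) -> dict:
        return {b: len(c) for b, c in sorted(self.branch_compounds.items())}

    def subcategory_counts(self) -> dict:
        return {s: len(c) for s, c in sorted(self.subcategory_compounds.items())}


def _valid_tree_number(tn: str) -> bool:
    if not tn or tn.startswith(".") or tn.endswith(".") or ".." in tn:
        return False
    head, _, rest = tn.partition(".")
    if not (head[:1] in "ABCDEFGHIJKLMNVZ" and head[1:].isdigit()):
        return False
    return all(part.isdigit() for part in rest.split(".")) if rest else True


def mesh_bucket(assignments: dict) -> MeshBucketCounts:
    """Route compound MeSH tree numbers into the three D27 branches.

    ``assignments`` maps compound id -> iterable of tree-number strings.  A
    compound is counted once per branch it touches (it may touch several);
    the subcategory tally keys on the branch prefix plus one more component.
    Malformed or non-D27 numbers are tallied as unclassified.
    """
    out = MeshBucketCounts(
        branch_compounds={b: set() for b in MESH_BRANCHES},
        subcategory_compounds={},
        unclassified={},
    )
    for cid in sorted(assignments):
        for tn in sorted(set(assignments[cid])):
            if not _valid_tree_number(tn):
                out.unclassified.setdefault(cid, set()).add(tn)
                continue
            branch = next(
                (b for b in MESH_BRANCHES if tn == b or tn.startswith(b + ".")),
                None,
            )
            if branch is None:
                out.unclassified.setdefault(cid, set()).add(tn)
                continue
            out.branch_compounds[branch].add(cid)
            rest = tn[len(branch):].lstrip(".")
            if rest:
                sub = f"{branch}.{rest.split('.')[0]}"
                out.subcategory_compounds.setdefault(sub, set()).add(cid)
    return out


def read_mesh_assignments(path) -> dict:
    """TSV: compound_id TAB tree_number (one row per assignment)."""
    out = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{line_no}: expected 'compound_id<TAB>tree_number'")
        out.setdefault(parts[0], set()).add(parts[1])
    return out
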