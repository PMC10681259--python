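"""Set overlaps, hypergeometric over-representation, and densitometry ratios.

The over-representation test is the one-sided upper-tail hypergeometric
(equivalently one-sided Fisher exact): for a query of n genes drawn from a
universe of N containing K category members, the p-value is P[X >= k].
The tail is summed in log space so p-values far below 1e-100 remain exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy import stats

from .riprank import bh_adjust

__all__ = [
    "GeneSet",
    "AnnotationTable",
    "OverlapResult",
    "hypergeometric_tail",
    "category_enrichment",
    "core_intersection",
    "overlap_count",
    "densitometry_fold_change",
]


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]

    @classmethod
    def from_iterable(cls, name: str, genes) -> "GeneSet":
        return cls(name, frozenset(genes))

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class AnnotationTable:
    """Gene -> category memberships over a stated universe."""

    universe: GeneSet
    categories: dict[str, GeneSet]

    def __post_init__(self) -> None:
        for name, cat in self.categories.items():
            extra = cat.genes - self.universe.genes
            if extra:
                raise ValidationError(
                    f"category {name!r} has {len(extra)} genes outside the universe"
                )


@dataclass
class OverlapResult:
    k: int  # observed overlap
    n: int  # query size
    K: int  # category/reference size
    N: int  # universe size
    expected: float
    p: float | None

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.n, self.K)):
            raise ValidationError("overlap k outside [0, min(n, K)]")


def _log_hypergeom_pmf(i: np.ndarray, N: int, K: int, n: int) -> np.ndarray:
    """log P[X = i] for X ~ Hypergeometric(N, K, n) via log-gamma."""
    i = np.asarray(i, float)

    def lchoose(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    return lchoose(K, i) + lchoose(N - K, n - i) - lchoose(N, n)


def hypergeometric_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail P[X >= k] for X ~ Hypergeometric(N, K, n), in log space.

    Parameters follow the urn convention: N genes in the universe, K in the
    category, n drawn; k observed in-category. k = 0 gives exactly 1.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValidationError("need 0 <= K <= N and 0 <= n <= N")
    if not (0 <= k <= min(n, K)):
        raise ValidationError("need 0 <= k <= min(n, K)")
    if k == 0:
        return 1.0
    lo = max(k, max(0, n - (N - K)))
    support = np.arange(lo, min(n, K) + 1)
    logp = logsumexp(_log_hypergeom_pmf(support, N, K, n))
    return float(min(1.0, np.exp(logp)))


def category_enrichment(
    query: GeneSet, ann: AnnotationTable
) -> tuple[pd.DataFrame, int]:
    """Per-category overlap and upper-tail hypergeometric p, BH-adjusted.

    Query genes outside the universe are dropped; their count is returned so
    the caller can warn. The ``query_fraction`` column is k/n — the headline
    composition figure (e.g. "24% of selected mRNAs are in the category").
    """
    N = len(ann.universe)
    if N == 0:
        raise ValidationError("empty universe")
    inside = query.genes & ann.universe.genes
    dropped = len(query.genes) - len(inside)
    n = len(inside)
    rows = []
    for name, cat in ann.categories.items():
        K = len(cat)
        k = len(inside & cat.genes)
        p = hypergeometric_tail(N, K, n, k) if n else 1.0
        rows.append(
            {
                "category": name,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "expected": n * K / N,
                "query_fraction": k / n if n else 0.0,
                "p": p,
            }
        )
    table = pd.DataFrame(rows)
    table["padj"] = bh_adjust(table["p"].to_numpy()) if len(table) else []
    return table, dropped


def core_intersection(sets: list[GeneSet], name: str = "core") -> GeneSet:
    """Exact intersection of one or more gene sets (e.g. the genes bound in
    every one of several published binding datasets)."""
    if not sets:
        raise ValidationError("need at least one set")
    genes = set(sets[0].genes)
    for s in sets[1:]:
        genes &= s.genes
    return GeneSet.from_iterable(name, sorted(genes))


def overlap_count(
    a: GeneSet, b: GeneSet, universe: GeneSet | None = None
) -> OverlapResult:
    """Overlap of two gene sets; hypergeometric p only when a universe is given."""
    k = len(a.genes & b.genes)
    if universe is None:
        return OverlapResult(k=k, n=len(a), K=len(b), N=0, expected=float("nan"), p=None)
    if not a.genes <= universe.genes or not b.genes <= universe.genes:
        raise ValidationError("sets must be subsets of the universe")
    N, n, K = len(universe), len(a), len(b)
    return OverlapResult(
        k=k, n=n, K=K, N=N, expected=n * K / N, p=hypergeometric_tail(N, K, n, k)
    )


def densitometry_fold_change(table: pd.DataFrame) -> dict:
    """Fold change of band intensities relative to a loading reference.

    ``table`` needs columns ``condition`` ("overexpression"/"control"),
    ``target`` and ``reference`` (positive band signals per lane). Relative
    abundance is target/reference per lane; each overexpression replicate's
    fold change is its relative abundance over the mean control relative
    abundance. A two-sided one-sample t-test of the log fold changes against
    0 gives the p-value.
    """
    required = {"condition", "target", "reference"}
    if not required <= set(table.columns):
        raise ValidationError(f"table needs columns {sorted(required)}")
    if np.any(table["reference"].to_numpy(float) <= 0):
        raise ValidationError("zero or negative reference signal")
    if np.any(table["target"].to_numpy(float) <= 0):
        raise ValidationError("zero or negative target signal")
    rel = table["target"].to_numpy(float) / table["reference"].to_numpy(float)
    cond = table["condition"].to_numpy()
    oe = rel[cond == "overexpression"]
    ctrl = rel[cond == "control"]
    if oe.size < 3 or ctrl.size < 3:
        raise ValidationError("need >= 3 replicates per condition")
    fc = oe / ctrl.mean()
    logfc = np.log(fc)
    if np.allclose(logfc.var(ddof=1), 0.0) and np.allclose(logfc.mean(), 0.0):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_1samp(logfc, 0.0)
    return {
        "mean_fold_change": float(fc.mean()),
        "fold_changes": fc.tolist(),
        "t": float(t),
        "p": float(p),
    }
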