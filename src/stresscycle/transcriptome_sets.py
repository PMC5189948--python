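"""Directional fold-change gene sets and regulon-overlap significance.

A stress/non-stress comparison is reduced to two gene sets — genes induced
more than ``up_cutoff``-fold and genes repressed below ``down_cutoff`` — and
the similarity of two comparisons is scored as the number of standard
deviations by which their observed set intersection exceeds the intersection
of same-sized random gene sets drawn from a common universe.  The null is
estimated by Monte-Carlo resampling; because the intersection of two
independent uniform random subsets is hypergeometric, a closed-form analytic
version of the same statistic is provided as an independent cross-check.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "FoldChangeTable",
    "DirectionalGeneSets",
    "OverlapResult",
    "compute_fold_changes",
    "classify_directional_sets",
    "mc_intersection_zscore",
    "analytic_intersection_zscore",
    "compare_conditions",
]


@dataclass(frozen=True)
class FoldChangeTable:
    """Per-gene expression ratios (stress / non-stress) for one comparison.

    ``entries`` maps gene identifiers (opaque, case-sensitive strings) to
    finite, strictly positive fold-changes.  ``n_excluded`` counts genes that
    were dropped during construction (missing in one input table, or with a
    non-positive / non-finite ratio).
    """

    comparison_label: str
    entries: dict[str, float]
    n_excluded: int = 0

    def __post_init__(self) -> None:
        for gene, fc in self.entries.items():
            if not (math.isfinite(fc) and fc > 0):
                raise ValueError(
                    f"fold-change for gene {gene!r} must be finite and > 0, got {fc!r}"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def genes(self) -> set[str]:
        return set(self.entries)


@dataclass(frozen=True)
class DirectionalGeneSets:
    """Up- and down-regulated gene sets plus the universe they came from."""

    up: frozenset[str]
    down: frozenset[str]
    universe: frozenset[str]
    up_cutoff: float = 2.0
    down_cutoff: float = 0.5

    def __post_init__(self) -> None:
        if not (self.up_cutoff > 1 > self.down_cutoff > 0):
            raise ValueError(
                "cutoffs must satisfy up_cutoff > 1 > down_cutoff > 0, got "
                f"{self.up_cutoff} / {self.down_cutoff}"
            )
        if not self.up <= self.universe or not self.down <= self.universe:
            raise ValueError("up and down sets must be subsets of the universe")
        if self.up & self.down:
            raise ValueError("up and down sets must be disjoint")

    @property
    def unclassified(self) -> frozenset[str]:
        return self.universe - self.up - self.down


@dataclass(frozen=True)
class OverlapResult:
    """Observed set intersection against a random-intersection null.

    ``z`` is ``(k_observed - null_mean) / null_sd``; it is ``None`` when the
    null is degenerate (zero standard deviation), in which case
    ``degenerate`` is set instead of reporting a non-number.
    """

    n1: int
    n2: int
    N: int
    k_observed: int
    null_mean: float
    null_sd: float
    z: float | None
    n_mc: int | None
    seed: int | None
    method: str
    degenerate: bool = False
    set1_label: str = ""
    set2_label: str = ""
    direction: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.k_observed <= min(self.n1, self.n2)):
            raise ValueError("k_observed must lie in [0, min(n1, n2)]")
        if max(self.n1, self.n2) > self.N:
            raise ValueError("set sizes cannot exceed the universe size")
        if self.null_sd < 0:
            raise ValueError("null_sd must be non-negative")
        if self.degenerate and self.z is not None:
            raise ValueError("degenerate results must not carry a z value")


def compute_fold_changes(
    expr_stress: Mapping[str, float],
    expr_control: Mapping[str, float],
    pseudocount: float = 0.0,
    comparison_label: str = "",
) -> FoldChangeTable:
    """Per-gene ratio (stress + pseudocount) / (control + pseudocount).

    Genes absent from either table are dropped; genes whose shifted control
    value is zero, or whose ratio is non-positive or non-finite, are excluded.
    Both counts are logged and summed into ``FoldChangeTable.n_excluded``.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    common = expr_stress.keys() & expr_control.keys()
    if not common:
        raise ValueError("no common genes between the two expression tables")
    n_dropped = (len(expr_stress) - len(common)) + (len(expr_control) - len(common))
    entries: dict[str, float] = {}
    n_bad = 0
    for gene in common:
        num = expr_stress[gene] + pseudocount
        den = expr_control[gene] + pseudocount
        if den == 0:
            n_bad += 1
            continue
        fc = num / den
        if not (math.isfinite(fc) and fc > 0):
            n_bad += 1
            continue
        entries[gene] = fc
    if n_dropped or n_bad:
        logger.info(
            "compute_fold_changes(%s): dropped %d genes absent from one table, "
            "excluded %d with undefined or non-positive ratios",
            comparison_label, n_dropped, n_bad,
        )
    return FoldChangeTable(comparison_label, entries, n_excluded=n_dropped + n_bad)


def classify_directional_sets(
    fc: FoldChangeTable,
    up_cutoff: float = 2.0,
    down_cutoff: float = 0.5,
) -> DirectionalGeneSets:
    """Split a fold-change table into up / down / unchanged gene sets.

    Cutoffs are strict: a gene with a ratio exactly equal to a cutoff belongs
    to neither directional set.  Defaults are the conventional two-fold
    cutoffs (ratio > 2 up, ratio < 0.5 down).
    """
    if len(fc) == 0:
        raise ValueError("cannot classify an empty fold-change table")
    if not (up_cutoff > 1 > down_cutoff > 0):
        raise ValueError("cutoffs must satisfy up_cutoff > 1 > down_cutoff > 0")
    up = frozenset(g for g, v in fc.entries.items() if v > up_cutoff)
    down = frozenset(g for g, v in fc.entries.items() if v < down_cutoff)
    return DirectionalGeneSets(
        up=up,
        down=down,
        universe=frozenset(fc.entries),
        up_cutoff=up_cutoff,
        down_cutoff=down_cutoff,
    )


def _random_subset_masks(
    rng: np.random.Generator, n_rows: int, N: int, n: int
) -> np.ndarray:
    """Boolean indicator matrix: each row a uniform random n-subset of range(N)."""
    if n == 0:
        return np.zeros((n_rows, N), dtype=bool)
    if n == N:
        return np.ones((n_rows, N), dtype=bool)
    u = rng.random((n_rows, N))
    idx = np.argpartition(u, n - 1, axis=1)[:, :n]
    mask = np.zeros((n_rows, N), dtype=bool)
    np.put_along_axis(mask, idx, True, axis=1)
    return mask


def sample_null_intersections(
    N: int,
    n1: int,
    n2: int,
    n_mc: int,
    rng: np.random.Generator,
    chunk: int = 4096,
) -> np.ndarray:
    """Monte-Carlo sample of |A ∩ B| for independent uniform random subsets.

    Both subsets are redrawn in every iteration (fully random null).  The
    marginal distribution is Hypergeometric(N, n1, n2), which is what
    :func:`analytic_intersection_zscore` evaluates in closed form.
    """
    out = np.empty(n_mc, dtype=np.int64)
    done = 0
    while done < n_mc:
        m = min(chunk, n_mc - done)
        a = _random_subset_masks(rng, m, N, n1)
        b = _random_subset_masks(rng, m, N, n2)
        out[done : done + m] = np.count_nonzero(a & b, axis=1)
        done += m
    return out


def mc_intersection_zscore(
    setA: Iterable[str],
    setB: Iterable[str],
    universe: Iterable[str],
    n_mc: int = 10_000,
    seed: int = 0,
    **labels: str,
) -> OverlapResult:
    """Monte-Carlo z-score for the overlap of two gene sets.

    In each of ``n_mc`` iterations two independent uniform random subsets of
    sizes |setA| and |setB| are drawn (without replacement) from the universe
    and their intersection size recorded.  The z-score is the observed
    intersection expressed in sample standard deviations (n-1 denominator)
    of that null sample.  Fixed seed implies bit-identical results.
    """
    A, B, U = set(setA), set(setB), set(universe)
    if not A <= U or not B <= U:
        raise ValueError("setA and setB must be subsets of the universe")
    if n_mc < 2:
        raise ValueError("n_mc must be at least 2")
    n1, n2, N = len(A), len(B), len(U)
    k_obs = len(A & B)
    rng = np.random.default_rng(seed)
    sizes = sample_null_intersections(N, n1, n2, n_mc, rng)
    null_mean = float(np.mean(sizes))
    null_sd = float(np.std(sizes, ddof=1))
    degenerate = null_sd == 0.0
    z = None if degenerate else (k_obs - null_mean) / null_sd
    return OverlapResult(
        n1=n1, n2=n2, N=N, k_observed=k_obs,
        null_mean=null_mean, null_sd=null_sd, z=z,
        n_mc=n_mc, seed=seed, method="monte_carlo",
        degenerate=degenerate, **labels,
    )


def analytic_intersection_zscore(
    n1: int, n2: int, N: int, k_observed: int, **labels: str
) -> OverlapResult:
    """Closed-form z-score under the hypergeometric random-intersection null.

    For independent uniform random subsets of sizes n1 and n2 of an N-gene
    universe the intersection size is Hypergeometric(N, n1, n2):
    mean n1*n2/N and variance n1*n2*(N-n1)*(N-n2) / (N^2*(N-1)).
    """
    if N < 2:
        raise ValueError("universe must contain at least 2 genes")
    if not (0 <= n1 <= N and 0 <= n2 <= N):
        raise ValueError("set sizes must lie in [0, N]")
    if not (0 <= k_observed <= min(n1, n2)):
        raise ValueError("k_observed must lie in [0, min(n1, n2)]")
    null_mean = n1 * n2 / N
    null_var = n1 * n2 * (N - n1) * (N - n2) / (N**2 * (N - 1))
    null_sd = math.sqrt(null_var)
    degenerate = null_sd == 0.0
    z = None if degenerate else (k_observed - null_mean) / null_sd
    return OverlapResult(
        n1=n1, n2=n2, N=N, k_observed=k_observed,
        null_mean=null_mean, null_sd=null_sd, z=z,
        n_mc=None, seed=None, method="analytic",
        degenerate=degenerate, **labels,
    )


def compare_conditions(
    dataset1: FoldChangeTable,
    dataset2: FoldChangeTable,
    up_cutoff: float = 2.0,
    down_cutoff: float = 0.5,
    n_mc: int = 10_000,
    seed: int = 0,
    universe: str = "intersection",
    method: str = "monte_carlo",
) -> tuple[OverlapResult, OverlapResult]:
    """Regulon similarity between two comparisons: up-vs-up and down-vs-down.

    The null universe defaults to the genes measured in *both* tables, so
    that data sets profiled on different platforms (RNA-seq vs microarray)
    are compared over genes each could have detected; ``universe="union"``
    uses all genes seen in either table instead.  Each table is classified
    with the given cutoffs restricted to the universe, and one
    :class:`OverlapResult` is returned per direction.
    """
    g1, g2 = dataset1.genes(), dataset2.genes()
    if universe == "intersection":
        U = g1 & g2
    elif universe == "union":
        U = g1 | g2
    else:
        raise ValueError("universe must be 'intersection' or 'union'")
    if len(U) < 2:
        raise ValueError("the two tables must share at least 2 genes")

    def _restrict(tab: FoldChangeTable) -> DirectionalGeneSets:
        kept = {g: v for g, v in tab.entries.items() if g in U}
        sets = classify_directional_sets(
            FoldChangeTable(tab.comparison_label, kept), up_cutoff, down_cutoff
        )
        # re-anchor on the comparison universe (matters in union mode)
        return DirectionalGeneSets(sets.up, sets.down, frozenset(U), up_cutoff, down_cutoff)

    s1, s2 = _restrict(dataset1), _restrict(dataset2)
    labels = dict(set1_label=dataset1.comparison_label, set2_label=dataset2.comparison_label)

    results = []
    for direction, a, b, child_seed in (
        ("up", s1.up, s2.up, seed),
        ("down", s1.down, s2.down, seed + 1),
    ):
        if method == "monte_carlo":
            res = mc_intersection_zscore(
                a, b, U, n_mc=n_mc, seed=child_seed, direction=direction, **labels
            )
        elif method == "analytic":
            res = analytic_intersection_zscore(
                len(a), len(b), len(U), len(a & b), direction=direction, **labels
            )
        else:
            raise ValueError("method must be 'monte_carlo' or 'analytic'")
        results.append(res)
    return results[0], results[1]
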