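"""Significance analysis of entropy rates between and within sample classes.

Between-class differences use the two-sided Wilcoxon rank-sum
(Mann-Whitney U) test: exact null distribution for combined n <= 20,
normal approximation with continuity correction otherwise.  Within-class
stability is probed by repeatedly splitting one class into disjoint random
halves and testing those against each other — a well-behaved pipeline
should show no signal there.

A grid evaluation (dataset x PIN x correction method x threshold) tallies
two error types at a significance level alpha: a *between-class* error is
a grid cell where the true class difference is no longer significant; a
*within-class* error is a cell where the half-vs-half comparison becomes
significant.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .correction import ReliabilityScores, filter_network
from .entropy import ExpressionMatrix, IntegratedSystem, entropy_table, integrate
from .network import InteractionNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "ComparisonResult",
    "ErrorCounts",
    "LabelledSystem",
    "compare_groups",
    "within_class_null",
    "evaluation_grid",
    "recount_errors",
]


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of a two-group entropy comparison."""

    p_value: float
    test: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


@dataclass
class ErrorCounts:
    """Cumulative error tallies per (PIN, correction method)."""

    alpha: float
    between_errors: dict[tuple[str, str], int] = field(default_factory=dict)
    within_errors: dict[tuple[str, str], int] = field(default_factory=dict)
    na_cells: dict[tuple[str, str], int] = field(default_factory=dict)
    n_cells: dict[tuple[str, str], int] = field(default_factory=dict)


@dataclass
class LabelledSystem:
    """A dataset/PIN combination with two-class sample labels."""

    dataset: str
    pin: str
    network: InteractionNetwork
    expression: ExpressionMatrix
    classes: Mapping[str, str]  # sample -> class label
    reference_class: str | None = None  # class used for within-class nulls

    def class_labels(self) -> list[str]:
        return sorted(set(self.classes.values()))

    def samples_of(self, label: str) -> list[str]:
        return [s for s in self.expression.samples if self.classes.get(s) == label]


EXACT_LIMIT = 20


def compare_groups(
    entropies_a: Sequence[float],
    entropies_b: Sequence[float],
    test: str = "wilcoxon",
) -> ComparisonResult:
    """Two-sided comparison of per-sample entropy rates.

    Default is the Wilcoxon rank-sum test (exact for combined n <= 20,
    normal approximation with continuity correction beyond); ``test="ttest"``
    selects Welch's t-test instead.
    """
    a = np.asarray(entropies_a, dtype=float)
    b = np.asarray(entropies_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if test == "wilcoxon":
        method = "exact" if a.size + b.size <= EXACT_LIMIT else "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
        name = f"wilcoxon-{method}"
    elif test == "ttest":
        res = sps.ttest_ind(a, b, equal_var=False)
        name = "welch-ttest"
    else:
        raise ValueError(f"unknown test {test!r}")
    return ComparisonResult(
        p_value=float(min(1.0, res.pvalue)),
        test=name,
        n_a=a.size,
        n_b=b.size,
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
    )


def within_class_null(
    entropies: Sequence[float],
    repetitions: int = 50,
    seed: int = 0,
    test: str = "wilcoxon",
) -> tuple[np.ndarray, float]:
    """Half-vs-half null comparisons within one class.

    Each repetition splits the class into two disjoint random halves of
    size floor(n/2) and applies :func:`compare_groups`.  Returns all
    p-values and their median.
    """
    values = np.asarray(entropies, dtype=float)
    n = values.size
    if n < 4:
        raise ValueError("within-class null needs at least 4 samples")
    half = n // 2
    rng = np.random.default_rng(seed)
    pvals = np.empty(repetitions)
    for r in range(repetitions):
        perm = rng.permutation(n)
        pvals[r] = compare_groups(values[perm[:half]], values[perm[half : 2 * half]], test=test).p_value
    return pvals, float(np.median(pvals))


def _sr_neq_by_class(
    net: InteractionNetwork, sys_: LabelledSystem
) -> tuple[dict[str, np.ndarray], int]:
    system = integrate(net, sys_.expression)
    table = entropy_table(system, measures=("neq",))
    out = {}
    for label in sys_.class_labels():
        samples = sys_.samples_of(label)
        out[label] = table.loc[samples, "sr_neq"].to_numpy()
    return out, system.network.n_edges


def evaluation_grid(
    systems: Sequence[LabelledSystem],
    corrections: Sequence[ReliabilityScores],
    thresholds: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
    alpha: float = 0.05,
    repetitions: int = 50,
    seed: int = 0,
    include_baseline: bool = True,
) -> tuple[pd.DataFrame, ErrorCounts]:
    """Between- and within-class significance across a filtering grid.

    For each (dataset, PIN) system, correction method, and threshold the
    network is filtered, the non-equilibrium entropy rate recomputed, the
    two classes compared, and the reference class probed with the
    within-class null.  An uncorrected baseline row (threshold ``none``)
    is included per system.  Cells whose filtered network cannot be
    integrated are marked NA and counted separately.
    """
    rows = []
    counts = ErrorCounts(alpha=alpha)

    def record(sys_: LabelledSystem, method: str, thr_label: str, net: InteractionNetwork) -> None:
        key = (sys_.pin, method)
        counts.n_cells[key] = counts.n_cells.get(key, 0) + 1
        labels = sys_.class_labels()
        if len(labels) != 2:
            raise ValueError(f"system {sys_.dataset}/{sys_.pin} must have exactly 2 classes")
        ref = sys_.reference_class or labels[0]
        row = {
            "dataset": sys_.dataset,
            "pin": sys_.pin,
            "method": method,
            "threshold": thr_label,
            "p_between": math.nan,
            "p_within_median": math.nan,
            "n_edges_after_filter": 0,
            "na_flag": False,
        }
        try:
            if net.n_edges == 0:
                raise ValueError("empty network")
            by_class, n_edges = _sr_neq_by_class(net, sys_)
            row["n_edges_after_filter"] = n_edges
            res = compare_groups(by_class[labels[0]], by_class[labels[1]])
            cell_key = f"{sys_.dataset}|{sys_.pin}|{method}|{thr_label}".encode()
            cell_seed = (seed + zlib.crc32(cell_key)) % 2**31
            _, p_within = within_class_null(by_class[ref], repetitions=repetitions, seed=cell_seed)
            row["p_between"] = res.p_value
            row["p_within_median"] = p_within
            if res.p_value >= alpha:
                counts.between_errors[key] = counts.between_errors.get(key, 0) + 1
            if p_within < alpha:
                counts.within_errors[key] = counts.within_errors.get(key, 0) + 1
        except (ValueError, KeyError) as exc:
            logger.warning(
                "grid cell (%s, %s, %s, %s) is NA: %s", sys_.dataset, sys_.pin, method, thr_label, exc
            )
            row["na_flag"] = True
            counts.na_cells[key] = counts.na_cells.get(key, 0) + 1
        rows.append(row)

    for sys_ in systems:
        if include_baseline:
            record(sys_, "none", "none", sys_.network)
        for scores in corrections:
            for thr in thresholds:
                net, _ = filter_network(sys_.network, scores, thr)
                record(sys_, scores.method or "scores", f"{thr:g}", net)
    grid = pd.DataFrame(rows)
    return grid, counts


def recount_errors(grid: pd.DataFrame, alpha: float = 0.05) -> ErrorCounts:
    """Recompute error tallies from an emitted p-value grid (used as a
    self-consistency check against :func:`evaluation_grid`)."""
    counts = ErrorCounts(alpha=alpha)
    for _, row in grid.iterrows():
        key = (row["pin"], row["method"])
        counts.n_cells[key] = counts.n_cells.get(key, 0) + 1
        if row["na_flag"]:
            counts.na_cells[key] = counts.na_cells.get(key, 0) + 1
            continue
        if row["p_between"] >= alpha:
            counts.between_errors[key] = counts.between_errors.get(key, 0) + 1
        if row["p_within_median"] < alpha:
            counts.within_errors[key] = counts.within_errors.get(key, 0) + 1
    return counts
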