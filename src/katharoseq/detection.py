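"""Limit of detection: rank tests of titration levels against negatives.

Each titration level (known cell input) is compared against the pooled
negative controls with a two-group Kruskal-Wallis test on either the
target composition or the read depth; Benjamini-Hochberg step-up across
the levels of one metric controls the false-discovery rate at ``alpha``
(default 0.05).  The limit of detection is the smallest level from which
every level upward is significant — requiring the whole upper tail avoids
non-monotone detection claims.

For tiny comparisons (total n < 8) the chi-square approximation to the
Kruskal-Wallis null is poor, and an exact permutation p-value over all
group assignments is used instead.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .composition import CompositionPoint
from .errors import MissingControlsError, ValidationError

logger = logging.getLogger(__name__)

EXACT_N_THRESHOLD = 8


def _kw_statistic(values: np.ndarray, sizes: Sequence[int]) -> float:
    """Tie-corrected Kruskal-Wallis H for groups concatenated in `values`."""
    n = len(values)
    ranks = stats.rankdata(values)
    h = 0.0
    start = 0
    for size in sizes:
        rsum = ranks[start : start + size].sum()
        h += rsum * rsum / size
        start += size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, counts = np.unique(values, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    if tie == 0:
        return 0.0
    return h / tie


@lru_cache(maxsize=64)
def _two_group_splits(n: int, n1: int) -> np.ndarray:
    return np.array(list(combinations(range(n), n1)), dtype=np.intp)


def kruskal_wallis(
    groups: Sequence[Sequence[float]], method: str = "asymptotic"
) -> Tuple[float, float]:
    """Kruskal-Wallis H and p-value for two or more groups.

    ``method='asymptotic'`` uses midranks with tie correction and the
    chi-square approximation with groups-1 degrees of freedom (via scipy);
    ``'exact'`` (two groups only) enumerates every assignment of the pooled
    observations to the two group sizes and returns P(H >= observed);
    ``'auto'`` picks exact when the total sample size is below
    ``EXACT_N_THRESHOLD`` and there are two groups.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(a) == 0 for a in arrays):
        raise ValidationError("need >= 2 nonempty groups")
    pooled = np.concatenate(arrays)
    if len(pooled) < 3:
        raise ValidationError("need total n >= 3")
    if np.ptp(pooled) == 0.0:
        return 0.0, 1.0
    if method == "auto":
        method = (
            "exact"
            if len(arrays) == 2 and len(pooled) < EXACT_N_THRESHOLD
            else "asymptotic"
        )
    if method == "asymptotic":
        h, p = stats.kruskal(*arrays)
        return float(h), float(p)
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")
    if len(arrays) != 2:
        raise ValidationError("exact permutation p-value supports two groups only")
    sizes = [len(a) for a in arrays]
    h_obs = _kw_statistic(pooled, sizes)
    splits = _two_group_splits(len(pooled), sizes[0])
    ranks = stats.rankdata(pooled)
    n = len(pooled)
    rsum1 = ranks[splits].sum(axis=1)
    rsum2 = ranks.sum() - rsum1
    h_all = 12.0 / (n * (n + 1)) * (
        rsum1**2 / sizes[0] + rsum2**2 / sizes[1]
    ) - 3.0 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    h_all = h_all / tie
    p = float(np.mean(h_all >= h_obs - 1e-12))
    return float(h_obs), p


def bh_adjust(
    p_values: Sequence[float], alpha: float = 0.05
) -> Tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: reject all ordered p(i) with i <= i*,
    i* = max{i : p(i) <= i*alpha/m} (boundary inclusive).

    Returns ``(reject, q_values)``; empty input yields empty arrays.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return np.asarray(reject, dtype=bool), np.asarray(q, dtype=float)


@dataclass(frozen=True)
class LevelTest:
    """One titration level's comparison against the pooled negatives."""

    input_cells: float
    n: int
    kw_statistic: Optional[float]
    p_value: Optional[float]
    q_value: Optional[float]
    rejected: Optional[bool]
    testable: bool = True


@dataclass
class LodResult:
    """Per-level test results and the resulting limit of detection.

    ``lod_cells`` is the smallest titration level that is significant with
    every larger level also significant, or None when no such level exists.
    """

    metric: str
    alpha: float
    per_level: List[LevelTest] = field(default_factory=list)
    lod_cells: Optional[float] = None

    def to_json(self) -> str:
        from dataclasses import asdict

        return json.dumps(
            {
                "metric": self.metric,
                "alpha": self.alpha,
                "lod_cells": self.lod_cells,
                "per_level": [asdict(t) for t in self.per_level],
            },
            sort_keys=True,
        )

    def to_tsv(self) -> str:
        lines = ["input_cells\tn\tkw_statistic\tp_value\tq_value\trejected\ttestable"]
        for t in self.per_level:
            lines.append(
                "\t".join(
                    _fmt(v)
                    for v in (
                        t.input_cells,
                        t.n,
                        t.kw_statistic,
                        t.p_value,
                        t.q_value,
                        t.rejected,
                        t.testable,
                    )
                )
            )
        return "\n".join(lines) + "\n"


def _fmt(v) -> str:
    if v is None:
        return "NA"
    if isinstance(v, bool):
        return str(v)
    if isinstance(v, float):
        return repr(v)
    return str(v)


def limit_of_detection(
    positives: Iterable[CompositionPoint],
    negatives: Iterable[CompositionPoint],
    metric: str = "target_fraction",
    alpha: float = 0.05,
) -> LodResult:
    """Determine the limit of detection of a titration experiment.

    Each level with at least two usable points is tested against the
    pooled negatives; levels with fewer points are marked untestable and
    excluded from the BH family (and logged).
    """
    positives = list(positives)
    negatives = list(negatives)
    neg_values = np.array([p.metric(metric) for p in negatives], dtype=float)
    if len(neg_values) < 2:
        raise MissingControlsError("limit_of_detection needs >= 2 negative controls")
    by_level: dict = {}
    for p in positives:
        if p.input_cells is None:
            raise ValidationError(f"positive point {p.sample_id!r} lacks input_cells")
        by_level.setdefault(float(p.input_cells), []).append(p.metric(metric))
    if len(by_level) < 2:
        raise MissingControlsError("limit_of_detection needs >= 2 titration levels")

    levels = sorted(by_level)
    testable_levels, stats_p = [], []
    untestable = []
    for level in levels:
        values = np.array(by_level[level], dtype=float)
        if len(values) < 2:
            logger.warning(
                "titration level %g has %d usable point(s); untestable, "
                "excluded from the FDR family",
                level,
                len(values),
            )
            untestable.append((level, len(values)))
            continue
        h, p = kruskal_wallis([values, neg_values], method="auto")
        testable_levels.append((level, len(values)))
        stats_p.append((h, p))

    reject, q = bh_adjust([p for _, p in stats_p], alpha=alpha)

    per_level: List[LevelTest] = []
    rejected_by_level = {}
    for (level, n), (h, p), rej, qv in zip(testable_levels, stats_p, reject, q):
        per_level.append(
            LevelTest(
                input_cells=level,
                n=n,
                kw_statistic=h,
                p_value=p,
                q_value=float(qv),
                rejected=bool(rej),
            )
        )
        rejected_by_level[level] = bool(rej)
    for level, n in untestable:
        per_level.append(
            LevelTest(
                input_cells=level,
                n=n,
                kw_statistic=None,
                p_value=None,
                q_value=None,
                rejected=None,
                testable=False,
            )
        )
    per_level.sort(key=lambda t: t.input_cells)

    lod: Optional[float] = None
    tested = [lvl for lvl, _ in testable_levels]
    for i, level in enumerate(tested):
        if all(rejected_by_level[l] for l in tested[i:]):
            lod = level
            break
    return LodResult(metric=metric, alpha=alpha, per_level=per_level, lod_cells=lod)
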