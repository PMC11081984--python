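"""Alveolus-level positivity analyses: grading, sampling, neighbours, dimensions.

An alveolus is graded by the fraction of its luminal epithelial cells that are
marker-positive: grade 1 for fractions up to 25%, grade 2 for (25%, 50%],
grade 3 for (50%, 75%], grade 4 above 75%.  An alveolus counts as "positive"
when it shows any degree of positivity (at least one positive luminal
epithelial cell).  The neighbour analysis asks, for randomly selected seed
alveoli of each stratum, what percentage of their immediately adjacent
alveoli (same lobule) are positive; strata are compared with a two-sided
Mann-Whitney rank test.  The same rank comparison applied to lumen
dimensions acts as a calibrated null when dimensions are label-independent.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.stats import mannwhitneyu, rankdata

from .errors import ComputationError, ConfigError
from .lcq_core import PointPattern
from .synthetic_tissue import Alveolus, LobuleAdjacency

__all__ = [
    "AlveolusGrade",
    "NeighbourStat",
    "GroupComparison",
    "grade_alveolus",
    "grade_alveoli",
    "sample_alveoli",
    "GradeDistribution",
    "grade_distribution",
    "neighbour_positivity",
    "neighbour_table",
    "compare_neighbour_positivity",
    "compare_dimensions",
    "rank_compare",
]

logger = logging.getLogger(__name__)

# Grade boundaries on the positive fraction; half-open above so the printed
# anchor percentages 25/50/75 map to grades 1/2/3.
_GRADE_EDGES = (0.25, 0.50, 0.75)

#: Largest number of group assignments enumerated by the exact rank test.
EXACT_ENUMERATION_LIMIT = 20_000


@dataclass(frozen=True)
class AlveolusGrade:
    alveolus_id: int
    n_epithelial: int
    n_positive: int
    fraction_positive: float
    grade: int
    any_positive: bool


@dataclass(frozen=True)
class NeighbourStat:
    """Positivity of the immediately adjacent alveoli of one seed alveolus."""

    seed_alveolus_id: int
    n_neighbours: int
    n_positive_neighbours: int
    pct_positive_neighbours: float


@dataclass(frozen=True)
class GroupComparison:
    test_name: str
    statistic: float
    p_value: float
    group_sizes: tuple[int, int]
    group_means: tuple[float, float]


def grade_alveolus(n_positive: int, n_epithelial: int, alveolus_id: int = 0) -> AlveolusGrade:
    """Grade one alveolus from its luminal-epithelial positive count."""
    if n_epithelial < 1:
        raise ComputationError(
            f"alveolus {alveolus_id}: grade undefined with no luminal epithelial cells"
        )
    if not (0 <= n_positive <= n_epithelial):
        raise ConfigError(
            f"alveolus {alveolus_id}: n_positive={n_positive} outside [0, {n_epithelial}]"
        )
    frac = n_positive / n_epithelial
    grade = 1 + sum(frac > edge for edge in _GRADE_EDGES)
    return AlveolusGrade(
        alveolus_id=alveolus_id,
        n_epithelial=n_epithelial,
        n_positive=n_positive,
        fraction_positive=frac,
        grade=grade,
        any_positive=n_positive >= 1,
    )


def grade_alveoli(pattern: PointPattern, alveoli: Sequence[Alveolus]) -> list[AlveolusGrade]:
    """Grade every alveolus from its member luminal epithelial cells."""
    by_id = {c.cell_id: c for c in pattern.cells}
    grades = []
    for alv in alveoli:
        members = [by_id[cid] for cid in alv.member_cell_ids]
        epithelial = [c for c in members if c.compartment == "epithelial"]
        n_pos = sum(c.positive for c in epithelial)
        grades.append(grade_alveolus(n_pos, len(epithelial), alveolus_id=alv.id))
    return grades


def sample_alveoli(
    grades: Sequence[AlveolusGrade],
    n_per_group: int,
    seed: int,
) -> tuple[list[AlveolusGrade], list[AlveolusGrade]]:
    """Stratified random sample: n_per_group positive and n_per_group negative alveoli.

    Sampling is without replacement, reproducible under ``seed``.  Returns
    (positive_sample, negative_sample).
    """
    if n_per_group < 1:
        raise ConfigError(f"n_per_group must be >= 1, got {n_per_group}")
    pos = sorted((g for g in grades if g.any_positive), key=lambda g: g.alveolus_id)
    neg = sorted((g for g in grades if not g.any_positive), key=lambda g: g.alveolus_id)
    for name, stratum in (("positive", pos), ("negative", neg)):
        if len(stratum) < n_per_group:
            raise ComputationError(
                f"stratum '{name}' has only {len(stratum)} alveoli; "
                f"{n_per_group} requested"
            )
    rng = np.random.default_rng(seed)
    pos_idx = rng.choice(len(pos), size=n_per_group, replace=False)
    neg_idx = rng.choice(len(neg), size=n_per_group, replace=False)
    return [pos[i] for i in pos_idx], [neg[i] for i in neg_idx]


@dataclass(frozen=True)
class GradeDistribution:
    """Four-bin grade histogram and the fraction of alveoli at the extremes."""

    counts: tuple[int, int, int, int]

    @property
    def n(self) -> int:
        return sum(self.counts)

    @property
    def extremity_fraction(self) -> float:
        return (self.counts[0] + self.counts[3]) / self.n


def grade_distribution(grades: Sequence[AlveolusGrade]) -> GradeDistribution:
    if len(grades) == 0:
        raise ComputationError("grade distribution undefined for an empty set of alveoli")
    counts = [0, 0, 0, 0]
    for g in grades:
        counts[g.grade - 1] += 1
    return GradeDistribution(counts=tuple(counts))


def neighbour_positivity(
    seed_alveolus_id: int,
    adjacency: LobuleAdjacency,
    grades: Iterable[AlveolusGrade],
) -> Optional[NeighbourStat]:
    """Percentage of a seed alveolus' same-lobule neighbours that are positive.

    Returns ``None`` for isolated alveoli (no neighbours); callers batch-drop
    those with a logged notice rather than failing.
    """
    any_pos = {g.alveolus_id: g.any_positive for g in grades}
    neigh = adjacency.neighbours(seed_alveolus_id)
    if len(neigh) == 0:
        logger.info("alveolus %d has no neighbours; excluded from neighbour analysis",
                    seed_alveolus_id)
        return None
    missing = [n for n in neigh if n not in any_pos]
    if missing:
        raise ConfigError(
            f"neighbours {missing} of alveolus {seed_alveolus_id} are ungraded"
        )
    n_pos = sum(any_pos[n] for n in neigh)
    return NeighbourStat(
        seed_alveolus_id=seed_alveolus_id,
        n_neighbours=len(neigh),
        n_positive_neighbours=n_pos,
        pct_positive_neighbours=100.0 * n_pos / len(neigh),
    )


def neighbour_table(
    seeds: Sequence[AlveolusGrade],
    adjacency: LobuleAdjacency,
    grades: Sequence[AlveolusGrade],
) -> list[NeighbourStat]:
    """Neighbour statistics for a batch of seed alveoli, dropping isolated seeds."""
    stats = []
    n_isolated = 0
    for seed in seeds:
        st = neighbour_positivity(seed.alveolus_id, adjacency, grades)
        if st is None:
            n_isolated += 1
        else:
            stats.append(st)
    if n_isolated:
        logger.info("excluded %d isolated seed alveoli from neighbour analysis", n_isolated)
    return stats


def rank_compare(x: Sequence[float], y: Sequence[float]) -> GroupComparison:
    """Two-sided Mann-Whitney rank comparison with mid-rank tie handling.

    Small problems (up to :data:`EXACT_ENUMERATION_LIMIT` group assignments)
    are solved by exact enumeration of all assignments of the pooled mid-ranks;
    larger ones use the normal approximation with tie and continuity
    corrections.  Completely tied inputs give p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 3 or n2 < 3:
        raise ComputationError(
            f"rank comparison needs at least 3 observations per group, got {n1} and {n2}"
        )
    pooled = np.concatenate([x, y])
    means = (float(x.mean()), float(y.mean()))
    mu = n1 * n2 / 2.0
    if np.ptp(pooled) == 0:
        return GroupComparison("mann-whitney (all values tied)", mu, 1.0, (n1, n2), means)
    ranks = rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    if math.comb(n1 + n2, n1) <= EXACT_ENUMERATION_LIMIT:
        dev_obs = abs(u_obs - mu)
        rank_const = n1 * (n1 + 1) / 2.0
        count = 0
        total = 0
        for comb in itertools.combinations(range(n1 + n2), n1):
            u = ranks[list(comb)].sum() - rank_const
            if abs(u - mu) >= dev_obs - 1e-9:
                count += 1
            total += 1
        return GroupComparison("mann-whitney-exact", float(u_obs), count / total,
                               (n1, n2), means)
    res = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                       use_continuity=True)
    return GroupComparison("mann-whitney-normal", float(res.statistic),
                           float(min(res.pvalue, 1.0)), (n1, n2), means)


def compare_neighbour_positivity(
    pos_seeds: Sequence[NeighbourStat],
    neg_seeds: Sequence[NeighbourStat],
) -> GroupComparison:
    """Rank-compare percent-positive-neighbours between positive- and negative-seed alveoli."""
    if len(pos_seeds) == 0 or len(neg_seeds) == 0:
        raise ComputationError("both seed groups must be non-empty")
    return rank_compare(
        [s.pct_positive_neighbours for s in pos_seeds],
        [s.pct_positive_neighbours for s in neg_seeds],
    )


def compare_dimensions(
    pos_alveoli: Sequence[Alveolus],
    neg_alveoli: Sequence[Alveolus],
) -> dict[str, GroupComparison]:
    """Rank-compare lumen major and minor semi-axes between positivity strata."""
    missing = [
        a.id
        for a in itertools.chain(pos_alveoli, neg_alveoli)
        if a.lumen_major_axis is None
        or a.lumen_minor_axis is None
        or not np.isfinite(a.lumen_major_axis)
        or not np.isfinite(a.lumen_minor_axis)
    ]
    if missing:
        raise ConfigError(f"alveoli missing lumen dimensions: {missing}")
    out = {}
    for dim, attr in (("major", "lumen_major_axis"), ("minor", "lumen_minor_axis")):
        out[dim] = rank_compare(
            [getattr(a, attr) for a in pos_alveoli],
            [getattr(a, attr) for a in neg_alveoli],
        )
    return out
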