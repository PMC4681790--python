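"""Empirical null distributions by repeated random splitting.

The theoretical null distributions of most of the global statistics are
unknown, so significance is calibrated empirically: the unspiked table's
samples are repeatedly split at random into two groups (44 vs the
remaining 44 in the original design), the statistic is computed for each
split, and the α-level rejection threshold is the value such that a
fraction α of the resampled statistics lies at or above it.  Because
every split of a fixed table is exchangeable, this controls the type I
error at α by construction.

The empirical p-value of an observed statistic follows the same
convention the procedure defines: the fraction of null statistics
*strictly* higher than the observed value (so p = 0 is possible; no
(r+1)/(N+1) correction is applied — a fidelity choice).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from joblib import Parallel, delayed

from ._seeds import child_rng, child_seed
from .abundance_io import AbundanceTable
from .techniques import GroupLabels, TechniqueConfig, compute_statistic, technique_id

__all__ = ["NullDistribution", "derive_null", "empirical_pvalue", "calibration_threshold"]


@dataclass(frozen=True)
class NullDistribution:
    """Resampled null statistics for one technique, with the rejection
    threshold at level ``alpha``."""

    technique_id: str
    statistics: tuple[float, ...]
    alpha: float
    threshold: float
    n_resamples: int
    seed: int

    def __post_init__(self) -> None:
        stats = tuple(float(s) for s in self.statistics)
        if list(stats) != sorted(stats):
            raise ValueError("statistics must be sorted ascending")
        object.__setattr__(self, "statistics", stats)
        if len(stats) != self.n_resamples:
            raise ValueError("n_resamples does not match the number of statistics")
        if self.n_resamples < np.ceil(1.0 / self.alpha):
            raise ValueError("too few resamples to resolve the alpha level")


def calibration_threshold(statistics: np.ndarray, alpha: float) -> float:
    """Rejection threshold: the smallest observed value ``v`` with
    ``count(statistics >= v) <= round(alpha * N)``.

    For a continuous statistic this leaves exactly ``round(alpha * N)``
    values at or above the threshold (e.g. 500 of 10,000 at α = 0.05).
    When ties make that count unattainable the next larger observed
    value is used (conservative).  If even the largest observed value is
    tied above the target the largest value itself is kept — pushing the
    threshold beyond every observed statistic would make rejection
    impossible and the realized level 0 rather than ≈ α.
    """
    s = np.sort(np.asarray(statistics, dtype=float))
    n = len(s)
    target = int(round(alpha * n))
    if target < 1:
        raise ValueError("n_resamples * alpha below 1: threshold undefined")
    values = np.unique(s)
    # count(s >= v) for each distinct v, descending in v
    counts = n - np.searchsorted(s, values, side="left")
    ok = counts <= target
    if ok.any():
        return float(values[np.argmax(ok)])
    return float(values[-1])


def _split_labels(sample_ids, group_size: int, rng: np.random.Generator) -> GroupLabels:
    perm = rng.permutation(len(sample_ids))
    ids = np.asarray(sample_ids, dtype=object)
    return GroupLabels(
        case=tuple(ids[perm[:group_size]]),
        control=tuple(ids[perm[group_size : 2 * group_size]]),
    )


def derive_null(
    table: AbundanceTable,
    cfg: TechniqueConfig,
    n_resamples: int,
    group_size: int,
    alpha: float = 0.05,
    seed: int = 0,
    n_jobs: int = 1,
) -> NullDistribution:
    """Resample null statistics from random splits of an unspiked table.

    Each resample draws ``group_size`` samples without replacement as
    one group against ``group_size`` of the rest (44 vs 44 in the
    original design) and evaluates the technique statistic.  Per-resample
    child seeds are derived from the resample index, so results are
    identical for any worker count.
    """
    if 2 * group_size > table.n_samples:
        raise ValueError("2 * group_size exceeds the number of samples")
    if n_resamples < 1.0 / alpha:
        raise ValueError(
            f"n_resamples={n_resamples} cannot resolve alpha={alpha}; "
            f"need at least {int(np.ceil(1.0 / alpha))}"
        )

    def one(i: int) -> float:
        rng = child_rng(seed, "null-split", i)
        labels = _split_labels(table.sample_ids, group_size, rng)
        return compute_statistic(table, labels, cfg, seed=child_seed(seed, "null-stat", i))

    if n_jobs == 1:
        values = [one(i) for i in range(n_resamples)]
    else:
        values = Parallel(n_jobs=n_jobs)(delayed(one)(i) for i in range(n_resamples))
    statistics = np.sort(np.asarray(values, dtype=float))
    return NullDistribution(
        technique_id=technique_id(cfg),
        statistics=tuple(statistics),
        alpha=alpha,
        threshold=calibration_threshold(statistics, alpha),
        n_resamples=n_resamples,
        seed=seed,
    )


def empirical_pvalue(null: NullDistribution, observed: float) -> float:
    """Fraction of null statistics strictly higher than ``observed``.

    If 1% of the null statistics exceed the observed value the p-value
    is 0.01; an observed value above every null statistic gives p = 0,
    below every null statistic p = 1.
    """
    s = np.asarray(null.statistics)
    return float(np.sum(s > observed) / len(s))
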