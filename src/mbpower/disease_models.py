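"""Spike-in disease models: feature-set selection and fold-change application.

A disease model names a category of features (rare, medium, common, or
correlated), a target cumulative share of total abundance (1% or 10% in
the original design), and a fold multiplier.  Features are accumulated
in a category-specific order until their combined baseline share of the
community first reaches the target; the spike then multiplies those
features' raw abundances by the fold in the case samples only.
Normalization to proportions happens after spiking, downstream.

Selection orders
----------------
rare
    increasing average abundance (the long tail first);
medium
    increasing distance of the average from the grand mean of averages;
common
    increasing distance of the average from that of the
    ``reference_rank``-th most abundant feature (default rank 100);
correlated
    decreasing correlation between the feature's per-sample relative
    abundance and that of the reference feature (the reference itself is
    excluded).

Ties are broken by feature index, so selection is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .abundance_io import AbundanceTable, normalize_relative

__all__ = ["DiseaseModel", "FeatureSet", "select_feature_set", "apply_spike"]

CATEGORIES = ("rare", "medium", "common", "correlated")


@dataclass(frozen=True)
class DiseaseModel:
    """A spike-in specification.

    ``target_fraction`` is the cumulative baseline share of total
    abundance the selected features must reach (0.01 and 0.10 in the
    original eight-model design); ``fold`` the multiplier applied to
    case samples (grids 1-5 for the 10% models, 1-40 for the 1% models;
    fold 1 is the embedded null).  ``correlation_method`` selects the
    coefficient for the correlated category.
    """

    category: str
    target_fraction: float = 0.10
    fold: float = 1.0
    reference_rank: int = 100
    correlation_method: str = "pearson"

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if not 0 < self.target_fraction <= 1:
            raise ValueError("target_fraction must lie in (0, 1]")
        if self.fold < 1:
            raise ValueError("fold must be >= 1")
        if self.reference_rank < 1:
            raise ValueError("reference_rank must be positive")
        if self.correlation_method not in ("pearson", "spearman"):
            raise ValueError("correlation_method must be 'pearson' or 'spearman'")


@dataclass(frozen=True)
class FeatureSet:
    """An ordered set of selected feature positions.

    ``achieved_fraction`` is the cumulative baseline relative abundance
    of the set: the smallest attainable value >= the model's target
    under the selection order.
    """

    indices: tuple[int, ...]
    achieved_fraction: float

    def __post_init__(self) -> None:
        if len(set(self.indices)) != len(self.indices):
            raise ValueError("duplicate feature indices")


def _selection_order(table: AbundanceTable, model: DiseaseModel) -> np.ndarray:
    averages = table.values.mean(axis=1)
    n = len(averages)
    if model.category in ("common", "correlated"):
        if (averages > 0).sum() < model.reference_rank:
            raise ValueError(
                f"table has fewer than {model.reference_rank} features with "
                "positive average abundance"
            )
        # rank 1 = most abundant; ties by index via stable sort on (-avg, idx)
        by_abundance = np.lexsort((np.arange(n), -averages))
        reference = by_abundance[model.reference_rank - 1]

    if model.category == "rare":
        key = averages
    elif model.category == "medium":
        key = np.abs(averages - averages.mean())
    elif model.category == "common":
        key = np.abs(averages - averages[reference])
    else:  # correlated
        rel = normalize_relative(table).values
        ref_profile = rel[reference]
        if model.correlation_method == "spearman":
            rel = stats.rankdata(rel, axis=1)
            ref_profile = stats.rankdata(ref_profile)
        centered = rel - rel.mean(axis=1, keepdims=True)
        ref_centered = ref_profile - ref_profile.mean()
        denom = np.sqrt((centered**2).sum(axis=1) * (ref_centered**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.where(denom > 0, centered @ ref_centered / np.where(denom > 0, denom, 1), -np.inf)
        key = -corr  # decreasing correlation
        order = np.lexsort((np.arange(n), key))
        return order[order != reference]  # reference itself excluded
    return np.lexsort((np.arange(n), key))


def select_feature_set(table: AbundanceTable, model: DiseaseModel) -> FeatureSet:
    """Accumulate features in the category's order until the cumulative
    baseline share of total abundance first reaches ``target_fraction``."""
    averages = table.values.mean(axis=1)
    total = averages.sum()
    if total <= 0:
        raise ValueError("table has zero total abundance")
    order = _selection_order(table, model)
    fractions = averages[order] / total
    cumulative = np.cumsum(fractions)
    reached = np.nonzero(cumulative >= model.target_fraction - 1e-12)[0]
    if len(reached) == 0:
        raise ValueError(
            f"target fraction {model.target_fraction} unreachable "
            f"(attainable maximum {cumulative[-1]:.6g})"
        )
    stop = int(reached[0])
    return FeatureSet(
        indices=tuple(int(i) for i in order[: stop + 1]),
        achieved_fraction=float(cumulative[stop]),
    )


def apply_spike(
    table: AbundanceTable,
    features: FeatureSet,
    fold: float,
    case_samples,
) -> AbundanceTable:
    """Multiply the selected features by ``fold`` in the case samples.

    Operates on the raw scale (spike first, normalize afterwards); all
    other cells, including every control column, are bitwise unchanged.
    A fold of 1 returns values identical to the input, embedding the
    null hypothesis at the lower end of every fold grid.
    """
    if fold < 1:
        raise ValueError("fold must be >= 1")
    case_samples = list(case_samples)
    if not case_samples:
        raise ValueError("case sample set is empty")
    if table.scale != "raw":
        raise ValueError("spike-ins operate on raw-scale tables; normalize afterwards")
    cols = table.sample_index(case_samples)
    rows = np.asarray(features.indices, dtype=int)
    values = table.values.copy()
    values[np.ix_(rows, cols)] *= fold
    return replace(table, values=values)
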