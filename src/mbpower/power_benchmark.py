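"""Empirical power estimation over the spike-in grid.

One power estimate repeats, ``n_replicates`` times (100 in the original
design): split the samples at random into equal case/control groups,
multiply the disease model's feature set by the fold in the case half,
normalize to proportions, evaluate the technique statistic, and reject
when it meets the resampling-calibrated threshold.  Power is the
rejection fraction.  Repeating the whole assessment (ten times in the
original design) yields a standard error of the power.

``run_benchmark`` orchestrates the full grid — table x disease models x
folds x techniques x repeats — from a single configuration mapping and
a root seed, sharing the random splits across techniques (and the
calibration splits across techniques) so every method sees identical
data, and reusing one calibrated threshold across repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from ._seeds import child_rng, child_seed
from .abundance_io import AbundanceTable, read_abundance_table
from .disease_models import DiseaseModel, FeatureSet, apply_spike, select_feature_set
from .null_calibration import NullDistribution, _split_labels, derive_null
from .synthetic_community import CommunityModel, generate_table
from .techniques import TechniqueConfig, compute_statistic, technique_id

__all__ = [
    "PowerEstimate",
    "estimate_power",
    "power_standard_error",
    "run_benchmark",
    "best_per_family",
    "TECHNIQUE_FAMILIES",
]


@dataclass(frozen=True)
class PowerEstimate:
    """Result of one power assessment (a single repeat)."""

    technique_id: str
    model: str
    fold: float
    rejections: int
    n_replicates: int
    power: float
    repeats: tuple[float, ...] = field(default_factory=tuple)
    standard_error: float = float("nan")

    def __post_init__(self) -> None:
        if not 0 <= self.rejections <= self.n_replicates:
            raise ValueError("rejections must lie in [0, n_replicates]")


def power_standard_error(repeats: Sequence[float]) -> float:
    """Standard error of repeat powers: sample sd / sqrt(number of repeats)."""
    r = np.asarray(list(repeats), dtype=float)
    if r.size < 2:
        raise ValueError("standard error requires at least two repeats")
    return float(r.std(ddof=1) / np.sqrt(r.size))


def _model_label(model: DiseaseModel) -> str:
    return f"{model.category}_{model.target_fraction:g}"


def estimate_power(
    table: AbundanceTable,
    model: DiseaseModel,
    cfg: TechniqueConfig,
    null: NullDistribution,
    n_replicates: int,
    seed: int,
    *,
    group_size: int | None = None,
    features: FeatureSet | None = None,
) -> PowerEstimate:
    """Single-repeat power of one technique under one disease model.

    The null must have been calibrated for the same technique
    configuration on the same unspiked table.  Each replicate draws a
    fresh random equal split, spikes the case half on the model's
    feature set (selected from the unspiked table), normalizes, and
    tests against ``null.threshold``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be positive")
    if technique_id(cfg) != null.technique_id:
        raise ValueError(
            f"null distribution was calibrated for {null.technique_id!r}, "
            f"not {technique_id(cfg)!r}"
        )
    if group_size is None:
        group_size = table.n_samples // 2
    if 2 * group_size > table.n_samples:
        raise ValueError("2 * group_size exceeds the number of samples")
    if features is None and model.fold > 1:
        features = select_feature_set(table, model)
    rejections = 0
    for r in range(n_replicates):
        labels = _split_labels(
            table.sample_ids, group_size, child_rng(seed, "power-split", r)
        )
        if model.fold > 1:
            spiked = apply_spike(table, features, model.fold, labels.case)
        else:
            spiked = table  # fold 1 multiplies by one: the embedded null
        stat = compute_statistic(
            spiked, labels, cfg, seed=child_seed(seed, "power-stat", r)
        )
        if stat >= null.threshold:
            rejections += 1
    return PowerEstimate(
        technique_id=null.technique_id,
        model=_model_label(model),
        fold=model.fold,
        rejections=rejections,
        n_replicates=n_replicates,
        power=rejections / n_replicates,
    )


# ---------------------------------------------------------------------------
# grid orchestration
# ---------------------------------------------------------------------------

TECHNIQUE_FAMILIES = {
    "metastats_global": "metastats",
    "lasso": "regularized",
    "ridge": "regularized",
    "elastic_net": "regularized",
    "mdmr": "mdmr",
    "pcr": "pcr",
    "plsr": "plsr",
    "diversity_family": "diversity",
}

RESULT_COLUMNS = [
    "technique_id",
    "family",
    "model",
    "fraction",
    "fold",
    "repeat",
    "rejections",
    "n_replicates",
    "power",
    "se",
]


def _load_table(config: Mapping[str, Any], seed: int) -> AbundanceTable:
    if "table" in config:
        return read_abundance_table(config["table"])
    community = dict(config.get("community", {}))
    community.setdefault("seed", child_seed(seed, "community"))
    return generate_table(CommunityModel(**community))


def run_benchmark(config: Mapping[str, Any]) -> pd.DataFrame:
    """Run the full power grid described by a configuration mapping.

    Expected keys: ``seed`` (root seed); ``table`` (TSV path) or
    ``community`` (:class:`CommunityModel` keyword arguments);
    ``group_size``; ``calibration`` (``n_resamples``, ``alpha``);
    ``power`` (``n_replicates``, ``n_repeats``); ``techniques`` (list of
    :class:`TechniqueConfig` keyword mappings); ``disease_models`` (list
    of :class:`DiseaseModel` keyword mappings, each with a ``folds``
    grid); optional ``n_jobs``.

    Returns one detail row per (technique, model, fold, repeat) plus one
    aggregate row per (technique, model, fold) with the mean power and
    its across-repeat standard error.  Deterministic given the root
    seed, for any worker count.
    """
    seed = int(config.get("seed", 0))
    n_jobs = int(config.get("n_jobs", 1))
    techniques = [TechniqueConfig(**dict(t)) for t in config["techniques"]]
    ids = [technique_id(t) for t in techniques]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate technique identifiers in configuration")
    model_specs = []
    for entry in config["disease_models"]:
        entry = dict(entry)
        folds = entry.pop("folds", [1])
        base = DiseaseModel(**entry)
        model_specs.append((base, [float(f) for f in folds]))

    table = _load_table(config, seed)
    group_size = int(config.get("group_size", table.n_samples // 2))
    cal = dict(config.get("calibration", {}))
    n_resamples = int(cal.get("n_resamples", 2000))
    alpha = float(cal.get("alpha", 0.05))
    pw = dict(config.get("power", {}))
    n_replicates = int(pw.get("n_replicates", 100))
    n_repeats = int(pw.get("n_repeats", 10))

    # one calibration per technique, all sharing the same random splits
    cal_seed = child_seed(seed, "calibration")
    nulls = {
        tid: derive_null(
            table, cfg, n_resamples, group_size, alpha, seed=cal_seed, n_jobs=n_jobs
        )
        for tid, cfg in zip(ids, techniques)
    }

    rows = []
    for base_model, folds in model_specs:
        label = _model_label(base_model)
        features = select_feature_set(table, base_model)
        for fold in folds:
            model = DiseaseModel(
                category=base_model.category,
                target_fraction=base_model.target_fraction,
                fold=fold,
                reference_rank=base_model.reference_rank,
                correlation_method=base_model.correlation_method,
            )
            for tid, cfg in zip(ids, techniques):
                family = TECHNIQUE_FAMILIES[cfg.technique]
                repeats = []
                for rep in range(n_repeats):
                    rep_seed = child_seed(seed, "power", label, rep)
                    est = estimate_power(
                        table,
                        model,
                        cfg,
                        nulls[tid],
                        n_replicates,
                        rep_seed,
                        group_size=group_size,
                        features=features,
                    )
                    repeats.append(est.power)
                    rows.append(
                        [tid, family, label, base_model.target_fraction, fold,
                         rep, est.rejections, n_replicates, est.power, np.nan]
                    )
                se = power_standard_error(repeats) if len(repeats) > 1 else np.nan
                rows.append(
                    [tid, family, label, base_model.target_fraction, fold,
                     "mean", np.nan, n_replicates, float(np.mean(repeats)), se]
                )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def best_per_family(results: pd.DataFrame) -> pd.DataFrame:
    """Keep, per (model, family), the parameterization with the highest
    mean power across the fold grid — the representative shown in the
    original comparison's figures."""
    agg = results[results["repeat"] == "mean"]
    keep = []
    for (model, family), grp in agg.groupby(["model", "family"]):
        mean_by_tid = grp.groupby("technique_id")["power"].mean()
        keep.append((model, family, mean_by_tid.idxmax()))
    keep_set = {(m, t) for m, _, t in keep}
    mask = [
        (row.model, row.technique_id) in keep_set for row in results.itertuples()
    ]
    return results[mask].reset_index(drop=True)
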