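"""Synthetic skewed microbial communities.

Real surface-microbiome OTU tables show a handful of very abundant
features above a long tail of rare ones (per-feature averages spanning
four to five orders of magnitude), substantial sparsity, and blocks of
mutually correlated features driven by shared ecology or phylogeny.  The
generator here emulates those properties with an explicit parametric
family so that every downstream stage (spike-ins, calibration, power
loops) is testable without any external dataset:

* per-feature expected abundances from a log-normal body whose top
  fraction is replaced by a Pareto tail (heavy right skew);
* per-cell values = expected abundance x latent block factor^loading x
  independent log-normal depth noise;
* presence thinning: each cell is zeroed with probability
  ``1 - presence(mean)``, where the presence curve rises monotonically
  with expected abundance (rare features are seen in fewer samples).

All draws flow from named child streams of one root seed, so a model is
fully reproducible and any stage can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log

import numpy as np

from ._seeds import child_rng
from .abundance_io import AbundanceTable

__all__ = ["CommunityModel", "sample_mean_abundances", "generate_table"]


@dataclass(frozen=True)
class CommunityModel:
    """Parameters of the synthetic community generator.

    Attributes
    ----------
    n_features, n_samples :
        Table dimensions.  ``n_samples`` defaults to 88, the design size
        of the hand-microbiome study this generator emulates;
        ``n_features`` defaults to a desk-scale 2000 (the real table has
        ~26k features, but the benchmarking machinery is size-agnostic).
    mean_log_abundance, sd_log_abundance :
        Location and scale of the log-normal body of per-feature
        expected abundances.
    tail_exponent, tail_fraction :
        Pareto shape for the heavy upper tail, and the fraction of
        features (the most abundant ones) replaced by tail draws.
    tail_scale :
        Lower bound of the Pareto tail (its x_min).
    abundance_floor :
        Lower clip for expected abundances, mimicking the detection
        floor visible in real per-feature summaries (minimum and first
        quartile nearly coincide).
    sparsity_curve :
        ``("hill", p_min, midpoint, gamma)``: presence probability
        ``p_min + (1 - p_min) * m^gamma / (m^gamma + midpoint^gamma)``,
        monotone increasing in the expected abundance ``m`` and bounded
        in (0, 1]; or ``None`` to disable thinning.
    correlation_blocks :
        Sequence of ``(size, loading)`` pairs.  Blocks are laid out over
        consecutive features; each block shares one standard-normal
        latent factor per sample, entering each member's log-abundance
        with the given loading in [0, 1).
    depth_dispersion :
        Standard deviation of the independent per-cell log-normal noise.
    seed :
        Root seed; all randomness derives from it via named streams.
    """

    n_features: int = 2000
    n_samples: int = 88
    mean_log_abundance: float = log(0.02)
    sd_log_abundance: float = 1.2
    tail_exponent: float = 1.0
    tail_fraction: float = 0.02
    tail_scale: float = 0.5
    abundance_floor: float = 0.008
    sparsity_curve: tuple | None = ("hill", 0.4, 0.05, 0.7)
    correlation_blocks: tuple = ((50, 0.9), (50, 0.8), (100, 0.6))
    depth_dispersion: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "correlation_blocks",
            tuple((int(s), float(l)) for s, l in self.correlation_blocks),
        )
        if self.n_features < 1:
            raise ValueError("n_features must be positive")
        if self.sd_log_abundance <= 0:
            raise ValueError("sd_log_abundance must be positive")
        if self.tail_exponent <= 0:
            raise ValueError("tail_exponent must be positive")
        if not 0 <= self.tail_fraction <= 1:
            raise ValueError("tail_fraction must lie in [0, 1]")
        if self.depth_dispersion <= 0:
            raise ValueError("depth_dispersion must be positive")
        for size, loading in self.correlation_blocks:
            if not 0 <= loading < 1:
                raise ValueError("block loadings must lie in [0, 1)")
            if size < 1:
                raise ValueError("block sizes must be positive")
        if sum(s for s, _ in self.correlation_blocks) > self.n_features:
            raise ValueError("correlation block sizes exceed n_features")
        if self.sparsity_curve is not None:
            kind, p_min, midpoint, gamma = self.sparsity_curve
            if kind != "hill":
                raise ValueError(f"unknown sparsity curve kind {kind!r}")
            if not 0 < p_min <= 1:
                raise ValueError("sparsity p_min must lie in (0, 1]")
            if midpoint <= 0 or gamma <= 0:
                raise ValueError("sparsity midpoint and gamma must be positive")


def _presence_probability(model: CommunityModel, means: np.ndarray) -> np.ndarray:
    if model.sparsity_curve is None:
        return np.ones_like(means)
    _, p_min, midpoint, gamma = model.sparsity_curve
    mg = means**gamma
    return p_min + (1.0 - p_min) * mg / (mg + midpoint**gamma)


def sample_mean_abundances(model: CommunityModel) -> np.ndarray:
    """Per-feature expected abundances: log-normal body, Pareto upper tail.

    Deterministic given ``model.seed``; strictly positive.
    """
    rng = child_rng(model.seed, "means")
    means = np.exp(
        rng.normal(model.mean_log_abundance, model.sd_log_abundance, model.n_features)
    )
    means = np.maximum(means, model.abundance_floor)
    n_tail = int(round(model.tail_fraction * model.n_features))
    if n_tail > 0:
        top = np.argsort(means)[-n_tail:]
        means[top] = model.tail_scale * (1.0 + rng.pareto(model.tail_exponent, n_tail))
    return means


def generate_table(model: CommunityModel) -> AbundanceTable:
    """Draw a raw-scale abundance table from the community model.

    Cell value for feature *f* in sample *j*:
    ``mean_f * exp(loading_f * eta_{b(f),j}) * exp(eps_{fj})`` with
    ``eta ~ N(0,1)`` shared over the feature's block and
    ``eps ~ N(0, depth_dispersion^2)`` independent, then zeroed with
    probability ``1 - presence(mean_f)``.
    """
    if model.n_samples < 4:
        raise ValueError("n_samples must be at least 4 for two-group testing")
    means = sample_mean_abundances(model)
    rng = child_rng(model.seed, "table")
    log_values = np.log(means)[:, None] + rng.normal(
        0.0, model.depth_dispersion, (model.n_features, model.n_samples)
    )
    pos = 0
    for size, loading in model.correlation_blocks:
        eta = rng.normal(0.0, 1.0, model.n_samples)
        log_values[pos : pos + size] += loading * eta
        pos += size
    values = np.exp(log_values)
    if model.sparsity_curve is not None:
        presence = _presence_probability(model, means)
        keep = rng.random((model.n_features, model.n_samples)) < presence[:, None]
        values = values * keep
    width_f = len(str(model.n_features))
    width_s = len(str(model.n_samples))
    return AbundanceTable(
        feature_ids=tuple(f"f{i:0{width_f}d}" for i in range(1, model.n_features + 1)),
        sample_ids=tuple(f"s{j:0{width_s}d}" for j in range(1, model.n_samples + 1)),
        values=values,
        scale="raw",
    )
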