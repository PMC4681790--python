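"""The six families of two-group test statistics.

Every public statistic is a pure function ``(table, labels, config) ->
scalar`` with the convention that larger values mean stronger evidence
of a difference between the case and control groups:

* ``metastats_global_statistic`` — per-feature Welch t-tests (Fisher's
  exact test for sparsely counted features), pooled through a
  Benjamini-Hochberg step-up; the statistic is the number of features
  rejected.  The classic univariate procedure turned into a single
  global test.
* ``penalized_logistic_statistic`` — lasso / ridge / elastic-net
  logistic regression with the penalty weight chosen by cross-validated
  deviance; the statistic is a chi-square lower-tail probability of the
  deviance reduction (ridge: the raw deviance reduction).
* ``mdmr_pseudo_f`` — distance-based multivariate regression
  (PERMANOVA-style pseudo-F) on a Minkowski distance matrix.
* ``pcr_cv_r2`` / ``plsr_cv_r2`` — principal-component and partial
  least squares regression of the 0/1 group indicator on component
  scores; the statistic is the ten-fold cross-validated R².
* ``diversity_family_statistic`` — Hill-number diversity profiles per
  sample; the statistic is the largest absolute two-sample t over the
  family of Hill orders.

None of these statistics carries its own reference distribution here;
significance comes from the resampling calibration in
:mod:`mbpower.null_calibration`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from ._seeds import child_seed
from .abundance_io import AbundanceTable, normalize_relative

__all__ = [
    "GroupLabels",
    "TechniqueConfig",
    "DistanceMatrix",
    "HillProfile",
    "TECHNIQUES",
    "feature_t_statistic",
    "fisher_sparse_feature_pvalue",
    "fdr_select",
    "metastats_global_statistic",
    "penalized_logistic_statistic",
    "minkowski_distance_matrix",
    "mdmr_pseudo_f",
    "pcr_cv_r2",
    "plsr_cv_r2",
    "hill_number",
    "diversity_family_statistic",
    "compute_statistic",
    "technique_id",
]

TECHNIQUES = (
    "metastats_global",
    "lasso",
    "ridge",
    "elastic_net",
    "mdmr",
    "pcr",
    "plsr",
    "diversity_family",
)

DEFAULT_HILL_ORDERS = (0.0, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, np.inf)


@dataclass(frozen=True)
class GroupLabels:
    """Assignment of sample ids to the case and control groups."""

    case: tuple[str, ...]
    control: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "case", tuple(self.case))
        object.__setattr__(self, "control", tuple(self.control))
        if not self.case or not self.control:
            raise ValueError("both groups must be non-empty")
        if set(self.case) & set(self.control):
            raise ValueError("a sample cannot be in both groups")

    @property
    def assignment(self) -> dict[str, str]:
        out = {s: "case" for s in self.case}
        out.update({s: "control" for s in self.control})
        return out


@dataclass(frozen=True)
class TechniqueConfig:
    """A technique identifier plus its tuning parameters.

    Only the parameters relevant to ``technique`` are consulted; the
    rest are inert.  ``n_components`` may be a positive integer or the
    string ``"all"`` (capped at the training-fold rank).
    ``sparse_total_threshold`` is the summed raw count at or below which
    a feature is handed to Fisher's exact test instead of the t-test.
    ``n_lambdas``/``lambda_min_ratio`` define the geometric penalty
    path, from the smallest weight that zeroes every coefficient down by
    the given ratio.
    """

    technique: str
    minkowski_p: float = 2.0
    n_components: int | str = 10
    per_feature_alpha: float = 0.05
    fdr_level: float = 0.05
    sparse_total_threshold: int = 8
    hill_orders: tuple[float, ...] = DEFAULT_HILL_ORDERS
    elastic_net_mixing: float = 0.5
    cv_folds: int = 10
    inner_permutations: int = 0
    n_lambdas: int = 100
    lambda_min_ratio: float = 0.01
    equal_var: bool = False

    def __post_init__(self) -> None:
        if self.technique not in TECHNIQUES:
            raise ValueError(f"unknown technique {self.technique!r}")
        if self.minkowski_p <= 0:
            raise ValueError("minkowski_p must be positive")
        if self.n_components != "all" and (
            not isinstance(self.n_components, (int, np.integer)) or self.n_components < 1
        ):
            raise ValueError("n_components must be a positive integer or 'all'")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be at least 2")
        if not 0 < self.elastic_net_mixing < 1:
            raise ValueError("elastic_net_mixing must lie in (0, 1)")
        orders = tuple(float(q) for q in self.hill_orders)
        if any(q < 0 for q in orders) or list(orders) != sorted(orders):
            raise ValueError("hill_orders must be nonnegative and sorted ascending")
        object.__setattr__(self, "hill_orders", orders)
        if self.sparse_total_threshold < 0:
            raise ValueError("sparse_total_threshold must be nonnegative")
        if not 0 < self.fdr_level < 1 or not 0 < self.per_feature_alpha < 1:
            raise ValueError("significance levels must lie in (0, 1)")


def technique_id(cfg: TechniqueConfig) -> str:
    """Stable identifier for a technique/parameter combination."""
    t = cfg.technique
    if t == "mdmr":
        return f"mdmr_p{cfg.minkowski_p:g}"
    if t in ("pcr", "plsr"):
        return f"{t}_k{cfg.n_components}"
    if t == "metastats_global":
        return "metastats"
    if t == "diversity_family":
        return "diversity"
    return t


# ---------------------------------------------------------------------------
# per-feature tests and FDR (the modified-Metastats building blocks)
# ---------------------------------------------------------------------------


def _welch_arrays(a: np.ndarray, b: np.ndarray, equal_var: bool = False):
    """Row-wise two-sample t over matrices ``a`` (features x n1) and ``b``.

    Rows where both groups have zero variance get the declared
    convention t = 0, p = 1 (no evidence either way).
    """
    n1, n2 = a.shape[1], b.shape[1]
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1, v2 = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    degenerate = (v1 == 0) & (v2 == 0)
    if equal_var:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se2 = sp2 * (1 / n1 + 1 / n2)
        df = np.full_like(se2, n1 + n2 - 2)
    else:
        se2 = v1 / n1 + v2 / n2
        safe = np.where(se2 > 0, se2, 1.0)
        df = safe**2 / np.where(
            se2 > 0,
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1),
            1.0,
        )
    safe_se2 = np.where(se2 > 0, se2, 1.0)
    t = (m1 - m2) / np.sqrt(safe_se2)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    return t, p


def feature_t_statistic(case_values, control_values, *, equal_var: bool = False):
    """Two-sample (Welch by default) t-test on one feature's abundances.

    Returns ``(t, p)`` with the two-sided p-value from the
    Welch-Satterthwaite reference distribution.  If both groups have
    zero variance the declared convention ``t = 0, p = 1`` applies.
    """
    a = np.atleast_2d(np.asarray(case_values, dtype=float))
    b = np.atleast_2d(np.asarray(control_values, dtype=float))
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("need at least two values per group")
    t, p = _welch_arrays(a, b, equal_var=equal_var)
    return float(t[0]), float(p[0])


def fisher_sparse_feature_pvalue(
    case_total, control_total, case_other, control_other
) -> float:
    """Two-sided Fisher's exact p for a sparse feature's 2x2 count table.

    Rows: (this feature, all other features); columns: (case, control).
    Exact tests require counts, so non-integer inputs are rejected.
    """
    cells = [case_total, control_total, case_other, control_other]
    ints = []
    for c in cells:
        if isinstance(c, float) and not float(c).is_integer():
            raise ValueError("Fisher's exact test requires integer counts")
        if not isinstance(c, (int, np.integer, float)):
            raise ValueError("Fisher's exact test requires integer counts")
        ints.append(int(c))
    if any(c < 0 for c in ints):
        raise ValueError("counts must be nonnegative")
    table = [[ints[0], ints[1]], [ints[2], ints[3]]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def fdr_select(pvalues, level: float) -> np.ndarray:
    """Benjamini-Hochberg step-up at the given level; True marks rejection."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    adjusted = stats.false_discovery_control(p, method="bh")
    return adjusted <= level


def _integer_counts(table: AbundanceTable) -> np.ndarray | None:
    """Raw count matrix if the table genuinely holds counts, else None.

    The Fisher branch needs integer counts.  A raw table whose values
    are integral (to 1e-6) is treated as counts; fractional "abundance"
    values (as in pre-normalized survey data) and relative tables
    provide no usable counts, and every feature is then t-tested.
    """
    if table.scale != "raw":
        return None
    rounded = np.rint(table.values)
    if np.abs(table.values - rounded).max() > 1e-6:
        return None
    return rounded.astype(np.int64)


def metastats_global_statistic(
    table: AbundanceTable, labels: GroupLabels, cfg: TechniqueConfig
) -> int:
    """Number of FDR-significant features: the global multivariate statistic.

    Features whose summed raw count is at most
    ``cfg.sparse_total_threshold`` are tested by Fisher's exact test on
    counts (when the table carries counts); all others by a two-sample
    t-test on relative abundances.  The pooled p-values pass through a
    Benjamini-Hochberg step-up at ``cfg.fdr_level`` and the rejection
    count is returned.
    """
    case_idx = table.sample_index(labels.case)
    ctrl_idx = table.sample_index(labels.control)
    if len(case_idx) < 2 or len(ctrl_idx) < 2:
        raise ValueError("need at least two samples per group")
    rel = normalize_relative(table).values
    counts = _integer_counts(table)
    pvalues = np.empty(table.n_features)
    if counts is None:
        sparse = np.zeros(table.n_features, dtype=bool)
    else:
        sparse = counts.sum(axis=1) <= cfg.sparse_total_threshold
        case_counts = counts[:, case_idx].sum(axis=1)
        ctrl_counts = counts[:, ctrl_idx].sum(axis=1)
        case_grand = case_counts.sum()
        ctrl_grand = ctrl_counts.sum()
        for f in np.nonzero(sparse)[0]:
            pvalues[f] = fisher_sparse_feature_pvalue(
                int(case_counts[f]),
                int(ctrl_counts[f]),
                int(case_grand - case_counts[f]),
                int(ctrl_grand - ctrl_counts[f]),
            )
    dense = ~sparse
    if dense.any():
        _, p_dense = _welch_arrays(
            rel[np.ix_(dense, case_idx)],
            rel[np.ix_(dense, ctrl_idx)],
            equal_var=cfg.equal_var,
        )
        pvalues[dense] = p_dense
    return int(fdr_select(pvalues, cfg.fdr_level).sum())


# ---------------------------------------------------------------------------
# penalized logistic regression (lasso / ridge / elastic net)
# ---------------------------------------------------------------------------


def _binomial_deviance(y: np.ndarray, prob: np.ndarray) -> float:
    prob = np.clip(prob, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.sum(y * np.log(prob) + (1 - y) * np.log(1 - prob)))


def _standardize(train: np.ndarray, test: np.ndarray | None = None):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    if test is None:
        return (train - mu) / sd
    return (train - mu) / sd, (test - mu) / sd


def _path_estimator(l1_ratio: float) -> LogisticRegression:
    # liblinear/lbfgs are much faster than saga at these sizes; saga only
    # where the elastic-net mix requires it
    if l1_ratio == 1.0:
        return LogisticRegression(solver="liblinear", l1_ratio=1.0, max_iter=5000)
    if l1_ratio == 0.0:
        return LogisticRegression(solver="lbfgs", l1_ratio=0.0, max_iter=5000)
    return LogisticRegression(
        solver="saga", l1_ratio=l1_ratio, max_iter=5000, tol=1e-3, warm_start=True
    )


def penalized_logistic_statistic(
    table: AbundanceTable,
    labels: GroupLabels,
    cfg: TechniqueConfig,
    *,
    seed: int = 0,
    return_details: bool = False,
) -> float | tuple[float, dict]:
    """Deviance-based statistic from penalized logistic regression.

    The penalty weight λ is chosen by ``cfg.cv_folds``-fold
    cross-validated deviance over a geometric path of ``cfg.n_lambdas``
    values descending from the smallest λ that zeroes all coefficients.
    For the lasso and elastic net the statistic is
    ``P(chi2_df <= null_deviance - model_deviance)`` with df the number
    of nonzero coefficients (df = 0 gives 0); for ridge, whose df is not
    sparse, the deviance reduction itself (clamped at 0).
    """
    if cfg.technique == "lasso":
        l1_ratio = 1.0
    elif cfg.technique == "ridge":
        l1_ratio = 0.0
    elif cfg.technique == "elastic_net":
        l1_ratio = cfg.elastic_net_mixing
    else:
        raise ValueError(f"not a penalized technique: {cfg.technique!r}")

    rel = normalize_relative(table)
    X, y = _design_and_response(rel, labels)
    n = len(y)

    X_std = _standardize(X)
    lam_max = np.abs(X_std.T @ (y - y.mean())).max() / (n * max(l1_ratio, 1e-3))
    lambdas = np.geomspace(lam_max, lam_max * cfg.lambda_min_ratio, cfg.n_lambdas)

    skf = StratifiedKFold(
        n_splits=cfg.cv_folds, shuffle=True, random_state=child_seed(seed, "folds")
    )
    cv_deviance = np.zeros(cfg.n_lambdas)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for train, test in skf.split(X, y):
            Xtr, Xte = _standardize(X[train], X[test])
            est = _path_estimator(l1_ratio)
            for i, lam in enumerate(lambdas):
                est.C = 1.0 / (len(train) * lam)
                est.fit(Xtr, y[train])
                cv_deviance[i] += _binomial_deviance(
                    y[test], est.predict_proba(Xte)[:, 1]
                )
        best = int(np.argmin(cv_deviance))  # ties resolve to the larger lambda
        est = _path_estimator(l1_ratio)
        est.C = 1.0 / (n * lambdas[best])
        est.fit(X_std, y)
    model_dev = _binomial_deviance(y, est.predict_proba(X_std)[:, 1])
    p1 = y.mean()
    null_dev = _binomial_deviance(y, np.full(n, p1))
    delta = max(null_dev - model_dev, 0.0)
    nonzero = np.nonzero(np.abs(est.coef_[0]) > 1e-8)[0]
    df = len(nonzero)
    if cfg.technique == "ridge":
        statistic = delta
    elif df == 0:
        statistic = 0.0
    else:
        statistic = float(stats.chi2.cdf(delta, df))
    if return_details:
        return statistic, {
            "lambda": float(lambdas[best]),
            "df": df,
            "nonzero_features": tuple(int(i) for i in nonzero),
            "deviance_reduction": delta,
        }
    return statistic


# ---------------------------------------------------------------------------
# distance-based regression (MDMR)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise sample distances with a zero diagonal."""

    sample_ids: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "d", d)
        n = len(self.sample_ids)
        if d.shape != (n, n):
            raise ValueError("distance matrix shape does not match sample ids")
        if not np.all(np.isfinite(d)):
            raise ValueError("non-finite distances")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise ValueError("distance matrix diagonal is not zero")


def minkowski_distance_matrix(table: AbundanceTable, p: float) -> DistanceMatrix:
    """Pairwise Minkowski distances between sample columns.

    ``d_ij = (sum_f |x_fi - x_fj|^p)^(1/p)``.  For p < 1 the same
    formula is applied even though it is not a metric (no triangle
    inequality); the original comparison used p in {0.25, 0.5, 1, 2, 4}.
    Distances are conventionally computed on relative abundances
    (the dispatcher normalizes first) but the formula accepts any table.
    """
    if p <= 0:
        raise ValueError("Minkowski exponent p must be positive")
    X = table.values.T  # samples x features
    diff = np.abs(X[:, None, :] - X[None, :, :])
    d = (diff**p).sum(axis=2) ** (1.0 / p)
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)
    return DistanceMatrix(sample_ids=table.sample_ids, d=d)


def mdmr_pseudo_f(dist: DistanceMatrix, labels: GroupLabels) -> float:
    """PERMANOVA-style pseudo-F of the two-group design on a distance matrix.

    Gower-centers ``A = -d^2/2`` into ``G = JAJ`` and contrasts the
    trace explained by the group-indicator hat matrix against the
    residual trace: ``F = [tr(HGH)/(m-1)] / [tr((I-H)G(I-H))/(n-m)]``
    with m = 2 groups.
    """
    ids = list(labels.case) + list(labels.control)
    pos = {s: i for i, s in enumerate(dist.sample_ids)}
    try:
        idx = np.array([pos[s] for s in ids])
    except KeyError as exc:
        raise KeyError(f"sample {exc.args[0]!r} not in distance matrix") from None
    d = dist.d[np.ix_(idx, idx)]
    n = len(ids)
    m = 2
    A = -0.5 * d**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    x = np.zeros((n, 2))
    x[:, 0] = 1.0
    x[: len(labels.case), 1] = 1.0
    H = x @ np.linalg.pinv(x.T @ x) @ x.T
    between = np.trace(H @ G @ H)
    residual = np.trace((np.eye(n) - H) @ G @ (np.eye(n) - H))
    if residual <= 1e-12 * max(abs(between), 1.0):
        raise ValueError("degenerate distances: zero residual trace")
    return float((between / (m - 1)) / (residual / (n - m)))


# ---------------------------------------------------------------------------
# component regressions (PCR / PLSR)
# ---------------------------------------------------------------------------


def _design_and_response(table: AbundanceTable, labels: GroupLabels):
    # canonical (sorted) within-group order, so statistics that depend on
    # row order only through seeded CV folds are invariant to how the
    # caller happened to order each group
    case_idx = table.sample_index(sorted(labels.case))
    ctrl_idx = table.sample_index(sorted(labels.control))
    order = np.concatenate([case_idx, ctrl_idx])
    X = table.values[:, order].T
    y = np.concatenate([np.ones(len(case_idx)), np.zeros(len(ctrl_idx))])
    return X, y


def _cv_press(X, y, k, cv_folds, seed, predictor) -> float:
    """PRESS over stratified folds; ``predictor(Xtr, ytr, Xte, k)`` refits
    the whole pipeline (standardization + components + regression) inside
    each training fold."""
    skf = StratifiedKFold(
        n_splits=cv_folds, shuffle=True, random_state=child_seed(seed, "folds")
    )
    press = 0.0
    for train, test in skf.split(X, y):
        pred = predictor(X[train], y[train], X[test], k)
        press += float(np.sum((y[test] - pred) ** 2))
    return press


def _pcr_predict(Xtr, ytr, Xte, k):
    Xtr_s, Xte_s = _standardize(Xtr, Xte)
    U, s, Vt = np.linalg.svd(Xtr_s, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-10)) if s.size else 0
    k_eff = rank if k == "all" else min(int(k), rank)
    V = Vt[:k_eff].T
    scores = Xtr_s @ V
    design = np.column_stack([np.ones(len(ytr)), scores])
    beta, *_ = np.linalg.lstsq(design, ytr, rcond=None)
    test_scores = Xte_s @ V
    return np.column_stack([np.ones(len(Xte)), test_scores]) @ beta


def _plsr_predict(Xtr, ytr, Xte, k):
    max_k = min(Xtr.shape[0] - 1, Xtr.shape[1])
    k_eff = max_k if k == "all" else min(int(k), max_k)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # deflation can exhaust Y early
        pls = PLSRegression(n_components=k_eff, scale=True)
        pls.fit(Xtr, ytr)
        return pls.predict(Xte).ravel()


def _cv_r2(table, labels, k, cv_folds, seed, predictor) -> float:
    if k != "all" and (not isinstance(k, (int, np.integer)) or k < 1):
        raise ValueError("component count must be a positive integer or 'all'")
    X, y = _design_and_response(table, labels)
    press = _cv_press(X, y, k, cv_folds, seed, predictor)
    tss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / tss


def pcr_cv_r2(
    table: AbundanceTable,
    labels: GroupLabels,
    k: int | str,
    *,
    cv_folds: int = 10,
    seed: int = 0,
) -> float:
    """Cross-validated R² of the 0/1 group indicator regressed on the
    top-k variance-ordered principal-component scores.

    Components, their loadings, and the regression are all refit inside
    each training fold (standardized columns, no leakage).  ``k`` beyond
    the training rank is capped.  The statistic ``1 - PRESS/TSS`` may be
    negative for models worse than the grand mean.
    """
    return _cv_r2(table, labels, k, cv_folds, seed, _pcr_predict)


def plsr_cv_r2(
    table: AbundanceTable,
    labels: GroupLabels,
    k: int | str,
    *,
    cv_folds: int = 10,
    seed: int = 0,
) -> float:
    """Cross-validated R² as :func:`pcr_cv_r2`, but with partial least
    squares components, extracted by successive maximization of
    covariance with the response (NIPALS deflation) per training fold."""
    return _cv_r2(table, labels, k, cv_folds, seed, _plsr_predict)


# ---------------------------------------------------------------------------
# Hill-number diversity family
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HillProfile:
    """Diversity profile: one effective species number per Hill order."""

    orders: tuple[float, ...]
    diversities: tuple[float, ...]


def hill_number(profile, q: float) -> float:
    """Effective number of species of order q.

    ``D_q = (sum_i p_i^q)^(1/(1-q))`` over the nonzero proportions, with
    the limits ``exp(-sum p ln p)`` at q = 1 and ``1/max(p)`` at
    q = inf.  q = 0 is species richness.
    """
    p = np.asarray(profile, dtype=float)
    if (p < 0).any():
        raise ValueError("proportions must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("profile must sum to 1 (relative abundances)")
    if q < 0:
        raise ValueError("Hill order q must be nonnegative")
    p = p[p > 0]
    if np.isinf(q):
        return float(1.0 / p.max())
    if q == 1.0:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


def diversity_family_statistic(
    table: AbundanceTable, labels: GroupLabels, cfg: TechniqueConfig
) -> float:
    """Largest |t| over the family of Hill orders.

    Each sample's relative profile is summarized by one Hill number per
    order in ``cfg.hill_orders``; each order gets a two-sample Welch t
    between groups, and the family statistic is ``max_q |t_q|``.  The
    multiplicity adjustment over the family is supplied by the outer
    resampling calibration, which consumes exactly this maximum.
    """
    rel = normalize_relative(table)
    profiles = np.array(
        [
            [hill_number(rel.values[:, j], q) for j in range(rel.n_samples)]
            for q in cfg.hill_orders
        ]
    )
    case_idx = rel.sample_index(labels.case)
    ctrl_idx = rel.sample_index(labels.control)
    if len(case_idx) < 2 or len(ctrl_idx) < 2:
        raise ValueError("need at least two samples per group")
    t, _ = _welch_arrays(
        profiles[:, case_idx], profiles[:, ctrl_idx], equal_var=cfg.equal_var
    )
    return float(np.max(np.abs(t)))


# ---------------------------------------------------------------------------
# dispatcher
# ---------------------------------------------------------------------------


def compute_statistic(
    table: AbundanceTable,
    labels: GroupLabels,
    cfg: TechniqueConfig,
    *,
    seed: int = 0,
) -> float:
    """Evaluate the configured technique's statistic on a (raw or
    relative) table.  Techniques that require proportions normalize
    internally, so callers can follow the spike-then-normalize order by
    passing the raw spiked table directly."""
    t = cfg.technique
    if t == "metastats_global":
        return float(metastats_global_statistic(table, labels, cfg))
    if t in ("lasso", "ridge", "elastic_net"):
        return penalized_logistic_statistic(table, labels, cfg, seed=seed)
    rel = normalize_relative(table)
    if t == "mdmr":
        return mdmr_pseudo_f(minkowski_distance_matrix(rel, cfg.minkowski_p), labels)
    if t == "pcr":
        return pcr_cv_r2(rel, labels, cfg.n_components, cv_folds=cfg.cv_folds, seed=seed)
    if t == "plsr":
        return plsr_cv_r2(rel, labels, cfg.n_components, cv_folds=cfg.cv_folds, seed=seed)
    if t == "diversity_family":
        return diversity_family_statistic(rel, labels, cfg)
    raise ValueError(f"unknown technique {t!r}")
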