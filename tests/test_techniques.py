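"""The six statistic families: oracles, conventions, and invariances."""

import numpy as np
import pytest
from scipy import stats as sps

from mbpower import (
    AbundanceTable,
    GroupLabels,
    TechniqueConfig,
    compute_statistic,
    diversity_family_statistic,
    fdr_select,
    feature_t_statistic,
    fisher_sparse_feature_pvalue,
    hill_number,
    mdmr_pseudo_f,
    metastats_global_statistic,
    minkowski_distance_matrix,
    pcr_cv_r2,
    penalized_logistic_statistic,
    plsr_cv_r2,
    technique_id,
)
from mbpower.techniques import _pcr_predict


def table_from(values, scale="raw"):
    values = np.asarray(values, dtype=float)
    return AbundanceTable(
        feature_ids=tuple(f"f{i}" for i in range(values.shape[0])),
        sample_ids=tuple(f"s{j}" for j in range(values.shape[1])),
        values=values,
        scale=scale,
    )


def labels_for(table, n_case):
    return GroupLabels(
        case=table.sample_ids[:n_case], control=table.sample_ids[n_case:]
    )


# ---------------------------------------------------------------------------
# Welch t, Fisher, FDR
# ---------------------------------------------------------------------------


def test_welch_t_matches_hand_evaluation():
    a, b = [10.0, 11.0, 12.0], [1.0, 2.0, 3.0]
    t, p = feature_t_statistic(a, b)
    # step-by-step Welch arithmetic as an independent oracle
    ma, mb = np.mean(a), np.mean(b)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    se2 = va / 3 + vb / 3
    t_hand = (ma - mb) / np.sqrt(se2)
    df_hand = se2**2 / ((va / 3) ** 2 / 2 + (vb / 3) ** 2 / 2)
    assert t == pytest.approx(t_hand, abs=1e-12)
    assert p == pytest.approx(2 * sps.t.sf(abs(t_hand), df_hand), abs=1e-12)


def test_welch_t_zero_difference_and_degenerate_conventions():
    assert feature_t_statistic([1, 2, 3], [1, 2, 3]) == (0.0, 1.0)
    assert feature_t_statistic([0, 0, 0, 0], [0, 0, 0, 0]) == (0.0, 1.0)
    with pytest.raises(ValueError):
        feature_t_statistic([1.0], [1.0, 2.0])


def enumerate_fisher_two_sided(a, b, c, d):
    """Full hypergeometric enumeration over tables with fixed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    pmf = lambda x: sps.hypergeom.pmf(x, n, r1, c1)
    observed = pmf(a)
    return sum(
        pmf(x)
        for x in range(max(0, c1 - r2), min(r1, c1) + 1)
        if pmf(x) <= observed * (1 + 1e-9)
    )


def test_fisher_sparse_examples_against_enumeration():
    assert fisher_sparse_feature_pvalue(0, 0, 100, 100) == pytest.approx(1.0)
    p = fisher_sparse_feature_pvalue(5, 0, 0, 5)
    assert p == pytest.approx(2 / 252, rel=1e-9)
    assert p == pytest.approx(enumerate_fisher_two_sided(5, 0, 0, 5), rel=1e-9)
    # symmetry in the group columns
    assert fisher_sparse_feature_pvalue(3, 7, 50, 40) == pytest.approx(
        fisher_sparse_feature_pvalue(7, 3, 40, 50)
    )


def test_fisher_requires_integer_counts():
    with pytest.raises(ValueError):
        fisher_sparse_feature_pvalue(2.5, 0, 5, 5)


def test_fdr_step_up_examples():
    assert fdr_select([0.001] * 10, 0.05).all()
    np.testing.assert_array_equal(
        fdr_select([0.01, 0.04, 0.03, 0.005], 0.05), [True] * 4
    )
    assert not fdr_select([0.9, 0.95], 0.05).any()
    assert fdr_select([], 0.05).size == 0


def test_fdr_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(0)
    for _ in range(20):
        p = rng.random(rng.integers(1, 40))
        expected = multipletests(p, alpha=0.05, method="fdr_bh")[0]
        np.testing.assert_array_equal(fdr_select(p, 0.05), expected)


# ---------------------------------------------------------------------------
# modified-Metastats global statistic
# ---------------------------------------------------------------------------


def test_global_statistic_zero_when_groups_identical():
    rng = np.random.default_rng(1)
    block = rng.lognormal(0, 1, (30, 5))
    table = table_from(np.hstack([block, block]))
    labels = labels_for(table, 5)  # control duplicates the case columns
    cfg = TechniqueConfig(technique="metastats_global")
    assert metastats_global_statistic(table, labels, cfg) == 0


def test_global_statistic_detects_large_shift():
    rng = np.random.default_rng(2)
    values = rng.lognormal(0, 0.5, (100, 88))
    values[0, :44] *= 30.0  # ~10 pooled standard deviations on the log scale
    table = table_from(values)
    labels = labels_for(table, 44)
    cfg = TechniqueConfig(technique="metastats_global")
    stat = metastats_global_statistic(table, labels, cfg)
    assert 1 <= stat <= table.n_features


def test_global_statistic_uses_fisher_branch_on_sparse_counts():
    rng = np.random.default_rng(3)
    counts = rng.poisson(50, (20, 20)).astype(float)
    counts[0] = 0.0
    counts[0, :6] = 1.0  # 6 occurrences, all in the case group
    table = table_from(counts)
    labels = labels_for(table, 10)
    cfg = TechniqueConfig(technique="metastats_global", sparse_total_threshold=8)
    # runs the Fisher branch (counts are integral) without error
    stat = metastats_global_statistic(table, labels, cfg)
    assert 0 <= stat <= 20


def test_global_statistic_needs_two_samples_per_group():
    table = table_from(np.ones((3, 3)))
    labels = GroupLabels(case=(table.sample_ids[0],), control=table.sample_ids[1:])
    with pytest.raises(ValueError):
        metastats_global_statistic(
            table, labels, TechniqueConfig(technique="metastats_global")
        )


# ---------------------------------------------------------------------------
# Minkowski distances and MDMR pseudo-F
# ---------------------------------------------------------------------------


def test_minkowski_hand_values():
    table = table_from(np.array([[0.0, 3.0], [0.0, 4.0]]))
    assert minkowski_distance_matrix(table, 2).d[0, 1] == pytest.approx(5.0)
    assert minkowski_distance_matrix(table, 1).d[0, 1] == pytest.approx(7.0)
    d_half = minkowski_distance_matrix(table, 0.5).d[0, 1]
    assert d_half == pytest.approx((np.sqrt(3) + 2.0) ** 2, rel=1e-6)
    with pytest.raises(ValueError):
        minkowski_distance_matrix(table, 0.0)


def test_mdmr_equals_anova_f_on_univariate_data():
    g1, g2 = [1.0, 2.0, 3.0], [7.0, 8.0, 9.0]
    table = table_from(np.array([g1 + g2]))
    labels = labels_for(table, 3)
    dist = minkowski_distance_matrix(table, 2)
    f_anova = sps.f_oneway(g1, g2).statistic
    assert mdmr_pseudo_f(dist, labels) == pytest.approx(f_anova, abs=1e-10)


def test_mdmr_equals_anova_f_on_random_univariate_groups():
    rng = np.random.default_rng(4)
    g1, g2 = rng.uniform(0, 4, 8), rng.uniform(1, 8, 6)
    table = table_from(np.concatenate([g1, g2])[None, :])
    labels = labels_for(table, 8)
    dist = minkowski_distance_matrix(table, 2)
    assert mdmr_pseudo_f(dist, labels) == pytest.approx(
        sps.f_oneway(g1, g2).statistic, abs=1e-10
    )


def test_mdmr_permutation_null_centers_near_one(small_table):
    dist = minkowski_distance_matrix(small_table, 2)
    rng = np.random.default_rng(5)
    ids = np.array(small_table.sample_ids)
    fs = []
    for _ in range(200):
        perm = rng.permutation(len(ids))
        labels = GroupLabels(case=tuple(ids[perm[:44]]), control=tuple(ids[perm[44:]]))
        fs.append(mdmr_pseudo_f(dist, labels))
    assert 0.7 <= np.mean(fs) <= 1.4


def test_mdmr_invariant_to_relabeling_within_groups(small_table):
    dist = minkowski_distance_matrix(small_table, 1)
    ids = small_table.sample_ids
    a = mdmr_pseudo_f(dist, GroupLabels(case=ids[:44], control=ids[44:]))
    b = mdmr_pseudo_f(
        dist, GroupLabels(case=ids[:44][::-1], control=ids[44:][::-1])
    )
    assert a == pytest.approx(b, rel=1e-12)


def test_mdmr_degenerate_distances_error():
    table = table_from(np.ones((2, 6)))
    labels = labels_for(table, 3)
    dist = minkowski_distance_matrix(table, 2)
    with pytest.raises(ValueError, match="degenerate"):
        mdmr_pseudo_f(dist, labels)


# ---------------------------------------------------------------------------
# PCR / PLSR cross-validated R²
# ---------------------------------------------------------------------------


def pc1_instance(seed=6, n=60, p=30, noise=0.05):
    """Two clusters separated along one dominant direction, so the 0/1
    response is (nearly) linear in the first component score."""
    rng = np.random.default_rng(seed)
    direction = rng.normal(0, 1, p)
    direction /= np.linalg.norm(direction)
    y = np.array([1.0] * (n // 2) + [0.0] * (n - n // 2))
    scores = (2 * y - 1) * 3.0 + rng.normal(0, 0.3, n)
    X = np.outer(scores, direction) + rng.normal(0, noise, (n, p))
    X -= X.min() - 0.1  # abundance tables are nonnegative; a constant
    # shift is absorbed by the per-fold centering
    order = np.argsort(-y, kind="stable")  # cases first
    return table_from(X[order].T), labels_for(table_from(X[order].T), int(y.sum()))


def test_pcr_recovers_pc1_aligned_response():
    table, labels = pc1_instance()
    assert pcr_cv_r2(table, labels, 1, seed=1) > 0.8


def test_pcr_near_zero_for_independent_response():
    rng = np.random.default_rng(7)
    table = table_from(rng.lognormal(0, 1, (40, 60)))
    labels = labels_for(table, 30)
    assert pcr_cv_r2(table, labels, 5, seed=1) <= 0.1


def test_pcr_all_components_reproduce_full_least_squares():
    rng = np.random.default_rng(8)
    X = rng.normal(0, 1, (30, 10))
    y = rng.integers(0, 2, 30).astype(float)
    pred_pcr = _pcr_predict(X, y, X, "all")
    # full-rank OLS on the standardized features is the oracle
    Xs = (X - X.mean(0)) / X.std(0)
    design = np.column_stack([np.ones(30), Xs])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    np.testing.assert_allclose(pred_pcr, design @ beta, atol=1e-10)


def test_plsr_beats_pcr_with_single_informative_feature():
    rng = np.random.default_rng(9)
    n, p = 88, 500
    X = rng.normal(0, 1, (n, p))
    y = np.array([1.0] * 44 + [0.0] * 44)
    X[:, 0] = y + rng.normal(0, 0.3, n)
    X -= X.min() - 0.1  # nonnegative, shift absorbed by standardization
    table = table_from(X.T)
    labels = labels_for(table, 44)
    plsr = plsr_cv_r2(table, labels, 1, seed=2)
    pcr = pcr_cv_r2(table, labels, 1, seed=2)
    # the defining contrast: covariance-driven components find the signal
    # that variance-ranked components ignore
    assert plsr > pcr + 0.05


def test_plsr_deterministic_given_seed(small_table, balanced_labels):
    a = plsr_cv_r2(small_table, balanced_labels, 3, seed=11)
    b = plsr_cv_r2(small_table, balanced_labels, 3, seed=11)
    assert a == b


def test_plsr_single_component_on_aligned_variance():
    table, labels = pc1_instance(seed=10)
    assert plsr_cv_r2(table, labels, 1, seed=3) > 0.8


# ---------------------------------------------------------------------------
# penalized logistic regression
# ---------------------------------------------------------------------------


def test_lasso_null_labels_give_zero_statistic():
    rng = np.random.default_rng(12)
    table = table_from(rng.lognormal(0, 1, (60, 40)))
    labels = labels_for(table, 20)
    cfg = TechniqueConfig(technique="lasso", n_lambdas=30)
    stat = penalized_logistic_statistic(table, labels, cfg, seed=4)
    assert stat == 0.0  # CV keeps the empty model: df = 0


def test_lasso_selects_the_informative_feature():
    rng = np.random.default_rng(13)
    n = 60
    X = rng.lognormal(0, 1, (40, n))
    y_case = 30
    X[5, :y_case] *= 8.0  # feature 5 tracks the case group
    table = table_from(X)
    labels = labels_for(table, y_case)
    cfg = TechniqueConfig(technique="lasso", n_lambdas=30)
    stat, details = penalized_logistic_statistic(
        table, labels, cfg, seed=5, return_details=True
    )
    assert stat > 0.9
    assert 5 in details["nonzero_features"]


def test_ridge_statistic_is_nonnegative():
    rng = np.random.default_rng(14)
    cfg = TechniqueConfig(technique="ridge", n_lambdas=20)
    for seed in range(3):
        table = table_from(rng.lognormal(0, 1, (30, 30)))
        labels = labels_for(table, 15)
        assert penalized_logistic_statistic(table, labels, cfg, seed=seed) >= 0.0


# ---------------------------------------------------------------------------
# Hill numbers and the diversity family
# ---------------------------------------------------------------------------


def test_hill_identities():
    uniform = np.full(5, 0.2)
    for q in (0.0, 0.5, 1.0, 2.0, np.inf):
        assert hill_number(uniform, q) == pytest.approx(5.0)
    assert hill_number([0.5, 0.3, 0.2, 0.0], 0.0) == 3.0  # richness
    assert hill_number([0.9, 0.1], 2.0) == pytest.approx(1.0 / 0.82, rel=1e-9)
    with pytest.raises(ValueError):
        hill_number([0.5, 0.4], 1.0)  # unnormalized


def test_hill_profile_non_increasing_in_q(small_table):
    from mbpower import normalize_relative

    rel = normalize_relative(small_table)
    orders = (0.0, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, np.inf)
    for j in range(0, rel.n_samples, 10):
        profile = [hill_number(rel.values[:, j], q) for q in orders]
        assert all(b <= a + 1e-9 for a, b in zip(profile[:-1], profile[1:]))


def test_diversity_family_zero_for_identical_groups():
    rng = np.random.default_rng(15)
    block = rng.lognormal(0, 1, (30, 5))
    table = table_from(np.hstack([block, block]))
    labels = labels_for(table, 5)
    cfg = TechniqueConfig(technique="diversity_family")
    assert diversity_family_statistic(table, labels, cfg) == 0.0


def test_richness_difference_maximizes_low_order():
    rng = np.random.default_rng(16)
    n_each = 20
    base = rng.dirichlet(np.full(50, 0.8), 2 * n_each).T  # features x samples
    values = np.vstack([base, np.zeros((20, 2 * n_each))])
    # case samples carry 20 extra rare species
    values[50:, :n_each] = 1e-4 * (1 + rng.random((20, n_each)))
    table = table_from(values)
    case = table.sample_ids[:n_each]
    control = table.sample_ids[n_each:]
    from mbpower import normalize_relative

    rel = normalize_relative(table)
    orders = (0.0, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, np.inf)
    ts = []
    for q in orders:
        div = np.array([hill_number(rel.values[:, j], q) for j in range(rel.n_samples)])
        t, _ = feature_t_statistic(div[:n_each], div[n_each:])
        ts.append(abs(t))
    assert orders[int(np.argmax(ts))] <= 0.5


def test_singleton_family_reduces_to_plain_t(small_table, balanced_labels):
    from mbpower import normalize_relative

    cfg = TechniqueConfig(technique="diversity_family", hill_orders=(1.0,))
    stat = diversity_family_statistic(small_table, balanced_labels, cfg)
    rel = normalize_relative(small_table)
    div = np.array(
        [hill_number(rel.values[:, j], 1.0) for j in range(rel.n_samples)]
    )
    case = rel.sample_index(balanced_labels.case)
    ctrl = rel.sample_index(balanced_labels.control)
    t, _ = feature_t_statistic(div[case], div[ctrl])
    assert stat == pytest.approx(abs(t), rel=1e-12)


# ---------------------------------------------------------------------------
# cross-cutting invariances
# ---------------------------------------------------------------------------

CHEAP_CONFIGS = [
    TechniqueConfig(technique="metastats_global"),
    TechniqueConfig(technique="mdmr", minkowski_p=1),
    TechniqueConfig(technique="pcr", n_components=3),
    TechniqueConfig(technique="plsr", n_components=3),
    TechniqueConfig(technique="diversity_family"),
]


@pytest.mark.parametrize("cfg", CHEAP_CONFIGS, ids=technique_id)
def test_statistic_invariant_to_feature_and_sample_order(cfg, small_table):
    ids = small_table.sample_ids
    labels = GroupLabels(case=ids[:44], control=ids[44:])
    base = compute_statistic(small_table, labels, cfg, seed=6)
    assert np.isfinite(base)

    rng = np.random.default_rng(17)
    feat_perm = rng.permutation(small_table.n_features)
    shuffled = AbundanceTable(
        feature_ids=tuple(small_table.feature_ids[i] for i in feat_perm),
        sample_ids=ids,
        values=small_table.values[feat_perm],
        scale=small_table.scale,
    )
    assert compute_statistic(shuffled, labels, cfg, seed=6) == pytest.approx(
        base, rel=1e-9, abs=1e-9
    )

    relabeled = GroupLabels(case=ids[:44][::-1], control=ids[44:][::-1])
    assert compute_statistic(small_table, relabeled, cfg, seed=6) == pytest.approx(
        base, rel=1e-9, abs=1e-9
    )
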