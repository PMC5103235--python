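"""Mean structure, AR(1) algebra, grouped likelihood, ML fitting."""

import math

import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

from allomap.allometry import AllometryParams, Direction, Establishment
from allomap.family_genetics import GenotypeGroups, group_progeny
from allomap.likelihood import (
    Ar1Covariance,
    FitConfig,
    Hypothesis,
    LongitudinalTraitPair,
    MonotonicityWarning,
    PhenotypeMatrix,
    ar1_matrix,
    fit,
    genotype_mean_vector,
    mvn_loglik_ar1,
    total_loglik,
)
from allomap.simulate import QtlEffect, SimulationSpec, simulate_dataset

HD = Direction.HEIGHT_FROM_DIAMETER
DH = Direction.DIAMETER_FROM_HEIGHT


def make_pair(pid, heights, diameters, h0=0.0):
    T = len(heights)
    return LongitudinalTraitPair(
        pid, np.arange(1, T + 1, dtype=float), np.asarray(heights, float),
        np.asarray(diameters, float), Establishment(h0),
    )


# ---------------------------------------------------------------------------
# containers


def test_trait_pair_validation():
    with pytest.raises(ValueError, match="equal length"):
        make_pair("p", [1.0, 2.0], [1.0])
    with pytest.raises(ValueError, match="exceed establishment"):
        make_pair("p", [0.5, 2.0], [1.0, 2.0], h0=1.0)
    with pytest.warns(MonotonicityWarning):
        make_pair("p", [3.0, 2.0], [1.0, 2.0])


def test_ar1_covariance_bounds():
    with pytest.raises(ValueError):
        Ar1Covariance(0.0, 0.5)
    with pytest.raises(ValueError):
        Ar1Covariance(1.0, 1.0)


def test_matrix_requires_common_age_grid():
    a = make_pair("a", [3.0, 4.0], [1.0, 2.0])
    b = LongitudinalTraitPair("b", [1.0, 3.0], [3.0, 4.0], [1.0, 2.0])
    with pytest.raises(ValueError, match="common grid"):
        PhenotypeMatrix.from_pairs([a, b])


# ---------------------------------------------------------------------------
# mean vectors


def test_mean_vector_constant_predictor():
    pair = make_pair("p", [5.0, 5.0, 5.0], [1.0, 1.0, 1.0])
    mu = genotype_mean_vector(AllometryParams(0.0, 0.0, HD), pair)
    assert np.allclose(mu, math.e)


def test_mean_vector_diameter_direction_hand_values():
    pair = make_pair("p", [math.e, math.e**2], [1.0, 2.0])
    mu = genotype_mean_vector(AllometryParams(0.0, 0.0, DH), pair)
    assert np.allclose(mu, [1.0, 0.5])


def test_mean_vector_empty_series():
    pair = LongitudinalTraitPair("p", np.array([]), np.array([]), np.array([]))
    assert genotype_mean_vector(AllometryParams(1.0, 1.0, HD), pair).size == 0


def test_mean_vector_uses_each_progenys_own_predictor():
    """The conditional mean differs across progeny with one shared genotype."""
    p1 = make_pair("p1", [5.0, 6.0], [1.0, 2.0])
    p2 = make_pair("p2", [5.0, 6.0], [3.0, 4.0])
    params = AllometryParams(1.0, 0.5, HD)
    mu1, mu2 = genotype_mean_vector(params, p1), genotype_mean_vector(params, p2)
    assert not np.allclose(mu1, mu2)


# ---------------------------------------------------------------------------
# AR(1) algebra


def test_ar1_matrix_hand_values():
    assert np.allclose(ar1_matrix(Ar1Covariance(1.0, 1e-12), 3), np.eye(3))
    m = ar1_matrix(Ar1Covariance(2.0, 0.5), 3)
    assert np.allclose(m, [[2, 1, 0.5], [1, 2, 1], [0.5, 1, 2]])
    assert np.linalg.det(ar1_matrix(Ar1Covariance(1.0, 0.9), 2)) == pytest.approx(0.19)


def test_ar1_matrix_positive_definite():
    for rho in (-0.9, 0.0, 0.95):
        m = ar1_matrix(Ar1Covariance(0.7, rho), 12)
        assert np.linalg.eigvalsh(m).min() > 0


def test_mvn_loglik_hand_values():
    assert mvn_loglik_ar1(np.array([0.0]), Ar1Covariance(1.0, 1e-15)) == pytest.approx(
        -0.5 * math.log(2 * math.pi)
    )
    val = mvn_loglik_ar1(np.zeros(2), Ar1Covariance(1.0, 0.5))
    assert val == pytest.approx(-math.log(2 * math.pi) - 0.5 * math.log(0.75))


def test_mvn_loglik_independence_limit():
    rng = np.random.default_rng(1)
    r = rng.normal(0, 1.5, 6)
    got = mvn_loglik_ar1(r, Ar1Covariance(2.5, 1e-14))
    assert got == pytest.approx(norm.logpdf(r, scale=math.sqrt(2.5)).sum())


def test_mvn_loglik_matches_dense_oracle():
    """Closed form vs scipy's generic dense MVN over randomized instances."""
    rng = np.random.default_rng(2024)
    for _ in range(60):
        T = int(rng.integers(1, 11))
        cov = Ar1Covariance(float(rng.uniform(0.05, 4)), float(rng.uniform(-0.95, 0.95)))
        r = rng.normal(0, 2, T)
        dense = multivariate_normal(np.zeros(T), ar1_matrix(cov, T)).logpdf(r)
        assert mvn_loglik_ar1(r, cov) == pytest.approx(dense, abs=1e-8)


def test_mvn_loglik_out_of_bounds_scores_minus_inf():
    class Raw:
        sigma2, rho = -1.0, 0.5

    assert mvn_loglik_ar1(np.zeros(3), Raw()) == -math.inf


# ---------------------------------------------------------------------------
# grouped likelihood


def _two_class_setup():
    pairs = [
        make_pair("a", [7.0, 7.5, 8.0], [1.0, 2.0, 3.0]),
        make_pair("b", [6.5, 7.2, 7.9], [1.2, 2.1, 3.3]),
        make_pair("c", [7.1, 7.6, 8.2], [0.9, 1.8, 2.9]),
        make_pair("d", [6.8, 7.4, 8.1], [1.1, 2.2, 3.1]),
    ]
    groups = GenotypeGroups(codes=[0, 1], group_members=[np.array([0, 1]), np.array([2, 3])],
                            n_j=[2, 2])
    return pairs, groups


def test_total_loglik_perfect_fit_value():
    """Zero residuals, sigma2=1, rho=0, T=24: loglik is exactly -12 ln(2 pi)."""
    params = AllometryParams(2.0, 1.0, HD)
    z = np.linspace(1, 20, 24)
    h = 0.3 + np.exp(2.0 + 1.0 / (1.0 + z))
    pair = LongitudinalTraitPair("p", np.arange(1.0, 25.0), h, z, Establishment(0.3))
    groups = GenotypeGroups(codes=[0], group_members=[np.array([0])], n_j=[1])
    ll = total_loglik(groups, [pair], params, Ar1Covariance(1.0, 1e-300), HD)
    assert ll == pytest.approx(-12 * math.log(2 * math.pi))


def test_total_loglik_matches_dense_mvn_oracle():
    pairs, groups = _two_class_setup()
    params = {0: AllometryParams(1.9, 0.9, HD), 1: AllometryParams(2.1, 1.1, HD)}
    cov = Ar1Covariance(0.8, 0.4)
    got = total_loglik(groups, pairs, params, cov, HD)
    dense = 0.0
    sigma = ar1_matrix(cov, 3)
    for code, members in zip(groups.codes, groups.group_members):
        p = params[code]
        for i in members:
            mu = genotype_mean_vector(p, pairs[i])
            dense += multivariate_normal(mu, sigma).logpdf(pairs[i].heights)
    assert got == pytest.approx(dense, abs=1e-8)


def test_tying_identity_two_classes_equal_one_class():
    """Identical class parameters collapse to a pooled single-class value.

    This identity is the null/alternative nesting in miniature.
    """
    pairs, groups = _two_class_setup()
    tied = AllometryParams(2.0, 1.0, HD)
    cov = Ar1Covariance(0.5, 0.3)
    pooled = GenotypeGroups(codes=[0], group_members=[np.arange(4)], n_j=[4])
    assert total_loglik(groups, pairs, tied, cov, HD) == pytest.approx(
        total_loglik(pooled, pairs, tied, cov, HD)
    )


def test_total_loglik_invariant_to_orderings():
    pairs, groups = _two_class_setup()
    params = {0: AllometryParams(1.9, 0.9, HD), 1: AllometryParams(2.1, 1.1, HD)}
    cov = Ar1Covariance(0.8, 0.4)
    base = total_loglik(groups, pairs, params, cov, HD)
    flipped = GenotypeGroups(codes=[1, 0], group_members=[np.array([2, 3]), np.array([0, 1])],
                             n_j=[2, 2])
    assert total_loglik(flipped, pairs, params, cov, HD) == pytest.approx(base)
    shuffled = GenotypeGroups(codes=[0, 1], group_members=[np.array([1, 0]), np.array([3, 2])],
                              n_j=[2, 2])
    assert total_loglik(shuffled, pairs, params, cov, HD) == pytest.approx(base)


def test_invalid_domain_scores_minus_inf():
    pairs, groups = _two_class_setup()
    bad = AllometryParams(1.0, -2.0, HD)  # b + d = 0 at d = 2
    assert total_loglik(groups, pairs, bad, Ar1Covariance(1.0, 0.1), HD) == -math.inf


# ---------------------------------------------------------------------------
# fitting


def test_fit_recovers_noiseless_parameters(fast_fit_config):
    qtl = QtlEffect(0, {0: (2.9, 0.9), 1: (3.0, 1.0), 2: (3.1, 1.1)})
    spec = SimulationSpec(n_progeny=48, T=10, n_snps=1, residual_sigma2=0.0,
                          qtls=[qtl], seed=9)
    snps, pairs = simulate_dataset(spec)
    groups = group_progeny(snps[0])
    alt = fit(groups, pairs, HD, Hypothesis.ALT_GENOTYPE_SPECIFIC, fast_fit_config)
    for code, (a_true, b_true) in qtl.params_by_class.items():
        assert alt.params[code].a == pytest.approx(a_true, rel=1e-4)
        assert alt.params[code].b == pytest.approx(b_true, rel=1e-4)


def test_fit_nesting_and_mle_dominates_truth(small_dataset, small_matrix, fast_fit_config):
    spec, snps, _ = small_dataset
    groups = group_progeny(snps[0])
    null_fit = fit(groups, small_matrix, HD, Hypothesis.NULL_COMMON, fast_fit_config)
    alt_fit = fit(groups, small_matrix, HD, Hypothesis.ALT_GENOTYPE_SPECIFIC,
                  fast_fit_config, warm_start=null_fit)
    assert alt_fit.loglik >= null_fit.loglik - 1e-6
    assert null_fit.n_params == 4 and alt_fit.n_params == 2 * groups.J + 2
    # maximized loglik dominates the value at the generating parameters
    truth = {c: AllometryParams(a, b, HD) for c, (a, b) in
             {0: (2.85, 1.0), 1: (3.0, 1.0), 2: (3.15, 1.0)}.items()}
    true_cov = Ar1Covariance(spec.residual_sigma2, spec.residual_rho)
    assert alt_fit.loglik >= total_loglik(groups, small_matrix, truth, true_cov, HD)


def test_fit_invariant_to_progeny_ordering(small_dataset, fast_fit_config):
    _, snps, pairs = small_dataset
    groups = group_progeny(snps[0])
    f1 = fit(groups, pairs, HD, Hypothesis.NULL_COMMON, fast_fit_config)
    perm = np.random.default_rng(0).permutation(len(pairs))
    pairs2 = [pairs[i] for i in perm]
    inv = np.empty_like(perm)
    inv[perm] = np.arange(len(perm))
    groups2 = GenotypeGroups(codes=groups.codes,
                             group_members=[inv[m] for m in groups.group_members],
                             n_j=groups.n_j)
    f2 = fit(groups2, pairs2, HD, Hypothesis.NULL_COMMON, fast_fit_config)
    assert f2.loglik == pytest.approx(f1.loglik, abs=1e-5)
    assert f2.common_params.a == pytest.approx(f1.common_params.a, abs=1e-3)


def test_fit_diameter_from_height_direction(fast_fit_config):
    spec = SimulationSpec(n_progeny=48, T=10, n_snps=1,
                          direction=DH, residual_sigma2_mi=0.0, seed=21)
    snps, pairs = simulate_dataset(spec)
    groups = group_progeny(snps[0])
    null_fit = fit(groups, pairs, DH, Hypothesis.NULL_COMMON, fast_fit_config)
    a0, b0 = spec.baseline_mi
    assert null_fit.common_params.a == pytest.approx(a0, rel=1e-3)
    assert null_fit.common_params.b == pytest.approx(b0, rel=1e-3)
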