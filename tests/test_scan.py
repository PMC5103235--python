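"""Likelihood-ratio testing, Bonferroni correction, genome scan behaviour."""

import math

import numpy as np
import pytest
from scipy.stats import chi2

from allomap.allometry import Direction
from allomap.family_genetics import SegregationType, SnpRecord
from allomap.likelihood import FitConfig
from allomap.scan import (
    ScanConfig,
    bonferroni_threshold,
    lrt_pvalue,
    manhattan_table,
    results_table,
    scan_genome,
)
from allomap.simulate import SimulationSpec, simulate_dataset

HD = Direction.HEIGHT_FROM_DIAMETER
DH = Direction.DIAMETER_FROM_HEIGHT


@pytest.mark.parametrize(
    "lr,J,expected_df,expected_p",
    [
        (0.0, 3, 4, 1.0),
        (9.488, 3, 4, chi2.sf(9.488, 4)),  # ~0.050
        (3.841, 2, 2, chi2.sf(3.841, 2)),  # ~0.147 (df=2, not 1)
    ],
)
def test_lrt_pvalue_chi_square_oracle(lr, J, expected_df, expected_p):
    got_lr, df, p = lrt_pvalue(0.0, lr / 2.0, J)
    assert got_lr == pytest.approx(lr)
    assert df == expected_df
    assert p == pytest.approx(expected_p, abs=1e-12)
    assert 0.0 <= p <= 1.0


def test_lrt_pvalue_reference_points():
    _, _, p4 = lrt_pvalue(0.0, 9.488 / 2, 3)
    assert p4 == pytest.approx(0.050, abs=5e-4)
    _, _, p2 = lrt_pvalue(0.0, 3.841 / 2, 2)
    assert p2 == pytest.approx(0.147, abs=5e-4)


def test_lrt_small_negative_clipped_to_zero():
    lr, df, p = lrt_pvalue(10.0, 10.0 - 1e-9, 3)
    assert lr == 0.0 and p == 1.0


def test_lrt_negative_beyond_tolerance_gives_nan():
    lr, df, p = lrt_pvalue(10.0, 9.0, 3)
    assert lr < 0 and math.isnan(p)


def test_lrt_requires_two_classes():
    with pytest.raises(ValueError):
        lrt_pvalue(0.0, 1.0, 1)


@pytest.mark.parametrize(
    "alpha,n,expected",
    [(0.01, 1, 0.01), (0.05, 1000, 5e-5), (0.01, 156362, 0.01 / 156362)],
)
def test_bonferroni_threshold(alpha, n, expected):
    assert bonferroni_threshold(alpha, n) == pytest.approx(expected, rel=1e-12)
    assert bonferroni_threshold(0.01, 156362) == pytest.approx(6.40e-8, rel=1e-2)


def test_bonferroni_rejects_bad_inputs():
    with pytest.raises(ValueError):
        bonferroni_threshold(0.05, 0)
    with pytest.raises(ValueError):
        bonferroni_threshold(1.5, 10)


@pytest.fixture(scope="module")
def scan_setup():
    from allomap.simulate import QtlEffect

    qtl = QtlEffect(0, {0: (2.85, 1.0), 1: (3.0, 1.0), 2: (3.15, 1.0)})
    spec = SimulationSpec(n_progeny=64, T=8, n_snps=10, qtls=[qtl], seed=42)
    snps, pairs = simulate_dataset(spec)
    # add an untestable monomorphic SNP
    mono = SnpRecord(
        "3/999", "3", 999, SegregationType.TESTCROSS,
        np.ones(spec.n_progeny, dtype=np.int8),
        snps[0].progeny_ids,
    )
    cfg = ScanConfig(alpha=0.01, fit=FitConfig(n_restarts=2, seed=5))
    return spec, snps + [mono], pairs, cfg


def test_scan_reports_every_snp_in_genome_order(scan_setup):
    spec, snps, pairs, cfg = scan_setup
    results = scan_genome(snps, pairs, HD, cfg)
    assert len(results) == len(snps)
    keys = [( (0, int(r.chromosome)) if r.chromosome.isdigit() else (1, 0), r.position)
            for r in results]
    assert keys == sorted(keys)
    untestable = [r for r in results if not r.testable]
    assert len(untestable) == 1 and "monomorphic" in untestable[0].reason
    for r in results:
        if r.testable:
            assert r.alt_loglik >= r.null_loglik - 1e-6
            assert 0.0 <= r.p_value <= 1.0
            assert r.df == 2 * (r.J - 1)


def test_planted_qtl_attains_min_pvalue_and_significance(scan_setup):
    spec, snps, pairs, cfg = scan_setup
    results = scan_genome(snps, pairs, HD, cfg)
    tested = [r for r in results if r.testable]
    best = min(tested, key=lambda r: r.p_value)
    assert best.snp_id == snps[0].snp_id
    assert best.significant  # huge effect passes even the Bonferroni bar


def test_scan_invariant_to_snp_input_order(scan_setup):
    spec, snps, pairs, cfg = scan_setup
    r1 = scan_genome(snps, pairs, HD, cfg)
    shuffled = [snps[i] for i in np.random.default_rng(3).permutation(len(snps))]
    r2 = scan_genome(shuffled, pairs, HD, cfg)
    assert [r.snp_id for r in r1] == [r.snp_id for r in r2]
    p1 = {r.snp_id: r.p_value for r in r1 if r.testable}
    p2 = {r.snp_id: r.p_value for r in r2 if r.testable}
    assert p1.keys() == p2.keys()
    for k in p1:
        assert p1[k] == pytest.approx(p2[k], rel=1e-9, abs=1e-300)


def test_pi_and_mi_scans_are_independent(scan_setup):
    """The two directions are separate tests; a SNP may appear in both."""
    spec, snps, pairs, cfg = scan_setup
    r_pi = scan_genome(snps[:4], pairs, HD, cfg)
    r_mi = scan_genome(snps[:4], pairs, DH, cfg)
    assert [r.direction for r in r_pi] == [HD] * 4
    assert [r.direction for r in r_mi] == [DH] * 4
    for a, b in zip(r_pi, r_mi):
        if a.testable and b.testable:
            assert a.null_loglik != pytest.approx(b.null_loglik)


def test_empty_progeny_intersection_is_hard_error(scan_setup):
    spec, snps, pairs, cfg = scan_setup
    alien = SnpRecord(
        "1/5", "1", 5, SegregationType.INTERCROSS,
        np.array([0, 1, 2], dtype=np.int8), ["X1", "X2", "X3"],
    )
    with pytest.raises(ValueError, match="no progeny IDs shared"):
        scan_genome([alien], pairs, HD, cfg)


def test_n_tests_override_changes_threshold(scan_setup):
    spec, snps, pairs, cfg = scan_setup
    loose = ScanConfig(alpha=0.5, n_tests_override=1, fit=cfg.fit)
    r = scan_genome(snps[:3], pairs, HD, loose)
    # with threshold 0.5 some null SNPs may pass; with 0.5/10^6 none should
    strict = ScanConfig(alpha=0.5, n_tests_override=10**9, fit=cfg.fit)
    r2 = scan_genome(snps[1:3], pairs, HD, strict)
    assert not any(x.significant for x in r2)


def test_result_tables_roundtrip_fields(scan_setup):
    spec, snps, pairs, cfg = scan_setup
    results = scan_genome(snps[:3], pairs, HD, cfg)
    df = results_table(results)
    assert len(df) == 3
    assert {"snp_id", "lr", "df", "p_value", "significant", "sigma2", "rho"} <= set(df.columns)
    man = manhattan_table(results)
    assert list(man.columns) == ["chromosome", "position", "neg_log10_p"]
    tested = [r for r in results if r.testable]
    assert len(man) == len(tested)
    assert np.allclose(man["neg_log10_p"], [-math.log10(r.p_value) for r in tested])
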