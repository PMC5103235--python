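"""Per-SNP likelihood-ratio genome scan for allometry QTLs.

Each testable SNP is fitted twice: under the null (one allometric
coefficient pair tied across genotype classes) and the alternative (one
pair per class), with the AR(1) covariance re-estimated in each fit. The
statistic LR = 2*(alt - null) is referred to a chi-square with
df = 2*(J - 1) — each genotype class beyond the first frees one (a, b)
pair — and genome-wide significance uses a Bonferroni threshold over the
number of SNPs actually tested.

Scanning for pioneering QTLs (height conditioned on diameter) and
maintaining QTLs (diameter conditioned on height) are two invocations of
the same machinery with the direction flipped; a locus may be significant
in both, which is the structural signature of a pleiotropic QTL.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from allomap.allometry import AllometryParams, Direction
from allomap.family_genetics import (
    DEFAULT_MIN_CLASS_SIZE,
    GenotypeGroups,
    SnpRecord,
    group_progeny,
)
from allomap.likelihood import (
    Ar1Covariance,
    FitConfig,
    Hypothesis,
    LongitudinalTraitPair,
    ModelFit,
    PhenotypeMatrix,
    fit,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ScanConfig",
    "ScanResult",
    "lrt_pvalue",
    "bonferroni_threshold",
    "scan_genome",
    "results_table",
    "manhattan_table",
]

#: Numerical slack on the nesting guarantee alt >= null.
LR_TOLERANCE = 1e-6


@dataclass
class ScanConfig:
    """Scan-wide options: significance level, class filter, optimizer."""

    alpha: float = 0.01
    n_tests_override: int | None = None  # Bonferroni denominator override
    min_class_size: int = DEFAULT_MIN_CLASS_SIZE
    fit: FitConfig = field(default_factory=FitConfig)

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")


@dataclass
class ScanResult:
    """Everything reported for one SNP in one scan direction."""

    snp_id: str
    chromosome: str
    position: int
    direction: Direction
    seg_type: str
    testable: bool
    reason: str | None = None
    J: int = 0
    n_j: list[int] = field(default_factory=list)
    null_loglik: float = math.nan
    alt_loglik: float = math.nan
    lr: float = math.nan
    df: int = 0
    p_value: float = math.nan
    significant: bool = False
    params_by_class: dict[int, AllometryParams] = field(default_factory=dict)
    null_params: AllometryParams | None = None
    covariance: Ar1Covariance | None = None
    converged: bool = True


def lrt_pvalue(
    null_loglik: float, alt_loglik: float, J: int, tolerance: float = LR_TOLERANCE
) -> tuple[float, int, float]:
    """Likelihood-ratio statistic, degrees of freedom, and p-value.

    LR = 2*(alt - null), clipped at zero; df = 2*(J - 1). A negative LR
    beyond ``tolerance`` signals a non-converged alternative fit and
    yields p = NaN rather than a fabricated probability.
    """
    if J < 2:
        raise ValueError(f"LRT needs J >= 2 genotype classes, got {J}")
    lr = 2.0 * (alt_loglik - null_loglik)
    df = 2 * (J - 1)
    if lr < -tolerance or not math.isfinite(lr):
        return lr, df, math.nan
    lr = max(lr, 0.0)
    return lr, df, float(stats.chi2.sf(lr, df))


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError(f"n_tests must be >= 1, got {n_tests}")
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    return alpha / n_tests


def _chrom_sort_key(chrom: str):
    return (0, int(chrom), "") if chrom.isdigit() else (1, 0, chrom)


def _subset_groups(groups: GenotypeGroups, row_map: np.ndarray) -> GenotypeGroups:
    """Re-express group member indices as rows of the phenotype matrix."""
    members = [row_map[m] for m in groups.group_members]
    return GenotypeGroups(
        codes=groups.codes,
        group_members=members,
        n_j=[m.size for m in members],
        testable=groups.testable,
        reason=groups.reason,
        dropped=groups.dropped,
    )


def scan_genome(
    snps: list[SnpRecord],
    data: list[LongitudinalTraitPair] | PhenotypeMatrix,
    direction: Direction,
    config: ScanConfig | None = None,
) -> list[ScanResult]:
    """LRT scan of every SNP against the longitudinal phenotypes.

    Progeny are matched by ID between the genotype table and the phenotype
    records (intersection; mismatches logged). The null model does not
    depend on genotype grouping, so its fit is cached per distinct set of
    progeny with observed genotypes and reused across SNPs. Output is in
    genome order (chromosome, then position) regardless of input order;
    untestable SNPs are reported with a reason code, never silently
    dropped.
    """
    config = config or ScanConfig()
    mat = data if isinstance(data, PhenotypeMatrix) else PhenotypeMatrix.from_pairs(list(data))
    pheno_index = {pid: i for i, pid in enumerate(mat.progeny_ids)}

    results: list[ScanResult] = []
    null_cache: dict[tuple[int, ...], ModelFit] = {}
    order = sorted(
        range(len(snps)), key=lambda i: (_chrom_sort_key(snps[i].chromosome), snps[i].position)
    )
    n_tested = 0
    for idx in order:
        snp = snps[idx]
        if snp.progeny_ids is not None:
            shared = [pid for pid in snp.progeny_ids if pid in pheno_index]
            if not shared:
                raise ValueError(
                    f"{snp.snp_id}: no progeny IDs shared between genotypes and phenotypes"
                )
            if len(shared) < len(snp.progeny_ids):
                logger.info(
                    "%s: %d genotyped progeny lack phenotypes",
                    snp.snp_id,
                    len(snp.progeny_ids) - len(shared),
                )
            keep = [k for k, pid in enumerate(snp.progeny_ids) if pid in pheno_index]
            geno = snp.genotypes[keep]
            row_map = np.array([pheno_index[snp.progeny_ids[k]] for k in keep])
            sub = SnpRecord(snp.snp_id, snp.chromosome, snp.position, snp.seg_type, geno, None)
        else:
            if snp.genotypes.size != mat.n:
                raise ValueError(
                    f"{snp.snp_id}: {snp.genotypes.size} genotypes for {mat.n} phenotyped progeny "
                    "and no progeny IDs to reconcile them"
                )
            row_map = np.arange(mat.n)
            sub = snp

        groups = _subset_groups(group_progeny(sub, config.min_class_size), row_map)
        res = ScanResult(
            snp_id=snp.snp_id,
            chromosome=snp.chromosome,
            position=snp.position,
            direction=direction,
            seg_type=snp.seg_type.value,
            testable=groups.testable,
            reason=groups.reason,
            J=groups.J,
            n_j=list(groups.n_j),
        )
        if not groups.testable:
            logger.info("%s skipped: %s", snp.snp_id, groups.reason)
            results.append(res)
            continue

        cache_key = tuple(sorted(np.concatenate(groups.group_members).tolist()))
        null_fit = null_cache.get(cache_key)
        if null_fit is None:
            null_fit = fit(groups, mat, direction, Hypothesis.NULL_COMMON, config.fit)
            null_cache[cache_key] = null_fit
        alt_fit = fit(
            groups, mat, direction, Hypothesis.ALT_GENOTYPE_SPECIFIC, config.fit, warm_start=null_fit
        )
        lr, df, p = lrt_pvalue(null_fit.loglik, alt_fit.loglik, groups.J)
        res.null_loglik = null_fit.loglik
        res.alt_loglik = alt_fit.loglik
        res.lr, res.df, res.p_value = lr, df, p
        res.params_by_class = alt_fit.params
        res.null_params = null_fit.common_params
        res.covariance = alt_fit.covariance
        res.converged = null_fit.converged and alt_fit.converged and math.isfinite(p)
        n_tested += 1
        results.append(res)

    n_tests = config.n_tests_override or max(n_tested, 1)
    threshold = bonferroni_threshold(config.alpha, n_tests)
    for res in results:
        if res.testable and math.isfinite(res.p_value):
            res.significant = res.p_value <= threshold
    logger.info(
        "scan (%s): %d SNPs tested, %d untestable, Bonferroni threshold %.3e",
        direction.short,
        n_tested,
        len(results) - n_tested,
        threshold,
    )
    return results


def results_table(results: list[ScanResult]) -> pd.DataFrame:
    """Flatten scan results into one row per SNP."""
    rows = []
    for r in results:
        row = {
            "snp_id": r.snp_id,
            "chromosome": r.chromosome,
            "position": r.position,
            "direction": r.direction.short,
            "seg_type": r.seg_type,
            "testable": r.testable,
            "reason": r.reason or "",
            "J": r.J,
            "n_j": ",".join(map(str, r.n_j)),
            "null_loglik": r.null_loglik,
            "alt_loglik": r.alt_loglik,
            "lr": r.lr,
            "df": r.df,
            "p_value": r.p_value,
            "significant": r.significant,
            "converged": r.converged,
            "sigma2": r.covariance.sigma2 if r.covariance else math.nan,
            "rho": r.covariance.rho if r.covariance else math.nan,
            "null_a": r.null_params.a if r.null_params else math.nan,
            "null_b": r.null_params.b if r.null_params else math.nan,
        }
        for code in (0, 1, 2):
            p = r.params_by_class.get(code)
            row[f"a_{code}"] = p.a if p else math.nan
            row[f"b_{code}"] = p.b if p else math.nan
        rows.append(row)
    return pd.DataFrame(rows)


def manhattan_table(results: list[ScanResult]) -> pd.DataFrame:
    """chromosome, position, -log10(p) for the tested SNPs."""
    rows = [
        {
            "chromosome": r.chromosome,
            "position": r.position,
            "neg_log10_p": -math.log10(r.p_value) if r.p_value > 0 else math.inf,
        }
        for r in results
        if r.testable and math.isfinite(r.p_value)
    ]
    return pd.DataFrame(rows, columns=["chromosome", "position", "neg_log10_p"])
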