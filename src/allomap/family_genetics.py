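"""Full-sib marker semantics.

A single cross between two heterozygous parents produces two kinds of
segregating SNPs: *testcross* markers (one parent heterozygous, the other
homozygous; progeny split 1:1 into two genotype classes) and *intercross*
markers (both parents heterozygous; progeny split 1:2:1 into three
classes). Genotypes are coded as copies of a designated reference allele,
0/1/2, with -1 for missing.

This module classifies markers, partitions progeny into genotype classes,
and decomposes fitted per-genotype mean curves into additive and dominance
effect trajectories along the predictor trait.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from allomap.allometry import (
    AllometryParams,
    Direction,
    diameter_mean_matrix,
    height_mean_matrix,
)

__all__ = [
    "MISSING",
    "SegregationType",
    "SnpRecord",
    "GenotypeGroups",
    "EffectTrajectories",
    "NonSegregatingError",
    "classify_segregation",
    "group_progeny",
    "effect_trajectories",
]

#: Missing-genotype sentinel in integer code arrays.
MISSING = -1

#: Default minimum progeny per genotype class; with ~64 full sibs a 1:2:1
#: marker yields ~16/32/16, so this only trims pathological markers.
DEFAULT_MIN_CLASS_SIZE = 5


class SegregationType(str, enum.Enum):
    TESTCROSS = "testcross"  # one parent heterozygous: 1:1, two classes
    INTERCROSS = "intercross"  # both parents heterozygous: 1:2:1, three classes


class NonSegregatingError(ValueError):
    """Both parents homozygous: the marker cannot segregate in the family."""


@dataclass
class SnpRecord:
    """One segregating SNP with per-progeny genotype codes.

    ``snp_id`` follows the "chromosome/position" convention
    (e.g. ``"5/4226091"``); ``genotypes`` counts copies of the reference
    allele, in {0, 1, 2} with -1 for missing.
    """

    snp_id: str
    chromosome: str
    position: int
    seg_type: SegregationType
    genotypes: np.ndarray
    progeny_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        observed = self.genotypes[self.genotypes != MISSING]
        if observed.size and not np.isin(observed, (0, 1, 2)).all():
            raise ValueError(f"{self.snp_id}: genotype codes must be 0/1/2 or -1 (missing)")
        n_classes = np.unique(observed).size
        if self.seg_type is SegregationType.TESTCROSS and n_classes > 2:
            raise ValueError(f"{self.snp_id}: testcross marker with {n_classes} genotype classes")


@dataclass
class GenotypeGroups:
    """Partition of progeny indices into genotype classes for one SNP.

    ``testable`` is False when fewer than two classes survive the
    minimum-class-size filter; ``reason`` then says why — the scan skips
    such SNPs with a logged reason rather than raising.
    """

    codes: list[int]  # genotype code of each retained class, ascending
    group_members: list[np.ndarray]  # progeny indices per class
    n_j: list[int]
    testable: bool = True
    reason: str | None = None
    dropped: list[int] = field(default_factory=list)  # codes dropped as too small

    @property
    def J(self) -> int:
        return len(self.codes)


@dataclass
class EffectTrajectories:
    """Additive and dominance effects along the predictor trait.

    NaN marks grid points where some genotype mean curve is undefined
    (emitted as gaps). ``dominant`` is None for two-class (testcross)
    markers, where only an additive contrast exists.
    """

    predictor_grid: np.ndarray
    additive: np.ndarray
    dominant: np.ndarray | None


def classify_segregation(parent1_genotype: int, parent2_genotype: int) -> SegregationType:
    """Classify a marker from the two parental genotype codes.

    Intercross iff both parents are heterozygous (code 1); testcross iff
    exactly one is. Raises :class:`NonSegregatingError` when neither is.
    """
    for g in (parent1_genotype, parent2_genotype):
        if g not in (0, 1, 2):
            raise ValueError(f"parental genotype code must be 0/1/2, got {g}")
    het1 = parent1_genotype == 1
    het2 = parent2_genotype == 1
    if het1 and het2:
        return SegregationType.INTERCROSS
    if het1 or het2:
        return SegregationType.TESTCROSS
    raise NonSegregatingError(
        f"both parents homozygous ({parent1_genotype}, {parent2_genotype}): marker does not segregate"
    )


def group_progeny(snp: SnpRecord, min_class_size: int = DEFAULT_MIN_CLASS_SIZE) -> GenotypeGroups:
    """Partition progeny into genotype classes, dropping small classes.

    Classes are ordered by ascending genotype code. Classes with fewer
    than ``min_class_size`` members are dropped; if fewer than two classes
    remain the SNP is flagged untestable (not an exception — the genome
    scan records the reason and moves on).
    """
    codes_all = np.asarray(snp.genotypes)
    observed_mask = codes_all != MISSING
    codes, kept, dropped = [], [], []
    for code in np.unique(codes_all[observed_mask]):
        members = np.flatnonzero(codes_all == code)
        if members.size >= min_class_size:
            codes.append(int(code))
            kept.append(members)
        else:
            dropped.append(int(code))
    if len(codes) < 2:
        n_obs = int(observed_mask.sum())
        reason = (
            "monomorphic among progeny"
            if np.unique(codes_all[observed_mask]).size < 2
            else f"fewer than 2 classes with >= {min_class_size} progeny (n observed = {n_obs})"
        )
        return GenotypeGroups(codes, kept, [m.size for m in kept], False, reason, dropped)
    return GenotypeGroups(codes, kept, [m.size for m in kept], True, None, dropped)


def _mean_curve(params: AllometryParams, h0: float, grid: np.ndarray) -> np.ndarray:
    if params.direction is Direction.HEIGHT_FROM_DIAMETER:
        return height_mean_matrix(params.a, params.b, np.array([h0]), grid[None, :])[0]
    return diameter_mean_matrix(params.a, params.b, np.array([h0]), grid[None, :])[0]


def effect_trajectories(
    mean_curves: dict[int, AllometryParams],
    grid,
    h0: float = 0.0,
) -> EffectTrajectories:
    """Decompose per-genotype mean curves into additive/dominance effects.

    ``mean_curves`` maps genotype code -> fitted :class:`AllometryParams`;
    all entries must share one direction. With three classes (intercross)
    the standard codominant decomposition at each grid point x is

        additive  a(x) = [mu_2(x) - mu_0(x)] / 2
        dominant  d(x) = mu_1(x) - [mu_2(x) + mu_0(x)] / 2

    which is exactly invertible: mu_2 = m + a, mu_0 = m - a, mu_1 = m + d
    with m the homozygote midpoint. Two classes yield the additive
    contrast only. Grid points where any curve is undefined are NaN.
    """
    grid = np.asarray(grid, dtype=float)
    codes = sorted(mean_curves)
    directions = {mean_curves[c].direction for c in codes}
    if len(directions) != 1:
        raise ValueError("all genotype curves must share one scaling direction")
    if len(codes) == 3:
        mu0, mu1, mu2 = (_mean_curve(mean_curves[c], h0, grid) for c in codes)
        additive = (mu2 - mu0) / 2.0
        dominant = mu1 - (mu2 + mu0) / 2.0
        return EffectTrajectories(grid, additive, dominant)
    if len(codes) == 2:
        mu_lo, mu_hi = (_mean_curve(mean_curves[c], h0, grid) for c in codes)
        return EffectTrajectories(grid, (mu_hi - mu_lo) / 2.0, None)
    raise ValueError(f"need 2 or 3 genotype classes, got {len(codes)}")
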