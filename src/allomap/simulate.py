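"""Synthetic full-sib datasets for end-to-end testing and calibration.

No raw data from the motivating poplar experiment are deposited anywhere,
so the generator emulates its *structure*: a single full-sib family of
~64 progeny measured annually for 24 growing seasons, genotyped at SNPs
that segregate either 1:1 (testcross — one parent heterozygous) or 1:2:1
(intercross — both parents heterozygous), with roughly 60% testcross
markers as in the original marker panel.

Phenotypes follow the package's own generative model exactly:

  * the conditioning trait grows along a logistic curve with
    progeny-level jitter on its asymptote and inflection age (the model
    conditions on observed values, so any smooth monotone curve serves;
    logistic is a standard bounded growth law);
  * the response trait's mean is the allometric equation evaluated at
    the progeny's conditioning series, with genotype-specific (a, b) at
    planted QTL markers and a family-wide baseline elsewhere;
  * a stationary AR(1) Gaussian residual series is added to the response.

QTL effects are injected only through the allometric coefficients — never
through the conditioning curve — which isolates exactly the signal the
likelihood-ratio scan claims to detect. SNPs are generated without
linkage: the scan tests markers marginally.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from allomap.allometry import Direction, Establishment, diameter_mean_matrix, height_mean_matrix
from allomap.family_genetics import SegregationType, SnpRecord
from allomap.likelihood import LongitudinalTraitPair, MonotonicityWarning

logger = logging.getLogger(__name__)

__all__ = [
    "LogisticCurve",
    "QtlEffect",
    "SimulationSpec",
    "simulate_genotypes",
    "simulate_trajectories",
    "simulate_dataset",
]

#: Testcross fraction of the original 156,362-SNP panel (94,591 testcross).
DEFAULT_PROP_TESTCROSS = 94591.0 / 156362.0

#: Populus has 19 chromosomes.
N_CHROMOSOMES = 19


@dataclass(frozen=True)
class LogisticCurve:
    """Bounded growth law K / (1 + exp(-rate * (t - midpoint)))."""

    asymptote: float
    rate: float
    midpoint: float

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return self.asymptote / (1.0 + np.exp(-self.rate * (np.asarray(t, float) - self.midpoint)))


@dataclass(frozen=True)
class QtlEffect:
    """A planted QTL: genotype code -> absolute (a, b) of the sim direction.

    Two codes make a testcross QTL, three an intercross QTL. When several
    QTLs are planted their displacements from the baseline combine
    additively on the (a, b) scale.
    """

    snp_index: int
    params_by_class: dict[int, tuple[float, float]]

    @property
    def seg_type(self) -> SegregationType:
        return (
            SegregationType.INTERCROSS
            if len(self.params_by_class) == 3
            else SegregationType.TESTCROSS
        )


@dataclass
class SimulationSpec:
    """Study-structure parameters; defaults mirror the emulated experiment.

    Units: heights and the establishment height in metres, diameters in
    centimetres, ages in years. ``residual_sigma2`` may be zero for
    noiseless self-consistency checks.

    The pioneering direction (height conditioned on diameter) grows the
    diameter logistically and places heights on the allometric curve; the
    maintaining direction does the reverse. Default coefficient baselines
    put the simulated trees at plausible sizes for a fast-growing
    24-season poplar trial (heights ~20-30 m, basal diameters up to
    ~28 cm).
    """

    n_progeny: int = 64
    T: int = 24
    n_snps: int = 100
    proportion_testcross: float = DEFAULT_PROP_TESTCROSS
    direction: Direction = Direction.HEIGHT_FROM_DIAMETER
    baseline: tuple[float, float] = (3.0, 1.0)  # (a, b) for height-from-diameter
    baseline_mi: tuple[float, float] = (-1.0, -6.0)  # (a, b) for diameter-from-height
    qtls: list[QtlEffect] = field(default_factory=list)
    diameter_curve: LogisticCurve = field(default_factory=lambda: LogisticCurve(28.0, 0.30, 9.0))
    height_curve: LogisticCurve = field(default_factory=lambda: LogisticCurve(26.0, 0.25, 10.0))
    asymptote_cv: float = 0.12  # progeny-level lognormal jitter on the asymptote
    midpoint_sd: float = 1.0  # progeny-level jitter on the inflection age (years)
    residual_sigma2: float = 1.0  # height residual variance, m^2 (pi direction)
    residual_sigma2_mi: float = 0.09  # diameter residual variance, cm^2 (mi direction)
    residual_rho: float = 0.7
    h0_range: tuple[float, float] = (0.2, 0.6)  # establishment-year height, m
    missing_rate: float = 0.0
    seed: int = 0

    @property
    def ages(self) -> np.ndarray:
        return np.arange(1, self.T + 1, dtype=float)

    def baseline_for(self, direction: Direction) -> tuple[float, float]:
        return (
            self.baseline if direction is Direction.HEIGHT_FROM_DIAMETER else self.baseline_mi
        )


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def progeny_ids(n: int) -> list[str]:
    return [f"P{i + 1:04d}" for i in range(n)]


def simulate_genotypes(spec: SimulationSpec) -> list[SnpRecord]:
    """Draw Mendelian genotypes for every SNP of the panel.

    Testcross markers sample progeny codes from {0, 1} with probability
    1/2 each; intercross markers from {0, 1, 2} with (1/4, 1/2, 1/4).
    SNPs are independent (no linkage map). Planted QTL markers are forced
    to the segregation type their effect dictionary implies.
    """
    rng = _rng(spec.seed, 0)
    ids = progeny_ids(spec.n_progeny)
    qtl_by_index = {q.snp_index: q for q in spec.qtls}
    if any(i >= spec.n_snps or i < 0 for i in qtl_by_index):
        raise ValueError("QTL snp_index outside the simulated panel")

    chroms = rng.integers(1, N_CHROMOSOMES + 1, size=spec.n_snps)
    positions = rng.integers(1, 50_000_000, size=spec.n_snps)
    is_testcross = rng.random(spec.n_snps) < spec.proportion_testcross
    snps: list[SnpRecord] = []
    for k in range(spec.n_snps):
        qtl = qtl_by_index.get(k)
        if qtl is not None:
            seg = qtl.seg_type
        else:
            seg = SegregationType.TESTCROSS if is_testcross[k] else SegregationType.INTERCROSS
        if seg is SegregationType.TESTCROSS:
            codes = rng.choice([0, 1], size=spec.n_progeny, p=[0.5, 0.5])
        else:
            codes = rng.choice([0, 1, 2], size=spec.n_progeny, p=[0.25, 0.5, 0.25])
        if spec.missing_rate > 0:
            codes = np.where(rng.random(spec.n_progeny) < spec.missing_rate, -1, codes)
        snps.append(
            SnpRecord(
                snp_id=f"{chroms[k]}/{positions[k]}",
                chromosome=str(chroms[k]),
                position=int(positions[k]),
                seg_type=seg,
                genotypes=codes.astype(np.int8),
                progeny_ids=ids,
            )
        )
    return snps


def _ar1_series(rng: np.random.Generator, n: int, T: int, sigma2: float, rho: float) -> np.ndarray:
    """Stationary AR(1) Gaussian residuals, (n, T)."""
    if sigma2 == 0.0:
        return np.zeros((n, T))
    sigma = np.sqrt(sigma2)
    out = np.empty((n, T))
    out[:, 0] = rng.normal(0.0, sigma, n)
    innov_sd = sigma * np.sqrt(1.0 - rho * rho)
    for t in range(1, T):
        out[:, t] = rho * out[:, t - 1] + rng.normal(0.0, innov_sd, n)
    return out


def _progeny_ab(spec: SimulationSpec, snps: list[SnpRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Per-progeny (a, b) from the baseline plus additive QTL displacements."""
    a0, b0 = spec.baseline_for(spec.direction)
    a = np.full(spec.n_progeny, a0)
    b = np.full(spec.n_progeny, b0)
    for qtl in spec.qtls:
        codes = snps[qtl.snp_index].genotypes
        for i in range(spec.n_progeny):
            code = int(codes[i])
            if code == -1:  # missing genotype: carries the baseline
                continue
            qa, qb = qtl.params_by_class[code]
            a[i] += qa - a0
            b[i] += qb - b0
    return a, b


def simulate_trajectories(
    spec: SimulationSpec, genotypes: list[SnpRecord]
) -> list[LongitudinalTraitPair]:
    """Generate height/diameter series for every progeny.

    The conditioning trait follows a progeny-jittered logistic curve; the
    response trait sits on the genotype's allometric curve through the
    conditioning values, plus stationary AR(1) residuals. Residual draws
    that push a height to or below the establishment height are redrawn
    (up to 100 attempts, then clamped), with the rejection count logged.
    """
    rng = _rng(spec.seed, 1)
    ids = progeny_ids(spec.n_progeny)
    ages = spec.ages
    n, T = spec.n_progeny, spec.T
    h0 = rng.uniform(*spec.h0_range, size=n)
    a, b = _progeny_ab(spec, genotypes)

    base = (
        spec.diameter_curve
        if spec.direction is Direction.HEIGHT_FROM_DIAMETER
        else spec.height_curve
    )
    asym = base.asymptote * np.exp(rng.normal(0.0, spec.asymptote_cv, n))
    mid = base.midpoint + rng.normal(0.0, spec.midpoint_sd, n)
    predictor = asym[:, None] / (1.0 + np.exp(-base.rate * (ages[None, :] - mid[:, None])))

    if spec.direction is Direction.HEIGHT_FROM_DIAMETER:
        z = predictor  # diameters, exogenous and monotone
        mean_y = height_mean_matrix(a[:, None], b[:, None], h0, z)
        if not np.isfinite(mean_y).all():
            raise ValueError("allometric coefficients put the mean curve outside its domain")
        sigma2 = spec.residual_sigma2
        y = mean_y + _ar1_series(rng, n, T, sigma2, spec.residual_rho)
        # keep heights strictly above the establishment height
        n_rejected = 0
        for i in range(n):
            tries = 0
            while np.any(y[i] <= h0[i]) and tries < 100:
                y[i] = mean_y[i] + _ar1_series(rng, 1, T, sigma2, spec.residual_rho)[0]
                tries += 1
                n_rejected += 1
            if np.any(y[i] <= h0[i]):
                y[i] = np.maximum(y[i], h0[i] + 0.01)
        if n_rejected:
            logger.info("redrew %d residual series to keep heights above h0", n_rejected)
    else:
        y = h0[:, None] + predictor  # heights, exogenous, monotone, > h0
        mean_z = diameter_mean_matrix(a[:, None], b[:, None], h0, y)
        if not np.isfinite(mean_z).all():
            raise ValueError("allometric coefficients put the mean curve outside its domain")
        z = mean_z + _ar1_series(rng, n, T, spec.residual_sigma2_mi, spec.residual_rho)

    pairs = []
    with warnings.catch_warnings():
        # residual noise legitimately breaks monotonicity in sampled series
        warnings.simplefilter("ignore", MonotonicityWarning)
        for i in range(n):
            pairs.append(
                LongitudinalTraitPair(
                    progeny_id=ids[i],
                    ages=ages,
                    heights=y[i],
                    diameters=z[i],
                    h0=Establishment(float(h0[i])),
                )
            )
    return pairs


def simulate_dataset(
    spec: SimulationSpec,
) -> tuple[list[SnpRecord], list[LongitudinalTraitPair]]:
    """Genotypes and matching trajectories in one call."""
    snps = simulate_genotypes(spec)
    return snps, simulate_trajectories(spec, snps)
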