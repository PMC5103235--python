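"""Grouped multivariate-normal likelihood with AR(1) longitudinal covariance.

One SNP, one scaling direction: progeny are partitioned into genotype
classes j = 1..J, each class carries its own allometric coefficient pair
(a_j, b_j), and the length-T trait vector of progeny i in class j is
modelled as multivariate normal with

  * mean vector given by the allometric equation evaluated at progeny i's
    *own observed* values of the conditioning trait (the model's defining
    structure: the genotypic value of one growth trait at each age is
    driven by the phenotypic value of its allometrically related trait),
  * a stationary first-order autoregressive covariance shared by all
    classes, Sigma(s, t) = sigma2 * rho**|s - t|.

The AR(1) closed forms keep the T x T algebra O(T):

  log|Sigma| = T*ln(sigma2) + (T - 1)*ln(1 - rho**2)
  r' Sigma^{-1} r = [r_1^2 + r_T^2 + (1 + rho^2) * sum_{2..T-1} r_t^2
                     - 2*rho * sum_{2..T} r_t r_{t-1}] / (sigma2*(1 - rho^2))

Maximum-likelihood fitting is by Nelder-Mead simplex search with
multi-start over the allometric coefficients and a bounded transform of
rho; the stationary variance is profiled out analytically at each
proposal (its conditional MLE is the mean scaled quadratic form), which
keeps the search space small and behaves gracefully as residual variance
approaches zero.
"""

from __future__ import annotations

import enum
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from allomap.allometry import (
    AllometryParams,
    Direction,
    Establishment,
    diameter_mean_matrix,
    height_mean_matrix,
)
from allomap.family_genetics import GenotypeGroups

logger = logging.getLogger(__name__)

__all__ = [
    "LongitudinalTraitPair",
    "MonotonicityWarning",
    "Ar1Covariance",
    "Hypothesis",
    "ModelFit",
    "FitConfig",
    "PhenotypeMatrix",
    "ar1_matrix",
    "mvn_loglik_ar1",
    "genotype_mean_vector",
    "total_loglik",
    "fit",
]

_LOG_2PI = math.log(2.0 * math.pi)


class MonotonicityWarning(UserWarning):
    """A height or diameter series is not non-decreasing in age.

    Stem-analysis data are monotone by construction; measurement or
    simulation noise need not be. The model itself does not require
    monotonicity, so this is advisory only.
    """

#: Floor on the profiled variance; keeps the log finite when residuals
#: vanish (noiseless data) while leaving the optimum's location intact.
_SIGMA2_FLOOR = 1e-300

#: |rho| bound used by the tanh transform during optimization.
_RHO_BOUND = 0.999


class Hypothesis(str, enum.Enum):
    NULL_COMMON = "null_common"  # one (a, b) tied across genotype classes
    ALT_GENOTYPE_SPECIFIC = "alt_genotype_specific"  # one (a_j, b_j) per class


@dataclass
class LongitudinalTraitPair:
    """Complete height and diameter series for one progeny.

    Heights are metres, diameters centimetres, ages years; the two series
    share one age grid with no gaps (complete-case analysis). Heights must
    strictly exceed the establishment-year height h0. Non-monotone series
    are tolerated with a warning (stem-analysis data are monotone by
    construction, but the model itself does not require it).
    """

    progeny_id: str
    ages: np.ndarray
    heights: np.ndarray
    diameters: np.ndarray
    h0: Establishment = field(default_factory=Establishment)

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        self.diameters = np.asarray(self.diameters, dtype=float)
        if not (self.ages.shape == self.heights.shape == self.diameters.shape):
            raise ValueError(
                f"{self.progeny_id}: ages, heights, diameters must have equal length"
            )
        if self.ages.ndim != 1:
            raise ValueError(f"{self.progeny_id}: series must be one-dimensional")
        if np.any(np.diff(self.ages) <= 0):
            raise ValueError(f"{self.progeny_id}: ages must be strictly increasing")
        if np.any(self.heights <= self.h0.h0):
            raise ValueError(
                f"{self.progeny_id}: all heights must exceed establishment height {self.h0.h0}"
            )
        for name, series in (("heights", self.heights), ("diameters", self.diameters)):
            if np.any(np.diff(series) < 0):
                warnings.warn(
                    f"{self.progeny_id}: {name} are not non-decreasing in age",
                    MonotonicityWarning,
                    stacklevel=2,
                )

    @property
    def T(self) -> int:
        return self.ages.size


@dataclass(frozen=True)
class Ar1Covariance:
    """Stationary variance and lag-one correlation of the AR(1) structure."""

    sigma2: float
    rho: float

    def __post_init__(self) -> None:
        if not (self.sigma2 > 0):
            raise ValueError(f"sigma2 must be positive, got {self.sigma2}")
        if not (-1.0 < self.rho < 1.0):
            raise ValueError(f"rho must lie in (-1, 1), got {self.rho}")


@dataclass
class ModelFit:
    """Result of one maximum-likelihood fit (null or alternative)."""

    hypothesis: Hypothesis
    direction: Direction
    params: dict[int, AllometryParams]  # class code -> params; {-1: tied} under the null
    covariance: Ar1Covariance
    loglik: float
    n_params: int
    converged: bool
    n_restarts_used: int

    @property
    def common_params(self) -> AllometryParams:
        if self.hypothesis is not Hypothesis.NULL_COMMON:
            raise ValueError("common_params is defined only for a null fit")
        return next(iter(self.params.values()))


@dataclass
class FitConfig:
    """Optimizer settings for :func:`fit`.

    ``n_restarts`` counts Nelder-Mead starts: the first from the
    log-linearized least-squares initializer (null) or the null solution
    (alternative), the rest from jittered copies. The reported fit is the
    best across starts; ``converged`` is set when the final improvement
    over the runner-up start is below ``restart_ftol``.
    """

    n_restarts: int = 5
    seed: int = 0
    maxiter_per_param: int = 200
    xatol: float = 1e-6
    fatol: float = 1e-9
    jitter_scale: float = 0.1
    restart_ftol: float = 1e-8


# ---------------------------------------------------------------------------
# AR(1) building blocks


def ar1_matrix(cov: Ar1Covariance, T: int) -> np.ndarray:
    """Dense T x T AR(1) covariance: entry (s, t) = sigma2 * rho**|s-t|."""
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    idx = np.arange(T)
    return cov.sigma2 * cov.rho ** np.abs(idx[:, None] - idx[None, :])


def _ar1_quadform(resid: np.ndarray, rho: float) -> np.ndarray:
    """Per-row quadratic form r' (Sigma/sigma2)^{-1} r for AR(1), O(T).

    ``resid`` is (n, T); uses the tridiagonal inverse of the unit-variance
    AR(1) correlation matrix.
    """
    T = resid.shape[1]
    if T == 1:
        return resid[:, 0] ** 2
    sq = resid**2
    core = sq[:, 0] + sq[:, -1] + (1.0 + rho * rho) * sq[:, 1:-1].sum(axis=1)
    cross = (resid[:, 1:] * resid[:, :-1]).sum(axis=1)
    return (core - 2.0 * rho * cross) / (1.0 - rho * rho)


def mvn_loglik_ar1(residuals: np.ndarray, cov: Ar1Covariance) -> float:
    """Log-density of a length-T residual vector under the AR(1) MVN.

    Uses the closed-form determinant and tridiagonal inverse; agrees with
    a dense multivariate-normal evaluation to high precision. Returns -inf
    for out-of-bounds (sigma2, rho) supplied as raw floats via duck-typed
    objects rather than raising, so optimizer proposals stay scored.
    """
    r = np.atleast_2d(np.asarray(residuals, dtype=float))
    T = r.shape[1]
    sigma2, rho = cov.sigma2, cov.rho
    if not (sigma2 > 0 and -1.0 < rho < 1.0):
        return -math.inf
    logdet = T * math.log(sigma2) + (T - 1) * math.log1p(-rho * rho)
    quad = _ar1_quadform(r, rho)[0] / sigma2
    return -0.5 * (T * _LOG_2PI + logdet + quad)


# ---------------------------------------------------------------------------
# Mean structure


def genotype_mean_vector(params_j: AllometryParams, individual: LongitudinalTraitPair) -> np.ndarray:
    """Length-T conditional mean vector for one progeny under genotype j.

    Height-from-diameter: element t is the allometric height at the
    progeny's own observed diameter z_i(t); diameter-from-height:
    the allometric diameter at the observed height y_i(t). Invalid
    evaluations come back NaN and are propagated by the likelihood
    as a -inf contribution.
    """
    h0 = np.array([individual.h0.h0])
    if params_j.direction is Direction.HEIGHT_FROM_DIAMETER:
        return height_mean_matrix(params_j.a, params_j.b, h0, individual.diameters[None, :])[0]
    return diameter_mean_matrix(params_j.a, params_j.b, h0, individual.heights[None, :])[0]


@dataclass
class PhenotypeMatrix:
    """Column-aligned phenotype arrays for fast likelihood evaluation.

    Built once from a collection of :class:`LongitudinalTraitPair` sharing
    one age grid and reused across every SNP of a genome scan.
    """

    progeny_ids: list[str]
    ages: np.ndarray
    heights: np.ndarray  # (n, T)
    diameters: np.ndarray  # (n, T)
    h0: np.ndarray  # (n,)

    @classmethod
    def from_pairs(cls, pairs: list[LongitudinalTraitPair]) -> "PhenotypeMatrix":
        if not pairs:
            raise ValueError("no phenotype records supplied")
        ages = pairs[0].ages
        for p in pairs[1:]:
            if p.ages.shape != ages.shape or not np.allclose(p.ages, ages):
                raise ValueError(
                    f"{p.progeny_id}: ages do not match the common grid "
                    f"(complete-case analysis requires one shared grid)"
                )
        return cls(
            progeny_ids=[p.progeny_id for p in pairs],
            ages=ages.copy(),
            heights=np.vstack([p.heights for p in pairs]),
            diameters=np.vstack([p.diameters for p in pairs]),
            h0=np.array([p.h0.h0 for p in pairs]),
        )

    @property
    def n(self) -> int:
        return len(self.progeny_ids)

    @property
    def T(self) -> int:
        return self.ages.size

    def response_predictor(self, direction: Direction) -> tuple[np.ndarray, np.ndarray]:
        if direction is Direction.HEIGHT_FROM_DIAMETER:
            return self.heights, self.diameters
        return self.diameters, self.heights


def _coerce_matrix(data) -> PhenotypeMatrix:
    if isinstance(data, PhenotypeMatrix):
        return data
    return PhenotypeMatrix.from_pairs(list(data))


def _residual_matrix(
    mat: PhenotypeMatrix,
    direction: Direction,
    class_rows: list[np.ndarray],
    class_ab: list[tuple[float, float]],
) -> np.ndarray | None:
    """Stacked residuals for all listed progeny; None if any mean invalid."""
    resp, pred = mat.response_predictor(direction)
    blocks = []
    for rows, (a, b) in zip(class_rows, class_ab):
        if direction is Direction.HEIGHT_FROM_DIAMETER:
            mean = height_mean_matrix(a, b, mat.h0[rows], pred[rows])
        else:
            mean = diameter_mean_matrix(a, b, mat.h0[rows], pred[rows])
        if not np.isfinite(mean).all():
            return None
        blocks.append(resp[rows] - mean)
    return np.vstack(blocks)


def total_loglik(
    groups: GenotypeGroups,
    data,
    params: dict[int, AllometryParams] | AllometryParams,
    cov: Ar1Covariance,
    direction: Direction,
) -> float:
    """Grouped log-likelihood: sum over classes and their progeny.

    ``params`` is either one pair applied to every class (the tied null)
    or a dict keyed by genotype class code. Any invalid mean evaluation
    makes the whole value -inf.
    """
    mat = _coerce_matrix(data)
    if isinstance(params, AllometryParams):
        class_ab = [(params.a, params.b)] * groups.J
    else:
        class_ab = [(params[c].a, params[c].b) for c in groups.codes]
    resid = _residual_matrix(mat, direction, groups.group_members, class_ab)
    if resid is None:
        return -math.inf
    T = mat.T
    logdet = T * math.log(cov.sigma2) + (T - 1) * math.log1p(-cov.rho**2)
    quad = _ar1_quadform(resid, cov.rho).sum() / cov.sigma2
    n = resid.shape[0]
    return -0.5 * (n * T * _LOG_2PI + n * logdet + quad)


# ---------------------------------------------------------------------------
# Fitting


def _profiled_negloglik(
    theta: np.ndarray,
    mat: PhenotypeMatrix,
    direction: Direction,
    class_rows: list[np.ndarray],
    n_classes: int,
) -> float:
    """-loglik with sigma2 profiled out; theta = (a_1, b_1, ..., atanh-ish rho)."""
    class_ab = [(theta[2 * j], theta[2 * j + 1]) for j in range(n_classes)]
    rho = _RHO_BOUND * math.tanh(theta[-1])
    resid = _residual_matrix(mat, direction, class_rows, class_ab)
    if resid is None:
        return math.inf
    n, T = resid.shape
    quad = _ar1_quadform(resid, rho).sum()
    sigma2_hat = max(quad / (n * T), _SIGMA2_FLOOR)
    ll = -0.5 * (
        n * T * (_LOG_2PI + 1.0 + math.log(sigma2_hat)) + n * (T - 1) * math.log1p(-rho * rho)
    )
    return -ll


def _lagged_autocorr(resid: np.ndarray) -> float:
    if resid.shape[1] < 2:
        return 0.0
    x, y = resid[:, :-1].ravel(), resid[:, 1:].ravel()
    denom = math.sqrt(float((x * x).sum()) * float((y * y).sum()))
    if denom <= 0:
        return 0.0
    return float(np.clip((x * y).sum() / denom, -0.95, 0.95))


def _initial_ab(
    mat: PhenotypeMatrix, direction: Direction, rows: np.ndarray
) -> tuple[float, float]:
    """Log-linearized least-squares initializer on one progeny subset.

    Height-from-diameter: ln(y - h0) = a + 1/(b + z); scan a coarse grid
    of b on both branches, a has a closed form per candidate b. The
    diameter-from-height direction swaps the roles: scan a, solve b.
    """
    resp, pred = mat.response_predictor(direction)
    resp, pred, h0 = resp[rows], pred[rows], mat.h0[rows]
    offsets = np.geomspace(0.05, 60.0, 48)
    if direction is Direction.HEIGHT_FROM_DIAMETER:
        excess = resp - h0[:, None]
        ok = excess > 0
        if ok.sum() < 3:
            return 0.0, 1.0
        v = np.log(excess[ok])
        z = pred[ok]
        best = (math.inf, 0.0, 1.0)
        for b in np.concatenate([-z.min() + offsets, -z.max() - offsets]):
            x = 1.0 / (b + z)
            a = float(np.mean(v - x))
            sse = float(((v - x - a) ** 2).sum())
            if sse < best[0]:
                best = (sse, a, b)
        return best[1], best[2]
    # diameter-from-height: z ~ 1/(ln(y - h0) - a) - b
    excess = pred - h0[:, None]
    ok = excess > 0
    if ok.sum() < 3:
        return 0.0, 1.0
    w = np.log(excess[ok])
    z = resp[ok]
    best = (math.inf, 0.0, 1.0)
    for a in np.concatenate([w.min() - offsets, w.max() + offsets]):
        recip = 1.0 / (w - a)
        b = float(np.mean(recip - z))
        sse = float(((recip - b - z) ** 2).sum())
        if sse < best[0]:
            best = (sse, a, b)
    return best[1], best[2]


def fit(
    groups: GenotypeGroups,
    data,
    direction: Direction,
    hypothesis: Hypothesis,
    config: FitConfig | None = None,
    warm_start: ModelFit | None = None,
) -> ModelFit:
    """Maximize the grouped AR(1) MVN likelihood by multi-start simplex search.

    Under the null hypothesis a single (a, b) pair is tied across genotype
    classes; under the alternative each class is free. The stationary
    variance is profiled out analytically; rho is searched through a tanh
    transform. When ``warm_start`` (typically the null fit) is given, its
    solution seeds the first start, so the alternative's maximized
    log-likelihood can never fall below the null's.
    """
    config = config or FitConfig()
    mat = _coerce_matrix(data)
    if hypothesis is Hypothesis.ALT_GENOTYPE_SPECIFIC and groups.J < 2:
        raise ValueError("alternative fit requires at least two genotype classes")
    if hypothesis is Hypothesis.NULL_COMMON:
        class_rows = [np.concatenate(groups.group_members)] if groups.group_members else []
        n_classes = 1
    else:
        class_rows = groups.group_members
        n_classes = groups.J
    if not class_rows or sum(r.size for r in class_rows) == 0:
        raise ValueError("no progeny to fit")

    rng = np.random.default_rng(config.seed)
    dim = 2 * n_classes + 1

    # first start: least-squares initializer (null) or warm start (alt)
    if warm_start is not None and hypothesis is Hypothesis.ALT_GENOTYPE_SPECIFIC:
        ab0 = []
        base = warm_start.common_params if warm_start.hypothesis is Hypothesis.NULL_COMMON else None
        for code in groups.codes:
            p = base if base is not None else warm_start.params[code]
            ab0.extend([p.a, p.b])
        rho0 = warm_start.covariance.rho
    else:
        ab0 = []
        for rows in class_rows:
            a0, b0 = _initial_ab(mat, direction, rows)
            ab0.extend([a0, b0])
        # rho from the initializer's residuals
        class_ab = [(ab0[2 * j], ab0[2 * j + 1]) for j in range(n_classes)]
        resid = _residual_matrix(mat, direction, class_rows, class_ab)
        rho0 = _lagged_autocorr(resid) if resid is not None else 0.0
    t0 = math.atanh(np.clip(rho0 / _RHO_BOUND, -0.999, 0.999))
    theta0 = np.array(ab0 + [t0])

    args = (mat, direction, class_rows, n_classes)
    best_f = math.inf
    best_theta = theta0
    history: list[float] = []
    maxiter = config.maxiter_per_param * dim
    n_used = 0
    for k in range(max(config.n_restarts, 1)):
        start = theta0 if k == 0 else theta0 + rng.normal(0.0, config.jitter_scale, dim) * (
            1.0 + np.abs(theta0)
        )
        if not np.isfinite(_profiled_negloglik(start, *args)):
            start = theta0  # jitter landed outside the domain; reuse the base start
        res = optimize.minimize(
            _profiled_negloglik,
            start,
            args=args,
            method="Nelder-Mead",
            options={
                "maxiter": maxiter,
                "xatol": config.xatol,
                "fatol": config.fatol,
                "adaptive": dim > 4,
            },
        )
        n_used = k + 1
        history.append(float(res.fun))
        if res.fun < best_f:
            best_f = float(res.fun)
            best_theta = res.x

    converged = bool(np.isfinite(best_f)) and (
        len(history) < 2 or (sorted(history)[1] - best_f) < max(config.restart_ftol, abs(best_f) * 1e-9)
        or min(history[:-1]) - best_f < config.restart_ftol
    )

    rho_hat = _RHO_BOUND * math.tanh(best_theta[-1])
    class_ab = [(best_theta[2 * j], best_theta[2 * j + 1]) for j in range(n_classes)]
    resid = _residual_matrix(mat, direction, class_rows, class_ab)
    if resid is None:
        raise RuntimeError("optimizer returned an invalid-domain solution")
    n_tot, T = resid.shape
    sigma2_hat = max(float(_ar1_quadform(resid, rho_hat).sum()) / (n_tot * T), 1e-12)
    cov = Ar1Covariance(sigma2_hat, rho_hat)
    if hypothesis is Hypothesis.NULL_COMMON:
        tied = AllometryParams(class_ab[0][0], class_ab[0][1], direction)
        params = {code: tied for code in (groups.codes or [-1])} or {-1: tied}
        n_params = 4
    else:
        params = {
            code: AllometryParams(a, b, direction)
            for code, (a, b) in zip(groups.codes, class_ab)
        }
        n_params = 2 * groups.J + 2
    return ModelFit(
        hypothesis=hypothesis,
        direction=direction,
        params=params,
        covariance=cov,
        loglik=-best_f,
        n_params=n_params,
        converged=converged,
        n_restarts_used=n_used,
    )
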