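"""Height-diameter allometric scaling equations.

The deterministic mathematical core of the package: one power-law-family
equation per scaling direction, with an exact analytic inversion.

Stem height ``H`` above its establishment-year value ``H0`` scales with
stem diameter ``D`` as

    H = H0 + exp(a + 1 / (b + D))                    (height-from-diameter)

and, inverting for the diameter a tree of height ``H`` carries,

    D = 1 / (ln(H - H0) - a) - b                     (diameter-from-height)

The two forms are mathematically interchangeable descriptions of the same
curve, but when each is fitted conditionally on the *observed* values of
its predictor trait — height regressed on observed diameters, or diameter
on observed heights — the two directions carry different residual
structures and therefore different fitted power coefficients ``(a, b)``.
This directional asymmetry is what separates loci modulating height gain
per unit diameter ("pioneering") from loci modulating girth gain per unit
height ("maintaining").

No sign constraint is imposed on ``a`` or ``b``: the equation has two
branches (``b + D > 0`` and ``b + D < 0``) and fitted coefficients may
live on either. On each branch the raw curve is strictly decreasing in
its predictor (dH/dD = -exp(a + 1/(b+D)) / (b+D)^2 < 0); the sign and
magnitude of fitted coefficients absorb this so that realistic data are
still well described.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Direction",
    "AllometryParams",
    "Establishment",
    "AllometryDomainError",
    "predict_height",
    "predict_diameter",
    "log_height_excess",
    "height_mean_matrix",
    "diameter_mean_matrix",
]

#: Singularity guard: |b + D| or |ln(H - H0) - a| below this is treated as
#: a domain violation rather than evaluated.
SINGULARITY_EPS = 1e-12

#: Largest exponent passed to exp(); beyond this the evaluation is flagged
#: invalid instead of overflowing (optimizers probe extreme parameters).
MAX_EXPONENT = 700.0


class Direction(str, enum.Enum):
    """Which trait is modelled conditionally on which."""

    HEIGHT_FROM_DIAMETER = "height_from_diameter"  # piQTL scan direction
    DIAMETER_FROM_HEIGHT = "diameter_from_height"  # miQTL scan direction

    @property
    def short(self) -> str:
        return "pi" if self is Direction.HEIGHT_FROM_DIAMETER else "mi"


class AllometryDomainError(ValueError):
    """Raised when a direct call hits a singular or invalid input."""


@dataclass(frozen=True)
class AllometryParams:
    """Power-coefficient pair (a, b) for one scaling direction.

    Both coefficients are dimensionless finite reals; ``direction`` records
    which equation they parameterize.
    """

    a: float
    b: float
    direction: Direction = Direction.HEIGHT_FROM_DIAMETER

    def __post_init__(self) -> None:
        if not (math.isfinite(self.a) and math.isfinite(self.b)):
            raise ValueError(f"allometry coefficients must be finite, got a={self.a}, b={self.b}")


@dataclass(frozen=True)
class Establishment:
    """Stem height in the establishment (planting) year, metres.

    Acts as the vertical offset of the allometric curve; any height value
    fed to the diameter-from-height equation must strictly exceed it.
    """

    h0: float = 0.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.h0) or self.h0 < 0:
            raise ValueError(f"establishment height must be finite and >= 0, got {self.h0}")


def _as_h0(h0: Establishment | float) -> float:
    return h0.h0 if isinstance(h0, Establishment) else float(h0)


def log_height_excess(a: float, b: float, d):
    """ln(H - H0) as a function of diameter: a + 1/(b + d).

    Internal log-space form used by the likelihood; returns NaN where the
    exponent is singular or would overflow exp().
    """
    d = np.asarray(d, dtype=float)
    denom = b + d
    with np.errstate(divide="ignore", invalid="ignore"):
        expo = a + 1.0 / denom
    bad = (np.abs(denom) < SINGULARITY_EPS) | ~np.isfinite(expo) | (expo > MAX_EXPONENT)
    return np.where(bad, np.nan, expo)


def predict_height(params: AllometryParams, h0: Establishment | float, d):
    """Stem height at diameter ``d``: ``h0 + exp(a + 1/(b + d))``.

    Strictly greater than ``h0`` wherever defined (exponential positivity).

    Raises
    ------
    AllometryDomainError
        If ``b + d`` is (numerically) zero at any requested diameter.
    """
    h0v = _as_h0(h0)
    expo = log_height_excess(params.a, params.b, d)
    if np.any(np.isnan(expo)):
        d_arr = np.atleast_1d(np.asarray(d, dtype=float))
        offending = d_arr[np.isnan(np.atleast_1d(expo))]
        raise AllometryDomainError(
            f"singular exponent b + d ~ 0 (or overflow) at diameter(s) {offending!r} with b={params.b}"
        )
    out = h0v + np.exp(expo)
    return float(out) if np.isscalar(d) else out


def predict_diameter(params: AllometryParams, h0: Establishment | float, h):
    """Stem diameter at height ``h``: ``1/(ln(h - h0) - a) - b``.

    Exact inverse of :func:`predict_height` for a shared ``(a, b)`` pair.

    Raises
    ------
    AllometryDomainError
        If ``h <= h0`` (logarithm undefined) or ``ln(h - h0) == a``
        (singularity of the reciprocal).
    """
    h0v = _as_h0(h0)
    h_arr = np.atleast_1d(np.asarray(h, dtype=float))
    excess = h_arr - h0v
    if np.any(excess <= 0):
        offending = h_arr[np.atleast_1d(excess <= 0)]
        raise AllometryDomainError(
            f"height(s) {offending!r} do not exceed establishment height h0={h0v}"
        )
    u = np.log(excess) - params.a
    if np.any(np.abs(u) < SINGULARITY_EPS):
        offending = h_arr[np.atleast_1d(np.abs(u) < SINGULARITY_EPS)]
        raise AllometryDomainError(
            f"singularity ln(h - h0) = a at height(s) {offending!r} with a={params.a}"
        )
    out = 1.0 / u - params.b
    return float(out[0]) if np.isscalar(h) else out


def height_mean_matrix(a, b, h0, z):
    """Vectorized height means: h0[:, None] + exp(a + 1/(b + z)).

    Parameters may be scalars (one genotype class) applied to an (n, T)
    predictor-diameter matrix ``z``. Invalid entries (singular exponent,
    overflow) come back as NaN so the likelihood can score the proposal
    -inf instead of raising; raising is reserved for direct user calls.
    """
    expo = log_height_excess(a, b, z)
    with np.errstate(over="ignore", invalid="ignore"):
        out = np.asarray(h0)[..., None] + np.exp(expo)
    return out


def diameter_mean_matrix(a, b, h0, y):
    """Vectorized diameter means: 1/(ln(y - h0) - a) - b, NaN where invalid."""
    y = np.asarray(y, dtype=float)
    excess = y - np.asarray(h0)[..., None]
    with np.errstate(divide="ignore", invalid="ignore"):
        u = np.log(excess) - a
        out = 1.0 / u - b
    bad = (excess <= 0) | (np.abs(u) < SINGULARITY_EPS)
    return np.where(bad, np.nan, out)
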