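"""Deterministic diploid selection algebra.

Single-locus, two-allele viability selection with the standard
parameterization

    w_aa = 1,   w_Aa = 1 + h*s,   w_AA = 1 + s,

where ``s`` is the selection coefficient of the derived/selected allele A
and ``h`` its dominance coefficient.  One generation of deterministic
selection changes the allele frequency by

    dp = s * p * (1 - p) * [p + h * (1 - 2p)] / w_bar,

which can be written in haploid form dp = S * p * (1 - p) with the
*effective* selection coefficient

    S = s * [p + h * (1 - 2p)] / w_bar.

On the logit scale the haploid form gives an approximately linear
trajectory, logit(p_t) ~ logit(p_0) + S * t, which is what a logistic
regression of allele counts on time estimates.  With additive dominance
(h = 0.5) the bracket equals 1/2 at every frequency, so the logit slope
estimates s/2; away from h = 0.5 the S <-> s mapping depends on p, which
is why :func:`s_from_S` takes a reference frequency.

Mean fitness is always computed exactly; the familiar rare/intermediate/
near-fixation limits (S ~ sh when rare, ~ s/2 at intermediate p,
~ s(1-h) near fixation) are treated as asymptotic approximations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FitnessParams",
    "FrequencyState",
    "InversionError",
    "mean_fitness",
    "deterministic_delta_p",
    "effective_selection",
    "s_from_S",
    "deterministic_trajectory",
    "logit",
    "expit",
]


class InversionError(ValueError):
    """No selection coefficient with positive genotype fitnesses maps to the requested S."""


@dataclass(frozen=True)
class FitnessParams:
    """A (selection coefficient, dominance coefficient) pair.

    Parameters
    ----------
    s
        Selection coefficient of the AA homozygote relative to aa
        (per generation, may be negative).
    h
        Dominance coefficient scaling the heterozygote advantage;
        0 = recessive, 0.5 = additive, 1 = dominant.
    """

    s: float
    h: float = 0.5

    def __post_init__(self) -> None:
        if not (1.0 + self.s > 0.0 and 1.0 + self.h * self.s > 0.0):
            raise ValueError(
                f"genotype fitnesses must be strictly positive: s={self.s}, h={self.h}"
            )

    @property
    def w_aa(self) -> float:
        return 1.0

    @property
    def w_Aa(self) -> float:
        return 1.0 + self.h * self.s

    @property
    def w_AA(self) -> float:
        return 1.0 + self.s


@dataclass(frozen=True)
class FrequencyState:
    """Allele frequency together with the implied population mean fitness."""

    p: float
    w_bar: float

    @classmethod
    def from_params(cls, p: float, fp: FitnessParams) -> "FrequencyState":
        return cls(p=float(p), w_bar=float(mean_fitness(p, fp)))


def _check_p(p):
    p = np.asarray(p, dtype=float)
    if np.any(p < 0.0) or np.any(p > 1.0):
        raise ValueError("allele frequency must lie in [0, 1]")
    return p


def logit(p):
    """log(p / (1 - p)); requires p strictly inside (0, 1)."""
    p = np.asarray(p, dtype=float)
    return np.log(p) - np.log1p(-p)


def expit(x):
    """Inverse logit, numerically stable for large |x|."""
    from scipy.special import expit as _expit

    return _expit(np.asarray(x, dtype=float))


def mean_fitness(p, fp: FitnessParams):
    """Population mean fitness w_bar = p^2 (1+s) + 2 p (1-p)(1+hs) + (1-p)^2."""
    p = _check_p(p)
    return 1.0 + fp.s * p**2 + 2.0 * fp.h * fp.s * p * (1.0 - p)


def deterministic_delta_p(p, fp: FitnessParams):
    """One-generation change in allele frequency under viability selection.

    dp = s p (1-p) [p + h (1-2p)] / w_bar.  Vanishes at the absorbing
    boundaries p = 0 and p = 1.
    """
    p = _check_p(p)
    w = mean_fitness(p, fp)
    return fp.s * p * (1.0 - p) * (p + fp.h * (1.0 - 2.0 * p)) / w


def effective_selection(p, fp: FitnessParams):
    """Effective (haploid-equivalent) selection coefficient.

    S = s [p + h (1-2p)] / w_bar, the coefficient satisfying
    dp = S p (1-p) exactly.
    """
    p = _check_p(p)
    w = mean_fitness(p, fp)
    return fp.s * (p + fp.h * (1.0 - 2.0 * p)) / w


def s_from_S(S: float, h: float, p: float) -> float:
    """Invert the effective selection coefficient back to the true s.

    Solves S = s a / (1 + s b) with a = p + h (1-2p) and
    b = p^2 + 2 h p (1-p); the map is linear-fractional in s, so the
    root is available in closed form, s = S / (a - S b).  The result is
    validated against the positivity of all genotype fitnesses.

    Parameters
    ----------
    S
        Effective selection coefficient to invert.
    h
        Dominance coefficient assumed for the inversion.
    p
        Reference allele frequency, strictly inside (0, 1).
    """
    if not (0.0 < p < 1.0):
        raise ValueError("reference frequency must be strictly inside (0, 1)")
    a = p + h * (1.0 - 2.0 * p)
    b = p**2 + 2.0 * h * p * (1.0 - p)
    denom = a - S * b
    if a == 0.0 or denom <= 0.0:
        raise InversionError(
            f"no admissible selection coefficient for S={S}, h={h}, p={p}"
        )
    s = S / denom
    if not (1.0 + s > 0.0 and 1.0 + h * s > 0.0):
        raise InversionError(
            f"inverted s={s} implies non-positive genotype fitness (S={S}, h={h}, p={p})"
        )
    return s


def deterministic_trajectory(p0: float, fp: FitnessParams, t: int) -> np.ndarray:
    """Iterate the selection recursion for ``t`` generations.

    Returns an array of length ``t + 1`` with path[0] = p0.  Each step is
    clamped to [0, 1] to absorb floating-point overshoot; the recursion
    itself is boundary-respecting.
    """
    if t < 0:
        raise ValueError("number of generations must be non-negative")
    _check_p(p0)
    path = np.empty(t + 1, dtype=float)
    path[0] = p0
    for k in range(t):
        p = path[k]
        p_next = p + deterministic_delta_p(p, fp)
        path[k + 1] = min(1.0, max(0.0, float(p_next)))
    return path
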