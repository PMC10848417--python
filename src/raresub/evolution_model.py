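"""Sequential mutation-acquisition likelihoods: driver vs passenger models.

The probability (up to a shared proportionality constant, which cancels in
every model comparison) that a series of ``k`` mutations, ``d`` of them
drivers, was sequentially acquired within one clonal lineage of a tumor of
``T`` cells at per-division mutation probability ``mu``, where each driver
expands its clone to a fraction ``c`` of the tumor, is::

    P_sequence(k, d) = (1 - (1 - mu)^(T c))^d * mu^(k - d - 1) * (1 - (1 - mu)^T)

The first factor is the per-driver probability that at least one cell of the
expanded clone acquires the next mutation (a Poisson-process hit over T*c
trials); passengers do not expand their clone, so each of the remaining
``k - d - 1`` mutations must land in the *same* cell, contributing a bare
factor ``mu``; the last factor is the probability of the initial mutation
arising anywhere in the tumor. Setting ``d = 0`` gives the passenger model,
bounded above by ``mu^(k-1)``. The driver:passenger comparison reduces to::

    P(k, 0) / P(k, d) = (mu / (1 - (1 - mu)^(T c)))^d      -> mu^d  when T*c*mu >> 1

Everything is evaluated in log-space (log1p/expm1) so exponents far below
the double-precision underflow threshold (e.g. 10^-266) survive. ``k`` and
``d`` may be fractional: cohort-average mutation counts are legal inputs.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ValidationError

#: per-site per-division mutation probability that reproduces the printed
#: driver-vs-passenger relative likelihoods (all consistent with mu^d)
DEFAULT_MU = 10 ** -4.5

_LOG10E = math.log10(math.e)


@dataclass(frozen=True)
class EvolutionParams:
    """Parameters of the sequential-acquisition framework.

    mu : mutation probability per site per cell division, in (0, 1)
    T  : tumor size in cells (>= 1)
    c  : clonal-expansion fraction reached after each driver, in (0, 1]
    k  : number of sequentially acquired mutations (>= 1; fractional allowed)
    d  : drivers among the k-1 subsequent mutations (0 <= d <= k-1)
    f  : optional CCF ceiling for bounded-expansion variants
    """

    mu: float
    T: float
    c: float = 1.0
    k: float = 1.0
    d: float = 0.0
    f: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.mu < 1:
            raise ValidationError(f"mu must be in (0,1), got {self.mu}")
        if self.T < 1:
            raise ValidationError(f"T must be >= 1, got {self.T}")
        if not 0 < self.c <= 1:
            raise ValidationError(f"c must be in (0,1], got {self.c}")
        if self.k < 1:
            raise ValidationError(f"k must be >= 1, got {self.k}")
        if not 0 <= self.d <= self.k - 1:
            raise ValidationError(f"need 0 <= d <= k-1, got d={self.d}, k={self.k}")
        if self.f is not None and not 0 < self.f <= 1:
            raise ValidationError(f"f must be in (0,1], got {self.f}")


def _log_hit(mu: float, n_trials: float) -> float:
    """log(1 - (1 - mu)^n): log-probability of >= 1 hit over n trials."""
    # (1-mu)^n = exp(n*log1p(-mu)); 1 - that = -expm1(...)
    inner = n_trials * math.log1p(-mu)
    return math.log(-math.expm1(inner))


@dataclass(frozen=True)
class SequenceProbability:
    log10: float
    value: float  # 0.0 when below double-precision underflow

    def __float__(self) -> float:
        return self.value


def p_sequence(params: EvolutionParams) -> SequenceProbability:
    """Unnormalised sequential-acquisition probability (log10 also returned).

    With d = 0 the value is mu^(k-1) * (1 - (1-mu)^T), independent of c.
    """
    mu, T, c, k, d = params.mu, params.T, params.c, params.k, params.d
    log_p = (k - d - 1) * math.log(mu) + _log_hit(mu, T)
    if d > 0:
        log_p += d * _log_hit(mu, T * c)
    log10 = log_p * _LOG10E
    value = 10 ** log10 if log10 > -300 else 0.0
    return SequenceProbability(log10=log10, value=value)


def passenger_upper_bound(k: float, mu: float) -> float:
    """mu^(k-1): the ceiling on the all-passenger sequential probability."""
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    return mu ** (k - 1)


@dataclass(frozen=True)
class LikelihoodRatio:
    log10: float
    value: float

    def __float__(self) -> float:
        return self.value


def passenger_vs_driver_ratio(
    k: float,
    d_driver: float,
    mu: float,
    T: float | None = None,
    c: float = 1.0,
    saturated: bool = False,
) -> LikelihoodRatio:
    """Relative likelihood of the all-passenger vs the d-driver model.

    P(k,0)/P(k,d) = (mu / (1 - (1-mu)^(Tc)))^d; under saturation
    (T*c*mu >> 1, or ``saturated=True``) this is exactly mu^d.
    """
    if d_driver < 0 or (k is not None and d_driver > k - 1):
        raise ValidationError(f"need 0 <= d <= k-1, got d={d_driver}, k={k}")
    if saturated or T is None:
        log10 = d_driver * math.log10(mu)
    else:
        log10 = d_driver * (math.log(mu) - _log_hit(mu, T * c)) * _LOG10E
    value = 10 ** log10 if log10 > -300 else 0.0
    return LikelihoodRatio(log10=log10, value=value)


def p_sequence_bounded(
    k: float,
    d: float,
    mu: float,
    T: float,
    f: float,
) -> SequenceProbability:
    """Sequential-acquisition probability with every clonal expansion capped
    at a CCF ceiling ``f`` (e.g. 0.5 for sub-majority lineages, or the
    assay's detection floor): each driver's target pool is T*f cells."""
    return p_sequence(EvolutionParams(mu=mu, T=T, c=f, k=k, d=d, f=f))


def combine_patient_probabilities(log10_values: list[float]) -> float:
    """Product of per-patient probabilities, in log10 (sum of exponents)."""
    if not log10_values:
        raise ValidationError("need at least one per-patient probability")
    return float(sum(log10_values))
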