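"""Luria-Delbruck fluctuation analysis.

A fluctuation experiment grows many parallel cultures from small inocula,
plates each on selective medium, and counts mutant colonies. Because a
mutation arising early in a culture's growth yields a jackpot of mutant
descendants, the count distribution is heavy-tailed; the expected number of
mutation *events* per culture, m, is inferred by maximum likelihood under
the Ma-Sandri-Sarkar (MSS) recursion for the Luria-Delbruck distribution:

    p_0 = exp(-m)
    p_n = (m / n) * sum_{i=0}^{n-1} p_i / (n - i + 1)

The per-cell, per-generation mutation rate is m / N_t with N_t the final
population size per culture (whole-culture plating assumed; partial plating
corrections are out of scope).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar

MAX_COUNT = 100_000  # recursion ceiling; larger counts are implausible inputs


class FluctuationError(ValueError):
    pass


@dataclass
class FluctuationExperiment:
    """Mutant colony counts from parallel cultures."""

    counts: list[int]
    n_total: float  # N_t, final cells per culture
    plating_fraction: float = 1.0

    def __post_init__(self) -> None:
        if len(self.counts) < 2:
            raise FluctuationError("need >= 2 parallel cultures")
        if any(c < 0 or c != int(c) for c in self.counts):
            raise FluctuationError("counts must be non-negative integers")
        if max(self.counts) > MAX_COUNT:
            raise FluctuationError(f"count exceeds ceiling {MAX_COUNT}")
        if self.n_total <= 0:
            raise FluctuationError("N_t must be positive")


@dataclass
class FluctuationResult:
    m_hat: float           # expected mutation events per culture
    rate: float            # m_hat / N_t, per cell per generation
    se_m: float            # from observed information at m_hat
    loglik: float
    all_zero: bool = False # m_hat == 0 exactly; only an upper CI is meaningful


_RECURSION_MAX = 4096  # above this the O(n^2) recursion is replaced spectrally


def ld_pmf(m: float, n_max: int) -> np.ndarray:
    """MSS probabilities p_0 .. p_{n_max} of observing n mutant colonies.

    Computed by the MSS recursion up to ``n_max`` = 4096. The distribution
    is compound Poisson (Poisson(m) mutation events, clone sizes with
    P(K=k) = 1/(k(k+1))), so for larger ``n_max`` — jackpot cultures — the
    same probabilities are evaluated through the generating function
    exp(m (Q(x) - 1)) on a zero-padded discrete Fourier grid; the two
    routes agree to ~1e-10 where both are feasible.
    """
    if m < 0:
        raise FluctuationError(f"m must be >= 0, got {m}")
    if n_max < 0:
        raise FluctuationError(f"n_max must be >= 0, got {n_max}")
    if n_max > _RECURSION_MAX:
        return _ld_pmf_spectral(m, n_max)
    p = np.zeros(n_max + 1)
    p[0] = np.exp(-m)
    if n_max == 0:
        return p
    # p_n = (m/n) * sum_{j=1}^{n} p_{n-j} * c_j with kernel c_j = 1/(j+1)
    c = 1.0 / (np.arange(1, n_max + 1) + 1.0)
    for n in range(1, n_max + 1):
        # reversed slice is a strided view; no copy
        p[n] = (m / n) * float(np.dot(p[n - 1 :: -1], c[:n]))
    return p


def _ld_pmf_spectral(m: float, n_max: int) -> np.ndarray:
    """Compound-Poisson pmf via FFT of the clone-size pgf.

    32x zero padding keeps the wrap-around (aliasing) contribution far below
    the true tail probability at every reported index.
    """
    size = 1 << int(np.ceil(np.log2(32 * (n_max + 1))))
    k = np.arange(1, size, dtype=float)
    q = np.zeros(size)
    q[1:] = 1.0 / (k * (k + 1.0))
    qhat = np.fft.rfft(q)
    p = np.fft.irfft(np.exp(m * (qhat - 1.0)), n=size)[: n_max + 1]
    return np.maximum(p, 0.0)


def _loglik(m: float, counts: Sequence[int]) -> float:
    p = ld_pmf(m, max(counts))
    with np.errstate(divide="ignore"):
        return float(np.sum(np.log(p[list(counts)])))


def mss_mle(experiment: FluctuationExperiment) -> FluctuationResult:
    """Maximum-likelihood m from the MSS likelihood, by bounded 1-D search.

    The bracket [1e-8, 2 * max(1, mean count)] is expanded geometrically if
    the optimum presses against its upper end. All-zero counts give
    m_hat = 0 exactly.
    """
    counts = experiment.counts
    if all(c == 0 for c in counts):
        return FluctuationResult(
            m_hat=0.0, rate=0.0, se_m=float("nan"),
            loglik=0.0, all_zero=True,
        )
    upper = 2.0 * max(1.0, float(np.mean(counts)))
    while True:
        res = minimize_scalar(
            lambda m: -_loglik(m, counts),
            bounds=(1e-8, upper),
            method="bounded",
            options={"xatol": 1e-12},
        )
        m_hat = float(res.x)
        if m_hat < 0.99 * upper or upper > 10 * MAX_COUNT:
            break
        upper *= 4.0
    ll = _loglik(m_hat, counts)
    se = _se_from_information(m_hat, counts)
    return FluctuationResult(
        m_hat=m_hat, rate=m_hat / experiment.n_total, se_m=se, loglik=ll,
    )


def _se_from_information(m_hat: float, counts: Sequence[int]) -> float:
    h = max(1e-5, 1e-4 * m_hat)
    if m_hat - h <= 0:
        h = m_hat / 2
    d2 = (
        _loglik(m_hat + h, counts)
        - 2 * _loglik(m_hat, counts)
        + _loglik(m_hat - h, counts)
    ) / h**2
    if d2 >= 0:
        return float("nan")
    return float(1.0 / np.sqrt(-d2))


def simulate_fluctuation(
    m: float,
    n_total: float,
    n_cultures: int,
    seed: int | np.random.Generator = 0,
) -> FluctuationExperiment:
    """Draw mutant counts under the constant-final-population LD model.

    Events per culture ~ Poisson(m); each event founds a clone whose final
    size K has P(K = k) = 1 / (k (k+1)), k >= 1 — the size distribution of a
    clone founded at a uniformly random cell division during exponential
    growth. Counts are the summed clone sizes, capped at the recursion
    ceiling.
    """
    if m < 0:
        raise FluctuationError(f"m must be >= 0, got {m}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    events = rng.poisson(m, size=n_cultures)
    totals = np.zeros(n_cultures, dtype=np.int64)
    n_total_events = int(events.sum())
    if n_total_events:
        u = rng.random(n_total_events)
        # inverse CDF of P(K<=k) = k/(k+1): K = ceil(u / (1-u))
        sizes = np.minimum(
            np.maximum(1, np.ceil(u / (1.0 - u))).astype(np.int64), MAX_COUNT
        )
        culture = np.repeat(np.arange(n_cultures), events)
        np.add.at(totals, culture, sizes)
    counts = [int(c) for c in np.minimum(totals, MAX_COUNT)]
    return FluctuationExperiment(counts=counts, n_total=n_total)
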