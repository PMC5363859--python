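"""Mutation frequency and rate estimation for mutation-accumulation cohorts.

The mean mutation frequency is the number of unique mutations divided by the
exposure (callable loci for homopolymer indels, callable base pairs for
point mutations, each summed over included lines); the mean rate divides the
frequency by the number of generations per line (~1000 in a typical design).
Exact binomial (Clopper-Pearson) intervals quantify the uncertainty on the
event count; at genome-scale exposures they coincide with Poisson intervals
to high accuracy.

Also here: the small-sample comparisons used around those rates — Fisher's
exact test on pooled 2x2 event/exposure tables, the Mann-Whitney U test for
copy-number distributions, indel size spectra, and a median-ratio estimator
of plasmid copy number from depth tracks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .catalog import HomopolymerLocus, iter_window
from .filters import SUBSTITUTION_CATEGORIES, MutationRecord


class RateError(ValueError):
    pass


# --------------------------------------------------------------------------
# Clopper-Pearson


def clopper_pearson(k: int, n: float, conf: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval for ``k`` successes in ``n`` trials.

    Bounds come from Beta quantiles: lo = B(alpha/2; k, n-k+1) (0 at k=0),
    hi = B(1-alpha/2; k+1, n-k) (1 at k=n). ``n`` may be a large float
    exposure (bp-generations); fractional trials are accepted because only
    the Beta quantiles are evaluated.
    """
    if not 0 < conf < 1:
        raise RateError(f"conf must be in (0,1), got {conf}")
    if n <= 0 or k < 0 or k > n:
        raise RateError(f"invalid (k, n) = ({k}, {n})")
    alpha = 1.0 - conf
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


@dataclass
class RateEstimate:
    """Event count, exposure, and rate with its Clopper-Pearson interval.

    ``rate``/``ci_low``/``ci_high`` are per unit exposure per generation when
    built through :func:`make_rate` with ``generations`` > 1.
    """

    k: int
    n: float
    generations: float
    rate: float
    ci_low: float
    ci_high: float
    conf: float = 0.95


def make_rate(k: int, exposure: float, generations: float = 1.0,
              conf: float = 0.95) -> RateEstimate:
    """Rate per exposure unit per generation; the binomial trial count is
    ``exposure * generations`` (e.g. locus-generations)."""
    trials = exposure * generations
    lo, hi = clopper_pearson(k, trials, conf)
    return RateEstimate(k, trials, generations, k / trials, lo, hi, conf)


def format_sig2(x: float) -> str:
    """Two-significant-figure rendering (round-half-even) as used in rate tables."""
    if x == 0:
        return "0.0"
    exponent = math.floor(math.log10(abs(x)))
    quantum = 10.0 ** (exponent - 1)
    # numpy.round is round-half-even
    val = float(np.round(x / quantum)) * quantum
    if exponent >= 1:
        return f"{val:.0f}"
    return f"{val:.{1 - exponent}f}"


# --------------------------------------------------------------------------
# Exposure bookkeeping


@dataclass
class ExposureLedger:
    """Per-line callable exposure.

    ``loci``: line -> callable homopolymer locus count (for the analysis
    window in use); ``bp``: line -> {"AT": callable A:T bp, "GC": callable
    G:C bp}; ``generations``: line -> generations passaged (default applied
    where missing).
    """

    loci: dict[str, float] = field(default_factory=dict)
    bp: dict[str, dict[str, float]] = field(default_factory=dict)
    generations: dict[str, float] = field(default_factory=dict)
    default_generations: float = 1000.0

    def gens(self, line: str) -> float:
        return self.generations.get(line, self.default_generations)

    def locus_generations(self, lines: Iterable[str]) -> float:
        return sum(self.loci.get(l, 0.0) * self.gens(l) for l in lines)

    def bp_generations(self, lines: Iterable[str], pair_class: str) -> float:
        return sum(self.bp.get(l, {}).get(pair_class, 0.0) * self.gens(l)
                   for l in lines)


def uniform_ledger(lines: Sequence[str], loci_per_line: float = 0.0,
                   at_bp: float = 0.0, gc_bp: float = 0.0,
                   generations: float = 1000.0) -> ExposureLedger:
    """Ledger with identical exposure in every line (the common design)."""
    return ExposureLedger(
        loci={l: loci_per_line for l in lines},
        bp={l: {"AT": at_bp, "GC": gc_bp} for l in lines},
        generations={l: generations for l in lines},
        default_generations=generations,
    )


# --------------------------------------------------------------------------
# Windowed homopolymer indel rates (per locus per generation)


def rate_window(
    indels: Sequence[MutationRecord],
    ledger: ExposureLedger,
    lines: Sequence[str],
    len_range: tuple[int, int] = (7, 16),
    pair_class: str = "AT",
    catalog: Sequence[HomopolymerLocus] | None = None,
    conf: float = 0.95,
) -> dict[str, RateEstimate]:
    """Indel, deletion and insertion rates per locus per generation.

    Events are hp_indel records from the included ``lines`` whose locus (when
    a catalog is given) falls in the length window and base-pair class; the
    exposure is the ledger's callable in-window loci summed over lines, times
    generations.
    """
    keep_ids: set[str] | None = None
    if catalog is not None:
        keep_ids = {
            loc.locus_id
            for loc in iter_window(catalog, len_range, pair_class)
        }
    line_set = set(lines)
    events = [
        r for r in indels
        if r.kind == "hp_indel" and r.line in line_set
        and (keep_ids is None or r.pos in keep_ids)
    ]
    trials = ledger.locus_generations(lines)
    if trials <= 0:
        raise RateError("ledger exposure is zero for the requested lines")
    gens = max((ledger.gens(l) for l in lines), default=1.0)

    def est(k: int) -> RateEstimate:
        lo, hi = clopper_pearson(k, trials, conf)
        return RateEstimate(k, trials, gens, k / trials, lo, hi, conf)

    k_del = sum(1 for r in events if (r.delta or 0) < 0)
    k_ins = sum(1 for r in events if (r.delta or 0) > 0)
    return {
        "indels": est(len(events)),
        "deletions": est(k_del),
        "insertions": est(k_ins),
    }


def point_rate_table(
    points: Sequence[MutationRecord],
    ledger: ExposureLedger,
    lines: Sequence[str],
    conf: float = 0.95,
) -> dict[str, RateEstimate]:
    """Per-category point mutation rates (per bp per generation).

    AT-categories are normalized by A:T bp exposure, GC-categories by G:C bp
    exposure; the AT, GC and total rows pool events over their categories
    with the matching (or summed) exposure.
    """
    line_set = set(lines)
    events = [r for r in points if r.kind == "point" and r.line in line_set]
    n_at = ledger.bp_generations(lines, "AT")
    n_gc = ledger.bp_generations(lines, "GC")
    if n_at <= 0 and n_gc <= 0:
        raise RateError("ledger has no bp exposure for the requested lines")

    counts = {cat: 0 for cat in SUBSTITUTION_CATEGORIES}
    for r in events:
        counts[r.category] += 1

    gens = max((ledger.gens(l) for l in lines), default=1.0)

    def est(k: int, trials: float) -> RateEstimate:
        lo, hi = clopper_pearson(k, trials, conf)
        return RateEstimate(k, trials, gens, k / trials, lo, hi, conf)

    table: dict[str, RateEstimate] = {}
    for cat in SUBSTITUTION_CATEGORIES:
        trials = n_at if cat.startswith("AT") else n_gc
        table[cat] = est(counts[cat], trials)
    k_at = sum(counts[c] for c in SUBSTITUTION_CATEGORIES if c.startswith("AT"))
    k_gc = sum(counts[c] for c in SUBSTITUTION_CATEGORIES if c.startswith("GC"))
    table["AT"] = est(k_at, n_at)
    table["GC"] = est(k_gc, n_gc)
    table["total"] = est(k_at + k_gc, n_at + n_gc)
    return table


# --------------------------------------------------------------------------
# Pairwise tests


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher's exact p for a 2x2 table (minimum-likelihood method:
    sum the probabilities of all same-margin tables no more probable than the
    observed one)."""
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise RateError("fisher_exact_2x2 needs a non-negative 2x2 table")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Rank-sum U statistic and two-sided p.

    For combined sample size <= 20 the p-value is exact: every assignment of
    the pooled values to the two groups is enumerated (ties handled
    correctly by construction) and p = 2*min(P(U<=u), P(U>=u)) capped at 1.
    Larger samples use the tie-corrected normal approximation.
    """
    x = list(map(float, x))
    y = list(map(float, y))
    if not x or not y:
        raise RateError("both samples must be non-empty")
    nx, ny = len(x), len(y)
    u_obs = _u_statistic(x, y)
    if nx + ny <= 20:
        pooled = x + y
        us = [
            _u_statistic([pooled[i] for i in idx],
                         [pooled[j] for j in range(nx + ny) if j not in set(idx)])
            for idx in combinations(range(nx + ny), nx)
        ]
        us = np.array(us)
        p_le = float(np.mean(us <= u_obs))
        p_ge = float(np.mean(us >= u_obs))
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return u_obs, p
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def _u_statistic(x: Sequence[float], y: Sequence[float]) -> float:
    """U for sample x: #{(xi, yj): xi > yj} + 0.5 * #{ties}."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


# --------------------------------------------------------------------------
# Indel spectrum & copy number


def indel_spectrum(
    indels: Sequence[MutationRecord], conf: float = 0.95
) -> dict[int, tuple[float, float, float]]:
    """delta -> (fraction, ci_low, ci_high) over unique indel events."""
    deltas = [r.delta for r in indels if r.kind == "hp_indel"]
    if any(d in (None, 0) for d in deltas):
        raise RateError("indel records must carry non-zero delta")
    total = len(deltas)
    if total == 0:
        return {}
    out = {}
    for delta in sorted(set(deltas)):
        k = deltas.count(delta)
        lo, hi = clopper_pearson(k, total, conf)
        out[delta] = (k / total, lo, hi)
    return out


def copy_number_ratio(
    depth: Mapping[str, Sequence[float]] | Sequence[float],
    target: Sequence[tuple] | tuple,
    background: Sequence[tuple] | tuple,
) -> float:
    """Median depth over target region(s) / median depth over background.

    Regions are (chrom, start, end) when ``depth`` maps chrom -> per-base
    track, or (start, end) for a single unnamed track. Robust to overall
    coverage scale (multiplying the track by c leaves the ratio fixed).
    """
    def collect(regions) -> np.ndarray:
        if isinstance(regions, tuple):
            regions = [regions]
        vals: list[float] = []
        for region in regions:
            if isinstance(depth, Mapping):
                chrom, start, end = region
                vals.extend(depth[chrom][start:end])
            else:
                start, end = region
                vals.extend(depth[start:end])
        if not vals:
            raise RateError("empty region")
        return np.asarray(vals, dtype=float)

    bg = float(np.median(collect(background)))
    if bg == 0:
        raise RateError("background median depth is zero")
    return float(np.median(collect(target))) / bg
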