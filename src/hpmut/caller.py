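"""Cohort-based homopolymer genotyping.

Mononucleotide runs are hard to genotype from a single sample because
polymerase and sequencer stutter smears the observed run length. In a
mutation-accumulation cohort, however, nearly all lines share the ancestral
allele at any given locus, so the cohort itself is the best available model
of the stutter process at that locus. Each sample is therefore compared to
the *leave-one-out profile*: the unweighted average of the length-frequency
distributions of all other samples.

The test statistic is the sample's read count at the profile's modal length
L0. Under the null (sample shares the cohort genotype), that count is
Binomial(depth, p0) where p0 is the profile's mass at L0; a sample whose
support for L0 is improbably low (lower-tail exact binomial probability
below ``p_threshold``) and whose own modal length differs from L0 is called
as a variant. Locus- and sample-level gates (depth window, locus quality,
modal concentration, cohort consensus agreement, data availability) guard
against miscalls at dirty or underpowered loci.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

from scipy.stats import binom

from .observe import (
    LengthHistogram,
    LocusObservations,
    histogram_stats,
    modal_length,
)

P0_CLAMP = 1e-6  # keeps the binomial null proper when the profile is a point mass


class CallerError(ValueError):
    pass


@dataclass
class CallerParams:
    """Gates and threshold for cohort calling.

    The p-value threshold defaults to 1e-6: a genome-scale screen tests on
    the order of 1e5-1e6 locus-sample pairs, so 1e-6 bounds the expected
    number of false positives near one. ``min_data_fraction`` mirrors the
    cohort data-availability rule used for point mutations (44 of 47 lines).
    ``max_depth`` guards collapsed repeats at roughly 5x the design depth.
    """

    p_threshold: float = 1e-6
    min_depth: int = 8
    max_depth: int = 250
    min_lq: float = 0.5
    min_modal_fraction: float = 0.5
    min_consensus_support: float = 0.5  # strict majority: fraction must exceed this
    min_data_fraction: float = 44 / 47
    depth_weighted_profile: bool = False


@dataclass
class LocusProfile:
    """Leave-one-out average length distribution at a locus."""

    locus_id: str
    freqs: dict[int, float]
    mode: int | None          # L0
    p0: float                 # profile mass at L0
    n_samples_used: int


@dataclass
class GenotypeCall:
    sample: str
    locus_id: str
    status: str               # reference | variant | no_call
    reason: str = ""
    called_length: int | None = None
    delta: int | None = None  # called_length - cohort consensus length
    p_value: float | None = None
    depth: int = 0
    modal_fraction: float = 0.0
    lq: float | None = None


def leave_one_out_profile(
    obs: LocusObservations,
    sample: str,
    ref_length: int | None = None,
    depth_weighted: bool = False,
) -> LocusProfile:
    """Average the other samples' length frequencies, unweighted by default.

    Unweighted averaging keeps one very deep sample from dominating the
    profile; samples with zero depth are excluded and ``n_samples_used``
    records how many contributed.
    """
    if ref_length is None:
        ref_length = obs.locus.ref_length
    freq_sum: dict[int, float] = {}
    n_used = 0
    total_depth = 0
    for name, hist in obs.histograms.items():
        if name == sample or hist.depth == 0:
            continue
        n_used += 1
        total_depth += hist.depth
        for length, count in hist.counts.items():
            w = count if depth_weighted else count / hist.depth
            freq_sum[length] = freq_sum.get(length, 0.0) + w
    if n_used == 0:
        return LocusProfile(obs.locus_id, {}, None, 0.0, 0)
    denom = total_depth if depth_weighted else n_used
    freqs = {length: s / denom for length, s in freq_sum.items()}
    mode = modal_length(freqs, ref_length)
    return LocusProfile(obs.locus_id, freqs, mode, freqs[mode], n_used)


def mode_agreement_pvalue(h: LengthHistogram, profile: LocusProfile) -> float:
    """Lower-tail exact binomial probability of the sample's support for L0.

    P(X <= k) with X ~ Binomial(depth, p0), k = sample reads at the profile
    mode, p0 clamped to [1e-6, 1 - 1e-6]. Small values mean the sample is
    depleted at the cohort's modal length.
    """
    n = h.depth
    if n == 0:
        raise CallerError("mode_agreement_pvalue undefined at depth 0")
    if profile.mode is None or profile.n_samples_used < 1:
        raise CallerError("profile has no contributing samples")
    k = h.counts.get(profile.mode, 0)
    p0 = min(max(profile.p0, P0_CLAMP), 1.0 - P0_CLAMP)
    return float(binom.cdf(k, n, p0))


def locus_quality(obs: LocusObservations) -> float | None:
    """Cohort-wide fraction of reads concordant with their own sample's mode.

    LQ near 1 means every sample's histogram is concentrated at one length —
    a clean, well-behaved locus. ``None`` when no sample has reads.
    """
    modal_reads = 0
    total_reads = 0
    ref_length = obs.locus.ref_length
    for hist in obs.histograms.values():
        if hist.depth == 0:
            continue
        mode = modal_length(hist.counts, ref_length)
        modal_reads += hist.counts[mode]
        total_reads += hist.depth
    if total_reads == 0:
        return None
    return modal_reads / total_reads


def _all_no_call(obs: LocusObservations, reason: str, lq: float | None) -> list[GenotypeCall]:
    calls = []
    for sample, hist in obs.histograms.items():
        mode, mfrac, depth = histogram_stats(hist, obs.locus.ref_length)
        calls.append(
            GenotypeCall(
                sample, obs.locus_id, "no_call", reason,
                depth=depth, modal_fraction=mfrac, lq=lq,
            )
        )
    return calls


def call_locus(
    obs: LocusObservations, params: CallerParams | None = None
) -> list[GenotypeCall]:
    """Genotype every sample at one locus; every sample gets a call record."""
    if params is None:
        params = CallerParams()
    ref_length = obs.locus.ref_length
    n_samples = len(obs.histograms)
    if n_samples == 0:
        return []

    lq = locus_quality(obs)

    # locus-level gates
    with_data = {
        s: h for s, h in obs.histograms.items() if h.depth >= params.min_depth
    }
    if len(with_data) / n_samples < params.min_data_fraction:
        return _all_no_call(obs, "insufficient_data", lq)
    if lq is None or lq < params.min_lq:
        return _all_no_call(obs, "low_lq", lq)

    # cohort consensus length: modal value of per-sample modes, strict majority
    sample_modes = {
        s: modal_length(h.counts, ref_length) for s, h in with_data.items()
    }
    mode_votes: dict[int, int] = {}
    for m in sample_modes.values():
        mode_votes[m] = mode_votes.get(m, 0) + 1
    consensus = modal_length(mode_votes, ref_length)
    if mode_votes[consensus] / len(with_data) <= params.min_consensus_support:
        return _all_no_call(obs, "multiallelic", lq)

    calls: list[GenotypeCall] = []
    for sample, hist in obs.histograms.items():
        mode, mfrac, depth = histogram_stats(hist, ref_length)
        base = GenotypeCall(
            sample, obs.locus_id, "no_call",
            depth=depth, modal_fraction=mfrac, lq=lq,
        )
        if depth < params.min_depth:
            calls.append(replace(base, reason="low_depth"))
            continue
        if depth > params.max_depth:
            calls.append(replace(base, reason="high_depth"))
            continue
        if mfrac < params.min_modal_fraction:
            calls.append(replace(base, reason="low_modal_fraction"))
            continue
        profile = leave_one_out_profile(
            obs, sample, ref_length, params.depth_weighted_profile
        )
        if profile.n_samples_used < 2:
            calls.append(replace(base, reason="insufficient_cohort"))
            continue
        p = mode_agreement_pvalue(hist, profile)
        if mode != profile.mode and p < params.p_threshold:
            calls.append(
                replace(
                    base, status="variant", reason="",
                    called_length=mode, delta=mode - consensus, p_value=p,
                )
            )
        else:
            calls.append(
                replace(
                    base, status="reference", reason="",
                    called_length=mode, delta=mode - consensus, p_value=p,
                )
            )
    return calls


def call_cohort(
    observations: Iterable[LocusObservations],
    params: CallerParams | None = None,
) -> list[GenotypeCall]:
    """Apply :func:`call_locus` over a catalog; deterministic in input order."""
    if params is None:
        params = CallerParams()
    calls: list[GenotypeCall] = []
    sample_set: frozenset[str] | None = None
    for obs in observations:
        names = frozenset(obs.histograms)
        if sample_set is None:
            sample_set = names
        elif names != sample_set:
            raise CallerError(
                f"sample sets differ across loci: {sorted(sample_set)} vs {sorted(names)}"
            )
        calls.extend(call_locus(obs, params))
    return calls


CALL_COLUMNS = [
    "locus_id", "sample", "status", "reason", "called_length",
    "delta", "p_value", "depth", "modal_fraction", "lq",
]


def write_calls(calls: Iterable[GenotypeCall], path: str | Path) -> None:
    def fmt(v) -> str:
        if v is None:
            return ""
        if isinstance(v, float):
            return repr(v)
        return str(v)

    with open(path, "w") as fh:
        fh.write("\t".join(CALL_COLUMNS) + "\n")
        for c in calls:
            fh.write(
                "\t".join(
                    fmt(v)
                    for v in (
                        c.locus_id, c.sample, c.status, c.reason, c.called_length,
                        c.delta, c.p_value, c.depth, c.modal_fraction, c.lq,
                    )
                )
                + "\n"
            )


def read_calls(path: str | Path) -> list[GenotypeCall]:
    calls = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != CALL_COLUMNS:
            raise CallerError(f"unexpected calls header: {header}")
        for line in fh:
            (locus_id, sample, status, reason, called_length, delta,
             p_value, depth, modal_fraction, lq) = line.rstrip("\n").split("\t")
            calls.append(
                GenotypeCall(
                    sample=sample,
                    locus_id=locus_id,
                    status=status,
                    reason=reason,
                    called_length=int(called_length) if called_length else None,
                    delta=int(delta) if delta else None,
                    p_value=float(p_value) if p_value else None,
                    depth=int(depth),
                    modal_fraction=float(modal_fraction),
                    lq=float(lq) if lq else None,
                )
            )
    return calls
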