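"""Observed homopolymer run lengths from aligned reads.

For each catalog locus and each sample, reads spanning the run are reduced to
the run length they actually carry (which differs from the reference length
when the template has an indel allele or the read has a stutter error), and
the per-sample tallies form a length histogram. These histograms — not the
raw alignments — are what the cohort caller consumes.

A read contributes an observation only if it is cleanly anchored: it must
align, CIGAR-consistently and without soft-clipping, across ``min_anchor``
non-run reference positions on each side of the run. The observed length is
the count of consecutive run-base characters in the read between the two
anchors, so inserted extra copies of the base are counted and deleted
positions are not. A non-run base inserted inside the run interrupts
counting and the read reports the 5'-anchored segment only (conservative:
an interrupted run is not a longer run).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pysam

from .catalog import HomopolymerLocus

DEFAULT_MIN_ANCHOR = 3
DEFAULT_MIN_MAPQ = 20


class ObservationError(ValueError):
    pass


@dataclass
class LengthHistogram:
    """Read support per observed run length, for one sample at one locus."""

    sample: str
    locus_id: str
    counts: dict[int, int] = field(default_factory=dict)

    @property
    def depth(self) -> int:
        return sum(self.counts.values())

    def add(self, length: int) -> None:
        self.counts[length] = self.counts.get(length, 0) + 1


@dataclass
class LocusObservations:
    """All samples' histograms at one locus."""

    locus: HomopolymerLocus
    histograms: dict[str, LengthHistogram]

    @property
    def locus_id(self) -> str:
        return self.locus.locus_id


def histogram_stats(
    h: LengthHistogram, ref_length: int
) -> tuple[int | None, float, int]:
    """Modal observed length, its fraction of depth, and depth.

    Ties at the maximal count are broken toward the length closest to
    ``ref_length``, then toward the shorter length, so a deadlocked histogram
    resolves to the least-surprising, most conservative allele. Returns
    ``(None, 0.0, 0)`` on an empty histogram.
    """
    depth = h.depth
    if depth == 0:
        return None, 0.0, 0
    mode = modal_length(h.counts, ref_length)
    return mode, h.counts[mode] / depth, depth


def modal_length(counts: Mapping[int, float], ref_length: int) -> int:
    """argmax of ``counts`` with the (closest-to-ref, then shorter) tie-break."""
    if not counts:
        raise ObservationError("modal_length of empty histogram")
    return min(counts, key=lambda L: (-counts[L], abs(L - ref_length), L))


def observed_run_length(
    alignment: pysam.AlignedSegment,
    locus: HomopolymerLocus,
    min_anchor: int = DEFAULT_MIN_ANCHOR,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> int | None:
    """Run length carried by one read at one locus, or ``None`` if unusable.

    ``None`` is returned when the read is unmapped, below ``min_mapq``,
    secondary/supplementary/duplicate, does not fully span the anchor window
    ``[start - min_anchor, end + min_anchor)``, is soft-clipped inside that
    window, or fails to align (match/mismatch) at any anchor position.
    """
    a = alignment
    if (
        a.is_unmapped
        or a.is_secondary
        or a.is_supplementary
        or a.is_duplicate
        or a.mapping_quality < min_mapq
    ):
        return None
    win_start = locus.start - min_anchor
    win_end = locus.end + min_anchor
    if win_start < 0:
        return None
    if a.reference_start > win_start or a.reference_end is None or a.reference_end < win_end:
        return None

    seq = a.query_sequence
    if seq is None:
        raise ObservationError(f"read {a.query_name}: no sequence")
    cigar_qlen = a.infer_query_length()
    if cigar_qlen is not None and cigar_qlen != len(seq):
        raise ObservationError(
            f"read {a.query_name}: CIGAR length {cigar_qlen} != sequence length {len(seq)}"
        )

    # ref pos -> query index for aligned (M/=/X) columns only
    ref_to_query: dict[int, int] = {}
    for qpos, rpos in a.get_aligned_pairs(matches_only=True):
        ref_to_query[rpos] = qpos

    # every anchor position must be an aligned (non-clipped, non-indel) column
    anchor_refs = list(range(win_start, locus.start)) + list(range(locus.end, win_end))
    for rpos in anchor_refs:
        if rpos not in ref_to_query:
            return None

    left_q = ref_to_query[locus.start - 1]   # last anchor base before the run
    right_q = ref_to_query[locus.end]        # first anchor base after the run
    segment = seq[left_q + 1 : right_q].upper()
    # count the 5'-anchored stretch of run bases; a non-run insertion interrupts
    length = 0
    for ch in segment:
        if ch != locus.base:
            break
        length += 1
    return length


def build_locus_observations(
    sam_paths: Mapping[str, str | Path],
    catalog: Sequence[HomopolymerLocus],
    min_anchor: int = DEFAULT_MIN_ANCHOR,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> list[LocusObservations]:
    """Histogram every sample's reads over every catalog locus.

    ``sam_paths`` maps sample name -> SAM/BAM path. Every locus appears in
    the output with one histogram per sample (depth 0 where no read passed).
    Each read contributes to every locus it spans.
    """
    samples = list(sam_paths)
    if len(set(samples)) != len(samples):
        raise ObservationError("duplicate sample names")

    by_chrom: dict[str, list[HomopolymerLocus]] = defaultdict(list)
    for locus in catalog:
        by_chrom[locus.chrom].append(locus)
    for loci in by_chrom.values():
        loci.sort(key=lambda l: l.start)

    hists: dict[tuple[str, str], LengthHistogram] = {
        (locus.locus_id, sample): LengthHistogram(sample, locus.locus_id)
        for locus in catalog
        for sample in samples
    }

    ends_by_chrom = {c: [l.end for l in loci] for c, loci in by_chrom.items()}

    for sample, path in sam_paths.items():
        with pysam.AlignmentFile(str(path), check_sq=False) as fh:
            for read in fh:
                if read.is_unmapped or read.reference_name not in by_chrom:
                    continue
                chrom = read.reference_name
                for locus in _spanned_loci(
                    by_chrom[chrom], ends_by_chrom[chrom], read, min_anchor
                ):
                    length = observed_run_length(read, locus, min_anchor, min_mapq)
                    if length is not None:
                        hists[locus.locus_id, sample].add(length)

    return [
        LocusObservations(
            locus,
            {s: hists[locus.locus_id, s] for s in samples},
        )
        for locus in catalog
    ]


def _spanned_loci(
    sorted_loci: list[HomopolymerLocus],
    sorted_ends: list[int],
    read: pysam.AlignedSegment,
    min_anchor: int,
) -> Iterator[HomopolymerLocus]:
    """Loci whose anchor window lies inside the read's reference span."""
    import bisect

    lo = bisect.bisect_left(sorted_ends, read.reference_start + min_anchor)
    ref_end = read.reference_end or read.reference_start
    for locus in sorted_loci[lo:]:
        if locus.start - min_anchor >= ref_end:
            break
        if (
            read.reference_start <= locus.start - min_anchor
            and ref_end >= locus.end + min_anchor
        ):
            yield locus


# --- histogram TSV round trip: the module boundary to the caller ------------

def write_histograms(
    observations: Iterable[LocusObservations], path: str | Path
) -> None:
    """TSV with columns locus_id, sample, length, count (depth-0 samples get
    a sentinel row with empty length so sample presence survives round trip)."""
    with open(path, "w") as fh:
        fh.write("locus_id\tsample\tlength\tcount\n")
        for obs in observations:
            for sample, hist in obs.histograms.items():
                if not hist.counts:
                    fh.write(f"{obs.locus_id}\t{sample}\t\t0\n")
                for length in sorted(hist.counts):
                    fh.write(
                        f"{obs.locus_id}\t{sample}\t{length}\t{hist.counts[length]}\n"
                    )


def read_histograms(
    path: str | Path, catalog: Sequence[HomopolymerLocus]
) -> list[LocusObservations]:
    """Inverse of :func:`write_histograms`; loci not in the TSV get empty histograms."""
    per_locus: dict[str, dict[str, Counter]] = defaultdict(dict)
    samples: list[str] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["locus_id", "sample", "length", "count"]:
            raise ObservationError(f"unexpected histogram header: {header}")
        for line in fh:
            locus_id, sample, length_s, count_s = line.rstrip("\n").split("\t")[:4]
            if sample not in samples:
                samples.append(sample)
            hist = per_locus[locus_id].setdefault(sample, Counter())
            if length_s != "":
                hist[int(length_s)] += int(count_s)
    out = []
    for locus in catalog:
        hists = {
            s: LengthHistogram(
                s, locus.locus_id, dict(per_locus.get(locus.locus_id, {}).get(s, {}))
            )
            for s in samples
        }
        out.append(LocusObservations(locus, hists))
    return out
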