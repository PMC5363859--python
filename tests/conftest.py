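"""Shared fixtures: in-memory alignment builders and small cohorts."""

from __future__ import annotations

import pysam
import pytest

from hpmut.catalog import HomopolymerLocus
from hpmut.observe import LengthHistogram, LocusObservations


@pytest.fixture
def sam_header() -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": "chrI", "LN": 100_000}],
        }
    )


@pytest.fixture
def make_read(sam_header):
    """Build an aligned read on chrI from (start, cigar, seq)."""

    def _make(
        start: int,
        cigar: str,
        seq: str,
        mapq: int = 60,
        flag: int = 0,
        name: str = "read1",
    ) -> pysam.AlignedSegment:
        a = pysam.AlignedSegment(sam_header)
        a.query_name = name
        a.query_sequence = seq
        a.flag = flag
        a.reference_id = 0
        a.reference_start = start
        a.mapping_quality = mapq
        a.cigarstring = cigar
        return a

    return _make


def make_obs(
    locus: HomopolymerLocus, histograms: dict[str, dict[int, int]]
) -> LocusObservations:
    """LocusObservations from {sample: {length: count}}."""
    return LocusObservations(
        locus,
        {
            sample: LengthHistogram(sample, locus.locus_id, dict(counts))
            for sample, counts in histograms.items()
        },
    )


@pytest.fixture
def a12_locus() -> HomopolymerLocus:
    return HomopolymerLocus("chrI", 1000, 1012, "A")
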