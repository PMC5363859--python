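"""Homopolymer locus catalogs.

A homopolymer locus is a maximal run of a single base (A, C, G or T) on the
reference strand. The catalog of all such runs above a minimum length is the
unit of exposure for homopolymer indel rate estimation: rates are reported
per locus per generation, restricted downstream to analysis windows such as
A:T runs of 7-16 nt.

Coordinates are 0-based half-open throughout, matching BED.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

VALID_BASES = frozenset("ACGT")

#: strand-collapsed base-pair class of a run base
PAIR_CLASS = {"A": "AT", "T": "AT", "G": "GC", "C": "GC"}


class CatalogError(ValueError):
    """Malformed catalog input (BED parse failure, invalid locus)."""


def classify_pair(base: str) -> str:
    """Collapse a run base onto its base-pair class: A/T -> "AT", G/C -> "GC"."""
    try:
        return PAIR_CLASS[base]
    except KeyError:
        raise CatalogError(f"not a DNA base: {base!r}") from None


@dataclass(frozen=True, order=True)
class HomopolymerLocus:
    """One maximal single-base run on a reference contig."""

    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    base: str

    def __post_init__(self) -> None:
        if self.base not in VALID_BASES:
            raise CatalogError(f"invalid run base {self.base!r}")
        if not 0 <= self.start < self.end:
            raise CatalogError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )

    @property
    def ref_length(self) -> int:
        return self.end - self.start

    @property
    def pair_class(self) -> str:
        return classify_pair(self.base)

    @property
    def locus_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def scan_homopolymers(
    sequence: str, min_len: int, chrom: str = "seq"
) -> list[HomopolymerLocus]:
    """Find all maximal single-base runs of length >= ``min_len``.

    The sequence is uppercased first; any character outside {A,C,G,T}
    (N, gaps, soft-mask artifacts after uppercasing resolve, etc.) never
    extends a run — runs are broken at ambiguous characters so that no call
    is ever made across unknown sequence.

    Parameters
    ----------
    sequence:
        Reference contig sequence.
    min_len:
        Minimum run length to report; must be >= 2.
    chrom:
        Contig name recorded on each locus.

    Returns
    -------
    Loci sorted by start, non-overlapping, each maximal (the flanking
    characters, where they exist, differ from the run base).
    """
    if min_len < 2:
        raise CatalogError(f"min_len must be >= 2, got {min_len}")
    seq = sequence.upper()
    loci: list[HomopolymerLocus] = []
    n = len(seq)
    i = 0
    while i < n:
        base = seq[i]
        if base not in VALID_BASES:
            i += 1
            continue
        j = i + 1
        while j < n and seq[j] == base:
            j += 1
        if j - i >= min_len:
            loci.append(HomopolymerLocus(chrom, i, j, base))
        i = j
    return loci


def scan_fasta(
    fasta_path: str | Path, min_len: int
) -> list[HomopolymerLocus]:
    """Scan every contig of a FASTA file; loci sorted by (contig order, start)."""
    loci: list[HomopolymerLocus] = []
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        loci.extend(scan_homopolymers(str(record.seq), min_len, chrom=record.id))
    return loci


def write_catalog(loci: Iterable[HomopolymerLocus], path: str | Path) -> None:
    """Serialize loci as 6-column BED: name = base+length (e.g. "A7"), score = length."""
    with open(path, "w") as fh:
        for locus in loci:
            fh.write(
                f"{locus.chrom}\t{locus.start}\t{locus.end}\t"
                f"{locus.base}{locus.ref_length}\t{locus.ref_length}\t+\n"
            )


def read_catalog(path: str | Path) -> list[HomopolymerLocus]:
    """Parse a catalog BED written by :func:`write_catalog`.

    Raises :class:`CatalogError` naming the offending line on malformed input.
    """
    loci: list[HomopolymerLocus] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise CatalogError(f"line {lineno}: expected >= 5 BED columns")
            chrom, start_s, end_s, name = fields[0], fields[1], fields[2], fields[3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise CatalogError(
                    f"line {lineno}: non-integer coordinates {start_s!r}/{end_s!r}"
                ) from None
            if start >= end:
                raise CatalogError(f"line {lineno}: start {start} >= end {end}")
            base = name[:1]
            if base not in VALID_BASES:
                raise CatalogError(f"line {lineno}: bad name field {name!r}")
            if name != f"{base}{end - start}":
                raise CatalogError(
                    f"line {lineno}: name {name!r} inconsistent with interval length "
                    f"{end - start}"
                )
            loci.append(HomopolymerLocus(chrom, start, end, base))
    return loci


def iter_window(
    loci: Iterable[HomopolymerLocus],
    len_range: tuple[int, int] | None = None,
    pair_class: str | None = None,
) -> Iterator[HomopolymerLocus]:
    """Restrict a catalog to a length window and/or base-pair class."""
    for locus in loci:
        if len_range is not None and not (
            len_range[0] <= locus.ref_length <= len_range[1]
        ):
            continue
        if pair_class is not None and locus.pair_class != pair_class:
            continue
        yield locus
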