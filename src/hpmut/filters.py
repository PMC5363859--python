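"""Cohort-level mutation filtering.

Raw per-line calls (homopolymer indels from the cohort caller, point
mutations from an upstream variant caller's VCF) become a list of *unique*
mutations: events seen in only a few lines of the cohort, at loci with data
in nearly all lines. The rationale is that a true mutation arising during
passaging is private to one (rarely two or three) lines, whereas ancestral
polymorphisms and systematic artifacts recur across many lines.

Filter chain (order configurable; default qual -> cluster -> unique):
  * QUAL threshold on point calls (default >= 100, inclusive).
  * Cluster removal: same-line point mutations within 20 bp of one another
    are discarded wholesale (chained transitively, so a 100/118/135 chain
    all goes).
  * Uniqueness: drop alleles present in more than ``max_lines`` lines and
    loci callable in fewer than ``ceil(min_data_fraction * n_lines)`` lines.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .catalog import CatalogError

COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

#: the six strand-collapsed substitution categories
SUBSTITUTION_CATEGORIES = ("AT>TA", "AT>GC", "AT>CG", "GC>CG", "GC>AT", "GC>TA")


@dataclass(frozen=True)
class MutationRecord:
    """One mutation event in one line.

    ``pos`` is a 1-based coordinate for point mutations and a locus_id
    string for homopolymer indels. ``delta`` is the indel size (negative =
    deletion) for kind "hp_indel"; ``ref``/``alt``/``qual`` apply to points.
    """

    line: str
    chrom: str
    pos: object
    kind: str                      # point | hp_indel
    ref: str | None = None
    alt: str | None = None
    delta: int | None = None
    category: str = ""
    qual: float | None = None

    def allele_key(self) -> tuple:
        """Identity used to count how many lines share a mutation."""
        if self.kind == "point":
            return (self.chrom, self.pos, self.alt)
        return (self.chrom, self.pos, self.delta)

    def locus_key(self) -> tuple:
        return (self.chrom, self.pos)


def classify_substitution(ref: str, alt: str) -> str:
    """Strand-collapsed substitution category, e.g. (G, T) -> "GC>TA".

    A substitution and its reverse complement map to the same category; the
    category is written with the A/T (or G/C) purine-pyrimidine pair of the
    reference first.
    """
    ref, alt = ref.upper(), alt.upper()
    if ref not in COMPLEMENT or alt not in COMPLEMENT or ref == alt:
        raise CatalogError(f"invalid substitution {ref}>{alt}")
    if ref in "TC":
        # take the A- or G-strand representation
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    pair = "AT" if ref == "A" else "GC"
    return f"{pair}>{alt}{COMPLEMENT[alt]}"


def filter_qual(
    records: Iterable[MutationRecord], min_qual: float = 100.0
) -> list[MutationRecord]:
    """Keep point records with QUAL >= ``min_qual`` (inclusive boundary);
    records missing QUAL are dropped with a warning. Indels pass through."""
    kept = []
    for r in records:
        if r.kind != "point":
            kept.append(r)
            continue
        if r.qual is None:
            warnings.warn(f"point record at {r.chrom}:{r.pos} has no QUAL; dropped")
            continue
        if r.qual >= min_qual:
            kept.append(r)
    return kept


def filter_clusters(
    records: Iterable[MutationRecord],
    window: int = 20,
    transitive: bool = True,
) -> list[MutationRecord]:
    """Remove clustered same-line point mutations.

    Any maximal group of >= 2 points in one line on one chromosome whose
    consecutive sorted positions are within ``window`` bp is removed
    entirely. With ``transitive=False`` only records with a pairwise
    neighbor within the window are removed (identical result for chains of
    length <= 2; differs for longer chains only in pathological spacings).
    """
    records = list(records)
    points = [r for r in records if r.kind == "point"]
    others = [r for r in records if r.kind != "point"]

    doomed: set[int] = set()
    groups: dict[tuple, list[MutationRecord]] = {}
    for r in points:
        groups.setdefault((r.line, r.chrom), []).append(r)
    for group in groups.values():
        group.sort(key=lambda r: r.pos)
        if transitive:
            run: list[MutationRecord] = [group[0]]
            for r in group[1:]:
                if r.pos - run[-1].pos <= window:
                    run.append(r)
                else:
                    if len(run) > 1:
                        doomed.update(id(x) for x in run)
                    run = [r]
            if len(run) > 1:
                doomed.update(id(x) for x in run)
        else:
            for i, r in enumerate(group):
                near = (i > 0 and r.pos - group[i - 1].pos <= window) or (
                    i + 1 < len(group) and group[i + 1].pos - r.pos <= window
                )
                if near:
                    doomed.add(id(r))

    return others + [r for r in points if id(r) not in doomed]


def filter_unique(
    records: Iterable[MutationRecord],
    n_lines: int,
    max_lines: int = 3,
    min_data_fraction: float = 44 / 47,
    callable_lines: Mapping[tuple, int] | None = None,
) -> list[MutationRecord]:
    """Keep mutations private to at most ``max_lines`` lines at well-covered loci.

    ``callable_lines`` maps locus_key -> number of lines with data at that
    locus; when omitted every locus is assumed callable in all ``n_lines``
    lines. A locus callable in fewer than ``ceil(min_data_fraction *
    n_lines)`` lines is dropped outright.
    """
    records = list(records)
    min_callable = math.ceil(min_data_fraction * n_lines)
    line_sets: dict[tuple, set[str]] = {}
    for r in records:
        line_sets.setdefault(r.allele_key(), set()).add(r.line)
    kept = []
    for r in records:
        if len(line_sets[r.allele_key()]) > max_lines:
            continue
        n_callable = (
            callable_lines.get(r.locus_key(), 0)
            if callable_lines is not None
            else n_lines
        )
        if n_callable < min_callable:
            continue
        kept.append(r)
    return kept


def read_point_vcf(path: str | Path, line: str) -> list[MutationRecord]:
    """Read point mutations for one cohort line from a VCF.

    Only CHROM, POS, REF, ALT and QUAL are consumed; multi-allelic records
    are split into one record per ALT; non-SNV alleles are skipped.
    """
    import pysam

    records: list[MutationRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            qual = None if rec.qual is None else float(rec.qual)
            ref = (rec.ref or "").upper()
            for alt in rec.alts or ():
                alt = alt.upper()
                if len(ref) != 1 or len(alt) != 1 or ref == alt:
                    continue
                if ref not in COMPLEMENT or alt not in COMPLEMENT:
                    continue
                records.append(
                    MutationRecord(
                        line=line, chrom=rec.chrom, pos=rec.pos, kind="point",
                        ref=ref, alt=alt,
                        category=classify_substitution(ref, alt), qual=qual,
                    )
                )
    return records


def indel_records_from_calls(calls: Sequence) -> list[MutationRecord]:
    """Convert variant GenotypeCalls into hp_indel MutationRecords."""
    from .caller import GenotypeCall  # local import avoids a cycle

    out = []
    for c in calls:
        if not isinstance(c, GenotypeCall) or c.status != "variant":
            continue
        chrom = c.locus_id.split(":")[0]
        out.append(
            MutationRecord(
                line=c.sample, chrom=chrom, pos=c.locus_id,
                kind="hp_indel", delta=c.delta,
            )
        )
    return out


def callable_lines_from_calls(calls: Sequence) -> dict[tuple, int]:
    """locus_key -> number of lines with a genotype (reference or variant)."""
    counts: dict[tuple, set[str]] = {}
    for c in calls:
        if c.status in ("reference", "variant"):
            chrom = c.locus_id.split(":")[0]
            counts.setdefault((chrom, c.locus_id), set()).add(c.sample)
    return {k: len(v) for k, v in counts.items()}
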