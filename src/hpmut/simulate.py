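"""Synthetic mutation-accumulation cohorts.

The generator emulates the study design the toolkit targets: a haploid
cohort of ~8 lines passaged for ~1000 generations and sequenced to ~50x
depth, with deletion-biased indel mutations at homopolymer loci and
length-dependent stutter noise on the reads. Everything is deterministic
under (config, seed); per-component RNG streams are derived by keyed
splitting so that, e.g., adding a line does not perturb the genomes or
reads of the others.

Two output levels are supported:

* full: reference FASTA + per-line SAM read files, for end-to-end tests of
  the alignment-facing extraction code;
* histogram: per-locus length histograms drawn directly from the stutter
  model, for fast replicated studies of the caller and rate estimators
  (identical stutter model, no read-level detail).

The stutter model perturbs each read's observed run length with per-read
slip probability 0.01 * (L - 4) capped at 0.30 for template allele length
L, split 2:1 in favor of -1 slips — deletion-biased and increasing with run
length, as real mononucleotide stutter is.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pysam
import yaml

from .catalog import VALID_BASES, HomopolymerLocus
from .filters import MutationRecord, classify_substitution
from .observe import LengthHistogram, LocusObservations

COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


class SimulationError(ValueError):
    pass


def default_planted_runs() -> dict[tuple[str, int], int]:
    """100 A-runs at each length 7..16 — 1000 loci spanning the analysis window."""
    return {("A", L): 100 for L in range(7, 17)}


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic cohort."""

    gc_content: float = 0.38
    planted_runs: dict[tuple[str, int], int] = field(
        default_factory=default_planted_runs
    )
    n_lines: int = 8
    generations: float = 1000.0
    point_rate: dict[str, float] = field(
        default_factory=lambda: {"AT": 3e-10, "GC": 3e-10}
    )
    indel_rate: float | Callable[[int], float] = 5e-7  # per locus per generation
    deletion_fraction: float = 0.75
    depth: float = 50.0
    read_length: int = 100
    stutter_slope: float = 0.01     # slip prob = slope * (L - offset), capped
    stutter_offset: int = 4
    stutter_cap: float = 0.30
    stutter_deletion_share: float = 2 / 3  # slips split 2:1 toward -1
    spacer: int | None = None       # distance between runs; >= read_length
    catalog_min_len: int = 5

    def rate_at(self, length: int) -> float:
        r = self.indel_rate(length) if callable(self.indel_rate) else self.indel_rate
        if r < 0:
            raise SimulationError("indel rate must be >= 0")
        return float(r)

    def slip_probability(self, length: int) -> float:
        p = self.stutter_slope * max(0, length - self.stutter_offset)
        return min(p, self.stutter_cap)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "planted_runs" in raw:
            raw["planted_runs"] = {
                (str(k).split(":")[0], int(str(k).split(":")[1])): int(v)
                for k, v in raw["planted_runs"].items()
            }
        return cls(**raw)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


# --------------------------------------------------------------------------
# Reference genome


def synth_genome(
    config: SimConfig, seed: int, chrom: str = "chrS"
) -> tuple[str, list[HomopolymerLocus]]:
    """Reference sequence with planted runs at known positions.

    Background is i.i.d. with the configured GC content but scrubbed online
    so no unplanned run reaches ``catalog_min_len`` and no spacer base
    extends a planted run; scanning the output therefore recovers exactly
    the planted catalog.
    """
    rng = _rng(seed, 0)
    spacer = config.spacer if config.spacer is not None else config.read_length + 10
    if spacer < config.read_length:
        raise SimulationError("spacer must be >= read_length")
    bases = np.array(list("ACGT"))
    probs = np.array(
        [
            (1 - config.gc_content) / 2,
            config.gc_content / 2,
            config.gc_content / 2,
            (1 - config.gc_content) / 2,
        ]
    )

    runs: list[tuple[str, int]] = []
    for (base, length), count in sorted(config.planted_runs.items()):
        if base not in VALID_BASES or length < 2 or count < 0:
            raise SimulationError(f"bad planted run spec ({base}, {length})x{count}")
        runs.extend([(base, length)] * count)
    rng.shuffle(runs)

    def draw_spacer(n: int, forbid_first: str | None, forbid_last: str | None) -> list[str]:
        out: list[str] = []
        while len(out) < n:
            ch = str(rng.choice(bases, p=probs))
            # never form a background run of catalog_min_len
            if (
                len(out) >= config.catalog_min_len - 1
                and all(c == ch for c in out[-(config.catalog_min_len - 1):])
            ):
                continue
            if not out and forbid_first is not None and ch == forbid_first:
                continue
            if len(out) == n - 1 and forbid_last is not None and ch == forbid_last:
                continue
            out.append(ch)
        return out

    pieces: list[str] = []
    loci: list[HomopolymerLocus] = []
    pos = 0
    prev_base: str | None = None
    for base, length in runs:
        sp = draw_spacer(spacer, forbid_first=prev_base, forbid_last=base)
        pieces.append("".join(sp))
        pos += spacer
        loci.append(HomopolymerLocus(chrom, pos, pos + length, base))
        pieces.append(base * length)
        pos += length
        prev_base = base
    pieces.append("".join(draw_spacer(spacer, forbid_first=prev_base, forbid_last=None)))
    return "".join(pieces), loci


def write_fasta(sequence: str, path: str | Path, chrom: str = "chrS") -> None:
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(sequence), 70):
            fh.write(sequence[i : i + 70] + "\n")


# --------------------------------------------------------------------------
# Mutation-accumulation truth


@dataclass
class TruthSet:
    """Planted mutations and resulting per-line alleles."""

    lines: list[str]
    alleles: dict[str, dict[str, int]]       # line -> locus_id -> allele length
    records: list[MutationRecord]            # planted events (indels + points)
    loci: list[HomopolymerLocus]

    def indel_truth(self) -> set[tuple[str, str, int]]:
        return {
            (r.line, r.pos, r.delta)
            for r in self.records
            if r.kind == "hp_indel"
        }


def simulate_ma_lines(
    config: SimConfig,
    loci: Sequence[HomopolymerLocus],
    seed: int,
    genome: str | None = None,
    chrom: str = "chrS",
) -> TruthSet:
    """Plant mutations independently per line.

    An indel occurs at a locus with probability 1 - exp(-rate(L) * g); its
    direction is -1 with ``deletion_fraction`` else +1. Point mutations are
    drawn Poisson per base-pair class and placed uniformly outside runs
    (only when ``genome`` is supplied).
    """
    lines = [f"line{str(i + 1).zfill(2)}" for i in range(config.n_lines)]
    alleles: dict[str, dict[str, int]] = {}
    records: list[MutationRecord] = []
    g = config.generations

    run_positions = None
    class_positions: dict[str, np.ndarray] = {}
    if genome is not None:
        in_run = np.zeros(len(genome), dtype=bool)
        for loc in loci:
            in_run[loc.start : loc.end] = True
        arr = np.frombuffer(genome.encode(), dtype="S1")
        for cls, members in (("AT", (b"A", b"T")), ("GC", (b"G", b"C"))):
            mask = (arr == members[0]) | (arr == members[1])
            class_positions[cls] = np.nonzero(mask & ~in_run)[0]

    for idx, line in enumerate(lines):
        rng = _rng(seed, 1, idx)
        my_alleles: dict[str, int] = {}
        for loc in loci:
            p_mut = 1.0 - np.exp(-config.rate_at(loc.ref_length) * g)
            allele = loc.ref_length
            if rng.random() < p_mut:
                delta = -1 if rng.random() < config.deletion_fraction else 1
                allele += delta
                records.append(
                    MutationRecord(
                        line=line, chrom=loc.chrom, pos=loc.locus_id,
                        kind="hp_indel", delta=delta,
                    )
                )
            my_alleles[loc.locus_id] = allele
        alleles[line] = my_alleles

        if genome is not None:
            for cls, positions in class_positions.items():
                lam = config.point_rate.get(cls, 0.0) * len(positions) * g
                for _ in range(rng.poisson(lam)):
                    pos = int(rng.choice(positions))
                    ref = genome[pos]
                    alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                    records.append(
                        MutationRecord(
                            line=line, chrom=chrom, pos=pos + 1, kind="point",
                            ref=ref, alt=alt,
                            category=classify_substitution(ref, alt),
                        )
                    )
    return TruthSet(lines, alleles, records, list(loci))


# --------------------------------------------------------------------------
# Reads (full path)


def _stuttered_length(allele: int, config: SimConfig, rng: np.random.Generator) -> int:
    p = config.slip_probability(allele)
    u = rng.random()
    if u < p * config.stutter_deletion_share:
        return max(0, allele - 1)
    if u < p:
        return allele + 1
    return allele


def simulate_reads(
    line: str,
    genome: str,
    truth: TruthSet,
    config: SimConfig,
    seed: int,
    out_sam: str | Path,
    chrom: str = "chrS",
) -> int:
    """Write one line's stutter-noisy reads as SAM; returns the read count.

    Read starts are uniform over the reference at mean coverage ``depth``.
    A read fully spanning a run (with at least one flank base each side)
    carries the line's allele perturbed by the stutter model, encoded in its
    CIGAR as an I or D at the 3' end of the run; other reads match the
    reference. MAPQ is 60 and no mapping error is simulated, so caller
    behavior is isolated from alignment behavior.
    """
    line_idx = truth.lines.index(line)
    rng = _rng(seed, 2, line_idx)
    glen = len(genome)
    rl = config.read_length
    n_reads = int(round(config.depth * glen / rl))
    starts = np.sort(rng.integers(0, glen - rl + 1, size=n_reads))

    loci = sorted(truth.loci, key=lambda l: l.start)
    locus_starts = np.array([l.start for l in loci])
    alleles = truth.alleles[line]

    with pysam.AlignmentFile(
        str(out_sam), "wh",
        reference_names=[chrom], reference_lengths=[glen],
    ) as out:
        for i, s in enumerate(map(int, starts)):
            # at most one locus can be fully inside the read (spacer >= read length)
            j = int(np.searchsorted(locus_starts, s))
            locus = loci[j] if j < len(loci) else None
            seq, cigar = _read_with_allele(genome, s, rl, locus, alleles, config, rng)
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"{line}.r{i}"
            a.query_sequence = seq
            a.flag = 0
            a.reference_id = 0
            a.reference_start = s
            a.mapping_quality = 60
            a.cigartuples = cigar
            out.write(a)
    return n_reads


def _read_with_allele(
    genome: str,
    s: int,
    rl: int,
    locus: HomopolymerLocus | None,
    alleles: Mapping[str, int],
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[str, list[tuple[int, int]]]:
    M, I, D = 0, 1, 2
    if (
        locus is None
        or not (s < locus.start and locus.end < s + rl)
    ):
        return genome[s : s + rl], [(M, rl)]

    allele = alleles[locus.locus_id]
    obs = _stuttered_length(allele, config, rng)
    ref_len = locus.ref_length
    left = genome[s : locus.start]
    cigar: list[tuple[int, int]] = []
    if obs >= ref_len:
        run_cigar = [(M, ref_len)] + ([(I, obs - ref_len)] if obs > ref_len else [])
    else:
        run_cigar = ([(M, obs)] if obs else []) + [(D, ref_len - obs)]
    used = len(left) + obs
    right_len = rl - used
    if right_len < 0:  # long insertion swallowed the right flank
        obs = rl - len(left)
        run_cigar = [(M, min(obs, ref_len))]
        if obs > ref_len:
            run_cigar.append((I, obs - ref_len))
        right_len = 0
    right = genome[locus.end : locus.end + right_len]
    if len(right) < right_len:  # read runs off the contig end
        right_len = len(right)
    seq = left + locus.base * obs + right
    cigar = [(M, len(left))] + run_cigar
    if right_len:
        cigar.append((M, right_len))
    # merge adjacent same-op entries (M,ref_len)+(M,right) etc.
    merged: list[tuple[int, int]] = []
    for op, ln in cigar:
        if ln == 0:
            continue
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + ln)
        else:
            merged.append((op, ln))
    return seq, merged


def simulate_cohort_sams(
    config: SimConfig, seed: int, outdir: str | Path, chrom: str = "chrS"
) -> tuple[Path, Path, TruthSet, dict[str, Path]]:
    """Full-path convenience: FASTA + catalog + truth + one SAM per line."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, loci = synth_genome(config, seed, chrom)
    fasta = outdir / "ref.fa"
    write_fasta(genome, fasta, chrom)
    from .catalog import write_catalog

    bed = outdir / "catalog.bed"
    write_catalog(loci, bed)
    truth = simulate_ma_lines(config, loci, seed, genome=genome, chrom=chrom)
    sams: dict[str, Path] = {}
    for line in truth.lines:
        path = outdir / f"{line}.sam"
        simulate_reads(line, genome, truth, config, seed, path, chrom)
        sams[line] = path
    return fasta, bed, truth, sams


# --------------------------------------------------------------------------
# Histograms (light path)


def simulate_histograms(
    config: SimConfig,
    truth: TruthSet,
    seed: int,
) -> list[LocusObservations]:
    """Per-locus length histograms drawn directly from the stutter model.

    Depth per sample per locus ~ Poisson(depth); reads land on the allele,
    allele-1, or allele+1 with the same probabilities the read simulator
    uses. Equivalent to the full path marginally, orders of magnitude
    faster.
    """
    out: list[LocusObservations] = []
    rngs = {
        line: _rng(seed, 3, i) for i, line in enumerate(truth.lines)
    }
    hists_by_line: dict[str, list[dict[int, int]]] = {}
    for line in truth.lines:
        rng = rngs[line]
        hlist: list[dict[int, int]] = []
        for loc in truth.loci:
            allele = truth.alleles[line][loc.locus_id]
            depth = int(rng.poisson(config.depth))
            p = config.slip_probability(allele)
            counts: dict[int, int] = {}
            if depth:
                n_del, n_ins = (
                    int(x)
                    for x in rng.multinomial(
                        depth,
                        [p * config.stutter_deletion_share,
                         p * (1 - config.stutter_deletion_share),
                         1 - p],
                    )[:2]
                )
                n_ref = depth - n_del - n_ins
                if n_ref:
                    counts[allele] = counts.get(allele, 0) + n_ref
                if n_del:
                    lo = max(0, allele - 1)
                    counts[lo] = counts.get(lo, 0) + n_del
                if n_ins:
                    counts[allele + 1] = counts.get(allele + 1, 0) + n_ins
            hlist.append(counts)
        hists_by_line[line] = hlist

    for k, loc in enumerate(truth.loci):
        out.append(
            LocusObservations(
                loc,
                {
                    line: LengthHistogram(line, loc.locus_id, hists_by_line[line][k])
                    for line in truth.lines
                },
            )
        )
    return out


# --------------------------------------------------------------------------
# Scoring


def score_recovery(
    calls: Sequence, truth: TruthSet, n_tests: int | None = None
) -> dict[str, float]:
    """Compare caller output (GenotypeCalls or hp_indel MutationRecords)
    against the planted truth.

    Returns sensitivity (recovered planted events / planted), the false
    positive count, and the FP rate per locus-sample test when ``n_tests``
    is given (default: loci x lines).
    """
    truth_set = truth.indel_truth()
    called: set[tuple[str, str, int]] = set()
    for c in calls:
        if isinstance(c, MutationRecord):
            if c.kind == "hp_indel":
                called.add((c.line, c.pos, c.delta))
        elif getattr(c, "status", None) == "variant":
            called.add((c.sample, c.locus_id, c.delta))
    tp = len(called & truth_set)
    fp = len(called - truth_set)
    if n_tests is None:
        n_tests = len(truth.loci) * len(truth.lines)
    return {
        "sensitivity": tp / len(truth_set) if truth_set else float("nan"),
        "false_positives": float(fp),
        "fp_rate": fp / n_tests if n_tests else float("nan"),
        "n_planted": float(len(truth_set)),
    }
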