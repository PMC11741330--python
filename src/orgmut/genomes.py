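"""Genome model for organelle mutation-accumulation analysis.

An organelle genome is represented as a (usually circular) nucleotide
sequence together with gene annotation, interval masks for the large
repeated regions that are excluded from variant calling (one copy of the
plastid inverted repeat, one copy of each large mitochondrial repeat
pair), a numt track giving the nuclear copy number of each mitochondrial
region, and artefact masks for regions prone to rearrangement-driven
false calls.

All positions at module interfaces are 1-based and inclusive; circular
position arithmetic wraps modulo the genome length.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .errors import ConfigError, DataError

VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True, order=True)
class Interval:
    """Closed interval of 1-based genome positions."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise DataError(f"invalid interval [{self.start}, {self.end}]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def contains_interval(self, other: "Interval") -> bool:
        return self.start <= other.start and other.end <= self.end

    def overlaps(self, other: "Interval") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass(frozen=True)
class GeneFeature:
    """A typed gene feature composed of one or more intervals.

    ``frame`` is the codon phase (0/1/2) of the first base of the first
    interval in strand order, CDS only.
    """

    gene_id: str
    kind: str  # CDS | intron | rRNA | tRNA
    intervals: tuple[Interval, ...]
    strand: str = "+"
    frame: int = 0

    KINDS = ("CDS", "intron", "rRNA", "tRNA")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise DataError(f"unknown feature kind {self.kind!r}")
        if self.strand not in "+-":
            raise DataError(f"invalid strand {self.strand!r}")
        if self.kind == "CDS" and self.total_length % 3 != 0:
            raise DataError(
                f"CDS {self.gene_id} has joined length {self.total_length}, "
                "not divisible by 3"
            )

    @property
    def total_length(self) -> int:
        return sum(iv.length for iv in self.intervals)

    def contains(self, pos: int) -> bool:
        return any(iv.contains(pos) for iv in self.intervals)


@dataclass(frozen=True)
class RepeatRecord:
    """A maximal simple-sequence repeat locus.

    ``unit`` is a single base for homopolymers or a 2-mer for
    dinucleotide arrays; ``base_class`` is "AT" or "GC" for homopolymers
    and "" for dinucleotides.  ``length`` may extend past the genome end
    for origin-spanning runs on circular genomes.
    """

    start: int
    length: int
    unit: str
    unit_count: int
    base_class: str = ""

    def __post_init__(self) -> None:
        if self.length != self.unit_count * len(self.unit):
            raise DataError("repeat length must equal unit_count * len(unit)")

    @property
    def end(self) -> int:
        """Inclusive end position; may exceed genome length when wrapping."""
        return self.start + self.length - 1

    def contains(self, pos: int, genome_length: int | None = None) -> bool:
        if self.start <= pos <= self.end:
            return True
        if genome_length is not None and self.end > genome_length:
            return pos <= self.end - genome_length  # wrapped tail
        return False


@dataclass
class GenomeSpec:
    """Sequence + annotation + masks for one organelle genome."""

    name: str
    sequence: str
    annotation: list[GeneFeature] = field(default_factory=list)
    repeat_mask: list[Interval] = field(default_factory=list)
    numt_track: list[tuple[Interval, int]] = field(default_factory=list)
    artefact_mask: list[Interval] = field(default_factory=list)
    circular: bool = True

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise DataError(f"genome {self.name}: non-ACGT characters {sorted(bad)}")
        n = len(self.sequence)
        for iv in [*self.repeat_mask, *self.artefact_mask] + [
            iv for iv, _ in self.numt_track
        ]:
            if iv.end > n:
                raise DataError(
                    f"genome {self.name}: interval [{iv.start}, {iv.end}] "
                    f"outside sequence of length {n}"
                )
        masks = sorted(self.repeat_mask)
        for a, b in zip(masks, masks[1:]):
            if a.overlaps(b):
                raise DataError(f"genome {self.name}: overlapping repeat masks")
        for feat in self.annotation:
            for iv in feat.intervals:
                if iv.end > n:
                    raise DataError(
                        f"feature {feat.gene_id} outside sequence bounds"
                    )
        _check_cds_frames(self.annotation)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def effective_size_G(self) -> int:
        """Genome size minus total masked repeat length (bp).

        This is the denominator G of the mutation-rate estimator: masked
        repeat copies contribute no callable sites, so they are removed
        from the genome size exactly as their variant calls are removed.
        """
        return len(self.sequence) - sum(iv.length for iv in self.repeat_mask)

    def base(self, pos: int) -> str:
        """Base at 1-based position, wrapping on circular genomes."""
        n = len(self.sequence)
        if self.circular:
            return self.sequence[(pos - 1) % n]
        if not 1 <= pos <= n:
            raise DataError(f"position {pos} outside linear genome {self.name}")
        return self.sequence[pos - 1]

    def in_repeat_mask(self, pos: int) -> bool:
        return any(iv.contains(pos) for iv in self.repeat_mask)

    def in_artefact_mask(self, pos: int) -> bool:
        return any(iv.contains(pos) for iv in self.artefact_mask)

    def numt_copies_at(self, pos: int) -> int:
        """Nuclear copy number of the region containing ``pos`` (0 if none)."""
        return sum(c for iv, c in self.numt_track if iv.contains(pos))

    def base_composition(self, exclude_masked: bool = True) -> dict[str, int]:
        """AT/GC bp counts, by default over the unmasked portion only."""
        if exclude_masked and self.repeat_mask:
            counts: Counter[str] = Counter()
            masked = sorted(self.repeat_mask)
            prev = 1
            for iv in masked:
                counts.update(self.sequence[prev - 1 : iv.start - 1])
                prev = iv.end + 1
            counts.update(self.sequence[prev - 1 :])
        else:
            counts = Counter(self.sequence)
        return {
            "AT": counts["A"] + counts["T"],
            "GC": counts["G"] + counts["C"],
        }


def _check_cds_frames(annotation: Sequence[GeneFeature]) -> None:
    """Reject same-strand overlapping CDS with inconsistent reading frames."""
    cds = [f for f in annotation if f.kind == "CDS"]
    for i, a in enumerate(cds):
        for b in cds[i + 1 :]:
            if a.strand != b.strand:
                continue
            for iva in a.intervals:
                for ivb in b.intervals:
                    if not iva.overlaps(ivb):
                        continue
                    pos = max(iva.start, ivb.start)
                    if cds_phase(a, pos) != cds_phase(b, pos):
                        raise DataError(
                            f"CDS {a.gene_id} and {b.gene_id} overlap on the "
                            f"same strand with inconsistent frames at {pos}"
                        )


def cds_phase(feature: GeneFeature, pos: int) -> int:
    """Codon phase (0/1/2) of genomic position ``pos`` within a CDS."""
    if feature.kind != "CDS":
        raise ConfigError("cds_phase requires a CDS feature")
    idx = cds_index(feature, pos)
    return (idx + feature.frame) % 3


def cds_index(feature: GeneFeature, pos: int) -> int:
    """0-based index of genomic ``pos`` in the joined CDS, strand order."""
    intervals = list(feature.intervals)
    if feature.strand == "-":
        intervals = sorted(intervals, key=lambda iv: iv.start, reverse=True)
    else:
        intervals = sorted(intervals, key=lambda iv: iv.start)
    offset = 0
    for iv in intervals:
        if iv.contains(pos):
            if feature.strand == "-":
                return offset + (iv.end - pos)
            return offset + (pos - iv.start)
        offset += iv.length
    raise DataError(f"position {pos} not in CDS {feature.gene_id}")


# ---------------------------------------------------------------------------
# Simple-repeat scanners


def find_homopolymers(
    genome: GenomeSpec, min_len: int = 5, exclude_masked: bool = True
) -> list[RepeatRecord]:
    """Maximal single-base runs of length >= ``min_len``.

    Runs spanning the origin of a circular genome are reported once, with
    start in [1, len] and length extending past the end.  Runs fully
    inside a masked repeat copy are excluded (the census, like variant
    calling, counts each large repeat once).
    """
    if min_len < 2:
        raise ConfigError("min_len must be >= 2")
    s = genome.sequence
    n = len(s)
    records: list[RepeatRecord] = []
    if n == 0:
        return records
    if genome.circular and len(set(s)) == 1:
        if n >= min_len:
            records.append(_hp_record(1, n, s[0]))
        return _mask_filter(records, genome, exclude_masked)

    for i in range(n):
        b = s[i]
        prev = s[(i - 1) % n] if genome.circular else (s[i - 1] if i > 0 else None)
        if prev == b:
            continue  # not a run start
        j = 1
        if genome.circular:
            while j < n and s[(i + j) % n] == b:
                j += 1
        else:
            while i + j < n and s[i + j] == b:
                j += 1
        if j >= min_len:
            records.append(_hp_record(i + 1, j, b))
    records.sort(key=lambda r: r.start)
    return _mask_filter(records, genome, exclude_masked)


def _hp_record(start: int, length: int, base: str) -> RepeatRecord:
    base_class = "AT" if base in "AT" else "GC"
    return RepeatRecord(
        start=start, length=length, unit=base, unit_count=length,
        base_class=base_class,
    )


def _mask_filter(
    records: list[RepeatRecord], genome: GenomeSpec, exclude_masked: bool
) -> list[RepeatRecord]:
    if not exclude_masked or not genome.repeat_mask:
        return records
    n = len(genome)
    kept = []
    for r in records:
        inside = any(
            iv.start <= r.start and r.end <= iv.end
            for iv in genome.repeat_mask
            if r.end <= n  # wrapped runs are never fully inside a linear mask
        )
        if not inside:
            kept.append(r)
    return kept


def find_dinucleotide_repeats(
    genome: GenomeSpec, min_units: int = 3, exclude_masked: bool = True
) -> list[RepeatRecord]:
    """Maximal tandem arrays of a non-homopolymeric 2-mer.

    An array is maximal when it cannot be extended by a full unit on
    either side; arrays of AA/CC/GG/TT units are homopolymers and are
    excluded here.
    """
    if min_units < 2:
        raise ConfigError("min_units must be >= 2")
    s = genome.sequence
    n = len(s)
    records: list[RepeatRecord] = []

    def at(k: int) -> str | None:
        if genome.circular:
            return s[k % n]
        return s[k] if 0 <= k < n else None

    for i in range(n):
        unit = (at(i) or "") + (at(i + 1) or "")
        if len(unit) < 2 or unit[0] == unit[1]:
            continue
        if at(i - 1) == unit[1]:
            continue  # alternation continues left: not the leftmost phase
        k = 1
        while 2 * (k + 1) <= n and at(i + 2 * k) == unit[0] and at(i + 2 * k + 1) == unit[1]:
            k += 1
        if k >= min_units:
            records.append(
                RepeatRecord(start=i + 1, length=2 * k, unit=unit, unit_count=k)
            )
    # perfect circular tiling has no left-maximal start; report it once
    if (
        not records
        and genome.circular
        and n >= 4
        and n % 2 == 0
        and s[0] != s[1]
        and s == s[:2] * (n // 2)
        and n // 2 >= min_units
    ):
        records.append(
            RepeatRecord(start=1, length=n, unit=s[:2], unit_count=n // 2)
        )
    records.sort(key=lambda r: r.start)
    return _mask_filter(records, genome, exclude_masked)


@dataclass
class HomopolymerCensus:
    """Per-(base class, length) homopolymer counts and the AT:GC ratio."""

    table: pd.DataFrame  # columns: base_class, length, count
    at_gc_ratio: float


def homopolymer_class_counts(
    genome_or_records: GenomeSpec | Iterable[RepeatRecord],
    min_len: int = 5,
) -> HomopolymerCensus:
    """Tabulate homopolymers by base class and length.

    The AT:GC ratio is the ratio of total A/T-run count to total G/C-run
    count (inf when no G/C runs exist).
    """
    if isinstance(genome_or_records, GenomeSpec):
        records = find_homopolymers(genome_or_records, min_len=min_len)
    else:
        records = list(genome_or_records)
    rows = [(r.base_class, r.length) for r in records]
    table = (
        pd.DataFrame(rows, columns=["base_class", "length"])
        .value_counts()
        .rename("count")
        .reset_index()
        .sort_values(["base_class", "length"])
        .reset_index(drop=True)
    )
    n_at = sum(1 for r in records if r.base_class == "AT")
    n_gc = sum(1 for r in records if r.base_class == "GC")
    ratio = n_at / n_gc if n_gc else float("inf")
    return HomopolymerCensus(table=table, at_gc_ratio=ratio)


def load_genome(
    fasta_path,
    gff3_path=None,
    masks_bed_path=None,
    numt_bed_path=None,
    artefact_bed_path=None,
    circular: bool = True,
) -> GenomeSpec:
    """Assemble a GenomeSpec from standard files.

    FASTA must contain exactly one record.  BED masks use the usual
    0-based half-open convention on disk and are converted to 1-based
    closed intervals; the numt BED carries the nuclear copy number in
    its score column.
    """
    from . import io as _io

    name, sequence = _io.read_single_fasta(fasta_path)
    annotation = _io.read_gff3_features(gff3_path) if gff3_path else []
    repeat_mask = _io.read_bed_intervals(masks_bed_path) if masks_bed_path else []
    artefact_mask = (
        _io.read_bed_intervals(artefact_bed_path) if artefact_bed_path else []
    )
    numt_track = _io.read_numt_bed(numt_bed_path) if numt_bed_path else []
    return GenomeSpec(
        name=name,
        sequence=sequence,
        annotation=annotation,
        repeat_mask=repeat_mask,
        numt_track=numt_track,
        artefact_mask=artefact_mask,
        circular=circular,
    )
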