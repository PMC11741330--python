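"""Assignment of small indels to simple-repeat loci and indel-bias tables.

In MSH1-deficient lines nearly all small indels are single-unit (or
few-unit) expansions and contractions of homopolymer runs, with a
residual handful at tandem dinucleotide arrays.  Each indel is assigned
to the repeat locus containing its (left-aligned) anchor whose unit the
inserted/deleted sequence repeats; everything else is non-repetitive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import DataError
from .genomes import GenomeSpec, RepeatRecord
from .variants import LineMeta, VariantCall

CONTEXT_CLASSES = (
    "homopolymer-A/T",
    "homopolymer-G/C",
    "dinucleotide",
    "non-repetitive",
)


@dataclass(frozen=True)
class IndelAssignment:
    variant: VariantCall
    locus: RepeatRecord | None
    context_class: str
    length_change: int  # + insertion / - deletion


def left_align_indel(call: VariantCall, genome: GenomeSpec) -> VariantCall:
    """Normalize an indel to its leftmost equivalent representation.

    The indel is shifted left one base at a time while the base before
    the anchor equals the last base of the indel sequence (rotating the
    sequence accordingly), which anchors repeat-locus indels at or
    before the repeat start regardless of how the caller reported them.
    """
    if call.var_type not in ("insertion", "deletion"):
        return call
    seq = call.indel_seq
    pos = call.position
    n = len(genome)
    while True:
        prev = pos if call.var_type == "insertion" else pos
        base_before = genome.base(prev) if (genome.circular or prev >= 1) else None
        if base_before is None or base_before != seq[-1]:
            break
        seq = seq[-1] + seq[:-1]
        pos -= 1
        if pos < 1:
            if not genome.circular:
                break
            pos += n
    if pos == call.position:
        return call
    import copy

    out = copy.copy(call)
    out.position = pos
    out.filter_flags = set(call.filter_flags)
    if call.var_type == "insertion":
        out.alt = seq
    else:
        out.ref = seq
    return out


def _is_unit_repetition(seq: str, unit: str) -> bool:
    """Whether ``seq`` is whole-unit steps of the repeat ``unit`` (any phase)."""
    if not seq or len(seq) % len(unit) != 0:
        return False
    k = len(seq) // len(unit)
    for phase in range(len(unit)):
        rotated = unit[phase:] + unit[:phase]
        if seq == rotated * k:
            return True
    return False


def assign_indel(
    variant: VariantCall,
    repeat_catalogue: Sequence[RepeatRecord],
    genome_length: int | None = None,
) -> IndelAssignment:
    """Assign one (left-aligned) indel to its repeat context.

    Homopolymer loci take precedence over dinucleotide arrays.  The
    anchor may sit one unit before the locus start (a left-aligned
    insertion lands just before the run).  An indel whose sequence does
    not repeat the locus unit is non-repetitive even when positioned
    inside a run.
    """
    if variant.var_type not in ("insertion", "deletion"):
        raise DataError("assign_indel requires an insertion or deletion call")
    seq = variant.indel_seq
    change = variant.length_change
    anchor = variant.position

    def anchored_at(r: RepeatRecord) -> bool:
        lo = r.start - len(r.unit)
        if lo <= anchor <= r.end:
            return True
        if genome_length is not None and r.end > genome_length:
            return anchor <= r.end - genome_length  # wrapped tail
        return False

    for r in sorted(repeat_catalogue, key=lambda r: len(r.unit)):
        if len(r.unit) == 1 and anchored_at(r) and _is_unit_repetition(seq, r.unit):
            cls = "homopolymer-A/T" if r.base_class == "AT" else "homopolymer-G/C"
            return IndelAssignment(variant, r, cls, change)
    for r in repeat_catalogue:
        if len(r.unit) == 2 and anchored_at(r) and _is_unit_repetition(seq, r.unit):
            return IndelAssignment(variant, r, "dinucleotide", change)
    return IndelAssignment(variant, None, "non-repetitive", change)


@dataclass
class IndelBiasTable:
    """Insertion/deletion counts per context class and per genome."""

    table: pd.DataFrame  # columns: genome, context_class, insertions, deletions
    length_histogram: pd.DataFrame  # columns: genome, length_change, count

    def totals(self, genome: str | None = None) -> tuple[int, int]:
        df = self.table
        if genome is not None:
            df = df[df["genome"] == genome]
        return int(df["insertions"].sum()), int(df["deletions"].sum())


def bias_table(assignments: Iterable[IndelAssignment]) -> IndelBiasTable:
    """Tabulate insertion vs deletion counts by repeat class and genome."""
    rows = []
    for a in assignments:
        rows.append(
            {
                "genome": a.variant.genome,
                "context_class": a.context_class,
                "length_change": a.length_change,
            }
        )
    if not rows:
        empty = pd.DataFrame(columns=["genome", "context_class", "insertions", "deletions"])
        hist = pd.DataFrame(columns=["genome", "length_change", "count"])
        return IndelBiasTable(table=empty, length_histogram=hist)
    df = pd.DataFrame(rows)
    df["kind"] = df["length_change"].map(lambda x: "insertions" if x > 0 else "deletions")
    table = (
        df.pivot_table(
            index=["genome", "context_class"],
            columns="kind",
            aggfunc="size",
            fill_value=0,
        )
        .reindex(columns=["insertions", "deletions"], fill_value=0)
        .reset_index()
    )
    table.columns.name = None
    hist = (
        df.groupby(["genome", "length_change"]).size().rename("count").reset_index()
    )
    return IndelBiasTable(table=table, length_histogram=hist)


def homopolymer_fraction(assignments: Sequence[IndelAssignment]) -> float:
    """Fraction of indels at homopolymer loci."""
    if not assignments:
        raise DataError("no indel assignments")
    n_hp = sum(1 for a in assignments if a.context_class.startswith("homopolymer"))
    return n_hp / len(assignments)


def recurrence_report(
    assignments: Iterable[IndelAssignment],
    lines: Mapping[str, LineMeta] | Sequence[LineMeta] | None = None,
) -> pd.DataFrame:
    """Repeat loci mutated in two or more MA lines.

    One row per recurrent locus with the lines hit, their signed indel
    lengths, whether the lengths differ (evidence of independent hits),
    and whether all lines share a founder family (possible inheritance
    from a common progenitor).
    """
    if lines is not None and not isinstance(lines, Mapping):
        lines = {m.line_id: m for m in lines}
    grouped: dict[tuple[str, int], list[IndelAssignment]] = {}
    for a in assignments:
        if a.locus is None:
            continue
        grouped.setdefault((a.variant.genome, a.locus.start), []).append(a)
    rows = []
    for (genome, start), hits in sorted(grouped.items()):
        hit_lines = sorted({a.variant.line_id for a in hits})
        if len(hit_lines) < 2:
            continue
        lengths = {a.variant.line_id: a.length_change for a in hits}
        families = (
            {lines[l].founder_family for l in hit_lines if l in lines}
            if lines is not None
            else set()
        )
        rows.append(
            {
                "genome": genome,
                "locus_start": start,
                "unit": hits[0].locus.unit,
                "n_lines": len(hit_lines),
                "lines": ",".join(hit_lines),
                "length_changes": ",".join(str(lengths[l]) for l in hit_lines),
                "lengths_differ": len(set(lengths.values())) > 1,
                "shared_founder_family": len(families) == 1 if families else False,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "genome",
            "locus_start",
            "unit",
            "n_lines",
            "lines",
            "length_changes",
            "lengths_differ",
            "shared_founder_family",
        ],
    )
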