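"""Readers and writers for the standard interchange formats.

FASTA via Biopython, GFF3 via gffutils, BED and flat tables via pandas.
BED files use the on-disk 0-based half-open convention; everything in
memory is 1-based inclusive.
"""

from __future__ import annotations

import os
from typing import TYPE_CHECKING

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DataError
from .genomes import GeneFeature, GenomeSpec, Interval, RepeatRecord

if TYPE_CHECKING:  # pragma: no cover
    from .variants import LineMeta, VariantCall


def read_single_fasta(path) -> tuple[str, str]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise DataError(f"{path}: expected exactly one FASTA record, got {len(records)}")
    rec = records[0]
    return rec.id, str(rec.seq).upper()


def write_fasta(path, name: str, sequence: str) -> None:
    rec = SeqRecord(Seq(sequence), id=name, description="")
    SeqIO.write([rec], str(path), "fasta")


def read_bed_intervals(path) -> list[Interval]:
    df = _read_bed(path)
    return [Interval(int(s) + 1, int(e)) for s, e in zip(df[1], df[2])]


def read_numt_bed(path) -> list[tuple[Interval, int]]:
    """Numt BED: copy number of each region is in the score column (5th)."""
    df = _read_bed(path)
    if df.shape[1] < 5:
        raise DataError(f"{path}: numt BED needs a score column with copy number")
    return [
        (Interval(int(s) + 1, int(e)), int(c))
        for s, e, c in zip(df[1], df[2], df[4])
    ]


def _read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise DataError(f"{path}: BED needs at least 3 columns")
    if (df[1] < 0).any() or (df[2] <= df[1]).any():
        raise DataError(f"{path}: malformed BED intervals")
    return df


def write_bed(path, chrom: str, intervals, scores=None) -> None:
    rows = []
    for i, iv in enumerate(intervals):
        row = [chrom, iv.start - 1, iv.end]
        if scores is not None:
            row += [f"region{i+1}", scores[i]]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# GFF3


def read_gff3_features(path) -> list[GeneFeature]:
    """Parse CDS / intron / rRNA / tRNA features into GeneFeature records.

    Multi-interval CDS (with introns) are joined by shared ID or Parent
    attribute; the reading frame is taken from the phase column of the
    first segment in strand order.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", force=True
    )
    grouped: dict[tuple[str, str], list] = {}
    for feat in db.all_features():
        kind = {"CDS": "CDS", "intron": "intron", "rRNA": "rRNA", "tRNA": "tRNA"}.get(
            feat.featuretype
        )
        if kind is None:
            continue
        gene_id = (
            feat.attributes.get("Parent", [None])[0]
            or feat.attributes.get("ID", [feat.id])[0]
        )
        grouped.setdefault((gene_id, kind), []).append(feat)

    features = []
    for (gene_id, kind), feats in grouped.items():
        feats.sort(key=lambda f: f.start)
        strand = feats[0].strand if feats[0].strand in "+-" else "+"
        first = feats[-1] if strand == "-" else feats[0]
        frame = int(first.frame) if kind == "CDS" and first.frame in "012" else 0
        features.append(
            GeneFeature(
                gene_id=gene_id,
                kind=kind,
                intervals=tuple(Interval(f.start, f.end) for f in feats),
                strand=strand,
                frame=frame,
            )
        )
    features.sort(key=lambda f: f.intervals[0].start)
    return features


def write_gff3(path, chrom: str, features) -> None:
    lines = ["##gff-version 3"]
    for feat in features:
        for iv in feat.intervals:
            phase = "."
            if feat.kind == "CDS":
                from .genomes import cds_phase

                anchor = iv.end if feat.strand == "-" else iv.start
                phase = str(cds_phase(feat, anchor))
            lines.append(
                "\t".join(
                    [
                        chrom,
                        "orgmut",
                        feat.kind,
                        str(iv.start),
                        str(iv.end),
                        ".",
                        feat.strand,
                        phase,
                        f"ID={feat.gene_id}",
                    ]
                )
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Repeat catalogue and line metadata tables


def write_repeat_catalogue(path, records: list[RepeatRecord]) -> None:
    pd.DataFrame(
        [
            {
                "start": r.start,
                "length": r.length,
                "unit": r.unit,
                "unit_count": r.unit_count,
                "base_class": r.base_class,
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


def read_repeat_catalogue(path) -> list[RepeatRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"base_class": str}, keep_default_na=False)
    return [
        RepeatRecord(
            start=int(r.start),
            length=int(r.length),
            unit=str(r.unit),
            unit_count=int(r.unit_count),
            base_class=str(r.base_class),
        )
        for r in df.itertuples()
    ]


def read_line_metadata(path) -> list["LineMeta"]:
    from .variants import LineMeta

    df = pd.read_csv(path, sep="\t")
    required = {"line_id", "genotype", "generations", "founder_family"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    return [
        LineMeta(
            line_id=str(r.line_id),
            genotype=str(r.genotype),
            generations=int(r.generations),
            founder_family=str(r.founder_family),
        )
        for r in df.itertuples()
    ]


def write_line_metadata(path, lines) -> None:
    pd.DataFrame(
        [
            {
                "line_id": m.line_id,
                "genotype": m.genotype,
                "generations": m.generations,
                "founder_family": m.founder_family,
            }
            for m in lines
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF output

_VCF_HEADER = """##fileformat=VCFv4.2
##source=orgmut
##INFO=<ID=RAWAF,Number=1,Type=Float,Description="Raw variant allele frequency">
##INFO=<ID=AF,Number=1,Type=Float,Description="Numt-corrected variant allele frequency">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth at site">
##INFO=<ID=LINE,Number=1,Type=String,Description="MA line id">
##INFO=<ID=VT,Number=1,Type=String,Description="Variant type">
##INFO=<ID=HOMOPLASMY,Number=1,Type=String,Description="Homoplasmy classification">
##FILTER=<ID=low_freq,Description="Frequency below detection threshold">
##FILTER=<ID=low_depth,Description="Depth below detection threshold">
##FILTER=<ID=background,Description="Below 3-fold of WT background frequency">
##FILTER=<ID=repeat_copy,Description="Inside excluded large-repeat copy">
##FILTER=<ID=artefact,Description="Inside artefact mask">
##FILTER=<ID=numt,Description="Explainable by numt/rearrangement homology">
"""


def write_vcf(path, genome: GenomeSpec, calls: list["VariantCall"]) -> None:
    """One genome per file; frequencies and flags go to INFO/FILTER."""
    lines = [_VCF_HEADER + f"##contig=<ID={genome.name},length={len(genome)}>"]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for c in sorted(calls, key=lambda c: (c.position, c.line_id)):
        ref, alt = _vcf_alleles(genome, c)
        filt = ";".join(sorted(c.filter_flags)) if c.filter_flags else "PASS"
        info = (
            f"LINE={c.line_id};VT={c.var_type};DP={c.depth};"
            f"RAWAF={c.raw_frequency:.6g};AF={c.corrected_frequency:.6g};"
            f"HOMOPLASMY={c.homoplasmy_state}"
        )
        lines.append(
            f"{c.genome}\t{c.position}\t.\t{ref}\t{alt}\t.\t{filt}\t{info}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _vcf_alleles(genome: GenomeSpec, call) -> tuple[str, str]:
    """VCF-style alleles: indels are anchored on the preceding base."""
    if call.var_type in ("SNV", "MNV"):
        return call.ref, call.alt
    anchor = genome.base(call.position - 1) if call.position > 1 else genome.base(len(genome))
    if call.var_type == "insertion":
        return anchor, anchor + call.alt
    return anchor + call.ref, anchor  # deletion


def write_variant_tsv(path, calls: list["VariantCall"]) -> None:
    pd.DataFrame(
        [
            {
                "line_id": c.line_id,
                "genome": c.genome,
                "position": c.position,
                "ref": c.ref,
                "alt": c.alt,
                "var_type": c.var_type,
                "raw_frequency": c.raw_frequency,
                "corrected_frequency": c.corrected_frequency,
                "depth": c.depth,
                "homoplasmy_state": c.homoplasmy_state,
                "filter_flags": ",".join(sorted(c.filter_flags)),
            }
            for c in calls
        ]
    ).to_csv(path, sep="\t", index=False)


def read_variant_tsv(path) -> list["VariantCall"]:
    from .variants import VariantCall

    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    calls = []
    for r in df.itertuples():
        flags = set(str(r.filter_flags).split(",")) - {""}
        calls.append(
            VariantCall(
                line_id=str(r.line_id),
                genome=str(r.genome),
                position=int(r.position),
                ref=str(r.ref),
                alt=str(r.alt),
                var_type=str(r.var_type),
                raw_frequency=float(r.raw_frequency),
                corrected_frequency=float(r.corrected_frequency),
                depth=int(r.depth),
                homoplasmy_state=str(r.homoplasmy_state),
                filter_flags=flags,
            )
        )
    return calls


def ensure_dir(path) -> None:
    os.makedirs(path, exist_ok=True)
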