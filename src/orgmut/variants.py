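"""Variant calling from per-site allele-count tables.

The pipeline turns pileup-style allele counts into germline variant
calls with the filter chain used for organelle mutation-accumulation
lines:

1. detection thresholds — allele frequency >= 20% and depth >= 50x;
2. background filter — frequency at least 3-fold the mean frequency of
   the same allele across all wild-type lines (sequencing noise at
   low-complexity sites is shared across samples);
3. repeat-copy masks — calls in the excluded copy of each large repeat
   are removed so variants are counted once;
4. artefact masks and an exact-match flank-homology check standing in
   for BLASTN screening of rearrangement/numt-explainable calls;
5. numt correction of mitochondrial allele frequencies — the expected
   number of nuclear (numt-derived) reads is subtracted from the
   reference allele count and the site depth before recomputing the
   frequency;
6. homoplasmy classification and MNV merging.

Filters accumulate flags rather than dropping records, so the passing
set is independent of the order in which filters run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .genomes import GenomeSpec

FILTER_FLAGS = ("low_freq", "low_depth", "background", "repeat_copy", "artefact", "numt")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types


@dataclass
class SiteCounts:
    """Allele counts for one sample at one genome position.

    ``allele_counts`` keys are A/C/G/T, "+SEQ" for insertions and "-N"
    for deletions of N bp starting at the next position.  Depth need not
    equal the sum of counts (clipped or ambiguous reads), but no single
    count may exceed depth.
    """

    sample_id: str
    genome: str
    position: int
    ref: str
    depth: int
    allele_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for allele, count in self.allele_counts.items():
            _validate_allele(allele)
            if count > self.depth:
                raise DataError(
                    f"{self.sample_id}:{self.position}: count for {allele} "
                    f"({count}) exceeds depth ({self.depth})"
                )


def _validate_allele(allele: str) -> None:
    if allele in "ACGT" and len(allele) == 1:
        return
    if allele.startswith("+") and len(allele) > 1 and set(allele[1:]) <= set("ACGT"):
        return
    if allele.startswith("-") and allele[1:].isdigit() and int(allele[1:]) >= 1:
        return
    raise DataError(f"unknown allele token {allele!r}")


@dataclass
class VariantCall:
    """A candidate or reported variant in one MA line.

    For insertions ``alt`` is the inserted sequence and ``ref`` is "-";
    for deletions ``ref`` is the deleted sequence (or "N"*len when the
    genome is unavailable) and ``alt`` is "-".  ``corrected_frequency``
    equals ``raw_frequency`` unless a numt correction was applied.
    A call is reported iff ``filter_flags`` is empty.
    """

    line_id: str
    genome: str
    position: int
    ref: str
    alt: str
    var_type: str  # SNV | MNV | insertion | deletion
    raw_frequency: float
    depth: int
    corrected_frequency: float = None  # type: ignore[assignment]
    alt_count: int = None  # type: ignore[assignment]
    homoplasmy_state: str = "unclassified"
    filter_flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.corrected_frequency is None:
            self.corrected_frequency = self.raw_frequency
        if self.alt_count is None:
            self.alt_count = int(round(self.raw_frequency * self.depth))

    @property
    def passes(self) -> bool:
        return not self.filter_flags

    @property
    def length_change(self) -> int:
        if self.var_type == "insertion":
            return len(self.alt)
        if self.var_type == "deletion":
            return -len(self.ref)
        return 0

    @property
    def indel_seq(self) -> str:
        if self.var_type == "insertion":
            return self.alt
        if self.var_type == "deletion":
            return self.ref
        return ""


@dataclass(frozen=True)
class LineMeta:
    """One MA line: genotype and the number of homozygous generations.

    Generations count only those spent in the homozygous state (7 for an
    F8 line, 6 for an F7 line; the heterozygous F1 is excluded).
    """

    line_id: str
    genotype: str  # WT | msh1
    generations: int
    founder_family: str = ""

    def __post_init__(self) -> None:
        if self.genotype not in ("WT", "msh1"):
            raise DataError(f"unknown genotype {self.genotype!r}")
        if self.generations < 1:
            raise DataError("generations must be >= 1")


@dataclass(frozen=True)
class NuclearCoverageEstimate:
    """Mean nuclear read depth for one sequenced sample."""

    sample_id: str
    mean_depth: float

    def __post_init__(self) -> None:
        if self.mean_depth < 0:
            raise DataError("nuclear coverage must be >= 0")


# ---------------------------------------------------------------------------
# Reading count tables

COUNT_COLUMNS = ["sample", "genome", "pos", "ref", "depth", "A", "C", "G", "T", "INS", "DEL"]


def read_site_counts(tsv_path, error_sink: list | None = None) -> Iterator[SiteCounts]:
    """Stream validated SiteCounts from a per-site count TSV.

    Malformed rows (unknown allele token, count exceeding depth) are
    skipped and reported with their 1-based line number, either into
    ``error_sink`` or as warnings.
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype={"INS": str, "DEL": str})
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"{tsv_path}: missing columns {sorted(missing)}")
    for i, row in enumerate(df.itertuples(), start=2):  # line 1 is the header
        try:
            yield _row_to_counts(row)
        except DataError as exc:
            msg = f"{tsv_path}:{i}: {exc}"
            if error_sink is not None:
                error_sink.append(msg)
            else:
                warnings.warn(msg, stacklevel=2)


def _row_to_counts(row) -> SiteCounts:
    counts: dict[str, int] = {}
    for base in "ACGT":
        c = int(getattr(row, base))
        if c:
            counts[base] = c
    for col, prefix in (("INS", "+"), ("DEL", "-")):
        cell = getattr(row, col)
        if isinstance(cell, str) and cell not in (".", ""):
            for token in cell.split(","):
                allele, _, count = token.partition(":")
                if not count:
                    raise DataError(f"malformed {col} token {token!r}")
                counts[allele] = int(count)
    return SiteCounts(
        sample_id=str(row.sample),
        genome=str(row.genome),
        position=int(row.pos),
        ref=str(row.ref).upper(),
        depth=int(row.depth),
        allele_counts=counts,
    )


class CountsTable:
    """Dense in-memory layout of a per-site count table for one genome.

    Base counts and depth are (n_samples, n_positions) arrays; indel
    alleles, which are sparse, live in a dict keyed by (sample index,
    position index).
    """

    def __init__(
        self,
        genome: str,
        samples: Sequence[str],
        positions: np.ndarray,
        ref: np.ndarray,
        depth: np.ndarray,
        base_counts: dict[str, np.ndarray],
        indel_counts: dict[tuple[int, int], dict[str, int]] | None = None,
    ) -> None:
        self.genome = genome
        self.samples = list(samples)
        self.positions = np.asarray(positions)
        self.ref = np.asarray(ref)
        self.depth = np.asarray(depth)
        self.base_counts = base_counts
        self.indel_counts = indel_counts or {}
        self._sample_index = {s: i for i, s in enumerate(self.samples)}
        self._pos_index = {int(p): i for i, p in enumerate(self.positions)}

    @classmethod
    def from_records(cls, records: Iterable[SiteCounts]) -> "CountsTable":
        records = list(records)
        if not records:
            raise DataError("empty count table")
        genome = records[0].genome
        samples = sorted({r.sample_id for r in records})
        positions = np.array(sorted({r.position for r in records}))
        si = {s: i for i, s in enumerate(samples)}
        pi = {int(p): i for i, p in enumerate(positions)}
        shape = (len(samples), len(positions))
        depth = np.zeros(shape, dtype=np.int64)
        base_counts = {b: np.zeros(shape, dtype=np.int64) for b in "ACGT"}
        ref = np.array(["N"] * len(positions))
        indel_counts: dict[tuple[int, int], dict[str, int]] = {}
        for r in records:
            i, j = si[r.sample_id], pi[r.position]
            depth[i, j] = r.depth
            ref[j] = r.ref
            for allele, c in r.allele_counts.items():
                if allele in "ACGT" and len(allele) == 1:
                    base_counts[allele][i, j] = c
                else:
                    indel_counts.setdefault((i, j), {})[allele] = c
        return cls(genome, samples, positions, ref, depth, base_counts, indel_counts)

    def to_records(self) -> Iterator[SiteCounts]:
        for i, sample in enumerate(self.samples):
            for j, pos in enumerate(self.positions):
                counts = {
                    b: int(self.base_counts[b][i, j])
                    for b in "ACGT"
                    if self.base_counts[b][i, j]
                }
                counts.update(self.indel_counts.get((i, j), {}))
                yield SiteCounts(
                    sample_id=sample,
                    genome=self.genome,
                    position=int(pos),
                    ref=str(self.ref[j]),
                    depth=int(self.depth[i, j]),
                    allele_counts=counts,
                )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.to_records():
            ins = ",".join(
                f"{a}:{c}" for a, c in sorted(r.allele_counts.items()) if a.startswith("+")
            )
            dele = ",".join(
                f"{a}:{c}" for a, c in sorted(r.allele_counts.items()) if a.startswith("-")
            )
            rows.append(
                {
                    "sample": r.sample_id,
                    "genome": r.genome,
                    "pos": r.position,
                    "ref": r.ref,
                    "depth": r.depth,
                    **{b: r.allele_counts.get(b, 0) for b in "ACGT"},
                    "INS": ins or ".",
                    "DEL": dele or ".",
                }
            )
        return pd.DataFrame(rows, columns=COUNT_COLUMNS)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "CountsTable":
        errors: list[str] = []
        table = cls.from_records(read_site_counts(path, error_sink=errors))
        for msg in errors:
            warnings.warn(msg, stacklevel=2)
        return table

    def site(self, sample_id: str, position: int) -> SiteCounts:
        i = self._sample_index[sample_id]
        j = self._pos_index[position]
        counts = {
            b: int(self.base_counts[b][i, j]) for b in "ACGT" if self.base_counts[b][i, j]
        }
        counts.update(self.indel_counts.get((i, j), {}))
        return SiteCounts(
            sample_id=sample_id,
            genome=self.genome,
            position=position,
            ref=str(self.ref[j]),
            depth=int(self.depth[i, j]),
            allele_counts=counts,
        )

    def allele_frequency(self, sample_id: str, position: int, allele: str) -> float:
        i = self._sample_index[sample_id]
        j = self._pos_index[position]
        d = int(self.depth[i, j])
        if d == 0:
            return 0.0
        if allele in "ACGT" and len(allele) == 1:
            return int(self.base_counts[allele][i, j]) / d
        return self.indel_counts.get((i, j), {}).get(allele, 0) / d


# ---------------------------------------------------------------------------
# Filter-chain operations


def call_candidates(
    counts: Iterable[SiteCounts],
    min_freq: float = 0.20,
    min_depth: int = 50,
    genome: GenomeSpec | None = None,
) -> list[VariantCall]:
    """One candidate call per (sample, position, non-reference allele).

    Thresholds are inclusive (frequency >= 20%, depth >= 50x); candidates
    failing them are returned with low_freq / low_depth flags rather than
    dropped.
    """
    if not 0 < min_freq <= 1:
        raise ConfigError("min_freq must be in (0, 1]")
    if min_depth < 1:
        raise ConfigError("min_depth must be >= 1")
    calls = []
    for site in counts:
        for allele, count in site.allele_counts.items():
            if allele == site.ref or count == 0:
                continue
            freq = count / site.depth if site.depth else 0.0
            call = _make_call(site, allele, count, freq, genome)
            if freq < min_freq:
                call.filter_flags.add("low_freq")
            if site.depth < min_depth:
                call.filter_flags.add("low_depth")
            calls.append(call)
    return calls


def _make_call(
    site: SiteCounts, allele: str, count: int, freq: float, genome: GenomeSpec | None
) -> VariantCall:
    if allele.startswith("+"):
        var_type, ref, alt = "insertion", "-", allele[1:]
    elif allele.startswith("-"):
        n = int(allele[1:])
        if genome is not None:
            deleted = "".join(genome.base(site.position + 1 + k) for k in range(n))
        else:
            deleted = "N" * n
        var_type, ref, alt = "deletion", deleted, "-"
    else:
        var_type, ref, alt = "SNV", site.ref, allele
    return VariantCall(
        line_id=site.sample_id,
        genome=site.genome,
        position=site.position,
        ref=ref,
        alt=alt,
        var_type=var_type,
        raw_frequency=freq,
        depth=site.depth,
        alt_count=count,
    )


def background_filter(
    call: VariantCall, wt_site_frequencies: Sequence[float], fold: float = 3.0
) -> VariantCall:
    """Flag calls without a ``fold``-fold excess over the WT background.

    ``wt_site_frequencies`` holds the same allele's frequency in every
    WT line (0 where absent).  A call passes when its raw frequency is
    at least ``fold`` times the WT mean; a WT mean of zero always passes.
    """
    if len(wt_site_frequencies) == 0:
        raise DataError("background filter undefined without WT lines")
    wt_mean = float(np.mean(wt_site_frequencies))
    # boundary is inclusive: exactly fold-times the mean passes
    if wt_mean > 0 and call.raw_frequency < fold * wt_mean * (1 - 1e-9):
        call.filter_flags.add("background")
    return call


def apply_masks(calls: Iterable[VariantCall], genome: GenomeSpec) -> list[VariantCall]:
    """Flag calls inside excluded repeat copies or artefact zones."""
    out = []
    for call in calls:
        if genome.in_repeat_mask(call.position):
            call.filter_flags.add("repeat_copy")
        if genome.in_artefact_mask(call.position):
            call.filter_flags.add("artefact")
        out.append(call)
    return out


def flank_homology_check(
    call: VariantCall,
    genomes: Sequence[GenomeSpec],
    flank_k: int = 30,
) -> bool:
    """True when the variant-bearing k-mer occurs elsewhere in the genome set.

    The k-mer is the variant allele with ``flank_k`` reference bases on
    each side.  An exact occurrence anywhere in the genomes (either
    strand; circular sequences searched across the origin) means the
    apparent variant is explainable as a relocated pre-existing sequence
    (a rearrangement or numt artefact) rather than a new mutation.
    """
    if flank_k < 10:
        raise ConfigError("flank_k must be >= 10")
    if call.var_type in ("SNV", "MNV") and call.alt == call.ref:
        raise DataError("alt allele equals ref: not a variant")
    home = next((g for g in genomes if g.name == call.genome), None)
    if home is None:
        raise DataError(f"genome {call.genome} not in genome set")
    kmer = _variant_kmer(call, home, flank_k)
    for g in genomes:
        hay = g.sequence + (g.sequence[: len(kmer) - 1] if g.circular else "")
        if kmer in hay or kmer in revcomp(hay):
            return True
    return False


def _variant_kmer(call: VariantCall, genome: GenomeSpec, flank_k: int) -> str:
    n = len(genome)
    pos = call.position

    def fetch(lo: int, hi: int) -> str:  # 1-based inclusive, may wrap
        if genome.circular:
            return "".join(genome.base(p) for p in range(lo, hi + 1))
        lo2, hi2 = max(lo, 1), min(hi, n)
        if (lo2, hi2) != (lo, hi):
            warnings.warn(
                f"variant at {pos} near end of linear genome {genome.name}: "
                "flank truncated",
                stacklevel=3,
            )
        return genome.sequence[lo2 - 1 : hi2]

    if call.var_type in ("SNV", "MNV"):
        left = fetch(pos - flank_k, pos - 1)
        right = fetch(pos + len(call.ref), pos + len(call.ref) + flank_k - 1)
        return left + call.alt + right
    if call.var_type == "insertion":
        left = fetch(pos - flank_k, pos)
        right = fetch(pos + 1, pos + flank_k)
        return left + call.alt + right
    # deletion of len(call.ref) bases starting at pos + 1
    left = fetch(pos - flank_k, pos)
    right = fetch(pos + 1 + len(call.ref), pos + len(call.ref) + flank_k)
    return left + right


def estimate_nuclear_coverage(
    total_reads: int,
    organelle_mapped_reads: int,
    read_length_bp: float,
    nuclear_genome_size_bp: int,
    sample_id: str = "",
) -> NuclearCoverageEstimate:
    """Mean nuclear depth from the share of reads not mapping to organelles."""
    if nuclear_genome_size_bp <= 0 or read_length_bp <= 0:
        raise ConfigError("read length and nuclear genome size must be > 0")
    if organelle_mapped_reads > total_reads:
        raise DataError("organelle-mapped reads exceed total reads")
    depth = (total_reads - organelle_mapped_reads) * read_length_bp / nuclear_genome_size_bp
    return NuclearCoverageEstimate(sample_id=sample_id, mean_depth=depth)


def numt_correct_frequency(
    call: VariantCall,
    nuclear_cov: NuclearCoverageEstimate | float,
    numt_copies_at_site: int,
) -> VariantCall:
    """Recompute the allele frequency after removing expected numt reads.

    Numt-derived reads match the reference allele, so the expected
    nuclear read count (nuclear coverage x numt copy number) is
    subtracted from both the reference count and the site depth before
    the frequency is recalculated.  The corrected reference count is
    floored at zero, which caps the corrected frequency at 1.
    """
    if numt_copies_at_site < 0:
        raise ConfigError("numt copy number must be >= 0")
    cov = nuclear_cov.mean_depth if isinstance(nuclear_cov, NuclearCoverageEstimate) else float(nuclear_cov)
    expected_nuclear = cov * numt_copies_at_site
    denom = max(call.depth - expected_nuclear, call.alt_count)
    call.corrected_frequency = call.alt_count / denom if denom > 0 else 0.0
    return call


def classify_homoplasmy(call: VariantCall, genome_kind: str) -> str:
    """Classify a call as homoplasmic or heteroplasmic.

    Plastid SNVs at frequency >= 98% are treated as fixed; for the
    mitochondrial genome only numt-corrected frequencies strictly above
    90% qualify (the correction is approximate, so the bar is a strict
    inequality).  Indels are never classified.
    """
    if genome_kind not in ("mito", "plastid"):
        raise ConfigError(f"unknown genome kind {genome_kind!r}")
    if call.var_type in ("insertion", "deletion"):
        state = "unclassified"
    elif genome_kind == "plastid":
        state = "homoplasmic" if call.corrected_frequency >= 0.98 else "heteroplasmic"
    else:
        state = "homoplasmic" if call.corrected_frequency > 0.90 else "heteroplasmic"
    call.homoplasmy_state = state
    return state


def merge_mnv(
    calls: Sequence[VariantCall], max_freq_delta: float = 0.1
) -> list[VariantCall]:
    """Merge runs of adjacent same-line SNVs into multinucleotide variants.

    Passing SNVs at consecutive positions in the same line whose raw
    frequencies differ by at most ``max_freq_delta`` are taken to be a
    single mutational event and merged into one MNV (counted as one
    variant).  Flagged calls and non-SNVs pass through untouched.
    """
    by_line: dict[tuple[str, str], list[VariantCall]] = {}
    out: list[VariantCall] = []
    for c in calls:
        if c.var_type == "SNV" and c.passes:
            by_line.setdefault((c.line_id, c.genome), []).append(c)
        else:
            out.append(c)
    for group in by_line.values():
        group.sort(key=lambda c: c.position)
        chain = [group[0]]
        for c in group[1:]:
            if (
                c.position == chain[-1].position + 1
                and abs(c.raw_frequency - chain[-1].raw_frequency) <= max_freq_delta
            ):
                chain.append(c)
            else:
                out.append(_collapse_chain(chain))
                chain = [c]
        out.append(_collapse_chain(chain))
    out.sort(key=lambda c: (c.genome, c.line_id, c.position))
    return out


def _collapse_chain(chain: list[VariantCall]) -> VariantCall:
    if len(chain) == 1:
        return chain[0]
    first = chain[0]
    return VariantCall(
        line_id=first.line_id,
        genome=first.genome,
        position=first.position,
        ref="".join(c.ref for c in chain),
        alt="".join(c.alt for c in chain),
        var_type="MNV",
        raw_frequency=float(np.mean([c.raw_frequency for c in chain])),
        depth=int(np.mean([c.depth for c in chain])),
        corrected_frequency=float(np.mean([c.corrected_frequency for c in chain])),
        alt_count=int(np.mean([c.alt_count for c in chain])),
        homoplasmy_state=first.homoplasmy_state,
    )


# ---------------------------------------------------------------------------
# End-to-end pipeline


def call_variants(
    table: CountsTable,
    genome: GenomeSpec,
    lines: Sequence[LineMeta],
    genome_kind: str,
    min_freq: float = 0.20,
    min_depth: int = 50,
    background_fold: float = 3.0,
    nuclear_coverage: Mapping[str, float] | float | None = None,
    flank_k: int = 30,
    run_flank_check: bool = True,
    merge_mnvs: bool = True,
    genome_set: Sequence[GenomeSpec] | None = None,
) -> list[VariantCall]:
    """Run the full filter chain on one genome's count table.

    Returns every threshold-passing candidate with accumulated filter
    flags; reported variants are those with ``call.passes``.  The numt
    correction uses ``nuclear_coverage`` (a per-sample mapping or a
    single mean depth) with the genome's numt track and applies to
    mitochondrial genomes only.
    """
    meta = {m.line_id: m for m in lines}
    wt_samples = [s for s in table.samples if s in meta and meta[s].genotype == "WT"]
    if not wt_samples:
        raise DataError("background filter undefined without WT lines")
    wt_idx = np.array([table.samples.index(s) for s in wt_samples])

    candidates = _threshold_candidates(table, genome, min_freq, min_depth)

    # background filter against WT mean frequencies, per position per allele
    depth_wt = table.depth[wt_idx].astype(float)
    safe_depth = np.where(depth_wt > 0, depth_wt, 1.0)
    wt_freq = {
        b: np.where(depth_wt > 0, table.base_counts[b][wt_idx] / safe_depth, 0.0)
        for b in "ACGT"
    }
    for call in candidates:
        j = table._pos_index[call.position]
        allele = _allele_token(call)
        if allele in "ACGT" and len(allele) == 1:
            freqs = wt_freq[allele][:, j]
        else:
            freqs = np.array(
                [
                    table.indel_counts.get((int(i), j), {}).get(allele, 0)
                    / max(int(table.depth[int(i), j]), 1)
                    for i in wt_idx
                ]
            )
        background_filter(call, freqs, fold=background_fold)

    candidates = apply_masks(candidates, genome)

    if run_flank_check:
        gset = list(genome_set) if genome_set is not None else [genome]
        for call in candidates:
            if call.passes and flank_homology_check(call, gset, flank_k=flank_k):
                call.filter_flags.add("numt")

    if genome_kind == "mito" and genome.numt_track and nuclear_coverage is not None:
        for call in candidates:
            copies = genome.numt_copies_at(call.position)
            if copies:
                cov = (
                    nuclear_coverage.get(call.line_id, 0.0)
                    if isinstance(nuclear_coverage, Mapping)
                    else float(nuclear_coverage)
                )
                numt_correct_frequency(call, cov, copies)

    for call in candidates:
        classify_homoplasmy(call, genome_kind)

    if merge_mnvs:
        candidates = merge_mnv(candidates)
    return candidates


def _allele_token(call: VariantCall) -> str:
    if call.var_type == "insertion":
        return "+" + call.alt
    if call.var_type == "deletion":
        return f"-{len(call.ref)}"
    return call.alt


def _threshold_candidates(
    table: CountsTable, genome: GenomeSpec, min_freq: float, min_depth: int
) -> list[VariantCall]:
    """Vectorised candidate screen: only threshold-passing sites become calls."""
    if not 0 < min_freq <= 1:
        raise ConfigError("min_freq must be in (0, 1]")
    if min_depth < 1:
        raise ConfigError("min_depth must be >= 1")
    calls: list[VariantCall] = []
    depth = table.depth
    ok_depth = depth >= min_depth
    safe_depth = np.where(depth > 0, depth, 1)
    for b in "ACGT":
        counts = table.base_counts[b]
        nonref = table.ref != b
        hits = np.argwhere(ok_depth & nonref[None, :] & (counts >= min_freq * safe_depth) & (counts > 0))
        for i, j in hits:
            site_pos = int(table.positions[j])
            calls.append(
                VariantCall(
                    line_id=table.samples[i],
                    genome=table.genome,
                    position=site_pos,
                    ref=str(table.ref[j]),
                    alt=b,
                    var_type="SNV",
                    raw_frequency=int(counts[i, j]) / int(depth[i, j]),
                    depth=int(depth[i, j]),
                    alt_count=int(counts[i, j]),
                )
            )
    for (i, j), alleles in table.indel_counts.items():
        d = int(depth[i, j])
        if d < min_depth:
            continue
        for allele, count in alleles.items():
            if count / d >= min_freq:
                site = SiteCounts(
                    sample_id=table.samples[i],
                    genome=table.genome,
                    position=int(table.positions[j]),
                    ref=str(table.ref[j]),
                    depth=d,
                    allele_counts={allele: count},
                )
                calls.append(_make_call(site, allele, count, count / d, genome))
    calls.sort(key=lambda c: (c.line_id, c.position))
    return calls
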