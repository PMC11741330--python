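"""Strand-collapsed single-nucleotide mutation spectra.

Each substitution is pooled with its reverse complement into one of six
classes (AT>GC, GC>AT, AT>CG, GC>TA, AT>TA, GC>CG).  Class rates are
normalized by the number of A/T or G/C base pairs available to mutate
in the unmasked genome, and by the total number of generations, so that
genomes of different composition are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import ConfigError, DataError
from .genomes import GenomeSpec
from .variants import LineMeta, VariantCall

SPECTRUM_CLASSES = ("AT>GC", "GC>AT", "AT>CG", "GC>TA", "AT>TA", "GC>CG")
TRANSITIONS = ("AT>GC", "GC>AT")

# strand-collapsed class for each (ref, alt) pair
_CLASS_OF = {
    ("A", "G"): "AT>GC", ("T", "C"): "AT>GC",
    ("G", "A"): "GC>AT", ("C", "T"): "GC>AT",
    ("A", "C"): "AT>CG", ("T", "G"): "AT>CG",
    ("G", "T"): "GC>TA", ("C", "A"): "GC>TA",
    ("A", "T"): "AT>TA", ("T", "A"): "AT>TA",
    ("G", "C"): "GC>CG", ("C", "G"): "GC>CG",
}


def classify_snv_class(ref: str, alt: str) -> str:
    """Strand-collapsed spectrum class of a substitution."""
    if ref not in "ACGT" or alt not in "ACGT" or len(ref) != 1 or len(alt) != 1:
        raise DataError(f"non-nucleotide substitution {ref!r}->{alt!r}")
    if ref == alt:
        raise DataError("ref and alt are identical: not a substitution")
    return _CLASS_OF[(ref, alt)]


def is_transition(spectrum_class: str) -> bool:
    return spectrum_class in TRANSITIONS


def source_pair(spectrum_class: str) -> str:
    """The base pair a class mutates away from ("AT" or "GC")."""
    if spectrum_class not in SPECTRUM_CLASSES:
        raise ConfigError(f"unknown spectrum class {spectrum_class!r}")
    return spectrum_class[:2]


def class_alt_for_ref(spectrum_class: str, ref: str) -> str:
    """Alt base a class produces at a given reference base.

    E.g. AT>GC yields G at an A and C at a T (the strand-collapsed pair).
    """
    for (r, a), cls in _CLASS_OF.items():
        if cls == spectrum_class and r == ref:
            return a
    raise DataError(f"reference base {ref!r} not eligible for class {spectrum_class}")


@dataclass
class SpectrumTable:
    """Per-class counts, frequency-weighted counts, and normalized rates."""

    table: pd.DataFrame  # index: class; columns: count, weighted, rate
    transition_fraction: float

    @property
    def total(self) -> int:
        return int(self.table["count"].sum())


def spectrum_table(
    snvs: Sequence[VariantCall],
    genome: GenomeSpec,
    lines: Iterable[LineMeta] | int,
    weight_by_frequency: bool = True,
) -> SpectrumTable:
    """Tabulate the strand-collapsed spectrum of a set of SNV calls.

    The per-class rate is weighted count / (source-pair bp x N), with
    the base composition taken over the unmasked genome so the masked
    repeat copies neither contribute sites nor variants.
    """
    from .rates import total_generations

    N = lines if isinstance(lines, int) else total_generations(lines)
    if N <= 0:
        raise ConfigError("total generations N must be > 0")
    comp = genome.base_composition(exclude_masked=True)
    counts = {c: 0 for c in SPECTRUM_CLASSES}
    weighted = {c: 0.0 for c in SPECTRUM_CLASSES}
    for v in snvs:
        if v.var_type != "SNV":
            continue
        cls = classify_snv_class(v.ref, v.alt)
        counts[cls] += 1
        weighted[cls] += v.corrected_frequency if weight_by_frequency else 1.0
    rows = []
    for cls in SPECTRUM_CLASSES:
        bp = comp[source_pair(cls)]
        rate = weighted[cls] / (bp * N) if bp else float("nan")
        rows.append({"class": cls, "count": counts[cls], "weighted": weighted[cls], "rate": rate})
    table = pd.DataFrame(rows).set_index("class")
    total = table["count"].sum()
    ts = table.loc[list(TRANSITIONS), "count"].sum() / total if total else float("nan")
    return SpectrumTable(table=table, transition_fraction=float(ts))
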