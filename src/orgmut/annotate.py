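"""Functional annotation of variants and the synonymous permutation test.

A variant is assigned one location class (CDS > rRNA > tRNA > intron >
intergenic on overlap); CDS SNVs are additionally classified as
synonymous or nonsynonymous by translating the reference and mutated
codon with the standard genetic code (plant organelles use it).

The permutation test asks whether the observed number of synonymous
changes among CDS SNVs shows a signature of selection: holding the
number and spectrum class of the observed SNVs fixed, their positions
are randomized uniformly over protein-coding sites whose reference base
matches each variant's source pair, and the one-tailed P-value is the
fraction of permutations with at least the observed synonymous count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio.Seq import Seq

from .errors import ConfigError, DataError
from .genomes import GeneFeature, GenomeSpec, cds_index
from .spectrum import class_alt_for_ref, classify_snv_class, source_pair
from .variants import VariantCall, revcomp

LOCATION_PRIORITY = ("CDS", "rRNA", "tRNA", "intron", "intergenic")


@dataclass(frozen=True)
class FunctionalAnnotation:
    variant: VariantCall
    location_class: str
    coding_effect: str  # synonymous | nonsynonymous | n/a


def containing_feature(genome: GenomeSpec, position: int) -> GeneFeature | None:
    """Highest-priority annotated feature containing a position."""
    best: GeneFeature | None = None
    best_rank = len(LOCATION_PRIORITY)
    for feat in genome.annotation:
        if feat.contains(position):
            rank = LOCATION_PRIORITY.index(feat.kind)
            if rank < best_rank:
                best, best_rank = feat, rank
    return best


def cds_sequence(genome: GenomeSpec, feature: GeneFeature) -> str:
    if feature.kind != "CDS":
        raise ConfigError("cds_sequence requires a CDS feature")
    joined = "".join(
        genome.sequence[iv.start - 1 : iv.end]
        for iv in sorted(feature.intervals, key=lambda iv: iv.start)
    )
    return revcomp(joined) if feature.strand == "-" else joined


def is_synonymous(
    genome: GenomeSpec, feature: GeneFeature, position: int, alt: str
) -> bool:
    """Whether substituting ``alt`` at ``position`` leaves the protein unchanged."""
    cds = cds_sequence(genome, feature)
    idx = cds_index(feature, position)
    alt_coding = revcomp(alt) if feature.strand == "-" else alt
    codon_start = idx - ((idx + feature.frame) % 3)
    if codon_start < 0 or codon_start + 3 > len(cds):
        raise DataError(
            f"position {position} falls in a partial codon of {feature.gene_id}"
        )
    ref_codon = cds[codon_start : codon_start + 3]
    alt_codon = (
        ref_codon[: idx - codon_start] + alt_coding + ref_codon[idx - codon_start + 1 :]
    )
    return str(Seq(ref_codon).translate()) == str(Seq(alt_codon).translate())


def annotate_variant(variant: VariantCall, genome: GenomeSpec) -> FunctionalAnnotation:
    """Location class and, for CDS SNVs, the coding effect of a variant."""
    feat = containing_feature(genome, variant.position)
    location = feat.kind if feat is not None else "intergenic"
    effect = "n/a"
    if location == "CDS" and variant.var_type == "SNV":
        effect = (
            "synonymous"
            if is_synonymous(genome, feat, variant.position, variant.alt)
            else "nonsynonymous"
        )
    return FunctionalAnnotation(variant=variant, location_class=location, coding_effect=effect)


def location_counts(annotations: Sequence[FunctionalAnnotation]) -> dict[str, int]:
    """SNV counts per location class (a Table-1-style summary)."""
    out = {k: 0 for k in LOCATION_PRIORITY}
    for a in annotations:
        out[a.location_class] += 1
    return out


# ---------------------------------------------------------------------------
# Synonymous-count permutation test


@dataclass
class PermutationResult:
    n_perms: int
    observed_synonymous: int
    p_value: float
    null_counts: np.ndarray

    def summary(self) -> dict:
        q = np.percentile(self.null_counts, [2.5, 50, 97.5])
        return {
            "n_perms": self.n_perms,
            "observed_synonymous": self.observed_synonymous,
            "p_value": self.p_value,
            "null_mean": float(self.null_counts.mean()),
            "null_q025": float(q[0]),
            "null_median": float(q[1]),
            "null_q975": float(q[2]),
        }


def cds_site_inventory(
    genome: GenomeSpec, spectrum_class: str, exclude_masked: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Eligible CDS positions for a class and their synonymous outcomes.

    A position is eligible when its reference base belongs to the
    class's source pair; the outcome is whether applying the class's
    substitution there is synonymous in the containing CDS.
    """
    pair = source_pair(spectrum_class)
    positions: list[int] = []
    synonymous: list[bool] = []
    seen: set[int] = set()
    for feat in genome.annotation:
        if feat.kind != "CDS":
            continue
        for iv in feat.intervals:
            for pos in range(iv.start, iv.end + 1):
                if pos in seen:
                    continue
                seen.add(pos)
                if exclude_masked and genome.in_repeat_mask(pos):
                    continue
                ref = genome.sequence[pos - 1]
                if ref not in pair:
                    continue
                target = containing_feature(genome, pos)
                if target is None or target.kind != "CDS":
                    continue
                alt = class_alt_for_ref(spectrum_class, ref)
                positions.append(pos)
                synonymous.append(is_synonymous(genome, target, pos, alt))
    if not positions:
        raise DataError(
            f"no eligible CDS positions for class {spectrum_class} "
            f"in genome {genome.name}"
        )
    return np.array(positions), np.array(synonymous, dtype=bool)


def permutation_test_synonymous(
    observed_cds_snvs: Sequence[VariantCall],
    genomes: Sequence[GenomeSpec],
    n_perms: int = 10000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> PermutationResult:
    """One-tailed permutation test for an excess of synonymous SNVs.

    Each observed CDS SNV keeps its spectrum class and genome but is
    re-placed uniformly (with replacement across variants) on eligible
    coding sites.  P = (# permutations with synonymous count >= observed)
    / n_perms, a plain proportion with no +1 smoothing.
    """
    if n_perms < 1:
        raise ConfigError("n_perms must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    by_name = {g.name: g for g in genomes}

    observed = 0
    per_variant_outcomes: list[np.ndarray] = []
    inventory_cache: dict[tuple[str, str], np.ndarray] = {}
    for v in observed_cds_snvs:
        if v.genome not in by_name:
            raise DataError(f"genome {v.genome} not in genome set")
        g = by_name[v.genome]
        cls = classify_snv_class(v.ref, v.alt)
        feat = containing_feature(g, v.position)
        if feat is None or feat.kind != "CDS":
            raise DataError(f"observed SNV at {v.position} is not in CDS")
        if is_synonymous(g, feat, v.position, v.alt):
            observed += 1
        key = (v.genome, cls)
        if key not in inventory_cache:
            _, syn = cds_site_inventory(g, cls)
            inventory_cache[key] = syn
        per_variant_outcomes.append(inventory_cache[key])

    null_counts = np.zeros(n_perms, dtype=np.int64)
    for syn in per_variant_outcomes:
        draws = rng.integers(0, len(syn), size=n_perms)
        null_counts += syn[draws]
    p = float(np.mean(null_counts >= observed)) if observed_cds_snvs else 1.0
    if not observed_cds_snvs:
        null_counts = np.zeros(n_perms, dtype=np.int64)
        p = 1.0
    return PermutationResult(
        n_perms=n_perms,
        observed_synonymous=observed,
        p_value=p,
        null_counts=null_counts,
    )
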