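"""Germline mutation-rate estimation for mutation-accumulation lines.

The point estimate is mu = V / (G * N), where V is the number of
identified variants (frequency-weighted for SNVs, unweighted for
indels), G is the effective genome size in bp (large repeat copies
excluded), and N is the total number of homozygous generations summed
across the MA lines.

When no variants are observed, the lowest rate that would still have
given a 95% probability of detecting at least one mutation under a
Poisson model is mu_upper = ln(1/alpha) / (G * N) with alpha = 0.05:
the probability of seeing zero events with expectation lambda = mu*G*N
is exp(-lambda), and setting it to alpha and solving gives the bound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import ConfigError
from .variants import LineMeta, VariantCall

# Study constants, overridable everywhere they are used: 150 homozygous
# msh1 generations (18 F8 lines x 7 + 4 F7 lines x 6, F1 excluded) and
# 2,835 WT generations (107 lines x 25 + 20 lines x 8) for the bounds.
MSH1_TOTAL_GENERATIONS = 150
WT_TOTAL_GENERATIONS = 2835
MITO_EFFECTIVE_BP = 357025
PLASTID_EFFECTIVE_BP = 128214


@dataclass(frozen=True)
class RateEstimate:
    genome: str
    variant_class: str  # SNV | indel
    V: float
    G: int
    N: int
    mu: float


@dataclass(frozen=True)
class UpperBound:
    genome: str
    G: int
    N: int
    alpha: float
    mu_upper: float


def total_generations(lines: Iterable[LineMeta], genotype: str | None = None) -> int:
    return sum(
        m.generations for m in lines if genotype is None or m.genotype == genotype
    )


def mutation_rate(
    variants: Sequence[VariantCall | float],
    lines: Iterable[LineMeta] | int,
    G: int,
    weight_by_frequency: bool = True,
    genome: str = "",
    variant_class: str = "SNV",
) -> RateEstimate:
    """mu = V / (G * N) from passing variant calls.

    With frequency weighting each variant contributes its (numt-)
    corrected frequency to V; otherwise each contributes 1.  ``variants``
    may also be a plain sequence of frequencies, and ``lines`` either
    line metadata (N = sum of generations) or N itself.
    """
    N = lines if isinstance(lines, int) else total_generations(lines)
    if N <= 0:
        raise ConfigError("total generations N must be > 0")
    if G <= 0:
        raise ConfigError("effective genome size G must be > 0")
    if weight_by_frequency:
        V = float(
            sum(
                v.corrected_frequency if isinstance(v, VariantCall) else float(v)
                for v in variants
            )
        )
    else:
        V = float(len(variants))
    return RateEstimate(
        genome=genome, variant_class=variant_class, V=V, G=G, N=N, mu=V / (G * N)
    )


def poisson_upper_bound(G: int, N: int, alpha: float = 0.05, genome: str = "") -> UpperBound:
    """Lowest mu giving probability >= 1-alpha of seeing at least one variant."""
    if not 0 < alpha < 1:
        raise ConfigError("alpha must be in (0, 1)")
    if G <= 0 or N <= 0:
        raise ConfigError("G and N must be > 0")
    return UpperBound(genome=genome, G=G, N=N, alpha=alpha, mu_upper=math.log(1 / alpha) / (G * N))


def single_variant_rate(G: int, N: int) -> float:
    """Rate implied by a single observed (homoplasmic) variant: 1 / (G*N)."""
    if G <= 0 or N <= 0:
        raise ConfigError("G and N must be > 0")
    return 1.0 / (G * N)


def fold_ratio(rate_a: float, rate_b: float | UpperBound) -> float:
    """rate_a / rate_b, e.g. a mutant rate over the WT upper bound."""
    b = rate_b.mu_upper if isinstance(rate_b, UpperBound) else float(rate_b)
    if b == 0:
        raise ConfigError("zero denominator in fold ratio")
    return float(rate_a) / b


def genic_fraction(location_counts: Mapping[str, int]) -> float:
    """Fraction of SNVs in gene sequence (CDS + rRNA + tRNA) among all SNVs.

    ``location_counts`` maps location classes (CDS, rRNA, tRNA, intron,
    intergenic) to SNV counts, as tabulated by the annotation step.
    """
    total = sum(location_counts.values())
    if total == 0:
        raise ConfigError("no variants in location counts")
    genic = sum(location_counts.get(k, 0) for k in ("CDS", "rRNA", "tRNA"))
    return genic / total


def round_sig(x: float, sig: int = 1) -> float:
    """Round to ``sig`` significant figures (for report formatting)."""
    if x == 0:
        return 0.0
    d = math.ceil(math.log10(abs(x)))
    return round(x, sig - d)
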