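# Methods

This note documents the models and procedures the package implements,
the parameter choices that matter, what the synthetic-data generator
does and does not emulate, and the numerical conventions used at edge
cases.

## Coordinate and data conventions

All positions at file and API boundaries are 1-based and inclusive; BED
files keep their on-disk 0-based half-open convention and are converted
on read. Organelle genomes are circular by default: position arithmetic
wraps modulo the length, and homopolymer runs spanning the origin are
reported once, with a start in [1, L] and an end that may exceed L.

Per-site count tables carry one row per (sample, position) with depth
and counts for A/C/G/T plus sparse insertion (`+SEQ`) and deletion
(`-N`) alleles. Depth need not equal the sum of counts (clipped or
ambiguous reads), but no single allele count may exceed depth; rows
violating that, or with unrecognised allele tokens, are rejected with
their line number.

## Variant filter chain

Candidates are every non-reference allele at a site, with raw frequency
defined as allele count / total site depth (a pileup counter's column
semantics, not count / sum-of-allele-counts). Filters accumulate flags
rather than deleting records, which makes the passing set independent
of filter order:

1. **Detection thresholds** — frequency ≥ 20 % and depth ≥ 50×, both
   inclusive. The high frequency cutoff suppresses both sequencing
   error and low-frequency somatic variants that are not germline.
2. **Wild-type background** — a call must have at least 3× the mean
   frequency of the same allele across all WT lines (absent alleles
   contribute 0; a zero WT mean always passes; the boundary is
   inclusive with a 1e-9 relative tolerance). Because focal lines are
   mutant and the panel is WT, no leave-one-out is needed. This is the
   filter that absorbs shared homopolymer noise.
3. **Repeat-copy masks** — calls in the excluded copy of each large
   repeat are flagged, so each variant is counted once; the same masks
   are subtracted from the genome size G.
4. **Artefact masks and flank homology** — besides user-supplied
   artefact intervals, a call is flagged when the variant-bearing k-mer
   (flank_k = 30 reference bases each side, alternate allele
   substituted; insertions and deletions spliced accordingly) occurs
   exactly anywhere else in the genome set, on either strand, across
   the origin of circular sequences. Such a "variant" is explainable as
   a relocated pre-existing sequence (rearrangement or numt) rather
   than a new mutation. An exact-match screen is deterministic and
   sufficient at the scale of organelle genomes; near-matches are the
   user's responsibility via artefact masks. Variants too close to the
   end of a linear sequence are checked with a truncated flank and a
   warning.

**Numt correction** (mitochondrial genomes): with mean nuclear coverage
d (estimated as (total − organelle-mapped reads) × read length /
nuclear genome size) and c numt copies of the region, expected nuclear
reads = c·d are subtracted from the reference count and the depth, and
the frequency is recomputed as alt / max(depth − c·d, alt). The
corrected reference count is floored at 0, equivalently the corrected
frequency is capped at 1 — the correction is approximate and no
negative-count rule is meaningful. The correction is monotone
non-decreasing in both c and d and is the identity at c = 0. Detection
thresholds are applied to the *raw* frequency; the corrected frequency
is used for weighting and homoplasmy classification only.

**Homoplasmy**: plastid SNVs are called homoplasmic at frequency
≥ 98 %; mitochondrial SNVs require a corrected frequency strictly
above 90 % (the strict inequality reflects the approximate
correction). Indels are left unclassified — their frequencies at
homopolymers are unreliable.

**MNV merging**: passing SNVs at consecutive positions in the same
line with raw frequencies within 0.1 of each other are merged into one
multinucleotide variant and counted once. The tolerance is this
package's choice; adjacency plus similar frequency is the natural
signature of a single mutational event.

## Rates, bounds, spectra

μ = V/(G·N). V sums the corrected frequencies of passing SNVs
(frequency weighting treats a heteroplasmic variant as a fractional
mutation) and counts indels unweighted. MNVs are excluded from the SNV
rate by default (they are reported separately). G is the effective
genome size (masked repeat length subtracted); N sums homozygous
generations over the analysed lines — 150 for the mutant panel
(18 lines × 7 + 4 × 6, the heterozygous F1 excluded) and 2,835 for the
pooled wild-type panel (107 × 25 + 20 × 8), both overridable.

The zero-observation bound solves e^(−μGN) = α for μ:
μ_upper = ln(1/α)/(G·N), α = 0.05 by default. It exceeds the
single-variant rate 1/(G·N) by exactly ln 20 ≈ 3.0.

Spectra collapse each substitution with its reverse complement into six
classes. Per-class rates divide the frequency-weighted count by the
AT or GC base-pair count of the *unmasked* portion of the genome
(masked copies contribute neither sites nor variants) and by N; the
caption-level quantity is a rate, so the division by N is included.

## Annotation and the permutation test

Location classes are assigned by interval containment with priority
CDS > rRNA > tRNA > intron > intergenic on overlap. CDS SNVs are
classified synonymous/nonsynonymous by translating the reference and
mutated codon with the standard genetic code (which plant organelles
use); multi-interval and minus-strand CDS are joined in strand order
with the annotated phase.

The permutation test holds the number and spectrum class of the
observed CDS SNVs fixed and redraws each variant's position uniformly —
with replacement across variants, collisions being negligible at genome
scale — over CDS sites whose reference base matches the class's source
pair (an AT→GC variant lands on an A or T and becomes G or C
respectively). The one-tailed P-value is the plain proportion of
permutations with at least the observed synonymous count (no +1
smoothing, matching the frequency definition of the test). A class with
no eligible site is an error. A single integer seed drives the draw.

## Homopolymer and indel analysis

Homopolymer records are maximal single-base runs of ≥ 5 bp;
dinucleotide arrays are maximal tandem 2-mer repeats of ≥ 3 units
(6 bp — two units are indistinguishable from chance; the threshold is a
config knob) reported in leftmost phase. Runs fully inside masked
repeat copies are excluded from the census, mirroring variant
counting.

Indels are left-aligned (shifting left while the preceding base equals
the last base of the indel, rotating the sequence) so that repeat-locus
indels anchor at the position just before the run. An indel is assigned
to the unique repeat locus containing its anchor whose unit the
inserted/deleted sequence repeats (any phase for dinucleotides);
indels longer than the run but still unit-repetitions count as
expansions of it; anything else is non-repetitive. Insertion/deletion
bias and length histograms are tabulated per repeat class and genome,
and loci hit in ≥ 2 lines are reported with per-line signed lengths,
whether the lengths differ (evidence of independent hits) and whether
all lines share a founder family.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
not reads or mapping:

- **Genomes** — random sequence at a target GC (0.45 "mito" / 0.35
  "plastid"), with planted homopolymers at recorded coordinates (the
  only runs ≥ 5 bp outside the repeat pair: chance runs in the
  background are broken, so the planted list is an exact truth
  catalogue; rare boundary artefacts trigger a deterministic
  regeneration), planted dinucleotide arrays, one large repeat pair
  duplicated verbatim with the second copy masked, a numt interval with
  copy number (mito only), and a toy gene set (CDS with and without an
  intron, a minus-strand CDS, rRNA, tRNA) for annotation tests.
  Genome lengths default to desk scale (50 kb / 30 kb) while all
  per-bp parameters stay at study scale.
- **Lines** — single-seed descent; per generation and genome, new SNVs
  arrive as Poisson(μ·G_eff), placed uniformly on class-consistent
  unmasked sites with the configured spectrum (defaults: 47 % / 83 %
  AT→GC for mito/plastid, matching the observed spectra). Homopolymer
  indels arrive per locus at rate m₀·(L−4) (m₀ = 2×10⁻⁴ per
  generation), increasing with run length L, with a deletion bias at
  A/T runs (p_ins = 0.35) and an insertion bias at G/C runs (0.60);
  dinucleotide arrays mutate at a constant 2×10⁻⁵. One indel per locus
  per line is allowed (multiple hits arise across lines). Wild-type
  rates are zero, as observed.
- **Heteroplasmy** — new variants start at frequency 0.5 and drift each
  generation by f′ ~ Beta(c·f, c·(1−f)) with organelle-specific
  concentration (mito 40, plastid 8 — the plastid sorts faster),
  absorbing at 0/1 beyond 0.02/0.98. This is a phenomenological model
  of germline bottleneck sorting, not a mechanistic one; frequencies
  and losses are qualitative. Setting the initial frequency to 1.0
  gives homoplasmic transmission, the calibration configuration.
- **Counts** — depth ~ Poisson(mean organelle depth, 300×/600×);
  substitution errors at e/3 = 0.067 % per non-reference base;
  homopolymer anchors receive extra indel-supporting reads at per-read
  probability q₀·(L−4) (q₀ = 0.008), split between insertion and
  deletion, shared across samples so the background filter sees a
  common noise profile; mito sites inside the numt gain
  Poisson(nuclear coverage × copies) reference-matching reads on top of
  depth. True variants contribute Binomial(depth, frequency) reads.

All randomness flows from one root seed through named substreams
(genomes / lines / reads), so components are independently
reproducible and equal seeds give byte-identical outputs.

What passing tests on this generator do **not** show about real data:
no read-level artefacts (mapping ambiguity, strand bias, duplicates),
no structural variation or recombination, no correlated error profiles
between libraries, and a stylised drift model. The filter chain's
behaviour under those real-world effects is exercised only through the
masks and the homology screen.

## Calibration and property checks

End-to-end rate recovery uses a reduced problem size chosen for
statistical resolution: one 30 kb plastid-like genome, 14 mutant lines
× 7 generations (λ = μ·G·N ≈ 8.5 expected variants) and homoplasmic
transmission, so the planted Poisson count is the estimand; under
drift, lineage loss makes μ unidentifiable from surviving variants,
which is exactly why the real analysis weights SNVs by frequency. A
replicate counts as recovered when the estimate falls in the central
95 % Poisson interval of λ; the discrete interval over-covers (~97.7 %
at λ ≈ 8.5), giving headroom for the ≥ 93/100 criterion. The wild-type
null check zeroes all mutation rates and requires zero passing calls;
with the default error model the probability of a noise read-out
passing the 20 % threshold at ≥ 50× is negligible.

## Numerical conventions and degenerate inputs

- Depth-0 sites produce no candidates (frequency treated as 0).
- All-same-base circular sequences yield one run covering the genome.
- A perfect circular dinucleotide tiling has no leftmost phase and is
  reported once from position 1.
- The numt-corrected frequency of a site with expected nuclear reads
  ≥ the reference count is 1.0 by the clamp.
- Significant-figure rounding (for report formatting) uses
  round-half-even via Python's `round`.
- Report floats are printed at 3 significant figures; JSON keeps full
  precision.

## Known limitations

- The flank-homology screen is exact-match only; diverged repeats need
  explicit artefact masks.
- The background filter needs a wild-type panel; it errors without one.
- Reproducing the published effective genome sizes (357,025 /
  128,214 bp) requires the user's own repeat-mask intervals for the
  real genomes; masks ship only for synthetic genomes.
- Indel frequency estimation at homopolymers is not attempted beyond
  raw counts, mirroring the unweighted indel rates.
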