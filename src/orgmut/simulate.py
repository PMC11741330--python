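"""Forward simulator for organelle mutation-accumulation experiments.

Generates fully specified synthetic datasets — a pair of circular
genomes of contrasting GC content and homopolymer density, a large numt
copy of part of the mitochondrial genome, mutation-accumulation lines
propagated by single-seed descent with per-generation germline SNVs and
repeat-slippage indels under a heteroplasmic drift model, and per-site
allele-count tables with sequencing noise that grows with homopolymer
length — together with the complete truth, so every stage of the
analysis can be tested against known answers.

Default parameters mirror the study conditions: a GC-neutral
"mitochondrial" genome (45% GC) and an AT-rich "plastid" genome
(35% GC); 20 wild-type lines (8 generations, 7 homozygous) and 22
mutant lines (18 with 7 homozygous generations, 4 with 6) from three
founder families each; mutant SNV rates of 6.1e-7 (mito) and 3.2e-6
(plastid) per bp per generation with the observed spectra (47% / 83%
AT>GC); zero wild-type rates.  Genome lengths are scaled to desk size
(50 kb / 30 kb) while keeping those per-bp parameters.

All randomness flows from one root seed through named substreams
(genomes / lines / reads), so each component is independently
reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import yaml

from .errors import ConfigError, DataError
from .genomes import (
    GeneFeature,
    GenomeSpec,
    Interval,
    RepeatRecord,
    find_homopolymers,
)
from .spectrum import SPECTRUM_CLASSES, class_alt_for_ref, source_pair
from .variants import CountsTable, LineMeta

# ---------------------------------------------------------------------------
# Configuration


@dataclass
class GenomeSimConfig:
    """One synthetic organelle genome."""

    name: str = "mito"
    kind: str = "mito"  # mito | plastid
    length: int = 50_000
    gc: float = 0.45
    n_at_homopolymers: int = 60
    n_gc_homopolymers: int = 21  # mito-like AT:GC ratio ~2.8
    homopolymer_len_geom_p: float = 0.6  # extra length beyond 5 ~ Geometric
    n_dinucleotide_arrays: int = 8
    repeat_pair_length: int = 2_000  # one large repeat pair, second copy masked
    numt_length: int = 10_000  # 0 disables; mito only
    numt_copies: int = 2
    n_genes: int = 4

    def validate(self) -> None:
        if self.length < 1_000:
            raise ConfigError("genome length must be >= 1 kb")
        if not 0 < self.gc < 1:
            raise ConfigError("gc must be in (0, 1)")
        if self.kind not in ("mito", "plastid"):
            raise ConfigError(f"unknown genome kind {self.kind!r}")
        if min(
            self.n_at_homopolymers,
            self.n_gc_homopolymers,
            self.n_dinucleotide_arrays,
            self.repeat_pair_length,
            self.numt_length,
            self.numt_copies,
            self.n_genes,
        ) < 0:
            raise ConfigError("genome feature counts must be >= 0")


@dataclass
class LinePlanConfig:
    """MA line plan: single-seed descent, generations in homozygous state."""

    n_wt: int = 20
    wt_generations: int = 7
    n_mut: int = 22
    mut_generations: tuple[int, ...] = (7,) * 18 + (6,) * 4
    n_founder_families: int = 3

    def validate(self) -> None:
        if len(self.mut_generations) != self.n_mut:
            raise ConfigError("mut_generations must list one entry per mutant line")
        if self.n_wt < 1 or self.n_mut < 0:
            raise ConfigError("need at least one WT line")


@dataclass
class MutationModelConfig:
    """Per-generation germline mutation process, per genome kind."""

    snv_rate: dict = field(
        default_factory=lambda: {"mito": 6.1e-7, "plastid": 3.2e-6}
    )
    wt_snv_rate: float = 0.0
    spectrum: dict = field(
        default_factory=lambda: {
            "mito": {
                "AT>GC": 0.47, "GC>AT": 0.43, "AT>CG": 0.02,
                "GC>TA": 0.04, "AT>TA": 0.02, "GC>CG": 0.02,
            },
            "plastid": {
                "AT>GC": 0.83, "GC>AT": 0.08, "AT>CG": 0.03,
                "GC>TA": 0.03, "AT>TA": 0.02, "GC>CG": 0.01,
            },
        }
    )
    # homopolymer slippage: per-locus per-generation rate m0*(L-4), L>=5
    hp_indel_rate_per_unit: float = 2e-4
    dinuc_indel_rate: float = 2e-5
    # insertion probability given an indel event, by run base class
    p_insertion: dict = field(
        default_factory=lambda: {"AT": 0.35, "GC": 0.60, "dinuc": 0.5}
    )
    indel_step_probs: tuple[float, ...] = (0.90, 0.09, 0.01)  # 1, 2, 3 units

    def validate(self) -> None:
        for kind, probs in self.spectrum.items():
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ConfigError(f"{kind} spectrum probabilities must sum to 1")
            if set(probs) != set(SPECTRUM_CLASSES):
                raise ConfigError(f"{kind} spectrum must cover all six classes")
        if any(r < 0 for r in self.snv_rate.values()) or self.wt_snv_rate < 0:
            raise ConfigError("rates must be >= 0")
        if abs(sum(self.indel_step_probs) - 1.0) > 1e-9:
            raise ConfigError("indel step probabilities must sum to 1")


@dataclass
class HeteroplasmyConfig:
    """Drift of heteroplasmic frequencies through the germline bottleneck.

    Each generation the frequency is perturbed by a Beta draw with
    organelle-specific concentration (the plastid sorts faster, i.e.
    lower concentration), absorbing at 0/1 outside the thresholds.  An
    ``initial_frequency`` of 1.0 makes transmission effectively
    homoplasmic (no drift), which is the calibration configuration.
    """

    initial_frequency: float = 0.5
    concentration: dict = field(default_factory=lambda: {"mito": 40.0, "plastid": 8.0})
    absorb_low: float = 0.02
    absorb_high: float = 0.98

    def validate(self) -> None:
        if not 0 < self.initial_frequency <= 1:
            raise ConfigError("initial_frequency must be in (0, 1]")
        if not 0 <= self.absorb_low < self.absorb_high <= 1:
            raise ConfigError("absorption thresholds out of order")


@dataclass
class SequencingConfig:
    """Pileup-level sequencing model (no read-level simulation)."""

    mean_depth: dict = field(default_factory=lambda: {"mito": 300, "plastid": 600})
    per_base_error: float = 0.002
    hp_slip_q0: float = 0.008  # per-read slippage at run length L: q0*(L-4)
    nuclear_coverage: float = 30.0

    def validate(self) -> None:
        if any(d <= 0 for d in self.mean_depth.values()):
            raise ConfigError("mean depth must be > 0")
        if not 0 <= self.per_base_error < 1 or not 0 <= self.hp_slip_q0 < 1:
            raise ConfigError("error rates must be in [0, 1)")
        if self.nuclear_coverage < 0:
            raise ConfigError("nuclear coverage must be >= 0")


@dataclass
class SimConfig:
    seed: int = 20240101
    genomes: list[GenomeSimConfig] = field(
        default_factory=lambda: [
            GenomeSimConfig(),
            GenomeSimConfig(
                name="plastid",
                kind="plastid",
                length=30_000,
                gc=0.35,
                n_at_homopolymers=123,
                n_gc_homopolymers=10,  # plastid-like AT:GC ratio ~12.3
                repeat_pair_length=3_000,
                numt_length=0,
            ),
        ]
    )
    lines: LinePlanConfig = field(default_factory=LinePlanConfig)
    mutation: MutationModelConfig = field(default_factory=MutationModelConfig)
    heteroplasmy: HeteroplasmyConfig = field(default_factory=HeteroplasmyConfig)
    sequencing: SequencingConfig = field(default_factory=SequencingConfig)

    def validate(self) -> None:
        for g in self.genomes:
            g.validate()
        self.lines.validate()
        self.mutation.validate()
        self.heteroplasmy.validate()
        self.sequencing.validate()

    def substream(self, name: str) -> np.random.Generator:
        """Independent named RNG substream derived from the root seed."""
        key = zlib.crc32(name.encode()) & 0x7FFFFFFF
        ss = np.random.SeedSequence(self.seed, spawn_key=(key,))
        return np.random.default_rng(ss)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(
            seed=raw.get("seed", cls().seed),
            genomes=[GenomeSimConfig(**g) for g in raw["genomes"]]
            if "genomes" in raw
            else cls().genomes,
            lines=LinePlanConfig(**_tupled(raw.get("lines", {}), "mut_generations")),
            mutation=MutationModelConfig(
                **_tupled(raw.get("mutation", {}), "indel_step_probs")
            ),
            heteroplasmy=HeteroplasmyConfig(**raw.get("heteroplasmy", {})),
            sequencing=SequencingConfig(**raw.get("sequencing", {})),
        )
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        def listify(obj):
            if isinstance(obj, dict):
                return {k: listify(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [listify(v) for v in obj]
            return obj

        with open(path, "w") as fh:
            yaml.safe_dump(listify(asdict(self)), fh, sort_keys=False)


def _tupled(d: dict, key: str) -> dict:
    if key in d:
        d = dict(d)
        d[key] = tuple(d[key])
    return d


# ---------------------------------------------------------------------------
# Truth containers


@dataclass
class TrueVariant:
    line_id: str
    genome: str
    position: int
    ref: str
    alt: str
    var_type: str  # SNV | insertion | deletion
    origin_generation: int
    frequency: float
    spectrum_class: str = ""
    locus_start: int = 0  # repeat locus anchor for indels, 0 otherwise

    @property
    def allele_token(self) -> str:
        if self.var_type == "insertion":
            return "+" + self.alt
        if self.var_type == "deletion":
            return f"-{len(self.ref)}"
        return self.alt


@dataclass
class TruthSet:
    variants: list[TrueVariant] = field(default_factory=list)

    def for_line(self, line_id: str) -> list[TrueVariant]:
        return [v for v in self.variants if v.line_id == line_id]

    def surviving(self, min_frequency: float = 0.0) -> list[TrueVariant]:
        return [v for v in self.variants if v.frequency > min_frequency]


@dataclass
class GenomeTruth:
    planted_homopolymers: list[RepeatRecord]
    planted_dinucleotides: list[RepeatRecord]
    repeat_pair: tuple[Interval, Interval] | None
    numt: tuple[Interval, int] | None


# ---------------------------------------------------------------------------
# Genome generation


def generate_genomes(
    config: SimConfig,
) -> tuple[list[GenomeSpec], dict[str, GenomeTruth]]:
    """Build the synthetic genome pair with fully recorded features.

    Planted homopolymers are the only runs >= 5 bp outside the large
    repeat pair (chance runs in the background are broken), so the
    planted list is an exact truth catalogue for the scanner.  The
    second copy of the repeat pair is recorded in the repeat mask, and
    the numt interval carries its nuclear copy number.
    """
    config.validate()
    rng = config.substream("genomes")
    genomes, truths = [], {}
    for gcfg in config.genomes:
        for attempt in range(20):
            try:
                spec, truth = _generate_one_genome(gcfg, rng)
                break
            except _RetryGeneration:
                continue
        else:  # pragma: no cover - would need pathological configs
            raise DataError(f"could not place features in genome {gcfg.name}")
        genomes.append(spec)
        truths[gcfg.name] = truth
    return genomes, truths


class _RetryGeneration(Exception):
    pass


def _random_sequence(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.array(list("ACGT")), size=length, p=probs)


def _break_chance_runs(seq: np.ndarray, protected: np.ndarray, rng) -> None:
    """Substitute bases so that no unprotected homopolymer >= 5 bp remains."""
    bases = "ACGT"
    for _ in range(50):
        s = "".join(seq)
        changed = False
        i, n = 0, len(s)
        while i < n:
            j = i
            while j < n and s[j] == s[i]:
                j += 1
            if j - i >= 5 and not protected[i:j].any():
                mid = (i + j) // 2
                choices = [b for b in bases if b != s[i]]
                seq[mid] = choices[rng.integers(len(choices))]
                changed = True
            i = j
        if not changed:
            return
    raise _RetryGeneration


def _generate_one_genome(
    gcfg: GenomeSimConfig, rng: np.random.Generator
) -> tuple[GenomeSpec, GenomeTruth]:
    n = gcfg.length
    seq = _random_sequence(n, gcfg.gc, rng)
    protected = np.zeros(n, dtype=bool)

    # reserve layout: repeat pair at fixed offsets, numt after it
    rep = None
    if gcfg.repeat_pair_length:
        L = gcfg.repeat_pair_length
        a = Interval(101, 100 + L)
        b = Interval(n // 2 + 1, n // 2 + L)
        if b.end > n or a.overlaps(b):
            raise ConfigError("repeat pair does not fit in genome")
        rep = (a, b)
        protected[a.start - 1 : a.end] = True
        protected[b.start - 1 : b.end] = True
    numt = None
    if gcfg.kind == "mito" and gcfg.numt_length:
        start = (rep[0].end + 500) if rep else 101
        numt_iv = Interval(start, start + gcfg.numt_length - 1)
        if numt_iv.end > (rep[1].start - 1 if rep else n):
            raise ConfigError("numt interval does not fit before repeat pair copy")
        numt = (numt_iv, gcfg.numt_copies)

    # plant homopolymers and dinucleotide arrays at spaced positions
    planted_hp: list[RepeatRecord] = []
    planted_dn: list[RepeatRecord] = []
    free = ~protected  # planted features stay outside the repeat pair / numt
    occupied = np.zeros(n, dtype=bool)  # planted bases, protected from breaking
    reserved = np.zeros(n, dtype=bool)  # planted bases + spacing margin

    def place(length: int) -> int:
        for _ in range(200):
            start0 = int(rng.integers(2, n - length - 2))
            window = slice(start0 - 2, start0 + length + 2)  # 2 bp margin
            if free[window].all() and not reserved[window].any():
                reserved[window] = True
                occupied[start0 : start0 + length] = True
                return start0
        raise _RetryGeneration

    def plant_run(base: str) -> None:
        length = 5 + int(rng.geometric(gcfg.homopolymer_len_geom_p) - 1)
        start0 = place(length)
        seq[start0 : start0 + length] = base
        # margins must break the run
        other = {"A": "C", "C": "A", "G": "T", "T": "G"}[base]
        for k in (start0 - 1, start0 + length):
            if seq[k] == base:
                seq[k] = other
        planted_hp.append(
            RepeatRecord(
                start=start0 + 1,
                length=length,
                unit=base,
                unit_count=length,
                base_class="AT" if base in "AT" else "GC",
            )
        )

    at_bases, gc_bases = "AT", "GC"
    for i in range(gcfg.n_at_homopolymers):
        plant_run(at_bases[i % 2])
    for i in range(gcfg.n_gc_homopolymers):
        plant_run(gc_bases[i % 2])
    dinuc_units = ["AT", "AG", "AC", "TG", "TC", "GC"]
    for i in range(gcfg.n_dinucleotide_arrays):
        unit = dinuc_units[i % len(dinuc_units)]
        units = 3 + int(rng.geometric(0.5) - 1)
        length = 2 * units
        start0 = place(length)
        seq[start0 : start0 + length] = list(unit * units)
        planted_dn.append(
            RepeatRecord(
                start=start0 + 1, length=length, unit=unit, unit_count=units
            )
        )

    # break chance homopolymers everywhere except the planted bases; the
    # repeat-pair source copy is edited too, then duplicated verbatim
    _break_chance_runs(seq, occupied, rng)
    if rep is not None:
        a, b = rep
        seq[b.start - 1 : b.end] = seq[a.start - 1 : a.end]

    sequence = "".join(seq)
    annotation = _toy_annotation(sequence, gcfg, rep, rng)
    spec = GenomeSpec(
        name=gcfg.name,
        sequence=sequence,
        annotation=annotation,
        repeat_mask=[rep[1]] if rep else [],
        numt_track=[numt] if numt else [],
        artefact_mask=[],
        circular=True,
    )
    # the planted list must be exactly the scanner's catalogue; rare
    # boundary artefacts (runs straddling the mask edge or the origin)
    # trigger a deterministic regeneration
    found = {(r.start, r.length, r.unit) for r in find_homopolymers(spec, min_len=5)}
    planted_keys = {(r.start, r.length, r.unit) for r in planted_hp}
    if found != planted_keys:
        raise _RetryGeneration
    truth = GenomeTruth(
        planted_homopolymers=planted_hp,
        planted_dinucleotides=planted_dn,
        repeat_pair=rep,
        numt=numt,
    )
    return spec, truth


def _toy_annotation(
    sequence: str, gcfg: GenomeSimConfig, rep, rng
) -> list[GeneFeature]:
    """Small gene set in the back half of the genome: CDS (one with an
    intron, one on the minus strand), an rRNA and a tRNA."""
    n = len(sequence)
    feats: list[GeneFeature] = []
    if gcfg.n_genes == 0:
        return feats
    # place genes after the repeat-pair copy, before the end
    lo = (rep[1].end + 200) if rep else n // 2
    cursor = lo
    gene_len = 600
    for i in range(gcfg.n_genes):
        if cursor + gene_len + 400 > n:
            break
        gid = f"{gcfg.name}_gene{i+1}"
        if i == 1:
            # CDS split by an intron
            ex1 = Interval(cursor, cursor + 299)
            intron = Interval(cursor + 300, cursor + 449)
            ex2 = Interval(cursor + 450, cursor + 749)
            feats.append(GeneFeature(gid, "CDS", (ex1, ex2), "+", 0))
            feats.append(GeneFeature(gid + "_intron", "intron", (intron,), "+"))
            cursor += 950
        elif i == 2:
            iv = Interval(cursor, cursor + gene_len - 1)
            feats.append(GeneFeature(gid, "CDS", (iv,), "-", 0))
            cursor += gene_len + 200
        elif i == 3:
            r_iv = Interval(cursor, cursor + 239)
            t_iv = Interval(cursor + 300, cursor + 371)
            feats.append(GeneFeature(gid + "_rrn", "rRNA", (r_iv,), "+"))
            feats.append(GeneFeature(gid + "_trn", "tRNA", (t_iv,), "+"))
            cursor += 700
        else:
            iv = Interval(cursor, cursor + gene_len - 1)
            feats.append(GeneFeature(gid, "CDS", (iv,), "+", 0))
            cursor += gene_len + 200
    return feats


# ---------------------------------------------------------------------------
# Line simulation


def simulate_lines(
    genomes: Sequence[GenomeSpec],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[LineMeta], TruthSet]:
    """Propagate MA lines and accumulate germline mutations.

    Per generation and genome, new SNVs arrive as Poisson(mu * G_eff)
    placed uniformly on unmasked sites consistent with the drawn
    spectrum class; homopolymer indels arrive per locus at rate
    m0 * (L - 4) with class-dependent insertion bias; frequencies start
    at the configured initial heteroplasmy and drift by Beta
    perturbation with absorption at 0/1.  Lost variants (frequency 0)
    are dropped from the truth.
    """
    config.validate()
    if rng is None:
        rng = config.substream("lines")
    lines = make_line_plan(config.lines)
    eligible = {g.name: _eligible_positions(g) for g in genomes}
    loci = {g.name: _mutable_loci(g) for g in genomes}
    truth = TruthSet()
    het = config.heteroplasmy
    for meta in lines:
        active: list[TrueVariant] = []
        for gen in range(1, meta.generations + 1):
            for g in genomes:
                kind = _kind_of(g, config)
                mu = (
                    config.mutation.snv_rate.get(kind, 0.0)
                    if meta.genotype == "msh1"
                    else config.mutation.wt_snv_rate
                )
                active += _new_snvs(meta, g, kind, gen, mu, eligible[g.name], config, rng)
                if meta.genotype == "msh1":
                    active += _new_indels(meta, g, gen, loci[g.name], active, config, rng)
            # heteroplasmic drift for every active variant
            for v in active:
                kind = _kind_of_name(v.genome, genomes, config)
                c = het.concentration.get(kind, 40.0)
                f = v.frequency
                if 0 < f < 1:
                    f = float(rng.beta(max(c * f, 1e-9), max(c * (1 - f), 1e-9)))
                    if f <= het.absorb_low:
                        f = 0.0
                    elif f >= het.absorb_high:
                        f = 1.0
                    v.frequency = f
        truth.variants += [v for v in active if v.frequency > 0]
    return lines, truth


def make_line_plan(plan: LinePlanConfig) -> list[LineMeta]:
    plan.validate()
    lines = []
    for i in range(plan.n_wt):
        fam = f"W{i % plan.n_founder_families + 1}"
        lines.append(LineMeta(f"W{i+1}", "WT", plan.wt_generations, fam))
    for i in range(plan.n_mut):
        fam = f"M{i % plan.n_founder_families + 1}"
        lines.append(LineMeta(f"M{i+1}", "msh1", plan.mut_generations[i], fam))
    return lines


def _kind_of(g: GenomeSpec, config: SimConfig) -> str:
    for gcfg in config.genomes:
        if gcfg.name == g.name:
            return gcfg.kind
    return "mito"


def _kind_of_name(name: str, genomes: Sequence[GenomeSpec], config: SimConfig) -> str:
    for g in genomes:
        if g.name == name:
            return _kind_of(g, config)
    return "mito"


def _eligible_positions(g: GenomeSpec) -> dict[str, np.ndarray]:
    """Unmasked 1-based positions by source base pair."""
    arr = np.frombuffer(g.sequence.encode(), dtype="S1")
    mask = np.zeros(len(g), dtype=bool)
    for iv in g.repeat_mask + g.artefact_mask:
        mask[iv.start - 1 : iv.end] = True
    pos = np.arange(1, len(g) + 1)
    is_at = (arr == b"A") | (arr == b"T")
    return {"AT": pos[is_at & ~mask], "GC": pos[~is_at & ~mask]}


def _mutable_loci(g: GenomeSpec) -> list[RepeatRecord]:
    from .genomes import find_dinucleotide_repeats

    return find_homopolymers(g, min_len=5) + find_dinucleotide_repeats(g, min_units=3)


def _new_snvs(meta, g, kind, gen, mu, eligible, config, rng) -> list[TrueVariant]:
    if mu <= 0:
        return []
    n_new = rng.poisson(mu * g.effective_size_G)
    out = []
    probs = config.mutation.spectrum.get(kind) or config.mutation.spectrum["mito"]
    classes = list(probs)
    p = np.array([probs[c] for c in classes])
    for _ in range(int(n_new)):
        cls = classes[int(rng.choice(len(classes), p=p))]
        pool = eligible[source_pair(cls)]
        pos = int(pool[int(rng.integers(len(pool)))])
        ref = g.sequence[pos - 1]
        out.append(
            TrueVariant(
                line_id=meta.line_id,
                genome=g.name,
                position=pos,
                ref=ref,
                alt=class_alt_for_ref(cls, ref),
                var_type="SNV",
                origin_generation=gen,
                frequency=config.heteroplasmy.initial_frequency,
                spectrum_class=cls,
            )
        )
    return out


def _new_indels(meta, g, gen, loci, active, config, rng) -> list[TrueVariant]:
    m = config.mutation
    taken = {
        (v.genome, v.locus_start)
        for v in active
        if v.var_type in ("insertion", "deletion")
    }
    out = []
    for r in loci:
        if (g.name, r.start) in taken:
            continue  # one indel per locus per line (multiple hits across lines)
        if len(r.unit) == 1:
            rate = m.hp_indel_rate_per_unit * max(r.length - 4, 0)
            p_ins = m.p_insertion.get(r.base_class, 0.5)
        else:
            rate = m.dinuc_indel_rate
            p_ins = m.p_insertion.get("dinuc", 0.5)
        if rng.random() >= rate:
            continue
        step = 1 + int(rng.choice(len(m.indel_step_probs), p=np.array(m.indel_step_probs)))
        if len(r.unit) == 1:
            step = min(step, r.unit_count)
        else:
            step = min(step, r.unit_count - 1) or 1
        seq = r.unit * step
        insertion = rng.random() < p_ins
        anchor = r.start - 1 if r.start > 1 else len(g)
        out.append(
            TrueVariant(
                line_id=meta.line_id,
                genome=g.name,
                position=anchor,
                ref="-" if insertion else seq,
                alt=seq if insertion else "-",
                var_type="insertion" if insertion else "deletion",
                origin_generation=gen,
                frequency=config.heteroplasmy.initial_frequency,
                locus_start=r.start,
            )
        )
        taken.add((g.name, r.start))
    return out


# ---------------------------------------------------------------------------
# Count rendering


def render_counts(
    genomes: Sequence[GenomeSpec],
    truth: TruthSet,
    lines: Sequence[LineMeta],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, CountsTable]:
    """Render per-sample per-site allele-count tables with noise.

    Depth is Poisson around the configured organelle mean; substitution
    errors hit each non-reference base at e/3 per read; homopolymer
    anchors receive extra indel-supporting error reads with per-read
    probability q0*(L-4)/2 each for insertion and deletion; mitochondrial
    sites inside the numt interval gain Poisson(nuclear coverage x copy
    number) reference-matching reads on top of depth (numt bleed-through).
    True variants contribute Binomial(depth, frequency) alternate reads.
    """
    config.validate()
    if rng is None:
        rng = config.substream("reads")
    seqc = config.sequencing
    samples = [m.line_id for m in lines]
    tables: dict[str, CountsTable] = {}
    for g in genomes:
        kind = _kind_of(g, config)
        n = len(g)
        S = len(samples)
        mean_depth = seqc.mean_depth.get(kind, 200)
        depth = rng.poisson(mean_depth, size=(S, n)).astype(np.int64)
        ref_arr = np.frombuffer(g.sequence.encode(), dtype="S1").astype("U1")
        base_counts = {b: np.zeros((S, n), dtype=np.int64) for b in "ACGT"}
        err_total = np.zeros((S, n), dtype=np.int64)
        e = seqc.per_base_error
        if e > 0:
            for b in "ACGT":
                nonref = ref_arr != b
                errs = rng.binomial(depth, e / 3) * nonref
                base_counts[b] += errs
                err_total += errs
        indel_counts: dict[tuple[int, int], dict[str, int]] = {}

        # homopolymer slippage noise, shared error profile across samples
        if seqc.hp_slip_q0 > 0:
            for r in find_homopolymers(g, min_len=5, exclude_masked=False):
                q = min(seqc.hp_slip_q0 * max(r.length - 4, 0), 0.49)
                if q <= 0:
                    continue
                j = (r.start - 2) % n  # 0-based anchor before the run
                ins_tok = "+" + r.unit
                del_tok = "-1"
                k_ins = rng.binomial(depth[:, j], q / 2)
                k_del = rng.binomial(depth[:, j], q / 2)
                for i in range(S):
                    if k_ins[i] or k_del[i]:
                        d = indel_counts.setdefault((i, j), {})
                        if k_ins[i]:
                            d[ins_tok] = d.get(ins_tok, 0) + int(k_ins[i])
                        if k_del[i]:
                            d[del_tok] = d.get(del_tok, 0) + int(k_del[i])

        # true variant signal
        sample_index = {s: i for i, s in enumerate(samples)}
        alt_used = np.zeros((S, n), dtype=np.int64)
        for v in truth.variants:
            if v.genome != g.name or v.frequency <= 0:
                continue
            i = sample_index[v.line_id]
            j = v.position - 1
            k = int(rng.binomial(depth[i, j], v.frequency))
            if k == 0:
                continue
            if v.var_type == "SNV":
                base_counts[v.alt][i, j] += k
                alt_used[i, j] += k
            else:
                d = indel_counts.setdefault((i, j), {})
                tok = v.allele_token
                d[tok] = d.get(tok, 0) + k

        # reference counts = depth - non-ref signal, floored at zero
        for b in "ACGT":
            is_ref = ref_arr == b
            refcnt = np.maximum(depth - err_total - alt_used, 0)
            base_counts[b] = np.where(is_ref, refcnt, base_counts[b])

        # numt bleed-through: extra reference reads inside the numt interval
        if kind == "mito" and g.numt_track and seqc.nuclear_coverage > 0:
            for iv, copies in g.numt_track:
                sl = slice(iv.start - 1, iv.end)
                extra = rng.poisson(seqc.nuclear_coverage * copies, size=(S, iv.length))
                depth[:, sl] += extra
                for b in "ACGT":
                    is_ref = ref_arr[sl] == b
                    base_counts[b][:, sl] += extra * is_ref

        # clamp per-allele counts at depth (invariant of the table format)
        for b in "ACGT":
            np.minimum(base_counts[b], depth, out=base_counts[b])
        for (i, j), d in indel_counts.items():
            for tok in list(d):
                d[tok] = min(d[tok], int(depth[i, j]))

        tables[g.name] = CountsTable(
            genome=g.name,
            samples=samples,
            positions=np.arange(1, n + 1),
            ref=ref_arr,
            depth=depth,
            base_counts=base_counts,
            indel_counts=indel_counts,
        )
    return tables


# ---------------------------------------------------------------------------
# Whole-dataset convenience


@dataclass
class SyntheticDataset:
    config: SimConfig
    genomes: list[GenomeSpec]
    genome_truth: dict[str, GenomeTruth]
    lines: list[LineMeta]
    truth: TruthSet
    counts: dict[str, CountsTable]

    def kind_of(self, genome_name: str) -> str:
        return _kind_of_name(genome_name, self.genomes, self.config)


def simulate_dataset(config: SimConfig | None = None) -> SyntheticDataset:
    """Run the full generator: genomes, line truth, count tables."""
    config = config or SimConfig()
    genomes, gtruth = generate_genomes(config)
    lines, truth = simulate_lines(genomes, config)
    counts = render_counts(genomes, truth, lines, config)
    return SyntheticDataset(
        config=config,
        genomes=genomes,
        genome_truth=gtruth,
        lines=lines,
        truth=truth,
        counts=counts,
    )


def write_dataset(dataset: SyntheticDataset, outdir) -> None:
    """Write the dataset as FASTA / GFF3 / BED / TSV files."""
    import os
    import pandas as pd

    from . import io as _io

    os.makedirs(outdir, exist_ok=True)
    for g in dataset.genomes:
        _io.write_fasta(os.path.join(outdir, f"{g.name}.fasta"), g.name, g.sequence)
        _io.write_gff3(os.path.join(outdir, f"{g.name}.gff3"), g.name, g.annotation)
        if g.repeat_mask:
            _io.write_bed(os.path.join(outdir, f"{g.name}_repeat_mask.bed"), g.name, g.repeat_mask)
        if g.numt_track:
            _io.write_bed(
                os.path.join(outdir, f"{g.name}_numt.bed"),
                g.name,
                [iv for iv, _ in g.numt_track],
                scores=[c for _, c in g.numt_track],
            )
        dataset.counts[g.name].to_tsv(os.path.join(outdir, f"{g.name}_counts.tsv"))
    _io.write_line_metadata(os.path.join(outdir, "lines.tsv"), dataset.lines)
    pd.DataFrame(
        [
            {
                "line_id": v.line_id,
                "genome": v.genome,
                "position": v.position,
                "ref": v.ref,
                "alt": v.alt,
                "var_type": v.var_type,
                "origin_generation": v.origin_generation,
                "frequency": v.frequency,
                "spectrum_class": v.spectrum_class,
                "locus_start": v.locus_start,
            }
            for v in dataset.truth.variants
        ]
    ).to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)
    dataset.config.to_yaml(os.path.join(outdir, "config.yaml"))
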