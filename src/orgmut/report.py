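"""End-to-end analysis assembly.

``analyze_dataset`` drives the full pipeline on an in-memory dataset
(typically from the simulator) and returns every headline quantity of
the analysis: filtered calls, frequency-weighted SNV and unweighted
indel rates, Poisson upper bounds for the wild-type panel, the mutation
spectrum, Table-style location counts, and the indel bias summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from . import annotate as _annotate
from . import indels as _indels
from . import rates as _rates
from . import spectrum as _spectrum
from .genomes import GenomeSpec, find_dinucleotide_repeats, find_homopolymers
from .simulate import SyntheticDataset
from .variants import LineMeta, VariantCall, call_variants


@dataclass
class GenomeAnalysis:
    genome: str
    kind: str
    calls: list[VariantCall]
    snvs: list[VariantCall]
    indels: list[VariantCall]
    snv_rate: _rates.RateEstimate
    indel_rate: _rates.RateEstimate
    wt_upper_bound: _rates.UpperBound
    spectrum: _spectrum.SpectrumTable
    location_counts: dict[str, int]
    indel_bias: _indels.IndelBiasTable
    indel_assignments: list[_indels.IndelAssignment] = field(default_factory=list)

    def summary(self) -> dict:
        ins, dele = self.indel_bias.totals(self.genome)
        return {
            "genome": self.genome,
            "kind": self.kind,
            "n_snvs": len(self.snvs),
            "n_indels": len(self.indels),
            "snv_rate_weighted": self.snv_rate.mu,
            "indel_rate": self.indel_rate.mu,
            "wt_upper_bound": self.wt_upper_bound.mu_upper,
            "fold_over_wt_bound": (
                _rates.fold_ratio(self.snv_rate.mu, self.wt_upper_bound)
                if self.wt_upper_bound.mu_upper
                else None
            ),
            "transition_fraction": self.spectrum.transition_fraction,
            "location_counts": self.location_counts,
            "insertions": ins,
            "deletions": dele,
        }


def analyze_genome(
    table,
    genome: GenomeSpec,
    lines: Sequence[LineMeta],
    kind: str,
    genome_set: Sequence[GenomeSpec] | None = None,
    nuclear_coverage=None,
    wt_total_generations: int | None = None,
    alpha: float = 0.05,
    **call_kwargs,
) -> GenomeAnalysis:
    """Filter chain + rates + spectrum + indel analysis for one genome."""
    calls = call_variants(
        table,
        genome,
        lines,
        genome_kind=kind,
        nuclear_coverage=nuclear_coverage,
        genome_set=genome_set,
        **call_kwargs,
    )
    mut_lines = [m for m in lines if m.genotype == "msh1"]
    mut_ids = {m.line_id for m in mut_lines}
    passing = [c for c in calls if c.passes and c.line_id in mut_ids]
    snvs = [c for c in passing if c.var_type == "SNV"]
    indel_calls = [c for c in passing if c.var_type in ("insertion", "deletion")]

    N_mut = _rates.total_generations(mut_lines)
    G = genome.effective_size_G
    snv_rate = _rates.mutation_rate(
        snvs, N_mut, G, weight_by_frequency=True, genome=genome.name
    )
    indel_rate = _rates.mutation_rate(
        indel_calls,
        N_mut,
        G,
        weight_by_frequency=False,
        genome=genome.name,
        variant_class="indel",
    )
    wt_lines = [m for m in lines if m.genotype == "WT"]
    N_wt = wt_total_generations or max(_rates.total_generations(wt_lines), 1)
    bound = _rates.poisson_upper_bound(G, N_wt, alpha=alpha, genome=genome.name)

    spec_table = _spectrum.spectrum_table(snvs, genome, N_mut)
    annotations = [_annotate.annotate_variant(v, genome) for v in snvs]
    loc_counts = _annotate.location_counts(annotations)

    catalogue = find_homopolymers(genome, min_len=5) + find_dinucleotide_repeats(
        genome, min_units=3
    )
    assignments = [
        _indels.assign_indel(v, catalogue, genome_length=len(genome))
        for v in indel_calls
    ]
    bias = _indels.bias_table(assignments)
    return GenomeAnalysis(
        genome=genome.name,
        kind=kind,
        calls=calls,
        snvs=snvs,
        indels=indel_calls,
        snv_rate=snv_rate,
        indel_rate=indel_rate,
        wt_upper_bound=bound,
        spectrum=spec_table,
        location_counts=loc_counts,
        indel_bias=bias,
        indel_assignments=assignments,
    )


def calibration_config(seed: int = 0) -> "SimConfig":
    """Desk-scale configuration for end-to-end rate-recovery checks.

    One plastid-like genome at the study's per-bp SNV rate, with
    immediate-fixation transmission (initial heteroplasmy 1.0) so the
    number of surviving germline variants is exactly the planted Poisson
    count and the rate is identifiable from a single replicate.  Line
    number is reduced to keep a 100-replicate run cheap; the per-bp,
    per-generation parameters are untouched.
    """
    from .simulate import GenomeSimConfig, HeteroplasmyConfig, LinePlanConfig, SimConfig

    cfg = SimConfig(seed=seed)
    cfg.genomes = [
        GenomeSimConfig(
            name="plastid",
            kind="plastid",
            length=30_000,
            gc=0.35,
            n_at_homopolymers=60,
            n_gc_homopolymers=5,
            repeat_pair_length=3_000,
            numt_length=0,
        )
    ]
    cfg.lines = LinePlanConfig(n_wt=6, wt_generations=7, n_mut=14, mut_generations=(7,) * 14)
    cfg.heteroplasmy = HeteroplasmyConfig(initial_frequency=1.0)
    return cfg


def parameter_recovery(
    n_replicates: int = 100, seed: int = 0, config=None
) -> dict:
    """Recover mu end-to-end on replicate simulations with known truth.

    For each replicate the full pipeline (simulate, render counts, call,
    estimate) runs with a fresh seed; the estimate counts passing mutant
    SNVs and divides by G*N.  A replicate is covered when the estimate
    falls inside the central 95% Poisson interval of the true expected
    count lambda = mu*G*N.
    """
    from scipy import stats

    from .simulate import generate_genomes, render_counts, simulate_lines

    base = config or calibration_config(seed)
    results = {"mu_hat": [], "covered": [], "lambda": None}
    for rep in range(n_replicates):
        cfg = calibration_config((seed * 100_003 + rep) % (2**31 - 1)) if config is None else config
        cfg.seed = (seed * 100_003 + rep) % (2**31 - 1)
        genomes, _ = generate_genomes(cfg)
        lines, truth = simulate_lines(genomes, cfg)
        counts = render_counts(genomes, truth, lines, cfg)
        g = genomes[0]
        kind = cfg.genomes[0].kind
        mu_true = cfg.mutation.snv_rate[kind]
        mut_lines = [m for m in lines if m.genotype == "msh1"]
        N = sum(m.generations for m in mut_lines)
        lam = mu_true * g.effective_size_G * N
        analysis = analyze_genome(
            counts[g.name], g, lines, kind=kind, genome_set=genomes,
            nuclear_coverage=cfg.sequencing.nuclear_coverage,
        )
        v_hat = len(analysis.snvs)
        mu_hat = v_hat / (g.effective_size_G * N)
        lo = stats.poisson.ppf(0.025, lam)
        hi = stats.poisson.ppf(0.975, lam)
        results["mu_hat"].append(mu_hat)
        results["covered"].append(bool(lo <= v_hat <= hi))
        results["lambda"] = lam
    results["coverage"] = sum(results["covered"]) / n_replicates
    return results


def wt_null_replicates(n_replicates: int = 100, seed: int = 0) -> dict:
    """Passing-call counts on replicates with no planted mutations.

    All germline rates are zeroed, so only sequencing noise (including
    the elevated homopolymer indel error) can produce calls; the filter
    chain is expected to report none in any line.
    """
    from .simulate import GenomeSimConfig, LinePlanConfig, SimConfig, simulate_dataset

    counts = []
    for rep in range(n_replicates):
        cfg = SimConfig(seed=(seed * 99_991 + rep) % (2**31 - 1))
        cfg.genomes = [
            GenomeSimConfig(
                name="mito", kind="mito", length=8_000, gc=0.45,
                n_at_homopolymers=24, n_gc_homopolymers=8,
                repeat_pair_length=1_000, numt_length=2_000,
            )
        ]
        cfg.lines = LinePlanConfig(n_wt=8, wt_generations=7, n_mut=4, mut_generations=(7,) * 4)
        cfg.mutation.snv_rate = {"mito": 0.0, "plastid": 0.0}
        cfg.mutation.hp_indel_rate_per_unit = 0.0
        cfg.mutation.dinuc_indel_rate = 0.0
        ds = simulate_dataset(cfg)
        analyses = analyze_dataset(ds)
        n_passing = sum(
            sum(1 for c in a.calls if c.passes) for a in analyses.values()
        )
        counts.append(n_passing)
    clean = sum(1 for c in counts if c == 0)
    return {"passing_counts": counts, "fraction_clean": clean / n_replicates}


def analyze_dataset(dataset: SyntheticDataset, **call_kwargs) -> dict[str, GenomeAnalysis]:
    """Run the full analysis on a simulated dataset, one entry per genome."""
    out = {}
    for g in dataset.genomes:
        kind = dataset.kind_of(g.name)
        out[g.name] = analyze_genome(
            dataset.counts[g.name],
            g,
            dataset.lines,
            kind=kind,
            genome_set=dataset.genomes,
            nuclear_coverage=dataset.config.sequencing.nuclear_coverage,
            **call_kwargs,
        )
    return out
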