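"""Shared fixtures: hand-built toy genomes and a small simulated dataset."""

import numpy as np
import pytest

from orgmut.genomes import GeneFeature, GenomeSpec, Interval
from orgmut.simulate import (
    GenomeSimConfig,
    LinePlanConfig,
    SimConfig,
    simulate_dataset,
)


def make_genome(sequence, name="toy", circular=True, **kwargs):
    return GenomeSpec(name=name, sequence=sequence, circular=circular, **kwargs)


@pytest.fixture
def coding_genome():
    """Linear toy genome with one CDS of known codons.

    Layout (1-based): positions 1-10 intergenic, 11-28 CDS
    (ATG GCT GCA AAA TGG TAA: Met Ala Ala Lys Trp Stop), 29-40 intergenic.
    The GCT/GCA alanine codons give 4-fold synonymous third positions;
    TGG (Trp) is nonsynonymous at every position.
    """
    seq = "CCGGTACCGG" + "ATGGCTGCAAAATGGTAA" + "CCGGTTAACCGG"
    cds = GeneFeature("toyA", "CDS", (Interval(11, 28),), "+", 0)
    return make_genome(seq, name="toy", circular=False, annotation=[cds])


def small_sim_config(seed=11, **overrides):
    """Reduced-size two-genome simulation used across tests."""
    cfg = SimConfig(seed=seed)
    cfg.genomes = [
        GenomeSimConfig(
            name="mito", kind="mito", length=12_000, gc=0.45,
            n_at_homopolymers=22, n_gc_homopolymers=8,
            repeat_pair_length=1_000, numt_length=2_500, numt_copies=2,
        ),
        GenomeSimConfig(
            name="plastid", kind="plastid", length=9_000, gc=0.35,
            n_at_homopolymers=24, n_gc_homopolymers=2,
            repeat_pair_length=1_000, numt_length=0,
        ),
    ]
    cfg.lines = LinePlanConfig(n_wt=6, wt_generations=7, n_mut=8, mut_generations=(7,) * 8)
    cfg.mutation.snv_rate = {"mito": 2e-5, "plastid": 5e-5}
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_dataset(small_sim_config())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
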