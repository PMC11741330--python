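"""Genome model: masks, effective size, and simple-repeat scanners."""

import itertools

import pytest

from orgmut.errors import ConfigError, DataError
from orgmut.genomes import (
    GeneFeature,
    Interval,
    RepeatRecord,
    find_dinucleotide_repeats,
    find_homopolymers,
    homopolymer_class_counts,
    load_genome,
)
from orgmut.simulate import generate_genomes

from conftest import make_genome, small_sim_config


def brute_force_homopolymers(seq, min_len=5, circular=True):
    """Independent oracle: group a rotation of the sequence at a run boundary."""
    n = len(seq)
    if n == 0:
        return []
    if circular and len(set(seq)) == 1:
        return [(1, n, seq[0])] if n >= min_len else []
    if circular:
        # rotate so the string does not start mid-run
        k = next(i for i in range(n) if seq[i - 1] != seq[i])
        rotated = seq[k:] + seq[:k]
    else:
        k, rotated = 0, seq
    out = []
    pos = 0
    for base, grp in itertools.groupby(rotated):
        length = len(list(grp))
        if length >= min_len:
            start = (pos + k) % n + 1
            out.append((start, length, base))
        pos += length
    return sorted(out)


class TestEffectiveSize:
    def test_mask_subtraction(self):
        g = make_genome("A" * 5000 + "C" * 5000, repeat_mask=[Interval(1001, 2000)])
        assert len(g) == 10_000
        assert g.effective_size_G == 9_000

    def test_no_mask(self):
        g = make_genome("ACGT" * 100)
        assert g.effective_size_G == 400

    def test_mask_split_conserves_G(self):
        seq = "ACGT" * 2500
        whole = make_genome(seq, repeat_mask=[Interval(101, 300)])
        split = make_genome(seq, repeat_mask=[Interval(101, 200), Interval(201, 300)])
        assert whole.effective_size_G == split.effective_size_G

    def test_overlapping_masks_rejected(self):
        with pytest.raises(DataError):
            make_genome("ACGT" * 100, repeat_mask=[Interval(1, 50), Interval(40, 80)])

    def test_out_of_bounds_interval_rejected(self):
        with pytest.raises(DataError):
            make_genome("ACGT" * 10, repeat_mask=[Interval(30, 50)])


class TestFindHomopolymers:
    def test_linear_example(self):
        g = make_genome("GGAAAAAG", circular=False)
        recs = find_homopolymers(g, min_len=5)
        assert [(r.start, r.length, r.unit) for r in recs] == [(3, 5, "A")]

    def test_below_threshold(self):
        g = make_genome("AAAA", circular=False)
        assert find_homopolymers(g, min_len=5) == []

    def test_min_len_validation(self):
        g = make_genome("ACGT" * 10)
        with pytest.raises(ConfigError):
            find_homopolymers(g, min_len=1)

    def test_wraps_origin_on_circular(self):
        # AAA...CGC...AA -> circular run of 5 A crossing the origin
        g = make_genome("AAACGTCGTGCAA")
        recs = find_homopolymers(g, min_len=5)
        assert len(recs) == 1
        r = recs[0]
        assert (r.start, r.length, r.unit) == (12, 5, "A")
        assert r.end > len(g)  # wrapped representation

    def test_masked_run_excluded(self):
        seq = "GC" * 10 + "AAAAA" + "GC" * 10 + "TTTTT" + "GC" * 10
        g = make_genome(seq, circular=False, repeat_mask=[Interval(21, 25)])
        recs = find_homopolymers(g)
        assert [(r.start, r.unit) for r in recs] == [(46, "T")]

    def test_maximality(self):
        g = make_genome("CCCCCC" + "ATAT" + "GGGGG", circular=False)
        for r in find_homopolymers(g):
            left = g.sequence[r.start - 2] if r.start > 1 else None
            right = g.sequence[r.end] if r.end < len(g) else None
            assert left != r.unit and right != r.unit

    def test_matches_planted_truth(self):
        cfg = small_sim_config(seed=77)
        genomes, truth = generate_genomes(cfg)
        for g in genomes:
            planted = truth[g.name].planted_homopolymers
            found = find_homopolymers(g, min_len=5)
            assert {(r.start, r.length, r.unit) for r in found} == {
                (r.start, r.length, r.unit) for r in planted
            }
            n_at_planted = sum(1 for r in planted if r.base_class == "AT")
            assert n_at_planted == {"mito": 22, "plastid": 24}[g.name]

    def test_matches_bruteforce_on_random(self, rng):
        for _ in range(50):
            n = int(rng.integers(10, 300))
            seq = "".join(rng.choice(list("ACGT"), size=n, p=[0.4, 0.1, 0.1, 0.4]))
            g = make_genome(seq)
            got = sorted((r.start, r.length, r.unit) for r in find_homopolymers(g))
            assert got == brute_force_homopolymers(seq)

    def test_rotation_preserves_multiset(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=200, p=[0.4, 0.1, 0.1, 0.4]))
        base = find_homopolymers(make_genome(seq), min_len=3)
        for k in (1, 17, 100):
            rotated = find_homopolymers(make_genome(seq[k:] + seq[:k]), min_len=3)
            assert sorted((r.length, r.unit) for r in rotated) == sorted(
                (r.length, r.unit) for r in base
            )

    def test_records_disjoint_and_bounded(self, rng):
        seq = "".join(rng.choice(list("AT"), size=500))
        g = make_genome(seq)
        recs = find_homopolymers(g, min_len=2)
        assert sum(r.length for r in recs) <= len(seq)
        spans = sorted((r.start, r.end) for r in recs)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 < s2


class TestDinucleotideRepeats:
    def test_basic_array(self):
        g = make_genome("CATATATAC", circular=False)
        recs = find_dinucleotide_repeats(g, min_units=3)
        assert len(recs) == 1
        r = recs[0]
        assert (r.start, r.unit, r.unit_count) == (2, "AT", 3)

    def test_homopolymer_not_an_array(self):
        g = make_genome("G" * 30, circular=False)
        assert find_dinucleotide_repeats(g, min_units=3) == []

    def test_too_short(self):
        g = make_genome("ATAT", circular=False)
        assert find_dinucleotide_repeats(g, min_units=3) == []

    def test_min_units_validation(self):
        with pytest.raises(ConfigError):
            find_dinucleotide_repeats(make_genome("ACGT" * 5), min_units=1)

    def test_matches_bruteforce(self, rng):
        def oracle(seq):
            """Brute force: every (start, unit) with a leftmost-phase maximal array."""
            n = len(seq)
            found = set()
            for i in range(n):
                for k in range(3, n // 2 + 1):
                    unit = seq[i : i + 2]
                    if len(unit) < 2 or unit[0] == unit[1]:
                        continue
                    if i + 2 * k > n or seq[i : i + 2 * k] != unit * k:
                        continue
                    left_ok = i == 0 or seq[i - 1] != unit[1]
                    right_ok = seq[i + 2 * k : i + 2 * k + 2] != unit
                    if left_ok and right_ok:
                        found.add((i + 1, unit, k))
            # keep only maximal k per start
            best = {}
            for s, u, k in found:
                if k > best.get((s, u), 0):
                    best[(s, u)] = k
            return {(s, u, k) for (s, u), k in best.items()}

        for _ in range(30):
            n = int(rng.integers(20, 120))
            seq = "".join(rng.choice(list("AT"), size=n))
            g = make_genome(seq, circular=False)
            got = {(r.start, r.unit, r.unit_count) for r in find_dinucleotide_repeats(g, 3)}
            assert got == oracle(seq)


class TestHomopolymerCensus:
    def test_equal_planted_counts_ratio_one(self):
        seq = "GC" * 5
        parts = []
        for base in ("A", "T", "G", "C"):
            parts.append(base * 6 + "GCATGCAT" if base in "AT" else base * 6 + "ATGCATGC")
        genome = make_genome("GCGCGCGC" + "ATCGATCG".join(parts), circular=False)
        census = homopolymer_class_counts(genome)
        assert census.at_gc_ratio == pytest.approx(1.0)

    def test_counts_by_length(self):
        g = make_genome("GC" * 5 + "AAAAA" + "GC" * 5 + "AAAAAA" + "GC" * 5, circular=False)
        census = homopolymer_class_counts(g)
        tbl = census.table.set_index(["base_class", "length"])["count"]
        assert tbl[("AT", 5)] == 1 and tbl[("AT", 6)] == 1

    def test_infinite_ratio_without_gc_runs(self):
        g = make_genome("GC" * 10 + "AAAAA" + "GC" * 10, circular=False)
        assert homopolymer_class_counts(g).at_gc_ratio == float("inf")


class TestLoadGenome:
    def test_roundtrip_from_files(self, tmp_path):
        from orgmut.simulate import simulate_dataset, write_dataset

        ds = simulate_dataset(small_sim_config(seed=5))
        write_dataset(ds, tmp_path)
        g = load_genome(
            tmp_path / "mito.fasta",
            gff3_path=tmp_path / "mito.gff3",
            masks_bed_path=tmp_path / "mito_repeat_mask.bed",
            numt_bed_path=tmp_path / "mito_numt.bed",
        )
        orig = next(x for x in ds.genomes if x.name == "mito")
        assert g.sequence == orig.sequence
        assert g.effective_size_G == orig.effective_size_G
        assert g.numt_track == orig.numt_track
        assert {f.gene_id for f in g.annotation} == {f.gene_id for f in orig.annotation}
        # CDS features keep kind and reading frame through the GFF3 round trip
        cds = [f for f in g.annotation if f.kind == "CDS"]
        assert cds and all(f.total_length % 3 == 0 for f in cds)

    def test_cds_not_multiple_of_three_rejected(self):
        with pytest.raises(DataError):
            GeneFeature("bad", "CDS", (Interval(1, 10),), "+", 0)

    def test_inconsistent_overlapping_frames_rejected(self):
        a = GeneFeature("a", "CDS", (Interval(1, 30),), "+", 0)
        b = GeneFeature("b", "CDS", (Interval(2, 31),), "+", 0)
        with pytest.raises(DataError):
            make_genome("ACGT" * 25, annotation=[a, b])

    def test_consistent_overlapping_frames_accepted(self):
        a = GeneFeature("a", "CDS", (Interval(1, 30),), "+", 0)
        b = GeneFeature("b", "CDS", (Interval(4, 33),), "+", 0)
        g = make_genome("ACGT" * 25, annotation=[a, b])
        assert len(g.annotation) == 2


class TestRepeatRecord:
    def test_length_invariant(self):
        with pytest.raises(DataError):
            RepeatRecord(start=1, length=7, unit="AT", unit_count=3)

    def test_wrap_containment(self):
        r = RepeatRecord(start=98, length=6, unit="A", unit_count=6, base_class="AT")
        assert r.contains(99)
        assert r.contains(2, genome_length=100)
        assert not r.contains(5, genome_length=100)
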