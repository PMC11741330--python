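"""Filter chain: thresholds, background, masks, numt correction, MNVs."""

import itertools

import pytest

from orgmut.errors import ConfigError, DataError
from orgmut.genomes import Interval
from orgmut.variants import (
    CountsTable,
    LineMeta,
    NuclearCoverageEstimate,
    SiteCounts,
    VariantCall,
    apply_masks,
    background_filter,
    call_candidates,
    classify_homoplasmy,
    estimate_nuclear_coverage,
    flank_homology_check,
    merge_mnv,
    numt_correct_frequency,
    read_site_counts,
)

from conftest import make_genome


def snv(pos=100, ref="A", alt="G", freq=0.5, depth=100, line="M1", genome="mito", **kw):
    return VariantCall(
        line_id=line, genome=genome, position=pos, ref=ref, alt=alt,
        var_type="SNV", raw_frequency=freq, depth=depth, **kw,
    )


COUNTS_TSV = """sample\tgenome\tpos\tref\tdepth\tA\tC\tG\tT\tINS\tDEL
M1\tmito\t10\tA\t100\t60\t0\t40\t0\t.\t.
M1\tmito\t11\tC\t0\t0\t0\t0\t0\t.\t.
M1\tmito\t12\tG\t80\t0\t0\t70\t0\t+AT:10\t-2:5
M1\tmito\t13\tT\t50\t90\t0\t0\t10\t.\t.
M1\tmito\t14\tT\t50\t0\t0\t0\t50\t+XX:3\t.
"""


class TestReadSiteCounts:
    def test_well_formed_and_malformed_rows(self, tmp_path):
        path = tmp_path / "counts.tsv"
        path.write_text(COUNTS_TSV)
        errors = []
        records = list(read_site_counts(path, error_sink=errors))
        # two bad rows: count > depth (line 5) and unknown allele (line 6)
        assert len(records) == 3
        assert len(errors) == 2
        assert any(":5:" in e for e in errors) and any(":6:" in e for e in errors)

    def test_depth_zero_row_retained(self, tmp_path):
        path = tmp_path / "counts.tsv"
        path.write_text(COUNTS_TSV)
        records = list(read_site_counts(path, error_sink=[]))
        assert any(r.depth == 0 for r in records)

    def test_indel_tokens_parsed(self, tmp_path):
        path = tmp_path / "counts.tsv"
        path.write_text(COUNTS_TSV)
        rec = next(r for r in read_site_counts(path, error_sink=[]) if r.position == 12)
        assert rec.allele_counts["+AT"] == 10
        assert rec.allele_counts["-2"] == 5

    def test_count_exceeding_depth_rejected_in_type(self):
        with pytest.raises(DataError):
            SiteCounts("s", "g", 1, "A", 10, {"G": 20})


class TestCallCandidates:
    def test_inclusive_frequency_boundary(self):
        site = SiteCounts("M1", "mito", 5, "A", 100, {"A": 80, "G": 20})
        (call,) = call_candidates([site])
        assert call.raw_frequency == pytest.approx(0.20)
        assert call.passes

    def test_low_depth_flag(self):
        site = SiteCounts("M1", "mito", 5, "A", 49, {"G": 25})
        (call,) = call_candidates([site])
        assert call.filter_flags == {"low_depth"}

    def test_low_freq_flag(self):
        site = SiteCounts("M1", "mito", 5, "A", 100, {"G": 19})
        (call,) = call_candidates([site])
        assert call.filter_flags == {"low_freq"}

    def test_one_call_per_alt_allele(self):
        site = SiteCounts("M1", "mito", 5, "A", 100, {"G": 30, "T": 25, "+C": 21})
        calls = call_candidates([site])
        assert len(calls) == 3
        assert {c.var_type for c in calls} == {"SNV", "insertion"}

    def test_threshold_validation(self):
        with pytest.raises(ConfigError):
            call_candidates([], min_freq=0.0)


class TestBackgroundFilter:
    def test_below_threefold_flagged(self):
        call = background_filter(snv(freq=0.30), [0.12, 0.12, 0.12])
        assert "background" in call.filter_flags  # 0.30 < 3 * 0.12

    def test_zero_background_passes(self):
        call = background_filter(snv(freq=0.30), [0.0, 0.0, 0.0])
        assert call.passes

    def test_exact_threefold_passes(self):
        call = background_filter(snv(freq=0.60), [0.20, 0.20])
        assert call.passes

    def test_empty_panel_rejected(self):
        with pytest.raises(DataError):
            background_filter(snv(), [])


class TestMasksAndHomology:
    def test_mask_flags_and_boundaries(self):
        g = make_genome(
            "ACGT" * 100, name="mito",
            repeat_mask=[Interval(100, 200)], artefact_mask=[Interval(300, 310)],
        )
        calls = [snv(pos=p) for p in (99, 100, 200, 201, 305)]
        out = apply_masks(calls, g)
        flags = {c.position: c.filter_flags for c in out}
        assert flags[99] == set() and flags[201] == set()
        assert flags[100] == {"repeat_copy"} and flags[200] == {"repeat_copy"}
        assert flags[305] == {"artefact"}

    def test_mask_counting(self):
        g = make_genome("ACGT" * 100, name="mito", repeat_mask=[Interval(50, 60)])
        calls = [snv(pos=p) for p in (10, 20, 55, 58, 300)]
        assert sum(c.passes for c in apply_masks(calls, g)) == 3

    def test_planted_duplicate_flagged(self, rng):
        seq = list(rng.choice(list("ACGT"), size=4000))
        pos = 1000
        alt = "T" if seq[pos - 1] != "T" else "A"
        kmer = seq[pos - 31 : pos - 1] + [alt] + seq[pos : pos + 30]
        seq[3000 : 3000 + 61] = kmer  # plant the variant-bearing 61-mer elsewhere
        g = make_genome("".join(seq), name="mito")
        call = snv(pos=pos, ref=seq[pos - 1], alt=alt)
        assert flank_homology_check(call, [g], flank_k=30) is True

    def test_random_alt_not_flagged(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=4000))
        pos = 1500
        alt = "T" if seq[pos - 1] != "T" else "A"
        g = make_genome(seq, name="mito")
        call = snv(pos=pos, ref=seq[pos - 1], alt=alt)
        # oracle: substring search over both strands of the modified k-mer
        modified = seq[: pos - 1] + alt + seq[pos:]
        kmer = modified[pos - 31 : pos + 30]
        from orgmut.variants import revcomp

        present = kmer in (seq + seq[:60]) or revcomp(kmer) in (seq + seq[:60])
        assert flank_homology_check(call, [g], flank_k=30) is present is False

    def test_ref_equals_alt_rejected(self):
        g = make_genome("ACGT" * 100, name="mito")
        with pytest.raises(DataError):
            flank_homology_check(snv(ref="A", alt="A"), [g])


class TestNuclearCoverage:
    def test_direct_arithmetic(self):
        est = estimate_nuclear_coverage(10**8, 2 * 10**7, 150, int(1.2 * 10**8))
        assert est.mean_depth == pytest.approx(100.0)

    def test_all_reads_organelle(self):
        assert estimate_nuclear_coverage(1000, 1000, 150, 10**6).mean_depth == 0.0

    def test_zero_reads(self):
        assert estimate_nuclear_coverage(0, 0, 150, 10**6).mean_depth == 0.0

    def test_invalid_sizes(self):
        with pytest.raises(ConfigError):
            estimate_nuclear_coverage(10, 1, 150, 0)
        with pytest.raises(DataError):
            estimate_nuclear_coverage(10, 20, 150, 10**6)


class TestNumtCorrection:
    def test_quoted_example(self):
        call = snv(freq=0.40, depth=100, alt_count=40)
        out = numt_correct_frequency(call, NuclearCoverageEstimate("s", 20.0), 1)
        assert out.corrected_frequency == pytest.approx(0.50)
        assert out.raw_frequency == pytest.approx(0.40)

    def test_zero_copies_identity(self):
        call = snv(freq=0.40, depth=100)
        out = numt_correct_frequency(call, 20.0, 0)
        assert out.corrected_frequency == out.raw_frequency

    def test_clamp_to_one(self):
        call = snv(freq=0.40, depth=100, alt_count=40)
        out = numt_correct_frequency(call, 80.0, 1)  # expected nuclear >= ref count
        assert out.corrected_frequency == pytest.approx(1.0)

    def test_monotone_in_copies_and_coverage(self):
        freqs = []
        for copies in range(4):
            call = snv(freq=0.30, depth=200, alt_count=60)
            freqs.append(numt_correct_frequency(call, 25.0, copies).corrected_frequency)
        assert freqs == sorted(freqs)
        assert freqs[0] == pytest.approx(0.30)
        covs = [
            numt_correct_frequency(snv(freq=0.3, depth=200, alt_count=60), c, 2).corrected_frequency
            for c in (0.0, 10.0, 30.0, 60.0)
        ]
        assert covs == sorted(covs)


class TestHomoplasmy:
    @pytest.mark.parametrize(
        "kind,freq,expected",
        [
            ("plastid", 0.98, "homoplasmic"),
            ("plastid", 0.979, "heteroplasmic"),
            ("mito", 0.90, "heteroplasmic"),  # strict > for mito
            ("mito", 0.901, "homoplasmic"),
        ],
    )
    def test_cutoffs(self, kind, freq, expected):
        call = snv(freq=freq, corrected_frequency=freq)
        assert classify_homoplasmy(call, kind) == expected

    def test_indels_unclassified(self):
        call = VariantCall(
            line_id="M1", genome="p", position=5, ref="-", alt="A",
            var_type="insertion", raw_frequency=0.99, depth=100,
        )
        assert classify_homoplasmy(call, "plastid") == "unclassified"


class TestMergeMNV:
    def test_adjacent_similar_freqs_merged(self):
        calls = [snv(pos=100, freq=0.95, alt="G"), snv(pos=101, ref="C", alt="T", freq=0.93)]
        merged = merge_mnv(calls)
        assert len(merged) == 1
        mnv = merged[0]
        assert mnv.var_type == "MNV"
        assert mnv.ref == "AC" and mnv.alt == "GT"
        assert mnv.raw_frequency == pytest.approx(0.94)

    def test_nonadjacent_not_merged(self):
        calls = [snv(pos=100), snv(pos=102)]
        assert len(merge_mnv(calls)) == 2

    def test_different_lines_not_merged(self):
        calls = [snv(pos=100, line="M1"), snv(pos=101, line="M2")]
        assert len(merge_mnv(calls)) == 2

    def test_dissimilar_freqs_not_merged(self):
        calls = [snv(pos=100, freq=0.95), snv(pos=101, freq=0.5)]
        assert len(merge_mnv(calls)) == 2


class TestFilterOrderIndependence:
    def test_flags_accumulate_commutatively(self):
        g = make_genome("ACGT" * 250, name="mito", repeat_mask=[Interval(100, 120)])
        wt = [0.1, 0.1, 0.1]  # 3-fold threshold 0.3 > call frequency 0.25

        def chain(order):
            call = snv(pos=110, freq=0.25)
            for step in order:
                if step == "bg":
                    background_filter(call, wt)
                else:
                    apply_masks([call], g)
            return call.filter_flags

        results = {frozenset(chain(p)) for p in itertools.permutations(["bg", "mask"])}
        assert len(results) == 1
        assert results.pop() == frozenset({"background", "repeat_copy"})


class TestCountsTable:
    def test_record_roundtrip(self):
        records = [
            SiteCounts("M1", "mito", 1, "A", 100, {"A": 98, "G": 2}),
            SiteCounts("M1", "mito", 2, "C", 90, {"C": 80, "+T": 10}),
            SiteCounts("W1", "mito", 1, "A", 110, {"A": 110}),
            SiteCounts("W1", "mito", 2, "C", 95, {"C": 95}),
        ]
        table = CountsTable.from_records(records)
        back = {(r.sample_id, r.position): r for r in table.to_records()}
        assert back[("M1", 2)].allele_counts["+T"] == 10
        assert back[("W1", 1)].depth == 110

    def test_tsv_roundtrip(self, tmp_path):
        records = [
            SiteCounts("M1", "mito", 1, "A", 100, {"A": 60, "G": 40, "-1": 5}),
            SiteCounts("W1", "mito", 1, "A", 80, {"A": 80}),
        ]
        table = CountsTable.from_records(records)
        path = tmp_path / "c.tsv"
        table.to_tsv(path)
        table2 = CountsTable.from_tsv(path)
        assert table2.allele_frequency("M1", 1, "G") == pytest.approx(0.4)
        assert table2.allele_frequency("M1", 1, "-1") == pytest.approx(0.05)


class TestLineMeta:
    def test_validation(self):
        with pytest.raises(DataError):
            LineMeta("x", "mutant", 7)
        with pytest.raises(DataError):
            LineMeta("x", "WT", 0)
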