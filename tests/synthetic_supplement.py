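"""Synthetic reconstructions of the study's supplementary variant tables.

The real per-variant supplementary tables (SD1: SNVs with heteroplasmic
frequencies; SD2: small indels with repeat context) are not
redistributable here, so these builders construct synthetic stand-ins
that reproduce the published aggregate structure: per-genome SNV counts
by spectrum class, homoplasmy-band counts (from which frequencies are
drawn uniformly within each band), and per-genome indel counts by
direction and repeat context.  Anything computed from counts alone is
exact by construction; frequency-weighted quantities are approximate
because per-variant frequencies were never published.
"""

import numpy as np

from orgmut.genomes import RepeatRecord
from orgmut.indels import assign_indel
from orgmut.variants import VariantCall

# published per-genome SNV class counts (total 49 mito / 75 plastid)
SD1_CLASS_COUNTS = {
    "mito": {"AT>GC": 23, "GC>AT": 21, "AT>CG": 2, "GC>TA": 2, "AT>TA": 1},
    "plastid": {"AT>GC": 62, "GC>AT": 6, "AT>CG": 3, "GC>TA": 2, "GC>CG": 1, "AT>TA": 1},
}
# published homoplasmy structure: (n_high, high_band, n_low, low_band)
SD1_FREQUENCY_BANDS = {
    "mito": (14, (0.905, 1.0), 35, (0.20, 0.90)),
    "plastid": (50, (0.98, 1.0), 25, (0.20, 0.97)),
}
_CLASS_REPRESENTATIVE = {
    "AT>GC": ("A", "G"), "GC>AT": ("G", "A"), "AT>CG": ("A", "C"),
    "GC>TA": ("G", "T"), "AT>TA": ("A", "T"), "GC>CG": ("G", "C"),
}


def synthetic_sd1(seed=0):
    """SNV table stand-in: published class counts, band-drawn frequencies."""
    rng = np.random.default_rng(seed)
    calls = {"mito": [], "plastid": []}
    for genome, class_counts in SD1_CLASS_COUNTS.items():
        n_high, high, n_low, low = SD1_FREQUENCY_BANDS[genome]
        total = sum(class_counts.values())
        freqs = np.concatenate(
            [rng.uniform(*high, size=n_high), rng.uniform(*low, size=n_low)]
        )
        rng.shuffle(freqs)
        assert len(freqs) == total
        i = 0
        for cls, count in class_counts.items():
            ref, alt = _CLASS_REPRESENTATIVE[cls]
            for _ in range(count):
                calls[genome].append(
                    VariantCall(
                        line_id=f"M{i % 22 + 1}", genome=genome,
                        position=1000 + 17 * i, ref=ref, alt=alt, var_type="SNV",
                        raw_frequency=float(freqs[i]),
                        corrected_frequency=float(freqs[i]), depth=300,
                    )
                )
                i += 1
    return calls


# published indel structure: per genome, per context, (insertions, deletions)
SD2_STRUCTURE = {
    "mito": {"homopolymer": (140, 110), "dinucleotide": (3, 2), "non-repetitive": (1, 2)},
    "plastid": {"homopolymer": (138, 267), "dinucleotide": (2, 3), "non-repetitive": (0, 0)},
}


def synthetic_sd2():
    """Indel table stand-in with a matching synthetic repeat catalogue.

    Returns (assignments per genome) produced through the package's own
    assignment machinery, with loci laid out so that every intended
    context is recovered.
    """
    assignments = {}
    for genome, contexts in SD2_STRUCTURE.items():
        catalogue = []
        calls = []
        cursor = 1000
        idx = 0
        for context, (n_ins, n_del) in contexts.items():
            for kind, n in (("insertion", n_ins), ("deletion", n_del)):
                for _ in range(n):
                    if context == "homopolymer":
                        unit = "A" if idx % 3 else "G"
                        locus = RepeatRecord(
                            start=cursor, length=6, unit=unit, unit_count=6,
                            base_class="AT" if unit in "AT" else "GC",
                        )
                        catalogue.append(locus)
                        pos, seq = cursor - 1, unit
                    elif context == "dinucleotide":
                        locus = RepeatRecord(start=cursor, length=8, unit="AT", unit_count=4)
                        catalogue.append(locus)
                        pos, seq = cursor - 2, "AT"
                    else:
                        pos, seq = cursor, "C"
                    ref, alt = (seq, "-") if kind == "deletion" else ("-", seq)
                    calls.append(
                        VariantCall(
                            line_id=f"M{idx % 22 + 1}", genome=genome, position=pos,
                            ref=ref, alt=alt, var_type=kind,
                            raw_frequency=0.8, depth=300,
                        )
                    )
                    cursor += 20
                    idx += 1
        assignments[genome] = [assign_indel(c, catalogue) for c in calls]
    return assignments
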