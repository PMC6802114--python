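"""SSR scanner vs an exhaustive oracle, motif classes, allele calling."""

import numpy as np
import pytest

from radforge._seq import random_dna, revcomp
from radforge.ssrscan import (
    SsrParams,
    call_ssr_alleles,
    canonical_motif,
    is_primitive,
    motif_classes,
    polymorphism_stats,
    scan_perfect,
    summarize_composition,
)

from _oracles import brute_force_ssr_scan as brute_force_scan


def _loci_tuples(loci):
    return sorted((l.start, l.end, l.motif, l.unit_count) for l in loci)


def test_embedded_dinucleotide_run():
    rng = np.random.default_rng(0)
    left, right = random_dna(rng, 50), random_dna(rng, 50)
    seq = left + "AC" * 5 + right
    hits = [l for l in scan_perfect(seq) if l.motif == "AC"]
    assert any(l.unit_count >= 5 and l.start <= 51 <= l.end for l in hits)


def test_trinucleotide_minimum_four_units():
    seq = "G" * 30 + "AAT" * 4 + "G" * 30
    loci = scan_perfect(seq)
    assert [(l.motif, l.unit_count) for l in loci] == [("AAT", 4)]
    seq3 = "G" * 30 + "AAT" * 3 + "G" * 30
    assert scan_perfect(seq3) == []


def test_dinucleotide_below_five_units_not_reported():
    seq = "GGT" * 10 + "AC" * 4 + "TGG" * 10
    assert all(l.motif != "AC" for l in scan_perfect(seq))


def test_runs_containing_n_are_broken():
    rng = np.random.default_rng(7)
    left, right = random_dna(rng, 40), random_dna(rng, 40)
    seq = left + "ACACACAC" + "N" + "ACACACACAC" + right
    loci = [l for l in scan_perfect(seq) if l.motif == "AC"]
    assert [(l.motif, l.unit_count) for l in loci] == [("AC", 5)]
    assert loci[0].start >= len(left) + 10  # only the post-N run qualifies


def test_scanner_matches_oracle_on_random_sequences_with_planted_ssrs():
    rng = np.random.default_rng(1)
    motifs = ["AC", "AG", "AAT", "ATC", "AGAT", "AAAAT", "AACCCT"]
    for trial in range(60):
        seq = list(random_dna(rng, 600))
        for _ in range(int(rng.integers(0, 4))):
            motif = motifs[int(rng.integers(0, len(motifs)))]
            units = int(rng.integers(3, 9))
            pos = int(rng.integers(0, 600 - units * len(motif)))
            seq[pos : pos + units * len(motif)] = list(motif * units)
        s = "".join(seq)
        assert _loci_tuples(scan_perfect(s)) == brute_force_scan(s)


def test_scan_commutes_with_reverse_complement():
    rng = np.random.default_rng(2)
    for _ in range(10):
        seq = list(random_dna(rng, 400))
        seq[100:116] = list("AGAT" * 4)
        seq[300:310] = list("GT" * 5)
        # pin the run boundaries so planted runs are exact whole-unit maximal
        seq[96:100] = list("CCCC")
        seq[116:120] = list("CCCC")
        seq[298:300] = list("CC")
        seq[310:312] = list("CC")
        s = "".join(seq)
        fwd = scan_perfect(s)
        rev = scan_perfect(revcomp(s))
        n = len(s)
        mirrored = sorted(
            (n - l.end + 1, n - l.start + 1, l.motif, l.unit_count) for l in rev
        )
        assert mirrored == _loci_tuples(fwd)


def test_reported_loci_never_overlap_and_are_maximal():
    rng = np.random.default_rng(3)
    seq = list(random_dna(rng, 500))
    seq[50:70] = list("AC" * 10)
    seq[68:80] = list("GT" * 6)  # erodes into the AC run
    s = "".join(seq)
    loci = scan_perfect(s)
    intervals = sorted((l.start, l.end) for l in loci)
    for (a1, b1), (a2, b2) in zip(intervals, intervals[1:]):
        assert b1 < a2
    for l in loci:
        m = len(l.found_motif)
        left = s[l.start - 1 - m : l.start - 1]
        right = s[l.end : l.end + m]
        assert left != l.found_motif and right != l.found_motif


# ---------------------------------------------------------------------------
# canonical classes


@pytest.mark.parametrize("motif,rep", [("GT", "AC"), ("TAA", "AAT"), ("AC", "AC")])
def test_canonical_motif_examples(motif, rep):
    assert canonical_motif(motif) == rep


def test_canonical_motif_rejects_non_primitive():
    with pytest.raises(ValueError):
        canonical_motif("ACAC")


def test_canonical_is_idempotent_and_orbit_constant():
    rng = np.random.default_rng(4)
    for _ in range(50):
        m = int(rng.integers(2, 7))
        motif = random_dna(rng, m)
        if not is_primitive(motif):
            continue
        rep = canonical_motif(motif)
        assert canonical_motif(rep) == rep
        for i in range(m):
            assert canonical_motif(motif[i:] + motif[:i]) == rep
            rc = revcomp(motif)
            assert canonical_motif(rc[i:] + rc[:i]) == rep


def test_dimer_and_trimer_class_inventories():
    assert motif_classes(2) == {"AC", "AG", "AT", "CG"}
    assert len(motif_classes(3)) == 10


def test_composition_summary_fractions():
    rng = np.random.default_rng(8)
    loci = []
    for part in ["AC" * 6] * 3 + ["AAT" * 5]:
        flank_l, flank_r = random_dna(rng, 40), random_dna(rng, 40)
        found = scan_perfect(flank_l + part + flank_r)
        assert len(found) == 1
        loci.extend(found)
    summary = summarize_composition(loci)
    by_len = summary["by_length"]
    assert by_len.loc[2, "count"] == 3 and by_len.loc[3, "count"] == 1
    assert by_len["fraction"].sum() == pytest.approx(1.0)
    assert summarize_composition([])["by_length"].empty


# ---------------------------------------------------------------------------
# allele calling


def _locus_and_contig(units_ref=10, motif="AC"):
    rng = np.random.default_rng(5)
    left, right = random_dna(rng, 120), random_dna(rng, 120)
    contig = left + motif * units_ref + right
    (locus,) = scan_perfect(contig, contig="tag1")
    return locus, contig, left, right


def test_heterozygote_alleles_recovered_from_spanning_reads():
    locus, contig, left, right = _locus_and_contig()
    reads_8 = [left[-40:] + "AC" * 8 + right[:40]] * 5
    reads_10 = [left[-40:] + "AC" * 10 + right[:40]] * 5
    call = call_ssr_alleles(locus, contig, {"ind1": reads_8 + reads_10})
    assert call.genotypes["ind1"] == (16, 20)
    assert sorted(a for a, _ in call.allele_table) == [16, 20]


def test_read_ending_inside_repeat_is_uninformative():
    locus, contig, left, right = _locus_and_contig()
    partial = left[-40:] + "AC" * 6  # no right flank
    call = call_ssr_alleles(locus, contig, {"ind1": [partial]})
    assert call is None


def test_reverse_complement_reads_are_informative():
    locus, contig, left, right = _locus_and_contig()
    read = revcomp(left[-30:] + "AC" * 9 + right[:30])
    call = call_ssr_alleles(locus, contig, {"ind1": [read] * 4})
    assert call.genotypes["ind1"] == (18, 18)


# ---------------------------------------------------------------------------
# polymorphism statistics


def test_polymorphism_stats_detect_planted_negative_trend():
    """Loci generated with allele number decreasing in motif length show a
    negative correlation with motif length and a significant rank test."""
    rng = np.random.default_rng(6)
    loci = []
    for i in range(300):
        m = int(rng.integers(2, 7))
        n_alleles = max(1, int(rng.poisson(8 - m)) + 1)
        base = 10 * m
        alleles = [(base + m * k, int(rng.integers(1, 20))) for k in range(n_alleles)]
        locus, contig, _, _ = _locus_and_contig()
        import copy

        l = copy.deepcopy(locus)
        l.motif = {2: "AC", 3: "AAT", 4: "AGAT", 5: "AAAAT", 6: "AACCCT"}[m]
        l.alleles = alleles
        loci.append(l)
    stats = polymorphism_stats(loci)
    assert stats.kruskal_p < 0.05
    per = stats.per_locus
    corr = np.corrcoef(per["motif_length"], per["n_alleles"])[0, 1]
    assert corr < 0


def test_polymorphism_stats_degenerate_inputs_are_nan():
    locus, contig, _, _ = _locus_and_contig()
    locus.alleles = [(20, 5)]
    stats = polymorphism_stats([locus])
    assert np.isnan(stats.kruskal_p) and np.isnan(stats.pearson_r)
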