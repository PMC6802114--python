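"""Primer design constraints and electronic PCR vs an exhaustive oracle."""

import numpy as np
import pytest

from radforge._seq import random_dna, revcomp
from radforge.errors import InputError
from radforge.primertools import (
    PrimerConstraints,
    PrimerPair,
    design_candidates,
    epcr,
    find_binding_sites,
    gc_fraction,
    mask_variants,
    melting_temperature,
    select_high_quality,
)
from radforge.ssrscan import SsrLocus


# ---------------------------------------------------------------------------
# masking


def test_mask_examples():
    assert mask_variants("ACGTACG", []) == "ACGTACG"
    assert mask_variants("ACGTACG", [7]) == "ACGTACN"
    masked = mask_variants("ACGTACGT", [1, 3, 8])
    assert masked.count("N") == 3 and len(masked) == 8
    with pytest.raises(InputError):
        mask_variants("ACGT", [5])


# ---------------------------------------------------------------------------
# design


def _at_filler(rng, n):
    return "".join("AT"[i] for i in rng.integers(0, 2, size=n))


def _island():
    """24-mer that satisfies all constraints while every sub-window fails:
    AT edges force GC > 60% on any shorter window."""
    island = "ATA" + "GC" * 7 + "ATTA" + "TAT"
    assert len(island) == 24
    assert island.count("G") + island.count("C") == 14
    return island


def _unique_pair_contig():
    rng = np.random.default_rng(0)
    parts = [
        _at_filler(rng, 60),
        "N",
        _island(),
        "N",
        _at_filler(rng, 64),
        "AC" * 8,
        _at_filler(rng, 64),
        "N",
        _island(),
        "N",
        _at_filler(rng, 64),
    ]
    contig = "".join(parts)
    ssr_start0 = 60 + 1 + 24 + 1 + 64
    locus = SsrLocus(
        contig="c",
        start=ssr_start0 + 1,
        end=ssr_start0 + 16,
        motif="AC",
        found_motif="AC",
        unit_count=8,
        left_flank=ssr_start0,
        right_flank=len(contig) - (ssr_start0 + 16),
    )
    return contig, locus


def _enumerate_valid_pairs(contig, locus, c=PrimerConstraints()):
    """Independent window enumerator computing Tm/GC from scratch."""
    a0, b0 = locus.start - 1, locus.end
    valid_left, valid_right = [], []
    for L in range(c.min_length, c.max_length + 1):
        for s in range(0, a0 - L + 1):
            w = contig[s : s + L]
            gc = (w.count("G") + w.count("C")) / L
            tm = 64.9 + 41.0 * (w.count("G") + w.count("C") - 16.4) / L
            if "N" not in w and c.min_gc <= gc <= c.max_gc and c.min_tm <= tm <= c.max_tm:
                valid_left.append(s)
        for s in range(b0, len(contig) - L + 1):
            w = contig[s : s + L]
            gc = (w.count("G") + w.count("C")) / L
            tm = 64.9 + 41.0 * (w.count("G") + w.count("C") - 16.4) / L
            if "N" not in w and c.min_gc <= gc <= c.max_gc and c.min_tm <= tm <= c.max_tm:
                valid_right.append((s, L))
    pairs = []
    for s in valid_left:
        for rs, L in valid_right:
            product = rs + L - s
            if c.min_product <= product <= c.max_product:
                pairs.append((s, rs, L))
    return pairs


def test_engineered_flanks_contain_exactly_one_valid_pair():
    contig, locus = _unique_pair_contig()
    oracle_pairs = _enumerate_valid_pairs(contig, locus)
    assert len(oracle_pairs) == 1
    candidates = design_candidates(locus, contig)
    assert len(candidates) == 1
    pair = candidates[0]
    s, rs, L = oracle_pairs[0]
    assert pair.left_start == s + 1
    assert pair.right_end == rs + L
    assert pair.left_seq == contig[s : s + 24]
    assert pair.right_seq == revcomp(contig[rs : rs + L])
    assert 125 <= pair.product_size <= 250
    assert 55 <= pair.tm_left <= 65 and 0.40 <= pair.gc_left <= 0.60


def test_all_n_flanks_give_no_candidates():
    contig, locus = _unique_pair_contig()
    blanked = "N" * locus.left_flank + contig[locus.left_flank :]
    blanked = blanked[: locus.end] + "N" * (len(contig) - locus.end)
    assert design_candidates(locus, blanked) == []


def test_low_gc_primer_rejected():
    # 39% GC (wider GC bounds would admit it; the 40% floor must reject)
    w = "GC" * 4 + "AT" * 6 + "G"  # 21-mer, 9 GC = 42.9%... construct 39%:
    w = ("G" * 9 + "A" * 14)[:23]  # 9/23 = 39.1%
    assert gc_fraction(w) < 0.40
    constraints = PrimerConstraints(min_tm=0, max_tm=100)  # isolate the GC rule
    contig, locus = _unique_pair_contig()
    contig2 = contig[: locus.left_flank - 23] + w + contig[locus.left_flank :]
    # the inserted window itself fails GC; candidate set cannot contain it
    for pair in design_candidates(locus, contig2, constraints):
        assert gc_fraction(pair.left_seq) >= 0.40


def test_tightening_constraints_never_enlarges_candidates():
    contig, locus = _unique_pair_contig()
    loose = PrimerConstraints()
    tight_tm = PrimerConstraints(min_tm=58, max_tm=62)
    tight_gc = PrimerConstraints(min_gc=0.45, max_gc=0.55)
    base = len(design_candidates(locus, contig, loose))
    assert len(design_candidates(locus, contig, tight_tm)) <= base
    assert len(design_candidates(locus, contig, tight_gc)) <= base


# ---------------------------------------------------------------------------
# e-PCR


from _oracles import epcr_oracle_sites


def _oracle_sites(primer, contigs, max_mm=2, max_gaps=2):
    return epcr_oracle_sites(primer, contigs, max_mm=max_mm, max_gaps=max_gaps)


def _impl_sites(primer, contigs, **kw):
    out = set()
    for s in find_binding_sites(primer, contigs, **kw):
        anchor_end = s.end - 1 if s.strand == "+" else s.start - 1
        out.add((s.contig, s.strand, anchor_end, s.mismatches))
    return out


def test_binding_sites_match_exhaustive_oracle():
    rng = np.random.default_rng(1)
    contigs = {f"c{i}": random_dna(rng, 250) for i in range(5)}
    # verbatim, 1-substitution, and 2-substitution primers from c0
    base = contigs["c0"][100:121]
    variants = [
        base,
        base[:5] + ("A" if base[5] != "A" else "C") + base[6:],
        revcomp(base),
    ]
    for primer in variants:
        assert _impl_sites(primer, contigs) == _oracle_sites(primer, contigs)


def test_verbatim_primers_give_one_zero_mismatch_product():
    rng = np.random.default_rng(2)
    contigs = {f"c{i}": random_dna(rng, 400) for i in range(4)}
    left = contigs["c1"][50:71]
    right = revcomp(contigs["c1"][200:221])
    pair = PrimerPair(
        locus_id="x", left_seq=left, right_seq=right,
        left_start=51, right_end=221, product_size=171,
        tm_left=60, tm_right=60, gc_left=0.5, gc_right=0.5,
    )
    hits = epcr(pair, contigs)
    assert len(hits) == 1
    (hit,) = hits
    assert hit.contig == "c1" and hit.product_size == 171
    assert hit.forward_site.mismatches == 0 and hit.reverse_site.mismatches == 0


def test_three_mismatch_primer_binds_nowhere():
    rng = np.random.default_rng(3)
    contigs = {"c0": random_dna(rng, 400)}
    primer = list(contigs["c0"][100:121])
    for pos in (2, 8, 14):  # away from the 3' anchor
        primer[pos] = next(c for c in "ACGT" if c != primer[pos])
    assert find_binding_sites("".join(primer), contigs) == []


def test_planted_second_amplicon_is_detected_and_pair_dropped():
    rng = np.random.default_rng(4)
    c0 = random_dna(rng, 500)
    left = c0[50:71]
    right = revcomp(c0[200:221])
    # plant a second amplicon on another contig
    c1 = random_dna(rng, 100) + c0[50:221] + random_dna(rng, 100)
    contigs = {"c0": c0, "c1": c1}
    pair = PrimerPair(
        locus_id="x", left_seq=left, right_seq=right,
        left_start=51, right_end=221, product_size=171,
        tm_left=60, tm_right=60, gc_left=0.5, gc_right=0.5,
    )
    hits = epcr(pair, contigs)
    assert len(hits) == 2
    panel = select_high_quality([(pair, hits)])
    assert panel == []
    single = epcr(pair, {"c0": c0})
    assert select_high_quality([(pair, single)]) == [pair]


def test_hits_invariant_under_reverse_complementing_contigs():
    rng = np.random.default_rng(5)
    contigs = {f"c{i}": random_dna(rng, 300) for i in range(3)}
    left = contigs["c2"][40:61]
    right = revcomp(contigs["c2"][150:171])
    pair = PrimerPair(
        locus_id="x", left_seq=left, right_seq=right,
        left_start=41, right_end=171, product_size=131,
        tm_left=60, tm_right=60, gc_left=0.5, gc_right=0.5,
    )
    fwd_hits = epcr(pair, contigs)
    rc_contigs = {k: revcomp(v) for k, v in contigs.items()}
    rc_hits = epcr(pair, rc_contigs)
    assert len(fwd_hits) == len(rc_hits) == 1
    # coordinates mirror
    n = 300
    assert rc_hits[0].forward_site.start == n - fwd_hits[0].reverse_site.end + 1
    assert rc_hits[0].product_size == fwd_hits[0].product_size


def test_melting_temperature_formula():
    assert melting_temperature("G" * 10 + "A" * 11) == pytest.approx(
        64.9 + 41 * (10 - 16.4) / 21
    )
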