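"""Independent brute-force oracles shared by the unit and acceptance suites.

Each oracle re-derives the expected result by exhaustive enumeration or full
dynamic programming, sharing no code with the implementation it checks.
"""

import itertools

import numpy as np

from radforge._seq import revcomp
from radforge.ssrscan import canonical_motif, is_primitive

MIN_UNITS = {2: 5, 3: 4, 4: 4, 5: 4, 6: 4}


def brute_force_pi(alleles):
    """Mean pairwise difference over all C(n,2) allele pairs."""
    pairs = list(itertools.combinations(alleles, 2))
    return sum(a != b for a, b in pairs) / len(pairs)


def brute_force_readthrough(anchor, scanned, probe_size=50, max_distance=5):
    """Explicit Hamming distance at every offset, first hit in 3'->5' order."""
    if len(anchor) < probe_size or len(scanned) < probe_size:
        return None
    probe = anchor[:probe_size]
    target = revcomp(scanned)
    for o in range(len(target) - probe_size + 1):
        d = sum(a != b for a, b in zip(probe, target[o : o + probe_size]))
        if d <= max_distance:
            boundary = len(scanned) - o
            return None if boundary >= len(scanned) else boundary
    return None


def nw_free_endgap_score(a, b, match=5.0, mismatch=-4.0, gap=-8.0):
    """Full-DP Needleman-Wunsch with free end gaps; no banding, no libraries."""
    n, m = len(a), len(b)
    dp = np.zeros((n + 1, m + 1))
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = dp[i - 1, j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            dp[i, j] = max(dp[i - 1, j] + gap, dp[i, j - 1] + gap, diag)
    return float(max(dp[n, :].max(), dp[:, m].max()))


def brute_force_ssr_scan(seq, min_units=MIN_UNITS):
    """Test every (start, motif length), extend to maximality, keep primitive
    runs meeting the unit minima, then apply the longest-wins overlap rule."""
    n = len(seq)
    runs = set()
    for m in range(2, 7):
        for start in range(n - 2 * m + 1):
            motif = seq[start : start + m]
            if set(motif) - set("ACGT") or not is_primitive(motif):
                continue
            units = 1
            while seq[start + units * m : start + (units + 1) * m] == motif:
                units += 1
            if units < min_units[m]:
                continue
            if start >= m and seq[start - m : start] == motif:
                continue  # not left-maximal
            runs.add((units * m, start, m, units))
    ordered = sorted(runs, key=lambda r: (-r[0], r[1], r[2]))
    taken, out = [], []
    for length, start, m, units in ordered:
        end = start + length
        if any(start < e and s < end for s, e in taken):
            continue
        taken.append((start, end))
        out.append((start + 1, end, canonical_motif(seq[start : start + m]), units))
    return sorted(out)


def epcr_oracle_sites(primer, contigs, max_mm=2, max_gaps=2):
    """Exhaustive binding-site search: every anchor position on both strands,
    recursive enumeration of all same-side-gap alignments within budgets."""
    anchor = primer[-3:]
    head = primer[:-3][::-1]

    def feasible(text, end0):
        found = {}

        def rec(i, j, mm, g, gap_side):
            if mm + g > max_mm + max_gaps:
                return
            if i == len(head):
                found.setdefault(mm + g, []).append((mm, g))
                return
            pos = end0 - j
            if pos >= 0:
                rec(i + 1, j + 1, mm + (head[i] != text[pos]), g, gap_side)
                if gap_side != "p":
                    rec(i, j + 1, mm, g + 1, "t")
            if gap_side != "t" and i < len(head) - 1:
                rec(i + 1, j, mm, g + 1, "p")

        rec(0, 0, 0, 0, "")
        if not found:
            return None
        minimal = found[min(found)]
        ok = [c for c in minimal if c[0] <= max_mm and c[1] <= max_gaps]
        return min(ok)[0] if ok else None

    out = set()
    for name, seq in contigs.items():
        for strand, text in (("+", seq), ("-", revcomp(seq))):
            for e in range(2, len(text)):
                if text[e - 2 : e + 1] != anchor:
                    continue
                mm = feasible(text, e - 3)
                if mm is not None:
                    anchor_end = e if strand == "+" else len(seq) - 1 - e
                    out.add((name, strand, anchor_end, mm))
    return out


def write_toy_vcf(path):
    """Six engineered records; exactly two pass the four VCF-level rules
    (quality >= 300, per-sample depth in [5, 200), MAF > 0.05, >= 10 called)."""
    samples = [f"s{i}" for i in range(12)]
    header = (
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples)
        + "\n"
    )

    def rec(pos, qual, gts, dps):
        cols = [f"{g}:{d}" for g, d in zip(gts, dps)]
        return f"c1\t{pos}\t.\tA\tC\t{qual}\tPASS\t.\tGT:DP\t" + "\t".join(cols)

    het = ["0/1"] * 4 + ["0/0"] * 8
    deep = [10] * 12
    lines = [
        rec(10, 250, het, deep),  # quality 250 < 300
        rec(20, 500, ["0/1"] + ["0/0"] * 11, deep),  # MAF 1/24 <= 0.05
        rec(30, 500, het, [10] * 9 + [2, 2, 2]),  # depth-masked to 9 called
        rec(40, 500, het, deep),  # passes
        rec(50, 500, ["0/1"] * 2 + ["0/0"] * 10, [10] * 10 + [300, 4]),  # passes
        rec(60, 500, ["./."] * 6 + ["0/1"] * 6, deep),  # 6 called < 10
    ]
    path.write_text(header + "\n".join(lines) + "\n")
    return path
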