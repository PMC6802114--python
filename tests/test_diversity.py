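"""Variant filters, nested datasets, and the pi estimator with its oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest

from radforge.diversity import (
    FilterParams,
    VariantSite,
    callable_mask,
    filter_variants,
    make_dataset2,
    make_dataset3,
    site_pi,
    total_pi,
)
from radforge.errors import ConfigurationError, InputError


def _site(genotypes, depths=None, qual=999.0, contig="c1", pos=20, n_alleles=2):
    g = np.array(genotypes)
    d = np.array(depths) if depths is not None else np.full(len(g), 10)
    return VariantSite(
        contig=contig,
        pos=pos,
        ref="A",
        alts=["C", "G", "T"][: n_alleles - 1],
        genotypes=g,
        depths=d,
        qual=qual,
    )


def brute_force_pi(alleles):
    """Mean pairwise difference over all C(n,2) allele pairs (oracle)."""
    pairs = list(itertools.combinations(alleles, 2))
    return sum(a != b for a, b in pairs) / len(pairs)


# ---------------------------------------------------------------------------
# site_pi


@pytest.mark.parametrize(
    "genotypes,expected",
    [
        ([[0, 1], [0, 1]], 2 * 2 / 6),  # counts 2/2 over n=4
        ([[0, 0], [0, 0]], 0.0),  # monomorphic
        ([[0, 1]], 1.0),  # n=2, counts 1/1
    ],
)
def test_site_pi_examples(genotypes, expected):
    assert site_pi(_site(genotypes)) == pytest.approx(expected)


def test_site_pi_needs_two_called_alleles():
    with pytest.raises(InputError):
        site_pi(_site([[-1, -1], [0, -1]]))


def test_site_pi_matches_pairwise_oracle_for_all_small_configurations():
    """Exhaustive over biallelic counts for n <= 12 plus random multiallelic."""
    for n in range(2, 13):
        for k in range(0, n + 1):
            alleles = [0] * k + [1] * (n - k)
            if n % 2:
                alleles = alleles + [-1]  # odd n: pad one missing allele
            g = np.array(alleles + [-1] * (len(alleles) % 2)).reshape(-1, 2)
            site = _site(g)
            called = [a for a in g.reshape(-1) if a != -1]
            if len(called) < 2:
                continue
            assert site_pi(site) == pytest.approx(brute_force_pi(called))
    rng = np.random.default_rng(0)
    for _ in range(50):
        n_ind = int(rng.integers(2, 7))
        g = rng.integers(0, 4, size=(n_ind, 2))
        site = _site(g, n_alleles=4)
        assert site_pi(site) == pytest.approx(brute_force_pi(list(g.reshape(-1))))


def test_site_pi_biallelic_upper_bound():
    for n_ind in (2, 3, 5):
        vals = []
        for k in range(0, 2 * n_ind + 1):
            alleles = [0] * k + [1] * (2 * n_ind - k)
            g = np.array(alleles).reshape(-1, 2)
            vals.append(site_pi(_site(g)))
        n = 2 * n_ind
        assert max(vals) <= n / (2 * (n - 1)) + 1e-12


# ---------------------------------------------------------------------------
# filters


def _toy_vcf(tmp_path):
    from _oracles import write_toy_vcf

    return write_toy_vcf(tmp_path / "toy.vcf")


def test_toy_vcf_filter_keeps_exactly_the_two_engineered_survivors(tmp_path):
    from radforge.diversity import read_vcf

    samples, sites = read_vcf(str(_toy_vcf(tmp_path)))
    assert len(sites) == 6
    kept = filter_variants(sites, FilterParams())
    assert [s.pos for s in kept] == [40, 50]
    # depth-masking really removed the out-of-range calls at pos 50
    assert kept[1].n_called == 10


def test_maf_exactly_at_threshold_is_removed():
    # n = 20 called alleles, 1 alt -> MAF exactly 0.05
    g = np.array([[0, 1]] + [[0, 0]] * 9)
    site = _site(g)
    assert site.maf == pytest.approx(0.05)
    assert filter_variants([site]) == []


@pytest.mark.parametrize("pos,kept", [(10, False), (11, True), (80, True), (81, False)])
def test_dataset2_position_window(pos, kept):
    samples = [f"s{i}" for i in range(10)]
    site = _site([[0, 1]] * 10, pos=pos)
    _, ds2 = make_dataset2([site], samples)
    assert bool(ds2) is kept


def test_dataset2_presence_rule_and_individual_dropping():
    samples = [f"s{i}" for i in range(20)]
    # after dropping 2, 18 remain; 14/18 called (77.8%) fails, 15/18 passes
    g14 = np.array([[0, 1]] * 14 + [[-1, -1]] * 4 + [[0, 1]] * 2)
    g15 = np.array([[0, 1]] * 15 + [[-1, -1]] * 3 + [[0, 1]] * 2)
    s14 = _site(g14, pos=40, depths=[10] * 20)
    s15 = _site(g15, pos=40, depths=[10] * 20)
    kept_samples, ds2 = make_dataset2([s14, s15], samples, samples[18:])
    assert len(kept_samples) == 18
    assert len(ds2) == 1 and ds2[0].n_called == 15


def test_dataset2_unknown_individual_is_configuration_error():
    with pytest.raises(ConfigurationError):
        make_dataset2([], ["a"], ["nope"])


def test_dataset3_one_site_per_contig_first_by_position():
    sites = [
        _site([[0, 1]] * 6, contig="c1", pos=p) for p in (30, 12, 77)
    ] + [_site([[0, 1]] * 6, contig="c2", pos=40)]
    ds3 = make_dataset3(sites)
    assert [(s.contig, s.pos) for s in ds3] == [("c1", 12), ("c2", 40)]


def test_datasets_are_nested(tmp_path):
    from radforge.diversity import read_vcf

    _, sites = read_vcf(str(_toy_vcf(tmp_path)))
    samples = [f"s{i}" for i in range(12)]
    ds1 = filter_variants(sites)
    _, ds2 = make_dataset2(ds1, samples)
    ds3 = make_dataset3(ds2)
    key = lambda s: (s.contig, s.pos)
    assert {key(s) for s in ds3} <= {key(s) for s in ds2} <= {key(s) for s in ds1}


# ---------------------------------------------------------------------------
# total pi


def _depth_table(n_sites, n_samples=4, depth=10, contig="c1"):
    return pd.DataFrame(
        {
            "contig": contig,
            "pos": np.repeat(np.arange(1, n_sites + 1), n_samples),
            "sample": np.tile([f"s{i}" for i in range(n_samples)], n_sites),
            "depth": depth,
        }
    )


def test_total_pi_without_variants_is_zero_with_degenerate_ci():
    est = total_pi([], _depth_table(1000), n_bootstrap=100, seed=0)
    assert est.pi_total == 0.0
    assert (est.ci_low, est.ci_high) == (0.0, 0.0)
    assert est.n_sites_total == 1000


def test_total_pi_single_variant_over_thousand_sites():
    # counts 1/3 over n=4 alleles give site pi = 1*3/C(4,2) = 0.5
    site = _site([[0, 0], [0, 1]], depths=[10, 10], pos=7)
    table = _depth_table(1000, n_samples=2)
    est = total_pi([site], table, n_bootstrap=0, seed=0)
    assert est.pi_total == pytest.approx(0.5 / 1000)
    assert est.n_variant_sites == 1


def test_total_pi_denominator_zero_is_an_error():
    table = _depth_table(100, depth=1)  # below min depth everywhere
    with pytest.raises(InputError):
        total_pi([], table)


def test_total_pi_invariant_to_site_and_individual_permutation():
    rng = np.random.default_rng(1)
    sites = [
        _site(rng.integers(0, 2, size=(4, 2)), pos=p) for p in range(1, 21)
    ]
    table = _depth_table(50)
    a = total_pi(sites, table, n_bootstrap=0, seed=0).pi_total
    rng.shuffle(sites)
    permuted = []
    perm = rng.permutation(4)
    for s in sites:
        s2 = _site(s.genotypes[perm], pos=s.pos)
        permuted.append(s2)
    b = total_pi(permuted, table, n_bootstrap=0, seed=0).pi_total
    assert a == pytest.approx(b)


def test_bootstrap_ci_narrows_with_more_sites():
    rng = np.random.default_rng(2)

    def run(n_sites):
        sites = []
        for p in range(1, n_sites + 1):
            if rng.random() < 0.01:
                g = rng.integers(0, 2, size=(4, 2))
                sites.append(_site(g, pos=p))
        table = _depth_table(n_sites)
        est = total_pi(sites, table, n_bootstrap=400, seed=3)
        return (est.ci_high - est.ci_low) / max(est.pi_total, 1e-12)

    assert run(10_000) < run(1_000)


def test_callable_mask_presence_rule():
    table = _depth_table(3, n_samples=4)
    table.loc[(table["pos"] == 2) & (table["sample"] != "s0"), "depth"] = 1
    mask = callable_mask(table, min_depth=5, min_presence=0.8)
    by_pos = dict(zip(mask["pos"], mask["callable"]))
    assert by_pos == {1: True, 2: False, 3: True}
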