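"""Filter variants into the three nested SNP datasets and estimate diversity.

Total nucleotide diversity divides summed per-site pi by the number of
callable sites, variant or not — the invariant-site denominator is what makes
the estimate a per-base-pair quantity.  The generator plants polymorphism with
expected per-site pi = theta/3 = 0.003, which the estimate should recover.
"""

from radforge import diversity, synthdata

config = synthdata.SimulationConfig(
    seed=3,
    genome_length=20_000,
    n_individuals=12,
    n_pools=1,
    per_site_theta=0.009,
    coverage=10,
)
truth = synthdata.simulate_genome(config)
sites, depth_table = synthdata.truth_variant_sites(truth)

dataset1 = diversity.filter_variants(sites)
samples2, dataset2 = diversity.make_dataset2(dataset1, truth.samples)
dataset3 = diversity.make_dataset3(dataset2)

estimate = diversity.total_pi(
    sites, depth_table, min_depth=5, min_presence=0.8, n_bootstrap=10_000, seed=3
)

print(f"planted SNPs:                {len(sites)}")
print(f"dataset 1 (quality/depth/MAF/presence): {len(dataset1)}")
print(f"dataset 2 (80% presence, 11-80 bp):     {len(dataset2)}")
print(f"dataset 3 (one per contig):             {len(dataset3)}")
print(f"callable sites (denominator):           {estimate.n_sites_total}")
print(f"pi_total = {estimate.pi_total:.5f} "
      f"[{estimate.ci_low:.5f}, {estimate.ci_high:.5f}] "
      f"({estimate.n_bootstrap} bootstrap replicates)")
print()
print("The generating per-site diversity is 0.003; the bootstrap interval")
print("across sites should cover it in ~95% of simulated datasets.")
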