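"""Simulate a ground-truthed two-marker study and write it to disk.

Generates nine populations along a west-to-east transect with the survey
sample sizes, an allele pool of ten 185-bp MHC sequences, 11
microsatellite loci with an isolation-by-distance gradient, and tagged
amplicon reads carrying realistic artifact classes.
"""

from collections import Counter

from mhcpop import SimulationConfig, build_allele_pool, simulate_genotypes, \
    simulate_reads, write_truth

cfg = SimulationConfig(seed=1)
pool = build_allele_pool(cfg)
truth = simulate_genotypes(pool, cfg)
reads = simulate_reads(truth)

print(f"{len(pool)} alleles of {cfg.amplicon_length} bp; "
      f"{len(truth.mhc.individuals)} individuals in "
      f"{cfg.n_populations} populations")
sizes = Counter(len(s) for s in truth.mhc.allele_sets.values())
print("alleles per individual:",
      {k: f"{100 * v / len(truth.mhc):.0f}%" for k, v in sorted(sizes.items())})
classes = Counter(rec["class"] for rec in reads.provenance.values())
print(f"{len(reads.reads)} reads:", dict(classes))
print("-> 'true' reads copy one of the individual's alleles (plus point")
print("   errors); 'chimera'/'noise' are the PCR artifacts the genotyper")
print("   has to remove.")

paths = write_truth(truth, "scratch_example_run/truth")
reads.write_fasta("scratch_example_run/reads.fasta")
print("written:", ", ".join(str(p) for p in paths.values()))
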