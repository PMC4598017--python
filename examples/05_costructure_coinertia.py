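"""Multivariate co-structure of the two markers.

Binary-encodes both genotype tables (each allele a dominant
presence/absence locus), computes Jaccard S3 distances, embeds them by
principal coordinates, runs between-class analysis with populations as
groups, and finally co-inertia with the RV permutation test.
"""

from mhcpop import SimulationConfig, binary_encode, build_allele_pool, \
    simulate_genotypes
from mhcpop.multivar import between_class_analysis, coinertia, \
    jaccard_s3_distance, principal_coordinates, plot_coinertia

cfg = SimulationConfig(seed=5)
pool = build_allele_pool(cfg)
truth = simulate_genotypes(pool, cfg)

mhc_bin, msat_bin, _ = binary_encode(truth.mhc, truth.microsat)
groups = dict(truth.mhc.populations)
bca_mhc = between_class_analysis(
    principal_coordinates(jaccard_s3_distance(mhc_bin)), groups)
bca_msat = between_class_analysis(
    principal_coordinates(jaccard_s3_distance(msat_bin)), groups)
print(f"between-class inertia: MHC "
      f"{bca_mhc.between_inertia_fraction:.3f}, microsat "
      f"{bca_msat.between_inertia_fraction:.3f}")

res = coinertia(bca_mhc, bca_msat, n_perm=999, seed=0)
print(f"RV = {res.rv:.3f}, permutation p = {res.p_value:.3f} "
      f"(population-level test, {res.n_permutations} permutations)")
print("first two co-inertia axes carry "
      f"{100 * res.eigenvalue_fractions[:2].sum():.0f}% of the co-inertia")
print("per-population vector lengths (long = markers disagree):")
print(res.vector_lengths.round(3).sort_values().to_string())
plot_coinertia(res, "coinertia_example.png")
print("arrow plot written to coinertia_example.png")
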