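"""Population differentiation at the two markers.

AMOVA on allele carriages with Jukes-Cantor distances (MHC Phi_ST) and
on gene copies with allele-identity distances (microsatellite F_ST),
plus pairwise matrices and Jost's D.  The neutral marker should show
clearly stronger structure than the near-homogenized adaptive one.
"""

import numpy as np

from mhcpop import SimulationConfig, amova, build_allele_pool, jost_dest, \
    mhc_units, microsat_units, pairwise_fst, pairwise_phist, simulate_genotypes
from mhcpop.diversity import mhc_allele_counts

pops = {f"P{i}": 15 for i in range(6)}
coords = {f"P{i}": (-150.0 + 10 * i, 60.0 - i) for i in range(6)}
cfg = SimulationConfig(samples_per_population=pops, coordinates=coords, seed=4)
pool = build_allele_pool(cfg)
truth = simulate_genotypes(pool, cfg)

d2, labels = mhc_units(truth.mhc, pool.sequences)
res_mhc = amova(d2, labels, n_perm=999, seed=0)
d2, labels = microsat_units(truth.microsat)
res_msat = amova(d2, labels, n_perm=999, seed=0)
print(f"MHC   Phi_ST = {res_mhc.phi_st: .4f} "
      f"({res_mhc.pct_among:.2f}% among populations, p={res_mhc.p_value:.3f})")
print(f"msat  F_ST   = {res_msat.phi_st: .4f} "
      f"({res_msat.pct_among:.2f}% among populations, p={res_msat.p_value:.3f})")

pw_h = pairwise_phist(truth.mhc, pool.sequences, n_perm=99, seed=1)
pw_m = pairwise_fst(truth.microsat, n_perm=99, seed=1)
tri = np.triu_indices(len(pw_h.populations), k=1)
print(f"significant pairs (p<0.05): microsat "
      f"{(np.asarray(pw_m.p_values)[tri] < 0.05).sum()}/{len(tri[0])}, "
      f"MHC {(np.asarray(pw_h.p_values)[tri] < 0.05).sum()}/{len(tri[0])}")

d = jost_dest(mhc_allele_counts(truth.mhc))
print(f"MHC Jost's D over all populations = {d:.4f}")
print("-> the neutral marker carries the population structure; the")
print("   adaptive marker's differentiation is an order of magnitude lower.")
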