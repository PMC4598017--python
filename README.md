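# mhcpop

Adaptive versus neutral population genetic structure from amplicon MHC
genotypes and microsatellites — a toolkit for wildlife immunogenetics
surveys that ask whether spatial patterns at an adaptive immune locus are
shaped by balancing selection, local adaptation, or simply by the gene
flow and drift visible at neutral markers.

The package covers the full comparative workflow end to end:

1. **Simulation** of a ground-truthed study design: an allele pool of
   185-bp MHC class II exon-2 sequences, 2–5 co-amplifying alleles per
   individual (loci unresolvable), 11 diploid microsatellite loci, nine
   sampling regions on a continental map with an isolation-by-distance
   gradient at the neutral marker and near-homogenized MHC frequencies,
   and MID-tagged pyrosequencing-style reads with point errors, chimeras
   and off-target noise.
2. **Amplicon genotyping**: exact tag/primer demultiplexing, variant
   tabulation with the maximum per-amplicon frequency
   (MPAF = max over carriers of the variant's within-individual read
   proportion), a deterministic artifact-classification ladder
   (true alleles at MPAF ≥ 4 %; 1–2 bp parental artifacts, stop-codon and
   frameshift products, singletons, replicate-unverified variants below
   it), depth-gated genotype calls (≥ 150 reads), and replicate
   concordance.
3. **Population genetics**: H_o / unbiased H_e, rarefied allelic richness
   A_r (exact hypergeometric rarefaction), nucleotide diversity π,
   MHC-like genotype diversity (GT, P_GT), the individual
   allele-diversity index A, Jukes–Cantor distances, one-level AMOVA
   Φ_ST / F_ST with permutation tests, pairwise differentiation matrices
   and Jost's D_EST.
4. **Co-structure**: binary (dominant) encoding, Jaccard S3 distances,
   principal coordinates with Lingoes correction, between-class analysis
   with populations as groups, and co-inertia analysis with the RV
   coefficient and its permutation test.
5. **Isolation by distance**: log great-circle distances, simple and
   partial Mantel tests (residual-permutation method), and the Pearson
   correlation between per-population diversity measures.
6. **Selection statistics**: Nei–Gojobori dN/dS with a codon-bootstrap
   Z-test of positive selection, and likelihood-ratio arithmetic
   (2ΔlnL ~ χ²) for externally fitted nested codon models.

## The statistics in brief

* **MPAF rule** — a variant is a credible allele when its read share
  within at least one individual reaches the threshold where known
  alleles live (4 %), it has an open reading frame, and it recurs in a
  second individual or a replicate run.
* **AMOVA** — Φ_ST = σ²_among / (σ²_among + σ²_within) from squared
  inter-unit molecular distances (JC69 between allele carriages for MHC,
  number of different alleles between gene copies for microsatellites);
  significance by shuffling units among populations.
* **Jost's D** — D = (k/(k−1)) · (H_T − H_S)/(1 − H_S) with
  nearly unbiased heterozygosity estimators.
* **RV coefficient** — total co-inertia of the two (population-level)
  score tables normalized by their own inertias; RV ∈ [0, 1], tested by
  row permutation.
* **Mantel r** — Pearson correlation of distance-matrix triangles;
  one-sided permutation significance; the partial variant correlates
  residuals after removing a control matrix (neutral differentiation).
* **NG86** — synonymous/nonsynonymous sites counted per codon position,
  differences averaged over shortest mutational pathways,
  Jukes–Cantor-corrected; Z = (dN − dS)/SE with a codon bootstrap.

## Worked example

The whole analysis runs from one config (see `examples/08_full_pipeline.py`;
all examples live in `examples/` and each prints what it computes):

```python
from mhcpop import run_pipeline, validate_config

cfg = validate_config({
    "outdir": "demo", "seed": 11,
    "simulation": {"samples_per_population": {p: 12 for p in
        ["RU", "YK", "NWT", "NU", "BC", "AB", "SK", "MB", "ON"]},
        "read_model": {"mean_depth": 400}},
    "ibd": {"n_perm": 499, "exclude": ["RU"]},
})
run_pipeline(cfg)
```

which prints (seed 11):

```
genotyping: 76 called, accuracy vs truth 100.0%
AMOVA: microsat 18.91% among populations vs MHC -1.15%
significant pairs: microsat 36/36, MHC 0/36
Mantel IBD: microsat r=0.40 (p=0.040), MHC r=0.21 (p=0.152)
co-inertia RV = 0.72, p = 0.718
```

Reading the numbers: every genotype called from the noisy reads matches
the simulated truth; the neutral microsatellites are strongly structured
(19 % of molecular variance among regions, all pairwise F_ST significant,
significant isolation by distance once the transoceanic RU region is
excluded) while the adaptive MHC shows essentially no differentiation, no
IBD, and no significant global co-structure with the neutral marker —
the signature expected when balancing selection homogenizes an immune
locus across a structured range.

A thin CLI mirrors the library for shell use:

```bash
mhcpop simulate --outdir demo --seed 1
mhcpop genotype --reads demo/reads.fasta --tags demo/tags.csv --min-depth 150
mhcpop run --config config.yml
```

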