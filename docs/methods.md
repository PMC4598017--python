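# Methods

This note documents the models behind `mhcpop`, the parameters that
matter, the numerical conventions, and what the synthetic study design
does and does not establish about real data.

## The scientific setting

Classical MHC class II genes are frequently multi-locus in carnivores:
several paralogous loci co-amplify with one primer pair, individuals
show 2–5 distinct alleles, and alleles cannot be ascribed to loci. A
survey therefore genotypes individuals as *allele sets*, validates those
sets from noisy amplicon reads, and asks whether the adaptive locus is
spatially structured like the genome-wide neutral background
(microsatellites) or decoupled from it. Weaker-than-neutral MHC
differentiation with no isolation by distance (IBD) is the classic
fingerprint of balancing selection; stronger, environment-correlated
structure would suggest local adaptation.

## Synthetic study design

### Allele pool

`build_allele_pool` derives a pool (default 10 alleles) from one random
ancestral 185-bp open reading frame by 3 + Poisson(4) point
substitutions per allele, rejecting candidates with internal stop codons
(frame offset 2, so positions 3–185 encode 61 codons) or fewer than 3
nucleotide differences from any other allele. Two consequences are
intentional:

* carrier-weighted nucleotide diversity lands near 0.05/site, the level
  typical of class II exon-2 allele sets (independent random sequences
  would sit at ~75 % mismatch and saturate Jukes–Cantor corrections);
* the ≥ 3-difference floor makes the genotyper's "1–2 bp artifact" rule
  meaningful: no true allele can be mistaken for a sequencing artifact
  of another.

### Population frequencies: the F-model with a spatial walk

Each marker class has a `MarkerModel(divergence_F, ibd_slope)`. Per
population, allele frequencies are drawn as
Dirichlet(base · (1 − F)/F), which has E[p] = base and
Var(p_i) = base_i(1 − base_i) · F, so the expected fixation index equals
the target F. `F = 0` returns the base vector exactly (the
zero-divergence limit used in null tests).

IBD is induced by a random walk of the base vector along the range:
populations are ordered by their projection onto the first principal
axis of the km-scaled coordinate cloud (longitudes unwrapped across the
date line), and each step perturbs log-frequencies with variance
`ibd_slope · log1p(step_km)`. Ordering by the dominant axis rather than
raw longitude matters on realistic maps whose neighbouring regions
alternate in latitude; a 2-D Gaussian-field alternative with variogram
proportional to log-distance was evaluated and rejected because the log
compresses the near/far contrast until the Mantel signal vanishes.

Defaults are the survey conditions the package emulates: nine regions
(RU…ON) with samples 26, 16, 35, 56, 41, 19, 13, 28, 35 (269 total);
microsatellites F = 0.10 with slope 0.06 per log-km — calibrated so the
realized multilocus Mantel r on the default map, with the transoceanic
RU region excluded, matches the strong empirical IBD reported for such
systems (r ≈ 0.54) — and MHC F = 0.01 with slope 0 (homogenized).
Allele-set sizes follow the observed distribution
{2: 26.7 %, 3: 30.4 %, 4: 39.9 %, 5: 2.9 %}.

### Reads

Per individual, total depth is negative-binomial (default mean 500,
dispersion 1.0, i.e. CV ≈ 1, mirroring the heavy coverage variation of
pooled pyrosequencing libraries; a sizable minority of individuals falls
under the 150-read genotyping floor, as in real runs). Reads are
allocated to the individual's alleles with log-normal amplification
biases (sd 0.3), then corrupted: probability 0.01 of being an off-target
random sequence, 0.02 of being a single-crossover chimera of two of the
individual's alleles, and independent per-base substitution errors at
10⁻³. Every read carries a MID tag pair (10-mers, pairwise Hamming
distance ≥ 6, synthesized to cover the cohort) and both primers; the
provenance table records each read's truth, making calling accuracy
exactly measurable.

What the generator does **not** model: quality scores, indel and
homopolymer errors (454's signature failure mode), within-locus allele
pairing, linkage between loci, coalescent genealogies, and any
correlation between MHC and microsatellite diversity. Passing tests
therefore demonstrate correctness of the statistical machinery under a
clean frequency-based model, not robustness to indel-heavy chemistry.

## Genotyping

MPAF — the maximum over carriers of a variant's share of that
individual's retained reads — is computed with *all* retained reads of
the individual in the denominator. The classification ladder is
deterministic and ordered to be conservative toward artifacts: below the
0.1 % floor → discarded (`BELOW_FLOOR`, a label added so every variant
keeps exactly one audit-trailed label); whitelisted known allele →
true; MPAF ≥ 4 % with clean ORF and ≥ 2 carriers or replicate
confirmation → true; otherwise 1–2 bp parental artifact (parent must
co-occur in every carrier), stop codon, frameshift, singleton,
replicate-unverified, or candidate.

One property worth knowing: recurrent chimeras (two individuals sharing
an allele pair produce identical recombinant sequences whenever the
crossover falls between the same pair of differing sites) can clear the
promotion bar through low-depth individuals, where a couple of reads
exceed 4 %. These false "true alleles" almost never reach the 4 %
within-individual share in a *called* (≥ 150 reads) individual, so
genotype accuracy stays ≥ 99 % in testing; the variant table should
nevertheless be read as a candidate list, exactly as in real surveys.
The frameshift label is retained but essentially unreachable under the
default filters, because off-length inserts are already discarded at
demultiplexing.

`complete_pct` in replicate concordance rounds half away from zero to an
integer percentage.

## Population statistics

* H_e uses Nei's small-sample correction 2n/(2n−1); H_o, H_e and A_r
  average over loci, dropping missing genotypes per locus.
* Rarefaction is the exact hypergeometric expectation
  Σ_i [1 − C(N−N_i, g)/C(N, g)] computed with log-gamma, with `g`
  defaulting to the smallest gene-copy count over population × locus
  cells.
* AMOVA treats the supplied molecular distance as the squared Euclidean
  distance of the variance decomposition: the JC69 value for MHC allele
  carriages, the number of different alleles for microsatellite
  pseudo-haplotypes (phase is arbitrary, units are permuted jointly
  across loci), and 1 − S3 for binary rows. Negative variance components
  are reported as-is (Φ_ST slightly below 0 on null data is expected
  estimator behaviour). Permutation p-values use (b+1)/(m+1) smoothing,
  one-sided.
* Jost's D uses the k-population estimator with each population's Σp²
  replaced by Σ n_i(n_i−1)/(n(n−1)) and H_T from unweighted mean
  frequencies; D = 1 for fixed differences and ≤ 0 in expectation for
  identical populations.
* MHC relative allele frequencies use the carriage-count denominator
  (sum of allele-set sizes per region), the convention that keeps
  frequencies summing to 1.

## Multivariate co-structure

Distances go to ordination via classical scaling; when the matrix is not
Euclidean-embeddable the Lingoes constant (−λ_min added to off-diagonal
squared distances) is applied by default. Between-class analysis takes
the principal axes of the size-weighted group-centroid cloud and reports
the between-class inertia fraction. Axes are oriented so the
largest-magnitude score is positive, making results platform-stable.

Co-inertia of two *between-class* ordinations runs at the population
level: the analyzed tables are the group-size-weighted centroid tables,
and the RV permutation test permutes population rows. This choice is
deliberate: permuting individual rows of between-class score tables
detects the group labels themselves (both tables' axes are chosen to
separate the same groups), yielding spuriously significant RV even when
one marker is pure noise. The population-level test matches the
group-aggregated co-inertia composition used in practice and has the
low power appropriate to nine populations. Ordinations without group
information are compared row-wise (that path has a uniform null, which
the test suite checks).

## Isolation by distance

Great-circle distances (haversine, R = 6371 km) are natural-log
transformed; the base only rescales, so Mantel r is unaffected by the
choice. Mantel tests are one-sided for positive association by default
(the IBD hypothesis); the partial test correlates residuals from linear
fits on the control matrix and permutes the residual *matrix* of the
focal matrix, Legendre's method. Raw F_ST is used by default with
F_ST/(1−F_ST) linearization behind a flag, and outlying populations
(e.g. a transoceanic region) can be excluded by name rather than being
hard-coded.

## Selection statistics

NG86 counts synonymous sites as the per-position fraction of one-step
changes that preserve the amino acid, with changes to stop codons
counted as nonsynonymous, so S + N = 3 per codon exactly. Differences in
multi-substitution codons average over all shortest pathways, excluding
pathways through stop codons (falling back to all pathways only if every
one is blocked). Proportions are Jukes–Cantor corrected with a
saturation error at p ≥ 0.75; pairs are averaged; the Z-test standard
error comes from a seeded codon bootstrap rather than the analytic
variance. The LRT module deliberately does *no* likelihood
optimization: it consumes externally fitted (label, lnL, k) records and
performs the 2ΔlnL ~ χ²(Δk) arithmetic, with a 10⁻⁶ tolerance for
printed-precision likelihoods.

## Pipeline and reproducibility

A single YAML config validates strictly (unknown keys are errors, with
paths into the document). Every stage seed derives from the global seed
by SHA-256 of `"{seed}:{stage}"` (mod 2³¹), so stages are independently
rerunnable and full runs are bit-reproducible; the manifest hashes every
artifact. The pipeline's statistics run on the *called* genotypes, not
the simulation truth, so the summary reflects the whole chain including
genotyping error.

Problem sizes in the shipped tests are chosen for desk-scale runs: the
fixation-index recovery check uses 9 × 50 individuals over 20 seeds per
target F, genotype recovery uses 5 × 100 individuals at depth 500, and
the headline-contrast check uses 9 × 20 individuals with 99–199
permutations over 20 seeds. These sizes give comfortable margins on the
assertions they support while keeping the default test run in tens of
seconds.

## Known limitations

* No indel/homopolymer error model, hence the frameshift branch of the
  classifier is untestable on simulated reads except by construction.
* The IBD walk is one-dimensional along the range's dominant axis;
  strongly two-dimensional maps will show attenuated distance–divergence
  monotonicity for off-axis population pairs.
* Jost's D pairwise significance requires per-individual allele data and
  is permutation-costly; the pipeline reports the statistic matrix with
  p-values only where configured.
* The NG86 Z-test assumes independent codons (bootstrap over codon
  columns); recombination within the fragment would violate it.
* Microsatellite mutation is not modelled (no stepwise mutation);
  allele labels are arbitrary, so R_ST-style statistics are out of
  scope.
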