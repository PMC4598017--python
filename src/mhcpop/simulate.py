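"""Ground-truthed simulation of the two-marker study design.

The generator emulates a range-wide carnivore survey: nine sampling
regions along a continental transect, each individual genotyped at a
multi-locus MHC class II exon-2 amplicon (2-5 co-amplifying alleles per
individual, loci unresolvable) and at 11 codominant microsatellite loci.
Neutral structure follows an isolation-by-distance gradient while MHC
allele frequencies are nearly homogenized across regions - the contrast
the downstream statistics are designed to detect.

Population allele frequencies follow the F-model: each region's frequency
vector is Dirichlet-distributed around a (possibly spatially drifting)
base vector with concentration ``(1 - F) / F`` so that the expected
fixation index equals the target ``divergence_F``.  Amplicon reads carry
the artifact classes that plague pyrosequencing amplicon data: point
errors, single-crossover chimeras between an individual's own alleles,
and low-frequency off-target noise sequences.  Every read is tagged with
its truth so that allele-calling accuracy is measurable exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .tables import MHCGenotypeTable, MicrosatGenotypeTable

STOP_CODONS = {"TAA", "TAG", "TGA"}
BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Forward/reverse amplification primers of the 185-bp class II DRB exon 2
#: fragment (DRB-5c / DRB-3c).
FORWARD_PRIMER = "TCAATGGGACGGAGCGGGTGC"
REVERSE_PRIMER = "CCGCTGCACAGTGAAACTCTC"

#: Default sampling design: nine regions spanning eastern Russia and the
#: Canadian range west to east, with the survey's sample sizes (13-56,
#: 269 individuals in total) and approximate region centroids (lon, lat).
DEFAULT_REGIONS: dict[str, tuple[int, tuple[float, float]]] = {
    "RU": (26, (160.0, 62.0)),
    "YK": (16, (-135.0, 63.0)),
    "NWT": (35, (-119.0, 64.0)),
    "NU": (56, (-100.0, 65.0)),
    "BC": (41, (-125.0, 55.0)),
    "AB": (19, (-115.0, 55.0)),
    "SK": (13, (-106.0, 55.0)),
    "MB": (28, (-98.0, 52.0)),
    "ON": (35, (-89.0, 50.0)),
}

#: Observed distribution of the number of MHC alleles per individual:
#: two 26.7%, three 30.4%, four 39.9%, five 2.9% (normalized).
DEFAULT_ALLELE_COUNT_WEIGHTS = {2: 0.267, 3: 0.304, 4: 0.399, 5: 0.029}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# configuration


@dataclass
class ReadModel:
    """Amplicon read-generation parameters.

    ``mean_depth``/``depth_dispersion`` parameterize a negative-binomial
    per-individual total depth (variance = m + m^2/k), reproducing the
    heavy coverage variation typical of pooled pyrosequencing libraries.
    """

    mean_depth: float = 500.0
    depth_dispersion: float = 1.0
    per_base_error_rate: float = 1e-3
    chimera_rate: float = 0.02
    noise_variant_rate: float = 0.01
    allele_amplification_bias_sd: float = 0.3


@dataclass
class MarkerModel:
    """Divergence target for one marker class.

    divergence_F: expected fixation index among populations, in [0, 1).
    ibd_slope: increase of divergence with log geographic distance
        (per log-km); 0 disables the spatial gradient.
    """

    divergence_F: float
    ibd_slope: float = 0.0


@dataclass
class SimulationConfig:
    n_populations: int = 9
    samples_per_population: dict[str, int] | None = None
    coordinates: dict[str, tuple[float, float]] | None = None
    mhc_pool_size: int = 10
    amplicon_length: int = 185
    frame_offset: int = 2
    alleles_per_individual_weights: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_ALLELE_COUNT_WEIGHTS)
    )
    n_microsat_loci: int = 11
    microsat_alleles_per_locus: int = 8
    mhc: MarkerModel = field(default_factory=lambda: MarkerModel(0.01, 0.0))
    microsat: MarkerModel = field(default_factory=lambda: MarkerModel(0.10, 0.06))
    read_model: ReadModel = field(default_factory=ReadModel)
    forward_mids: list[str] | None = None
    reverse_mids: list[str] | None = None
    forward_primer: str = FORWARD_PRIMER
    reverse_primer: str = REVERSE_PRIMER
    seed: int = 0

    def __post_init__(self) -> None:
        if self.samples_per_population is None or self.coordinates is None:
            names = list(DEFAULT_REGIONS)[: self.n_populations]
            if len(names) < self.n_populations:
                names += [f"P{i}" for i in range(len(names), self.n_populations)]
            if self.samples_per_population is None:
                self.samples_per_population = {
                    n: DEFAULT_REGIONS[n][0] if n in DEFAULT_REGIONS else 30
                    for n in names
                }
            if self.coordinates is None:
                self.coordinates = {
                    n: DEFAULT_REGIONS[n][1]
                    if n in DEFAULT_REGIONS
                    else (-150.0 + 10.0 * i, 60.0)
                    for i, n in enumerate(names)
                }
        self.n_populations = len(self.samples_per_population)
        self.validate()

    def validate(self) -> None:
        w = self.alleles_per_individual_weights
        total = sum(w.values())
        if not math.isclose(total, 1.0, abs_tol=5e-3):
            raise ValueError(f"allele-count weights sum to {total}, expected 1")
        self.alleles_per_individual_weights = {k: v / total for k, v in w.items()}
        for m, name in ((self.mhc, "mhc"), (self.microsat, "microsat")):
            if not 0 <= m.divergence_F < 1:
                raise ValueError(f"{name}.divergence_F must lie in [0, 1)")
        if self.amplicon_length - self.frame_offset < 3:
            raise ValueError("amplicon too short to hold a codon in frame")
        if self.frame_offset not in (0, 1, 2):
            raise ValueError("frame_offset must be 0, 1 or 2")
        if self.read_model.mean_depth < 0:
            raise ValueError("mean_depth must be >= 0")
        if max(w) > self.mhc_pool_size:
            raise ValueError("allele-set sizes exceed the allele pool")

    @property
    def population_names(self) -> list[str]:
        return list(self.samples_per_population)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=str)


# ---------------------------------------------------------------------------
# allele pool


@dataclass
class AllelePool:
    """Distinct amplicon-length allele sequences, id -> DNA."""

    sequences: dict[str, str]
    frame_offset: int

    @property
    def ids(self) -> list[str]:
        return list(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)


def _random_orf(rng: np.random.Generator, length: int, frame: int) -> str:
    """Random sequence whose in-frame translation has no internal stop."""
    head = "".join(rng.choice(list(BASES), size=frame))
    n_codons = (length - frame) // 3
    tail_len = (length - frame) % 3
    codons = []
    while len(codons) < n_codons:
        c = "".join(rng.choice(list(BASES), size=3))
        if c not in STOP_CODONS:
            codons.append(c)
    tail = "".join(rng.choice(list(BASES), size=tail_len))
    return head + "".join(codons) + tail


def _has_internal_stop(seq: str, frame: int) -> bool:
    body = seq[frame:]
    n = len(body) // 3
    return any(body[3 * i : 3 * i + 3] in STOP_CODONS for i in range(max(n - 0, 0)))


def build_allele_pool(config: SimulationConfig) -> AllelePool:
    """Generate ``mhc_pool_size`` allele sequences of the amplicon length.

    Alleles are derived from a common ancestral sequence by point
    substitutions (a handful per allele, as in real class II exon-2
    allele sets) so that pairwise distances stay far from saturation;
    every pair differs by at least 3 nucleotides so the 1-2 bp artifact
    rule downstream is exercisable, and no allele carries an internal
    stop codon in the configured frame.
    """
    if config.mhc_pool_size < 2:
        raise ValueError("allele pool must contain at least 2 alleles "
                         "(genotypes carry 2-5 alleles)")
    L, frame = config.amplicon_length, config.frame_offset
    if 4 ** L < config.mhc_pool_size:
        raise ValueError("pool size exceeds the sequence space")
    rng = np.random.default_rng(config.seed)
    ancestor = _random_orf(rng, L, frame)
    seqs: list[str] = []
    attempts = 0
    while len(seqs) < config.mhc_pool_size:
        attempts += 1
        if attempts > 1000 * config.mhc_pool_size:
            raise ValueError("could not satisfy pool constraints "
                             "(length/pool size combination too tight)")
        # a handful of substitutions per allele gives nucleotide diversity
        # around 0.05/site, typical of class II exon-2 allele sets
        n_mut = 3 + rng.poisson(4)
        pos = rng.choice(L, size=min(n_mut, L), replace=False)
        s = list(ancestor)
        for p in pos:
            s[p] = rng.choice([b for b in BASES if b != s[p]])
        cand = "".join(s)
        if _has_internal_stop(cand, frame):
            continue
        if any(_hamming(cand, other) < 3 for other in seqs):
            continue
        seqs.append(cand)
    ids = [f"Gu{i + 1:02d}" for i in range(len(seqs))]
    return AllelePool(dict(zip(ids, seqs)), frame)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


# ---------------------------------------------------------------------------
# genotypes


@dataclass
class TruthSet:
    """Everything the simulation knows, for downstream oracles."""

    pool: AllelePool
    mhc: MHCGenotypeTable
    microsat: MicrosatGenotypeTable
    coordinates: dict[str, tuple[float, float]]
    mhc_population_frequencies: "np.ndarray"  # pops x alleles
    microsat_population_frequencies: dict[str, "np.ndarray"]  # locus -> pops x alleles
    config: SimulationConfig


def _haversine_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    lon1, lat1, lon2, lat2 = map(math.radians, (*a, *b))
    dlat, dlon = lat2 - lat1, lon2 - lon1
    h = math.sin(dlat / 2) ** 2 + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2) ** 2
    return 2 * 6371.0 * math.asin(min(1.0, math.sqrt(h)))


def _transect_positions(
    coords: Mapping[str, tuple[float, float]]
) -> tuple[list[str], dict[str, float]]:
    """Populations ordered along the dominant geographic axis.

    Longitudes are unwrapped across the date line, coordinates scaled to
    km (equirectangular at the mean latitude), and populations projected
    onto the first principal axis of the point cloud.  Returns the
    ordering and each population's position (km) along that axis, so the
    drift walk measures separation along the range rather than
    north-south zigzag between neighbours.
    """
    names = list(coords)
    lon = np.array([c[0] - 360.0 if c[0] > 0 else c[0] for c in coords.values()])
    lat = np.array([c[1] for c in coords.values()])
    mean_lat = math.radians(lat.mean())
    km_per_deg = 2 * math.pi * 6371.0 / 360.0
    xy = np.column_stack([lon * km_per_deg * math.cos(mean_lat),
                          lat * km_per_deg])
    xy = xy - xy.mean(axis=0)
    _, _, Vt = np.linalg.svd(xy, full_matrices=False)
    proj = xy @ Vt[0]
    if proj[np.argmax(np.abs(proj))] < 0:
        proj = -proj
    positions = dict(zip(names, proj))
    order = sorted(names, key=lambda n: positions[n])
    return order, positions


def _drift_bases(
    base: np.ndarray,
    coords: Mapping[str, tuple[float, float]],
    slope: float,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Random-walk the base frequency vector along the range transect.

    Per-step variance on the log-frequency scale is ``slope`` times the
    log of the step's length along the transect axis, so divergence
    accumulates monotonically with separation - the simplest mechanism
    producing an isolation-by-distance signal.
    """
    if slope <= 0:
        return {p: base.copy() for p in coords}
    order, positions = _transect_positions(coords)
    out: dict[str, np.ndarray] = {}
    z = np.log(base)
    out[order[0]] = base.copy()
    for prev, cur in zip(order, order[1:]):
        step_km = abs(positions[cur] - positions[prev])
        sd = math.sqrt(slope * math.log1p(step_km))
        z = z + rng.normal(0.0, sd, size=len(base))
        p = np.exp(z - z.max())
        out[cur] = p / p.sum()
    return {p: out[p] for p in coords}


def _population_frequencies(
    base_by_pop: Mapping[str, np.ndarray],
    F: float,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Dirichlet draw with concentration (1-F)/F; F=0 returns the base."""
    out = {}
    for pop, base in base_by_pop.items():
        if F == 0:
            out[pop] = base.copy()
        else:
            conc = base * (1 - F) / F
            out[pop] = rng.dirichlet(np.maximum(conc, 1e-9))
    return out


def simulate_genotypes(pool: AllelePool, config: SimulationConfig) -> TruthSet:
    """Draw per-population allele frequencies and individual genotypes.

    MHC genotypes are allele *sets* sampled without replacement (loci are
    unresolvable by design, so no within-locus pairing is modelled);
    microsatellite genotypes are two independent gene copies per locus
    from the population's frequency vector.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    pops = config.population_names
    coords = config.coordinates

    # --- MHC frequencies
    k = len(pool)
    base_mhc = rng.dirichlet(np.full(k, 1.0))
    base_mhc = np.maximum(base_mhc, 1e-4)
    base_mhc /= base_mhc.sum()
    mhc_bases = _drift_bases(base_mhc, coords, config.mhc.ibd_slope, rng)
    mhc_freqs = _population_frequencies(mhc_bases, config.mhc.divergence_F, rng)

    # --- microsatellite frequencies, one base vector per locus
    loci = [f"L{i + 1:02d}" for i in range(config.n_microsat_loci)]
    msat_freqs: dict[str, dict[str, np.ndarray]] = {}
    for locus in loci:
        base = rng.dirichlet(np.full(config.microsat_alleles_per_locus, 1.0))
        base = np.maximum(base, 1e-4)
        base /= base.sum()
        bases = _drift_bases(base, coords, config.microsat.ibd_slope, rng)
        msat_freqs[locus] = _population_frequencies(
            bases, config.microsat.divergence_F, rng
        )

    sizes = sorted(config.alleles_per_individual_weights)
    size_w = np.array([config.alleles_per_individual_weights[s] for s in sizes])
    allele_ids = pool.ids
    msat_labels = {
        locus: [100 + 2 * i for i in range(config.microsat_alleles_per_locus)]
        for locus in loci
    }

    mhc_records = []
    ms_inds: list[str] = []
    ms_pops: dict[str, str] = {}
    ms_geno: dict[str, dict[str, tuple[int, int] | None]] = {}
    for pop in pops:
        n = config.samples_per_population[pop]
        p_mhc = mhc_freqs[pop]
        for j in range(n):
            ind = f"{pop}_{j + 1:03d}"
            size = int(rng.choice(sizes, p=size_w))
            chosen = rng.choice(k, size=size, replace=False, p=p_mhc)
            mhc_records.append((ind, pop, [allele_ids[c] for c in chosen]))
            g: dict[str, tuple[int, int] | None] = {}
            for locus in loci:
                pf = msat_freqs[locus][pop]
                a, b = rng.choice(len(pf), size=2, replace=True, p=pf)
                lab = msat_labels[locus]
                g[locus] = (min(lab[a], lab[b]), max(lab[a], lab[b]))
            ms_geno[ind] = g
            ms_inds.append(ind)
            ms_pops[ind] = pop

    return TruthSet(
        pool=pool,
        mhc=MHCGenotypeTable.from_records(mhc_records),
        microsat=MicrosatGenotypeTable(ms_inds, ms_pops, loci, ms_geno),
        coordinates=dict(coords),
        mhc_population_frequencies=np.array([mhc_freqs[p] for p in pops]),
        microsat_population_frequencies={
            locus: np.array([msat_freqs[locus][p] for p in pops]) for locus in loci
        },
        config=config,
    )


# ---------------------------------------------------------------------------
# reads


def generate_mid_tags(
    n_forward: int, n_reverse: int, length: int = 10, min_distance: int = 6,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Synthesize MID tag lists with pairwise Hamming distance >= 6.

    Mirrors pyrosequencing MID adaptors: 10-mers whose mutual distances
    make read misassignment from sequencing error vanishingly unlikely.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    tags: list[str] = []
    attempts = 0
    while len(tags) < n_forward + n_reverse:
        attempts += 1
        if attempts > 100000:
            raise ValueError("cannot satisfy MID distance constraints")
        cand = "".join(rng.choice(list(BASES), size=length))
        if all(_hamming(cand, t) >= min_distance for t in tags):
            tags.append(cand)
    return tags[:n_forward], tags[n_forward:]


@dataclass
class ReadSet:
    """Simulated amplicon reads plus per-read truth labels."""

    reads: list[tuple[str, str]]  # (read id, full sequence incl. tags/primers)
    provenance: dict[str, dict]   # read id -> truth record
    assignment: dict[tuple[str, str], str]  # (fwd mid, rev mid) -> individual
    forward_mids: list[str]
    reverse_mids: list[str]

    def write_fasta(self, path: str | Path, wrap: int | None = None) -> None:
        with open(path, "w") as fh:
            for rid, seq in self.reads:
                fh.write(f">{rid}\n")
                if wrap:
                    for i in range(0, len(seq), wrap):
                        fh.write(seq[i : i + wrap] + "\n")
                else:
                    fh.write(seq + "\n")

    def write_provenance(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.provenance, fh, indent=1)


def _mutate(seq: str, positions: np.ndarray, rng: np.random.Generator) -> str:
    s = list(seq)
    for p in positions:
        s[p] = rng.choice([b for b in BASES if b != s[p]])
    return "".join(s)


def simulate_reads(truth: TruthSet, config: SimulationConfig | None = None,
                   individuals: Sequence[str] | None = None,
                   seed_offset: int = 2) -> ReadSet:
    """Emit tagged amplicon reads for every individual in the truth set.

    Per individual the total depth is negative-binomial around
    ``mean_depth``; reads are allocated to the individual's alleles with
    log-normal amplification biases, then corrupted: with probability
    ``noise_variant_rate`` a read comes from a random off-pool sequence,
    else with probability ``chimera_rate`` it is a single-crossover
    hybrid of two of the individual's alleles, and every read suffers
    independent per-base substitution errors.  ``provenance`` records
    the truth of every read (class, source allele(s), error count).
    """
    config = config or truth.config
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, seed_offset]))
    rm = config.read_model
    L = config.amplicon_length
    inds = list(individuals) if individuals is not None else list(truth.mhc.individuals)

    fwd, rev = config.forward_mids, config.reverse_mids
    if fwd is None or rev is None:
        n_pairs_needed = len(inds)
        n_f = max(2, math.ceil(math.sqrt(n_pairs_needed)))
        n_r = max(2, math.ceil(n_pairs_needed / n_f))
        fwd, rev = generate_mid_tags(n_f, n_r, seed=config.seed)
    pairs = [(f, r) for r in rev for f in fwd]
    if len(pairs) < len(inds):
        raise ValueError(
            f"{len(inds)} individuals need more tag pairs than the "
            f"{len(fwd)}x{len(rev)} MID scheme provides"
        )
    assignment = {pairs[i]: ind for i, ind in enumerate(inds)}

    k_disp = rm.depth_dispersion
    reads: list[tuple[str, str]] = []
    provenance: dict[str, dict] = {}
    serial = 0
    for i, ind in enumerate(inds):
        alleles = sorted(truth.mhc.allele_sets[ind])
        seqs = [truth.pool.sequences[a] for a in alleles]
        if rm.mean_depth == 0:
            depth = 0
        else:
            p_nb = k_disp / (k_disp + rm.mean_depth)
            depth = int(rng.negative_binomial(k_disp, p_nb))
        if depth == 0:
            continue
        bias = rng.lognormal(0.0, rm.allele_amplification_bias_sd, size=len(alleles))
        alloc = rng.multinomial(depth, bias / bias.sum())
        fmid, rmid = pairs[i]
        flank_l = fmid + config.forward_primer
        flank_r = revcomp(config.reverse_primer) + revcomp(rmid)
        source_ids = np.repeat(np.arange(len(alleles)), alloc)
        u = rng.random(depth)
        n_err = rng.binomial(L, rm.per_base_error_rate, size=depth)
        for r in range(depth):
            serial += 1
            rid = f"read{serial:07d}"
            rec: dict = {"individual": ind}
            if u[r] < rm.noise_variant_rate:
                insert = "".join(rng.choice(list(BASES), size=L))
                rec.update({"class": "noise", "source": None})
            elif u[r] < rm.noise_variant_rate + rm.chimera_rate and len(alleles) >= 2:
                a, b = rng.choice(len(alleles), size=2, replace=False)
                x = int(rng.integers(1, L))
                insert = seqs[a][:x] + seqs[b][x:]
                rec.update(
                    {"class": "chimera", "source": [alleles[a], alleles[b]],
                     "crossover": x}
                )
            else:
                a = int(source_ids[r])
                insert = seqs[a]
                rec.update({"class": "true", "source": alleles[a]})
            if n_err[r]:
                pos = rng.choice(L, size=min(int(n_err[r]), L), replace=False)
                insert = _mutate(insert, pos, rng)
            rec["n_errors"] = int(n_err[r])
            provenance[rid] = rec
            reads.append((rid, flank_l + insert + flank_r))
    return ReadSet(reads, provenance, assignment, list(fwd), list(rev))


# ---------------------------------------------------------------------------
# on-disk study bundle


def write_truth(truth: TruthSet, outdir: str | Path) -> dict[str, Path]:
    """Write the genotype tables, coordinates, frequencies and config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["mhc_genotypes"] = outdir / "mhc_genotypes.tsv"
    truth.mhc.to_tsv(paths["mhc_genotypes"])
    paths["microsat_genotypes"] = outdir / "microsat_genotypes.tsv"
    truth.microsat.to_tsv(paths["microsat_genotypes"])
    paths["alleles"] = outdir / "mhc_alleles.fasta"
    with open(paths["alleles"], "w") as fh:
        for aid, seq in truth.pool.sequences.items():
            fh.write(f">{aid}\n{seq}\n")
    paths["coordinates"] = outdir / "coordinates.csv"
    with open(paths["coordinates"], "w") as fh:
        fh.write("population,lon,lat\n")
        for pop, (lon, lat) in truth.coordinates.items():
            fh.write(f"{pop},{lon},{lat}\n")
    paths["config"] = outdir / "config.json"
    with open(paths["config"], "w") as fh:
        fh.write(truth.config.to_json())
    return paths
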