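"""Adaptive (MHC amplicon) versus neutral (microsatellite) population structure.

A toolkit for the full comparative workflow: simulation of a
ground-truthed two-marker study design, pyrosequencing-amplicon allele
calling with multi-step artifact filtering, population diversity and
differentiation statistics (AMOVA Phi_ST / F_ST, Jost's D, rarefied
allelic richness), binary-encoded multivariate co-structure (between-
class analysis, co-inertia, RV test), isolation-by-distance Mantel
tests, and desk-scale selection statistics (NG86 dN/dS, LRT arithmetic).
"""

from .simulate import (
    AllelePool,
    MarkerModel,
    ReadModel,
    SimulationConfig,
    TruthSet,
    build_allele_pool,
    generate_mid_tags,
    simulate_genotypes,
    simulate_reads,
    write_truth,
)
from .tables import MHCGenotypeTable, MicrosatGenotypeTable
from .genotyping import (
    MHCGenotypeCall,
    TagScheme,
    Variant,
    VariantClassification,
    call_genotypes,
    classify_variants,
    demultiplex,
    implied_min_loci,
    replicate_concordance,
    tabulate_variants,
    translate_and_flag,
)
from .diversity import (
    allele_diversity_index,
    diversity_report,
    heterozygosity,
    mhc_allele_counts,
    mhc_genotype_diversity,
    nucleotide_diversity,
    rarefied_allelic_richness,
    rarefied_richness_from_counts,
    relative_allele_frequencies,
)
from .differentiation import (
    AMOVAResult,
    PairwiseDifferentiation,
    amova,
    binary_encode,
    jc69_distance,
    jost_dest,
    mhc_units,
    microsat_units,
    pairwise_dest,
    pairwise_fst,
    pairwise_phist,
)
from .multivar import (
    CoinertiaResult,
    Ordination,
    between_class_analysis,
    coinertia,
    jaccard_s3_distance,
    principal_coordinates,
)
from .ibd import (
    MantelResult,
    diversity_correlation,
    exclude_population,
    geographic_log_distance,
    haversine_km,
    linearized,
    mantel,
    partial_mantel,
)
from .selection import (
    CodonAlignment,
    DnDsResult,
    LRTResult,
    ModelFit,
    lrt,
    ng86_dnds,
)
from .pipeline import PipelineConfig, run_pipeline, stage_seed, validate_config

__version__ = "0.1.0"
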