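"""End-to-end orchestration: simulate -> genotype -> statistics.

A single YAML config drives every stage; a global seed deterministically
derives per-stage seeds (stable stage-name hashing) so that stages can
be rerun in isolation and full runs are bit-reproducible.  Outputs land
in one run directory with a MANIFEST.json listing every artifact with a
content hash, plus a summary JSON reporting the adaptive-vs-neutral
contrast: AMOVA Phi_ST / F_ST, pairwise significance fractions, Mantel
correlations, the co-inertia RV test and the diversity correlation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields, is_dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import diversity as div
from . import differentiation as diff
from . import genotyping as gt
from . import ibd as ibd_mod
from . import multivar as mv
from . import selection as sel
from .simulate import (
    MarkerModel,
    ReadModel,
    SimulationConfig,
    build_allele_pool,
    simulate_genotypes,
    simulate_reads,
    write_truth,
)
from .tables import MHCGenotypeTable

log = logging.getLogger("mhcpop.pipeline")

_STAGES = ("simulate", "genotype", "popgen", "multivar", "ibd", "selection")


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31 derived from the global seed."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


@dataclass
class GenotypingParams:
    min_depth: int = 150
    mpaf_true_threshold: float = 0.04
    mpaf_floor: float = 0.001


@dataclass
class PopgenParams:
    n_perm_amova: int = 1000
    n_perm_pairwise: int = 199
    rarefaction_g: int | None = None


@dataclass
class MultivarParams:
    n_perm: int = 999
    make_plot: bool = True


@dataclass
class IBDParams:
    n_perm: int = 999
    exclude: list[str] = field(default_factory=list)
    linearize_fst: bool = False


@dataclass
class SelectionParams:
    bootstrap_reps: int = 200
    fits: str | None = None
    lrt_pairs: list[str] = field(default_factory=list)


@dataclass
class PipelineConfig:
    outdir: str = "run"
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    genotyping: GenotypingParams = field(default_factory=GenotypingParams)
    popgen: PopgenParams = field(default_factory=PopgenParams)
    multivar: MultivarParams = field(default_factory=MultivarParams)
    ibd: IBDParams = field(default_factory=IBDParams)
    selection: SelectionParams = field(default_factory=SelectionParams)


def _build_dataclass(cls, data: Mapping[str, Any], path: str, errors: list[str]):
    kwargs = {}
    known = {f.name: f for f in fields(cls)}
    for key, value in data.items():
        if key not in known:
            errors.append(f"{path}{key}: unknown key")
            continue
        f = known[key]
        sub = {
            "simulation": SimulationConfig,
            "genotyping": GenotypingParams,
            "popgen": PopgenParams,
            "multivar": MultivarParams,
            "ibd": IBDParams,
            "selection": SelectionParams,
            "read_model": ReadModel,
            "mhc": MarkerModel,
            "microsat": MarkerModel,
        }.get(key)
        if sub is not None and isinstance(value, Mapping):
            kwargs[key] = _build_dataclass(sub, value, f"{path}{key}.", errors)
        else:
            kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        errors.append(f"{path.rstrip('.') or cls.__name__}: {exc}")
        return None


def _coerce_weight_keys(doc: dict) -> dict:
    sim = doc.get("simulation")
    if isinstance(sim, dict) and isinstance(
        sim.get("alleles_per_individual_weights"), dict
    ):
        sim["alleles_per_individual_weights"] = {
            int(k): float(v)
            for k, v in sim["alleles_per_individual_weights"].items()
        }
    if isinstance(sim, dict) and isinstance(sim.get("coordinates"), dict):
        sim["coordinates"] = {
            str(k): tuple(v) for k, v in sim["coordinates"].items()
        }
    if isinstance(sim, dict) and isinstance(sim.get("samples_per_population"), dict):
        sim["samples_per_population"] = {
            str(k): int(v) for k, v in sim["samples_per_population"].items()
        }
    return doc


def validate_config(source: str | Path | Mapping[str, Any]) -> PipelineConfig:
    """Parse and validate a pipeline config; raises with every violation."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            doc = yaml.safe_load(fh) or {}
    else:
        doc = dict(source)
    if not isinstance(doc, dict):
        raise ValueError("config document must be a mapping")
    doc = _coerce_weight_keys(json.loads(json.dumps(doc)))  # deep copy
    errors: list[str] = []
    cfg = _build_dataclass(PipelineConfig, doc, "", errors)
    if cfg is not None and cfg.selection.fits:
        if not Path(cfg.selection.fits).exists():
            errors.append(f"selection.fits: file not found: {cfg.selection.fits}")
    if errors:
        raise ValueError("invalid config:\n  " + "\n  ".join(errors))
    return cfg


def config_to_dict(cfg: PipelineConfig) -> dict:
    return json.loads(json.dumps(asdict(cfg), default=str))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage in dependency order; returns the manifest."""
    t0 = time.time()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(
        filename=outdir / "run.log",
        level=logging.INFO,
        format="%(asctime)s %(levelname)s %(name)s %(message)s",
        force=False,
    )
    summary: dict[str, Any] = {}
    artifacts: dict[str, str] = {}

    def record(name: str, path: Path) -> None:
        artifacts[name] = str(path.relative_to(outdir))

    # ---- simulate
    sim_cfg = cfg.simulation
    sim_cfg.seed = stage_seed(cfg.seed, "simulate")
    sim_cfg.validate()
    log.info("simulate: seed=%d", sim_cfg.seed)
    pool = build_allele_pool(sim_cfg)
    truth = simulate_genotypes(pool, sim_cfg)
    reads = simulate_reads(truth, sim_cfg)
    paths = write_truth(truth, outdir / "truth")
    for name, p in paths.items():
        record(f"truth/{name}", p)
    reads_path = outdir / "reads.fasta"
    reads.write_fasta(reads_path)
    record("reads", reads_path)
    prov_path = outdir / "read_provenance.json"
    reads.write_provenance(prov_path)
    record("provenance", prov_path)

    # ---- genotype
    gp = cfg.genotyping
    scheme = gt.TagScheme(
        reads.forward_mids, reads.reverse_mids,
        sim_cfg.forward_primer, sim_cfg.reverse_primer, reads.assignment,
    )
    inserts, discards = gt.demultiplex(reads.reads, scheme, sim_cfg.amplicon_length)
    variants = gt.tabulate_variants(inserts)
    classifications = gt.classify_variants(
        variants, gp.mpaf_true_threshold, gp.mpaf_floor, sim_cfg.frame_offset,
        known_alleles=pool.sequences,
    )
    populations = dict(truth.mhc.populations)
    calls, flags = gt.call_genotypes(
        variants, classifications, gp.min_depth, gp.mpaf_true_threshold,
        populations=populations,
        allele_names={seq: aid for aid, seq in pool.sequences.items()},
    )
    vt = gt.variants_to_frame(variants, classifications)
    vt_path = outdir / "variants.tsv"
    vt.to_csv(vt_path, sep="\t", index=False)
    record("variants", vt_path)
    calls_path = outdir / "genotype_calls.tsv"
    gt.calls_to_frame(calls).to_csv(calls_path, sep="\t", index=False)
    record("genotype_calls", calls_path)

    called = [c for c in calls if c.status == "CALLED"]
    truth_sets = truth.mhc.allele_sets
    exact = sum(1 for c in called if c.alleles == truth_sets[c.individual])
    summary["genotyping"] = {
        "n_reads": len(reads.reads),
        "n_discarded_reads": len(discards),
        "n_variants": len(variants),
        "n_true_alleles": sum(
            1 for c in classifications.values() if c.label == gt.TRUE_ALLELE
        ),
        "n_called": len(called),
        "n_low_depth": len(calls) - len(called),
        "accuracy_vs_truth": exact / len(called) if called else None,
        "implied_min_loci": gt.implied_min_loci(called) if called else None,
        "flagged": flags,
    }

    # ---- popgen on CALLED individuals
    pg = cfg.popgen
    seed_pg = stage_seed(cfg.seed, "popgen")
    mhc_called = MHCGenotypeTable.from_records(
        (c.individual, populations[c.individual], c.alleles)
        for c in called if len(c.alleles) >= 2
    )
    msat = truth.microsat.subset(mhc_called.individuals)
    report = div.diversity_report(mhc_called, msat, pool.sequences,
                                  pg.rarefaction_g)
    rep_path = outdir / "diversity.tsv"
    report.to_csv(rep_path, sep="\t")
    record("diversity", rep_path)

    d2_m, pops_m = diff.mhc_units(mhc_called, pool.sequences)
    amova_mhc = diff.amova(d2_m, pops_m, pg.n_perm_amova, seed_pg)
    d2_s, pops_s = diff.microsat_units(msat)
    amova_msat = diff.amova(d2_s, pops_s, pg.n_perm_amova, seed_pg + 1)
    pw_mhc = diff.pairwise_phist(mhc_called, pool.sequences,
                                 pg.n_perm_pairwise, seed_pg + 2)
    pw_msat = diff.pairwise_fst(msat, pg.n_perm_pairwise, seed_pg + 3)
    for name, pw in (("phist_mhc", pw_mhc), ("fst_microsat", pw_msat)):
        p = outdir / f"pairwise_{name}.csv"
        pw.statistic.to_csv(p)
        record(f"pairwise_{name}", p)
        p2 = outdir / f"pairwise_{name}_pvalues.csv"
        pw.p_values.to_csv(p2)
        record(f"pairwise_{name}_p", p2)
    tri = np.triu_indices(len(pw_mhc.populations), k=1)
    summary["differentiation"] = {
        "amova_mhc": {"phi_st": amova_mhc.phi_st,
                      "pct_among": amova_mhc.pct_among,
                      "p": amova_mhc.p_value},
        "amova_microsat": {"phi_st": amova_msat.phi_st,
                           "pct_among": amova_msat.pct_among,
                           "p": amova_msat.p_value},
        "pairwise_significant_mhc":
            int((np.asarray(pw_mhc.p_values)[tri] < 0.05).sum()),
        "pairwise_significant_microsat":
            int((np.asarray(pw_msat.p_values)[tri] < 0.05).sum()),
        "n_pairs": len(tri[0]),
    }

    # ---- multivar
    mvp = cfg.multivar
    seed_mv = stage_seed(cfg.seed, "multivar")
    bm, bs, enc_log = diff.binary_encode(mhc_called, msat)
    groups = {i: populations[i] for i in bm.index}
    bca_mhc = mv.between_class_analysis(
        mv.principal_coordinates(mv.jaccard_s3_distance(bm)), groups)
    bca_msat = mv.between_class_analysis(
        mv.principal_coordinates(mv.jaccard_s3_distance(bs)), groups)
    coa = mv.coinertia(bca_mhc, bca_msat, mvp.n_perm, seed_mv)
    summary["costructure"] = {
        "rv": coa.rv,
        "p": coa.p_value,
        "eigenvalue_fractions": coa.eigenvalue_fractions[:2].tolist(),
        "vector_lengths": coa.vector_lengths.round(4).to_dict()
        if coa.vector_lengths is not None else None,
        "between_class_inertia_mhc": bca_mhc.between_inertia_fraction,
        "between_class_inertia_microsat": bca_msat.between_inertia_fraction,
    }
    if mvp.make_plot:
        plot_path = outdir / "coinertia.png"
        mv.plot_coinertia(coa, plot_path)
        record("coinertia_plot", plot_path)

    # ---- ibd
    ip = cfg.ibd
    seed_ibd = stage_seed(cfg.seed, "ibd")
    geo = ibd_mod.geographic_log_distance(truth.coordinates)
    stat_mhc = pw_mhc.statistic
    stat_msat = pw_msat.statistic
    if ip.linearize_fst:
        stat_mhc = ibd_mod.linearized(stat_mhc)
        stat_msat = ibd_mod.linearized(stat_msat)
    if ip.exclude:
        geo_t = ibd_mod.exclude_population(geo, *ip.exclude)
        stat_mhc = ibd_mod.exclude_population(stat_mhc, *ip.exclude)
        stat_msat = ibd_mod.exclude_population(stat_msat, *ip.exclude)
    else:
        geo_t = geo
    order = list(stat_mhc.index)
    geo_t = geo_t.loc[order, order]
    stat_msat = stat_msat.loc[order, order]
    m_mhc = ibd_mod.mantel(stat_mhc, geo_t, ip.n_perm, seed_ibd)
    m_msat = ibd_mod.mantel(stat_msat, geo_t, ip.n_perm, seed_ibd + 1)
    pm_mhc = ibd_mod.partial_mantel(stat_mhc, geo_t,
                                    stat_msat.loc[order, order],
                                    ip.n_perm, seed_ibd + 2)
    r_div, p_div = ibd_mod.diversity_correlation(
        report["A_r"],
        [np.mean([len(mhc_called.allele_sets[i])
                  for i in mhc_called.individuals_in(p)])
         for p in report.index],
    )
    summary["ibd"] = {
        "mantel_mhc": {"r": m_mhc.r, "p": m_mhc.p_value},
        "mantel_microsat": {"r": m_msat.r, "p": m_msat.p_value},
        "partial_mantel_mhc_given_microsat": {"r": pm_mhc.r, "p": pm_mhc.p_value},
        "diversity_correlation": {"r": r_div, "p": p_div},
        "excluded": ip.exclude,
    }

    # ---- selection
    sp = cfg.selection
    seed_sel = stage_seed(cfg.seed, "selection")
    aln = sel.CodonAlignment(
        {
            aid: seq[sim_cfg.frame_offset:][: 3 * ((sim_cfg.amplicon_length
                                                    - sim_cfg.frame_offset) // 3)]
            for aid, seq in pool.sequences.items()
        }
    )
    dnds = sel.ng86_dnds(aln, sp.bootstrap_reps, seed_sel)
    summary["selection"] = {
        "dN": dnds.dN, "dS": dnds.dS, "z": dnds.z, "p": dnds.p_value,
    }
    if sp.fits:
        fits = sel.load_model_fits(sp.fits)
        lrts = []
        for pair in sp.lrt_pairs:
            null_l, alt_l = pair.split(":")
            res = sel.lrt(fits[null_l], fits[alt_l])
            lrts.append(asdict(res))
        summary["selection"]["lrt"] = lrts

    # ---- manifest
    summary_path = outdir / "summary.json"
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    record("summary", summary_path)
    manifest = {
        "seed": cfg.seed,
        "stage_seeds": {s: stage_seed(cfg.seed, s) for s in _STAGES},
        "config": config_to_dict(cfg),
        "artifacts": {
            name: {"path": rel, "sha256": _sha256(outdir / rel)}
            for name, rel in artifacts.items()
        },
        "elapsed_s": round(time.time() - t0, 2),
    }
    with open(outdir / "MANIFEST.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    log.info("pipeline finished in %.1fs", manifest["elapsed_s"])
    return manifest
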