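"""End-to-end orchestration: simulate -> qc -> phenotype -> variants -> scan.

A :class:`RunConfig` carries every stage parameter with its standard default
and round-trips losslessly through a flat YAML file.  ``run_pipeline`` wires
the stages together, logs per-stage record counts, and writes a JSON manifest
with the parameter hash, derived seeds and SHA-256 digests of every output,
so identical config+seed runs are byte-identical and verifiably so.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import phenotype as ph
from . import readqc, scan, simulate, variants

log = logging.getLogger("bsascan")

_STAGES = ("simulate", "qc", "phenotype", "variants", "scan")


@dataclass
class RunConfig:
    # global
    seed: int = 1
    out_dir: str = "bsascan_out"
    simulate: bool = True
    # inputs when not simulating
    fastq_in: str | None = None
    vcf_in: str | None = None
    phenotype_in: str | None = None
    res_bulk: str = "bulk_res"
    sus_bulk: str = "bulk_sus"
    donor: str = "donor"
    recurrent: str = "recurrent"
    # simulate stage
    n_lines: int = 200
    n_chromosomes: int = 3
    chrom_length: int = 2_000_000
    markers_per_chrom: int = 400
    rate_cm_per_mb: float = 1.0
    mean_depth: float = 40.0
    error_rate: float = 0.001
    overdispersion: float = 0.0
    qtl: bool = True
    n_replicates: int = 3
    fastq_reads: int = 2_000
    read_len: int = 150
    # qc stage
    adapter: str = "AGATCGGAAGAGC"
    # phenotype stage
    bulk_size: int = 30
    # scan stage
    window: int = 1_000_000
    step: int = 5_000
    min_depth: int = 10
    min_sites: int = 5
    level: float = 0.99
    replicates: int = 10_000

    def validate(self) -> None:
        if self.window < self.step:
            raise ValueError(f"window ({self.window}) must be >= step ({self.step})")
        if self.bulk_size * 2 > self.n_lines:
            raise ValueError("population too small for two disjoint bulks")
        if not self.simulate and not (self.vcf_in and self.phenotype_in):
            raise ValueError("without --simulate, vcf_in and phenotype_in are required")

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def param_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages; return (and write) the run manifest."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="%(name)s %(levelname)s %(message)s")
    ss = np.random.SeedSequence(cfg.seed)
    seeds = {name: int(child.generate_state(1)[0] % (2**31))
             for name, child in zip(("cross", "traits", "reps", "depths", "fastq", "null"),
                                    ss.spawn(6))}
    manifest: dict = {"config": dataclasses.asdict(cfg), "param_hash": cfg.param_hash(),
                      "seeds": seeds, "stages": [], "counts": {}, "outputs": {}}

    genome = None
    if cfg.simulate:
        genome = simulate.GenomeModel.default(cfg.n_chromosomes, cfg.chrom_length,
                                              cfg.markers_per_chrom, seed=0)
        qtl = simulate.QTLSpec.default(genome) if cfg.qtl else None
        pop = simulate.simulate_cross(genome, cfg.n_lines, seeds["cross"],
                                      rate_cm_per_mb=cfg.rate_cm_per_mb)
        traits = simulate.simulate_traits(pop, qtl, seed=seeds["traits"])
        pheno_table = simulate.replicate_table(traits, cfg.n_replicates, seed=seeds["reps"])
        pheno_path = out / "phenotypes.tsv"
        pheno_table.to_csv(pheno_path, sep="\t", index=False, float_format="%.6g")
        reads, fq_truth = simulate.synth_fastq(
            cfg.fastq_reads, cfg.read_len,
            simulate.FastqDefects(adapter=cfg.adapter, p_adapter=0.05, p_low5=0.05,
                                  p_low3=0.05, p_n=0.05, p_lowq=0.05),
            seed=seeds["fastq"])
        fastq_path = out / "reads.fq.gz"
        simulate.write_fastq(reads, fastq_path)
        fq_truth.to_csv(out / "reads_truth.tsv", sep="\t", index=False)
        log.info("simulate: %d lines, %d markers, %d reads",
                 pop.n, sum(genome.n_markers(c) for c in genome.chrom_names), len(reads))
        manifest["stages"].append("simulate")
        manifest["counts"]["simulate"] = {"lines": pop.n, "reads": len(reads)}
    else:
        qtl = None
        pheno_path = Path(cfg.phenotype_in)
        fastq_path = Path(cfg.fastq_in) if cfg.fastq_in else None

    # --- qc ---------------------------------------------------------------
    if fastq_path is not None:
        clean_path = out / "clean.fq.gz"
        report = readqc.qc_stream(fastq_path, clean_path, adapter=cfg.adapter)
        report.to_tsv(out / "qc_report.tsv")
        log.info("qc: %d reads in -> %d reads out", report.reads_in, report.reads_out)
        manifest["stages"].append("qc")
        manifest["counts"]["qc"] = {"reads_in": report.reads_in, "reads_out": report.reads_out}

    # --- phenotype --------------------------------------------------------
    import pandas as pd
    pheno = pd.read_csv(pheno_path, sep="\t")
    stats = ph.trait_stats_table(pheno)
    stats.to_csv(out / "trait_stats.tsv", sep="\t", index=False, float_format="%.4g")
    corr = ph.correlation_matrix(pheno)
    corr.to_tsv(out / "trait_correlations.tsv")
    bulks = ph.select_bulks(pheno, n=cfg.bulk_size)
    bulk_df = pd.DataFrame({"line": bulks.resistant + bulks.susceptible,
                            "bulk": ["resistant"] * len(bulks.resistant)
                                    + ["susceptible"] * len(bulks.susceptible)})
    bulk_df.to_csv(out / "bulks.tsv", sep="\t", index=False)
    log.info("phenotype: %d lines -> bulks of %d/%d", pheno["line"].nunique(),
             len(bulks.resistant), len(bulks.susceptible))
    manifest["stages"].append("phenotype")
    manifest["counts"]["phenotype"] = {"lines": int(pheno["line"].nunique()),
                                       "bulk_size": len(bulks.resistant)}

    # --- variant table ----------------------------------------------------
    if cfg.simulate:
        dm = simulate.DepthModel(cfg.mean_depth, cfg.error_rate, cfg.overdispersion)
        sites, truth = simulate.simulate_bulk_depths(
            pop, bulks.resistant, bulks.susceptible, dm, seed=seeds["depths"], qtl=qtl,
            impacts={"HIGH": 8, "MODERATE": 16, "LOW": 24})
        vcf_path = out / "variants.vcf"
        variants.write_vcf(sites, vcf_path, contigs=genome.lengths)
        truth.to_csv(out / "marker_truth.tsv", sep="\t", index=False, float_format="%.6g")
    else:
        vcf_path = Path(cfg.vcf_in)
        sites = variants.read_vcf(vcf_path)
    summary = variants.summary_table(sites)
    summary.to_csv(out / "variant_summary.tsv", sep="\t", index=False)
    log.info("variants: %d records, %d samples", len(sites), len(variants.site_table_samples(sites)))
    manifest["stages"].append("variants")
    manifest["counts"]["variants"] = {"records": len(sites)}

    # --- scan -------------------------------------------------------------
    records, drops = scan.filter_informative_sites(
        sites, cfg.res_bulk, cfg.sus_bulk, cfg.donor, cfg.recurrent, cfg.min_depth)
    windows = scan.sliding_windows(
        records, _contigs_for(sites, genome), cfg.window, cfg.step, cfg.min_sites)
    nm = scan.NullModel(n_bulk=cfg.bulk_size, replicates=cfg.replicates)
    windows = scan.attach_thresholds(windows, nm, seed=seeds["null"])
    regions = scan.call_candidate_regions(windows, cfg.level, cfg.step, nm.levels, sites)
    records.to_csv(out / "snp_index.tsv", sep="\t", index=False, float_format="%.6g")
    windows.to_csv(out / "windows.tsv", sep="\t", index=False, float_format="%.6g")
    (out / "regions.bed").write_text(scan.regions_to_bed(regions))
    scan.plot_scan(windows, out / "scan.png", level=cfg.level)
    log.info("scan: %d informative sites (dropped %s), %d windows, %d regions",
             len(records), drops, len(windows), len(regions))
    manifest["stages"].append("scan")
    manifest["counts"]["scan"] = {"informative_sites": len(records), "dropped": drops,
                                  "windows": len(windows), "regions": len(regions)}

    for p in sorted(out.iterdir()):
        if p.is_file() and p.name != "manifest.json" and p.suffix != ".png":
            manifest["outputs"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def synthetic_scan(seed: int, n_lines: int = 2_000, bulk_size: int = 30,
                   mean_depth: float = 40.0, qtl: bool = True,
                   replicates: int = 10_000, error_rate: float = 0.001):
    """One in-memory synthetic study -> deltaSNP-index scan, no file I/O.

    Simulates a BC2F2 population, selects phenotypic-extreme bulks (with or
    without a planted QTL), draws pooled depths and runs the windowed scan
    with Monte-Carlo thresholds.  Returns a dict with the windows table, the
    called regions per level, the QTL spec used (or None) and the population.
    Used by calibration/recovery experiments and the examples.
    """
    import pandas as pd

    ss = np.random.SeedSequence(seed)
    s_cross, s_traits, s_depths, s_null = (int(c.generate_state(1)[0] % (2**31))
                                           for c in ss.spawn(4))
    genome = simulate.GenomeModel.default(seed=0)
    qtl_spec = simulate.QTLSpec.default(genome) if qtl else None
    pop = simulate.simulate_cross(genome, n_lines, s_cross)
    traits = simulate.simulate_traits(pop, qtl_spec, seed=s_traits)
    long = traits.reset_index()
    long.insert(1, "replicate", "R1")
    bulks = ph.select_bulks(long, n=bulk_size)
    dm = simulate.DepthModel(mean_depth, error_rate)
    sites, truth = simulate.simulate_bulk_depths(
        pop, bulks.resistant, bulks.susceptible, dm, seed=s_depths, qtl=qtl_spec)
    records, drops = scan.filter_informative_sites(
        sites, simulate.SAMPLE_RES_BULK, simulate.SAMPLE_SUS_BULK,
        simulate.SAMPLE_DONOR, simulate.SAMPLE_RECURRENT)
    windows = scan.sliding_windows(records, genome.lengths)
    nm = scan.NullModel(n_bulk=bulk_size, replicates=replicates)
    windows = scan.attach_thresholds(windows, nm, seed=s_null)
    regions = {level: scan.call_candidate_regions(windows, level, levels=nm.levels)
               for level in nm.levels}
    return {"genome": genome, "pop": pop, "qtl": qtl_spec, "bulks": bulks,
            "sites": sites, "truth": truth, "records": records, "drops": drops,
            "windows": windows, "regions": regions, "null_model": nm}


def _contigs_for(sites, genome) -> dict[str, int]:
    if genome is not None:
        return genome.lengths
    # without a declared genome, close each chromosome at its last variant
    grouped = sites.groupby("chrom", sort=False)["pos"].max()
    return {c: int(v) for c, v in grouped.items()}
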