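"""End-to-end orchestration: simulate -> coverage -> discover -> genotype ->
concord -> popgen -> report, with a flat key=value configuration, a global
seed and a run manifest for reproducibility.

Rerunning with the same configuration and seed reproduces byte-identical
tabular outputs (the manifest records content hashes so this is checkable).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import coverage as cov
from . import discovery as disc
from . import genotyping as gt
from . import popgen as pg
from . import simulate as sim

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "coverage", "discover", "genotype", "concord", "popgen")


@dataclass
class PipelineConfig:
    """Every stage parameter, with defaults equal to the published rule set."""

    seed: int = 0
    outdir: str = "rrlsnp_run"
    stages: str = ",".join(ALL_STAGES)

    # genome
    n_chroms: int = 2
    chrom_length: int = 100_000
    gc_fraction: float = 0.45
    site_density: float = 5.0

    # truth panel
    n_snps: int = 600
    maf_min: float = 0.1
    maf_max: float = 0.5
    mix_vinifera_only: float = 0.442
    mix_wild_only: float = 0.288
    mix_shared: float = 0.243
    mix_fixed: float = 0.027
    disruption_rate: float = 0.05
    n_cultivated: int = 11
    n_wild: int = 6

    # reads
    mean_depth: float = 20.0
    size_min: int = 40
    size_max: int = 250
    weight_in: float = 10.0
    weight_out: float = 1.0
    error_rate_start: float = 0.002
    error_rate_end: float = 0.02

    # discovery filters (published thresholds)
    min_depth: int = 10
    max_depth: int = 1000
    min_minor_frac: float = 0.05
    max_third_fourth_frac: float = 0.02
    min_q: float = 20.0
    max_p: float = 0.01
    mc_draws: int = 10_000

    # genotype calling
    genotype_error_rate: float = 0.01
    het_alpha: float = 0.01

    # popgen
    bin_size: int = 1000
    background_pairs: int = 20_000
    max_missing: int = 1
    max_distance: int = 40_000
    keep_partial_bin: bool = False
    pca_min_called: int = 14

    # external inputs (used when the simulate stage is not requested)
    reference: str = ""
    sam: str = ""
    pileup: str = ""
    array_matrix: str = ""
    repeat_bed: str = ""

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Parse a flat ``key = value`` text file; unknown keys are rejected
        before any stage runs."""
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"line {lineno}: expected key = value")
                key, value = (t.strip() for t in line.split("=", 1))
                if key not in fields:
                    raise ValueError(f"line {lineno}: unknown configuration key {key!r}")
                ftype = fields[key].type
                if ftype in ("int",):
                    kwargs[key] = int(value)
                elif ftype in ("float",):
                    kwargs[key] = float(value)
                elif ftype in ("bool",):
                    kwargs[key] = value.lower() in ("1", "true", "yes")
                else:
                    kwargs[key] = value
        return cls(**kwargs)

    def stage_list(self) -> list[str]:
        stages = [s.strip() for s in self.stages.split(",") if s.strip()]
        unknown = set(stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        return stages

    def filter_config(self) -> disc.FilterConfig:
        return disc.FilterConfig(
            min_depth=self.min_depth,
            max_depth=self.max_depth,
            min_minor_frac=self.min_minor_frac,
            max_third_fourth_frac=self.max_third_fourth_frac,
            min_mean_q=self.min_q,
            max_contingency_p=self.max_p,
            mc_draws=self.mc_draws,
        )


@dataclass
class RunManifest:
    config: dict
    stages: list[str]
    outputs: dict[str, str] = field(default_factory=dict)
    hashes: dict[str, str] = field(default_factory=dict)
    counts: dict[str, int | float] = field(default_factory=dict)

    def write(self, path: str | Path) -> Path:
        """Atomic write (temp file + rename)."""
        path = Path(path)
        tmp = path.with_suffix(".tmp")
        with open(tmp, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")
        os.replace(tmp, path)
        return path

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the requested stages in dependency order."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = config.stage_list()
    manifest = RunManifest(config=dataclasses.asdict(config), stages=stages)

    genome = panel = readset = None
    result = None
    lenient = strict = truth = None

    if "simulate" in stages:
        genome = sim.generate_genome(
            n_chroms=config.n_chroms,
            chrom_length=config.chrom_length,
            gc_fraction=config.gc_fraction,
            site_density=config.site_density,
            seed=config.seed,
        )
        panel = sim.plant_variants(
            genome,
            n_snps=config.n_snps,
            maf_range=(config.maf_min, config.maf_max),
            class_mix={
                "vinifera_only": config.mix_vinifera_only,
                "wild_only": config.mix_wild_only,
                "shared": config.mix_shared,
                "fixed": config.mix_fixed,
            },
            restriction_disruption_rate=config.disruption_rate,
            samples=sim.default_samples(config.n_cultivated, config.n_wild),
            size_window=(config.size_min, config.size_max),
            seed=config.seed,
        )
        profile = sim.ErrorProfile(
            rates=np.linspace(config.error_rate_start, config.error_rate_end, sim.READ_LEN),
            quality_means=sim.ErrorProfile.default().quality_means,
        )
        readset = sim.simulate_reads(
            genome,
            panel,
            mean_depth=config.mean_depth,
            size_window=(config.size_min, config.size_max),
            weight_in=config.weight_in,
            weight_out=config.weight_out,
            error_profile=profile,
            seed=config.seed,
        )
        paths = sim.emit_outputs(readset, panel, genome, outdir)
        manifest.outputs.update({k: str(v) for k, v in paths.items()})
        manifest.counts["n_reads"] = len(readset)
        manifest.counts["n_planted_variants"] = len(panel.variants)
        manifest.counts["tag_fraction"] = round(readset.tag_fraction(), 4)
        truth = gt.truth_matrix(panel, source="truth")
    else:
        if config.reference:
            genome = sim.SyntheticGenome(
                chromosomes=sim.read_fasta(config.reference),
                seed=config.seed,
                site_density=0.0,
            )
        if config.sam:
            readset = sim.read_sam(config.sam)

    if "coverage" in stages:
        if readset is None or genome is None:
            raise ValueError("coverage stage needs reads and a reference")
        repeats = cov.read_bed(config.repeat_bed) if config.repeat_bed else None
        profile_obs = cov.depth_histogram(readset, genome, repeats)
        lam = profile_obs.mean_depth
        expected = cov.poisson_expected(
            lam, profile_obs.account.mappable_bases,
            max_depth=max(len(profile_obs.depth_histogram) - 1, 1),
        )
        df, crossover = cov.enrichment_report(profile_obs, expected)
        path = outdir / "coverage_enrichment.tsv"
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        manifest.outputs["coverage"] = str(path)
        manifest.counts["mean_coverage"] = round(lam, 4)
        manifest.counts["coverage_crossover_depth"] = (
            crossover if crossover is not None else -1
        )

    if "discover" in stages:
        if readset is not None and genome is not None:
            sites = disc.aggregate_pileup(readset, genome)
        elif config.pileup:
            sites = disc.read_pileup(config.pileup)
        else:
            raise ValueError("discover stage needs reads or a pileup")
        result = disc.discover(sites, config.filter_config(), seed=config.seed)
        manifest.counts["sites_seen"] = result.n_sites_seen
        manifest.counts["candidate_snps"] = len(result.candidates)
        manifest.counts["high_quality_snps"] = len(result.high_quality)
        for reason, cnt in sorted(result.rejection_counts().items()):
            manifest.counts[f"rejected_{reason}"] = cnt
        if genome is not None:
            manifest.outputs["vcf_candidate"] = str(
                disc.write_vcf(result.candidates, genome, outdir / "snps_candidate.vcf")
            )
            manifest.outputs["vcf_high_quality"] = str(
                disc.write_vcf(result.high_quality, genome, outdir / "snps_high_quality.vcf")
            )
        audit_path = outdir / "filter_audit.tsv"
        with open(audit_path, "w") as fh:
            fh.write("#chrom\tpos\treason\n")
            for chrom, pos, reason in result.audit:
                fh.write(f"{chrom}\t{pos + 1}\t{reason}\n")
        manifest.outputs["filter_audit"] = str(audit_path)
        for tier, snpset in (
            ("candidate", result.candidates),
            ("high_quality", result.high_quality),
        ):
            bias = disc.read_position_distribution(snpset)
            manifest.counts[f"position_slope_{tier}"] = round(bias.slope, 6)

    if "genotype" in stages:
        if result is None:
            raise ValueError("genotype stage needs discovery output")
        samples = readset.samples if readset is not None else []
        groups = (
            [g for _, g in panel.samples]
            if panel is not None
            else ["unknown"] * len(samples)
        )
        lenient = gt.genotype_matrix(
            result.high_quality, samples, groups, rule="lenient"
        )
        strict = gt.genotype_matrix(
            result.high_quality, samples, groups, rule="strict",
            error_rate=config.genotype_error_rate, alpha=config.het_alpha,
        )
        manifest.outputs["genotypes_lenient"] = str(
            lenient.write_tsv(outdir / "genotypes_lenient.tsv")
        )
        manifest.outputs["genotypes_strict"] = str(
            strict.write_tsv(outdir / "genotypes_strict.tsv")
        )
        manifest.counts["genotype_calls_lenient"] = lenient.n_called()
        manifest.counts["genotype_calls_strict"] = strict.n_called()

    if "concord" in stages:
        other = None
        if config.array_matrix:
            other = gt.GenotypeMatrix.read_tsv(config.array_matrix, source="array")
        elif truth is not None:
            other = truth
        if strict is None or other is None:
            logger.warning("concord stage skipped: needs strict calls and a second matrix")
        else:
            table = gt.concordance(strict, other)
            path = outdir / "concordance.tsv"
            with open(path, "w") as fh:
                fh.write(table.to_dataframe().to_csv(sep="\t"))
                fh.write(f"# overall_percent\t{table.overall_percent():.4f}\n")
            manifest.outputs["concordance"] = str(path)
            manifest.counts["co_called_genotypes"] = table.grand_total
            manifest.counts["concordance_percent"] = round(table.overall_percent(), 4)

    if "popgen" in stages:
        if result is None or panel is None:
            raise ValueError("popgen stage needs discovery output and group labels")
        groups_arr = np.array([g for _, g in panel.samples])
        classes = []
        for snp in result.high_quality:
            ref_c = np.array(
                [snp.site.sample_counts(snp.ref_allele, snp.alt_allele, s)[0]
                 for s in panel.sample_ids]
            )
            alt_c = np.array(
                [snp.site.sample_counts(snp.ref_allele, snp.alt_allele, s)[1]
                 for s in panel.sample_ids]
            )
            classes.append(pg.classify_segregation(ref_c, alt_c, groups_arr))
        seg = pg.segregation_summary(classes)
        seg_path = outdir / "segregation.tsv"
        with open(seg_path, "w") as fh:
            fh.write("class\tshare\n")
            for k, v in seg.items():
                fh.write(f"{k}\t{v:.6f}\n")
        manifest.outputs["segregation"] = str(seg_path)

        ld_matrix = pg.ld_site_filter(
            lenient, group="cultivated", max_missing=config.max_missing
        )
        manifest.counts["ld_snps"] = ld_matrix.n_sites
        bins = pg.ld_decay_profile(
            ld_matrix,
            bin_size=config.bin_size,
            max_distance=config.max_distance,
            keep_partial_bin=config.keep_partial_bin,
        )
        if ld_matrix.n_sites >= 2 and len(set(c for c, _ in ld_matrix.sites)) >= 2:
            background = pg.background_ld(
                ld_matrix, n_pairs=config.background_pairs, seed=config.seed
            )
            pg.mwu_bins(bins, background)
            manifest.counts["background_pairs_scored"] = len(background)
            manifest.counts["background_median_r2"] = (
                round(float(np.median(background)), 6) if len(background) else -1
            )
        ld_path = outdir / "ld_profile.tsv"
        with open(ld_path, "w") as fh:
            fh.write("mean_distance\tmedian_r2\tn\tp_vs_background\n")
            for b in bins:
                p = "" if b.p_vs_background is None else f"{b.p_vs_background:.6g}"
                fh.write(f"{b.mean_distance:.1f}\t{b.median_r2:.6f}\t{b.n}\t{p}\n")
        manifest.outputs["ld_profile"] = str(ld_path)
        manifest.counts["ld_bins"] = len(bins)

        try:
            pca_res = pg.pca(lenient, min_called_samples=config.pca_min_called)
            pca_path = outdir / "pca.tsv"
            with open(pca_path, "w") as fh:
                k = pca_res.coordinates.shape[1]
                fh.write("sample\t" + "\t".join(f"PC{i+1}" for i in range(k)) + "\n")
                fh.write(
                    "#variance_fraction\t"
                    + "\t".join(f"{v:.6f}" for v in pca_res.variance_fraction)
                    + "\n"
                )
                for i, s in enumerate(pca_res.samples):
                    fh.write(
                        s + "\t"
                        + "\t".join(f"{x:.6f}" for x in pca_res.coordinates[i])
                        + "\n"
                    )
            manifest.outputs["pca"] = str(pca_path)
            manifest.counts["pca_snps"] = pca_res.n_sites_used
        except ValueError as exc:
            logger.warning("PCA skipped: %s", exc)

    for key, p in manifest.outputs.items():
        manifest.hashes[key] = _sha256(Path(p))
    manifest.write(outdir / "manifest.json")
    return manifest


def report(outdir: str | Path) -> str:
    """Human-readable run summary assembled from the manifest and the
    per-stage tables; missing sections are marked absent."""
    outdir = Path(outdir)
    lines = ["RRL pipeline run summary", "=" * 40]
    try:
        manifest = RunManifest.read(outdir / "manifest.json")
    except FileNotFoundError:
        return "no manifest found; run the pipeline first"

    lines.append("\n[counts]")
    for k, v in sorted(manifest.counts.items()):
        lines.append(f"  {k}: {v}")

    def section(title: str, key: str, fmt):
        lines.append(f"\n[{title}]")
        path = manifest.outputs.get(key)
        if not path or not Path(path).exists():
            lines.append("  (absent)")
            return
        fmt(Path(path))

    def cat_table(path: Path, limit: int = 15):
        rows = path.read_text().splitlines()
        for row in rows[:limit]:
            lines.append("  " + row)
        if len(rows) > limit:
            lines.append(f"  ... ({len(rows) - limit} more rows)")

    section("coverage enrichment", "coverage", cat_table)
    section("segregation shares", "segregation", cat_table)
    section("LD decay profile", "ld_profile", cat_table)
    section("PCA", "pca", cat_table)
    section("concordance", "concordance", cat_table)
    return "\n".join(lines)
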