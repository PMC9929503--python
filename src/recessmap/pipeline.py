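"""End-to-end orchestration: simulate -> segregate -> gwas -> bsa -> annotate.

One RunConfig (YAML-serialisable) drives the whole cascade under a single
seed; every intermediate is written to the output directory as a text
fixture (FASTA/GFF3/VCF/TSV/JSON) so the same files feed the standalone
CLI subcommands in real-data mode. Identical (config, seed) pairs yield
identical summaries and identical fixture bytes.

Random-draw order under the run seed: reference -> mapping-family
founders -> F1 parents -> F2 panel -> segregation cohorts -> panel
depths -> pools.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate as ann
from . import assoc, bsa, io, segregation
from .models import DEFAULT_CROSS_PLANS, CrossPlan, Individual, PoolSpec, VariantTable
from .simcross import (
    GenomeSpec,
    Reference,
    build_reference,
    cross,
    founder,
    founder_pair_at_locus,
    genotype_panel,
    phenotype_of,
    simulate_pool_counts,
)

log = logging.getLogger("recessmap")


@dataclass
class RunConfig:
    """All tunables of one pipeline run; round-trips losslessly via YAML."""

    seed: int = 1
    genome: GenomeSpec = field(default_factory=GenomeSpec)
    # F2 sequencing panel
    n_yellow: int = 20
    n_black: int = 20
    panel_mean_depth: float = 12.91
    # pooled bulks
    pool_n: int = 24
    pool_coverage: dict = field(
        default_factory=lambda: {"WW": 35.31, "YY": 33.79, "F1het": 29.94}
    )
    pool_error_rate: float = 0.01
    # segregation design
    n_per_sampling: int = 500
    n_samplings: int = 3
    # association
    alpha_gwas: float = 0.01
    min_mean_dp: float = 5.0
    max_mean_dp: float = 250.0
    min_call_rate: float = 0.95
    # bulk-segregant screen
    epsilon_homozygous: float = 0.10
    pool_min_depth: int = 10
    alpha_balance: float = 0.001
    other_epsilon: float = 0.05
    phenotype_rule: str = "recessive"
    outdir: str = "results/run"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["genome"] = dataclasses.asdict(self.genome)
        d["genome"]["chromosomes"] = [list(c) for c in self.genome.chromosomes]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        g = dict(d.pop("genome", {}))
        if "chromosomes" in g:
            g["chromosomes"] = tuple(tuple(c) for c in g["chromosomes"])
        return cls(genome=GenomeSpec(**g), **d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class Study:
    """Everything one simulated study produces, in memory."""

    config: RunConfig
    reference: Reference
    panel: list[Individual]
    panel_phenotypes: list[str]
    panel_genotypes: np.ndarray  # (n_variants, n_samples)
    panel_depths: np.ndarray
    pools: pd.DataFrame
    cohort_counts: pd.DataFrame  # cross, n_black, n_yellow


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_study(config: RunConfig) -> Study:
    """Forward-simulate the full study design under the run seed."""
    rng_ref, rng_found, rng_f2, rng_seg, rng_depth, rng_pool = _spawn(config.seed, 6)
    spec = config.genome
    t0 = time.perf_counter()

    reference = build_reference(spec, rng_ref)
    vt = reference.variants
    ci = reference.causal_index
    log.info("reference built: %d variants, causal index %d", len(vt), ci)

    # mapping family: WT x YM founders -> two F1 carriers -> F2 panel
    wt = founder(vt, "WT", rng_found, "WT_founder")
    ym = founder(vt, "YM", rng_found, "YM_founder")
    f1_dam = cross(ym, wt, 1, vt, rng_found, spec.cm_per_mb, id_prefix="F1d", line="F1")[0]
    f1_sire = cross(wt, ym, 1, vt, rng_found, spec.cm_per_mb, id_prefix="F1s", line="F1")[0]

    yellow: list[Individual] = []
    black: list[Individual] = []
    while len(yellow) < config.n_yellow or len(black) < config.n_black:
        for ind in cross(f1_dam, f1_sire, 80, vt, rng_f2, spec.cm_per_mb):
            ph = phenotype_of(ind, ci, config.phenotype_rule)
            if ph == "yellow" and len(yellow) < config.n_yellow:
                yellow.append(ind)
            elif ph == "black" and len(black) < config.n_black:
                black.append(ind)
    panel = yellow + black
    for i, ind in enumerate(panel):
        ind.id = f"{'Y' if i < len(yellow) else 'B'}{(i % len(yellow)) + 1:02d}"
    phenotypes = ["yellow"] * len(yellow) + ["black"] * len(black)

    # segregation cohorts at the causal locus only (phenotype depends on
    # nothing else), using the same meiosis model
    seg_rows = []
    for plan in DEFAULT_CROSS_PLANS:
        dam, sire, vt1 = founder_pair_at_locus(plan.dam_genotype, plan.sire_genotype)
        nb = ny = 0
        for _ in range(config.n_samplings):
            for ind in cross(dam, sire, config.n_per_sampling, vt1, rng_seg):
                if phenotype_of(ind, 0, config.phenotype_rule) == "yellow":
                    ny += 1
                else:
                    nb += 1
        seg_rows.append({"cross": plan.label, "n_black": nb, "n_yellow": ny})
    cohort_counts = pd.DataFrame(seg_rows)

    G, DP = genotype_panel(panel, config.panel_mean_depth, rng_depth)

    # pooled bulks from unrelated founder-line and F1 individuals
    ww_members = [founder(vt, "WT", rng_pool, f"WWp{i}") for i in range(config.pool_n)]
    yy_members = [founder(vt, "YM", rng_pool, f"YYp{i}") for i in range(config.pool_n)]
    het_members = []
    for i in range(config.pool_n):
        w = founder(vt, "WT", rng_pool, f"hw{i}")
        y = founder(vt, "YM", rng_pool, f"hy{i}")
        het_members.append(
            cross(w, y, 1, vt, rng_pool, spec.cm_per_mb, id_prefix=f"HET{i}", line="F1")[0]
        )
    frames = []
    for pool_id, members in (("WW", ww_members), ("YY", yy_members), ("F1het", het_members)):
        spec_p = PoolSpec(
            pool_id=pool_id,
            n_individuals=config.pool_n,
            mean_coverage=config.pool_coverage[pool_id],
            error_rate=config.pool_error_rate,
        )
        frames.append(simulate_pool_counts(members, spec_p, vt, rng_pool))
    pools = frames[0]
    for f in frames[1:]:
        pools = pools.merge(f, on=["chrom", "pos"])
    pools = pools.rename(columns={c: c.replace("f1het", "het") for c in pools.columns})

    log.info("simulation done in %.1fs", time.perf_counter() - t0)
    return Study(
        config=config,
        reference=reference,
        panel=panel,
        panel_phenotypes=phenotypes,
        panel_genotypes=G,
        panel_depths=DP,
        pools=pools,
        cohort_counts=cohort_counts,
    )


def write_fixture_set(study: Study, outdir: str | Path) -> dict[str, str]:
    """Write the complete text fixture set; returns the file map."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ref = study.reference
    files = {
        "fasta": str(out / "reference.fa"),
        "gff3": str(out / "genes.gff3"),
        "vcf": str(out / "panel.vcf"),
        "pools": str(out / "pools.tsv"),
        "phenotypes": str(out / "phenotypes.tsv"),
        "segregation_counts": str(out / "segregation_counts.tsv"),
        "manifest": str(out / "manifest.json"),
    }
    io.write_fasta({c: ref.chrom_seq(c) for c, _ in ref.spec.chromosomes}, files["fasta"])
    io.write_gff3([ref.gene], files["gff3"])
    io.write_vcf(
        ref.variants.df[["chrom", "pos", "ref", "alt"]],
        study.panel_genotypes,
        study.panel_depths,
        [ind.id for ind in study.panel],
        dict(ref.spec.chromosomes),
        files["vcf"],
    )
    io.write_tsv(study.pools, files["pools"])
    io.write_phenotypes(
        [ind.id for ind in study.panel], study.panel_phenotypes, files["phenotypes"]
    )
    io.write_tsv(study.cohort_counts, files["segregation_counts"])
    io.write_manifest(
        {
            "seed": study.config.seed,
            "config": study.config.to_dict(),
            "n_variants": len(ref.variants),
            "n_samples": len(study.panel),
            "files": {k: Path(v).name for k, v in files.items()},
        },
        files["manifest"],
    )
    return files


@dataclass
class RunSummary:
    config: RunConfig
    segregation: pd.DataFrame
    scan: pd.DataFrame
    threshold: float
    region: assoc.PeakRegion | None
    funnel: bsa.FunnelReport
    effects: pd.DataFrame
    effect_summary: dict[str, int]
    top_candidate: dict | None
    files: dict[str, str]

    def to_dict(self) -> dict:
        return {
            "seed": self.config.seed,
            "n_sites_scanned": int(len(self.scan)),
            "threshold": round(self.threshold, 4),
            "region": None
            if self.region is None
            else {
                "chrom": self.region.chrom,
                "start": self.region.start,
                "end": self.region.end,
                "n_significant": self.region.n_significant,
                "span_mb": self.region.span_mb,
            },
            "funnel": self.funnel.to_dict(),
            "effect_summary": self.effect_summary,
            "top_candidate": self.top_candidate,
            "segregation": self.segregation.to_dict(orient="records"),
            "files": self.files,
        }


def run_all(config: RunConfig, write_files: bool = True) -> RunSummary:
    """Execute every stage in order on one simulated study."""
    study = simulate_study(config)
    ref = study.reference

    stage = "segregation"
    try:
        plan_gts = {p.label: (p.dam_genotype, p.sire_genotype) for p in DEFAULT_CROSS_PLANS}
        seg_table = segregation.segregation_table(study.cohort_counts, plan_gts)

        stage = "gwas"
        vdf = ref.variants.df[["chrom", "pos", "ref", "alt", "is_causal"]]
        keep = np.array(
            [
                assoc.site_filter(
                    study.panel_genotypes[i],
                    study.panel_depths[i],
                    config.min_mean_dp,
                    config.max_mean_dp,
                    config.min_call_rate,
                )[0]
                for i in range(len(vdf))
            ]
        )
        y = np.array([1 if p == "yellow" else 0 for p in study.panel_phenotypes])
        scan, threshold = assoc.genome_scan(
            vdf[keep], study.panel_genotypes[keep], y, config.alpha_gwas
        )
        region = assoc.peak_region(scan)

        stage = "bsa"
        sig = set(
            zip(scan.loc[scan["significant"], "chrom"], scan.loc[scan["significant"], "pos"])
        )
        funnel = bsa.apply_cascade(
            vdf.reset_index(drop=True),
            study.pools,
            region,
            sig,
            study.panel_genotypes,
            np.array(study.panel_phenotypes),
            epsilon=config.epsilon_homozygous,
            min_depth=config.pool_min_depth,
            alpha_balance=config.alpha_balance,
            other_epsilon=config.other_epsilon,
        )

        stage = "annotate"
        ref_seqs = {c: ref.chrom_seq(c) for c, _ in ref.spec.chromosomes}
        effects, effect_summary = ann.annotate_candidates(
            funnel.candidates, [ref.gene], ref_seqs
        )
    except Exception as err:  # annotate stage failures carry their stage name
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    top = None
    stops = effects[effects["consequence"] == "stop_gain"] if len(effects) else effects
    if len(stops):
        top = stops.iloc[0].to_dict()
        top = {k: (v.item() if hasattr(v, "item") else v) for k, v in top.items()}

    files: dict[str, str] = {}
    if write_files:
        out = Path(config.outdir)
        files = write_fixture_set(study, out / "fixtures")
        io.write_tsv(seg_table, out / "segregation.tsv")
        manhattan = scan[["chrom", "pos", "neglog10p", "significant"]]
        io.write_tsv(scan, out / "gwas.tsv")
        io.write_tsv(manhattan, out / "manhattan.tsv")
        io.write_tsv(funnel.to_frame(), out / "funnel.tsv")
        io.write_tsv(effects, out / "candidates.tsv")
        files.update(
            {
                "segregation": str(out / "segregation.tsv"),
                "gwas": str(out / "gwas.tsv"),
                "manhattan": str(out / "manhattan.tsv"),
                "funnel": str(out / "funnel.tsv"),
                "candidates": str(out / "candidates.tsv"),
            }
        )

    summary = RunSummary(
        config=config,
        segregation=seg_table,
        scan=scan,
        threshold=threshold,
        region=region,
        funnel=funnel,
        effects=effects,
        effect_summary=effect_summary,
        top_candidate=top,
        files=files,
    )
    if write_files:
        Path(config.outdir, "summary.json").write_text(
            json.dumps(summary.to_dict(), indent=2, sort_keys=True, default=str) + "\n"
        )
    return summary


def report(summary: RunSummary) -> str:
    """Human-readable run report."""
    lines = ["# Recessive-locus mapping run", ""]
    lines.append("## Segregation ratios")
    lines.append(summary.segregation.to_string(index=False))
    lines.append("")
    lines.append(f"## Association scan: {len(summary.scan)} sites, "
                 f"-log10(p) threshold {summary.threshold:.2f}")
    if summary.region is None:
        lines.append("No genome-wide significant SNPs; no candidate interval.")
    else:
        r = summary.region
        lines.append(
            f"Peak on {r.chrom}: {r.start:,}-{r.end:,} "
            f"({r.span_mb:.2f} Mb, {r.n_significant} significant SNPs)"
        )
    lines.append("")
    lines.append("## Bulk-segregant funnel")
    for name, n_in, n_out in summary.funnel.stages:
        lines.append(f"  {name}: {n_in} -> {n_out}")
    if summary.funnel.candidates is None or len(summary.funnel.candidates) == 0:
        lines.append("No perfectly associated SNPs.")
    lines.append("")
    lines.append("## Candidate consequences")
    lines.append(json.dumps(summary.effect_summary, sort_keys=True))
    if summary.top_candidate:
        t = summary.top_candidate
        lines.append(
            f"Top candidate: {t['chrom']}:{t['pos']} {t['ref']}>{t['alt']} "
            f"{t['consequence']} {t['hgvs_c']} {t['hgvs_p']}"
        )
    if summary.files.get("manhattan"):
        lines.append(f"Manhattan table: {summary.files['manhattan']}")
    return "\n".join(lines)
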