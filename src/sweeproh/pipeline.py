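"""End-to-end pipeline: config, stage orchestration, outputs, manifest.

A run executes, in order: variant filters -> (optional LD prune) ->
windowed statistics (pi, F_ST, pi-ratio, Tajima's D) -> ROH detection ->
F_ROH -> ROH islands -> joint-tail sweep selection at both configured
tails -> region merging -> overlap of sweeps with islands and with a QTL
track.  Every output is a tidy TSV/BED and the resolved thresholds, stage
row counts and configuration are echoed in a run manifest.  A rerun with
the same configuration and seed reproduces every table byte-identically.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (
    GenomeLayout,
    GenomicInterval,
    filter_maf_missing,
    ld_prune,
    make_windows,
)
from .roh import (
    CLASS_LABELS,
    LENGTH_CLASSES,
    ROHParams,
    common_roh,
    detect_roh_all,
    f_roh,
    roh_islands,
    snp_roh_ratio,
)
from .sweep import (
    ScanConfig,
    annotate_tajima,
    intersect,
    merge_regions,
    qtl_overlap,
    resolve_thresholds,
    select_windows,
)
from .synthgen import SimParams, simulate_populations
from .vcfio import (
    read_intervals,
    read_layout_table,
    read_population_table,
    read_vcf,
    write_intervals,
    write_vcf,
)
from .windowstats import fst_windows, pi_ratio_windows, pi_windows

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"


@dataclass
class PipelineConfig:
    """Structured run configuration (YAML on disk).

    Defaults mirror the published analysis parameters: 100 kb windows with
    10 kb steps, PLINK ROH parameter block, 1%/5% scan tails, LD pruning
    50/10/0.1 applied before the ROH stage, LD decay to 1000 kb with MAF
    0.05 and 60% call rate.
    """

    seed: int | None = None
    output_dir: str = "out"
    vcf: str | None = None
    layout: str | None = None
    populations: str | None = None
    qtl: str | None = None
    window_size: int = 100_000
    window_step: int = 10_000
    reference_pop: str = "pop2"
    target_pop: str = "pop1"
    tails: tuple[float, ...] = (0.01, 0.05)
    roh_params: ROHParams = field(default_factory=ROHParams)
    prune_enabled: bool = True
    prune_stage: str = "roh"  # "roh" | "all" | "none"
    prune_window_snps: int = 50
    prune_step_snps: int = 10
    prune_r2_max: float = 0.1
    maf_min: float = 0.0
    max_missing_frac: float = 1.0
    island_tail: float = 0.01
    island_merge_gap: int = 100_000
    common_roh_min_samples: int = 2
    max_join_gap: int = 0
    treat_zero_pi_as_max: bool = False
    simulate: dict[str, Any] | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        roh_block = raw.pop("roh_params", {})
        tails = raw.pop("tails", (0.01, 0.05))
        cfg = cls(**raw)
        cfg.tails = tuple(float(t) for t in tails)
        cfg.roh_params = ROHParams(**roh_block)
        return cfg

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["tails"] = list(self.tails)
        return d


def sim_params_from_config(config: PipelineConfig) -> SimParams:
    """Build generator parameters from the config's ``simulate`` block."""
    if config.simulate is None:
        raise ValueError("config has no simulate block")
    if config.seed is None:
        raise ValueError("seed is required for simulation (field: seed)")
    block = dict(config.simulate)
    chroms = block.pop("chromosomes")
    layout = GenomeLayout(
        chrom_names=tuple(c["name"] for c in chroms),
        chrom_lengths=tuple(int(c["length"]) for c in chroms),
        autosome_flags=tuple(bool(c.get("autosome", True)) for c in chroms),
    )
    sweeps = tuple(
        (
            s["pop"],
            GenomicInterval(s["chrom"], int(s["start"]), int(s["end"])),
            float(s.get("intensity", 1.0)),
        )
        for s in block.pop("sweeps", [])
    )
    rohs = tuple(
        (r["sample"], GenomicInterval(r["chrom"], int(r["start"]), int(r["end"])))
        for r in block.pop("roh", [])
    )
    return SimParams(
        layout=layout,
        sweep_specs=sweeps,
        roh_specs=rohs,
        seed=config.seed,
        **block,
    )


def cmd_simulate(config: PipelineConfig) -> dict[str, Path]:
    """Generate synthetic genotypes plus truth files into the output dir."""
    params = sim_params_from_config(config)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix, truth = simulate_populations(params)

    paths = {
        "vcf": outdir / "synthetic.vcf",
        "layout": outdir / "layout.tsv",
        "populations": outdir / "populations.tsv",
        "truth_sweeps": outdir / "truth_sweeps.bed",
        "truth_roh": outdir / "truth_roh.bed",
        "truth_fractions": outdir / "truth_autozygous_fraction.tsv",
        "params": outdir / "sim_params.json",
    }
    write_vcf(matrix, params.layout, paths["vcf"])
    with open(paths["layout"], "w") as fh:
        for name, length, auto in zip(
            params.layout.chrom_names,
            params.layout.chrom_lengths,
            params.layout.autosome_flags,
        ):
            fh.write(f"{name}\t{length}\t{int(auto)}\n")
    spec = params.population_spec()
    with open(paths["populations"], "w") as fh:
        for sample, pop in spec.assignments.items():
            fh.write(f"{sample}\t{pop}\n")
    write_intervals(
        [
            GenomicInterval(iv.chrom, iv.start, iv.end, name=pop, category=f"{i:g}")
            for pop, iv, i in truth.sweep_intervals
        ],
        paths["truth_sweeps"],
    )
    write_intervals(
        [
            GenomicInterval(iv.chrom, iv.start, iv.end, name=sample)
            for sample, ivs in truth.roh_intervals.items()
            for iv in ivs
        ],
        paths["truth_roh"],
    )
    pd.DataFrame(
        sorted(truth.realized_autozygous_fraction.items()),
        columns=["sample", "planted_fraction"],
    ).to_csv(paths["truth_fractions"], sep="\t", index=False, float_format=FLOAT_FMT)
    with open(paths["params"], "w") as fh:
        json.dump(
            {
                "seed": params.seed,
                "n_pops": params.n_pops,
                "samples_per_pop": params.samples_per_pop,
                "snp_spacing_mean": params.snp_spacing_mean,
                "divergence_F": params.divergence_F,
                "n_variants": matrix.n_variants,
            },
            fh,
            indent=2,
        )
        fh.write("\n")
    logger.info("simulated %d variants x %d samples", matrix.n_variants, matrix.n_samples)
    return paths


def _window_stats_frame(stats, pops: list[str]) -> pd.DataFrame:
    rows = []
    for st in stats:
        row: dict[str, Any] = {
            "chrom": st.window.chrom,
            "start": st.window.start,
            "end": st.window.end,
            "n_snps": st.n_snps,
            "fst": st.fst,
            "pi_ratio": st.pi_ratio,
        }
        for pop in pops:
            row[f"pi_{pop}"] = st.pi_by_pop.get(pop)
            row[f"tajima_d_{pop}"] = st.tajima_d_by_pop.get(pop)
        rows.append(row)
    return pd.DataFrame(rows)


def cmd_run(config: PipelineConfig) -> dict[str, Any]:
    """Execute the full analysis; returns in-memory results plus manifest."""
    if config.seed is None:
        raise ValueError("seed is required (field: seed)")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.vcf is None and config.simulate is not None:
        cmd_simulate(config)
        config.vcf = str(outdir / "synthetic.vcf")
        config.layout = str(outdir / "layout.tsv")
        config.populations = str(outdir / "populations.tsv")
    for name in ("vcf", "layout", "populations"):
        path = getattr(config, name)
        if path is None or not Path(path).exists():
            raise ValueError(f"missing required input: {name} ({path})")

    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
        "thresholds": {},
    }
    timings: dict[str, float] = {}

    def stage(name):
        timings[name] = time.time()

    def done(name, **counts):
        manifest["stages"][name] = {
            "seconds": round(time.time() - timings[name], 3),
            **counts,
        }

    stage("load")
    layout = read_layout_table(config.layout)
    pops = read_population_table(config.populations)
    matrix = read_vcf(config.vcf, layout)
    pops.validate_against(matrix.sample_ids)
    done("load", n_variants=matrix.n_variants, n_samples=matrix.n_samples)

    stage("filter")
    if config.maf_min > 0 or config.max_missing_frac < 1:
        matrix = filter_maf_missing(matrix, config.maf_min, config.max_missing_frac)
    done("filter", n_variants=matrix.n_variants)

    stage("prune")
    pruned = matrix
    if config.prune_enabled and config.prune_stage != "none":
        pruned = ld_prune(
            matrix,
            config.prune_window_snps,
            config.prune_step_snps,
            config.prune_r2_max,
        )
    stats_matrix = pruned if config.prune_stage == "all" else matrix
    roh_matrix = pruned if config.prune_stage in ("roh", "all") else matrix
    done("prune", n_variants=pruned.n_variants if config.prune_enabled else matrix.n_variants)

    stage("window_stats")
    grid = make_windows(layout, config.window_size, config.window_step)
    stats = pi_windows(stats_matrix, pops, grid, tajima=True)
    fst_windows(stats_matrix, pops, config.reference_pop, config.target_pop, grid, stats)
    pi_ratio_windows(stats, config.reference_pop, config.target_pop)
    pop_labels = pops.populations
    wdf = _window_stats_frame(stats, pop_labels)
    wdf.to_csv(outdir / "window_stats.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    done("window_stats", n_windows=len(stats))

    stage("roh")
    segments = detect_roh_all(roh_matrix, config.roh_params)
    seg_df = pd.DataFrame(
        [
            {
                "sample": s.sample_id,
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "n_snps": s.n_snps,
                "kb": s.length / 1000.0,
                "het": s.het_count,
                "missing": s.missing_count,
            }
            for s in segments
        ],
        columns=["sample", "chrom", "start", "end", "n_snps", "kb", "het", "missing"],
    )
    seg_df.to_csv(outdir / "roh_segments.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    froh = f_roh(segments, layout, sample_ids=list(matrix.sample_ids))
    froh_df = pd.DataFrame(
        [
            {
                "sample": s,
                "population": pops.assignments[s],
                "n_segments": froh.n_segments[s],
                "froh": froh.total[s],
                **{f"froh_{lbl}": froh.by_class[lbl][s] for lbl in CLASS_LABELS},
            }
            for s in matrix.sample_ids
        ]
    )
    froh_df.to_csv(outdir / "froh.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    common = common_roh(segments, config.common_roh_min_samples)
    write_intervals(common, outdir / "common_roh.bed")
    done("roh", n_segments=len(segments), n_common=len(common))

    stage("islands")
    islands_by_pop: dict[str, list] = {}
    for pop in pop_labels:
        ratios = snp_roh_ratio(segments, roh_matrix, pops.samples_of(pop))
        islands_by_pop[pop] = roh_islands(
            ratios, roh_matrix, config.island_tail, config.island_merge_gap
        )
    island_rows = [
        {
            "population": pop,
            "chrom": isl.chrom,
            "start": isl.start,
            "end": isl.end,
            "n_snps": isl.n_snps,
            "peak_ratio": isl.peak_ratio,
            "mean_ratio": isl.mean_ratio,
        }
        for pop, isls in islands_by_pop.items()
        for isl in isls
    ]
    pd.DataFrame(
        island_rows,
        columns=["population", "chrom", "start", "end", "n_snps", "peak_ratio", "mean_ratio"],
    ).to_csv(outdir / "roh_islands.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    done("islands", **{f"n_islands_{p}": len(i) for p, i in islands_by_pop.items()})

    stage("sweep")
    regions_by_tail: dict[float, list] = {}
    for tail in config.tails:
        scan = ScanConfig(
            tail=tail,
            reference_pop=config.reference_pop,
            target_pop=config.target_pop,
            treat_zero_pi_as_max=config.treat_zero_pi_as_max,
        )
        resolve_thresholds(stats, scan)
        selected = select_windows(stats, scan)
        regions = merge_regions(selected, config.max_join_gap)
        annotate_tajima(regions, pop_labels)
        regions_by_tail[tail] = regions
        manifest["thresholds"][f"tail_{tail:g}"] = {
            "fst": scan.fst_threshold,
            "pi_ratio": scan.pi_ratio_threshold,
            "n_selected_windows": len(selected),
            "n_regions": len(regions),
        }
        tag = f"{100 * tail:g}pct"
        pd.DataFrame(
            [
                {
                    "chrom": r.chrom,
                    "start": r.start,
                    "end": r.end,
                    "n_windows": r.n_windows,
                    "max_fst": r.max_fst,
                    "max_pi_ratio": r.max_pi_ratio,
                    **{
                        f"mean_tajima_d_{p}": r.mean_tajima_d.get(p)
                        for p in pop_labels
                    },
                }
                for r in regions
            ],
            columns=["chrom", "start", "end", "n_windows", "max_fst", "max_pi_ratio"]
            + [f"mean_tajima_d_{p}" for p in pop_labels],
        ).to_csv(
            outdir / f"sweep_regions_{tag}.tsv",
            sep="\t",
            index=False,
            float_format=FLOAT_FMT,
        )
    done("sweep", **{f"n_regions_{t:g}": len(r) for t, r in regions_by_tail.items()})

    stage("overlap")
    target_islands = [i.interval() for i in islands_by_pop.get(config.target_pop, [])]
    overlap_results: dict[str, Any] = {}
    qtls = read_intervals(config.qtl) if config.qtl else []
    for tail, regions in regions_by_tail.items():
        tag = f"{100 * tail:g}pct"
        sweeps = [r.interval() for r in regions]
        both = intersect(sweeps, target_islands)
        write_intervals(both, outdir / f"sweep_island_overlap_{tag}.bed")
        overlap_results[tag] = {"n_sweep_island": len(both)}
        if qtls:
            report = qtl_overlap(sweeps, qtls)
            pd.DataFrame(
                sorted(report.category_counts.items()),
                columns=["category", "n_qtls"],
            ).assign(
                percent=lambda d: 100.0 * d.n_qtls / max(report.n_qtls_hit, 1)
            ).to_csv(
                outdir / f"qtl_categories_{tag}.tsv",
                sep="\t",
                index=False,
                float_format=FLOAT_FMT,
            )
            overlap_results[tag]["n_qtls_hit"] = report.n_qtls_hit
    done("overlap", **{k: v.get("n_sweep_island", 0) for k, v in overlap_results.items()})

    manifest["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return {
        "matrix": matrix,
        "stats": stats,
        "segments": segments,
        "froh": froh,
        "islands": islands_by_pop,
        "regions_by_tail": regions_by_tail,
        "manifest": manifest,
        "outdir": outdir,
    }


def cmd_report(output_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Summary tables from a completed run directory.

    Produces the ROH length-class distribution per population, the F_ROH
    population summary (total and per class, mean +/- SD), and QTL category
    counts when a QTL track was supplied.
    """
    outdir = Path(output_dir)
    needed = ["roh_segments.tsv", "froh.tsv"]
    missing = [n for n in needed if not (outdir / n).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run directory, missing: {missing}")

    seg = pd.read_csv(outdir / "roh_segments.tsv", sep="\t")
    froh = pd.read_csv(outdir / "froh.tsv", sep="\t")
    pop_of = dict(zip(froh["sample"], froh["population"]))

    class_rows = []
    for pop in sorted(set(pop_of.values())):
        samples = {s for s, p in pop_of.items() if p == pop}
        sub = seg[seg["sample"].isin(samples)] if len(seg) else seg
        lengths = sub["kb"] * 1000.0 if len(sub) else pd.Series(dtype=float)
        total = len(sub)
        for (lo, hi_), label in zip(LENGTH_CLASSES, CLASS_LABELS):
            in_class = sub[(lengths >= lo) & (lengths < hi_)] if total else sub
            n = len(in_class)
            class_rows.append(
                {
                    "population": pop,
                    "length_class": label,
                    "n_roh": n,
                    "percent": 100.0 * n / total if total else 0.0,
                    "mean_length_mb": (in_class["kb"].mean() / 1000.0) if n else np.nan,
                    "sd_length_mb": (in_class["kb"].std(ddof=1) / 1000.0)
                    if n > 1
                    else np.nan,
                }
            )
    roh_classes = pd.DataFrame(class_rows)

    agg_cols = ["froh"] + [f"froh_{lbl}" for lbl in CLASS_LABELS]
    froh_summary = (
        froh.groupby("population")[agg_cols].agg(["mean", "std"]).reset_index()
    )
    froh_summary.columns = [
        "_".join(c).rstrip("_") for c in froh_summary.columns.to_flat_index()
    ]

    tables = {"roh_length_classes": roh_classes, "froh_summary": froh_summary}
    for path in sorted(outdir.glob("qtl_categories_*.tsv")):
        tables[path.stem] = pd.read_csv(path, sep="\t")
    for name, df in tables.items():
        df.to_csv(outdir / f"report_{name}.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    return tables
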