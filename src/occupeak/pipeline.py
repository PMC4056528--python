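"""End-to-end orchestration: load inputs, run the analysis stages in order,
and emit one TSV per figure-level report table plus a run manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import annotate, enrichment, integrate, metagene, motifs, temporal
from .formats_io import (
    Peak,
    read_chrom_sizes,
    read_expression_table,
    read_fasta,
    read_gene_models,
    read_motif_meme,
    read_peaks_bed,
    read_signal_bedgraph,
)

logger = logging.getLogger(__name__)

STAGES = ("annotate", "cluster", "enrich", "scan", "p2g", "integrate")
TIME_LABELS = ("d0", "d9", "d28")

DEFAULT_PARAMS: dict[str, Any] = {
    # peaks significant at the 1e-10 level are retained
    "significance_threshold": 10.0,
    "motif_p_threshold": 1e-4,  # motif scan significance cut
    "fc_threshold": 1.5,  # >= 1.5-fold expression change
    "fdr_threshold": 0.05,  # BH FDR cut for DE classes
    "strict_log2_fc": False,
    "classification_mode": "summit",
    "background_length": 100,
    "metagene_floor": 0.5,
    "motif_eps": 1e-3,
}


class PipelineError(RuntimeError):
    pass


class DependencyError(PipelineError):
    """A stage was requested whose prerequisite stage is disabled."""


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(config_path: str | Path) -> dict:
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "inputs" not in cfg:
        raise PipelineError(f"{config_path}: config must define 'inputs'")
    params = dict(DEFAULT_PARAMS)
    params.update(cfg.get("params") or {})
    cfg["params"] = params
    cfg.setdefault("stages", list(STAGES))
    cfg.setdefault("seed", 0)
    return cfg


def run_pipeline(config_path: str | Path, outdir: str | Path | None = None) -> dict:
    """Execute the configured stages; returns the run manifest."""
    cfg = load_config(config_path)
    outdir = Path(outdir or cfg.get("outdir") or "occupeak_out")
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(cfg["stages"])
    for s in stages:
        if s not in STAGES:
            raise PipelineError(f"unknown stage {s!r}")
    manifest: dict[str, Any] = {
        "config": cfg,
        "seed": cfg["seed"],
        "inputs": {},
        "stages": {},
        "outputs": [],
        "status": "running",
    }
    inputs = cfg["inputs"]
    missing = []
    for key, value in _iter_input_paths(inputs):
        p = Path(value)
        if not p.exists():
            missing.append(f"{key}: {value}")
        else:
            manifest["inputs"][key] = {"path": str(p), "sha256": _checksum(p)}
    if missing:
        raise PipelineError("missing input files: " + "; ".join(missing))

    ctx: dict[str, Any] = {"cfg": cfg, "outdir": outdir, "manifest": manifest}
    try:
        _load_inputs(ctx)
        for stage in STAGES:
            if stage not in stages:
                continue
            t0 = time.monotonic()
            _STAGE_FUNCS[stage](ctx)
            manifest["stages"][stage] = {
                "seconds": round(time.monotonic() - t0, 3)
            }
        manifest["status"] = "complete"
    except Exception as exc:
        manifest["status"] = f"failed: {exc}"
        _write_manifest(manifest, outdir)
        raise
    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def _iter_input_paths(inputs: Mapping) -> list[tuple[str, str]]:
    out = []
    for key, value in inputs.items():
        if isinstance(value, Mapping):
            for sub, path in value.items():
                out.append((f"{key}.{sub}", path))
        else:
            out.append((key, value))
    return out


def _emit(ctx: dict, name: str, frame: pd.DataFrame) -> None:
    path = ctx["outdir"] / name
    frame.to_csv(path, sep="\t", index=False)
    ctx["manifest"]["outputs"].append(str(path))


def _load_inputs(ctx: dict) -> None:
    cfg = ctx["cfg"]
    inputs = cfg["inputs"]
    params = cfg["params"]
    ctx["genes"] = read_gene_models(
        inputs["genes"], dialect=inputs.get("genes_dialect", "bed12")
    )
    if "chrom_sizes" in inputs:
        ctx["chrom_sizes"] = read_chrom_sizes(inputs["chrom_sizes"])
    else:
        ctx["chrom_sizes"] = None
    raw_sets = []
    for label in TIME_LABELS:
        peaks = read_peaks_bed(
            inputs["peaks"][label],
            significance_threshold=params["significance_threshold"],
        )
        raw_sets.append(peaks)
    ctx["peak_sets"] = [
        [p for p in peaks if not p.low_significance] for peaks in raw_sets
    ]
    n_dropped = sum(len(r) - len(f) for r, f in zip(raw_sets, ctx["peak_sets"]))
    if n_dropped:
        logger.info("filtered %d sub-threshold peaks", n_dropped)
    ctx["index"] = annotate.GeneRegionIndex(
        ctx["genes"],
        chrom_sizes=ctx["chrom_sizes"],
    )


def _require(ctx: dict, key: str, stage: str, needed_by: str) -> Any:
    if key not in ctx:
        raise DependencyError(
            f"stage {needed_by!r} requires stage {stage!r}, which was "
            "disabled or has not run"
        )
    return ctx[key]


def _stage_annotate(ctx: dict) -> None:
    params = ctx["cfg"]["params"]
    mode = params["classification_mode"]
    index = ctx["index"]
    labels_per_time = []
    frames = []
    for t, label in enumerate(TIME_LABELS):
        table = annotate.annotation_table(ctx["peak_sets"][t], index, mode=mode)
        labels_per_time.append(list(table["category"]))
        dist = annotate.category_distribution(table["category"])
        dist.insert(0, "time", label)
        frames.append(dist)
        table.insert(0, "time", label)
        _emit(ctx, f"annotation_{label}.tsv", table)
    ctx["labels_per_time"] = labels_per_time
    _emit(ctx, "table_2A_category_distribution.tsv", pd.concat(frames))


def _stage_cluster(ctx: dict) -> None:
    _require(ctx, "labels_per_time", "annotate", "cluster")
    regions = temporal.build_consensus(ctx["peak_sets"])
    temporal.assign_temporal_clusters(regions)
    ctx["regions"] = regions
    index = ctx["index"]
    mode = ctx["cfg"]["params"]["classification_mode"]
    region_categories = []
    region_genes = []
    for r in regions:
        best = _strongest_member(r)
        cat, gene = annotate.classify_peak(best, index, mode=mode)
        region_categories.append(cat)
        region_genes.append(gene or "")
    ctx["region_categories"] = region_categories
    ctx["region_genes"] = region_genes
    table = temporal.regions_table(regions)
    table["category"] = region_categories
    table["gene_id"] = region_genes
    _emit(ctx, "table_3A_regions.tsv", table)
    _emit(ctx, "table_3B_cluster_summary.tsv", temporal.cluster_summary(regions))


def _strongest_member(region: temporal.ConsensusRegion) -> Peak:
    members = [p for peaks in region.member_peaks for p in peaks]
    return max(members, key=lambda p: (p.neglog10_p, -p.interval.start))


def _stage_enrich(ctx: dict) -> None:
    cfg = ctx["cfg"]
    params = cfg["params"]
    index = ctx["index"]
    chrom_sizes = ctx["chrom_sizes"]
    if chrom_sizes is None:
        raise PipelineError("enrich stage requires chrom_sizes input")
    labels_per_time = _require(ctx, "labels_per_time", "annotate", "enrich")
    rng = np.random.default_rng(cfg["seed"])
    frames = []
    bg_labels_all: list[str] = []
    for t, label in enumerate(TIME_LABELS):
        n = len(ctx["peak_sets"][t])
        if n == 0:
            continue
        background = enrichment.sample_random_intervals(
            chrom_sizes, n, length=params["background_length"], seed=rng
        )
        bg_labels = [
            index.classify_point(iv.chrom, iv.midpoint)[0] for iv in background
        ]
        bg_labels_all.extend(bg_labels)
        results = enrichment.category_enrichment(labels_per_time[t], bg_labels)
        frame = enrichment.enrichment_table(results)
        frame.insert(0, "time", label)
        frames.append(frame)
    ctx["background_labels"] = bg_labels_all
    _emit(ctx, "table_2B_enrichment.tsv", pd.concat(frames))
    # per-cluster category distribution vs an equal number of random regions
    if "regions" in ctx:
        rows = []
        regions = ctx["regions"]
        cats = ctx["region_categories"]
        for cluster in sorted({r.cluster_id for r in regions}):
            members = [
                cats[i] for i, r in enumerate(regions) if r.cluster_id == cluster
            ]
            background = enrichment.sample_random_intervals(
                chrom_sizes, len(members),
                length=params["background_length"], seed=rng,
            )
            bg = [
                index.classify_point(iv.chrom, iv.midpoint)[0]
                for iv in background
            ]
            results = enrichment.category_enrichment(members, bg)
            frame = enrichment.enrichment_table(results)
            frame.insert(0, "cluster", cluster)
            rows.append(frame)
        _emit(ctx, "table_3C_cluster_category.tsv", pd.concat(rows))


def _stage_scan(ctx: dict) -> None:
    cfg = ctx["cfg"]
    params = cfg["params"]
    inputs = cfg["inputs"]
    pwm = read_motif_meme(inputs["motif"])
    sequences = read_fasta(inputs["genome"])
    scored = motifs.ScoredPWM(pwm, eps=params["motif_eps"])
    hits = motifs.scan_sequence(
        pwm, sequences, p_threshold=params["motif_p_threshold"], scored=scored
    )
    ctx["pwm"] = pwm
    ctx["hits"] = hits
    hits_frame = pd.DataFrame(
        {
            "chrom": [h.interval.chrom for h in hits],
            "start": [h.interval.start for h in hits],
            "end": [h.interval.end for h in hits],
            "name": [f"hit_{i}" for i in range(len(hits))],
            "score": [h.score for h in hits],
            "strand": [h.strand for h in hits],
            "p_value": [h.p_value for h in hits],
        }
    )
    _emit(ctx, "motif_hits.tsv", hits_frame)
    # summit-distance profile on the matrix-deposition time point (d9)
    profiles = motifs.summit_distance_profile(ctx["peak_sets"][1], hits)
    rows = []
    for prof in profiles:
        for c, p in zip(prof.bin_centers, prof.probabilities):
            rows.append(
                {"tier": prof.tier, "bin_center": c, "probability": p,
                 "n_sites": prof.n_sites}
            )
    _emit(ctx, "table_2D_summit_profile.tsv", pd.DataFrame(rows))
    # motif-site category distribution joins the 2B comparison
    index = ctx["index"]
    motif_labels = [
        index.classify_point(h.interval.chrom, h.center)[0] for h in hits
    ]
    dist = annotate.category_distribution(motif_labels)
    _emit(ctx, "motif_category_distribution.tsv", dist)


def _stage_p2g(ctx: dict) -> None:
    cfg = ctx["cfg"]
    inputs = cfg["inputs"]
    params = cfg["params"]
    ip = read_signal_bedgraph(inputs["ip"]["d9"])
    input_track = read_signal_bedgraph(inputs["input"])
    profiles: dict[str, metagene.GeneBindingProfile] = {}
    for gene in ctx["genes"]:
        try:
            schema = metagene.build_window_schema(gene)
        except metagene.GeneTooShortError:
            logger.info("gene %s too short for decile schema", gene.gene_id)
            continue
        profiles[gene.gene_id] = metagene.window_signal_ratio(
            schema, ip, input_track,
            floor=params["metagene_floor"], chrom_sizes=ctx["chrom_sizes"],
        )
    ctx["profiles"] = profiles
    frame = metagene.profiles_frame(list(profiles.values()))
    frame.insert(0, "gene_id", frame.index)
    _emit(ctx, "table_5E_profiles.tsv", frame.reset_index(drop=True))
    bins = metagene.binding_level_bins(profiles)
    _emit(
        ctx,
        "binding_level_bins.tsv",
        pd.DataFrame(
            {"gene_id": list(bins), "bin": [bins[g] for g in bins]}
        ),
    )


def _stage_integrate(ctx: dict) -> None:
    cfg = ctx["cfg"]
    inputs = cfg["inputs"]
    params = cfg["params"]
    conditions = cfg.get("conditions") or {}
    cond_treat = conditions.get("treatment", "knockdown")
    cond_control = conditions.get("control", "control")
    condition_map = conditions.get("samples")
    if condition_map is None:
        raise PipelineError("config must map samples to conditions")
    expr = read_expression_table(inputs["expression"], condition_map)
    de = integrate.moderated_t_de(expr, cond_treat, cond_control)
    classified = integrate.classify_genes(
        de,
        fc_threshold=params["fc_threshold"],
        fdr_threshold=params["fdr_threshold"],
        strict_log2=params["strict_log2_fc"],
    )
    _emit(ctx, "table_5A_de.tsv", classified)
    classes = dict(zip(classified["gene_id"], classified["gene_class"]))
    ctx["gene_classes"] = classes

    index = ctx["index"]
    mode = params["classification_mode"]
    # peaks-per-gene comparisons over all peaks and per-time subsets
    frames = []
    subsets = {
        "all": [p for peaks in ctx["peak_sets"] for p in peaks],
        "d0": list(ctx["peak_sets"][0]),
        "d9": list(ctx["peak_sets"][1]),
    }
    for name, peaks in subsets.items():
        mapping, _ = annotate.associate_peaks_to_genes(peaks, index, mode=mode)
        frames.append(integrate.peaks_per_gene_test(mapping, classes, name))
    _emit(ctx, "table_5B_peaks_per_gene.tsv", pd.concat(frames))

    # category distribution comparisons between classes (Fisher)
    regions = _require(ctx, "regions", "cluster", "integrate")
    region_cats = ctx["region_categories"]
    region_genes = ctx["region_genes"]
    counts: dict[str, dict[str, int]] = {
        c: {cat: 0 for cat in annotate.CATEGORIES} for c in integrate.GENE_CLASSES
    }
    for cat, gene in zip(region_cats, region_genes):
        cls = classes.get(gene)
        if cls is not None:
            counts[cls][cat] += 1
    frames = []
    for cls in (integrate.UP, integrate.DOWN):
        comp = enrichment.compare_category_distributions(
            counts[cls], counts[integrate.NONRESPONSIVE]
        )
        comp.insert(0, "gene_class", cls)
        frames.append(comp)
    _emit(ctx, "table_5C_category_by_class.tsv", pd.concat(frames))

    # per-category fold change of region intensities, d9 vs d0
    gene_regions: dict[str, list[Peak]] = {}
    region_peaks: list[Peak] = []
    cat_by_name: dict[str, str] = {}
    i0: dict[str, float] = {}
    i1: dict[str, float] = {}
    for i, r in enumerate(regions):
        name = f"region_{i}"
        pseudo = Peak(interval=r.interval, name=name)
        region_peaks.append(pseudo)
        cat_by_name[name] = region_cats[i]
        i0[name] = r.intensity[0]
        i1[name] = r.intensity[1]
        if region_genes[i]:
            gene_regions.setdefault(region_genes[i], []).append(pseudo)
    fc = integrate.foldchange_by_location(gene_regions, classes, cat_by_name, i0, i1)
    _emit(ctx, "table_5D_foldchange_by_location.tsv", fc)

    # per-window rank-sum tests of metagene profiles, per class vs control
    profiles = _require(ctx, "profiles", "p2g", "integrate")
    nonresp = [
        g for g, c in classes.items()
        if c == integrate.NONRESPONSIVE and g in profiles
    ]
    frames = []
    for cls in (integrate.DOWN, integrate.UP):
        ids = [g for g, c in classes.items() if c == cls and g in profiles]
        if not ids or not nonresp:
            continue
        tests = metagene.group_window_test(profiles, ids, nonresp)
        tests.insert(0, "gene_class", cls)
        frames.append(tests)
    if frames:
        _emit(ctx, "table_5E_window_tests.tsv", pd.concat(frames))

    # conservation of best motif sites, down/up vs length-matched controls
    hits = _require(ctx, "hits", "scan", "integrate")
    conservation = read_signal_bedgraph(inputs["conservation"])
    best_sites = {
        p.name: motifs.best_site_per_peak(p, hits) for p in region_peaks
    }
    summaries, n_excluded = integrate.gene_conservation(
        gene_regions, best_sites, conservation
    )
    gene_lengths = {g.gene_id: g.length for g in ctx["genes"]}
    rows = []
    cons_rows = []
    for gid, s in sorted(summaries.items()):
        cons_rows.append(
            {"gene_id": gid, "gene_class": classes.get(gid, ""),
             "mean_phylop": s.mean_phylop, "n_sites": s.n_sites}
        )
    rng = np.random.default_rng(cfg["seed"])
    pool = {
        g: gene_lengths[g]
        for g in summaries
        if classes.get(g) == integrate.NONRESPONSIVE
    }
    for cls in (integrate.DOWN, integrate.UP):
        targets = {
            g: gene_lengths[g] for g in summaries if classes.get(g) == cls
        }
        if len(targets) < 3 or len(pool) < len(targets):
            logger.info("conservation comparison skipped for class %s", cls)
            continue
        matches, diag = integrate.length_matched_controls(targets, pool, seed=rng)
        group = [summaries[g] for g in sorted(targets)]
        control = [summaries[m] for m in sorted(matches.values())]
        res = integrate.conservation_ks(group, control)
        rows.append(
            {
                "gene_class": cls,
                "n_genes": len(group),
                "mean_group": float(np.mean([s.mean_phylop for s in group])),
                "mean_matched_control": float(
                    np.mean([s.mean_phylop for s in control])
                ),
                "ks_D": res.statistic,
                "ks_p": res.p_value,
                "max_abs_length_delta": diag["max_abs_delta"],
            }
        )
    _emit(ctx, "gene_conservation.tsv", pd.DataFrame(cons_rows))
    _emit(ctx, "table_5F_conservation.tsv", pd.DataFrame(rows))
    ctx["manifest"]["n_genes_without_motif_peaks"] = n_excluded


_STAGE_FUNCS = {
    "annotate": _stage_annotate,
    "cluster": _stage_cluster,
    "enrich": _stage_enrich,
    "scan": _stage_scan,
    "p2g": _stage_p2g,
    "integrate": _stage_integrate,
}


def write_pipeline_config(
    paths: Mapping[str, Path],
    outdir: str | Path,
    config_path: str | Path,
    seed: int = 0,
    n_replicates: int = 3,
) -> Path:
    """Emit a ready-to-run pipeline config for a simulated study directory."""
    samples = {
        "control": [f"ctrl_{i + 1}" for i in range(n_replicates)],
        "knockdown": [f"kd_{i + 1}" for i in range(n_replicates)],
    }
    cfg = {
        "inputs": {
            "genome": str(paths["genome"]),
            "chrom_sizes": str(paths["chrom_sizes"]),
            "genes": str(paths["genes"]),
            "peaks": {t: str(paths[f"peaks_{t}"]) for t in TIME_LABELS},
            "ip": {t: str(paths[f"ip_{t}"]) for t in TIME_LABELS},
            "input": str(paths["input"]),
            "conservation": str(paths["conservation"]),
            "motif": str(paths["motif"]),
            "expression": str(paths["expression"]),
        },
        "conditions": {
            "treatment": "knockdown",
            "control": "control",
            "samples": samples,
        },
        "params": dict(DEFAULT_PARAMS),
        "stages": list(STAGES),
        "outdir": str(outdir),
        "seed": seed,
    }
    config_path = Path(config_path)
    with open(config_path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return config_path


__all__ = [
    "STAGES",
    "DEFAULT_PARAMS",
    "PipelineError",
    "DependencyError",
    "load_config",
    "run_pipeline",
    "write_pipeline_config",
]
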