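"""Synthetic study generator with machine-readable ground truth.

Produces a toy genome, non-overlapping gene models, three time-point peak
sets populating all seven presence/absence patterns crossed with the six
genomic categories, IP/Input signal tracks with extra enrichment around the
TSS of designated "down" genes, planted motif instances near peak summits
(jitter tied to peak-score tier), a conservation track with an offset over
motif sites of down-class genes, and a 2-condition x 3-replicate expression
matrix with planted up/down genes.  Every emitted file round-trips through
formats_io; everything is reproducible from the seed.
"""

from __future__ import annotations

import bisect
import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import annotate
from .formats_io import (
    ExpressionMatrix,
    GeneModel,
    GenomicInterval,
    Peak,
    PWMRecord,
    SignalTrack,
    write_chrom_sizes,
    write_expression_table,
    write_fasta,
    write_gene_models_bed12,
    write_motif_meme,
    write_peaks_bed,
    write_signal_bedgraph,
)
from .integrate import DOWN, NONRESPONSIVE, UP
from .temporal import PATTERN_TO_CLUSTER

logger = logging.getLogger(__name__)

_BASES = "ACGT"

PATTERNS: tuple[tuple[bool, bool, bool], ...] = tuple(PATTERN_TO_CLUSTER)
TIME_LABELS = ("d0", "d9", "d28")


class SimulationError(RuntimeError):
    pass


@dataclass
class SimulationConfig:
    seed: int = 0
    # genome
    n_chromosomes: int = 2
    chrom_length: int = 5_000_000
    gc_content: float = 0.5
    # genes
    n_genes: int = 300
    gene_length_min: int = 5_000
    gene_length_max: int = 30_000
    exon_count_min: int = 2
    exon_count_max: int = 8
    gene_margin: int = 1_000
    # peaks
    peaks_per_cell: int = 40  # per (pattern, category) combination
    # genic bias: fewer intergenic placements so peaks are depleted there
    # relative to random background
    category_cell_counts: dict[str, int] = field(default_factory=dict)
    peak_width: int = 200
    peak_edge_jitter: int = 20
    region_margin: int = 70  # reserved space around each region envelope
    cluster_log2_count_mean: dict[int, float] = field(
        default_factory=lambda: {1: 9.0, 4: 8.5, 5: 8.0, 2: 7.5, 3: 7.0,
                                 6: 6.5, 7: 6.0}
    )
    count_log2_sd: float = 0.5
    library_size: float = 1e7
    # motif / conservation
    motif_consensus: str = "TGTGGTTT"
    motif_peak_prob: float = 0.85
    motif_jitter_sd: tuple[float, float, float] = (5.0, 20.0, 40.0)
    conservation_noise_sd: float = 0.1
    conservation_offset: float = 1.0
    # signal tracks
    signal_bin: int = 50
    input_baseline: float = 1.0
    input_noise_sd: float = 0.05
    bump_scale: float = 0.05  # bump amplitude per normalized read count
    bump_sd: float = 100.0
    tss_bump_amplitude: float = 3.0
    # expression
    n_up: int = 60
    n_down: int = 25
    expression_baseline_mean: float = 8.0
    expression_baseline_sd: float = 1.0
    expression_effect_log2: float = 1.0
    expression_noise_sd: float = 0.2
    n_replicates: int = 3
    max_placement_attempts: int = 200


@dataclass
class RegionTruth:
    region_id: str
    chrom: str
    anchor: int  # summit shared by all member peaks
    pattern: str  # e.g. "101" over (d0, d9, d28)
    cluster_id: int
    category: str
    gene_id: str  # "" for unassociated intergenic regions
    tier: str = ""
    motif_offset: int | None = None
    motif_start: int | None = None
    motif_strand: str = "+"
    max_neglog10_p: float = 0.0


@dataclass
class GeneTruth:
    gene_id: str
    gene_class: str
    length: int


@dataclass
class SimulationTruth:
    regions: list[RegionTruth]
    genes: list[GeneTruth]

    def regions_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(r) for r in self.regions])

    def genes_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(g) for g in self.genes])


def consensus_pwm(
    consensus: str, peak_prob: float = 0.85, pseudocount: float = 0.01
) -> PWMRecord:
    """A PWM peaked at the given consensus word over a uniform background."""
    probs = np.full((len(consensus), 4), (1.0 - peak_prob) / 3.0)
    for i, base in enumerate(consensus.upper()):
        probs[i, _BASES.index(base)] = peak_prob
    return PWMRecord(probs=probs, pseudocount=pseudocount, name="planted")


def simulate_genome(
    config: SimulationConfig, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """IID bases at the configured GC content, as uint8 code arrays."""
    if config.n_chromosomes < 1:
        raise SimulationError("need at least one chromosome")
    gc = config.gc_content
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return {
        f"chr{i + 1}": rng.choice(4, size=config.chrom_length, p=p).astype(np.uint8)
        for i in range(config.n_chromosomes)
    }


def codes_to_sequences(genome: Mapping[str, np.ndarray]) -> dict[str, str]:
    lut = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    return {
        chrom: lut[codes].tobytes().decode() for chrom, codes in genome.items()
    }


def simulate_genes(
    config: SimulationConfig,
    chrom_sizes: Mapping[str, int],
    rng: np.random.Generator,
) -> list[GeneModel]:
    """Place non-overlapping gene models with 2-8 exons on both strands."""
    chroms = sorted(chrom_sizes)
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    genes: list[GeneModel] = []
    for i in range(config.n_genes):
        for attempt in range(config.max_placement_attempts):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            length = int(
                rng.integers(config.gene_length_min, config.gene_length_max + 1)
            )
            lo = 25_000  # keep upstream windows on-chromosome
            hi = chrom_sizes[chrom] - length - 25_000
            if hi <= lo:
                continue
            start = int(rng.integers(lo, hi))
            end = start + length
            spans = placed[chrom]
            j = bisect.bisect_left(spans, (start, end))
            margin = config.gene_margin
            ok = True
            if j > 0 and spans[j - 1][1] + margin > start:
                ok = False
            if j < len(spans) and end + margin > spans[j][0]:
                ok = False
            if not ok:
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(
                rng.integers(config.exon_count_min, config.exon_count_max + 1)
            )
            cuts = np.sort(
                rng.choice(
                    np.arange(1, length), size=2 * (n_exons - 1), replace=False
                )
            )
            bounds = np.concatenate([[0], cuts, [length]])
            exons = tuple(
                (start + int(bounds[2 * k]), start + int(bounds[2 * k + 1]))
                for k in range(n_exons)
            )
            genes.append(
                GeneModel(f"gene_{i:04d}", chrom, strand, start, end, exons)
            )
            spans.insert(j, (start, end))
            break
        else:
            raise SimulationError(
                f"could not place gene {i} without overlap after "
                f"{config.max_placement_attempts} attempts"
            )
    return genes


def assign_gene_classes(
    config: SimulationConfig,
    genes: Sequence[GeneModel],
    rng: np.random.Generator,
) -> dict[str, str]:
    if config.n_up + config.n_down > len(genes):
        raise SimulationError("more planted DE genes than genes")
    ids = [g.gene_id for g in genes]
    perm = rng.permutation(len(ids))
    classes = {gid: NONRESPONSIVE for gid in ids}
    for k in perm[: config.n_down]:
        classes[ids[k]] = DOWN
    for k in perm[config.n_down : config.n_down + config.n_up]:
        classes[ids[k]] = UP
    return classes


class _Reserver:
    """Tracks reserved envelopes per chromosome for collision-free placement."""

    def __init__(self) -> None:
        self._spans: dict[str, list[tuple[int, int]]] = {}

    def try_reserve(self, chrom: str, start: int, end: int) -> bool:
        spans = self._spans.setdefault(chrom, [])
        j = bisect.bisect_left(spans, (start, end))
        if j > 0 and spans[j - 1][1] > start:
            return False
        if j < len(spans) and end > spans[j][0]:
            return False
        spans.insert(j, (start, end))
        return True


def _category_windows(
    genes: Sequence[GeneModel],
    params: annotate.WindowParams,
    chrom_sizes: Mapping[str, int],
) -> dict[str, list[tuple[str, int, int]]]:
    out: dict[str, list[tuple[str, int, int]]] = {c: [] for c in annotate.PRECEDENCE}
    for g in genes:
        for iv, cat in annotate.gene_region_windows(g, params, chrom_sizes[g.chrom]):
            out[cat].append((g.chrom, iv.start, iv.end))
    return out


def simulate_peaksets(
    config: SimulationConfig,
    genes: Sequence[GeneModel],
    index: annotate.GeneRegionIndex,
    chrom_sizes: Mapping[str, int],
    gene_classes: Mapping[str, str],
    rng: np.random.Generator,
) -> tuple[list[list[Peak]], list[RegionTruth]]:
    """Plant consensus truth regions into every (pattern, category) cell.

    Every down-class gene additionally receives one promoter region with
    pattern (0,1,1), which also guarantees down genes have associated peaks.
    """
    windows = _category_windows(genes, index.params, chrom_sizes)
    reserver = _Reserver()
    half = config.peak_width // 2
    env = half + config.region_margin
    truth: list[RegionTruth] = []
    peak_sets: list[list[Peak]] = [[], [], []]
    chroms = sorted(chrom_sizes)

    def place_anchor(category: str) -> tuple[str, int, str | None]:
        for _ in range(config.max_placement_attempts):
            if category == annotate.INTERGENIC:
                chrom = chroms[int(rng.integers(0, len(chroms)))]
                anchor = int(rng.integers(env, chrom_sizes[chrom] - env))
            else:
                cands = windows[category]
                if not cands:
                    raise SimulationError(
                        f"no windows available for category {category}"
                    )
                chrom, ws, we = cands[int(rng.integers(0, len(cands)))]
                if we - ws < 1:
                    continue
                anchor = int(rng.integers(ws, we))
                if not (env <= anchor < chrom_sizes[chrom] - env):
                    continue
            cat, gene_id = index.classify_point(chrom, anchor)
            if cat != category:
                continue
            if not reserver.try_reserve(chrom, anchor - env, anchor + env):
                continue
            return chrom, anchor, gene_id
        raise SimulationError(
            f"could not place a {category} anchor after "
            f"{config.max_placement_attempts} attempts"
        )

    def emit_region(
        pattern: tuple[bool, bool, bool], category: str
    ) -> RegionTruth:
        chrom, anchor, gene_id = place_anchor(category)
        rid = f"r{len(truth):05d}"
        cluster = PATTERN_TO_CLUSTER[pattern]
        mu = config.cluster_log2_count_mean[cluster]
        max_nl10p = 0.0
        for t, present in enumerate(pattern):
            if not present:
                continue
            count = float(2 ** (mu + rng.normal(0.0, config.count_log2_sd)))
            nl10p = 10.0 + count * 0.02 + float(rng.exponential(0.5))
            max_nl10p = max(max_nl10p, nl10p)
            j1 = int(rng.integers(-config.peak_edge_jitter,
                                  config.peak_edge_jitter + 1))
            j2 = int(rng.integers(-config.peak_edge_jitter,
                                  config.peak_edge_jitter + 1))
            start = anchor - half + j1
            end = anchor + half + j2
            peak_sets[t].append(
                Peak(
                    interval=GenomicInterval(chrom, start, end),
                    name=f"{rid}_{TIME_LABELS[t]}",
                    neglog10_p=nl10p,
                    summit_offset=anchor - start,
                    read_count=count,
                )
            )
        rt = RegionTruth(
            region_id=rid,
            chrom=chrom,
            anchor=anchor,
            pattern="".join("1" if p else "0" for p in pattern),
            cluster_id=cluster,
            category=category,
            gene_id=gene_id or "",
            max_neglog10_p=max_nl10p,
        )
        truth.append(rt)
        return rt

    cell_counts = {annotate.INTERGENIC: max(1, config.peaks_per_cell // 4)}
    cell_counts.update(config.category_cell_counts)
    for pattern in PATTERNS:
        for category in annotate.CATEGORIES:
            n_cell = cell_counts.get(category, config.peaks_per_cell)
            for _ in range(n_cell):
                emit_region(pattern, category)

    # promoter (d9, d28) region for each down gene: guarantees associated
    # peaks and a d9-vs-d0 promoter signal gain for the down class
    down_genes = [g for g in genes if gene_classes[g.gene_id] == DOWN]
    params = index.params
    for g in down_genes:
        placed = False
        for _ in range(config.max_placement_attempts):
            if g.strand == "+":
                ws, we = g.tx_start - params.promoter_up, g.tx_start + params.promoter_down
            else:
                ws, we = g.tx_end - params.promoter_down, g.tx_end + params.promoter_up
            anchor = int(rng.integers(ws, we))
            if not (env <= anchor < chrom_sizes[g.chrom] - env):
                continue
            cat, gid = index.classify_point(g.chrom, anchor)
            if cat != annotate.PROMOTER or gid != g.gene_id:
                continue
            if not reserver.try_reserve(g.chrom, anchor - env, anchor + env):
                continue
            rid = f"r{len(truth):05d}"
            pattern = (False, True, True)
            cluster = PATTERN_TO_CLUSTER[pattern]
            mu = config.cluster_log2_count_mean[cluster]
            max_nl10p = 0.0
            for t, present in enumerate(pattern):
                if not present:
                    continue
                count = float(2 ** (mu + rng.normal(0.0, config.count_log2_sd)))
                nl10p = 10.0 + count * 0.02 + float(rng.exponential(0.5))
                max_nl10p = max(max_nl10p, nl10p)
                start = anchor - half
                end = anchor + half
                peak_sets[t].append(
                    Peak(
                        interval=GenomicInterval(g.chrom, start, end),
                        name=f"{rid}_{TIME_LABELS[t]}",
                        neglog10_p=nl10p,
                        summit_offset=anchor - start,
                        read_count=count,
                    )
                )
            truth.append(
                RegionTruth(
                    region_id=rid,
                    chrom=g.chrom,
                    anchor=anchor,
                    pattern="011",
                    cluster_id=cluster,
                    category=annotate.PROMOTER,
                    gene_id=g.gene_id,
                    max_neglog10_p=max_nl10p,
                )
            )
            placed = True
            break
        if not placed:
            logger.warning(
                "could not place a promoter region for down gene %s", g.gene_id
            )
    return peak_sets, truth


def simulate_conservation_and_motifs(
    config: SimulationConfig,
    truth: Sequence[RegionTruth],
    genome: Mapping[str, np.ndarray],
    gene_classes: Mapping[str, str],
    chrom_sizes: Mapping[str, int],
    rng: np.random.Generator,
) -> SignalTrack:
    """Plant the consensus word near each region anchor (jitter by score
    tier) and build a conservation track with an offset over motif sites of
    down-class genes.  Mutates ``genome`` in place; updates truth records."""
    consensus = config.motif_consensus.upper()
    w = len(consensus)
    if w > config.peak_width:
        raise SimulationError("motif consensus longer than peak width")
    codes_fwd = np.array([_BASES.index(b) for b in consensus], dtype=np.uint8)
    codes_rev = (3 - codes_fwd)[::-1].copy()
    # score tiers from the peak significance ranking
    order = sorted(range(len(truth)), key=lambda i: -truth[i].max_neglog10_p)
    tier_names = ("top", "middle", "bottom")
    tiers = np.array_split(np.arange(len(order)), 3)
    max_off = config.peak_width // 2 - config.peak_edge_jitter - w
    for tier_idx, rows in enumerate(tiers):
        sd = config.motif_jitter_sd[tier_idx]
        for r in rows:
            rt = truth[order[r]]
            rt.tier = tier_names[tier_idx]
            for _ in range(config.max_placement_attempts):
                offset = int(round(rng.normal(0.0, sd))) if sd > 0 else 0
                if abs(offset) <= max_off:
                    break
            else:
                offset = 0
            site_start = rt.anchor + offset - w // 2
            site_start = max(0, min(site_start, chrom_sizes[rt.chrom] - w))
            strand = "+" if rng.random() < 0.5 else "-"
            word = codes_fwd if strand == "+" else codes_rev
            genome[rt.chrom][site_start : site_start + w] = word
            rt.motif_offset = site_start + w // 2 - rt.anchor
            rt.motif_start = site_start
            rt.motif_strand = strand
    # conservation track: binned baseline noise + offset over down-gene sites
    bin_size = config.signal_bin
    seg: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    values_by_chrom: dict[str, np.ndarray] = {}
    for chrom in sorted(chrom_sizes):
        n_bins = math.ceil(chrom_sizes[chrom] / bin_size)
        starts = np.arange(n_bins, dtype=np.int64) * bin_size
        ends = np.minimum(starts + bin_size, chrom_sizes[chrom])
        values = rng.normal(0.0, config.conservation_noise_sd, n_bins)
        seg[chrom] = (starts, ends, values)
        values_by_chrom[chrom] = values
    for rt in truth:
        if rt.motif_start is None:
            continue
        if gene_classes.get(rt.gene_id) != DOWN:
            continue
        b0 = rt.motif_start // bin_size
        b1 = (rt.motif_start + w - 1) // bin_size
        values_by_chrom[rt.chrom][b0 : b1 + 1] += config.conservation_offset
    return SignalTrack(seg)


def _binned_track(
    chrom_sizes: Mapping[str, int], bin_size: int, fill
) -> tuple[dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]], dict[str, np.ndarray]]:
    seg = {}
    arrays = {}
    for chrom in sorted(chrom_sizes):
        n_bins = math.ceil(chrom_sizes[chrom] / bin_size)
        starts = np.arange(n_bins, dtype=np.int64) * bin_size
        ends = np.minimum(starts + bin_size, chrom_sizes[chrom])
        values = fill(chrom, n_bins)
        seg[chrom] = (starts, ends, values)
        arrays[chrom] = values
    return seg, arrays


def simulate_signal_tracks(
    config: SimulationConfig,
    peak_sets: Sequence[Sequence[Peak]],
    genes: Sequence[GeneModel],
    gene_classes: Mapping[str, str],
    chrom_sizes: Mapping[str, int],
    rng: np.random.Generator,
) -> tuple[list[SignalTrack], SignalTrack]:
    """IP tracks (one per time point) and an Input track.

    Input is a noisy flat baseline; IP adds Gaussian bumps at peak summits
    scaled by read counts, plus flat TSS-proximal gene-body enrichment for
    down-class genes.
    """
    bin_size = config.signal_bin

    def baseline(chrom: str, n: int) -> np.ndarray:
        return np.clip(
            config.input_baseline + rng.normal(0.0, config.input_noise_sd, n),
            0.01,
            None,
        )

    input_seg, _ = _binned_track(chrom_sizes, bin_size, baseline)
    input_track = SignalTrack(input_seg)
    ip_tracks: list[SignalTrack] = []
    sigma = config.bump_sd
    reach = int(3 * sigma)
    for t in range(len(peak_sets)):
        seg, arrays = _binned_track(chrom_sizes, bin_size, baseline)
        for p in peak_sets[t]:
            chrom = p.interval.chrom
            values = arrays[chrom]
            summit = p.summit
            b0 = max(0, (summit - reach) // bin_size)
            b1 = min(values.size - 1, (summit + reach) // bin_size)
            centers = (np.arange(b0, b1 + 1) + 0.5) * bin_size
            amp = p.read_count * config.bump_scale
            values[b0 : b1 + 1] += amp * np.exp(
                -((centers - summit) ** 2) / (2 * sigma**2)
            )
        for g in genes:
            if gene_classes.get(g.gene_id) != DOWN:
                continue
            if g.strand == "+":
                s, e = g.tx_start - 1000, g.tx_start + g.length // 2
            else:
                s, e = g.tx_end - g.length // 2, g.tx_end + 1000
            values = arrays[g.chrom]
            b0 = max(0, s // bin_size)
            b1 = min(values.size - 1, e // bin_size)
            values[b0 : b1 + 1] += config.tss_bump_amplitude
        ip_tracks.append(SignalTrack(seg))
    return ip_tracks, input_track


def simulate_expression(
    config: SimulationConfig,
    gene_ids: Sequence[str],
    gene_classes: Mapping[str, str],
    rng: np.random.Generator,
) -> ExpressionMatrix:
    """log2 intensities: baseline + class effect (knockdown side) + noise."""
    if config.n_replicates < 2:
        raise SimulationError("need >= 2 replicates per condition")
    n = len(gene_ids)
    reps = config.n_replicates
    baseline = rng.normal(
        config.expression_baseline_mean, config.expression_baseline_sd, n
    )
    effect = np.zeros(n)
    for i, gid in enumerate(gene_ids):
        cls = gene_classes.get(gid, NONRESPONSIVE)
        if cls == UP:
            effect[i] = config.expression_effect_log2
        elif cls == DOWN:
            effect[i] = -config.expression_effect_log2
    ctrl = baseline[:, None] + rng.normal(0, config.expression_noise_sd, (n, reps))
    kd = (
        baseline[:, None]
        + effect[:, None]
        + rng.normal(0, config.expression_noise_sd, (n, reps))
    )
    samples = [f"ctrl_{i + 1}" for i in range(reps)] + [
        f"kd_{i + 1}" for i in range(reps)
    ]
    conditions = {s: ("control" if s.startswith("ctrl") else "knockdown")
                  for s in samples}
    return ExpressionMatrix(
        gene_ids=list(gene_ids),
        samples=samples,
        conditions=conditions,
        values=np.hstack([ctrl, kd]),
    )


@dataclass
class SimulationResult:
    config: SimulationConfig
    chrom_sizes: dict[str, int]
    genes: list[GeneModel]
    gene_classes: dict[str, str]
    peak_sets: list[list[Peak]]
    truth: SimulationTruth
    pwm: PWMRecord
    sequences: dict[str, str]
    ip_tracks: list[SignalTrack]
    input_track: SignalTrack
    conservation: SignalTrack
    expression: ExpressionMatrix
    paths: dict[str, Path] = field(default_factory=dict)


def simulate_study(
    config: SimulationConfig, outdir: str | Path | None = None
) -> SimulationResult:
    """Run the full generator; write all artifacts when ``outdir`` is set."""
    rng = np.random.default_rng(config.seed)
    genome = simulate_genome(config, rng)
    chrom_sizes = {c: int(a.size) for c, a in genome.items()}
    genes = simulate_genes(config, chrom_sizes, rng)
    index = annotate.GeneRegionIndex(genes, chrom_sizes=chrom_sizes)
    gene_classes = assign_gene_classes(config, genes, rng)
    peak_sets, region_truth = simulate_peaksets(
        config, genes, index, chrom_sizes, gene_classes, rng
    )
    pwm = consensus_pwm(config.motif_consensus, config.motif_peak_prob)
    conservation = simulate_conservation_and_motifs(
        config, region_truth, genome, gene_classes, chrom_sizes, rng
    )
    ip_tracks, input_track = simulate_signal_tracks(
        config, peak_sets, genes, gene_classes, chrom_sizes, rng
    )
    expression = simulate_expression(
        config, [g.gene_id for g in genes], gene_classes, rng
    )
    truth = SimulationTruth(
        regions=list(region_truth),
        genes=[
            GeneTruth(g.gene_id, gene_classes[g.gene_id], g.length)
            for g in genes
        ],
    )
    sequences = codes_to_sequences(genome)
    result = SimulationResult(
        config=config,
        chrom_sizes=chrom_sizes,
        genes=genes,
        gene_classes=gene_classes,
        peak_sets=peak_sets,
        truth=truth,
        pwm=pwm,
        sequences=sequences,
        ip_tracks=ip_tracks,
        input_track=input_track,
        conservation=conservation,
        expression=expression,
    )
    if outdir is not None:
        result.paths = write_study(result, Path(outdir))
    return result


def write_study(result: SimulationResult, outdir: Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["genome"] = outdir / "genome.fa"
    write_fasta(result.sequences, paths["genome"])
    paths["chrom_sizes"] = outdir / "chrom.sizes"
    write_chrom_sizes(result.chrom_sizes, paths["chrom_sizes"])
    paths["genes"] = outdir / "genes.bed12"
    write_gene_models_bed12(result.genes, paths["genes"])
    for t, label in enumerate(TIME_LABELS):
        key = f"peaks_{label}"
        paths[key] = outdir / f"peaks_{label}.bed"
        write_peaks_bed(result.peak_sets[t], paths[key])
        key = f"ip_{label}"
        paths[key] = outdir / f"ip_{label}.bedgraph"
        write_signal_bedgraph(result.ip_tracks[t], paths[key])
    paths["input"] = outdir / "input.bedgraph"
    write_signal_bedgraph(result.input_track, paths["input"])
    paths["conservation"] = outdir / "conservation.bedgraph"
    write_signal_bedgraph(result.conservation, paths["conservation"])
    paths["motif"] = outdir / "motif.meme"
    write_motif_meme(result.pwm, paths["motif"])
    paths["expression"] = outdir / "expression.tsv"
    write_expression_table(result.expression, paths["expression"])
    paths["truth_regions"] = outdir / "truth_regions.tsv"
    result.truth.regions_frame().to_csv(
        paths["truth_regions"], sep="\t", index=False
    )
    paths["truth_genes"] = outdir / "truth_genes.tsv"
    result.truth.genes_frame().to_csv(paths["truth_genes"], sep="\t", index=False)
    paths["config"] = outdir / "config.yaml"
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(config_to_dict(result.config), fh, sort_keys=True)
    return paths


def config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["cluster_log2_count_mean"] = {
        int(k): float(v) for k, v in d["cluster_log2_count_mean"].items()
    }
    d["motif_jitter_sd"] = [float(x) for x in d["motif_jitter_sd"]]
    return d


def config_from_dict(d: Mapping) -> SimulationConfig:
    kwargs = dict(d)
    if "cluster_log2_count_mean" in kwargs:
        kwargs["cluster_log2_count_mean"] = {
            int(k): float(v) for k, v in kwargs["cluster_log2_count_mean"].items()
        }
    if "motif_jitter_sd" in kwargs:
        kwargs["motif_jitter_sd"] = tuple(kwargs["motif_jitter_sd"])
    return SimulationConfig(**kwargs)


__all__ = [
    "SimulationError",
    "SimulationConfig",
    "RegionTruth",
    "GeneTruth",
    "SimulationTruth",
    "SimulationResult",
    "consensus_pwm",
    "simulate_genome",
    "codes_to_sequences",
    "simulate_genes",
    "assign_gene_classes",
    "simulate_peaksets",
    "simulate_conservation_and_motifs",
    "simulate_signal_tracks",
    "simulate_expression",
    "simulate_study",
    "write_study",
    "config_to_dict",
    "config_from_dict",
    "TIME_LABELS",
    "PATTERNS",
]
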