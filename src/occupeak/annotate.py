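"""Peak classification into six mutually exclusive genomic categories and
peak-to-gene association.

Windows are strand-aware: promoter spans 1 kb upstream to 150 bp downstream
of the TSS, upstream spans 1-20 kb upstream of the TSS, and the TTS region
spans 150 bp inside the gene end through 1 kb beyond the TTS.  A peak is
classified at a single point (summit when present, else interval midpoint);
when windows of several genes contain the point, precedence
promoter > tts_region > exon > intron > upstream applies, then nearest TSS,
then gene id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .formats_io import GeneModel, GenomicInterval, Peak

logger = logging.getLogger(__name__)

PROMOTER = "promoter"
UPSTREAM = "upstream"
EXON = "exon"
INTRON = "intron"
TTS_REGION = "tts_region"
INTERGENIC = "intergenic"

CATEGORIES: tuple[str, ...] = (
    PROMOTER, UPSTREAM, EXON, INTRON, TTS_REGION, INTERGENIC
)
# genic fine structure outranks flanking windows; promoter first
PRECEDENCE: tuple[str, ...] = (PROMOTER, TTS_REGION, EXON, INTRON, UPSTREAM)
_PREC_RANK = {cat: i for i, cat in enumerate(PRECEDENCE)}


@dataclass(frozen=True)
class WindowParams:
    promoter_up: int = 1000
    promoter_down: int = 150
    upstream_far: int = 20000
    tts_near: int = 150
    tts_far: int = 1000


def _clip(start: int, end: int, chrom_size: int | None) -> tuple[int, int]:
    start = max(0, start)
    if chrom_size is not None:
        end = min(end, chrom_size)
    return start, end


def gene_region_windows(
    gene: GeneModel,
    params: WindowParams = WindowParams(),
    chrom_size: int | None = None,
) -> list[tuple[GenomicInterval, str]]:
    """Strand-aware category windows for one gene, clipped at chromosome
    bounds; windows that become empty after clipping are dropped."""
    out: list[tuple[int, int, str]] = []
    if gene.strand == "+":
        tss, tts = gene.tx_start, gene.tx_end
        out.append((tss - params.promoter_up, tss + params.promoter_down, PROMOTER))
        out.append((tss - params.upstream_far, tss - params.promoter_up, UPSTREAM))
        out.append((tts - params.tts_near, tts + params.tts_far, TTS_REGION))
    else:
        tss, tts = gene.tx_end, gene.tx_start
        out.append((tss - params.promoter_down, tss + params.promoter_up, PROMOTER))
        out.append((tss + params.promoter_up, tss + params.upstream_far, UPSTREAM))
        out.append((tts - params.tts_far, tts + params.tts_near, TTS_REGION))
    for s, e in gene.exons:
        out.append((s, e, EXON))
    for s, e in gene.introns:
        out.append((s, e, INTRON))
    windows: list[tuple[GenomicInterval, str]] = []
    for s, e, cat in out:
        s, e = _clip(s, e, chrom_size)
        if s >= e:
            logger.debug("gene %s: %s window empty after clipping", gene.gene_id, cat)
            continue
        windows.append((GenomicInterval(gene.chrom, s, e, gene.strand), cat))
    return windows


class GeneRegionIndex:
    """Per-chromosome searchable map from positions to candidate
    (gene, category) windows.  Query results are deterministic and
    independent of gene insertion order."""

    def __init__(
        self,
        genes: Sequence[GeneModel],
        params: WindowParams = WindowParams(),
        chrom_sizes: Mapping[str, int] | None = None,
    ) -> None:
        self.params = params
        self.genes = {g.gene_id: g for g in sorted(genes, key=lambda g: g.gene_id)}
        per_chrom: dict[str, list[tuple[int, int, int, str, int]]] = {}
        for g in self.genes.values():
            size = chrom_sizes.get(g.chrom) if chrom_sizes else None
            for iv, cat in gene_region_windows(g, params, size):
                per_chrom.setdefault(g.chrom, []).append(
                    (iv.start, iv.end, _PREC_RANK[cat], g.gene_id, g.tss)
                )
        self._index: dict[str, dict[str, np.ndarray]] = {}
        for chrom, rows in per_chrom.items():
            rows.sort()
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            ranks = np.array([r[2] for r in rows], dtype=np.int64)
            gene_ids = np.array([r[3] for r in rows], dtype=object)
            tss = np.array([r[4] for r in rows], dtype=np.int64)
            self._index[chrom] = {
                "starts": starts,
                "ends": ends,
                "ranks": ranks,
                "gene_ids": gene_ids,
                "tss": tss,
                "max_end": np.maximum.accumulate(ends),
            }
        self._warned_chroms: set[str] = set()

    def candidates(self, chrom: str, pos: int) -> list[tuple[str, str]]:
        """All (category, gene_id) windows containing ``pos``."""
        if chrom not in self._index:
            return []
        idx = self._index[chrom]
        hi = int(np.searchsorted(idx["starts"], pos, side="right"))
        if hi == 0:
            return []
        sl = slice(0, hi)
        mask = idx["ends"][sl] > pos
        hits = np.nonzero(mask)[0]
        return [
            (PRECEDENCE[idx["ranks"][i]], str(idx["gene_ids"][i])) for i in hits
        ]

    def classify_point(self, chrom: str, pos: int) -> tuple[str, str | None]:
        if chrom not in self._index:
            if chrom not in self._warned_chroms:
                logger.warning("chromosome %s absent from index; intergenic", chrom)
                self._warned_chroms.add(chrom)
            return INTERGENIC, None
        idx = self._index[chrom]
        hi = int(np.searchsorted(idx["starts"], pos, side="right"))
        if hi == 0:
            return INTERGENIC, None
        mask = idx["ends"][:hi] > pos
        if not mask.any():
            return INTERGENIC, None
        hits = np.nonzero(mask)[0]
        ranks = idx["ranks"][hits]
        best_rank = ranks.min()
        tied = hits[ranks == best_rank]
        if tied.size > 1:
            # deterministic tie-break: nearest TSS, then gene id
            dist = np.abs(idx["tss"][tied] - pos)
            order = sorted(
                range(tied.size),
                key=lambda i: (dist[i], str(idx["gene_ids"][tied[i]])),
            )
            winner = tied[order[0]]
        else:
            winner = tied[0]
        return PRECEDENCE[int(idx["ranks"][winner])], str(idx["gene_ids"][winner])

    def nearest_tss(self, chrom: str, pos: int) -> tuple[str, int] | None:
        """(gene_id, distance) of the nearest TSS on ``chrom``, or None."""
        best: tuple[int, str] | None = None
        for g in self.genes.values():
            if g.chrom != chrom:
                continue
            d = abs(g.tss - pos)
            if best is None or (d, g.gene_id) < best:
                best = (d, g.gene_id)
        if best is None:
            return None
        return best[1], best[0]


def classification_point(peak: Peak) -> int:
    return peak.summit


def classify_peak(
    peak: Peak, index: GeneRegionIndex, mode: str = "summit"
) -> tuple[str, str | None]:
    """Assign exactly one category (and gene for non-intergenic labels).

    ``mode`` is ``summit`` (summit, falling back to midpoint), ``midpoint``,
    or ``largest_overlap`` (category whose windows overlap the peak interval
    most, precedence breaking ties).
    """
    if mode == "summit":
        return index.classify_point(peak.interval.chrom, peak.summit)
    if mode == "midpoint":
        return index.classify_point(peak.interval.chrom, peak.interval.midpoint)
    if mode == "largest_overlap":
        return _classify_largest_overlap(peak, index)
    raise ValueError(f"unknown classification mode {mode!r}")


def _classify_largest_overlap(
    peak: Peak, index: GeneRegionIndex
) -> tuple[str, str | None]:
    chrom = peak.interval.chrom
    if chrom not in index._index:
        return INTERGENIC, None
    idx = index._index[chrom]
    hi = int(np.searchsorted(idx["starts"], peak.interval.end, side="left"))
    overlaps: dict[tuple[str, str], int] = {}
    for i in range(hi):
        ov = min(int(idx["ends"][i]), peak.interval.end) - max(
            int(idx["starts"][i]), peak.interval.start
        )
        if ov > 0:
            key = (PRECEDENCE[int(idx["ranks"][i])], str(idx["gene_ids"][i]))
            overlaps[key] = overlaps.get(key, 0) + ov
    if not overlaps:
        return INTERGENIC, None
    best = min(
        overlaps.items(),
        key=lambda kv: (-kv[1], _PREC_RANK[kv[0][0]], kv[0][1]),
    )
    return best[0]


def category_distribution(labels: Iterable[str]) -> pd.DataFrame:
    """Counts and fractions per category; empty input yields an empty frame."""
    labels = list(labels)
    counts = {cat: 0 for cat in CATEGORIES}
    for lab in labels:
        if lab not in counts:
            raise ValueError(f"unknown category {lab!r}")
        counts[lab] += 1
    total = len(labels)
    if total == 0:
        return pd.DataFrame(columns=["category", "count", "fraction"])
    return pd.DataFrame(
        {
            "category": list(CATEGORIES),
            "count": [counts[c] for c in CATEGORIES],
            "fraction": [counts[c] / total for c in CATEGORIES],
        }
    )


@dataclass(frozen=True)
class IntergenicRule:
    """How intergenic peaks associate with genes; None = unassigned."""

    max_distance: int | None = None


def associate_peaks_to_genes(
    peaks: Sequence[Peak],
    index: GeneRegionIndex,
    intergenic_rule: IntergenicRule = IntergenicRule(),
    mode: str = "summit",
) -> tuple[dict[str, list[Peak]], list[Peak]]:
    """Map peaks to genes; returns (gene_id -> peaks, unassigned peaks).

    Non-intergenic peaks map to their classifying gene; intergenic peaks map
    to the nearest TSS when within ``intergenic_rule.max_distance``, else
    remain unassigned.
    """
    mapping: dict[str, list[Peak]] = {}
    unassigned: list[Peak] = []
    for peak in peaks:
        cat, gene_id = classify_peak(peak, index, mode=mode)
        if gene_id is None and intergenic_rule.max_distance is not None:
            near = index.nearest_tss(peak.interval.chrom, peak.summit)
            if near is not None and near[1] <= intergenic_rule.max_distance:
                gene_id = near[0]
        if gene_id is None:
            unassigned.append(peak)
        else:
            mapping.setdefault(gene_id, []).append(peak)
    return mapping, unassigned


def annotation_table(
    peaks: Sequence[Peak], index: GeneRegionIndex, mode: str = "summit"
) -> pd.DataFrame:
    """Per-peak annotation: name, category, gene id, distance to TSS."""
    rows = []
    for peak in peaks:
        cat, gene_id = classify_peak(peak, index, mode=mode)
        dist = None
        if gene_id is not None:
            dist = peak.summit - index.genes[gene_id].tss
        rows.append(
            {
                "peak": peak.name,
                "chrom": peak.interval.chrom,
                "start": peak.interval.start,
                "end": peak.interval.end,
                "category": cat,
                "gene_id": gene_id if gene_id is not None else ".",
                "tss_distance": dist if dist is not None else np.nan,
            }
        )
    return pd.DataFrame(rows)


__all__ = [
    "CATEGORIES",
    "PRECEDENCE",
    "PROMOTER",
    "UPSTREAM",
    "EXON",
    "INTRON",
    "TTS_REGION",
    "INTERGENIC",
    "WindowParams",
    "gene_region_windows",
    "GeneRegionIndex",
    "classify_peak",
    "category_distribution",
    "IntergenicRule",
    "associate_peaks_to_genes",
    "annotation_table",
]
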