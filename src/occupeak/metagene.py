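"""Metagene window analysis: decile + flank window schema per gene, mean
IP/Input signal ratios per window, per-window rank-sum group tests, and
binding-level binning.

Each gene gets 10 upstream 1-kb windows, 10 gene-body deciles, and 10
downstream 1-kb windows, indexed 5' -> 3' as -10..-1, b1..b10, +1..+10.
Body deciles split the transcript by integer division with the first
(L mod 10) deciles one base longer.  Flank windows may nominally extend past
chromosome bounds; they are clipped at query time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .formats_io import GeneModel, SignalTrack
from .stats import bh_fdr, mann_whitney_u

logger = logging.getLogger(__name__)


def window_labels(flank: int = 10, n_deciles: int = 10) -> list[str]:
    return (
        [f"-{k}" for k in range(flank, 0, -1)]
        + [f"b{k}" for k in range(1, n_deciles + 1)]
        + [f"+{k}" for k in range(1, flank + 1)]
    )


@dataclass(frozen=True)
class WindowSchema:
    gene_id: str
    chrom: str
    labels: tuple[str, ...]
    spans: tuple[tuple[int, int], ...]  # half-open; may exceed chrom bounds


class GeneTooShortError(ValueError):
    pass


def build_window_schema(
    gene: GeneModel, flank_kb: int = 10, n_deciles: int = 10
) -> WindowSchema:
    """Windows ordered 5' -> 3' in transcript direction.

    For '-' genes the genomic coordinates run opposite to the index order,
    so window -1 lies genomically downstream of tx_end.
    """
    length = gene.length
    if length < n_deciles:
        raise GeneTooShortError(
            f"gene {gene.gene_id} length {length} < {n_deciles} deciles"
        )
    base = length // n_deciles
    rem = length % n_deciles
    sizes = [base + 1 if i < rem else base for i in range(n_deciles)]
    body_bounds = np.concatenate([[0], np.cumsum(sizes)])
    flank = flank_kb  # one window per kb of flank
    kb = 1000
    spans: list[tuple[int, int]] = []
    if gene.strand == "+":
        tss, tts = gene.tx_start, gene.tx_end
        for k in range(flank, 0, -1):
            spans.append((tss - k * kb, tss - (k - 1) * kb))
        for i in range(n_deciles):
            spans.append(
                (gene.tx_start + int(body_bounds[i]),
                 gene.tx_start + int(body_bounds[i + 1]))
            )
        for k in range(1, flank + 1):
            spans.append((tts + (k - 1) * kb, tts + k * kb))
    else:
        tss, tts = gene.tx_end, gene.tx_start
        for k in range(flank, 0, -1):
            spans.append((tss + (k - 1) * kb, tss + k * kb))
        for i in range(n_deciles):
            # decile 1 sits at the tx_end side for '-' genes
            spans.append(
                (gene.tx_end - int(body_bounds[i + 1]),
                 gene.tx_end - int(body_bounds[i]))
            )
        for k in range(1, flank + 1):
            spans.append((tts - k * kb, tts - (k - 1) * kb))
    return WindowSchema(
        gene_id=gene.gene_id,
        chrom=gene.chrom,
        labels=tuple(window_labels(flank, n_deciles)),
        spans=tuple(spans),
    )


@dataclass
class GeneBindingProfile:
    gene_id: str
    values: np.ndarray  # one mean IP/Input ratio per window
    aggregate: float  # mean of window ratios
    clipped_windows: tuple[str, ...] = ()


def window_signal_ratio(
    schema: WindowSchema,
    ip: SignalTrack,
    input_track: SignalTrack,
    floor: float = 0.5,
    chrom_sizes: Mapping[str, int] | None = None,
) -> GeneBindingProfile:
    """Per-window (mean IP + floor) / (mean Input + floor).

    Windows reaching outside the chromosome are clipped; fully clipped
    windows get value 0 and are flagged.
    """
    values = np.zeros(len(schema.spans))
    clipped: list[str] = []
    size = chrom_sizes.get(schema.chrom) if chrom_sizes else None
    for i, (start, end) in enumerate(schema.spans):
        start = max(0, start)
        if size is not None:
            end = min(end, size)
        if start >= end:
            values[i] = 0.0
            clipped.append(schema.labels[i])
            continue
        mean_ip = ip.mean(schema.chrom, start, end)
        mean_in = input_track.mean(schema.chrom, start, end)
        denom = mean_in + floor
        if denom <= 0:
            values[i] = 0.0
            clipped.append(schema.labels[i])
            continue
        values[i] = (mean_ip + floor) / denom
    return GeneBindingProfile(
        gene_id=schema.gene_id,
        values=values,
        aggregate=float(values.mean()),
        clipped_windows=tuple(clipped),
    )


def profiles_frame(
    profiles: Sequence[GeneBindingProfile], labels: Sequence[str] | None = None
) -> pd.DataFrame:
    if labels is None:
        labels = window_labels()
    return pd.DataFrame(
        [p.values for p in profiles],
        index=[p.gene_id for p in profiles],
        columns=list(labels),
    )


def group_window_test(
    profiles: Mapping[str, GeneBindingProfile],
    group_ids: Sequence[str],
    reference_ids: Sequence[str],
) -> pd.DataFrame:
    """Per-window two-sided Wilcoxon rank-sum of group vs reference window
    values, Benjamini-Hochberg corrected across windows."""
    group = [profiles[g] for g in group_ids if g in profiles]
    ref = [profiles[g] for g in reference_ids if g in profiles]
    if not group or not ref:
        raise ValueError("both groups must be non-empty")
    labels = window_labels()
    n_windows = len(group[0].values)
    if n_windows != len(labels):
        labels = [str(i) for i in range(n_windows)]
    rows = []
    for w in range(n_windows):
        a = np.array([p.values[w] for p in group])
        b = np.array([p.values[w] for p in ref])
        pooled = np.concatenate([a, b])
        if np.all(pooled == pooled[0]):
            # every value tied across both groups carries no information
            rows.append(
                {"window": labels[w], "U": a.size * b.size / 2.0, "p": 1.0,
                 "median_group": float(np.median(a)),
                 "median_reference": float(np.median(b))}
            )
            continue
        res = mann_whitney_u(a, b)
        rows.append(
            {
                "window": labels[w],
                "U": res.statistic,
                "p": res.p_value,
                "median_group": float(np.median(a)),
                "median_reference": float(np.median(b)),
            }
        )
    df = pd.DataFrame(rows)
    df["q"] = bh_fdr(df["p"].to_numpy())
    return df


ROMAN = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X")


def binding_level_bins(
    profiles: Mapping[str, GeneBindingProfile], n_bins: int = 5
) -> dict[str, str]:
    """Quantile bins of aggregate binding level; bin I = top quantile."""
    if len(profiles) < n_bins:
        raise ValueError(
            f"need at least {n_bins} genes for {n_bins} bins, "
            f"got {len(profiles)}"
        )
    gene_ids = list(profiles)
    levels = np.array([profiles[g].aggregate for g in gene_ids])
    # rank descending; ties broken by gene id for determinism
    order = sorted(range(len(gene_ids)), key=lambda i: (-levels[i], gene_ids[i]))
    bins: dict[str, str] = {}
    n = len(gene_ids)
    for rank, i in enumerate(order):
        b = min(n_bins - 1, rank * n_bins // n)
        bins[gene_ids[i]] = ROMAN[b]
    return bins


__all__ = [
    "window_labels",
    "WindowSchema",
    "GeneTooShortError",
    "build_window_schema",
    "GeneBindingProfile",
    "window_signal_ratio",
    "profiles_frame",
    "group_window_test",
    "binding_level_bins",
]
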