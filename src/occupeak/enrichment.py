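"""Random background interval sampling and category-enrichment comparisons."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import CATEGORIES
from .formats_io import GenomicInterval
from .stats import bh_fdr, fisher_exact_2x2


class SamplingError(RuntimeError):
    """Random interval sampling could not satisfy the constraints."""


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    observed_count: int
    background_count: int
    observed_fraction: float
    background_fraction: float
    ratio: float  # inf flags a zero background category


def sample_random_intervals(
    chrom_sizes: Mapping[str, int],
    n: int,
    length: int = 100,
    seed: int | np.random.Generator = 0,
    exclude: Sequence[GenomicInterval] | None = None,
    max_attempts_factor: int = 100,
) -> list[GenomicInterval]:
    """Sample ``n`` fixed-length intervals uniformly over the genome.

    Chromosomes are chosen proportionally to their allowed start space;
    start positions are uniform.  Reproducible for a given seed.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    chroms = sorted(chrom_sizes)
    spaces = []
    for c in chroms:
        space = chrom_sizes[c] - length + 1
        if space <= 0:
            raise SamplingError(
                f"chromosome {c} (size {chrom_sizes[c]}) shorter than "
                f"interval length {length}"
            )
        spaces.append(space)
    spaces = np.array(spaces, dtype=float)
    probs = spaces / spaces.sum()
    excluded: dict[str, list[tuple[int, int]]] = {}
    if exclude:
        for iv in exclude:
            excluded.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for c in excluded:
            excluded[c].sort()
    out: list[GenomicInterval] = []
    attempts = 0
    max_attempts = max(n, 1) * max_attempts_factor
    while len(out) < n:
        if attempts >= max_attempts:
            raise SamplingError(
                f"exclusion set leaves too little space: placed {len(out)} "
                f"of {n} intervals in {attempts} attempts"
            )
        attempts += 1
        ci = int(rng.choice(len(chroms), p=probs))
        start = int(rng.integers(0, spaces[ci]))
        end = start + length
        if excluded:
            bad = False
            for s, e in excluded.get(chroms[ci], ()):
                if start < e and s < end:
                    bad = True
                    break
            if bad:
                continue
        out.append(GenomicInterval(chroms[ci], start, end))
    return out


def category_enrichment(
    observed_labels: Sequence[str],
    background_labels: Sequence[str],
) -> list[EnrichmentResult]:
    """Per-category observed/background fractions and their ratio.

    Both label sets must come from the same classification index/params.
    Ratios > 1 mark over-representation; a zero-count background category
    yields an infinite ratio flag rather than an error.
    """
    n_obs = len(observed_labels)
    n_bg = len(background_labels)
    if n_obs == 0 or n_bg == 0:
        raise ValueError("both observed and background sets must be non-empty")
    obs_counts = {c: 0 for c in CATEGORIES}
    bg_counts = {c: 0 for c in CATEGORIES}
    for lab in observed_labels:
        obs_counts[lab] += 1
    for lab in background_labels:
        bg_counts[lab] += 1
    results = []
    for cat in CATEGORIES:
        of = obs_counts[cat] / n_obs
        bf = bg_counts[cat] / n_bg
        if bf > 0:
            ratio = of / bf
        else:
            ratio = math.inf if of > 0 else math.nan
        results.append(
            EnrichmentResult(cat, obs_counts[cat], bg_counts[cat], of, bf, ratio)
        )
    return results


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "category": [r.category for r in results],
            "observed_count": [r.observed_count for r in results],
            "background_count": [r.background_count for r in results],
            "observed_fraction": [r.observed_fraction for r in results],
            "background_fraction": [r.background_fraction for r in results],
            "ratio": [r.ratio for r in results],
        }
    )


def compare_category_distributions(
    counts_a: Mapping[str, int],
    counts_b: Mapping[str, int],
) -> pd.DataFrame:
    """Per-category 2x2 Fisher tests (in-category vs rest, A vs B), with
    Benjamini-Hochberg correction across the six categories."""
    total_a = sum(counts_a.get(c, 0) for c in CATEGORIES)
    total_b = sum(counts_b.get(c, 0) for c in CATEGORIES)
    rows = []
    for cat in CATEGORIES:
        a_in = counts_a.get(cat, 0)
        b_in = counts_b.get(cat, 0)
        table = [[a_in, total_a - a_in], [b_in, total_b - b_in]]
        res = fisher_exact_2x2(table)
        rows.append(
            {
                "category": cat,
                "count_a": a_in,
                "count_b": b_in,
                "odds_ratio": res.extra.get("odds_ratio", math.nan),
                "p": res.p_value,
                "note": res.extra.get("note", ""),
            }
        )
    df = pd.DataFrame(rows)
    df["q"] = bh_fdr(df["p"].to_numpy())
    return df


__all__ = [
    "SamplingError",
    "EnrichmentResult",
    "sample_random_intervals",
    "category_enrichment",
    "enrichment_table",
    "compare_category_distributions",
]
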