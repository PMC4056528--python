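"""Differential-expression classification from the knockdown experiment and
binding <-> expression group comparisons, including conservation analysis.

The moderated t-test shrinks per-gene variances with an empirical-Bayes
prior: posterior variance s~^2 = (d0 s0^2 + d s^2)/(d0 + d), where the prior
degrees of freedom d0 and scale s0^2 are estimated by moment matching on
log s^2 across genes (matching the mean and variance of log of a scaled
F-variate); t statistics get d0 + d degrees of freedom.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special
from scipy import stats as sps

from .formats_io import ExpressionMatrix, Peak, SignalTrack
from .motifs import MotifHit
from .stats import bh_fdr, ks_two_sample, mann_whitney_u

logger = logging.getLogger(__name__)

UP = "up"
DOWN = "down"
NONRESPONSIVE = "nonresponsive"
GENE_CLASSES = (UP, DOWN, NONRESPONSIVE)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration)."""
    if x <= 0:
        return math.inf
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return y


def estimate_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """(d0, s0^2) by moment matching on log s^2 (genes with s^2 > 0)."""
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if positive.size < 2:
        return 0.0, float(positive.mean()) if positive.size else 1.0
    z = np.log(positive)
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        # variances essentially constant across genes -> infinite prior df
        return math.inf, float(math.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(e_var)
    s0_sq = math.exp(
        e_mean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0)
    )
    return d0, s0_sq


def moderated_t_de(
    expr: ExpressionMatrix, cond_treat: str, cond_control: str
) -> pd.DataFrame:
    """Per-gene empirical-Bayes moderated t-test, treat vs control.

    Returns a frame with log2fc (treat - control means, values already on
    log2 scale), moderated t, p, and the residual/prior degrees of freedom.
    """
    a = expr.condition_values(cond_treat)
    b = expr.condition_values(cond_control)
    n_a, n_b = a.shape[1], b.shape[1]
    if n_a < 2 or n_b < 2:
        raise ValueError("need >= 2 replicates per condition")
    df = n_a + n_b - 2
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    log2fc = mean_a - mean_b
    ss = a.var(axis=1, ddof=1) * (n_a - 1) + b.var(axis=1, ddof=1) * (n_b - 1)
    s2 = ss / df
    if len(expr.gene_ids) < 2 or np.all(s2 <= 0):
        if np.all(s2 <= 0):
            logger.warning("zero variance in all genes; ordinary t fallback")
        d0, s0_sq = 0.0, float(s2.mean()) if np.any(s2 > 0) else 1.0
    else:
        d0, s0_sq = estimate_variance_prior(s2, df)
    if math.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df
    se = np.sqrt(s2_post * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, log2fc / se, 0.0)
    if math.isinf(df_total):
        p = 2.0 * sps.norm.sf(np.abs(t))
    else:
        p = 2.0 * sps.t.sf(np.abs(t), df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return pd.DataFrame(
        {
            "gene_id": expr.gene_ids,
            "log2fc": log2fc,
            "t": t,
            "p": p,
            "df_residual": df,
            "df_prior": d0,
            "s2_prior": s0_sq,
        }
    )


def classify_genes(
    de: pd.DataFrame,
    fc_threshold: float = 1.5,
    fdr_threshold: float = 0.05,
    strict_log2: bool = False,
) -> pd.DataFrame:
    """Attach BH q-values and up/down/nonresponsive labels.

    Default fold-change reading: |log2fc| >= log2(fc_threshold).  With
    ``strict_log2`` the cut is |log2fc| >= fc_threshold instead.
    """
    out = de.copy()
    out["q"] = bh_fdr(out["p"].to_numpy())
    cut = fc_threshold if strict_log2 else math.log2(fc_threshold)
    cls = np.full(len(out), NONRESPONSIVE, dtype=object)
    sig = out["q"].to_numpy() < fdr_threshold
    fc = out["log2fc"].to_numpy()
    cls[sig & (fc >= cut)] = UP
    cls[sig & (fc <= -cut)] = DOWN
    out["gene_class"] = cls
    return out


def class_counts(classified: pd.DataFrame) -> dict[str, int]:
    counts = classified["gene_class"].value_counts().to_dict()
    return {c: int(counts.get(c, 0)) for c in GENE_CLASSES}


def peaks_per_gene_test(
    gene_peaks: Mapping[str, Sequence[Peak]],
    classes: Mapping[str, str],
    subset_label: str = "all",
) -> pd.DataFrame:
    """Mean peaks/gene per class with a Mann-Whitney test vs nonresponsive.

    Genes with no associated peaks count 0.  Classes with no genes are
    skipped with a log note.
    """
    per_class: dict[str, list[int]] = {c: [] for c in GENE_CLASSES}
    for gene_id, cls in classes.items():
        if cls not in per_class:
            raise ValueError(f"unknown gene class {cls!r}")
        per_class[cls].append(len(gene_peaks.get(gene_id, ())))
    ref = np.array(per_class[NONRESPONSIVE], dtype=float)
    rows = []
    for cls in GENE_CLASSES:
        vals = np.array(per_class[cls], dtype=float)
        if vals.size == 0:
            logger.info("class %s empty; skipped", cls)
            continue
        mean = float(vals.mean())
        sem = float(vals.std(ddof=1) / math.sqrt(vals.size)) if vals.size > 1 else 0.0
        if cls == NONRESPONSIVE or ref.size == 0:
            p = 1.0 if cls == NONRESPONSIVE else math.nan
        else:
            p = mann_whitney_u(vals, ref).p_value
        rows.append(
            {
                "subset": subset_label,
                "gene_class": cls,
                "n_genes": int(vals.size),
                "mean_peaks_per_gene": mean,
                "sem": sem,
                "p_vs_nonresponsive": p,
            }
        )
    return pd.DataFrame(rows)


def foldchange_by_location(
    gene_peaks: Mapping[str, Sequence[Peak]],
    classes: Mapping[str, str],
    peak_category: Mapping[str, str],
    intensity_t0: Mapping[str, float],
    intensity_t1: Mapping[str, float],
) -> pd.DataFrame:
    """Per-category, per-class mean log2 intensity change (t1 vs t0) of
    associated peaks, with Mann-Whitney tests vs the nonresponsive class.

    Intensities are normalized log2 values keyed by peak name, so the
    per-peak change is intensity_t1 - intensity_t0.
    """
    changes: dict[tuple[str, str], list[float]] = {}
    for gene_id, peaks in gene_peaks.items():
        cls = classes.get(gene_id)
        if cls is None:
            continue
        for p in peaks:
            cat = peak_category.get(p.name)
            if cat is None:
                continue
            fc = intensity_t1.get(p.name, 0.0) - intensity_t0.get(p.name, 0.0)
            changes.setdefault((cls, cat), []).append(fc)
    rows = []
    categories = sorted({cat for _, cat in changes})
    for cat in categories:
        ref = np.array(changes.get((NONRESPONSIVE, cat), []), dtype=float)
        for cls in GENE_CLASSES:
            vals = np.array(changes.get((cls, cat), []), dtype=float)
            if vals.size == 0:
                continue
            sem = (
                float(vals.std(ddof=1) / math.sqrt(vals.size))
                if vals.size > 1
                else 0.0
            )
            if cls == NONRESPONSIVE:
                p = 1.0
            elif ref.size == 0:
                p = math.nan
            else:
                pooled = np.concatenate([vals, ref])
                p = (
                    1.0
                    if np.all(pooled == pooled[0])
                    else mann_whitney_u(vals, ref).p_value
                )
            rows.append(
                {
                    "category": cat,
                    "gene_class": cls,
                    "n_peaks": int(vals.size),
                    "mean_log2fc": float(vals.mean()),
                    "sem": sem,
                    "p_vs_nonresponsive": p,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ConservationSummary:
    gene_id: str
    mean_phylop: float
    n_sites: int


def gene_conservation(
    gene_peaks: Mapping[str, Sequence[Peak]],
    best_sites: Mapping[str, MotifHit | None],
    conservation: SignalTrack,
) -> tuple[dict[str, ConservationSummary], int]:
    """Per-gene mean conservation over best motif sites of associated peaks.

    ``best_sites`` maps peak name -> best MotifHit (or None).  A site's
    score is the mean conservation over its bases; the gene score averages
    its peaks' site scores.  Peaks without a motif hit are excluded; genes
    with no motif-bearing peaks are dropped and counted.
    """
    summaries: dict[str, ConservationSummary] = {}
    n_excluded_genes = 0
    for gene_id, peaks in gene_peaks.items():
        site_scores = []
        for p in peaks:
            hit = best_sites.get(p.name)
            if hit is None:
                continue
            site_scores.append(
                conservation.mean(
                    hit.interval.chrom, hit.interval.start, hit.interval.end
                )
            )
        if site_scores:
            summaries[gene_id] = ConservationSummary(
                gene_id, float(np.mean(site_scores)), len(site_scores)
            )
        else:
            n_excluded_genes += 1
    return summaries, n_excluded_genes


class MatchingError(RuntimeError):
    pass


def length_matched_controls(
    target_lengths: Mapping[str, int],
    pool_lengths: Mapping[str, int],
    seed: int | np.random.Generator = 0,
) -> tuple[dict[str, str], dict[str, float]]:
    """Greedy nearest-length matching of control genes without replacement.

    Targets are processed in decreasing length; ties in |length difference|
    are randomized under the seed.  Returns (target -> control, diagnostics
    with max/mean absolute length difference).
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if len(pool_lengths) < len(target_lengths):
        raise MatchingError(
            f"pool ({len(pool_lengths)}) smaller than targets "
            f"({len(target_lengths)})"
        )
    pool = dict(pool_lengths)
    matches: dict[str, str] = {}
    deltas: list[int] = []
    targets = sorted(
        target_lengths.items(), key=lambda kv: (-kv[1], kv[0])
    )
    for gene_id, length in targets:
        if not pool:
            raise MatchingError(f"pool exhausted before matching {gene_id}")
        best_delta = min(abs(l - length) for l in pool.values())
        candidates = sorted(
            g for g, l in pool.items() if abs(l - length) == best_delta
        )
        chosen = candidates[int(rng.integers(0, len(candidates)))]
        matches[gene_id] = chosen
        deltas.append(best_delta)
        del pool[chosen]
    diagnostics = {
        "max_abs_delta": float(max(deltas)) if deltas else 0.0,
        "mean_abs_delta": float(np.mean(deltas)) if deltas else 0.0,
    }
    return matches, diagnostics


def conservation_ks(
    group_a: Sequence[ConservationSummary],
    group_b: Sequence[ConservationSummary],
):
    """Two-sample KS on gene-level mean conservation scores."""
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValueError("need n >= 3 genes per group for the KS comparison")
    a = [s.mean_phylop for s in group_a]
    b = [s.mean_phylop for s in group_b]
    return ks_two_sample(a, b)


__all__ = [
    "UP",
    "DOWN",
    "NONRESPONSIVE",
    "GENE_CLASSES",
    "estimate_variance_prior",
    "moderated_t_de",
    "classify_genes",
    "class_counts",
    "peaks_per_gene_test",
    "foldchange_by_location",
    "ConservationSummary",
    "gene_conservation",
    "MatchingError",
    "length_matched_controls",
    "conservation_ks",
]
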