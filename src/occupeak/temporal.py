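"""Cross-time-point consensus regions and presence/absence clustering.

Peaks from the T (default 3) time points are merged by single-linkage on
>= 1 bp overlap.  Each merged region carries a boolean presence vector and a
per-time intensity: log2(1 + read_sum * 1e7 / library_size), i.e. read
counts normalized to 10 million reads with a pseudocount of 1 so that absent
peaks map to intensity 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .formats_io import GenomicInterval, Peak, ValidationError

DEFAULT_TIME_LABELS = ("d0", "d9", "d28")

# Clusters 1, 4, 5, 6, 7 are fixed by the temporal patterns they are
# described with; 2 and 3 are assigned to (d0,d9) and (d0,d28) in that order.
PATTERN_TO_CLUSTER: dict[tuple[bool, bool, bool], int] = {
    (True, True, True): 1,
    (True, True, False): 2,
    (True, False, True): 3,
    (False, True, True): 4,
    (False, False, True): 5,
    (False, True, False): 6,
    (True, False, False): 7,
}
CLUSTER_TO_PATTERN = {v: k for k, v in PATTERN_TO_CLUSTER.items()}


def normalize_intensity(read_count: float, library_size: float = 1e7) -> float:
    """log2(1 + read_count * 1e7 / library_size); 0 reads -> 0.0."""
    if read_count < 0:
        raise ValidationError(f"negative read count {read_count}")
    if library_size <= 0:
        raise ValidationError(f"library size must be > 0, got {library_size}")
    return math.log2(1.0 + read_count * 1e7 / library_size)


@dataclass
class ConsensusRegion:
    interval: GenomicInterval
    presence: tuple[bool, ...]
    intensity: tuple[float, ...]
    member_peaks: tuple[tuple[Peak, ...], ...]
    cluster_id: int | None = None

    def __post_init__(self) -> None:
        if not any(self.presence):
            raise ValidationError("consensus region with all-absent presence")
        if any(not math.isfinite(v) for v in self.intensity):
            raise ValidationError("non-finite intensity")

    @property
    def presence_string(self) -> str:
        return "".join("1" if p else "0" for p in self.presence)


def build_consensus(
    peak_sets: Sequence[Sequence[Peak]],
    library_sizes: Sequence[float] | None = None,
) -> list[ConsensusRegion]:
    """Single-linkage merge of peaks overlapping by >= 1 bp across all
    time-point sets."""
    n_times = len(peak_sets)
    if library_sizes is None:
        library_sizes = [1e7] * n_times
    if len(library_sizes) != n_times:
        raise ValidationError("one library size per time point required")
    tagged: list[tuple[str, int, int, int, Peak]] = []
    for t, peaks in enumerate(peak_sets):
        for p in peaks:
            tagged.append((p.interval.chrom, p.interval.start, p.interval.end, t, p))
    tagged.sort(key=lambda r: (r[0], r[1], r[2], r[3]))
    regions: list[ConsensusRegion] = []
    group: list[tuple[int, Peak]] = []
    cur_chrom: str | None = None
    cur_start = cur_end = 0

    def flush() -> None:
        if not group:
            return
        members: list[list[Peak]] = [[] for _ in range(n_times)]
        for t, p in group:
            members[t].append(p)
        presence = tuple(bool(m) for m in members)
        intensity = tuple(
            normalize_intensity(sum(p.read_count for p in m), library_sizes[t])
            for t, m in enumerate(members)
        )
        regions.append(
            ConsensusRegion(
                interval=GenomicInterval(cur_chrom, cur_start, cur_end),
                presence=presence,
                intensity=intensity,
                member_peaks=tuple(tuple(m) for m in members),
            )
        )

    for chrom, start, end, t, p in tagged:
        if chrom != cur_chrom or start >= cur_end:
            flush()
            group = []
            cur_chrom, cur_start, cur_end = chrom, start, end
        group.append((t, p))
        cur_end = max(cur_end, end)
    flush()
    return regions


def assign_temporal_clusters(
    regions: Sequence[ConsensusRegion],
) -> list[ConsensusRegion]:
    """Attach canonical cluster ids (T = 3) in place and return the list."""
    for r in regions:
        if len(r.presence) != 3:
            raise ValidationError("cluster numbering defined for T = 3")
        assert any(r.presence)
        r.cluster_id = PATTERN_TO_CLUSTER[tuple(r.presence)]
    return list(regions)


def cluster_summary(
    regions: Sequence[ConsensusRegion],
    time_labels: Sequence[str] = DEFAULT_TIME_LABELS,
) -> pd.DataFrame:
    """Per-cluster, per-time mean intensity +/- SEM and region counts.

    Empty clusters are omitted; singleton clusters report SEM 0 with a flag.
    """
    rows = []
    by_cluster: dict[int, list[ConsensusRegion]] = {}
    for r in regions:
        if r.cluster_id is None:
            raise ValidationError("clusters must be assigned before summary")
        by_cluster.setdefault(r.cluster_id, []).append(r)
    for cid in sorted(by_cluster):
        members = by_cluster[cid]
        n = len(members)
        for t, label in enumerate(time_labels):
            vals = np.array([r.intensity[t] for r in members])
            sem = float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
            rows.append(
                {
                    "cluster": cid,
                    "time": label,
                    "n": n,
                    "mean_intensity": float(vals.mean()),
                    "sem": sem,
                    "sem_undefined": n == 1,
                }
            )
    return pd.DataFrame(rows)


def regions_table(
    regions: Sequence[ConsensusRegion],
    time_labels: Sequence[str] = DEFAULT_TIME_LABELS,
) -> pd.DataFrame:
    """Consensus regions as a BED6+ style table."""
    rows = []
    for i, r in enumerate(regions):
        row = {
            "chrom": r.interval.chrom,
            "start": r.interval.start,
            "end": r.interval.end,
            "name": f"region_{i}",
            "score": 0,
            "strand": ".",
            "presence": r.presence_string,
            "cluster": r.cluster_id if r.cluster_id is not None else ".",
        }
        for t, label in enumerate(time_labels):
            row[f"intensity_{label}"] = r.intensity[t]
        rows.append(row)
    return pd.DataFrame(rows)


__all__ = [
    "DEFAULT_TIME_LABELS",
    "PATTERN_TO_CLUSTER",
    "CLUSTER_TO_PATTERN",
    "normalize_intensity",
    "ConsensusRegion",
    "build_consensus",
    "assign_temporal_clusters",
    "cluster_summary",
    "regions_table",
]
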