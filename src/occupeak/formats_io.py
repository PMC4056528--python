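"""Canonical in-memory genomic types and readers/writers for every external
format the pipeline touches.

All coordinates are held internally as 0-based half-open (BED convention).
The refFlat-like dialect carries 1-based inclusive starts and is converted on
read.  Regions with no signal coverage contribute value 0 to interval means,
matching read-density semantics of uncovered bases.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np


class FormatError(ValueError):
    """Base class for file-format problems."""


class ParseError(FormatError):
    """A line could not be parsed; message names the offending line."""


class ValidationError(FormatError):
    """Parsed values violate a structural invariant."""


class ConfigurationError(FormatError):
    """Caller-supplied configuration is inconsistent with the file."""


class UnsupportedAlphabetError(FormatError):
    """Motif file uses an alphabet other than ACGT."""


STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic span [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Peak:
    """A called binding region with optional summit and per-library score."""

    interval: GenomicInterval
    name: str = "."
    neglog10_p: float = 0.0
    summit_offset: int | None = None
    read_count: float = 0.0
    low_significance: bool = False

    def __post_init__(self) -> None:
        if self.neglog10_p < 0:
            raise ValidationError(f"peak {self.name}: negative -log10 p")
        if self.read_count < 0:
            raise ValidationError(f"peak {self.name}: negative read count")
        if self.summit_offset is not None:
            if not 0 <= self.summit_offset < len(self.interval):
                raise ValidationError(
                    f"peak {self.name}: summit offset {self.summit_offset} "
                    f"outside interval of length {len(self.interval)}"
                )

    @property
    def summit(self) -> int:
        """Absolute summit position; interval midpoint when no summit given."""
        if self.summit_offset is not None:
            return self.interval.start + self.summit_offset
        return self.interval.midpoint


@dataclass(frozen=True)
class GeneModel:
    """Transcript model with strand and exon structure."""

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be +/-")
        if not (0 <= self.tx_start < self.tx_end):
            raise ValidationError(f"gene {self.gene_id}: invalid tx span")
        if not self.exons:
            raise ValidationError(f"gene {self.gene_id}: no exons")
        prev_end = None
        for s, e in self.exons:
            if not (self.tx_start <= s < e <= self.tx_end):
                raise ValidationError(
                    f"gene {self.gene_id}: exon ({s},{e}) outside tx span"
                )
            if prev_end is not None and s < prev_end:
                raise ValidationError(
                    f"gene {self.gene_id}: exons overlap or unsorted"
                )
            prev_end = e
        if self.exons[0][0] != self.tx_start or self.exons[-1][1] != self.tx_end:
            raise ValidationError(
                f"gene {self.gene_id}: exons must span [tx_start, tx_end)"
            )

    @property
    def tss(self) -> int:
        """Transcription start site (strand-aware)."""
        return self.tx_start if self.strand == "+" else self.tx_end

    @property
    def tts(self) -> int:
        """Transcription termination site (strand-aware)."""
        return self.tx_end if self.strand == "+" else self.tx_start

    @property
    def length(self) -> int:
        return self.tx_end - self.tx_start

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        out = []
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if e0 < s1:
                out.append((e0, s1))
        return tuple(out)

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.tx_start, self.tx_end, self.strand)


class SignalTrack:
    """Piecewise-constant base-wise values (e.g. IP/Input densities,
    conservation scores) supporting interval mean queries.

    Segments are sorted and non-overlapping per chromosome; bases not covered
    by any segment contribute value 0 to interval means.
    """

    def __init__(
        self,
        segments: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
    ) -> None:
        self._segments: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends, values) in segments.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=np.float64)
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(ends <= starts):
                raise ValidationError(f"{chrom}: empty or inverted segment")
            if np.any(starts[1:] < ends[:-1]):
                i = int(np.argmax(starts[1:] < ends[:-1]))
                raise ValidationError(
                    f"{chrom}: overlapping segments near "
                    f"{int(starts[i])}-{int(ends[i])} and {int(starts[i + 1])}"
                )
            if not np.all(np.isfinite(values)):
                raise ValidationError(f"{chrom}: non-finite signal value")
            self._segments[chrom] = (starts, ends, values)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, int, int, float]]
    ) -> "SignalTrack":
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in records:
            per_chrom.setdefault(chrom, []).append((start, end, value))
        segs = {}
        for chrom, rows in per_chrom.items():
            starts, ends, values = zip(*rows)
            segs[chrom] = (np.array(starts), np.array(ends), np.array(values))
        return cls(segs)

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(self._segments)

    def records(self) -> Iterator[tuple[str, int, int, float]]:
        for chrom in sorted(self._segments):
            starts, ends, values = self._segments[chrom]
            for s, e, v in zip(starts, ends, values):
                yield chrom, int(s), int(e), float(v)

    def mean(self, chrom: str, start: int, end: int) -> float:
        """Mean value over [start, end); uncovered bases count as 0."""
        if end <= start:
            raise ValidationError(f"empty query interval {start}-{end}")
        if chrom not in self._segments:
            return 0.0
        starts, ends, values = self._segments[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if lo >= hi:
            return 0.0
        ov = np.minimum(ends[lo:hi], end) - np.maximum(starts[lo:hi], start)
        total = float(np.sum(ov * values[lo:hi]))
        return total / (end - start)

    def means(self, intervals: Sequence[GenomicInterval]) -> np.ndarray:
        return np.array([self.mean(iv.chrom, iv.start, iv.end) for iv in intervals])


_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass(frozen=True)
class PWMRecord:
    """Position weight matrix over ACGT with background and pseudocount."""

    probs: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    pseudocount: float = 0.01
    name: str = "motif"

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=np.float64)
        bg = np.asarray(self.background, dtype=np.float64)
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "background", bg)
        if probs.ndim != 2 or probs.shape[1] != 4 or probs.shape[0] < 2:
            raise ValidationError("PWM must be width>=2 by 4")
        if np.any(probs < 0):
            raise ValidationError("PWM probabilities must be non-negative")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("PWM rows must each sum to 1")
        if not math.isclose(float(bg.sum()), 1.0, abs_tol=1e-9):
            raise ValidationError("background must sum to 1")
        if self.pseudocount <= 0:
            raise ValidationError("pseudocount must be > 0")

    @property
    def width(self) -> int:
        return int(self.probs.shape[0])

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in np.argmax(self.probs, axis=1))

    def log_odds_matrix(self) -> np.ndarray:
        """log2((p + pc)/(1 + 4 pc) / bg), the scoring matrix in bits."""
        reg = (self.probs + self.pseudocount) / (1.0 + 4.0 * self.pseudocount)
        return np.log2(reg / self.background[None, :])


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of log2-scale intensities with condition labels."""

    gene_ids: list[str]
    samples: list[str]
    conditions: dict[str, str]  # sample -> condition
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.gene_ids), len(self.samples)):
            raise ValidationError("expression matrix shape mismatch")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = sorted(
                {g for g in self.gene_ids if self.gene_ids.count(g) > 1}
            )
            raise ValidationError(f"duplicate gene ids: {', '.join(dupes)}")
        counts: dict[str, int] = {}
        for s in self.samples:
            cond = self.conditions.get(s)
            if cond is not None:
                counts[cond] = counts.get(cond, 0) + 1
        for cond, n in counts.items():
            if n < 2:
                raise ValidationError(
                    f"condition {cond!r} has {n} sample(s); need >= 2"
                )

    def condition_samples(self, condition: str) -> list[str]:
        return [s for s in self.samples if self.conditions.get(s) == condition]

    def condition_values(self, condition: str) -> np.ndarray:
        cols = [self.samples.index(s) for s in self.condition_samples(condition)]
        if not cols:
            raise ConfigurationError(f"no samples for condition {condition!r}")
        return self.values[:, cols]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _split_line(line: str) -> list[str]:
    return line.rstrip("\n").split("\t")


def read_peaks_bed(
    path: str | Path,
    score_is_neglog10p: bool = True,
    significance_threshold: float = 10.0,
) -> list[Peak]:
    """Read peaks from a BED file with >= 5 columns.

    Column layout: chrom, start, end, name, score, [strand], [summit offset],
    [read count].  Peaks below ``significance_threshold`` are flagged via
    ``low_significance`` rather than dropped; filtering is an explicit
    pipeline step.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = _split_line(line)
            if len(fields) < 5:
                raise ParseError(f"{path}:{lineno}: expected >= 5 columns")
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                name = fields[3]
                score = float(fields[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if start >= end:
                raise ValidationError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            strand = fields[5] if len(fields) > 5 and fields[5] in STRANDS else "."
            summit = None
            if len(fields) > 6 and fields[6] not in (".", ""):
                summit = int(fields[6])
            read_count = 0.0
            if len(fields) > 7 and fields[7] not in (".", ""):
                read_count = float(fields[7])
            neglog10_p = score if score_is_neglog10p else 0.0
            peaks.append(
                Peak(
                    interval=GenomicInterval(chrom, start, end, strand),
                    name=name,
                    neglog10_p=neglog10_p,
                    summit_offset=summit,
                    read_count=read_count,
                    low_significance=neglog10_p < significance_threshold,
                )
            )
    return peaks


def write_peaks_bed(peaks: Iterable[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            summit = "." if p.summit_offset is None else str(p.summit_offset)
            fh.write(
                "\t".join(
                    [
                        p.interval.chrom,
                        str(p.interval.start),
                        str(p.interval.end),
                        p.name,
                        repr(float(p.neglog10_p)),
                        p.interval.strand,
                        summit,
                        repr(float(p.read_count)),
                    ]
                )
                + "\n"
            )


def filter_significant(peaks: Iterable[Peak], threshold: float = 10.0) -> list[Peak]:
    """Retain peaks meeting the -log10 p significance threshold (default 10)."""
    return [p for p in peaks if p.neglog10_p >= threshold]


def read_gene_models(path: str | Path, dialect: str = "bed12") -> list[GeneModel]:
    """Read gene models from ``bed12`` or a refFlat-like TSV dialect.

    The refFlat-like dialect is: gene_id, chrom, strand, txStart (1-based,
    inclusive), txEnd, exonCount, exonStarts (1-based, comma list), exonEnds.
    """
    if dialect not in ("bed12", "refflat"):
        raise ConfigurationError(f"unknown dialect {dialect!r}")
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = _split_line(line)
            try:
                if dialect == "bed12":
                    genes.append(_parse_bed12(fields))
                else:
                    genes.append(_parse_refflat(fields))
            except (IndexError, ValueError) as exc:
                if isinstance(exc, FormatError):
                    raise type(exc)(f"{path}:{lineno}: {exc}") from exc
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return genes


def _parse_bed12(fields: list[str]) -> GeneModel:
    if len(fields) < 12:
        raise ParseError("expected 12 columns in bed12")
    chrom = fields[0]
    start, end = int(fields[1]), int(fields[2])
    name, strand = fields[3], fields[5]
    block_count = int(fields[9])
    sizes = [int(x) for x in fields[10].rstrip(",").split(",") if x]
    offsets = [int(x) for x in fields[11].rstrip(",").split(",") if x]
    if len(sizes) != block_count or len(offsets) != block_count:
        raise ValidationError(
            f"gene {name}: blockCount {block_count} inconsistent with "
            f"{len(sizes)} sizes / {len(offsets)} starts"
        )
    exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
    return GeneModel(name, chrom, strand, start, end, exons)


def _parse_refflat(fields: list[str]) -> GeneModel:
    if len(fields) < 8:
        raise ParseError("expected 8 columns in refflat dialect")
    gene_id, chrom, strand = fields[0], fields[1], fields[2]
    tx_start = int(fields[3]) - 1  # 1-based inclusive -> 0-based half-open
    tx_end = int(fields[4])
    exon_count = int(fields[5])
    starts = [int(x) - 1 for x in fields[6].rstrip(",").split(",") if x]
    ends = [int(x) for x in fields[7].rstrip(",").split(",") if x]
    if len(starts) != exon_count or len(ends) != exon_count:
        raise ValidationError(
            f"gene {gene_id}: exonCount {exon_count} inconsistent"
        )
    return GeneModel(
        gene_id, chrom, strand, tx_start, tx_end, tuple(zip(starts, ends))
    )


def write_gene_models_bed12(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            offsets = ",".join(str(s - g.tx_start) for s, e in g.exons)
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        str(g.tx_start),
                        str(g.tx_end),
                        g.gene_id,
                        "0",
                        g.strand,
                        str(g.tx_start),
                        str(g.tx_end),
                        "0",
                        str(len(g.exons)),
                        sizes,
                        offsets,
                    ]
                )
                + "\n"
            )


def read_signal_bedgraph(path: str | Path) -> SignalTrack:
    """Read a 4-column bedGraph into a SignalTrack (sorted on load)."""
    records: list[tuple[str, int, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = _split_line(line)
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns")
            try:
                records.append(
                    (fields[0], int(fields[1]), int(fields[2]), float(fields[3]))
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return SignalTrack.from_records(records)


def write_signal_bedgraph(track: SignalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track.records():
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.6g}\n")


def read_motif_meme(path: str | Path, pseudocount: float = 0.01) -> PWMRecord:
    """Read one motif from a MEME minimal-format file.

    Rows of the letter-probability matrix are renormalized to sum to 1.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    name = "motif"
    background = np.full(4, 0.25)
    rows: list[list[float]] = []
    width = None
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("ALPHABET"):
            alphabet = line.split("=", 1)[1].strip() if "=" in line else ""
            if alphabet and alphabet.upper() != "ACGT":
                raise UnsupportedAlphabetError(
                    f"unsupported alphabet {alphabet!r}; only ACGT"
                )
        elif line.startswith("Background letter frequencies"):
            i += 1
            tokens = lines[i].split()
            freq = dict(zip(tokens[0::2], (float(x) for x in tokens[1::2])))
            if set(freq) != set("ACGT"):
                raise UnsupportedAlphabetError(
                    f"background letters {sorted(freq)} != ACGT"
                )
            background = np.array([freq[b] for b in _BASES])
        elif line.startswith("MOTIF"):
            parts = line.split()
            if len(parts) > 1:
                name = parts[1]
        elif line.startswith("letter-probability matrix"):
            m = re.search(r"w=\s*(\d+)", line)
            if m:
                width = int(m.group(1))
            j = i + 1
            while j < len(lines):
                vals = lines[j].split()
                if len(vals) != 4:
                    break
                try:
                    rows.append([float(v) for v in vals])
                except ValueError:
                    break
                j += 1
            i = j
            continue
        i += 1
    if not rows:
        raise ParseError(f"{path}: no letter-probability matrix found")
    if width is not None and width != len(rows):
        raise ValidationError(
            f"{path}: declared width {width} != {len(rows)} matrix rows"
        )
    probs = np.array(rows, dtype=np.float64)
    row_sums = probs.sum(axis=1, keepdims=True)
    if np.any(row_sums <= 0):
        raise ValidationError(f"{path}: zero-sum matrix row")
    probs = probs / row_sums
    if probs.shape[0] < 4:
        raise ValidationError(f"{path}: motif width {probs.shape[0]} < 4")
    background = background / background.sum()
    return PWMRecord(probs=probs, background=background,
                     pseudocount=pseudocount, name=name)


def write_motif_meme(pwm: PWMRecord, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(
            " ".join(f"{b} {f:.6f}" for b, f in zip(_BASES, pwm.background))
            + "\n\n"
        )
        fh.write(f"MOTIF {pwm.name}\n")
        fh.write(
            f"letter-probability matrix: alength= 4 w= {pwm.width} "
            "nsites= 20 E= 0\n"
        )
        for row in pwm.probs:
            fh.write(" " + " ".join(f"{v:.6f}" for v in row) + "\n")


def read_expression_table(
    path: str | Path, condition_map: Mapping[str, Sequence[str]]
) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column gene id, header samples).

    ``condition_map`` maps condition name -> list of sample column names.
    """
    with open(path) as fh:
        header = _split_line(fh.readline())
        samples = header[1:]
        sample_set = set(samples)
        conditions: dict[str, str] = {}
        for cond, names in condition_map.items():
            for s in names:
                if s not in sample_set:
                    raise ConfigurationError(
                        f"sample {s!r} for condition {cond!r} absent from header"
                    )
                conditions[s] = cond
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        seen: set[str] = set()
        dupes: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = _split_line(line)
            gid = fields[0]
            if gid in seen:
                dupes.add(gid)
            seen.add(gid)
            try:
                rows.append([float(v) for v in fields[1:]])
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric value for gene {gid!r}"
                ) from exc
            gene_ids.append(gid)
        if dupes:
            raise ValidationError(
                f"{path}: duplicate gene ids: {', '.join(sorted(dupes))}"
            )
    return ExpressionMatrix(
        gene_ids=gene_ids,
        samples=samples,
        conditions=conditions,
        values=np.array(rows) if rows else np.empty((0, len(samples))),
    )


def write_expression_table(expr: ExpressionMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(expr.samples) + "\n")
        for gid, row in zip(expr.gene_ids, expr.values):
            fh.write(gid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into a dict of upper-cased sequences."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), rebuild=True)
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


def write_fasta(sequences: Mapping[str, str], path: str | Path,
                line_width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                chrom, size = _split_line(line)[:2]
                sizes[chrom] = int(size)
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


__all__ = [
    "FormatError",
    "ParseError",
    "ValidationError",
    "ConfigurationError",
    "UnsupportedAlphabetError",
    "GenomicInterval",
    "Peak",
    "GeneModel",
    "SignalTrack",
    "PWMRecord",
    "ExpressionMatrix",
    "read_peaks_bed",
    "write_peaks_bed",
    "filter_significant",
    "read_gene_models",
    "write_gene_models_bed12",
    "read_signal_bedgraph",
    "write_signal_bedgraph",
    "read_motif_meme",
    "write_motif_meme",
    "read_expression_table",
    "write_expression_table",
    "read_fasta",
    "write_fasta",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "replace",
]
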