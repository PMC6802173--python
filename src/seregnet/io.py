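"""Core genomic domain types and readers/writers for the standard flat formats.

Every coordinate in this package is 0-based, half-open (`[start, end)`),
matching BED/refFlat conventions.  Chromosome names are compared by exact
string equality; :func:`check_chromosome_vocabulary` warns when two inputs
share no chromosome names at all (usually a "chr1" vs "1" mismatch).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, PeakParseError

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "Peak",
    "PeakSet",
    "GeneModel",
    "read_peaks",
    "write_peaks",
    "read_refflat",
    "write_refflat",
    "read_intervals_bed",
    "filter_repeat_regions",
    "collapse_to_genes",
    "check_chromosome_vocabulary",
    "read_expression_table",
    "write_expression_table",
    "read_ortholog_map",
    "read_read_placements",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Peak:
    """A signal-scored interval called for one factor in one cell state.

    The ``center`` is geometric — ``floor((start + end) / 2)`` — regardless
    of any summit column in the source file; all point-based occupancy
    analyses (feature assignment, overlap windows) use this center.
    """

    interval: GenomicInterval
    signal: float
    factor: str = ""
    cell_state: str = ""
    name: str = ""

    def __post_init__(self):
        if self.signal < 0:
            raise ValueError(f"signal must be >= 0, got {self.signal}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def center(self) -> int:
        return (self.interval.start + self.interval.end) // 2


@dataclass
class PeakSet:
    """Ordered peaks sharing one factor label and one cell state."""

    factor: str
    cell_state: str
    peaks: list[Peak] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def centers(self) -> np.ndarray:
        return np.array([p.center for p in self.peaks], dtype=np.int64)

    def signals(self) -> np.ndarray:
        return np.array([p.signal for p in self.peaks], dtype=float)

    def chroms(self) -> set[str]:
        return {p.chrom for p in self.peaks}

    def replace_peaks(self, peaks: Sequence[Peak]) -> "PeakSet":
        return PeakSet(self.factor, self.cell_state, list(peaks))


@dataclass(frozen=True)
class GeneModel:
    """A refFlat-style transcript with strand-aware TSS.

    ``tss`` is ``tx_start`` on the + strand and ``tx_end - 1`` on the −
    strand (the last base of the half-open span).
    """

    symbol: str
    tx_name: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[GenomicInterval, ...] = ()

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not 0 <= self.tx_start < self.tx_end:
            raise ValueError("require 0 <= tx_start < tx_end")
        prev_end = self.tx_start
        for ex in self.exons:
            if ex.chrom != self.chrom:
                raise ValueError("exon on a different chromosome")
            if ex.start < prev_end or ex.end > self.tx_end:
                raise ValueError("exons must be sorted, disjoint, inside the span")
            prev_end = ex.end

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.tx_start, self.tx_end)


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------

_NARROWPEAK_COLS = 10


def _detect_signal_column(path: Path, n_cols: int) -> int:
    """Default signal column: BED score (5) or narrowPeak signalValue (7), 1-based."""
    if str(path).endswith((".narrowPeak", ".narrowpeak")) or n_cols == _NARROWPEAK_COLS:
        return 7
    return 5


def read_peaks(
    path: str | Path,
    factor: str = "",
    cell_state: str = "",
    signal_column: int | None = None,
) -> PeakSet:
    """Read a BED3+/narrowPeak file into a :class:`PeakSet`.

    Parameters
    ----------
    signal_column
        1-based column holding the occupancy signal.  Defaults to column 5
        for BED dialects and column 7 (signalValue) for narrowPeak (detected
        by extension or a 10-column layout).  Files with only 3 columns get
        signal 0 for every peak.

    Raises
    ------
    PeakParseError
        Non-integer coordinates or ``start >= end``, with the line number.
    FormatError
        The requested signal column is absent.
    """
    path = Path(path)
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise PeakParseError(path, lineno, f"expected >= 3 columns, got {len(fields)}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise PeakParseError(path, lineno, f"non-integer coordinates {fields[1]!r}, {fields[2]!r}") from None
            if start >= end:
                raise PeakParseError(path, lineno, f"start >= end ({start} >= {end})")
            if start < 0:
                raise PeakParseError(path, lineno, f"negative start {start}")
            col = signal_column if signal_column is not None else _detect_signal_column(path, len(fields))
            if len(fields) >= col:
                try:
                    signal = float(fields[col - 1])
                except ValueError:
                    raise PeakParseError(path, lineno, f"non-numeric signal {fields[col - 1]!r}") from None
            elif signal_column is not None or len(fields) > 3:
                raise FormatError(f"{path}:{lineno}: signal column {col} absent ({len(fields)} columns)")
            else:
                signal = 0.0
            name = fields[3] if len(fields) > 3 else ""
            peaks.append(Peak(GenomicInterval(chrom, start, end), signal, factor, cell_state, name))
    if not peaks:
        logger.warning("no peaks read from %s", path)
    return PeakSet(factor, cell_state, peaks)


def write_peaks(peakset: PeakSet, path: str | Path) -> None:
    """Write a PeakSet as 5-column BED (chrom, start, end, name, signal)."""
    with open(path, "w") as fh:
        for i, p in enumerate(peakset):
            name = p.name or f"{peakset.factor or 'peak'}_{i}"
            # repr gives the shortest exact round-trip form of the float
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{name}\t{p.signal!r}\n")


def read_intervals_bed(path: str | Path) -> list[GenomicInterval]:
    """Read plain intervals (e.g. a repeat mask) from BED3+."""
    path = Path(path)
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
            except (IndexError, ValueError) as exc:
                raise PeakParseError(path, lineno, str(exc)) from None
    return out


def filter_repeat_regions(
    peaks: PeakSet, repeats: Iterable[GenomicInterval]
) -> PeakSet:
    """Drop peaks whose *center* lies inside any repeat interval.

    Order-preserving and idempotent; an empty repeat set is the identity.
    """
    reps = list(repeats)
    if not reps:
        return peaks.replace_peaks(list(peaks.peaks))
    # merge per chromosome so a sorted-search answers center containment
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in sorted(reps):
        merged = by_chrom.setdefault(iv.chrom, [])
        if merged and iv.start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], iv.end))
        else:
            merged.append((iv.start, iv.end))
    starts = {c: np.array([s for s, _ in ivs]) for c, ivs in by_chrom.items()}
    ends = {c: np.array([e for _, e in ivs]) for c, ivs in by_chrom.items()}

    kept: list[Peak] = []
    removed = 0
    for p in peaks:
        if p.chrom in starts:
            i = int(np.searchsorted(starts[p.chrom], p.center, side="right")) - 1
            if i >= 0 and p.center < ends[p.chrom][i]:
                removed += 1
                continue
        kept.append(p)
    logger.info("repeat filter removed %d of %d peaks", removed, len(peaks))
    return peaks.replace_peaks(kept)


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

def read_refflat(path: str | Path) -> list[GeneModel]:
    """Parse a UCSC 11-column refFlat file into GeneModels.

    Columns: geneName, name, chrom, strand, txStart, txEnd, cdsStart,
    cdsEnd, exonCount, exonStarts, exonEnds (comma-separated, trailing
    comma tolerated).  Duplicate symbols are retained as distinct
    transcripts; use :func:`collapse_to_genes` for gene-level work.
    """
    path = Path(path)
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 11:
                raise PeakParseError(path, lineno, f"expected 11 columns, got {len(f)}")
            strand = f[3].replace("−", "-")  # tolerate unicode minus
            if strand not in ("+", "-"):
                raise PeakParseError(path, lineno, f"unknown strand {f[3]!r}")
            try:
                tx_start, tx_end = int(f[4]), int(f[5])
                exon_count = int(f[8])
                exon_starts = [int(x) for x in f[9].rstrip(",").split(",") if x]
                exon_ends = [int(x) for x in f[10].rstrip(",").split(",") if x]
            except ValueError:
                raise PeakParseError(path, lineno, "non-integer coordinate field") from None
            if len(exon_starts) != exon_count or len(exon_ends) != exon_count:
                raise PeakParseError(
                    path, lineno,
                    f"exonCount {exon_count} inconsistent with exon lists "
                    f"({len(exon_starts)} starts, {len(exon_ends)} ends)",
                )
            try:
                exons = tuple(
                    GenomicInterval(f[2], s, e) for s, e in zip(exon_starts, exon_ends)
                )
                genes.append(GeneModel(f[0], f[1], f[2], strand, tx_start, tx_end, exons))
            except ValueError as exc:
                raise PeakParseError(path, lineno, str(exc)) from None
    return genes


def write_refflat(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            es = ",".join(str(e.start) for e in g.exons) + ","
            ee = ",".join(str(e.end) for e in g.exons) + ","
            fh.write(
                f"{g.symbol}\t{g.tx_name}\t{g.chrom}\t{g.strand}\t{g.tx_start}"
                f"\t{g.tx_end}\t{g.tx_start}\t{g.tx_end}\t{len(g.exons)}\t{es}\t{ee}\n"
            )


def collapse_to_genes(genes: Iterable[GeneModel]) -> list[GeneModel]:
    """One model per symbol: the widest transcript, ties by transcript name."""
    best: dict[str, GeneModel] = {}
    for g in genes:
        cur = best.get(g.symbol)
        if cur is None:
            best[g.symbol] = g
            continue
        key = (-(g.tx_end - g.tx_start), g.tx_name)
        cur_key = (-(cur.tx_end - cur.tx_start), cur.tx_name)
        if key < cur_key:
            best[g.symbol] = g
    return [best[s] for s in sorted(best)]


def check_chromosome_vocabulary(a: set[str], b: set[str], what: str = "inputs") -> bool:
    """Warn (and return False) when two chromosome name sets are disjoint."""
    if a and b and not (a & b):
        logger.warning(
            "disjoint chromosome vocabularies between %s: %s vs %s",
            what, sorted(a)[:5], sorted(b)[:5],
        )
        return False
    return True


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Read a gene-by-sample TSV (first column = gene symbol) into a DataFrame."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise FormatError(f"{path}: negative expression values")
    if df.index.duplicated().any():
        raise FormatError(f"{path}: duplicated gene symbols")
    return df


def write_expression_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


def read_ortholog_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (source symbol, target symbol) -> dict."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def read_read_placements(path: str | Path) -> pd.DataFrame:
    """Read fragment placements from BED3 (the start coordinate is the position)."""
    rows = []
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            rows.append((f[0], int(f[1])))
    return pd.DataFrame(rows, columns=["chrom", "position"])
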