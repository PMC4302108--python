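"""Genomic data model and flat-file readers/writers.

All coordinates are 0-based half-open (BED convention) throughout the
package; GTF input (1-based inclusive) is converted on read. Chromosome
names are taken verbatim -- no ``chr`` normalization is attempted, so that
mismatched inputs fail loudly rather than silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

STRANDS = ("+", "-", ".")


class FormatError(ValueError):
    """A malformed line in an on-disk genomic file."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``.

    ``strand`` is ``'+'``, ``'-'`` or ``'.'`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

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

    def validate_against(self, chrom_sizes: Mapping[str, int]) -> None:
        """Check the interval fits inside a declared chromosome table."""
        if self.chrom not in chrom_sizes:
            raise ValueError(f"chromosome {self.chrom!r} not in chrom.sizes table")
        if self.end > chrom_sizes[self.chrom]:
            raise ValueError(
                f"interval end {self.end} beyond {self.chrom} "
                f"length {chrom_sizes[self.chrom]}"
            )


@dataclass(frozen=True)
class PeakRecord:
    """One called binding event, optionally with summit and score."""

    interval: GenomicInterval
    summit_offset: int | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < len(self.interval)
        ):
            raise ValueError(
                f"summit offset {self.summit_offset} outside peak of "
                f"width {len(self.interval)}"
            )
        if self.score is not None and self.score < 0:
            raise ValueError("peak score must be nonnegative")

    @property
    def summit(self) -> int:
        """Absolute summit position; midpoint when no summit was called."""
        if self.summit_offset is None:
            return self.interval.midpoint
        return self.interval.start + self.summit_offset


@dataclass
class PeakSet:
    """All peaks of one factor in one cell type."""

    factor: str
    cell_type: str
    peaks: list[PeakRecord] = field(default_factory=list)

    def sorted(self) -> "PeakSet":
        key = lambda p: (p.interval.chrom, p.interval.start, p.interval.end)
        return PeakSet(self.factor, self.cell_type, sorted(self.peaks, key=key))

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass
class GeneModel:
    """A gene body with TSS, exons and optional UTRs (stranded)."""

    gene_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)
    utr5: list[GenomicInterval] = field(default_factory=list)
    utr3: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: genes must be stranded")
        for ex in self.exons:
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(f"gene {self.gene_id}: exon outside gene body")

    @property
    def tss(self) -> int:
        """Transcription start site: ``start`` on +, ``end - 1`` on -."""
        if self.interval.strand == "+":
            return self.interval.start
        return self.interval.end - 1

    @property
    def effective_exons(self) -> list[GenomicInterval]:
        """Exons, falling back to the whole gene body when none are given."""
        return self.exons if self.exons else [self.interval]


class TagCollection:
    """Per-chromosome sorted 5'-end tag positions with fast range counts."""

    def __init__(self, positions: Mapping[str, Iterable[int]] | None = None):
        self._pos: dict[str, np.ndarray] = {}
        if positions:
            for chrom, pos in positions.items():
                arr = np.asarray(sorted(pos), dtype=np.int64)
                self._pos[chrom] = arr

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._pos)

    def positions(self, chrom: str) -> np.ndarray:
        return self._pos.get(chrom, np.empty(0, dtype=np.int64))

    def count(self, chrom: str, start: int, end: int) -> int:
        """Number of tag positions in half-open ``[start, end)``."""
        pos = self.positions(chrom)
        return int(np.searchsorted(pos, end) - np.searchsorted(pos, start))

    def total(self) -> int:
        return sum(len(a) for a in self._pos.values())


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _split_line(line: str, path: str, lineno: int, min_fields: int) -> list[str]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < min_fields:
        raise FormatError(
            f"{path}:{lineno}: expected >= {min_fields} tab-separated "
            f"fields, got {len(fields)}"
        )
    return fields


def _parse_int(text: str, path: str, lineno: int, what: str) -> int:
    try:
        return int(text)
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: bad {what} {text!r}") from exc


def read_peaks(path: str, format: str = "bed", *, factor: str, cell_type: str) -> PeakSet:
    """Read a BED3+ or ENCODE narrowPeak file into a :class:`PeakSet`.

    narrowPeak column 10 is the summit offset from the peak start; the
    sentinel ``-1`` means no summit was called. Records are returned sorted
    by (chrom, start).
    """
    if format not in ("bed", "narrowPeak"):
        raise ValueError(f"unknown peak format {format!r}")
    peaks: list[PeakRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = _split_line(line, path, lineno, 3)
            chrom = fields[0]
            start = _parse_int(fields[1], path, lineno, "start")
            end = _parse_int(fields[2], path, lineno, "end")
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start {start} >= end {end}")
            summit = None
            score = None
            if format == "narrowPeak":
                if len(fields) < 10:
                    raise FormatError(
                        f"{path}:{lineno}: narrowPeak requires 10 columns"
                    )
                score = float(fields[6])  # signalValue
                raw = _parse_int(fields[9], path, lineno, "summit offset")
                summit = None if raw == -1 else raw
            elif len(fields) >= 5:
                try:
                    score = float(fields[4])
                except ValueError:
                    score = None
            peaks.append(
                PeakRecord(GenomicInterval(chrom, start, end), summit, score)
            )
    return PeakSet(factor, cell_type, peaks).sorted()


REGIONS_HEADER = "#chrom\tstart\tend\tgroup\toccupancy\tstrand\tfactors"


def write_regions(regions: Sequence, path: str) -> None:
    """Write classified occupancy regions as BED6+ (factors ';'-joined).

    Round-trips losslessly through :func:`read_regions` (member peaks are
    not serialized).
    """
    with open(path, "w") as fh:
        fh.write(REGIONS_HEADER + "\n")
        for reg in regions:
            iv = reg.interval
            factors = ";".join(sorted(reg.factors))
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{reg.group}\t"
                f"{reg.occupancy}\t.\t{factors}\n"
            )


def read_regions(path: str):
    """Read a BED6+ file written by :func:`write_regions`."""
    from .occupancy import OccupancyRegion  # local import to avoid cycle

    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = _split_line(line, path, lineno, 7)
            iv = GenomicInterval(
                fields[0],
                _parse_int(fields[1], path, lineno, "start"),
                _parse_int(fields[2], path, lineno, "end"),
            )
            factors = set(fields[6].split(";")) if fields[6] else set()
            regions.append(
                OccupancyRegion(
                    interval=iv,
                    factors=factors,
                    group=fields[3] if fields[3] != "." else None,
                )
            )
    return regions


def read_genes(path: str, format: str = "bed12") -> list[GeneModel]:
    """Read gene models from BED12 or a minimal GTF.

    ``gtf_lite`` accepts feature rows ``gene``, ``exon``, ``five_prime_utr``
    and ``three_prime_utr`` with a ``gene_id "X"`` attribute; coordinates are
    converted from 1-based inclusive to 0-based half-open.
    """
    if format == "bed12":
        return _read_bed12(path)
    if format == "gtf_lite":
        return _read_gtf_lite(path)
    raise ValueError(f"unknown gene format {format!r}")


def _read_bed12(path: str) -> list[GeneModel]:
    genes: dict[str, GeneModel] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = _split_line(line, path, lineno, 12)
            chrom = fields[0]
            start = _parse_int(fields[1], path, lineno, "start")
            end = _parse_int(fields[2], path, lineno, "end")
            gene_id = fields[3]
            strand = fields[5]
            if gene_id in genes:
                raise FormatError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
            nblocks = _parse_int(fields[9], path, lineno, "blockCount")
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")[:nblocks]]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")[:nblocks]]
            exons = [
                GenomicInterval(chrom, start + off, start + off + size, strand)
                for off, size in zip(starts, sizes)
            ]
            genes[gene_id] = GeneModel(
                gene_id, GenomicInterval(chrom, start, end, strand), exons
            )
    return list(genes.values())


def _gtf_attr(attrs: str, key: str, path: str, lineno: int) -> str:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key + " "):
            return part.split(" ", 1)[1].strip().strip('"')
    raise FormatError(f"{path}:{lineno}: missing attribute {key!r}")


def _read_gtf_lite(path: str) -> list[GeneModel]:
    bodies: dict[str, GenomicInterval] = {}
    parts: dict[str, dict[str, list[GenomicInterval]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = _split_line(line, path, lineno, 9)
            chrom, _src, feature = fields[0], fields[1], fields[2]
            start = _parse_int(fields[3], path, lineno, "start") - 1  # to 0-based
            end = _parse_int(fields[4], path, lineno, "end")
            strand = fields[6]
            gene_id = _gtf_attr(fields[8], "gene_id", path, lineno)
            iv = GenomicInterval(chrom, start, end, strand)
            if feature == "gene":
                if gene_id in bodies:
                    raise FormatError(
                        f"{path}:{lineno}: duplicate gene_id {gene_id!r}"
                    )
                bodies[gene_id] = iv
                order.append(gene_id)
            elif feature in ("exon", "five_prime_utr", "three_prime_utr"):
                parts.setdefault(gene_id, {}).setdefault(feature, []).append(iv)
            # other feature rows ignored
    genes = []
    for gid in order:
        p = parts.get(gid, {})
        genes.append(
            GeneModel(
                gid,
                bodies[gid],
                exons=p.get("exon", []),
                utr5=p.get("five_prime_utr", []),
                utr3=p.get("three_prime_utr", []),
            )
        )
    return genes


def read_chrom_sizes(path: str) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>length`` table."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = _split_line(line, path, lineno, 2)
            sizes[fields[0]] = _parse_int(fields[1], path, lineno, "length")
    return sizes


def read_tags(path: str) -> TagCollection:
    """Read a tag BED: each record contributes its 5' end.

    For stranded records the 5' end is ``start`` on ``+`` and ``end - 1``
    on ``-``; unstranded records contribute ``start``.
    """
    per_chrom: dict[str, list[int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = _split_line(line, path, lineno, 3)
            start = _parse_int(fields[1], path, lineno, "start")
            end = _parse_int(fields[2], path, lineno, "end")
            strand = fields[5] if len(fields) >= 6 else "."
            pos = end - 1 if strand == "-" else start
            per_chrom.setdefault(fields[0], []).append(pos)
    return TagCollection(per_chrom)


class BedGraph:
    """Piecewise-constant genomic signal; absent intervals read as 0."""

    def __init__(self, intervals: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        # chrom -> (starts, ends, values), sorted, non-overlapping
        self._data = dict(intervals)

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, int, int, float]]) -> "BedGraph":
        per: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in records:
            per.setdefault(chrom, []).append((start, end, value))
        data = {}
        for chrom, rows in per.items():
            rows.sort()
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            values = np.array([r[2] for r in rows], dtype=float)
            data[chrom] = (starts, ends, values)
        return cls(data)

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._data)

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base signal over ``[start, end)`` (0 where no record)."""
        out = np.zeros(end - start, dtype=float)
        if chrom not in self._data:
            return out
        starts, ends, values = self._data[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        for i in range(lo, hi):
            a = max(int(starts[i]), start)
            b = min(int(ends[i]), end)
            if a < b:
                out[a - start : b - start] = values[i]
        return out

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            for chrom in self.chromosomes:
                starts, ends, values = self._data[chrom]
                for s, e, v in zip(starts, ends, values):
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_bedgraph(path: str) -> BedGraph:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = _split_line(line, path, lineno, 4)
            records.append(
                (
                    fields[0],
                    _parse_int(fields[1], path, lineno, "start"),
                    _parse_int(fields[2], path, lineno, "end"),
                    float(fields[3]),
                )
            )
    return BedGraph.from_records(records)


def write_bed(intervals: Sequence[GenomicInterval], path: str, names: Sequence[str] | None = None) -> None:
    """Write plain intervals as BED3 (or BED4 when names are given)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            if names is not None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{names[i]}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_bed(path: str) -> list[GenomicInterval]:
    """Read a BED3+ file as plain intervals (extra columns ignored)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = _split_line(line, path, lineno, 3)
            strand = fields[5] if len(fields) >= 6 and fields[5] in STRANDS else "."
            out.append(
                GenomicInterval(
                    fields[0],
                    _parse_int(fields[1], path, lineno, "start"),
                    _parse_int(fields[2], path, lineno, "end"),
                    strand,
                )
            )
    return out


def write_narrowpeak(peak_set: PeakSet, path: str) -> None:
    """Write a PeakSet as 10-column ENCODE narrowPeak."""
    with open(path, "w") as fh:
        for i, p in enumerate(peak_set.peaks):
            iv = p.interval
            score = p.score if p.score is not None else 0.0
            summit = p.summit_offset if p.summit_offset is not None else -1
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                f"{peak_set.factor}_peak{i + 1}\t0\t.\t{score:g}\t-1\t-1\t{summit}\n"
            )


def write_bed12(genes: Sequence[GeneModel], path: str) -> None:
    """Write gene models as BED12 (exons as blocks)."""
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            exons = sorted(g.effective_exons, key=lambda e: e.start)
            sizes = ",".join(str(len(e)) for e in exons) + ","
            starts = ",".join(str(e.start - iv.start) for e in exons) + ","
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{g.gene_id}\t0\t{iv.strand}\t"
                f"{iv.start}\t{iv.end}\t0\t{len(exons)}\t{sizes}\t{starts}\n"
            )


def write_tags(tags: TagCollection, path: str) -> None:
    """Write tag positions as 1-bp BED records (5' ends, + strand)."""
    with open(path, "w") as fh:
        for chrom in tags.chromosomes:
            for pos in tags.positions(chrom):
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\n")


def fetch_sequence(fasta, interval: GenomicInterval) -> str:
    """Fetch an interval's sequence (uppercase) from a pyfaidx.Fasta."""
    seq = fasta[interval.chrom][interval.start : interval.end]
    return str(seq).upper()


def write_fasta(sequences: Mapping[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
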