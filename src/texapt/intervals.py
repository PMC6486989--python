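"""Genomic interval data model, strand-aware set operations and file I/O.

All genomic coordinates are 0-based half-open (the BED convention).
RepeatMasker consensus coordinates (``rep_start``/``rep_end``) stay 1-based
inclusive, as in the source table; conversion happens only where a consensus
position is projected back onto the genome.

The set operations (:func:`intersect`, :func:`window_intersect`,
:func:`split_intersect`, :func:`subtract`) reproduce BEDTools semantics:
half-open overlap of at least ``min_overlap`` base pairs, optional strand
matching, deterministic (query index, subject index) ordering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")


class BedParseError(ValueError):
    """A line of a BED-family file could not be parsed."""


class SchemaError(ValueError):
    """A tabular input is missing required columns."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open stranded genomic span, the coordinate currency of the package.

    Parameters
    ----------
    chrom : chromosome identifier
    start : 0-based inclusive start (bp)
    end : 0-based exclusive end (bp)
    strand : one of ``+``, ``-``, ``.``
    name : free-text label
    score : numeric BED column 5 (used e.g. as a mapping-quality proxy for tags)
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""
    score: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval", min_overlap: int = 1) -> bool:
        return (
            self.chrom == other.chrom
            and min(self.end, other.end) - max(self.start, other.start) >= min_overlap
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


class GenomeTable:
    """Ordered chromosome-name -> length table (a ``chrom.sizes`` file)."""

    def __init__(self, entries: Iterable[tuple[str, int]]):
        self._lengths: dict[str, int] = {}
        for chrom, length in entries:
            if length <= 0:
                raise ValueError(f"non-positive length for {chrom}")
            if chrom in self._lengths:
                raise ValueError(f"duplicate chromosome {chrom}")
            self._lengths[chrom] = int(length)

    @property
    def chroms(self) -> list[str]:
        return list(self._lengths)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def __len__(self) -> int:
        return len(self._lengths)

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeTable) and self._lengths == other._lengths

    def length(self, chrom: str) -> int:
        return self._lengths[chrom]

    def items(self) -> list[tuple[str, int]]:
        return list(self._lengths.items())

    def validate(self, intervals: Iterable[GenomicInterval]) -> None:
        """Raise if any interval falls outside its chromosome."""
        for iv in intervals:
            if iv.chrom not in self._lengths:
                raise ValueError(f"unknown chromosome {iv.chrom}")
            if iv.end > self._lengths[iv.chrom]:
                raise ValueError(
                    f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds "
                    f"chromosome length {self._lengths[iv.chrom]}"
                )

    @classmethod
    def read(cls, path: str | Path) -> "GenomeTable":
        entries = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                chrom, length = line.split("\t")[:2]
                entries.append((chrom, int(length)))
        return cls(entries)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, length in self._lengths.items():
                fh.write(f"{chrom}\t{length}\n")


@dataclass(frozen=True)
class TECopy:
    """One transposable-element instance from a RepeatMasker-style table.

    ``rep_start``/``rep_end`` give the 1-based inclusive span of the copy on
    its subfamily consensus sequence; truncated copies cover only part of
    ``consensus_length``.
    """

    interval: GenomicInterval
    te_class: str
    te_family: str
    te_subfamily: str
    rep_start: int
    rep_end: int
    consensus_length: int

    def __post_init__(self) -> None:
        if not (1 <= self.rep_start <= self.rep_end <= self.consensus_length):
            raise ValueError(
                f"invalid consensus span {self.rep_start}..{self.rep_end} "
                f"(consensus length {self.consensus_length}) for "
                f"{self.te_subfamily} at {self.interval.chrom}:{self.interval.start}"
            )


@dataclass(frozen=True)
class TranscriptModel:
    """A stranded transcript with exon blocks (a BED12 record)."""

    interval: GenomicInterval
    exons: tuple[tuple[int, int], ...]
    transcript_id: str
    gene_id: str
    tier: str = "mRNA"  # one of mRNA, lncRNA_tier1, lncRNA_tier2

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError("transcripts must be stranded (+ or -)")
        prev_end = None
        for s, e in self.exons:
            if not (self.interval.start <= s < e <= self.interval.end):
                raise ValueError("exon block outside transcript span")
            if prev_end is not None and s < prev_end:
                raise ValueError("exon blocks must be sorted and non-overlapping")
            prev_end = e

    @property
    def tss(self) -> int:
        """5' end: start on +, end - 1 on - (0-based position)."""
        return self.interval.start if self.interval.strand == "+" else self.interval.end - 1

    def exon_intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(self.interval.chrom, s, e, self.interval.strand,
                            name=self.transcript_id)
            for s, e in self.exons
        ]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_bed(path: str | Path, expect_strand: bool = False) -> list[GenomicInterval]:
    """Read a BED3-BED6 file into a list of :class:`GenomicInterval`.

    Strand is taken from column 6 when present, else ``.``; the score column
    (5) is kept when present. Malformed lines raise :class:`BedParseError`
    naming the line number.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if not 3 <= len(fields) <= 12:
                raise BedParseError(f"{path}:{lineno}: expected 3-12 columns, got {len(fields)}")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                name = fields[3] if len(fields) > 3 else ""
                score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
                strand = fields[5] if len(fields) > 5 else "."
                iv = GenomicInterval(chrom, start, end, strand, name, score)
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
            if expect_strand and iv.strand == ".":
                raise BedParseError(f"{path}:{lineno}: strand required but missing")
            out.append(iv)
    return out


def write_bed(path: str | Path, intervals: Sequence[GenomicInterval]) -> None:
    """Write intervals as BED6 (name ``.`` when empty; integer scores stay integral)."""
    with open(path, "w") as fh:
        for iv in intervals:
            score = int(iv.score) if float(iv.score).is_integer() else iv.score
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{score}\t{iv.strand}\n"
            )


def read_te_table(path: str | Path) -> list[TECopy]:
    """Read the 10-column TE table (TSV).

    Columns: chrom, start (0-based), end, strand, class, family, subfamily,
    repStart, repEnd, consensusLength. Rows violating the consensus-span
    invariants are rejected with a logged count rather than aborting the run.
    """
    required = ["chrom", "start", "end", "strand", "class", "family",
                "subfamily", "repStart", "repEnd", "consensusLength"]
    copies: list[TECopy] = []
    n_rejected = 0
    with open(path) as fh:
        header: list[str] | None = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                header = line.lstrip("#").strip().split("\t")
                continue
            fields = line.split("\t")
            if header is None:
                header = required  # headerless files must follow column order
            if len(fields) != len(header):
                raise SchemaError(f"{path}:{lineno}: {len(fields)} fields for {len(header)} columns")
            row = dict(zip(header, fields))
            missing = [c for c in required if c not in row]
            if missing:
                raise SchemaError(f"{path}: missing columns {missing}")
            try:
                copies.append(
                    TECopy(
                        interval=GenomicInterval(
                            row["chrom"], int(row["start"]), int(row["end"]),
                            row["strand"], name=row["subfamily"],
                        ),
                        te_class=row["class"],
                        te_family=row["family"],
                        te_subfamily=row["subfamily"],
                        rep_start=int(row["repStart"]),
                        rep_end=int(row["repEnd"]),
                        consensus_length=int(row["consensusLength"]),
                    )
                )
            except ValueError:
                n_rejected += 1
    if n_rejected:
        logger.warning("read_te_table: rejected %d invalid rows from %s", n_rejected, path)
    return copies


def write_te_table(path: str | Path, copies: Sequence[TECopy]) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tstrand\tclass\tfamily\tsubfamily\t"
                 "repStart\trepEnd\tconsensusLength\n")
        for c in copies:
            iv = c.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\t{c.te_class}\t"
                f"{c.te_family}\t{c.te_subfamily}\t{c.rep_start}\t{c.rep_end}\t"
                f"{c.consensus_length}\n"
            )


def read_bed12(path: str | Path, tier: str = "mRNA") -> list[TranscriptModel]:
    """Read transcript models from BED12; name column is ``transcript_id|gene_id``."""
    out: list[TranscriptModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise BedParseError(f"{path}:{lineno}: BED12 requires 12 columns")
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
                name, strand = f[3], f[5]
                n_blocks = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
                if len(sizes) != n_blocks or len(offsets) != n_blocks:
                    raise ValueError("block count mismatch")
                exons = tuple(
                    (start + off, start + off + size)
                    for off, size in zip(offsets, sizes)
                )
                tid, _, gid = name.partition("|")
                out.append(
                    TranscriptModel(
                        interval=GenomicInterval(chrom, start, end, strand, name),
                        exons=exons,
                        transcript_id=tid,
                        gene_id=gid or tid,
                        tier=tier,
                    )
                )
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed12(path: str | Path, transcripts: Sequence[TranscriptModel]) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            iv = t.interval
            sizes = ",".join(str(e - s) for s, e in t.exons)
            offs = ",".join(str(s - iv.start) for s, _ in t.exons)
            name = f"{t.transcript_id}|{t.gene_id}"
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\t"
                f"{iv.start}\t{iv.end}\t0\t{len(t.exons)}\t{sizes}\t{offs}\n"
            )


# ---------------------------------------------------------------------------
# set operations
# ---------------------------------------------------------------------------

def _group_indices(intervals: Sequence[GenomicInterval], by_strand: bool):
    groups: dict[tuple, list[int]] = {}
    for i, iv in enumerate(intervals):
        key = (iv.chrom, iv.strand) if by_strand else (iv.chrom,)
        groups.setdefault(key, []).append(i)
    return groups


def intersect(
    query: Sequence[GenomicInterval],
    subject: Sequence[GenomicInterval],
    strand_match: bool = False,
    min_overlap: int = 1,
) -> list[tuple[int, int]]:
    """All (query index, subject index) pairs overlapping by >= ``min_overlap`` bp.

    Half-open convention: intervals sharing only a boundary never overlap.
    With ``strand_match`` only identically-stranded pairs are reported
    (BEDTools ``-s``). Output sorted by (query index, subject index).
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    q_groups = _group_indices(query, strand_match)
    s_groups = _group_indices(subject, strand_match)
    pairs: list[tuple[int, int]] = []
    for key, q_idx in q_groups.items():
        s_idx = s_groups.get(key)
        if not s_idx:
            continue
        qs = np.array([[query[i].start, query[i].end] for i in q_idx])
        ss = np.array([[subject[j].start, subject[j].end] for j in s_idx])
        ov = (
            np.minimum(qs[:, None, 1], ss[None, :, 1])
            - np.maximum(qs[:, None, 0], ss[None, :, 0])
        ) >= min_overlap
        qi, sj = np.nonzero(ov)
        pairs.extend((q_idx[a], s_idx[b]) for a, b in zip(qi.tolist(), sj.tolist()))
    pairs.sort()
    return pairs


def window_intersect(
    query: Sequence[GenomicInterval],
    subject: Sequence[GenomicInterval],
    w: int,
    genome: GenomeTable | None = None,
    strand_match: bool = False,
) -> list[tuple[int, int]]:
    """Pairs within ``w`` bp: each query is widened by ``w`` on both sides
    (clipped at chromosome bounds) before ordinary intersection (BEDTools
    ``window -w``). ``w=0`` reduces exactly to :func:`intersect`."""
    if w < 0:
        raise ValueError("window must be >= 0")
    widened = []
    for iv in query:
        start = max(0, iv.start - w)
        end = iv.end + w
        if genome is not None and iv.chrom in genome:
            end = min(end, genome.length(iv.chrom))
        widened.append(replace(iv, start=start, end=end))
    return intersect(widened, subject, strand_match=strand_match)


def split_intersect(
    query: Sequence[GenomicInterval],
    transcripts: Sequence[TranscriptModel],
    strand_match: bool = True,
) -> list[tuple[int, int]]:
    """(query index, transcript index) pairs with >= 1 bp overlap on EXONS only
    (BEDTools ``-split``); intron-only overlap yields no pair."""
    exon_ivs: list[GenomicInterval] = []
    exon_owner: list[int] = []
    for ti, t in enumerate(transcripts):
        for iv in t.exon_intervals():
            exon_ivs.append(iv)
            exon_owner.append(ti)
    raw = intersect(query, exon_ivs, strand_match=strand_match)
    pairs = sorted({(qi, exon_owner[si]) for qi, si in raw})
    return pairs


def subtract(
    query: Sequence[GenomicInterval],
    subject: Sequence[GenomicInterval],
    strand_match: bool = False,
) -> list[GenomicInterval]:
    """Query intervals with zero overlap against ``subject`` (BEDTools ``-v``)."""
    hit = {qi for qi, _ in intersect(query, subject, strand_match=strand_match)}
    return [iv for i, iv in enumerate(query) if i not in hit]
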