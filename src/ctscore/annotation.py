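"""Transcript models and exon-rank classification from GTF annotation.

Cryptic transcription is scored per gene on a single transcript backbone:
the longest annotated transcript, with exons ranked in transcription order
(5'->3') so that rank 1 is the promoter-proximal exon on either strand.
Intermediate exons -- the candidate landing zone for intragenic (cryptic)
initiation -- are ranks 4 through penultimate; a transcript needs at least
5 exons to have any.

Internal coordinates are 0-based half-open. GTF input (1-based inclusive)
is converted at the boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import pandas as pd

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "ExonClassification",
    "Annotation",
    "GtfParseError",
    "read_gtf",
    "select_longest_transcript",
    "classify_exons",
    "build_annotation",
    "write_annotation_cache",
    "read_annotation_cache",
]


class GtfParseError(ValueError):
    """Raised for malformed GTF input, naming the offending line."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a stranded chromosome."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"interval end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript as an ordered exon chain in transcription (5'->3') order.

    For minus-strand transcripts the genomically last exon is rank 1.
    ``exonic_length`` is the summed exon length in bp -- the quantity both
    RPKM normalisation and longest-transcript selection use.
    """

    transcript_id: str
    gene_id: str
    strand: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        starts = [e.start for e in self.exons]
        ends = [e.end for e in self.exons]
        # non-overlap + strict monotone order; minus-strand chains may run in
        # transcription (descending) or coordinate (ascending) rank order
        asc = all(ends[i] <= starts[i + 1] for i in range(len(starts) - 1))
        desc = all(ends[i + 1] <= starts[i] for i in range(len(starts) - 1))
        ok = asc if self.strand == "+" else (asc or desc)
        if not ok:
            raise ValueError(
                f"transcript {self.transcript_id}: exons overlap or are not "
                f"monotonically ordered"
            )

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def exonic_length(self) -> int:
        return sum(e.length for e in self.exons)

    def exon(self, rank: int) -> GenomicInterval:
        """Return the exon at 1-based transcription rank."""
        return self.exons[rank - 1]

    @property
    def span(self) -> GenomicInterval:
        """Genomic span from first to last exon (the gene body)."""
        start = min(e.start for e in self.exons)
        end = max(e.end for e in self.exons)
        return GenomicInterval(self.exons[0].chrom, start, end, self.strand)


@dataclass(frozen=True)
class ExonClassification:
    """Partition of a transcript's exon ranks into first / intermediate / unused.

    Intermediate exons are ranks {4 .. n-1}; the set is empty (and the
    transcript unscorable) for fewer than 5 exons.
    """

    transcript_id: str
    n_exons: int
    first_rank: int = 1
    intermediate_ranks: frozenset[int] = field(default_factory=frozenset)

    @property
    def unused_ranks(self) -> frozenset[int]:
        used = {self.first_rank} | self.intermediate_ranks
        return frozenset(r for r in range(1, self.n_exons + 1) if r not in used)

    @property
    def scorable(self) -> bool:
        return bool(self.intermediate_ranks)


def classify_exons(model: TranscriptModel | int) -> ExonClassification:
    """Classify a transcript's exons: rank 1 is first, ranks 4..n-1 intermediate.

    Accepts a TranscriptModel or a bare exon count.
    """
    if isinstance(model, TranscriptModel):
        n, tid = model.n_exons, model.transcript_id
    else:
        n, tid = int(model), ""
    intermediate = frozenset(range(4, n)) if n >= 5 else frozenset()
    return ExonClassification(transcript_id=tid, n_exons=n, intermediate_ranks=intermediate)


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr_field: str, lineno: int) -> dict[str, str]:
    attrs = dict(_ATTR_RE.findall(attr_field))
    if not attrs:
        raise GtfParseError(f"line {lineno}: empty or malformed attribute field: {attr_field!r}")
    return attrs


def read_gtf(path, rank_order: str = "transcription") -> list[TranscriptModel]:
    """Parse a GTF file into TranscriptModels (exons only; other features ignored).

    GTF coordinates (1-based inclusive) are converted to the internal
    0-based half-open convention. Exons are sorted into transcription order
    (5'->3'; rank 1 is promoter-proximal on either strand) by default, or
    genomic coordinate order with ``rank_order="coordinate"``.

    Raises
    ------
    GtfParseError
        If an exon feature lacks transcript_id/gene_id or a line is malformed,
        naming the line number.
    ValueError
        If exons within one transcript overlap.
    """
    if rank_order not in ("transcription", "coordinate"):
        raise ValueError(f"rank_order must be 'transcription' or 'coordinate', got {rank_order!r}")
    exons: dict[str, list[tuple[str, str, int, int, str]]] = {}
    gene_of: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            chrom, _source, feature, start, end, _score, strand, _frame, attr = fields
            if feature != "exon":
                continue
            attrs = _parse_attributes(attr, lineno)
            if "transcript_id" not in attrs:
                raise GtfParseError(f"line {lineno}: exon feature missing transcript_id")
            if "gene_id" not in attrs:
                raise GtfParseError(f"line {lineno}: exon feature missing gene_id")
            tid = attrs["transcript_id"]
            try:
                start0, end0 = int(start) - 1, int(end)
            except ValueError:
                raise GtfParseError(f"line {lineno}: non-integer coordinates {start!r}/{end!r}")
            exons.setdefault(tid, []).append((chrom, strand, start0, end0, tid))
            gene_of[tid] = attrs["gene_id"]

    models = []
    for tid, recs in exons.items():
        strand = recs[0][1]
        reverse = strand == "-" and rank_order == "transcription"
        recs_sorted = sorted(recs, key=lambda r: r[2], reverse=reverse)
        intervals = tuple(
            GenomicInterval(chrom=c, start=s, end=e, strand=st)
            for (c, st, s, e, _t) in recs_sorted
        )
        models.append(
            TranscriptModel(
                transcript_id=tid, gene_id=gene_of[tid], strand=strand, exons=intervals
            )
        )
    return models


def select_longest_transcript(
    models: Iterable[TranscriptModel],
) -> dict[str, TranscriptModel]:
    """Pick one transcript per gene: maximal exonic length, ties to the
    lexicographically smallest transcript_id."""
    chosen: dict[str, TranscriptModel] = {}
    for m in models:
        cur = chosen.get(m.gene_id)
        if cur is None:
            chosen[m.gene_id] = m
            continue
        key_new = (-m.exonic_length, m.transcript_id)
        key_cur = (-cur.exonic_length, cur.transcript_id)
        if key_new < key_cur:
            chosen[m.gene_id] = m
    return chosen


class Annotation:
    """Per-gene chosen transcripts plus their exon classifications.

    The coordinate backbone of the whole pipeline: downstream modules look
    up exon ranks, lengths and gene bodies here.
    """

    def __init__(self, transcripts: Mapping[str, TranscriptModel]):
        self.transcripts: dict[str, TranscriptModel] = dict(
            sorted(transcripts.items())
        )
        self.classifications: dict[str, ExonClassification] = {
            g: classify_exons(t) for g, t in self.transcripts.items()
        }

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[str]:
        return iter(self.transcripts)

    def __getitem__(self, gene_id: str) -> TranscriptModel:
        return self.transcripts[gene_id]

    def genes(self) -> list[str]:
        return list(self.transcripts)

    def exonic_lengths(self) -> pd.Series:
        return pd.Series(
            {g: t.exonic_length for g, t in self.transcripts.items()}, name="exonic_length"
        )

    def n_exons(self) -> pd.Series:
        return pd.Series({g: t.n_exons for g, t in self.transcripts.items()}, name="n_exons")

    def to_frame(self) -> pd.DataFrame:
        """Long table: one row per (gene, transcript, exon_rank)."""
        rows = []
        for g, t in self.transcripts.items():
            for rank, ex in enumerate(t.exons, start=1):
                rows.append(
                    (g, t.transcript_id, t.strand, rank, ex.chrom, ex.start, ex.end, ex.length)
                )
        return pd.DataFrame(
            rows,
            columns=[
                "gene_id", "transcript_id", "strand", "exon_rank",
                "chrom", "start0", "end0", "length",
            ],
        )


def build_annotation(models: Iterable[TranscriptModel]) -> Annotation:
    """Longest-transcript selection over a transcript collection."""
    return Annotation(select_longest_transcript(models))


def write_annotation_cache(annotation: Annotation, path) -> None:
    annotation.to_frame().to_csv(path, sep="\t", index=False)


def read_annotation_cache(path) -> Annotation:
    df = pd.read_csv(path, sep="\t")
    transcripts: dict[str, TranscriptModel] = {}
    for (gene, tid, strand), grp in df.groupby(
        ["gene_id", "transcript_id", "strand"], sort=False
    ):
        grp = grp.sort_values("exon_rank")
        exons = tuple(
            GenomicInterval(r.chrom, int(r.start0), int(r.end0), strand)
            for r in grp.itertuples()
        )
        transcripts[gene] = TranscriptModel(
            transcript_id=tid, gene_id=gene, strand=strand, exons=exons
        )
    return Annotation(transcripts)
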