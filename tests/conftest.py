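import numpy as np
import pandas as pd
import pytest

from ctscore.annotation import (
    Annotation,
    GenomicInterval,
    TranscriptModel,
)
from ctscore.quant import ExonCountTable


def make_transcript(
    tid: str,
    gene: str,
    strand: str = "+",
    lengths: tuple[int, ...] = (200, 100, 100, 100, 100, 150),
    chrom: str = "chr1",
    start: int = 1000,
    intron: int = 200,
) -> TranscriptModel:
    """Build a transcript with the given exon lengths in transcription order."""
    coords = []
    p = start
    for L in lengths:
        coords.append((p, p + L))
        p += L + intron
    ivs = [GenomicInterval(chrom, s, e, strand) for s, e in coords]
    if strand == "-":
        ivs = ivs[::-1]  # transcription order: genomically last exon first
    return TranscriptModel(transcript_id=tid, gene_id=gene, strand=strand, exons=tuple(ivs))


def make_count_table(
    annotation: Annotation, counts_by_gene: dict[str, dict[int, dict[str, int]]]
) -> ExonCountTable:
    """ExonCountTable from {gene: {rank: {sample: count}}} (absent cells 0)."""
    samples = sorted({s for g in counts_by_gene.values() for r in g.values() for s in r})
    rows, lens, data = [], [], []
    for gene in annotation.genes():
        t = annotation[gene]
        for rank in range(1, t.n_exons + 1):
            rows.append((gene, t.transcript_id, rank))
            lens.append(t.exon(rank).length)
            cell = counts_by_gene.get(gene, {}).get(rank, {})
            data.append([int(cell.get(s, 0)) for s in samples])
    index = pd.MultiIndex.from_tuples(rows, names=["gene_id", "transcript_id", "exon_rank"])
    counts = pd.DataFrame(data, index=index, columns=samples)
    lib = counts.sum(axis=0).clip(lower=1)
    return ExonCountTable(counts=counts, lengths=pd.Series(lens, index=index), library_sizes=lib)


@pytest.fixture
def hand_gene_annotation() -> Annotation:
    """One 6-exon gene with first exon 200 bp and two 100-bp intermediates:
    the backbone of the hand-computed ratio oracle."""
    t = make_transcript("T1", "G1", lengths=(200, 100, 100, 100, 100, 150))
    return Annotation({"G1": t})


@pytest.fixture
def tiny_gtf(tmp_path):
    """Gene G with a 3-exon and a 5-exon transcript, plus a minus-strand gene."""
    lines = []

    def exon(chrom, start1, end1, strand, gene, tid):
        lines.append(
            f"{chrom}\tsrc\texon\t{start1}\t{end1}\t.\t{strand}\t.\t"
            f'gene_id "{gene}"; transcript_id "{tid}";'
        )

    # plus-strand gene G: T1 3 exons, T2 5 exons
    for s, e in [(101, 200), (301, 400), (501, 600)]:
        exon("chr1", s, e, "+", "G", "T1")
    for s, e in [(101, 200), (251, 300), (351, 400), (451, 500), (551, 700)]:
        exon("chr1", s, e, "+", "G", "T2")
    # minus-strand gene H: exons [100,200) and [300,400) in 0-based terms
    exon("chr1", 101, 200, "-", "H", "H1")
    exon("chr1", 301, 400, "-", "H", "H1")
    path = tmp_path / "tiny.gtf"
    path.write_text("\n".join(lines) + "\n")
    return path
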