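"""Exon-count ingestion, RPKM, gene filters and the cryptic-transcription ratio.

The CT ratio for a gene is the pooled read density over its intermediate
exons (ranks 4..n-1 of the longest transcript) divided by the first-exon
read density. Excess intermediate signal relative to the promoter-proximal
exon is the RNA-seq proxy for intragenic (cryptic) initiation that escapes
H3K36me3-mediated suppression.

Genes are filtered once per dataset: fewer than four exons, or mean RPKM
across all samples below exp(-2), removes the gene for every sample, so the
scored universe is a single set per study.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import Annotation

__all__ = [
    "MIN_RPKM",
    "ExonCountTable",
    "CTScoreTable",
    "read_exon_counts",
    "gene_rpkm",
    "filter_genes",
    "compute_ct_scores",
    "condition_ratio",
    "ct_fold_change",
]

#: Expression floor from the analysis protocol: genes whose mean RPKM across
#: all samples falls below exp(-2) are discarded.
MIN_RPKM: float = math.exp(-2)

STATUS_SCORED = "scored"
STATUS_FILTERED_EXONS = "filtered_exons"
STATUS_FILTERED_EXPRESSION = "filtered_expression"
STATUS_NO_FIRST = "no_first_signal"
STATUS_NO_INTERMEDIATE = "no_intermediate_signal"


@dataclass
class ExonCountTable:
    """Integer read counts per (gene, transcript, exon_rank) per sample.

    ``counts`` is indexed by (gene_id, transcript_id, exon_rank) with one
    integer column per sample; ``lengths`` holds the exon length in bp on
    the same index; ``library_sizes`` the total assigned reads per sample.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    library_sizes: pd.Series

    def __post_init__(self) -> None:
        cnt = self.counts.to_numpy()
        if (cnt < 0).any():
            raise ValueError("negative read counts present")
        if not np.issubdtype(cnt.dtype, np.integer) and not np.allclose(cnt, np.round(cnt)):
            raise ValueError("non-integer read counts present")
        if (self.lengths < 1).any():
            raise ValueError("exon lengths must be >= 1 bp")
        if (self.library_sizes <= 0).any():
            raise ValueError("library sizes must be positive")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


def read_exon_counts(
    path,
    annotation: Annotation,
    metadata: pd.DataFrame | None = None,
) -> ExonCountTable:
    """Read an exon-level count TSV and validate it against the annotation.

    Expected columns: gene_id, transcript_id, exon_rank, length, then one
    column per sequencing run. If ``metadata`` declares technical replicates
    (columns sharing a ``replicate_group``/``sample`` label), replicate runs
    are collapsed by summing counts. Library size is the column sum.
    """
    df = pd.read_csv(path, sep="\t")
    required = ["gene_id", "transcript_id", "exon_rank", "length"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"count table missing columns: {missing}")
    sample_cols = [c for c in df.columns if c not in required]
    if len(set(sample_cols)) != len(sample_cols):
        raise ValueError("duplicate sample column names")

    known = {t.transcript_id for t in annotation.transcripts.values()}
    offenders = sorted(set(df["transcript_id"]) - known)
    if offenders:
        raise ValueError(f"unknown transcript_id(s): {offenders}")

    counts = df.set_index(["gene_id", "transcript_id", "exon_rank"])[sample_cols]
    if (counts.to_numpy() < 0).any():
        bad = counts[(counts < 0).any(axis=1)].index.tolist()
        raise ValueError(f"negative counts at rows {bad}")
    lengths = df.set_index(["gene_id", "transcript_id", "exon_rank"])["length"]

    counts = _collapse_replicates(counts, metadata)
    lib = counts.sum(axis=0)
    return ExonCountTable(counts=counts, lengths=lengths, library_sizes=lib)


def _collapse_replicates(
    counts: pd.DataFrame, metadata: pd.DataFrame | None
) -> pd.DataFrame:
    """Sum count columns declared technical replicates of one sample."""
    if metadata is None or "replicate_group" not in metadata.columns:
        return counts
    groups = metadata.set_index("sample")["replicate_group"]
    mapped = {c: groups.get(c, c) for c in counts.columns}
    return counts.T.groupby(counts.columns.map(mapped)).sum().T


def gene_rpkm(
    table: ExonCountTable, annotation: Annotation
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-gene RPKM matrix and its mean across samples.

    RPKM(g, s) = count_sum(g, s) / (exonic_length_kb(g) * libsize_millions(s)),
    with exonic length taken from the gene's chosen (longest) transcript.
    """
    if (table.library_sizes <= 0).any():
        raise ValueError("library size must be positive")
    gene_counts = table.counts.groupby(level="gene_id").sum()
    exonic_kb = annotation.exonic_lengths().reindex(gene_counts.index) / 1_000.0
    lib_m = table.library_sizes / 1e6
    rpkm = gene_counts.div(exonic_kb, axis=0).div(lib_m, axis=1)
    return rpkm, rpkm.mean(axis=1).rename("mean_rpkm")


def filter_genes(
    annotation: Annotation,
    rpkm_means: pd.Series,
    min_exons: int = 4,
    min_rpkm: float = MIN_RPKM,
) -> pd.DataFrame:
    """Dataset-level gene filter: pass/fail with a reason per gene.

    A gene fails with ``filtered_exons`` if its chosen transcript has fewer
    than ``min_exons`` exons, else with ``filtered_expression`` if its mean
    RPKM over all samples is below ``min_rpkm``. Exon count takes priority
    in the recorded reason.
    """
    n_exons = annotation.n_exons()
    genes = n_exons.index
    rpkm_means = rpkm_means.reindex(genes).fillna(0.0)
    reason = pd.Series("", index=genes, dtype=object)
    reason[rpkm_means < min_rpkm] = STATUS_FILTERED_EXPRESSION
    reason[n_exons < min_exons] = STATUS_FILTERED_EXONS
    return pd.DataFrame({
        "n_exons": n_exons,
        "mean_rpkm": rpkm_means,
        "passed": reason == "",
        "reason": reason,
    })


@dataclass
class CTScoreTable:
    """Per (gene, sample) cryptic-transcription scores.

    ``frame`` columns: gene_id, sample, first_density, intermediate_density,
    ratio, log2_ratio, status. A ratio is present iff status == 'scored'.
    """

    frame: pd.DataFrame

    def scored(self) -> pd.DataFrame:
        return self.frame[self.frame["status"] == STATUS_SCORED]

    def ratio_matrix(self) -> pd.DataFrame:
        """Gene x sample matrix of ratios (NaN where unscored)."""
        return self.scored().pivot(index="gene_id", columns="sample", values="ratio")

    def log2_matrix(self) -> pd.DataFrame:
        return self.scored().pivot(index="gene_id", columns="sample", values="log2_ratio")

    def write(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "CTScoreTable":
        return cls(pd.read_csv(path, sep="\t"))


def compute_ct_scores(
    table: ExonCountTable,
    annotation: Annotation,
    filters: pd.DataFrame,
    aggregate: str = "pooled",
) -> CTScoreTable:
    """Compute the CT ratio per gene and sample.

    first_density = count(rank 1) / length(rank 1);
    intermediate_density pools counts over pooled length of ranks 4..n-1
    (``aggregate="pooled"``, coverage-weighted) or averages per-exon
    densities (``aggregate="mean"``). ratio = intermediate / first.

    Degenerate cases carry a status instead of a ratio: zero first-exon
    count -> ``no_first_signal``; zero pooled intermediate count (or no
    intermediate exons at all) -> ``no_intermediate_signal``.
    """
    if aggregate not in ("pooled", "mean"):
        raise ValueError(f"aggregate must be 'pooled' or 'mean', got {aggregate!r}")
    samples = table.samples
    counts = table.counts

    # restrict to the chosen transcript of each gene
    chosen = {g: t.transcript_id for g, t in annotation.transcripts.items()}
    idx = counts.index
    gene_lv = idx.get_level_values("gene_id")
    tid_lv = idx.get_level_values("transcript_id")
    rank_lv = idx.get_level_values("exon_rank").to_numpy()
    on_chosen = np.fromiter(
        (chosen.get(g) == t for g, t in zip(gene_lv, tid_lv)), bool, len(idx)
    )
    n_exons = annotation.n_exons()
    n_by_row = n_exons.reindex(gene_lv).to_numpy()

    first_mask = on_chosen & (rank_lv == 1)
    inter_mask = on_chosen & (rank_lv >= 4) & (rank_lv <= n_by_row - 1)

    genes = filters.index
    cmat = counts.to_numpy(dtype=float)
    lvec = table.lengths.reindex(idx).to_numpy(dtype=float)
    gene_codes = pd.Categorical(gene_lv, categories=genes)
    codes = gene_codes.codes
    ng, ns = len(genes), len(samples)

    def _gsum(mask: np.ndarray, values: np.ndarray, width: int) -> np.ndarray:
        out = np.zeros((ng, width))
        np.add.at(out, codes[mask], values[mask])
        return out

    first_cnt = _gsum(first_mask, cmat, ns)
    first_len = _gsum(first_mask, lvec[:, None], 1)[:, 0]
    inter_cnt = _gsum(inter_mask, cmat, ns)
    inter_len = _gsum(inter_mask, lvec[:, None], 1)[:, 0]
    has_inter = inter_len > 0

    with np.errstate(divide="ignore", invalid="ignore"):
        first_density = np.where(
            first_len[:, None] > 0, first_cnt / np.maximum(first_len, 1e-300)[:, None], np.nan
        )
        if aggregate == "pooled":
            inter_density = np.where(has_inter[:, None], inter_cnt / inter_len[:, None], np.nan)
        else:
            dens = np.where(inter_mask[:, None], cmat / lvec[:, None], 0.0)
            n_inter = _gsum(inter_mask, np.ones((len(idx), 1)), 1)[:, 0]
            inter_density = np.where(
                n_inter[:, None] > 0,
                _gsum(inter_mask, dens, ns) / np.maximum(n_inter, 1)[:, None],
                np.nan,
            )
        ratio = inter_density / first_density

    status = np.full((ng, ns), STATUS_SCORED, dtype=object)
    passed = filters["passed"].to_numpy()
    status[~passed, :] = filters["reason"].to_numpy()[~passed, None]
    deg = passed[:, None] & ~has_inter[:, None] & np.ones((1, ns), bool)
    status[deg] = STATUS_NO_INTERMEDIATE
    no_inter_sig = passed[:, None] & has_inter[:, None] & (inter_cnt == 0)
    status[no_inter_sig] = STATUS_NO_INTERMEDIATE
    no_first = passed[:, None] & has_inter[:, None] & (first_cnt == 0)
    status[no_first] = STATUS_NO_FIRST

    scored = status == STATUS_SCORED
    ratio = np.where(scored, ratio, np.nan)
    first_density = np.where(passed[:, None], first_density, np.nan)
    inter_density = np.where(scored | no_inter_sig, inter_density, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2_ratio = np.log2(ratio)

    frame = pd.DataFrame({
        "gene_id": np.repeat(genes.to_numpy(), ns),
        "sample": np.tile(np.asarray(samples, dtype=object), ng),
        "first_density": first_density.ravel(),
        "intermediate_density": inter_density.ravel(),
        "ratio": ratio.ravel(),
        "log2_ratio": log2_ratio.ravel(),
        "status": status.ravel(),
    })
    return CTScoreTable(frame)


def score_dataset(
    table: ExonCountTable,
    annotation: Annotation,
    min_exons: int = 4,
    min_rpkm: float = MIN_RPKM,
    aggregate: str = "pooled",
) -> tuple[CTScoreTable, pd.Series, pd.DataFrame]:
    """RPKM -> dataset-level gene filter -> CT scores, in one call.

    Returns (scores, mean RPKM per gene, filter table).
    """
    _, rpkm_means = gene_rpkm(table, annotation)
    filters = filter_genes(annotation, rpkm_means, min_exons=min_exons, min_rpkm=min_rpkm)
    scores = compute_ct_scores(table, annotation, filters, aggregate=aggregate)
    return scores, rpkm_means, filters


def condition_ratio(
    scores: CTScoreTable, samples: list[str], agg: str = "mean"
) -> pd.Series:
    """Per-gene CT ratio summarised over a condition's samples.

    A gene contributes only if scored in every listed sample.
    """
    mat = scores.ratio_matrix().reindex(columns=samples)
    mat = mat.dropna(axis=0, how="any")
    if agg == "mean":
        return mat.mean(axis=1)
    if agg == "median":
        return mat.median(axis=1)
    raise ValueError(f"agg must be 'mean' or 'median', got {agg!r}")


def ct_fold_change(ratios_a: pd.Series, ratios_b: pd.Series) -> pd.Series:
    """Per-gene CT fold change: ratio_a / ratio_b on the natural scale.

    Genes unscored (absent/NaN) in either condition are dropped. Orientation
    is caller-defined; the pipeline convention is a = untreated, b = treated.
    """
    common = ratios_a.dropna().index.intersection(ratios_b.dropna().index)
    return (ratios_a.loc[common] / ratios_b.loc[common]).rename("fold_change")
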