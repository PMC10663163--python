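"""Synthetic data embodying the cryptic-initiation model the pipeline assumes.

Generative model
----------------
Each gene g carries one primary transcript with n_g exons of lengths L_j.
Canonical transcription deposits an expected ``lambda_g * L_j * s`` reads on
exon j in a sample with size factor s (lambda_g is expression in reads per
bp). A condition with cryptic rate theta >= 0 adds intragenic initiation:
every exon at or downstream of the cryptic start rank (>= 2, so the first
exon is never touched) gains ``theta * lambda_g * L_j * s`` expected reads.
Counts are negative-binomial with variance mean + alpha * mean^2 (alpha = 0
degenerates to Poisson).

Under this model the expected CT ratio has a closed form
(:func:`expected_ct_ratio`): 1 + theta for a fixed start at rank 4, and a
length-weighted mixture over start ranks for the uniform start rule —
the oracle for pipeline recovery tests.

All randomness flows from one seed through per-table child streams, so
every emitted artifact is byte-reproducible.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import Annotation, GenomicInterval, TranscriptModel, build_annotation
from .chip import CoverageTrack
from .quant import ExonCountTable

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_annotation",
    "simulate_counts",
    "simulate_metadata",
    "simulate_chip_coverage",
    "simulate_signature_expression",
    "expected_ct_ratio",
    "write_gtf",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulator.

    theta maps condition name -> cryptic rate; the first key is the
    reference (baseline) condition. cage_log2_effect adds a cage-B batch
    shift on the log2 CT scale; confounding_weight in [0, 1] skews cage-B
    membership toward non-reference conditions (0 = balanced).
    """

    seed: int
    n_genes: int = 200
    exon_count_range: tuple[int, int] = (3, 12)
    exon_length_range: tuple[int, int] = (80, 1200)
    intron_length_range: tuple[int, int] = (100, 1000)
    intergenic_gap_range: tuple[int, int] = (500, 2000)
    expr_log_mean: float = float(np.log(0.2))
    expr_log_sd: float = 1.0
    theta: dict[str, float] = field(default_factory=lambda: {"control": 0.0, "treated": 0.5})
    start_rule: tuple = ("fixed", 4)
    dispersion: float = 0.1
    samples_per_condition: int = 6
    size_factor_sd: float = 0.0
    cage_log2_effect: float = 0.0
    confounding_weight: float = 0.0
    decoy_isoforms: bool = False
    chrom: str = "chr1"
    n_planted: int = 0
    theta_planted: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.theta.values()):
            raise ValueError("cryptic rates must be >= 0")
        if self.dispersion < 0:
            raise ValueError("NB dispersion must be >= 0")
        if not 0 <= self.confounding_weight <= 1:
            raise ValueError("confounding_weight must lie in [0, 1]")
        if self.n_planted and self.theta_planted is None:
            raise ValueError("n_planted > 0 requires theta_planted rates")
        if self.theta_planted and any(v < 0 for v in self.theta_planted.values()):
            raise ValueError("planted cryptic rates must be >= 0")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent child stream for one emitted table."""
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stream]))


@dataclass
class SimTruth:
    """Generative ground truth matching the emitted tables exactly."""

    lam: pd.Series                 # per-gene expression, reads per bp
    n_exons: pd.Series
    exon_lengths: dict[str, np.ndarray]
    start_rank: pd.Series          # cryptic start rank per gene
    theta: dict[str, float]        # per-condition cryptic rate
    theta_by_sample: pd.Series
    size_factors: pd.Series
    planted: frozenset[str] = frozenset()  # genes on the planted-rate schedule


_STREAM_ANNOT, _STREAM_META, _STREAM_COUNTS, _STREAM_EXPR = 1, 2, 3, 4


def simulate_annotation(config: SimConfig) -> tuple[Annotation, dict[str, int]]:
    """Lay out non-overlapping gene loci on one chromosome.

    Returns (annotation of chosen transcripts, chrom_sizes). With
    ``decoy_isoforms`` a strictly shorter secondary isoform per gene
    exercises longest-transcript selection.
    """
    rng = config.rng(_STREAM_ANNOT)
    lo_n, hi_n = config.exon_count_range
    lo_l, hi_l = config.exon_length_range
    models: list[TranscriptModel] = []
    pos = 1000
    for i in range(config.n_genes):
        gene = f"G{i:04d}"
        n_ex = int(rng.integers(lo_n, hi_n + 1))
        lens = np.exp(rng.uniform(np.log(lo_l), np.log(hi_l), size=n_ex)).astype(int)
        lens = np.maximum(lens, 1)
        introns = rng.integers(*config.intron_length_range, size=max(n_ex - 1, 1))
        strand = "+" if rng.random() < 0.5 else "-"
        coords = []
        p = pos
        for j in range(n_ex):
            coords.append((p, p + int(lens[j])))
            p += int(lens[j]) + (int(introns[j]) if j < n_ex - 1 else 0)
        gene_end = coords[-1][1]
        exons_genomic = [
            GenomicInterval(config.chrom, s, e, strand) for s, e in coords
        ]
        order = exons_genomic if strand == "+" else exons_genomic[::-1]
        models.append(
            TranscriptModel(
                transcript_id=f"{gene}.t1", gene_id=gene, strand=strand, exons=tuple(order)
            )
        )
        if config.decoy_isoforms and n_ex >= 2:
            # drop the 3'-most exon: guaranteed shorter than the primary
            models.append(
                TranscriptModel(
                    transcript_id=f"{gene}.t2", gene_id=gene, strand=strand,
                    exons=tuple(order[:-1]),
                )
            )
        pos = gene_end + int(rng.integers(*config.intergenic_gap_range))
    chrom_sizes = {config.chrom: pos + 10_000}
    return build_annotation(models), chrom_sizes


def write_gtf(annotation: Annotation, path, source: str = "ctscore_sim") -> None:
    """Emit the annotation as GTF (1-based inclusive), in coordinate order."""
    rows = []
    for gene in annotation.genes():
        t = annotation[gene]
        for ex in sorted(t.exons, key=lambda e: e.start):
            rows.append(
                f"{ex.chrom}\t{source}\texon\t{ex.start + 1}\t{ex.end}\t.\t{t.strand}\t.\t"
                f'gene_id "{gene}"; transcript_id "{t.transcript_id}";'
            )
    with open(path, "w") as fh:
        fh.write("\n".join(rows) + "\n")


def simulate_metadata(config: SimConfig) -> pd.DataFrame:
    """Sample sheet: sample, condition, cage, sex, day, replicate_group.

    Cage-B membership per condition is (0.5 + w/2) for non-reference
    conditions and (0.5 - w/2) for the reference, realised as exact counts
    so the planted confounding is deterministic. Day is parsed from
    condition names like 'D6' where present, else 0.
    """
    rng = config.rng(_STREAM_META)
    conditions = list(config.theta)
    ref = conditions[0]
    rows = []
    idx = 0
    for cond in conditions:
        n = config.samples_per_condition
        frac_b = 0.5 + (config.confounding_weight / 2) * (1 if cond != ref else -1)
        n_b = int(round(n * frac_b))
        cages = np.array(["B"] * n_b + ["A"] * (n - n_b))
        rng.shuffle(cages)
        m = re.fullmatch(r"[Dd](\d+)", cond)
        day = int(m.group(1)) if m else 0
        for j in range(n):
            sample = f"s{idx:03d}_{cond}"
            rows.append({
                "sample": sample,
                "replicate_group": sample,
                "condition": cond,
                "cage": cages[j],
                "sex": "M" if idx % 2 == 0 else "F",
                "day": day,
            })
            idx += 1
    return pd.DataFrame(rows)


def _theta_by_sample(
    config: SimConfig, metadata: pd.DataFrame, rates: dict[str, float]
) -> pd.Series:
    """Per-sample cryptic rate from condition rates, with the optional cage
    batch effect applied multiplicatively on the (1 + theta) scale so it is
    additive on log2."""
    theta_cond = metadata.set_index("sample")["condition"].map(rates)
    if theta_cond.isna().any():
        missing = sorted(metadata.loc[theta_cond.isna().to_numpy(), "condition"].unique())
        raise ValueError(f"no cryptic rate for condition(s): {missing}")
    if config.cage_log2_effect != 0.0:
        cage_b = (metadata.set_index("sample")["cage"] == "B").astype(float)
        return (1 + theta_cond) * np.power(2.0, config.cage_log2_effect * cage_b) - 1
    return theta_cond.astype(float)


def _draw_start_ranks(config: SimConfig, n_exons: pd.Series, rng) -> pd.Series:
    rule = config.start_rule
    if rule[0] == "fixed":
        return pd.Series(int(rule[1]), index=n_exons.index)
    if rule[0] == "uniform":
        return pd.Series(
            [int(rng.integers(2, n + 1)) if n >= 2 else 2 for n in n_exons],
            index=n_exons.index,
        )
    raise ValueError(f"unknown start rule {rule!r}")


def simulate_counts(
    config: SimConfig,
    annotation: Annotation,
    metadata: pd.DataFrame,
) -> tuple[ExonCountTable, SimTruth]:
    """Draw exon-level counts under the cryptic-initiation model."""
    rng = config.rng(_STREAM_COUNTS)
    genes = annotation.genes()
    n_exons = annotation.n_exons()
    lam = pd.Series(
        np.exp(rng.normal(config.expr_log_mean, config.expr_log_sd, len(genes))),
        index=genes, name="lambda",
    )
    start_rank = _draw_start_ranks(config, n_exons, rng)

    samples = metadata["sample"].tolist()
    size = pd.Series(
        np.exp(rng.normal(0.0, config.size_factor_sd, len(samples)))
        if config.size_factor_sd > 0 else np.ones(len(samples)),
        index=samples, name="size_factor",
    )
    theta_s = _theta_by_sample(config, metadata, config.theta).reindex(samples)
    planted: frozenset[str] = frozenset()
    theta_p = theta_s
    if config.n_planted:
        eligible = [g for g in genes if n_exons[g] >= 5]
        if config.n_planted > len(eligible):
            raise ValueError("fewer scoreable genes than requested planted genes")
        planted = frozenset(rng.choice(eligible, size=config.n_planted, replace=False))
        theta_p = _theta_by_sample(config, metadata, config.theta_planted).reindex(samples)

    index_rows, len_rows = [], []
    mean_blocks = []
    theta_vec = theta_s.to_numpy()
    theta_vec_p = theta_p.to_numpy()
    size_vec = size.to_numpy()
    for gene in genes:
        t = annotation[gene]
        lens = np.array([e.length for e in t.exons], dtype=float)
        ranks = np.arange(1, t.n_exons + 1)
        cryptic = (ranks >= start_rank[gene]).astype(float)
        base = lam[gene] * lens  # per-exon canonical mean at s=1
        tvec = theta_vec_p if gene in planted else theta_vec
        mean = np.outer(base, size_vec) * (1 + np.outer(cryptic, tvec))
        mean_blocks.append(mean)
        for r, L in zip(ranks, lens):
            index_rows.append((gene, t.transcript_id, int(r)))
            len_rows.append(int(L))
    mean_mat = np.vstack(mean_blocks)
    if config.dispersion > 0:
        r_nb = 1.0 / config.dispersion
        p_nb = r_nb / (r_nb + mean_mat)
        counts = rng.negative_binomial(r_nb, np.clip(p_nb, 1e-12, 1.0))
    else:
        counts = rng.poisson(mean_mat)

    index = pd.MultiIndex.from_tuples(
        index_rows, names=["gene_id", "transcript_id", "exon_rank"]
    )
    counts_df = pd.DataFrame(counts, index=index, columns=samples)
    lengths = pd.Series(len_rows, index=index, name="length")
    table = ExonCountTable(
        counts=counts_df, lengths=lengths, library_sizes=counts_df.sum(axis=0)
    )
    truth = SimTruth(
        lam=lam,
        n_exons=n_exons,
        exon_lengths={g: np.array([e.length for e in annotation[g].exons]) for g in genes},
        start_rank=start_rank,
        theta=dict(config.theta),
        theta_by_sample=theta_s,
        size_factors=size,
        planted=planted,
    )
    return table, truth


def b12_rescue_config(seed: int, n_genes: int = 200, n_planted: int = 25) -> SimConfig:
    """Preset emulating the reprogramming/rescue design: a baseline (MEF),
    an induced condition (OSKM) with globally elevated cryptic initiation,
    and a treated condition (OSKM+B12) in which a planted gene subset is
    rescued to near-baseline rates while the background stays induced."""
    return SimConfig(
        seed=seed,
        n_genes=n_genes,
        exon_count_range=(5, 12),
        theta={"MEF": 0.0, "OSKM": 0.15, "OSKM_B12": 0.15},
        n_planted=n_planted,
        theta_planted={"MEF": 0.0, "OSKM": 0.8, "OSKM_B12": 0.05},
    )


def write_counts_tsv(table: ExonCountTable, path) -> None:
    df = table.counts.copy()
    df.insert(0, "length", table.lengths)
    df.reset_index().to_csv(path, sep="\t", index=False)


def expected_ct_ratio(
    theta: float,
    start_rule: tuple = ("fixed", 4),
    n_exons: int = 6,
    lengths=None,
) -> float:
    """Closed-form expected CT ratio under the simulator's generative model.

    Fixed start at rank k <= 4: every intermediate exon carries the cryptic
    component, so E[ratio] = 1 + theta. Uniform start over ranks {2..n}:
    intermediate exon j carries it with probability P(start <= j) =
    (j - 1)/(n - 1), giving a length-weighted mixture. The first-exon
    density is unaffected in both cases (start >= 2).
    """
    n = int(n_exons)
    if n < 5:
        raise ValueError("expected ratio needs >= 5 exons (non-empty intermediate set)")
    inter = np.arange(4, n)
    L = np.ones(len(inter)) if lengths is None else np.asarray(
        [lengths[j - 1] for j in inter], dtype=float
    )
    if start_rule[0] == "fixed":
        k = int(start_rule[1])
        carries = (inter >= k).astype(float)
        return 1 + theta * float((L * carries).sum() / L.sum())
    if start_rule[0] == "uniform":
        p_le = (inter - 1) / (n - 1)
        return 1 + theta * float((L * p_le).sum() / L.sum())
    raise ValueError(f"unknown start rule {start_rule!r}")


def simulate_chip_coverage(
    annotation: Annotation,
    expression: pd.Series,
    chrom_sizes: dict[str, int],
    background: float = 1.0,
    enrichment: float = 1.0,
) -> CoverageTrack:
    """Deterministic ChIP-like track: depth = background everywhere, plus
    enrichment * lambda_g inside gene g's body."""
    runs: dict[str, list[list[float]]] = {c: [] for c in chrom_sizes}
    bodies: dict[str, list[tuple[int, int, float]]] = {c: [] for c in chrom_sizes}
    for gene in annotation.genes():
        span = annotation[gene].span
        bump = enrichment * float(expression.get(gene, 0.0))
        bodies[span.chrom].append((span.start, span.end, bump))
    for chrom, size in chrom_sizes.items():
        pos = 0
        for start, end, bump in sorted(bodies[chrom]):
            if start > pos and background > 0:
                runs[chrom].append([pos, start, background])
            depth = background + bump
            if depth > 0:
                runs[chrom].append([start, end, depth])
            pos = end
        if pos < size and background > 0:
            runs[chrom].append([pos, size, background])
    return CoverageTrack(
        runs={c: np.asarray(v, dtype=float).reshape(-1, 3) for c, v in runs.items()},
        chrom_sizes=dict(chrom_sizes),
    )


def simulate_signature_expression(
    signature: list[str],
    config: SimConfig,
    n_control: int = 6,
    n_poised: int = 6,
    delta: float = 3.0,
    noise_sd: float = 1.0,
    n_background: int = 100,
) -> tuple[pd.DataFrame, pd.Series]:
    """Expression matrix (already on a transformed scale) where 'poised'
    samples sit ``delta`` standard deviations above controls on signature
    genes. Returns (matrix, group labels)."""
    if not signature:
        raise ValueError("signature must be non-empty")
    rng = config.rng(_STREAM_EXPR)
    samples = [f"ctrl{i}" for i in range(n_control)] + [f"poised{i}" for i in range(n_poised)]
    groups = pd.Series(["control"] * n_control + ["poised"] * n_poised, index=samples)
    genes = list(signature) + [f"BG{i:04d}" for i in range(n_background)]
    mat = rng.normal(0.0, noise_sd, size=(len(genes), len(samples)))
    shift = np.zeros((len(genes), len(samples)))
    shift[: len(signature), n_control:] = delta * noise_sd
    df = pd.DataFrame(mat + shift, index=genes, columns=samples)
    return df, groups
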