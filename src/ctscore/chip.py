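"""Gene-body coverage meta-profiles and body-read fractions from bedGraph tracks.

H3K36me3 is deposited co-transcriptionally over gene bodies, so its loss is
visible as (i) a drop in the fraction of ChIP coverage mass falling inside
gene bodies and (ii) a flattening of the body portion of the meta-gene
profile, most prominently for highly expressed genes. This module computes
both from run-length coverage tracks: fixed 50-bp flank bins (1 kb each
side), a gene body linearly rescaled to a fixed bin count with
mass-preserving averaging, and "w0" semantics throughout (uncovered bases
contribute zeros to bin denominators).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import Annotation
from .stats import assign_strata

__all__ = [
    "CoverageTrack",
    "read_bedgraph",
    "bin_coverage",
    "meta_gene_matrix",
    "gene_body_fraction",
    "split_by_expression",
    "reads_to_track",
]


@dataclass
class CoverageTrack:
    """Run-length genome coverage: sorted non-overlapping (start, end, depth) runs.

    Gaps between runs are depth 0. ``chrom_sizes`` bounds every run.
    """

    runs: dict[str, np.ndarray]  # per chrom: float array of shape (k, 3)
    chrom_sizes: dict[str, int]

    def __post_init__(self) -> None:
        for chrom, arr in self.runs.items():
            arr = np.asarray(arr, dtype=float).reshape(-1, 3)
            if chrom not in self.chrom_sizes:
                raise ValueError(f"unknown chromosome {chrom!r}")
            size = self.chrom_sizes[chrom]
            if len(arr):
                if (arr[:, 2] < 0).any():
                    raise ValueError(f"{chrom}: negative depth")
                if (arr[:, 0] < 0).any() or (arr[:, 1] > size).any():
                    raise ValueError(f"{chrom}: interval outside chromosome bounds")
                if (arr[:, 1] <= arr[:, 0]).any():
                    raise ValueError(f"{chrom}: empty or inverted interval")
                order = np.argsort(arr[:, 0], kind="stable")
                arr = arr[order]
                if (arr[1:, 0] < arr[:-1, 1]).any():
                    raise ValueError(f"{chrom}: overlapping intervals")
            self.runs[chrom] = arr

    def total_mass(self) -> float:
        """Sum of depth x length over the genome."""
        return float(
            sum(((a[:, 1] - a[:, 0]) * a[:, 2]).sum() for a in self.runs.values())
        )

    def mass_between(self, chrom: str, start: float, end: float) -> float:
        """Coverage mass (integral of depth) over [start, end); fractional
        endpoints supported for body rescaling."""
        arr = self.runs.get(chrom)
        if arr is None or len(arr) == 0 or end <= start:
            return 0.0
        lo = np.minimum(np.maximum(arr[:, 0], start), end)
        hi = np.minimum(np.maximum(arr[:, 1], start), end)
        return float(((hi - lo) * arr[:, 2]).sum())

    def mean_depth(self, chrom: str, start: float, end: float) -> float:
        """Mean depth over [start, end), zeros included (w0 semantics)."""
        if end <= start:
            return 0.0
        return self.mass_between(chrom, start, end) / (end - start)

    def scale(self, factor: float) -> "CoverageTrack":
        return CoverageTrack(
            runs={c: np.column_stack([a[:, 0], a[:, 1], a[:, 2] * factor])
                  for c, a in self.runs.items()},
            chrom_sizes=dict(self.chrom_sizes),
        )


def read_bedgraph(path, chrom_sizes: dict[str, int]) -> CoverageTrack:
    """Parse a bedGraph (0-based half-open) into a validated CoverageTrack."""
    runs: dict[str, list[list[float]]] = {c: [] for c in chrom_sizes}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"line {lineno}: bedGraph rows need 4 fields")
            chrom, start, end, depth = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if chrom not in chrom_sizes:
                raise ValueError(f"line {lineno}: unknown chromosome {chrom!r}")
            if end > chrom_sizes[chrom]:
                raise ValueError(f"line {lineno}: interval past end of {chrom}")
            if depth < 0:
                raise ValueError(f"line {lineno}: negative depth")
            runs[chrom].append([start, end, depth])
    return CoverageTrack(
        runs={c: np.asarray(v, dtype=float).reshape(-1, 3) for c, v in runs.items()},
        chrom_sizes=dict(chrom_sizes),
    )


def write_bedgraph(track: CoverageTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.runs):
            for start, end, depth in track.runs[chrom]:
                fh.write(f"{chrom}\t{int(start)}\t{int(end)}\t{depth:g}\n")


def reads_to_track(
    reads: pd.DataFrame, chrom_sizes: dict[str, int]
) -> CoverageTrack:
    """Pile up a read-interval table (chrom, start, end) into a coverage track.

    Testing helper standing in for an upstream depth computation.
    """
    runs = {}
    for chrom, size in chrom_sizes.items():
        sub = reads[reads["chrom"] == chrom]
        depth = np.zeros(size)
        for r in sub.itertuples():
            depth[int(r.start): int(r.end)] += 1
        runs[chrom] = _dense_to_runs(depth)
    return CoverageTrack(runs=runs, chrom_sizes=dict(chrom_sizes))


def _dense_to_runs(depth: np.ndarray) -> np.ndarray:
    """Run-length encode a dense per-base depth vector, dropping zero runs."""
    if depth.size == 0:
        return np.empty((0, 3))
    change = np.flatnonzero(np.diff(depth)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [depth.size]])
    vals = depth[starts]
    keep = vals > 0
    return np.column_stack([starts[keep], ends[keep], vals[keep]]).astype(float)


def bin_coverage(track: CoverageTrack, w: int = 50) -> dict[str, np.ndarray]:
    """Mean depth per fixed-width window, per chromosome.

    The terminal partial bin is averaged over its actual width, so coverage
    mass is conserved: sum(bin_mean * bin_width) equals the track's mass.
    """
    if w < 1:
        raise ValueError("window width must be >= 1")
    out = {}
    for chrom, size in track.chrom_sizes.items():
        n_bins = int(np.ceil(size / w))
        edges = np.minimum(np.arange(n_bins + 1) * w, size).astype(float)
        masses = _masses_at_edges(track, chrom, edges)
        widths = np.diff(edges)
        out[chrom] = masses / widths
    return out


def _masses_at_edges(track: CoverageTrack, chrom: str, edges: np.ndarray) -> np.ndarray:
    """Coverage mass within each interval of a sorted edge vector."""
    arr = track.runs.get(chrom)
    if arr is None or len(arr) == 0:
        return np.zeros(len(edges) - 1)
    starts, ends, depths = arr[:, 0], arr[:, 1], arr[:, 2]
    # cumulative mass function evaluated at arbitrary positions
    cum = np.concatenate([[0.0], np.cumsum((ends - starts) * depths)])

    def cmf(pos: np.ndarray) -> np.ndarray:
        i = np.searchsorted(ends, pos, side="left")  # run containing/after pos
        i = np.minimum(i, len(starts) - 1)
        base = cum[i]
        partial = np.clip(pos - starts[i], 0.0, ends[i] - starts[i]) * depths[i]
        full = pos >= ends[i]
        return np.where(full, cum[i + 1], base + partial)

    vals = cmf(np.asarray(edges, dtype=float))
    return np.diff(vals)


def meta_gene_matrix(
    track: CoverageTrack,
    annotation: Annotation,
    extend: int = 1000,
    w: int = 50,
    body_bins: int = 100,
) -> pd.DataFrame:
    """Meta-gene coverage matrix: flank bins at ``w`` bp, body rescaled to
    ``body_bins`` mass-preserving bins, rows oriented 5'->3'.

    Columns: u1..u{extend/w} (upstream flank), b1..b{body_bins} (body),
    d1..d{extend/w} (downstream flank). Flanks clipped at chromosome edges
    keep their genomic width in the denominator (w0: absent bases count as
    zero depth). A ``clipped`` column flags genes whose flanks were clipped.
    """
    n_flank = extend // w
    rows = []
    clipped_flags = []
    genes = annotation.genes()
    for gene in genes:
        model = annotation[gene]
        body = model.span
        chrom, size = body.chrom, track.chrom_sizes[body.chrom]

        def flank_means(lo: int, hi: int) -> np.ndarray:
            edges = np.linspace(lo, hi, n_flank + 1)
            arr = np.zeros(n_flank)
            c_lo, c_hi = max(lo, 0), min(hi, size)
            if c_hi > c_lo:
                ce = np.clip(edges, 0, size)
                arr = _masses_at_edges(track, chrom, ce) / (edges[1:] - edges[:-1])
            return arr

        left = flank_means(body.start - extend, body.start)
        right = flank_means(body.end, body.end + extend)
        body_edges = np.linspace(body.start, body.end, body_bins + 1)
        body_means = _masses_at_edges(track, chrom, body_edges) / np.diff(body_edges)
        profile = np.concatenate([left, body_means, right])
        if model.strand == "-":
            profile = profile[::-1]
        rows.append(profile)
        clipped_flags.append(body.start - extend < 0 or body.end + extend > size)
    cols = (
        [f"u{i}" for i in range(1, n_flank + 1)]
        + [f"b{i}" for i in range(1, body_bins + 1)]
        + [f"d{i}" for i in range(1, n_flank + 1)]
    )
    df = pd.DataFrame(rows, index=pd.Index(genes, name="gene_id"), columns=cols)
    df.attrs["clipped"] = pd.Series(clipped_flags, index=df.index)
    return df


def gene_body_fraction(track: CoverageTrack, annotation: Annotation) -> float:
    """Fraction of total coverage mass inside (merged) gene bodies."""
    total = track.total_mass()
    if total <= 0:
        raise ValueError("track has zero total coverage mass")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for gene in annotation.genes():
        span = annotation[gene].span
        by_chrom.setdefault(span.chrom, []).append((span.start, span.end))
    inside = 0.0
    for chrom, ivs in by_chrom.items():
        for start, end in _merge_intervals(ivs):
            inside += track.mass_between(chrom, start, end)
    return inside / total


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for start, end in sorted(ivs):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def split_by_expression(
    matrix: pd.DataFrame, rpkm_means: pd.Series, K: int = 3
) -> dict[int, pd.DataFrame]:
    """Partition meta-gene rows into expression strata (terciles by default).

    Returns {stratum: row subset}; stratum K is the most highly expressed.
    Column means per group are the meta-profile traces.
    """
    strata = assign_strata(rpkm_means.reindex(matrix.index).dropna(), K=K)
    out = {}
    for k in range(1, K + 1):
        genes = strata[strata == k].index
        out[k] = matrix.loc[matrix.index.intersection(genes)]
    return out
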