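"""Rescued-gene selection, gene-set over-representation and the reprogramming score.

Genes whose cryptic transcription rises under reprogramming and falls back
under vitamin B12 are selected by a two-tailed percentile rule on the two
CT fold-change vectors (upper 25% of the induction comparison AND bottom
25% of the rescue comparison). Over-representation of a gene set in the
selection is scored by the exact hypergeometric upper tail. The
reprogramming score summarises how far a sample's transcriptome has moved
toward the "poised to reprogram" expression signature: the mean, over
signature genes, of per-gene z-scores of a variance-stabilised expression
matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .stats import bh_adjust

__all__ = [
    "GeneSetCollection",
    "SelectionResult",
    "read_gmt",
    "select_rescued_genes",
    "hypergeometric_test",
    "enrich_collection",
    "build_signature",
    "reprogramming_score",
]


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT dialect) with optional descriptions."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [name for name, s in self.sets.items() if not s]
        if empty:
            raise ValueError(f"empty gene sets: {empty}")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: set_name TAB description TAB gene1 TAB gene2 ..."""
    sets: dict[str, frozenset[str]] = {}
    desc: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"line {lineno}: GMT rows need set_name, description and >=1 gene"
                )
            name, description, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise ValueError(f"line {lineno}: gene set {name!r} is empty")
            sets[name] = frozenset(genes)
            desc[name] = description
    return GeneSetCollection(sets=sets, descriptions=desc)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


@dataclass
class SelectionResult:
    """Outcome of the two-percentile rescued-gene selection."""

    delta1: pd.Series
    delta2: pd.Series
    threshold_upper: float
    threshold_lower: float
    selected: frozenset[str]

    def to_frame(self) -> pd.DataFrame:
        genes = self.delta1.index
        return pd.DataFrame({
            "gene_id": genes,
            "delta1": self.delta1.to_numpy(),
            "delta2": self.delta2.reindex(genes).to_numpy(),
            "selected": [g in self.selected for g in genes],
        })


def select_rescued_genes(
    delta1: pd.Series, delta2: pd.Series, q: float = 25.0
) -> SelectionResult:
    """Select genes in the upper q% of ``delta1`` AND the bottom q% of ``delta2``.

    ``delta1`` is the CT fold change of the induction comparison (reprogrammed
    vs baseline; rescued genes sit in its upper tail) and ``delta2`` that of
    the rescue comparison (treated vs reprogrammed; rescued genes sit in its
    lower tail). Thresholds are linear-interpolation empirical quantiles with
    boundary values included. Genes missing either delta are excluded from
    the universe.
    """
    common = delta1.dropna().index.intersection(delta2.dropna().index)
    if len(common) == 0:
        raise ValueError("no genes with both fold changes defined")
    d1 = delta1.loc[common].astype(float)
    d2 = delta2.loc[common].astype(float)
    hi = float(np.quantile(d1.to_numpy(), 1 - q / 100.0))
    lo = float(np.quantile(d2.to_numpy(), q / 100.0))
    selected = frozenset(common[(d1 >= hi) & (d2 <= lo)])
    if len(selected) == len(common):
        warnings.warn(
            "degenerate selection: every gene lies on both percentile boundaries",
            UserWarning,
            stacklevel=2,
        )
    return SelectionResult(
        delta1=d1, delta2=d2, threshold_upper=hi, threshold_lower=lo, selected=selected
    )


def hypergeometric_test(
    selected: set[str], gene_set: set[str], universe: set[str]
) -> dict:
    """Exact upper-tail hypergeometric over-representation test.

    With N = |universe|, m = |gene_set ∩ universe|, n = |selected| and
    k = |selected ∩ gene_set|, returns p = P(X >= k) for
    X ~ Hypergeom(N, m, n).
    """
    universe = set(universe)
    selected = set(selected)
    if not selected <= universe:
        raise ValueError("selected genes must be a subset of the universe")
    in_set = set(gene_set) & universe
    N, m, n = len(universe), len(in_set), len(selected)
    k = len(selected & in_set)
    p = float(hypergeom.sf(k - 1, N, m, n))
    return {"k": k, "m": m, "n": n, "N": N, "p": p}


def enrich_collection(
    selected: set[str],
    collection: GeneSetCollection,
    universe: set[str],
    min_size: int = 8,
    max_size: int = 499,
    p_cut: float | None = 0.005,
) -> pd.DataFrame:
    """Hypergeometric over-representation across a collection.

    Sets whose in-universe size falls outside [min_size, max_size] are
    skipped. Rows are sorted by p ascending; unadjusted p is primary, a BH
    column is provided for convenience. ``p_cut`` (if given) keeps only
    rows with p < p_cut.
    """
    rows = []
    for name, genes in collection.items():
        m = len(set(genes) & set(universe))
        if m < min_size or m > max_size:
            continue
        res = hypergeometric_test(selected, genes, universe)
        rows.append({"set_name": name, **res})
    df = pd.DataFrame(rows, columns=["set_name", "k", "m", "n", "N", "p"])
    if len(df):
        df["p_bh"] = bh_adjust(df["p"].to_numpy())
        df = df.sort_values(["p", "set_name"], kind="stable").reset_index(drop=True)
        if p_cut is not None:
            df = df[df["p"] < p_cut].reset_index(drop=True)
    return df


def build_signature(
    diff_table: pd.DataFrame, fdr_cut: float = 0.05, fc_cut: float = 2.0
) -> list[str]:
    """Signature genes from a differential table: FDR < fdr_cut AND fold change > fc_cut.

    The fold-change filter is one-sided (strictly greater), matching a
    signature built from genes up in the poised state versus baseline.
    """
    for col in ("gene", "fold_change", "fdr"):
        if col not in diff_table.columns:
            raise ValueError(f"differential table missing column {col!r}")
    keep = (diff_table["fdr"] < fdr_cut) & (diff_table["fold_change"] > fc_cut)
    genes = diff_table.loc[keep, "gene"].astype(str).tolist()
    if not genes:
        raise ValueError("no genes pass the signature thresholds")
    return genes


def _log2_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    lib = counts.sum(axis=0)
    return np.log2(counts.div(lib, axis=1) * 1e6 + 1.0)


def reprogramming_score(
    expr: pd.DataFrame,
    signature: list[str],
    transform: str | Callable[[pd.DataFrame], pd.DataFrame] | None = "log2cpm",
) -> pd.Series:
    """Per-sample reprogramming score: mean z-score over signature genes.

    ``expr`` is a gene x sample matrix. ``transform`` stabilises variance
    before z-scoring: the default log2(CPM + 1) for raw counts, ``None`` for
    matrices already on a transformed scale, or any callable — so an
    externally computed regularised-log matrix can be passed straight in.
    Genes are z-scored across samples (ddof=1); missing or zero-variance
    signature genes are dropped with a warning.
    """
    if expr.shape[1] < 2:
        raise ValueError("at least two samples are required")
    if transform == "log2cpm":
        mat = _log2_cpm(expr.astype(float))
    elif transform is None:
        mat = expr.astype(float)
    elif callable(transform):
        mat = transform(expr)
    else:
        raise ValueError(f"unknown transform {transform!r}")

    present = [g for g in signature if g in mat.index]
    missing = sorted(set(signature) - set(present))
    if missing:
        warnings.warn(f"signature genes absent from matrix: {missing}", UserWarning, stacklevel=2)
    if not present:
        raise ValueError("no signature genes present in the expression matrix")
    sub = mat.loc[present]
    sd = sub.std(axis=1, ddof=1)
    flat = sd[sd == 0].index.tolist()
    if flat:
        warnings.warn(f"zero-variance signature genes dropped: {flat}", UserWarning, stacklevel=2)
        sub = sub.drop(index=flat)
        sd = sd.drop(index=flat)
    if sub.empty:
        raise ValueError("all signature genes have zero variance")
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
    return z.mean(axis=0).rename("reprogramming_score")
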