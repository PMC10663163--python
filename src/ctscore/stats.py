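"""Expression stratification, per-sample summaries and condition comparisons.

The analysis unit downstream of scoring is the per-sample median of the
log2 CT ratio, optionally within expression strata (deciles for RNA-seq
figures, terciles for ChIP rows). Comparisons between conditions use the
unpaired two-tailed Wilcoxon rank-sum test (gene-level distributions), the
Student t-test (per-sample medians vs a baseline day) or an ordinary
least-squares model on the medians with nuisance covariables (cage in the
colitis time course; sex and expression quantile in the human cohort),
with treatment-vs-reference contrasts and no multiplicity adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .quant import CTScoreTable

__all__ = [
    "TestResult",
    "assign_strata",
    "summarize_medians",
    "wilcoxon_rank_sum",
    "t_test",
    "fit_linear_model",
    "bh_adjust",
]


@dataclass(frozen=True)
class TestResult:
    """One statistical comparison: estimate, uncertainty and two-sided p."""

    method: str
    estimate: float
    se: float | None
    statistic: float
    df: float | None
    p_value: float
    description: str = ""

    def as_row(self) -> dict:
        return {
            "method": self.method,
            "estimate": self.estimate,
            "se": self.se,
            "statistic": self.statistic,
            "df": self.df,
            "p": self.p_value,
            "contrast": self.description,
        }


def assign_strata(rpkm_means: pd.Series, K: int = 10) -> pd.Series:
    """Rank-based quantile binning of genes by mean expression.

    Stratum 1 is the lowest-expression bin; sizes differ by at most one,
    with any remainder allocated to the upper strata so the top stratum has
    ceil(n/K) genes. Ties resolve by stable gene_id order.
    """
    n = len(rpkm_means)
    if n < K:
        raise ValueError(f"cannot split {n} genes into {K} strata")
    order = rpkm_means.sort_index().sort_values(kind="stable").index
    base, rem = divmod(n, K)
    sizes = [base + (1 if k >= K - rem else 0) for k in range(K)]
    labels = np.repeat(np.arange(1, K + 1), sizes)
    return pd.Series(labels, index=order, name="stratum").reindex(rpkm_means.index)


def summarize_medians(
    scores: CTScoreTable, strata: pd.Series | None = None
) -> pd.DataFrame:
    """Median log2 CT ratio per sample (and per stratum when given).

    Only scored entries contribute. Cells with zero scored genes are absent
    from the output. Columns: sample[, stratum], median_log2_ratio, n_genes.
    """
    df = scores.scored()
    if strata is not None:
        df = df.assign(stratum=df["gene_id"].map(strata)).dropna(subset=["stratum"])
        df["stratum"] = df["stratum"].astype(int)
        keys = ["sample", "stratum"]
    else:
        keys = ["sample"]
    out = (
        df.groupby(keys)["log2_ratio"]
        .agg(median_log2_ratio="median", n_genes="count")
        .reset_index()
    )
    return out[out["n_genes"] > 0]


def wilcoxon_rank_sum(x, y, exact_limit: int = 20) -> TestResult:
    """Two-tailed unpaired Wilcoxon (Mann-Whitney) rank-sum test.

    Exact enumeration when n_x + n_y <= ``exact_limit`` and the pooled data
    are tie-free; otherwise the normal approximation with continuity and
    tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (pooled.size <= exact_limit and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(
        method=f"wilcoxon_{method}",
        estimate=float(np.median(x) - np.median(y)),
        se=None,
        statistic=float(res.statistic),
        df=None,
        p_value=float(res.pvalue),
    )


def t_test(x, y, mode: str = "unpaired") -> TestResult:
    """Two-tailed t-test: 'unpaired' (pooled variance), 'welch' or 'paired'."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if mode == "unpaired":
        res = sps.ttest_ind(x, y, equal_var=True)
        df = x.size + y.size - 2
    elif mode == "welch":
        res = sps.ttest_ind(x, y, equal_var=False)
        df = float(res.df)
    elif mode == "paired":
        if x.size != y.size:
            raise ValueError("paired test requires equal-length groups")
        d = x - y
        if np.allclose(d.std(ddof=1) if d.size > 1 else 0.0, 0.0):
            raise ValueError("paired differences have zero variance")
        res = sps.ttest_rel(x, y)
        df = x.size - 1
    else:
        raise ValueError(f"mode must be unpaired|welch|paired, got {mode!r}")
    if df < 1:
        raise ValueError("not enough observations for df >= 1")
    if not np.isfinite(res.statistic):
        raise ValueError("zero variance in both groups")
    return TestResult(
        method=f"t_{mode}",
        estimate=float(x.mean() - y.mean()),
        se=float((x.mean() - y.mean()) / res.statistic) if res.statistic != 0 else np.nan,
        statistic=float(res.statistic),
        df=float(df),
        p_value=float(res.pvalue),
    )


def _design_matrix(
    data: pd.DataFrame,
    factor: str,
    covariables: list[str],
    reference: str | None,
) -> tuple[pd.DataFrame, list[str]]:
    """Dummy-coded design with intercept; returns (X, factor contrast columns)."""
    X = pd.DataFrame({"Intercept": np.ones(len(data))}, index=data.index)
    levels = pd.unique(data[factor].astype(str))
    ref = str(reference) if reference is not None else sorted(levels)[0]
    if ref not in set(levels):
        raise ValueError(f"reference level {ref!r} not found in factor {factor!r}")
    contrast_cols = []
    for lev in [l for l in sorted(levels) if l != ref]:
        col = f"{factor}[{lev}]"
        X[col] = (data[factor].astype(str) == lev).astype(float)
        contrast_cols.append(col)
    for cov in covariables:
        vals = data[cov]
        if pd.api.types.is_numeric_dtype(vals):
            X[cov] = vals.astype(float)
        else:
            clevels = sorted(pd.unique(vals.astype(str)))
            for lev in clevels[1:]:
                X[f"{cov}[{lev}]"] = (vals.astype(str) == lev).astype(float)
    return X, contrast_cols


def fit_linear_model(
    data: pd.DataFrame,
    response: str,
    factor: str,
    covariables: list[str] | None = None,
    reference: str | None = None,
) -> list[TestResult]:
    """OLS on per-sample medians with treatment-vs-reference contrasts.

    ``factor`` is the condition of interest (dummy-coded against
    ``reference``, default the lexicographically first level); categorical
    covariables are dummy-coded, numeric ones enter linearly. Returns one
    TestResult per non-reference level of the factor (estimate, se, t,
    residual df, two-sided p), unadjusted for multiplicity.

    Raises on a rank-deficient design, naming the aliased columns.
    """
    covariables = list(covariables or [])
    X, contrast_cols = _design_matrix(data, factor, covariables, reference)
    Xv = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(Xv)
    if rank < X.shape[1]:
        aliased = []
        for j, col in enumerate(X.columns):
            others = np.delete(Xv, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                aliased.append(col)
        raise ValueError(f"design matrix is rank-deficient; aliased columns: {aliased}")
    y = data[response].to_numpy(dtype=float)
    fit = sm.OLS(y, Xv).fit()
    results = []
    for col in contrast_cols:
        j = list(X.columns).index(col)
        results.append(
            TestResult(
                method="ols_contrast",
                estimate=float(fit.params[j]),
                se=float(fit.bse[j]),
                statistic=float(fit.tvalues[j]),
                df=float(fit.df_resid),
                p_value=float(fit.pvalues[j]),
                description=f"{col} vs reference",
            )
        )
    return results


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
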