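"""Expression normalisation, sex-bias calls, and retention-bias statistics.

Counts are normalised with median-of-ratios size factors (ratio of each
sample's counts to the per-gene geometric mean, median over genes expressed
in every sample).  Sex bias is the log2 fold change of mean normalised male
over mean normalised female expression, stabilised with a pseudocount; the
male/female/unbiased class comes from a fold-change threshold or, with
replicates, from a two-sided Welch test with Benjamini-Hochberg FDR.

The retention-bias correlation bins male-biased genes by bias strength and
rank-correlates per-bin conserved fractions with bin order; for small bin
counts the Spearman p-value is computed exactly from the full permutation
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per sample (column).

    Only genes with nonzero counts in every sample enter the median.
    """
    mat = counts.to_numpy(dtype=float)
    all_pos = (mat > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError("no gene with nonzero counts in all samples")
    logs = np.log(mat[all_pos])
    log_geo = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - log_geo, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_counts(
    counts: pd.DataFrame, factors: pd.Series | None = None
) -> pd.DataFrame:
    if factors is None:
        factors = size_factors(counts)
    return counts / factors


def fpkm(
    counts: pd.DataFrame,
    gene_lengths_bp: pd.Series,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Fragments per kilobase per million: count * 1e9 / (length * libsize)."""
    lengths = gene_lengths_bp.reindex(counts.index)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("gene lengths must be positive for all genes")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    if (library_sizes <= 0).any():
        raise ValueError("zero library size")
    return counts.mul(1e9).div(lengths, axis=0).div(library_sizes, axis=1)


@dataclass(frozen=True)
class SexBiasCall:
    gene_id: str
    log2fc: float
    bias: str  # male | female | unbiased


def sex_bias(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    factors: pd.Series | None = None,
    pseudocount: float = 0.5,
    tau: float = 1.0,
    method: str = "threshold",
    fdr: float = 0.1,
) -> pd.DataFrame:
    """Per-gene log2 fold change (male minus female) and bias class.

    ``samples`` needs columns sample, sex ('male'/'female').  With
    ``method='threshold'`` a gene is biased when |log2fc| > tau.  With
    ``method='test'`` (requires >= 2 replicates per sex) a Welch t-test on
    log2 normalised counts is BH-adjusted at the given FDR.
    """
    samples = samples.set_index("sample") if "sample" in samples.columns else samples
    sexes = samples.loc[counts.columns, "sex"]
    males = counts.columns[sexes == "male"]
    females = counts.columns[sexes == "female"]
    if len(males) == 0 or len(females) == 0:
        raise ValueError("both sexes must be present")
    norm = normalize_counts(counts, factors)
    m = norm[males].mean(axis=1)
    f = norm[females].mean(axis=1)
    log2fc = np.log2((m + pseudocount) / (f + pseudocount))

    if method == "threshold":
        significant = log2fc.abs() > tau
    elif method == "test":
        if len(males) < 2 or len(females) < 2:
            raise ValueError("method='test' needs >= 2 replicates per sex")
        logm = np.log2(norm[males] + pseudocount)
        logf = np.log2(norm[females] + pseudocount)
        t, p = stats.ttest_ind(
            logm, logf, axis=1, equal_var=False, nan_policy="omit"
        )
        p = np.where(np.isnan(p), 1.0, p)
        from statsmodels.stats.multitest import multipletests

        significant = pd.Series(
            multipletests(p, alpha=fdr, method="fdr_bh")[0], index=counts.index
        )
    else:
        raise ValueError(f"unknown method {method!r}")

    bias = pd.Series("unbiased", index=counts.index)
    bias[significant & (log2fc > 0)] = "male"
    bias[significant & (log2fc < 0)] = "female"
    return pd.DataFrame(
        {"gene_id": counts.index, "log2fc": log2fc, "bias": bias}
    ).reset_index(drop=True)


def _exact_spearman_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact Spearman p from the full permutation distribution."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    perms = np.array(list(permutations(range(n))))
    ry_perm = ry[perms]
    rx_c = rx - rx.mean()
    ry_c = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum(axis=1))
    rhos = (ry_c @ rx_c) / denom
    return float(np.mean(np.abs(rhos) >= obs - 1e-12))


def spearman_with_exact_p(
    x: np.ndarray, y: np.ndarray, exact_max_n: int = 8
) -> tuple[float, float]:
    rho, p = stats.spearmanr(x, y)
    if len(x) <= exact_max_n:
        p = _exact_spearman_p(np.asarray(x, float), np.asarray(y, float))
    return float(rho), float(p)


@dataclass
class BiasRetentionResult:
    rho: float
    p_value: float
    bin_table: pd.DataFrame
    which: str


def bias_retention_correlation(
    calls: pd.DataFrame,
    conserved: pd.Series,
    n_bins: int = 7,
    binning: str = "equal_count",
    which: str = "male",
) -> BiasRetentionResult:
    """Spearman correlation between bias-strength bin and conserved fraction.

    ``calls`` is the sex_bias output; ``conserved`` a boolean Series indexed
    by gene_id.  Genes of the requested bias class are binned by |log2fc|
    (equal-count by default, equal-width optionally); the conserved fraction
    per bin is rank-correlated with bin order.
    """
    sub = calls[calls["bias"] == which].copy()
    sub["conserved"] = conserved.reindex(sub["gene_id"]).to_numpy()
    sub = sub.dropna(subset=["conserved"])
    if len(sub) < n_bins:
        raise ValueError("fewer genes than bins")
    mag = sub["log2fc"].abs()
    if binning == "equal_count":
        sub["bin"] = pd.qcut(mag.rank(method="first"), n_bins, labels=False)
    elif binning == "equal_width":
        sub["bin"] = pd.cut(mag, n_bins, labels=False)
    else:
        raise ValueError(f"unknown binning {binning!r}")
    table = (
        sub.groupby("bin", observed=True)
        .agg(
            n=("gene_id", "size"),
            mean_abs_log2fc=("log2fc", lambda v: float(np.abs(v).mean())),
            conserved_fraction=("conserved", "mean"),
        )
        .reset_index()
    )
    table = table[table["n"] > 0]
    if len(table) < 3:
        raise ValueError("fewer than 3 non-empty bins")
    rho, p = spearman_with_exact_p(
        table["bin"].to_numpy(), table["conserved_fraction"].to_numpy()
    )
    return BiasRetentionResult(rho, p, table, which)


def expression_trend_by_age(
    male_expression: pd.Series,
    assignments: pd.Series,
    conserved: pd.Series,
) -> pd.DataFrame:
    """Mean male expression per (age class x conserved/lost) cell.

    All three inputs are indexed by gene_id; genes missing from any input
    are dropped.  Empty cells are emitted as NaN.
    """
    df = pd.DataFrame(
        {
            "expression": male_expression,
            "age_class": assignments,
            "conserved": conserved,
        }
    ).dropna()
    ages = sorted(df["age_class"].unique())
    records = []
    for age in ages:
        for flag, label in ((True, "conserved"), (False, "lost")):
            cell = df[(df["age_class"] == age) & (df["conserved"] == flag)]
            records.append(
                {
                    "age_class": age,
                    "group": label,
                    "n": len(cell),
                    "mean_expression": (
                        float(cell["expression"].mean()) if len(cell) else np.nan
                    ),
                }
            )
    return pd.DataFrame.from_records(records)
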