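"""FPKM, replicate correlation and negative-binomial exact-test DE.

The differential-expression routine is a conditional exact test on a
negative-binomial model with a single common dispersion:

1. counts are scaled to a common effective library size (the geometric mean
   of the per-sample totals) and rounded back to integers;
2. a common dispersion ``phi`` is estimated by pooled method-of-moments
   (median over well-expressed features);
3. for each feature the two group sums are compared conditionally on their
   total: every split ``(a, b)`` of the total is enumerated and the
   two-sided p-value is the probability mass of splits no more likely than
   the observed one;
4. log2 fold changes use a 0.5 prior count; BH adjustment and the
   ``padj <= 0.05, |log2FC| >= 1`` rule assign the up/down/ns flag.

With ``phi = 0`` and balanced groups the conditional distribution reduces
to Binomial(total, 1/2), which is used as an exactness check in the tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionMatrix",
    "compute_fpkm",
    "replicate_correlation",
    "bh_adjust",
    "estimate_common_dispersion",
    "exact_test_pvalue",
    "exact_test_de",
    "DE_FLAGS",
]

DE_FLAGS = ("up", "down", "ns")

#: relative tolerance when collecting splits tied with the observed one;
#: matches the convention of scipy.stats.binomtest.
_TIE_RTOL = 1e-7


@dataclass
class ExpressionMatrix:
    """Features x samples fragment counts with sample condition labels."""

    counts: pd.DataFrame
    conditions: pd.Series
    feature_lengths: pd.Series | None = None
    library_sizes: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(float)
        if (self.library_sizes <= 0).any():
            raise ValueError("library sizes must be positive")

    @property
    def feature_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.sample_ids if self.conditions[s] == condition]

    def fpkm(self) -> pd.DataFrame:
        if self.feature_lengths is None:
            raise ValueError("feature lengths required for FPKM")
        return compute_fpkm(self.counts, self.library_sizes, self.feature_lengths)


def compute_fpkm(
    counts: pd.DataFrame,
    library_sizes: pd.Series | Mapping[str, float],
    feature_lengths: pd.Series | Mapping[str, float],
) -> pd.DataFrame:
    """FPKM_{t,s} = counts_{t,s} * 1e9 / (length_t * library_size_s)."""
    lib = pd.Series(library_sizes).reindex(counts.columns).astype(float)
    lens = pd.Series(feature_lengths).reindex(counts.index).astype(float)
    if lib.isna().any() or (lib <= 0).any():
        raise ValueError("library sizes must be positive and cover all samples")
    if lens.isna().any() or (lens <= 0).any():
        raise ValueError("feature lengths must be positive and cover all features")
    denom = np.outer(lens.values, lib.values)
    return pd.DataFrame(
        counts.values * 1e9 / denom, index=counts.index, columns=counts.columns
    )


def replicate_correlation(
    fpkm: pd.DataFrame, samples: Sequence[str]
) -> tuple[pd.DataFrame, float]:
    """Pairwise squared Pearson correlation of log2(FPKM+1) between replicates.

    Returns the full symmetric R^2 table and the minimum off-diagonal value.
    Zero-variance replicates yield NaN entries with a warning.
    """
    if len(samples) < 2:
        raise ValueError("need >= 2 replicates for correlation")
    x = np.log2(fpkm[list(samples)].values + 1.0)
    sd = x.std(axis=0)
    table = pd.DataFrame(np.eye(len(samples)), index=samples, columns=samples)
    vals = []
    for (i, a), (j, b) in combinations(enumerate(samples), 2):
        if sd[i] == 0 or sd[j] == 0:
            warnings.warn(
                f"replicate {a if sd[i] == 0 else b} has zero variance; "
                "R^2 undefined for its pairs"
            )
            r2 = np.nan
        else:
            r2 = float(np.corrcoef(x[:, i], x[:, j])[0, 1] ** 2)
            vals.append(r2)
        table.loc[a, b] = table.loc[b, a] = r2
    return table, (min(vals) if vals else float("nan"))


def bh_adjust(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be 1-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def _nb_pmf(k: np.ndarray, mean: float, dispersion: float) -> np.ndarray:
    """NB pmf parameterized by mean and dispersion (variance = m + phi m^2)."""
    if mean <= 0:
        return np.where(np.asarray(k) == 0, 1.0, 0.0)
    if dispersion <= 1e-12:
        return stats.poisson.pmf(k, mean)
    size = 1.0 / dispersion
    prob = size / (size + mean)
    return stats.nbinom.pmf(k, size, prob)


def estimate_common_dispersion(
    counts: pd.DataFrame,
    conditions: pd.Series,
    min_mean: float = 5.0,
) -> float:
    """Pooled method-of-moments common NB dispersion.

    The within-condition sample variance is pooled across conditions and the
    moment identity ``E[s2] = mean + phi mean^2`` is solved jointly over all
    features with grand mean > ``min_mean``:

        phi_hat = max(0, sum_t (s2_t - mean_t) / sum_t mean_t^2).

    The joint ratio form is preferred over a median of per-feature moment
    estimates: with few replicates the per-feature estimate is so noisy (and
    truncated at zero) that its median is biased well below the true
    dispersion, which would make the exact test anticonservative.  Returns
    0.0 with a warning if no feature qualifies.
    """
    x = counts.values.astype(float)
    groups = [np.flatnonzero(conditions[counts.columns].values == c)
              for c in pd.unique(conditions[counts.columns])]
    num = np.zeros(x.shape[0])
    df_tot = 0
    for idx in groups:
        if len(idx) < 2:
            continue
        num += x[:, idx].var(axis=1, ddof=1) * (len(idx) - 1)
        df_tot += len(idx) - 1
    if df_tot == 0:
        raise ValueError("dispersion estimation needs >= 2 replicates somewhere")
    s2 = num / df_tot
    mu = x.mean(axis=1)
    keep = mu > min_mean
    if not keep.any():
        warnings.warn("no feature exceeds the mean floor; dispersion set to 0")
        return 0.0
    return float(max(0.0, (s2[keep] - mu[keep]).sum() / (mu[keep] ** 2).sum()))


def exact_test_pvalue(
    sum_a: int,
    sum_b: int,
    n_a: int,
    n_b: int,
    dispersion: float,
    enum_cap: int = 100_000,
) -> float:
    """Two-sided conditional exact NB test p-value for two group sums.

    Under H0 both sums are NB with means proportional to their replicate
    numbers and sum-dispersion ``phi/n``; the p-value sums the conditional
    probability of all splits of the total that are no more likely than the
    observed split.  Totals above ``enum_cap`` fall back to a normal
    approximation of the conditional distribution.
    """
    total = int(sum_a) + int(sum_b)
    if total == 0:
        return 1.0
    mu = total / (n_a + n_b)
    mean_a, mean_b = n_a * mu, n_b * mu
    if total <= enum_cap:
        a = np.arange(total + 1)
        pa = _nb_pmf(a, mean_a, dispersion / n_a)
        pb = _nb_pmf(total - a, mean_b, dispersion / n_b)
        prod = pa * pb
        norm = prod.sum()
        if norm <= 0 or not np.isfinite(norm):
            return 1.0
        observed = prod[sum_a]
        p = prod[prod <= observed * (1 + _TIE_RTOL)].sum() / norm
        return float(min(1.0, p))
    var_a = mean_a + (dispersion / n_a) * mean_a**2
    var_b = mean_b + (dispersion / n_b) * mean_b**2
    cond_var = var_a * var_b / (var_a + var_b)
    z = (sum_a - mean_a) / np.sqrt(cond_var)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def exact_test_de(
    counts: pd.DataFrame,
    conditions: pd.Series | Mapping[str, str],
    baseline: str = "control",
    treatment: str = "heat",
    library_sizes: pd.Series | None = None,
    dispersion: float | None = None,
    max_padj: float = 0.05,
    min_abs_lfc: float = 1.0,
    prior_count: float = 0.5,
    enum_cap: int = 100_000,
) -> pd.DataFrame:
    """NB exact-test differential expression, treatment vs baseline.

    Returns a DataFrame indexed by feature id with columns
    ``log2fc, pvalue, padj, de_flag``.
    """
    cond = pd.Series(conditions).reindex(counts.columns)
    if cond.isna().any():
        raise ValueError("every sample needs a condition label")
    a_samples = [s for s in counts.columns if cond[s] == baseline]
    b_samples = [s for s in counts.columns if cond[s] == treatment]
    if not a_samples or not b_samples:
        raise ValueError(
            f"need >= 1 replicate per condition ({baseline!r}, {treatment!r})"
        )
    if (counts.values < 0).any():
        raise ValueError("counts must be non-negative")

    lib = (
        counts.sum(axis=0).astype(float)
        if library_sizes is None
        else pd.Series(library_sizes).reindex(counts.columns).astype(float)
    )
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")
    geo = float(np.exp(np.mean(np.log(lib.values))))
    norm = np.rint(counts.values * (geo / lib.values)[None, :]).astype(np.int64)
    norm_df = pd.DataFrame(norm, index=counts.index, columns=counts.columns)

    if dispersion is None:
        dispersion = estimate_common_dispersion(norm_df, cond)

    ia = [counts.columns.get_loc(s) for s in a_samples]
    ib = [counts.columns.get_loc(s) for s in b_samples]
    sum_a = norm[:, ia].sum(axis=1)
    sum_b = norm[:, ib].sum(axis=1)
    n_a, n_b = len(ia), len(ib)

    pvals = np.ones(len(counts))
    for i, (sa, sb) in enumerate(zip(sum_a, sum_b)):
        pvals[i] = exact_test_pvalue(int(sa), int(sb), n_a, n_b, dispersion, enum_cap)

    log2fc = np.log2((sum_b / n_b + prior_count) / (sum_a / n_a + prior_count))
    log2fc = np.where((sum_a == 0) & (sum_b == 0), 0.0, log2fc)
    padj = bh_adjust(pvals)
    flags = np.where(
        (padj <= max_padj) & (np.abs(log2fc) >= min_abs_lfc),
        np.where(log2fc >= min_abs_lfc, "up", "down"),
        "ns",
    )
    return pd.DataFrame(
        {"log2fc": log2fc, "pvalue": pvals, "padj": padj, "de_flag": flags},
        index=counts.index.rename("feature_id"),
    )
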