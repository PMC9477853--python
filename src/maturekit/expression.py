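"""Normalization, expression filtering, differential testing and sample PCA.

The statistical substrate of the time-course analysis:

* median-of-ratios size factors (the DESeq-style estimator: per-sample
  median of count / per-gene geometric mean, over genes observed in every
  sample),
* a CPM >= threshold "expressed gene" filter requiring all replicates of at
  least one condition to pass,
* a negative-binomial exact test for two-group contrasts with a common
  method-of-moments dispersion, and
* sample-level PCA on log, per-gene standardized normalized expression.

The exact test conditions on the total count of each gene: if the two group
sums are ``s_a`` and ``s_b`` and each group sum is NB with size ``n_g / phi``
(the sum of ``n_g`` i.i.d. NB(mu, phi) variables), then the conditional
distribution of ``s_a`` given ``s_a + s_b`` is free of ``mu``, and the
two-sided p-value is the total conditional probability of outcomes no more
likely than the observed one. As ``phi -> 0`` this reduces to the binomial
exact test of the Poisson case.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import norm as _normal
from sklearn.decomposition import PCA

from .containers import CountMatrix, NormalizedMatrix, as_counts_frame
from .errors import DegenerateInputError, InvalidArgumentError

DEFAULT_FOLD_THRESHOLD = 2.0
DEFAULT_P_THRESHOLD = 1e-3
DEFAULT_LFC_PSEUDOCOUNT = 0.5


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    Reference genes are those with a nonzero count in every sample (so the
    per-gene geometric mean is positive). For each sample the factor is the
    median over reference genes of count / geometric mean.

    Raises
    ------
    DegenerateInputError
        If no gene is observed in all samples.
    """
    frame = as_counts_frame(counts)
    arr = frame.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise DegenerateInputError(
            "no reference genes: every gene has a zero count in some sample"
        )
    logs = np.log(arr[positive])
    log_geomean = logs.mean(axis=1)
    ratios = np.exp(logs - log_geomean[:, None])
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=frame.columns, name="size_factor")


def normalize(counts: CountMatrix) -> NormalizedMatrix:
    """Divide each sample by its median-of-ratios size factor."""
    factors = size_factors(counts)
    values = counts.counts.astype(float).div(factors, axis=1)
    return NormalizedMatrix(values, factors, counts.metadata.copy(), counts.timepoint_order)


# ---------------------------------------------------------------------------
# expressed-gene filter
# ---------------------------------------------------------------------------

def cpm(counts: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    """Counts per million per sample."""
    frame = as_counts_frame(counts)
    totals = frame.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise DegenerateInputError(f"samples with zero total counts: {bad}")
    return frame * 1e6 / totals


def expressed_genes(
    counts: CountMatrix,
    cpm_threshold: float = 5.0,
    scope: Iterable[str] | None = None,
) -> set[str]:
    """Genes with CPM >= threshold in *all* replicates of at least one condition.

    ``scope`` restricts which conditions are eligible; default is every
    condition present in the matrix.
    """
    conditions = list(scope) if scope is not None else counts.conditions()
    if not conditions:
        raise InvalidArgumentError("empty condition scope")
    cpm_values = cpm(counts)
    expressed: set[str] = set()
    meta = counts.metadata
    for cond in conditions:
        cond_samples = [s for s in counts.samples if meta.loc[s, "condition"] == cond]
        # a "condition" here is one (condition tag, timepoint) group, so the
        # all-replicates rule applies within each timepoint of each series
        for tp in counts.timepoint_order:
            group = [s for s in cond_samples if meta.loc[s, "timepoint"] == tp]
            if not group:
                continue
            ok = (cpm_values[group] >= cpm_threshold).all(axis=1)
            expressed.update(cpm_values.index[ok])
    return expressed


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def estimate_common_dispersion(
    norm_values: pd.DataFrame, groups: Sequence[Sequence[str]]
) -> float:
    """Common NB dispersion by method of moments on normalized counts.

    For every gene the within-group sample variance is pooled across groups
    (groups with fewer than 2 samples contribute nothing); the per-gene
    moment estimate ``(var - mean) / mean^2`` is then averaged over genes
    with positive mean. Clipped below at 1e-8.
    """
    usable = [list(g) for g in groups if len(g) >= 2]
    if not usable:
        raise InvalidArgumentError(
            "dispersion estimation needs at least one group with >= 2 samples; "
            "pass an explicit dispersion otherwise"
        )
    n_total = sum(len(g) for g in usable)
    pooled_num = np.zeros(len(norm_values))
    mean_sum = np.zeros(len(norm_values))
    df = 0
    for g in usable:
        sub = norm_values[g].to_numpy(dtype=float)
        pooled_num += sub.var(axis=1, ddof=1) * (len(g) - 1)
        mean_sum += sub.mean(axis=1) * len(g)
        df += len(g) - 1
    pooled_var = pooled_num / df
    grand_mean = mean_sum / n_total
    ok = grand_mean > 0
    if not ok.any():
        raise DegenerateInputError("all genes have zero mean; cannot estimate dispersion")
    phi_g = (pooled_var[ok] - grand_mean[ok]) / grand_mean[ok] ** 2
    return float(max(phi_g.mean(), 1e-8))


def _conditional_exact_pvalue(a: int, s: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided exact p-value for group-A sum ``a`` given total ``s``.

    Sums conditional probabilities of all outcomes with probability at most
    that of the observed outcome (the same two-sided convention as the
    binomial exact test).
    """
    if s == 0:
        return 1.0
    if s > 50_000:
        # the conditional law is beta-binomial(s, n_a/phi, n_b/phi); at this
        # scale a normal approximation with continuity correction is ample
        r_a, r_b = (n_a, n_b) if phi < 1e-8 else (n_a / phi, n_b / phi)
        mean = s * r_a / (r_a + r_b)
        var = s * r_a * r_b / (r_a + r_b) ** 2
        if phi >= 1e-8:
            var *= (r_a + r_b + s) / (r_a + r_b + 1)
        z = (abs(a - mean) - 0.5) / np.sqrt(var)
        return float(min(1.0, 2 * _normal.sf(max(z, 0.0))))
    k = np.arange(s + 1)
    if phi < 1e-8:
        # Poisson limit: conditional law is Binomial(s, n_a / (n_a + n_b))
        p_a = n_a / (n_a + n_b)
        logw = (
            gammaln(s + 1)
            - gammaln(k + 1)
            - gammaln(s - k + 1)
            + k * np.log(p_a)
            + (s - k) * np.log1p(-p_a)
        )
    else:
        r_a, r_b = n_a / phi, n_b / phi
        logw = (
            gammaln(k + r_a)
            - gammaln(k + 1)
            + gammaln(s - k + r_b)
            - gammaln(s - k + 1)
        )
    logw = logw - logsumexp(logw)
    w = np.exp(logw)
    w_obs = w[a]
    return float(min(1.0, w[w <= w_obs * (1 + 1e-12)].sum()))


@dataclass
class DEResult:
    """Per-gene differential expression result for one two-group contrast."""

    table: pd.DataFrame  # columns: log2_fc, p_value, mean_a, mean_b, call
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]
    dispersion: float
    fold_threshold: float
    p_threshold: float

    def __getitem__(self, col: str) -> pd.Series:
        return self.table[col]

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def called(self, direction: str) -> pd.Index:
        return self.table.index[self.table["call"] == direction]


def de_test(
    counts: CountMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    genes: Iterable[str] | None = None,
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    pseudocount: float = DEFAULT_LFC_PSEUDOCOUNT,
    dispersion: float | None = None,
) -> DEResult:
    """NB exact test of group B vs group A (log2 fold change is B over A).

    Counts are normalized by median-of-ratios factors computed on the two
    groups, group sums of the normalized counts are rounded to integers and
    compared by the conditional NB exact test at a common moment-estimated
    dispersion. Calls: ``up`` if lfc >= log2(fold_threshold) and
    p < p_threshold, ``down`` symmetrically, else ``stable``. Genes with zero
    counts in both groups are ``stable`` with p = 1.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise InvalidArgumentError("both groups must contain at least one sample")
    sub = counts.subset_samples(group_a + group_b)
    if genes is not None:
        gene_list = [g for g in genes if g in sub.counts.index]
        missing = set(genes) - set(gene_list)
        if missing:
            raise InvalidArgumentError(f"genes not in matrix: {sorted(missing)[:5]}")
        sub = CountMatrix(sub.counts.loc[gene_list], sub.metadata, sub.timepoint_order)
    if sub.counts[group_a].to_numpy().sum() == 0 or sub.counts[group_b].to_numpy().sum() == 0:
        raise DegenerateInputError("one group has zero total counts across all genes")

    factors = size_factors(sub.counts)
    norm_values = sub.counts.astype(float).div(factors, axis=1)

    if dispersion is None:
        dispersion = estimate_common_dispersion(norm_values, [group_a, group_b])

    mean_a = norm_values[group_a].mean(axis=1)
    mean_b = norm_values[group_b].mean(axis=1)
    sum_a = np.rint(norm_values[group_a].sum(axis=1).to_numpy()).astype(np.int64)
    sum_b = np.rint(norm_values[group_b].sum(axis=1).to_numpy()).astype(np.int64)

    log2_fc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))
    n_a, n_b = len(group_a), len(group_b)
    p_values = np.ones(len(norm_values))
    for i, (sa, sb) in enumerate(zip(sum_a, sum_b)):
        total = int(sa + sb)
        if total == 0:
            continue
        p_values[i] = _conditional_exact_pvalue(int(sa), total, n_a, n_b, dispersion)

    lfc_cut = np.log2(fold_threshold)
    call = np.where(
        (p_values < p_threshold) & (log2_fc >= lfc_cut),
        "up",
        np.where((p_values < p_threshold) & (log2_fc <= -lfc_cut), "down", "stable"),
    )
    zero_both = (sum_a + sum_b) == 0
    call = np.where(zero_both, "stable", call)
    table = pd.DataFrame(
        {
            "log2_fc": np.where(zero_both, 0.0, log2_fc),
            "p_value": p_values,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "call": call,
        },
        index=norm_values.index,
    )
    return DEResult(
        table,
        tuple(group_a),
        tuple(group_b),
        float(dispersion),
        fold_threshold,
        p_threshold,
    )


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    scores: pd.DataFrame  # samples x components
    percent_variance: np.ndarray

    def __post_init__(self) -> None:
        pv = np.asarray(self.percent_variance, dtype=float)
        if (pv < -1e-9).any() or pv.sum() > 100 + 1e-6:
            raise InvalidArgumentError("percent variance must be in [0, 100] and sum <= 100")


def pca_samples(
    norm: NormalizedMatrix | pd.DataFrame,
    min_reads: float = 10.0,
    n_components: int | None = None,
) -> PcaResult:
    """Sample-level PCA of log normalized expression.

    Genes are kept if they exceed ``min_reads`` normalized units in at least
    one sample (strict inequality), log2(x+1)-transformed, then per-gene
    mean-centered and scaled to unit variance before PCA of the samples.
    """
    values = norm.values if isinstance(norm, NormalizedMatrix) else norm
    n_samples = values.shape[1]
    if n_samples < 2:
        raise InvalidArgumentError("PCA needs at least 2 samples")
    if n_components is None:
        n_components = min(n_samples, 10)
    if n_components > n_samples:
        raise InvalidArgumentError(
            f"requested {n_components} components for {n_samples} samples"
        )
    keep = (values > min_reads).any(axis=1)
    filtered = values.loc[keep]
    if filtered.empty:
        raise DegenerateInputError("no genes pass the PCA expression filter")
    x = np.log2(filtered.to_numpy(dtype=float) + 1.0)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    nonconst = sd[:, 0] > 0
    x = (x[nonconst] - mean[nonconst]) / sd[nonconst]
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(x.T)
    scores = pd.DataFrame(
        coords,
        index=values.columns,
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    return PcaResult(scores, pca.explained_variance_ratio_ * 100.0)
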