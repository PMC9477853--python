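"""Two-stage reference-based NNLS deconvolution of bulk expression.

Pipeline (mirroring how a labeled single-nucleus reference is turned into
class profiles and fit to a bulk sample):

1. balance cluster sizes by downsampling every cluster to the size of the
   smallest one (seeded, without replacement),
2. depth-normalize cells to the median depth, log1p, and average within
   clusters to get mean-log cluster profiles,
3. merge clusters into transcriptional classes by average-linkage
   hierarchical grouping on correlation distance over the top-variance
   genes, keeping classes whose mean within-class correlation clears a
   threshold,
4. fit the bulk profile as a non-negative linear combination of class
   profiles (NNLS), reporting weights and percent proportions,
5. repeat steps 1-4 restricted to cholinergic-flagged clusters
   (the second stage).

The fit is performed in log space on the mean-log profiles by default;
``linear_space=True`` exponentiates profiles (expm1) before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import nnls
from scipy.spatial.distance import squareform

from .containers import CellMatrix
from .errors import DegenerateInputError, InvalidArgumentError

DEFAULT_CORR_THRESHOLD = 0.8
DEFAULT_N_TOP_VAR = 1000


# ---------------------------------------------------------------------------
# reference preparation
# ---------------------------------------------------------------------------

def downsample_clusters(cells: CellMatrix, seed: int) -> CellMatrix:
    """Sample every cluster down to the smallest cluster's size.

    Selection is seeded and without replacement; surviving cells keep their
    original order, so equally sized input passes through unchanged.
    """
    sizes = cells.cluster_sizes()
    if (sizes == 0).any():
        raise InvalidArgumentError("empty cluster in cell matrix")
    target = int(sizes.min())
    rng = np.random.default_rng(seed)
    keep_positions: list[int] = []
    positions = np.arange(len(cells.counts))
    labels = cells.clusters.to_numpy()
    for cluster in cells.cluster_ids:
        pos = positions[labels == cluster]
        chosen = rng.choice(pos, size=target, replace=False)
        keep_positions.extend(sorted(chosen.tolist()))
    keep_positions.sort()
    keep_index = cells.counts.index[keep_positions]
    return CellMatrix(
        cells.counts.loc[keep_index],
        cells.clusters.loc[keep_index],
        cells.cluster_flags,
    )


def _lognorm_cells(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-cell depth scaling to the median depth, then log1p."""
    depths = counts.sum(axis=1)
    if (depths <= 0).any():
        raise DegenerateInputError("cells with zero total counts")
    scaled = counts.to_numpy(dtype=float) * (float(depths.median()) / depths.to_numpy())[:, None]
    return pd.DataFrame(np.log1p(scaled), index=counts.index, columns=counts.columns)


@dataclass
class ClusterProfiles:
    """Mean log expression per cluster from a balanced cell matrix."""

    profiles: pd.DataFrame  # cluster x gene
    cells_used: int


def cluster_profiles(balanced: CellMatrix) -> ClusterProfiles:
    """Mean over cells of log1p(depth-normalized counts), per cluster."""
    sizes = balanced.cluster_sizes()
    if sizes.nunique() != 1:
        raise InvalidArgumentError(
            "cluster sizes are unbalanced; run downsample_clusters first"
        )
    logs = _lognorm_cells(balanced.counts)
    prof = logs.groupby(balanced.clusters).mean()
    prof.index.name = "cluster"
    return ClusterProfiles(prof.sort_index(), int(sizes.iloc[0]))


@dataclass
class ClassModel:
    """Cluster-to-class assignment with per-class mean profiles."""

    assignment: pd.Series  # cluster -> class label
    class_profiles: pd.DataFrame  # class x gene (mean of member cluster profiles)
    merge_genes: pd.Index  # the top-variance gene subset used for merging
    corr_threshold: float

    @property
    def classes(self) -> list[str]:
        return list(self.class_profiles.index)


def merge_clusters(
    profiles: ClusterProfiles,
    n_top_var: int = DEFAULT_N_TOP_VAR,
    corr_threshold: float = DEFAULT_CORR_THRESHOLD,
) -> ClassModel:
    """Group highly correlated clusters into transcriptional classes.

    Pearson correlations between cluster profiles are computed on the
    ``n_top_var`` highest-variance genes (variance across cluster
    profiles). Average-linkage hierarchical clustering on distance 1 - r is
    cut at the coarsest level (fewest classes) at which every multi-member
    class keeps a mean within-class pairwise correlation >= the threshold.
    """
    if not -1 < corr_threshold <= 1:
        raise InvalidArgumentError("corr_threshold must lie in (-1, 1]")
    prof = profiles.profiles
    n_clusters = prof.shape[0]
    if n_clusters < 1:
        raise InvalidArgumentError("no clusters to merge")
    n_top_var = min(n_top_var, prof.shape[1])
    variances = prof.var(axis=0, ddof=1) if n_clusters > 1 else prof.iloc[0] * 0
    top_genes = variances.sort_values(ascending=False, kind="stable").index[:n_top_var]
    if n_clusters == 1:
        assignment = pd.Series(["class1"], index=prof.index, name="class")
        return ClassModel(assignment, prof.set_axis(["class1"]), top_genes, corr_threshold)

    sub = prof[top_genes]
    corr = np.corrcoef(sub.to_numpy())
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")

    def _valid(labels: np.ndarray) -> bool:
        for lab in np.unique(labels):
            members = np.flatnonzero(labels == lab)
            if len(members) < 2:
                continue
            pair_r = corr[np.ix_(members, members)]
            mean_r = (pair_r.sum() - len(members)) / (len(members) * (len(members) - 1))
            if mean_r < corr_threshold:
                return False
        return True

    chosen = None
    for k in range(1, n_clusters + 1):
        labels = fcluster(z, t=k, criterion="maxclust")
        if _valid(labels):
            chosen = labels
            break
    assert chosen is not None  # k = n_clusters (all singletons) always passes
    # name classes in order of first cluster appearance for determinism
    remap: dict[int, str] = {}
    for lab in chosen:
        if lab not in remap:
            remap[lab] = f"class{len(remap) + 1}"
    assignment = pd.Series([remap[lab] for lab in chosen], index=prof.index, name="class")
    class_prof = prof.groupby(assignment).mean()
    class_prof = class_prof.loc[sorted(class_prof.index, key=lambda c: int(c.removeprefix("class")))]
    return ClassModel(assignment, class_prof, top_genes, corr_threshold)


# ---------------------------------------------------------------------------
# NNLS fit
# ---------------------------------------------------------------------------

@dataclass
class DeconvolutionResult:
    weights: pd.Series  # raw NNLS weights, >= 0
    proportions: pd.Series  # percent, sums to 100 unless degenerate
    residual: float
    stage: str
    degenerate: bool = False


def nnls_fit(
    bulk: pd.Series,
    model: ClassModel,
    stage: str = "all_classes",
    linear_space: bool = False,
    restrict_to_merge_genes: bool = False,
) -> DeconvolutionResult:
    """Non-negative least-squares fit of a bulk profile to class profiles.

    Solves ``argmin || b - P^T w ||_2, w >= 0`` over the inner join of bulk
    and reference genes. Proportions are 100 * w / sum(w); an all-zero
    solution is flagged degenerate and reported as zero proportions.
    """
    prof = model.class_profiles
    genes = prof.columns.intersection(bulk.index)
    if restrict_to_merge_genes:
        genes = genes.intersection(model.merge_genes)
    if genes.empty:
        raise InvalidArgumentError("no shared genes between bulk and reference")
    a = prof[genes].to_numpy(dtype=float).T  # gene x class
    b = bulk.loc[genes].to_numpy(dtype=float)
    if linear_space:
        a = np.expm1(a)
        b = np.expm1(b) if (b >= 0).all() else b
    w, residual = nnls(a, b)
    weights = pd.Series(w, index=prof.index, name="weight")
    total = weights.sum()
    degenerate = total <= 0
    proportions = (
        pd.Series(0.0, index=prof.index, name="proportion_pct")
        if degenerate
        else (100.0 * weights / total).rename("proportion_pct")
    )
    return DeconvolutionResult(weights, proportions, float(residual), stage, degenerate)


def build_class_model(
    cells: CellMatrix,
    seed: int,
    n_top_var: int = DEFAULT_N_TOP_VAR,
    corr_threshold: float = DEFAULT_CORR_THRESHOLD,
) -> ClassModel:
    """downsample -> cluster profiles -> merge, as one step."""
    balanced = downsample_clusters(cells, seed)
    profiles = cluster_profiles(balanced)
    return merge_clusters(profiles, n_top_var=n_top_var, corr_threshold=corr_threshold)


def two_stage_deconvolve(
    bulk: pd.Series,
    cells: CellMatrix,
    seed: int,
    n_top_var: int = DEFAULT_N_TOP_VAR,
    corr_threshold: float = DEFAULT_CORR_THRESHOLD,
    linear_space: bool = False,
) -> tuple[DeconvolutionResult, DeconvolutionResult, ClassModel, ClassModel]:
    """Full two-stage deconvolution.

    Stage 1 runs the full pipeline on all clusters; stage 2 repeats it
    restricted to cholinergic-flagged clusters (top-variance genes are
    recomputed within the stage). Returns both results and both class
    models.

    Raises
    ------
    InvalidArgumentError
        If no cluster carries the cholinergic flag (stage 1 result is not
        recoverable from the exception; call the stages separately if a
        partial result is needed).
    """
    model1 = build_class_model(cells, seed, n_top_var, corr_threshold)
    stage1 = nnls_fit(bulk, model1, stage="all_classes", linear_space=linear_space)
    chol = cells.cholinergic_clusters()
    if not chol:
        raise InvalidArgumentError("no cholinergic clusters; cannot run stage 2")
    chol_cells = cells.subset_clusters(chol)
    model2 = build_class_model(chol_cells, seed, n_top_var, corr_threshold)
    stage2 = nnls_fit(bulk, model2, stage="cholinergic_only", linear_space=linear_space)
    return stage1, stage2, model1, model2
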