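"""In-memory containers for count data.

Conventions used throughout the package:

* Bulk count matrices are gene x sample ``pandas.DataFrame`` objects with
  unique string indices, wrapped with per-sample metadata in
  :class:`CountMatrix`.
* Single-cell matrices are cell x gene frames wrapped in :class:`CellMatrix`
  together with a per-cell cluster label and per-cluster annotation flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, InvalidConfigError

REQUIRED_METADATA_COLUMNS = ("timepoint", "replicate", "condition")


@dataclass
class CountMatrix:
    """Gene x sample integer counts plus ordered sample metadata.

    Parameters
    ----------
    counts
        Gene x sample frame of non-negative integers. Index = gene IDs,
        columns = sample IDs, both unique.
    metadata
        One row per sample (index = sample ID) with columns ``timepoint``,
        ``replicate`` and ``condition``.
    timepoint_order
        The ordered vocabulary of timepoint labels. Defaults to order of
        first appearance in ``metadata``.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame
    timepoint_order: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise InvalidConfigError("duplicate gene IDs in count matrix")
        if self.counts.columns.duplicated().any():
            raise InvalidConfigError("duplicate sample IDs in count matrix")
        if (self.counts.to_numpy() < 0).any():
            raise InvalidConfigError("negative counts in count matrix")
        missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in self.metadata.columns]
        if missing:
            raise InvalidConfigError(f"metadata missing columns: {missing}")
        unknown = set(self.counts.columns) - set(self.metadata.index)
        if unknown:
            raise InvalidConfigError(f"samples without metadata: {sorted(unknown)}")
        if not self.timepoint_order:
            seen: list[str] = []
            for tp in self.metadata.loc[list(self.counts.columns), "timepoint"]:
                if tp not in seen:
                    seen.append(tp)
            self.timepoint_order = tuple(seen)
        bad_tp = set(self.metadata["timepoint"]) - set(self.timepoint_order)
        if bad_tp:
            raise InvalidConfigError(f"timepoints outside declared order: {sorted(bad_tp)}")

    # -- convenience accessors -------------------------------------------------

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def samples_for(self, timepoint: str | None = None, condition: str | None = None) -> list[str]:
        """Sample IDs matching the given timepoint and/or condition."""
        meta = self.metadata.loc[list(self.counts.columns)]
        mask = pd.Series(True, index=meta.index)
        if timepoint is not None:
            mask &= meta["timepoint"] == timepoint
        if condition is not None:
            mask &= meta["condition"] == condition
        return list(meta.index[mask])

    def conditions(self) -> list[str]:
        seen: list[str] = []
        for c in self.metadata.loc[list(self.counts.columns), "condition"]:
            if c not in seen:
                seen.append(c)
        return seen

    def transitions(self, condition: str | None = None) -> list[tuple[str, str]]:
        """Consecutive timepoint pairs present in the matrix (optionally per condition)."""
        present = [
            tp
            for tp in self.timepoint_order
            if self.samples_for(timepoint=tp, condition=condition)
        ]
        return list(zip(present[:-1], present[1:]))

    def subset_samples(self, samples: list[str]) -> "CountMatrix":
        missing = [s for s in samples if s not in self.counts.columns]
        if missing:
            raise InvalidArgumentError(f"unknown samples: {missing}")
        return CountMatrix(
            self.counts[samples].copy(),
            self.metadata.loc[samples].copy(),
            self.timepoint_order,
        )


@dataclass
class NormalizedMatrix:
    """Median-of-ratios normalized expression with the size factors attached.

    Invariant: ``values * size_factors == counts`` column-wise.
    """

    values: pd.DataFrame
    size_factors: pd.Series
    metadata: pd.DataFrame
    timepoint_order: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if (self.size_factors <= 0).any():
            raise InvalidConfigError("size factors must be positive")

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def samples_for(self, timepoint: str | None = None, condition: str | None = None) -> list[str]:
        meta = self.metadata.loc[list(self.values.columns)]
        mask = pd.Series(True, index=meta.index)
        if timepoint is not None:
            mask &= meta["timepoint"] == timepoint
        if condition is not None:
            mask &= meta["condition"] == condition
        return list(meta.index[mask])


@dataclass
class CellMatrix:
    """Cell x gene counts with cluster labels and per-cluster flags.

    ``cluster_flags`` carries boolean annotations per cluster; the
    deconvolution stage looks up the ``cholinergic`` flag.
    """

    counts: pd.DataFrame
    clusters: pd.Series
    cluster_flags: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise InvalidConfigError("duplicate cell IDs")
        unlabeled = set(self.counts.index) - set(self.clusters.index)
        if unlabeled:
            raise InvalidConfigError(f"cells without cluster label: {sorted(unlabeled)[:5]}")
        if (self.counts.to_numpy() < 0).any():
            raise InvalidConfigError("negative counts in cell matrix")
        self.clusters = self.clusters.loc[self.counts.index]

    @property
    def cluster_ids(self) -> list[str]:
        return sorted(self.clusters.unique())

    def cluster_sizes(self) -> pd.Series:
        return self.clusters.value_counts().sort_index()

    def cholinergic_clusters(self) -> list[str]:
        if self.cluster_flags is None or "cholinergic" not in self.cluster_flags.columns:
            raise InvalidArgumentError("cell matrix carries no cholinergic cluster flags")
        flags = self.cluster_flags["cholinergic"].astype(bool)
        return sorted(flags.index[flags])

    def subset_clusters(self, keep: list[str]) -> "CellMatrix":
        mask = self.clusters.isin(keep)
        flags = None
        if self.cluster_flags is not None:
            flags = self.cluster_flags.loc[[c for c in self.cluster_flags.index if c in keep]]
        return CellMatrix(self.counts.loc[mask.to_numpy()], self.clusters[mask], flags)


def library_sizes(counts: pd.DataFrame) -> pd.Series:
    """Total counts per sample."""
    return counts.sum(axis=0)


def as_counts_frame(counts: "CountMatrix | pd.DataFrame") -> pd.DataFrame:
    if isinstance(counts, CountMatrix):
        return counts.counts
    return counts


def check_integer_counts(frame: pd.DataFrame) -> None:
    arr = frame.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise InvalidConfigError("counts must be numeric")
    if np.any(arr != np.floor(arr)):
        raise InvalidConfigError("counts must be integers")
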