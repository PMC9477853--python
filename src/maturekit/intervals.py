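"""Interval-based chromatin (peak set) operations.

Peak sets are pandas frames with columns ``chrom``, ``start``, ``end``,
``name``, ``score`` in BED convention: 0-based, half-open. All operations
are order-invariant and return coordinate-sorted output. Overlap means at
least one shared base; subtraction removes whole features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidArgumentError
from .track import ScoreTrack

PEAK_COLUMNS = ("chrom", "start", "end", "name", "score")


def sort_peaks(peaks: pd.DataFrame) -> pd.DataFrame:
    return peaks.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)


def _merged_by_chrom(peaks: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Union of intervals per chromosome as sorted disjoint (starts, ends)."""
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, group in peaks.groupby("chrom"):
        ivals = group[["start", "end"]].sort_values("start").to_numpy()
        starts, ends = [], []
        for s, e in ivals:
            if ends and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        merged[chrom] = (np.asarray(starts), np.asarray(ends))
    return merged


def overlaps_any(peaks: pd.DataFrame, other: pd.DataFrame) -> np.ndarray:
    """Boolean mask: does each peak share >= 1 base with any interval in other?"""
    merged = _merged_by_chrom(other)
    out = np.zeros(len(peaks), dtype=bool)
    for i, row in enumerate(peaks.itertuples(index=False)):
        entry = merged.get(row.chrom)
        if entry is None:
            continue
        starts, ends = entry
        idx = np.searchsorted(starts, row.end, side="left")
        out[i] = idx > 0 and ends[idx - 1] > row.start
    return out


def top_peaks(peaks: pd.DataFrame, n: int) -> pd.DataFrame:
    """The n highest-score peaks; ties broken by (chrom, start) ascending."""
    if n < 1:
        raise InvalidArgumentError("n must be >= 1")
    if n >= len(peaks):
        if n > len(peaks):
            warnings.warn(
                f"requested top {n} of {len(peaks)} peaks; returning all",
                stacklevel=2,
            )
        return sort_peaks(peaks)
    ranked = peaks.sort_values(
        ["score", "chrom", "start"], ascending=[False, True, True], kind="stable"
    ).head(n)
    return sort_peaks(ranked)


def exclude_regions(
    peaks: pd.DataFrame, blacklists: Sequence[pd.DataFrame]
) -> pd.DataFrame:
    """Drop every peak overlapping (>= 1 bp) any blacklist interval."""
    peaks = sort_peaks(peaks)
    if not blacklists:
        return peaks
    combined = pd.concat([b[["chrom", "start", "end"]] for b in blacklists], ignore_index=True)
    if combined.empty:
        return peaks
    return peaks[~overlaps_any(peaks, combined)].reset_index(drop=True)


@dataclass
class GainLossResult:
    gained: pd.DataFrame
    lost: pd.DataFrame
    pct_gained: float
    pct_lost: float


def gain_loss(earlier: pd.DataFrame, later: pd.DataFrame, n: int = 100_000) -> GainLossResult:
    """Peaks gained/lost between consecutive timepoints by whole-feature subtraction.

    gained = top-n of the later set minus anything overlapping *any*
    earlier peak; lost = top-n of the earlier set minus anything overlapping
    any later peak. Percents are relative to the top-n set sizes.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        top_later = top_peaks(later, n)
        top_earlier = top_peaks(earlier, n)
    gained = top_later[~overlaps_any(top_later, earlier)].reset_index(drop=True)
    lost = top_earlier[~overlaps_any(top_earlier, later)].reset_index(drop=True)
    pct_gained = 100.0 * len(gained) / len(top_later) if len(top_later) else 0.0
    pct_lost = 100.0 * len(lost) / len(top_earlier) if len(top_earlier) else 0.0
    return GainLossResult(gained, lost, pct_gained, pct_lost)


def classify_tss_proximity(
    peaks: pd.DataFrame,
    tss: pd.DataFrame,
    cutoff_bp: int = 2000,
) -> pd.DataFrame:
    """Label each peak proximal/distal by midpoint distance to the nearest TSS.

    A peak is proximal iff the distance from its midpoint to the nearest
    TSS is <= ``cutoff_bp`` (so exactly 2000 bp counts as proximal at the
    default cutoff). Peaks on chromosomes without any TSS are classified
    distal with a warning; their distance is reported as +inf.
    """
    if tss.empty:
        raise InvalidArgumentError("TSS annotation is empty")
    peaks = sort_peaks(peaks)
    tss_by_chrom = {c: np.sort(g["tss"].to_numpy()) for c, g in tss.groupby("chrom")}
    midpoints = ((peaks["start"] + peaks["end"]) // 2).to_numpy()
    distances = np.full(len(peaks), np.inf)
    missing_chroms = set()
    for chrom, group_idx in peaks.groupby("chrom").indices.items():
        pos = tss_by_chrom.get(chrom)
        if pos is None:
            missing_chroms.add(chrom)
            continue
        mids = midpoints[group_idx]
        right = np.searchsorted(pos, mids)
        d = np.full(len(mids), np.inf)
        has_right = right < pos.size
        d[has_right] = np.abs(pos[right[has_right]] - mids[has_right])
        has_left = right > 0
        d[has_left] = np.minimum(d[has_left], np.abs(pos[right[has_left] - 1] - mids[has_left]))
        distances[group_idx] = d
    if missing_chroms:
        warnings.warn(
            f"no TSS on chromosomes {sorted(missing_chroms)}; peaks there classified distal",
            stacklevel=2,
        )
    out = peaks.copy()
    out["tss_distance"] = distances
    out["proximal"] = distances <= cutoff_bp
    return out


def proximity_summary(classified: pd.DataFrame) -> dict:
    n = len(classified)
    n_prox = int(classified["proximal"].sum())
    return {
        "n_peaks": n,
        "n_proximal": n_prox,
        "n_distal": n - n_prox,
        "pct_proximal": 100.0 * n_prox / n if n else float("nan"),
        "pct_distal": 100.0 * (n - n_prox) / n if n else float("nan"),
    }


def peaks_near_genes(
    peaks: pd.DataFrame,
    genes: Sequence[str],
    tss: pd.DataFrame,
    window_bp: int = 50_000,
) -> pd.Series:
    """Per-gene count of peaks with midpoint within +/- window_bp of the TSS."""
    tss_indexed = tss.set_index("gene_id")
    missing = [g for g in genes if g not in tss_indexed.index]
    if missing:
        raise InvalidArgumentError(f"genes missing from TSS annotation: {missing}")
    mids_by_chrom = {
        c: np.sort(((g["start"] + g["end"]) // 2).to_numpy())
        for c, g in peaks.groupby("chrom")
    }
    counts = {}
    for gene in genes:
        row = tss_indexed.loc[gene]
        mids = mids_by_chrom.get(row["chrom"])
        if mids is None:
            counts[gene] = 0
            continue
        lo = np.searchsorted(mids, row["tss"] - window_bp, side="left")
        hi = np.searchsorted(mids, row["tss"] + window_bp, side="right")
        counts[gene] = int(hi - lo)
    return pd.Series(counts, name="n_peaks")


@dataclass
class PeakCountComparison:
    mean_difference: float
    t_statistic: float
    p_value: float


def compare_peak_counts(
    gained_counts: Sequence[int], lost_counts: Sequence[int]
) -> PeakCountComparison:
    """Welch two-sample two-tailed t-test between gained and lost counts."""
    gained = np.asarray(gained_counts, dtype=float)
    lost = np.asarray(lost_counts, dtype=float)
    if len(gained) != len(lost):
        raise InvalidArgumentError("count vectors must cover the same genes")
    if len(gained) < 2:
        raise InvalidArgumentError("need at least 2 genes")
    t, p = stats.ttest_ind(gained, lost, equal_var=False)
    if np.isnan(t):  # both vectors constant and equal
        t, p = 0.0, 1.0
    return PeakCountComparison(float(gained.mean() - lost.mean()), float(t), float(p))


@dataclass
class ConservationResult:
    foreground_mean: float
    background_mean: float
    region_means: pd.Series


def region_conservation(
    regions: pd.DataFrame,
    track: ScoreTrack,
    chrom_sizes: Mapping[str, int],
    background_n: int = 49_896,
    background_len: int = 2000,
    seed: int = 0,
) -> ConservationResult:
    """Mean per-base score over regions vs seeded random same-genome background.

    Foreground: mean over regions of each region's per-base mean score.
    Background: the same statistic over ``background_n`` random intervals of
    ``background_len`` bp drawn uniformly from chromosomes that can hold them.
    """
    if regions.empty:
        raise InvalidArgumentError("empty region set")
    fg = pd.Series(
        [
            track.interval_mean(r.chrom, r.start, r.end)
            for r in regions.itertuples(index=False)
        ],
        index=regions["name"] if "name" in regions.columns else None,
        name="region_mean",
    )
    eligible = [(c, s) for c, s in chrom_sizes.items() if s >= background_len]
    if not eligible:
        raise InvalidArgumentError("no chromosome can hold a background interval")
    rng = np.random.default_rng(seed)
    names = [c for c, _ in eligible]
    weights = np.array([s - background_len + 1 for _, s in eligible], dtype=float)
    weights /= weights.sum()
    chrom_draws = rng.choice(len(names), size=background_n, p=weights)
    bg_total = 0.0
    for ci in chrom_draws:
        chrom = names[ci]
        start = int(rng.integers(0, chrom_sizes[chrom] - background_len + 1))
        bg_total += track.interval_mean(chrom, start, start + background_len)
    return ConservationResult(float(fg.mean()), bg_total / background_n, fg)
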