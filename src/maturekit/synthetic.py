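"""Seeded synthetic data with known ground truth.

Every generator is a pure function of its configuration plus an integer
seed, and returns both the simulated artifact and a truth record so that
downstream operations (differential calling, deconvolution, peak set
algebra) can be tested against known answers.

Counts are negative-binomial with the mean/dispersion parameterization
``var = mu + phi * mu**2`` (a single global ``phi``), matching the
assumptions of the exact test in :mod:`maturekit.expression`. Dynamic genes
are assigned by exact counts (``floor(fraction * n)``), not per-gene coin
flips, so truth-table tallies are deterministic. Per-sample library-size
factors are log-normal with a configured coefficient of variation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import CellMatrix, CountMatrix
from .errors import GenerationError, InvalidConfigError
from .track import ScoreTrack

DEFAULT_TIMEPOINTS = ("E10.5", "E13.5", "P4", "P13", "P21", "P56", "P2yr")
# per-transition dynamic fractions emulating a maturation time course that is
# highly dynamic embryonically and nearly frozen after the third postnatal week
DEFAULT_DYNAMIC_FRACTIONS = (0.4, 0.4, 0.2, 0.1, 0.01, 0.01)


@dataclass
class TimecourseConfig:
    """Configuration for the bulk time-course generator."""

    n_genes: int = 2000
    timepoints: tuple[str, ...] = DEFAULT_TIMEPOINTS
    replicates_per_timepoint: int = 3
    dynamic_fraction_per_transition: tuple[float, ...] = DEFAULT_DYNAMIC_FRACTIONS
    lfc_magnitude: float = 2.0  # log2 units; 4-fold effects
    base_mean_log_range: tuple[float, float] = (5.0, 10.0)  # log2 of mean counts
    dispersion: float = 0.05
    library_size_cv: float = 0.1
    condition: str = "in_vivo"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise InvalidConfigError("n_genes must be positive")
        if self.replicates_per_timepoint <= 0:
            raise InvalidConfigError("replicates_per_timepoint must be positive")
        if len(self.timepoints) < 2:
            raise InvalidConfigError("need at least 2 timepoints")
        if len(self.dynamic_fraction_per_transition) != len(self.timepoints) - 1:
            raise InvalidConfigError(
                "dynamic_fraction_per_transition must have one entry per transition"
            )
        for f in self.dynamic_fraction_per_transition:
            if not 0.0 <= f <= 1.0:
                raise InvalidConfigError("dynamic fractions must lie in [0, 1]")
        if self.lfc_magnitude <= 0:
            raise InvalidConfigError("lfc_magnitude must be positive")
        if self.dispersion < 0:
            raise InvalidConfigError("dispersion must be non-negative")
        if self.library_size_cv < 0:
            raise InvalidConfigError("library_size_cv must be non-negative")


@dataclass
class TruthTable:
    """Ground truth for a generated series.

    ``classes``/``effects`` are gene x transition frames (classes in
    {up, down, stable}; effects are signed log2 fold changes, zero iff
    stable). ``library_factors`` holds the per-sample true scaling.
    """

    classes: pd.DataFrame
    effects: pd.DataFrame
    library_factors: pd.Series
    base_means: pd.Series
    config: TimecourseConfig | None = None

    def net_effects(self) -> pd.Series:
        """Summed log2 effect over all transitions (first vs last timepoint)."""
        return self.effects.sum(axis=1)

    def dynamic_genes(self, transition: str | None = None) -> pd.Index:
        if transition is not None:
            return self.classes.index[self.classes[transition] != "stable"]
        return self.classes.index[(self.classes != "stable").any(axis=1)]


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def _library_factors(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    if cv <= 0:
        return np.ones(n)
    sigma2 = math.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2, sigma=math.sqrt(sigma2), size=n)


def transition_labels(timepoints: Sequence[str]) -> list[str]:
    return [f"{a}->{b}" for a, b in zip(timepoints[:-1], timepoints[1:])]


def _counts_from_truth(
    rng: np.random.Generator,
    base_means: np.ndarray,
    effects: np.ndarray,
    timepoints: Sequence[str],
    replicates: int,
    dispersion: float,
    library_cv: float,
    condition: str,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    n_genes = base_means.shape[0]
    cum = np.concatenate(
        [np.zeros((n_genes, 1)), np.cumsum(effects, axis=1)], axis=1
    )  # gene x timepoint cumulative log2 effect
    sample_ids, tp_of_sample, rep_of_sample = [], [], []
    for tp in timepoints:
        for r in range(1, replicates + 1):
            sample_ids.append(f"{condition}_{tp}_r{r}")
            tp_of_sample.append(tp)
            rep_of_sample.append(r)
    lib = _library_factors(rng, len(sample_ids), library_cv)
    counts = np.empty((n_genes, len(sample_ids)), dtype=np.int64)
    for j, tp in enumerate(tp_of_sample):
        tp_idx = list(timepoints).index(tp)
        mu = base_means * np.exp2(cum[:, tp_idx]) * lib[j]
        counts[:, j] = _nb_sample(rng, mu, dispersion)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    frame = pd.DataFrame(counts, index=genes, columns=sample_ids)
    meta = pd.DataFrame(
        {"timepoint": tp_of_sample, "replicate": rep_of_sample, "condition": condition},
        index=sample_ids,
    )
    return frame, meta, lib


def generate_timecourse(config: TimecourseConfig) -> tuple[CountMatrix, TruthTable]:
    """Simulate an ordered bulk time course with known per-transition truth.

    Gene mean at timepoint ``t`` = base mean x 2**(cumulative true LFC up
    to ``t``) x per-sample library factor; counts are NB(mean, dispersion).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = [f"g{i:05d}" for i in range(n)]
    trans = transition_labels(config.timepoints)
    base_means = np.exp2(rng.uniform(*config.base_mean_log_range, size=n))

    classes = pd.DataFrame("stable", index=genes, columns=trans)
    effects = pd.DataFrame(0.0, index=genes, columns=trans)
    for t, frac in zip(trans, config.dynamic_fraction_per_transition):
        n_dyn = int(math.floor(frac * n))
        if n_dyn == 0:
            continue
        chosen = rng.permutation(n)[:n_dyn]
        n_up = (n_dyn + 1) // 2
        up, down = chosen[:n_up], chosen[n_up:]
        classes.iloc[up, classes.columns.get_loc(t)] = "up"
        effects.iloc[up, effects.columns.get_loc(t)] = config.lfc_magnitude
        classes.iloc[down, classes.columns.get_loc(t)] = "down"
        effects.iloc[down, effects.columns.get_loc(t)] = -config.lfc_magnitude

    frame, meta, lib = _counts_from_truth(
        rng,
        base_means,
        effects.to_numpy(),
        config.timepoints,
        config.replicates_per_timepoint,
        config.dispersion,
        config.library_size_cv,
        config.condition,
    )
    truth = TruthTable(
        classes,
        effects,
        pd.Series(lib, index=frame.columns, name="library_factor"),
        pd.Series(base_means, index=genes, name="base_mean"),
        config,
    )
    return CountMatrix(frame, meta, tuple(config.timepoints)), truth


def generate_paired_series(
    truth: TruthTable,
    shared_up_frac: float,
    shared_down_frac: float,
    opposite_frac: float,
    seed: int,
    timepoints: tuple[str, ...] = ("DIV0", "DIV7", "DIV28"),
    condition: str = "in_vitro",
) -> tuple[CountMatrix, TruthTable]:
    """Simulate a paired (e.g. in vitro) series recapitulating part of the truth.

    Among genes with a net up (down) effect in the source truth, exactly
    ``floor(shared_up_frac * n_up)`` carry the same-direction net effect in
    the paired series, ``floor(opposite_frac * n_up)`` carry the opposite
    effect, and the remainder are flat. Genes stable in the source stay flat.
    The paired truth's ``pairing`` column records the assignment.
    """
    for name, f in (
        ("shared_up_frac", shared_up_frac),
        ("shared_down_frac", shared_down_frac),
        ("opposite_frac", opposite_frac),
    ):
        if f < 0:
            raise InvalidConfigError(f"{name} must be non-negative")
    if shared_up_frac + opposite_frac > 1 or shared_down_frac + opposite_frac > 1:
        raise InvalidConfigError("shared + opposite fractions must not exceed 1")
    if truth.config is None:
        raise InvalidConfigError("source truth must carry its generating config")
    cfg = truth.config
    rng = np.random.default_rng(seed)
    genes = list(truth.classes.index)
    n = len(genes)
    net = truth.net_effects().to_numpy()
    trans = transition_labels(timepoints)
    n_trans = len(trans)

    effects = np.zeros((n, n_trans))
    pairing = np.full(n, "source_stable", dtype=object)
    for direction, frac_shared in (("up", shared_up_frac), ("down", shared_down_frac)):
        idx = np.flatnonzero(net > 0) if direction == "up" else np.flatnonzero(net < 0)
        if idx.size == 0:
            continue
        perm = idx[rng.permutation(idx.size)]
        n_shared = int(math.floor(frac_shared * idx.size))
        n_opp = int(math.floor(opposite_frac * idx.size))
        shared, opp, flat = (
            perm[:n_shared],
            perm[n_shared : n_shared + n_opp],
            perm[n_shared + n_opp :],
        )
        effects[shared] = (net[shared] / n_trans)[:, None]
        effects[opp] = (-net[opp] / n_trans)[:, None]
        pairing[shared] = f"shared_{direction}"
        pairing[opp] = "opposite"
        pairing[flat] = "paired_stable"

    base_means = np.exp2(rng.uniform(*cfg.base_mean_log_range, size=n))
    frame, meta, lib = _counts_from_truth(
        rng,
        base_means,
        effects,
        timepoints,
        cfg.replicates_per_timepoint,
        cfg.dispersion,
        cfg.library_size_cv,
        condition,
    )
    classes = pd.DataFrame(
        np.where(effects > 0, "up", np.where(effects < 0, "down", "stable")),
        index=genes,
        columns=trans,
    )
    paired_cfg = TimecourseConfig(
        n_genes=n,
        timepoints=timepoints,
        replicates_per_timepoint=cfg.replicates_per_timepoint,
        dynamic_fraction_per_transition=tuple(0.0 for _ in trans),
        lfc_magnitude=cfg.lfc_magnitude,
        base_mean_log_range=cfg.base_mean_log_range,
        dispersion=cfg.dispersion,
        library_size_cv=cfg.library_size_cv,
        condition=condition,
        seed=seed,
    )
    paired_truth = TruthTable(
        classes,
        pd.DataFrame(effects, index=genes, columns=trans),
        pd.Series(lib, index=frame.columns, name="library_factor"),
        pd.Series(base_means, index=genes, name="base_mean"),
        paired_cfg,
    )
    paired_truth.classes["pairing"] = pairing
    return CountMatrix(frame, meta, tuple(timepoints)), paired_truth


# ---------------------------------------------------------------------------
# single-cell reference and bulk mixtures
# ---------------------------------------------------------------------------

@dataclass
class MixtureTruth:
    """True composition of a simulated bulk mixture."""

    weights: tuple[float, ...]
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights):
            raise InvalidConfigError("mixture weights must be non-negative")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be non-negative")


def generate_single_cell_reference(
    n_classes: int,
    clusters_per_class: int,
    cells_per_cluster: Sequence[int],
    n_genes: int,
    within_class_corr: float = 0.9,
    seed: int = 0,
    cholinergic_classes: Sequence[int] | None = None,
    dispersion: float = 0.1,
) -> tuple[CellMatrix, pd.Series, pd.DataFrame]:
    """Cluster-structured single-cell reference with latent classes.

    Class archetypes are independent log-normal expression profiles; cluster
    archetypes perturb their class archetype so that the expected Pearson
    correlation between two clusters of the same class is
    ``within_class_corr`` (between classes it is ~0). Cell counts are NB
    around the cluster archetype scaled by a per-cell depth factor.

    Returns
    -------
    (cells, class_truth, archetypes)
        ``cells``: the labeled :class:`CellMatrix`; ``class_truth``: cluster
        -> class assignment; ``archetypes``: cluster x gene log-mean matrix.
    """
    if n_classes < 1:
        raise InvalidConfigError("n_classes must be >= 1")
    if clusters_per_class < 1:
        raise InvalidConfigError("clusters_per_class must be >= 1")
    n_clusters = n_classes * clusters_per_class
    if len(cells_per_cluster) != n_clusters:
        raise InvalidConfigError(
            f"cells_per_cluster must have length {n_clusters} "
            f"(n_classes x clusters_per_class), got {len(cells_per_cluster)}"
        )
    if not 0 < within_class_corr <= 1:
        raise InvalidConfigError("within_class_corr must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    spread = 1.2  # sd of log archetype expression across genes
    class_logs = rng.normal(loc=1.5, scale=spread, size=(n_classes, n_genes))
    eps = spread * math.sqrt((1 - within_class_corr) / within_class_corr)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    cholinergic = set(cholinergic_classes or ())

    cluster_ids, class_of, rows, cell_ids, labels = [], {}, [], [], []
    archetypes = np.empty((n_clusters, n_genes))
    k = 0
    for c in range(n_classes):
        for j in range(clusters_per_class):
            cid = f"cluster{k:02d}"
            cluster_ids.append(cid)
            class_of[cid] = f"class{c}"
            arch = class_logs[c] + rng.normal(scale=eps, size=n_genes)
            archetypes[k] = arch
            mu = np.exp(arch)
            for cell in range(cells_per_cluster[k]):
                depth = rng.lognormal(mean=0.0, sigma=0.2)
                rows.append(_nb_sample(rng, mu * depth, dispersion))
                cell_ids.append(f"{cid}_cell{cell:03d}")
                labels.append(cid)
            k += 1

    counts = pd.DataFrame(np.asarray(rows), index=cell_ids, columns=genes)
    clusters = pd.Series(labels, index=cell_ids, name="cluster")
    flags = pd.DataFrame(
        {
            "cholinergic": [
                int(class_of[cid].removeprefix("class")) in cholinergic
                for cid in cluster_ids
            ]
        },
        index=cluster_ids,
    )
    class_truth = pd.Series(class_of, name="class").loc[cluster_ids]
    arch_frame = pd.DataFrame(archetypes, index=cluster_ids, columns=genes)
    return CellMatrix(counts, clusters, flags), class_truth, arch_frame


def generate_bulk_mixture(
    class_profiles: pd.DataFrame, truth: MixtureTruth
) -> pd.Series:
    """Bulk profile = weighted sum of class profiles + Gaussian noise, clipped at 0.

    ``class_profiles`` is class x gene (rows in the order the weights refer to).
    """
    if len(truth.weights) != class_profiles.shape[0]:
        raise InvalidConfigError(
            f"{len(truth.weights)} weights for {class_profiles.shape[0]} classes"
        )
    rng = np.random.default_rng(truth.seed)
    w = np.asarray(truth.weights, dtype=float)
    bulk = w @ class_profiles.to_numpy(dtype=float)
    if truth.noise_sd > 0:
        bulk = bulk + rng.normal(scale=truth.noise_sd, size=bulk.shape)
    return pd.Series(np.clip(bulk, 0.0, None), index=class_profiles.columns, name="bulk")


# ---------------------------------------------------------------------------
# peak universes and score tracks
# ---------------------------------------------------------------------------

@dataclass
class PeakUniverseTruth:
    """Per-transition gained/lost peak IDs and per-peak proximal flag."""

    gained: dict[str, list[str]] = field(default_factory=dict)
    lost: dict[str, list[str]] = field(default_factory=dict)
    proximal: dict[str, bool] = field(default_factory=dict)


def _overlaps_sorted(start: int, end: int, starts: np.ndarray, ends: np.ndarray) -> bool:
    idx = np.searchsorted(starts, end, side="left")
    return idx > 0 and ends[idx - 1] > start


def generate_peak_universe(
    chrom_sizes: Mapping[str, int],
    timepoints: Sequence[str],
    n_peaks_per_tp: int,
    gain_frac: float,
    loss_frac: float,
    proximal_frac: float,
    tss_list: pd.DataFrame,
    seed: int = 0,
    peak_width: int = 200,
    proximal_cutoff: int = 2000,
    max_tries_per_peak: int = 200,
) -> tuple[dict[str, pd.DataFrame], PeakUniverseTruth]:
    """Per-timepoint non-overlapping peak sets with known gain/loss truth.

    Between consecutive timepoints exactly ``floor(loss_frac * n)`` peaks of
    the earlier set are dropped and ``floor(gain_frac * n)`` new peaks are
    added; new peaks never overlap any peak of the earlier set, so whole-
    feature subtraction recovers the truth exactly. A
    ``floor(proximal_frac * n)`` share of each batch is placed with its
    midpoint within ``proximal_cutoff`` of a TSS; the rest are kept distal.

    ``tss_list`` needs columns ``gene_id``, ``chrom``, ``tss``, ``strand``.
    """
    for name, f in (("gain_frac", gain_frac), ("loss_frac", loss_frac), ("proximal_frac", proximal_frac)):
        if not 0 <= f <= 1:
            raise InvalidConfigError(f"{name} must lie in [0, 1]")
    if n_peaks_per_tp < 1:
        raise InvalidConfigError("n_peaks_per_tp must be >= 1")
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    if (sizes < peak_width).any():
        raise InvalidConfigError("every chromosome must be at least one peak wide")
    rng = np.random.default_rng(seed)
    tss_by_chrom = {
        c: np.sort(g["tss"].to_numpy()) for c, g in tss_list.groupby("chrom")
    }

    def _tss_distance(chrom: str, midpoint: float) -> float:
        pos = tss_by_chrom.get(chrom)
        if pos is None or pos.size == 0:
            return math.inf
        i = np.searchsorted(pos, midpoint)
        best = math.inf
        if i < pos.size:
            best = min(best, abs(pos[i] - midpoint))
        if i > 0:
            best = min(best, abs(pos[i - 1] - midpoint))
        return best

    def _place_batch(
        n_new: int, occupied: dict[str, list[tuple[int, int]]], id_prefix: str
    ) -> list[dict]:
        n_prox = int(math.floor(proximal_frac * n_new))
        placed: list[dict] = []
        for i in range(n_new):
            want_proximal = i < n_prox
            ok = False
            for _ in range(max_tries_per_peak):
                if want_proximal and tss_by_chrom:
                    row = tss_list.iloc[rng.integers(len(tss_list))]
                    chrom = row["chrom"]
                    offset = rng.integers(-proximal_cutoff, proximal_cutoff + 1)
                    mid = int(row["tss"]) + int(offset)
                    start = mid - peak_width // 2
                else:
                    ci = rng.choice(len(chroms), p=sizes / sizes.sum())
                    chrom = chroms[ci]
                    start = int(rng.integers(0, chrom_sizes[chrom] - peak_width + 1))
                    mid = start + peak_width // 2
                end = start + peak_width
                if start < 0 or end > chrom_sizes[chrom]:
                    continue
                dist = _tss_distance(chrom, start + peak_width / 2)
                if want_proximal and dist > proximal_cutoff:
                    continue
                if not want_proximal and dist <= proximal_cutoff:
                    continue
                occ = occupied.setdefault(chrom, [])
                if occ:
                    occ_sorted = sorted(occ)
                    st = np.array([x[0] for x in occ_sorted])
                    en = np.array([x[1] for x in occ_sorted])
                    if _overlaps_sorted(start, end, st, en):
                        continue
                occ.append((start, end))
                placed.append(
                    {
                        "chrom": chrom,
                        "start": start,
                        "end": end,
                        "name": f"{id_prefix}_{len(placed):05d}",
                        "score": float(rng.uniform(50, 1000)),
                        "proximal": bool(want_proximal),
                    }
                )
                ok = True
                break
            if not ok:
                raise GenerationError(
                    "could not place a non-overlapping peak satisfying the "
                    "proximity constraint; genome too small or fractions too tight"
                )
        return placed

    truth = PeakUniverseTruth()
    peak_sets: dict[str, pd.DataFrame] = {}
    occupied: dict[str, list[tuple[int, int]]] = {}
    current = _place_batch(n_peaks_per_tp, occupied, f"{timepoints[0]}")
    for p in current:
        truth.proximal[p["name"]] = p["proximal"]
    peak_sets[timepoints[0]] = _peaks_frame(current)

    for prev_tp, tp in zip(timepoints[:-1], timepoints[1:]):
        label = f"{prev_tp}->{tp}"
        n_prev = len(current)
        n_lost = int(math.floor(loss_frac * n_prev))
        n_gained = int(math.floor(gain_frac * n_peaks_per_tp))
        drop_idx = set(rng.permutation(n_prev)[:n_lost].tolist())
        retained = [p for i, p in enumerate(current) if i not in drop_idx]
        lost = [p for i, p in enumerate(current) if i in drop_idx]
        # new peaks must avoid *all* earlier peaks (including the dropped
        # ones) so gained/lost recovery by subtraction is exact
        gained = _place_batch(n_gained, occupied, f"{tp}")
        for p in gained:
            truth.proximal[p["name"]] = p["proximal"]
        truth.gained[label] = [p["name"] for p in gained]
        truth.lost[label] = [p["name"] for p in lost]
        current = retained + gained
        peak_sets[tp] = _peaks_frame(current)
    return peak_sets, truth


def _peaks_frame(records: list[dict]) -> pd.DataFrame:
    frame = pd.DataFrame(
        [{k: r[k] for k in ("chrom", "start", "end", "name", "score")} for r in records]
    )
    return frame.sort_values(["chrom", "start", "end"]).reset_index(drop=True)


def generate_score_track(
    chrom_sizes: Mapping[str, int],
    seed: int = 0,
    mean_segment_length: int = 500,
    constant: float | None = None,
) -> ScoreTrack:
    """Piecewise-constant non-negative score track covering the genome.

    Segment lengths are geometric around ``mean_segment_length``; values are
    Uniform(0, 1), or a single ``constant`` everywhere when given.
    """
    if any(s <= 0 for s in chrom_sizes.values()):
        raise InvalidConfigError("chromosome sizes must be positive")
    rng = np.random.default_rng(seed)
    segments: dict[str, pd.DataFrame] = {}
    for chrom, size in chrom_sizes.items():
        starts, ends, values = [], [], []
        pos = 0
        while pos < size:
            length = int(rng.geometric(1.0 / mean_segment_length))
            end = min(pos + max(length, 1), size)
            starts.append(pos)
            ends.append(end)
            values.append(constant if constant is not None else float(rng.uniform(0, 1)))
            pos = end
        segments[chrom] = pd.DataFrame({"start": starts, "end": ends, "value": values})
    return ScoreTrack(segments)
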