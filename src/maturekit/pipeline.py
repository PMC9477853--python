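"""Top-level pipeline: normalize -> per-transition DE -> dynamics ->
optional deconvolution -> optional concordance -> optional peak dynamics.

Driven by one structured (YAML) configuration; every stage writes TSV
artifacts plus a machine-readable ``summary.json``. Deterministic stages
reproduce identical outputs on rerun with the same config and inputs. A
failure stops at the failed stage, leaving earlier artifacts intact, and
missing inputs are enumerated before any computation starts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import io as mio
from .concordance import build_concordance, lfc_correlation, summarize_concordance
from .containers import CountMatrix
from .deconvolution import two_stage_deconvolve
from .dynamics import percent_dynamic
from .errors import InvalidConfigError
from .expression import de_test, expressed_genes, normalize, pca_samples
from .intervals import classify_tss_proximity, gain_loss, proximity_summary

log = logging.getLogger("maturekit")

DEFAULT_THRESHOLDS = {
    "fold": 2.0,
    "p": 0.001,
    "cpm": 5.0,
    "pca_min_reads": 10.0,
    "tss_cutoff": 2000,
    "top_n": 100_000,
    "corr_threshold": 0.8,
    "window_bp": 50_000,
}


@dataclass
class RunConfig:
    counts: str
    metadata: str
    outdir: str
    seed: int = 0
    thresholds: dict = field(default_factory=dict)
    # optional stages
    concordance: dict | None = None  # {x_condition, y_condition}
    deconvolution: dict | None = None  # {cells, cell_meta, bulk_sample}
    peaks: dict | None = None  # {beds: {tp: path}, order: [...], tss: path, top_n}

    def __post_init__(self) -> None:
        merged = dict(DEFAULT_THRESHOLDS)
        merged.update(self.thresholds)
        for key, value in merged.items():
            if key != "corr_threshold" and value <= 0:
                raise InvalidConfigError(f"threshold {key} must be positive")
        self.thresholds = merged

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def input_paths(self) -> list[str]:
        paths = [self.counts, self.metadata]
        if self.deconvolution:
            paths += [self.deconvolution["cells"], self.deconvolution["cell_meta"]]
        if self.peaks:
            paths += list(self.peaks["beds"].values())
            if self.peaks.get("tss"):
                paths.append(self.peaks["tss"])
        return paths


def _series_transitions(counts: CountMatrix, condition: str) -> list[tuple[str, str]]:
    return counts.transitions(condition=condition)


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the configured stages, write artifacts, return the summary dict."""
    missing = [p for p in config.input_paths() if not Path(p).exists()]
    if missing:
        raise InvalidConfigError(f"missing inputs: {missing}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds
    cfg_hash = mio.config_hash(
        {
            "counts": config.counts,
            "metadata": config.metadata,
            "thresholds": thr,
            "seed": config.seed,
        }
    )
    summary: dict[str, Any] = {"seed": config.seed, "config_hash": cfg_hash}

    counts = mio.read_counts(config.counts, config.metadata)
    log.info("loaded %d genes x %d samples", *counts.counts.shape)

    # --- normalization and PCA ---------------------------------------------
    norm = normalize(counts)
    mio.write_table(
        norm.size_factors.to_frame(), outdir / "size_factors.tsv", "sample", config.seed, cfg_hash
    )
    mio.write_table(norm.values, outdir / "normalized.tsv", "gene_id", config.seed, cfg_hash)
    pca = pca_samples(norm, min_reads=thr["pca_min_reads"])
    mio.write_table(pca.scores, outdir / "pca_scores.tsv", "sample", config.seed, cfg_hash)
    summary["pca_pct_variance"] = [round(float(v), 4) for v in pca.percent_variance]

    # --- per-condition, per-transition DE -----------------------------------
    expressed = expressed_genes(counts, cpm_threshold=thr["cpm"])
    summary["n_expressed"] = len(expressed)
    de_by_condition: dict[str, dict] = {}
    for condition in counts.conditions():
        de_results = {}
        for tp_a, tp_b in _series_transitions(counts, condition):
            de = de_test(
                counts,
                counts.samples_for(timepoint=tp_a, condition=condition),
                counts.samples_for(timepoint=tp_b, condition=condition),
                genes=sorted(expressed),
                fold_threshold=thr["fold"],
                p_threshold=thr["p"],
            )
            label = f"{tp_a}->{tp_b}"
            de_results[label] = de
            safe = label.replace("->", "_to_").replace(".", "p")
            mio.write_de(de, outdir / f"de_{condition}_{safe}.tsv", config.seed)
        if de_results:
            de_by_condition[condition] = de_results
            trans = percent_dynamic(de_results, expressed)
            mio.write_table(
                trans, outdir / f"transition_summary_{condition}.tsv", None, config.seed, cfg_hash
            )
            summary[f"percent_dynamic_{condition}"] = {
                t: {"pct_up": round(r["pct_up"], 4), "pct_down": round(r["pct_down"], 4)}
                for t, r in trans.iterrows()
            }

    # --- first-to-last contrasts + concordance -------------------------------
    if config.concordance:
        x_cond = config.concordance["x_condition"]
        y_cond = config.concordance["y_condition"]
        contrasts = {}
        for cond in (x_cond, y_cond):
            present = [
                tp for tp in counts.timepoint_order
                if counts.samples_for(timepoint=tp, condition=cond)
            ]
            if len(present) < 2:
                raise InvalidConfigError(f"condition {cond!r} has fewer than 2 timepoints")
            contrasts[cond] = de_test(
                counts,
                counts.samples_for(timepoint=present[0], condition=cond),
                counts.samples_for(timepoint=present[-1], condition=cond),
                genes=sorted(expressed),
                fold_threshold=thr["fold"],
                p_threshold=thr["p"],
            )
        table = build_concordance(contrasts[x_cond], contrasts[y_cond])
        mio.write_table(table, outdir / "concordance.tsv", "gene_id", config.seed, cfg_hash)
        summ = summarize_concordance(table)
        r, p = lfc_correlation(table)
        conc = summ.as_dict()
        conc["pearson_r"] = round(r, 6)
        conc["pearson_p"] = p
        summary["concordance"] = conc

    # --- deconvolution -------------------------------------------------------
    if config.deconvolution:
        cells = mio.read_cells(
            config.deconvolution["cells"], config.deconvolution["cell_meta"]
        )
        bulk_sample = config.deconvolution.get("bulk_sample") or counts.samples[-1]
        # log-space bulk profile to match the mean-log reference profiles
        bulk = pd.Series(
            np.log1p(norm.values[bulk_sample].to_numpy()), index=norm.values.index
        )
        stage1, stage2, model1, model2 = two_stage_deconvolve(
            bulk,
            cells,
            seed=config.seed,
            corr_threshold=thr["corr_threshold"],
        )
        for stage, model, res in (
            ("stage1", model1, stage1),
            ("stage2", model2, stage2),
        ):
            out = pd.DataFrame(
                {"weight": res.weights, "proportion_pct": res.proportions}
            )
            mio.write_table(out, outdir / f"deconvolution_{stage}.tsv", "class", config.seed, cfg_hash)
            mio.write_table(
                model.assignment.to_frame(), outdir / f"cluster_classes_{stage}.tsv",
                "cluster", config.seed, cfg_hash,
            )
        summary["deconvolution"] = {
            "stage1_proportions": {k: round(float(v), 4) for k, v in stage1.proportions.items()},
            "stage2_proportions": {k: round(float(v), 4) for k, v in stage2.proportions.items()},
            "corr_threshold": thr["corr_threshold"],
            "downsample_seed": config.seed,
        }

    # --- peak dynamics -------------------------------------------------------
    if config.peaks:
        beds = {tp: mio.read_bed(path) for tp, path in config.peaks["beds"].items()}
        order = config.peaks.get("order") or list(beds)
        top_n = int(config.peaks.get("top_n", thr["top_n"]))
        tss = mio.read_tss(config.peaks["tss"]) if config.peaks.get("tss") else None
        peak_summary = {}
        for tp_a, tp_b in zip(order[:-1], order[1:]):
            res = gain_loss(beds[tp_a], beds[tp_b], n=top_n)
            label = f"{tp_a}->{tp_b}"
            safe = label.replace("->", "_to_").replace(".", "p")
            mio.write_bed(res.gained, outdir / f"gained_{safe}.bed")
            mio.write_bed(res.lost, outdir / f"lost_{safe}.bed")
            entry = {
                "pct_gained": round(res.pct_gained, 4),
                "pct_lost": round(res.pct_lost, 4),
            }
            if tss is not None:
                gained_cls = classify_tss_proximity(
                    res.gained, tss, cutoff_bp=int(thr["tss_cutoff"])
                )
                entry["gained_pct_distal"] = round(
                    proximity_summary(gained_cls)["pct_distal"], 4
                )
            peak_summary[label] = entry
        summary["peaks"] = peak_summary

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
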