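"""Paired-contrast fold-change concordance.

Given two differential-expression contrasts over a shared gene universe
(e.g. an in vitro culture series on X and the in vivo time course on Y),
each gene falls into exactly one of eight categories: shared_up,
shared_down, opposite, x_specific_up/down, y_specific_up/down, or stable.
The "core program" is shared_up + shared_down — genes significantly
regulated in the same direction in both systems.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, InvalidArgumentError
from .expression import DEResult

CATEGORIES = (
    "shared_up",
    "shared_down",
    "opposite",
    "x_specific_up",
    "x_specific_down",
    "y_specific_up",
    "y_specific_down",
    "stable",
)


def build_concordance(
    de_x: DEResult,
    de_y: DEResult,
    quadrant_mode: str = "calls",
    lfc_cut: float = 0.0,
) -> pd.DataFrame:
    """Per-gene concordance table over the inner join of the two contrasts.

    ``quadrant_mode="calls"`` (default) takes significance and direction
    from the DE calls (fold and p thresholds as configured in each
    contrast). ``quadrant_mode="lfc-only"`` instead counts a gene as
    "significant" on an axis when |lfc| > ``lfc_cut`` — the simple quadrant
    accounting used for perturbation-response scatters.
    """
    tx = de_x.table if isinstance(de_x, DEResult) else de_x
    ty = de_y.table if isinstance(de_y, DEResult) else de_y
    shared = tx.index.intersection(ty.index)
    if shared.empty:
        raise DegenerateInputError("no shared genes between the two contrasts")
    tx, ty = tx.loc[shared], ty.loc[shared]

    if quadrant_mode == "calls":
        dir_x = np.where(tx["call"] == "up", 1, np.where(tx["call"] == "down", -1, 0))
        dir_y = np.where(ty["call"] == "up", 1, np.where(ty["call"] == "down", -1, 0))
    elif quadrant_mode == "lfc-only":
        dir_x = np.where(
            tx["log2_fc"] > lfc_cut, 1, np.where(tx["log2_fc"] < -lfc_cut, -1, 0)
        )
        dir_y = np.where(
            ty["log2_fc"] > lfc_cut, 1, np.where(ty["log2_fc"] < -lfc_cut, -1, 0)
        )
    else:
        raise InvalidArgumentError(f"unknown quadrant_mode: {quadrant_mode!r}")

    category = np.select(
        [
            (dir_x == 1) & (dir_y == 1),
            (dir_x == -1) & (dir_y == -1),
            (dir_x != 0) & (dir_y != 0),  # remaining both-sig cases differ in sign
            (dir_x == 1) & (dir_y == 0),
            (dir_x == -1) & (dir_y == 0),
            (dir_x == 0) & (dir_y == 1),
            (dir_x == 0) & (dir_y == -1),
        ],
        [
            "shared_up",
            "shared_down",
            "opposite",
            "x_specific_up",
            "x_specific_down",
            "y_specific_up",
            "y_specific_down",
        ],
        default="stable",
    )
    return pd.DataFrame(
        {
            "lfc_x": tx["log2_fc"],
            "lfc_y": ty["log2_fc"],
            "sig_x": dir_x != 0,
            "sig_y": dir_y != 0,
            "dir_x": dir_x,
            "dir_y": dir_y,
            "category": category,
        },
        index=shared,
    )


@dataclass
class ConcordanceSummary:
    counts: pd.Series
    core_program_size: int
    recap_up_pct: float
    recap_down_pct: float
    recap_up_pct_excl_opposite: float
    recap_down_pct_excl_opposite: float

    def as_dict(self) -> dict:
        out = {f"n_{k}": int(v) for k, v in self.counts.items()}
        out.update(
            core_program_size=self.core_program_size,
            recap_up_pct=self.recap_up_pct,
            recap_down_pct=self.recap_down_pct,
            recap_up_pct_excl_opposite=self.recap_up_pct_excl_opposite,
            recap_down_pct_excl_opposite=self.recap_down_pct_excl_opposite,
        )
        return out


def summarize_concordance(table: pd.DataFrame) -> ConcordanceSummary:
    """Category counts, core-program size and recapitulation percents.

    The up-recapitulation percent is 100 x shared_up / (all Y-up genes) =
    shared_up / (shared_up + opposite-with-Y-up + y_specific_up); the
    variant excluding opposite-regulated genes from the denominator is also
    reported. NaN when there are no Y-dynamic genes in a direction.
    """
    if table.empty:
        raise DegenerateInputError("concordance table is empty")
    counts = table["category"].value_counts().reindex(CATEGORIES, fill_value=0)
    opp_y_up = int(((table["category"] == "opposite") & (table["dir_y"] == 1)).sum())
    opp_y_down = int(((table["category"] == "opposite") & (table["dir_y"] == -1)).sum())

    def _pct(shared: int, denom: int) -> float:
        return 100.0 * shared / denom if denom > 0 else float("nan")

    su, sd = int(counts["shared_up"]), int(counts["shared_down"])
    return ConcordanceSummary(
        counts=counts,
        core_program_size=su + sd,
        recap_up_pct=_pct(su, su + opp_y_up + int(counts["y_specific_up"])),
        recap_down_pct=_pct(sd, sd + opp_y_down + int(counts["y_specific_down"])),
        recap_up_pct_excl_opposite=_pct(su, su + int(counts["y_specific_up"])),
        recap_down_pct_excl_opposite=_pct(sd, sd + int(counts["y_specific_down"])),
    )


def lfc_correlation(
    table: pd.DataFrame, subset: pd.Series | None = None
) -> tuple[float, float]:
    """Pearson correlation of (lfc_x, lfc_y) with the two-sided linear-model p."""
    sub = table if subset is None else table.loc[subset.reindex(table.index, fill_value=False)]
    if len(sub) < 3:
        raise InvalidArgumentError("correlation needs at least 3 genes")
    x, y = sub["lfc_x"].to_numpy(), sub["lfc_y"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("zero variance on one axis; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def shared_across_datasets(
    focal_up: Iterable[str],
    focal_down: Iterable[str],
    others: Sequence[tuple[Iterable[str], Iterable[str]]],
) -> dict:
    """Genes of a focal dataset regulated the same way in every other dataset.

    ``others`` is a sequence of (up set, down set) pairs; the shared set is
    the intersection of the focal set with *all* other sets of the same
    direction. Percents are relative to the focal set sizes (NaN if empty).
    """
    if not others:
        raise InvalidArgumentError("need at least one other dataset")
    focal_up, focal_down = set(focal_up), set(focal_down)
    shared_up, shared_down = set(focal_up), set(focal_down)
    for up, down in others:
        shared_up &= set(up)
        shared_down &= set(down)

    def _pct(shared: set, focal: set) -> float:
        return 100.0 * len(shared) / len(focal) if focal else float("nan")

    return {
        "shared_up_count": len(shared_up),
        "shared_down_count": len(shared_down),
        "shared_up_pct": _pct(shared_up, focal_up),
        "shared_down_pct": _pct(shared_down, focal_down),
        "focal_up_count": len(focal_up),
        "focal_down_count": len(focal_down),
    }
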