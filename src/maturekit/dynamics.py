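"""Temporal summaries over ordered transitions and effector-category rules.

``percent_dynamic`` summarizes per-transition differential calls into the
percent of expressed genes moving up or down. ``categorize_effectors``
applies the keyword rules used to group effector genes (channels,
receptors, collagens, transcription factors, chromatin regulators,
kinases) from gene symbols and free-text descriptions, and
``induced_fraction_by_category`` computes the fraction of each category
that is lowly expressed at the first timepoint yet induced by the last.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InvalidArgumentError
from .expression import DEResult

EFFECTOR_CATEGORIES = (
    "transcription_factor",
    "chromatin_regulator",
    "channel",
    "receptor",
    "kinase",
    "collagen",
)


def percent_dynamic(
    de_results: Mapping[str, DEResult], expressed: Iterable[str]
) -> pd.DataFrame:
    """Per-transition counts and percents of expressed genes called up/down.

    ``de_results`` maps transition labels (in order) to their DE results;
    only genes in ``expressed`` are counted and the denominator is
    ``len(expressed)``. No re-testing happens here: the summary tallies the
    calls already present in each result.
    """
    expressed = set(expressed)
    if not expressed:
        raise DegenerateInputError("expressed gene set is empty")
    rows = []
    for label, de in de_results.items():
        table = de.table if isinstance(de, DEResult) else de
        sub = table.loc[table.index.intersection(expressed)]
        n_up = int((sub["call"] == "up").sum())
        n_down = int((sub["call"] == "down").sum())
        rows.append(
            {
                "transition": label,
                "n_up": n_up,
                "n_down": n_down,
                "pct_up": 100.0 * n_up / len(expressed),
                "pct_down": 100.0 * n_down / len(expressed),
            }
        )
    return pd.DataFrame(rows).set_index("transition")


def categorize_effectors(
    catalog: pd.DataFrame, multi_label: bool = False
) -> pd.Series | pd.DataFrame:
    """Assign effector categories from gene symbols and descriptions.

    Rules (case-insensitive substring matches on the description; the
    symbol prefix test is case-sensitive on the canonical capitalization):

    * channel: description contains "channel"
    * receptor: contains "receptor" but not "nuclear"
    * collagen: symbol begins with "Col"
    * transcription_factor: contains "transcription", or contains both
      "receptor" and "nuclear" (nuclear receptors act as ligand-dependent
      transcription factors)
    * chromatin_regulator: contains "histone" or "chromatin"
    * kinase: contains "kinase"

    With ``multi_label=False`` (default) collisions resolve by precedence
    transcription_factor > chromatin_regulator > channel > receptor >
    kinase > collagen; unmatched genes get "none". With
    ``multi_label=True`` a boolean gene x category frame is returned.
    """
    if catalog.empty:
        raise InvalidArgumentError("gene catalog is empty")
    if catalog["symbol"].duplicated().any():
        raise InvalidArgumentError("duplicate symbols in catalog")
    symbols = catalog["symbol"].astype(str)
    desc = catalog["description"].fillna("").astype(str).str.lower()

    has = lambda word: desc.str.contains(word, regex=False)  # noqa: E731
    matches = pd.DataFrame(
        {
            "transcription_factor": has("transcription") | (has("receptor") & has("nuclear")),
            "chromatin_regulator": has("histone") | has("chromatin"),
            "channel": has("channel"),
            "receptor": has("receptor") & ~has("nuclear"),
            "kinase": has("kinase"),
            "collagen": symbols.str.startswith("Col"),
        }
    )
    matches.index = symbols.to_numpy()
    if multi_label:
        return matches
    assigned = pd.Series("none", index=matches.index, name="category")
    for cat in reversed(EFFECTOR_CATEGORIES):
        assigned[matches[cat]] = cat
    return assigned


def induced_fraction_by_category(
    assignments: pd.Series,
    norm_values: pd.DataFrame,
    first_timepoint_samples: Sequence[str],
    de_first_last: DEResult,
    expr_ceiling: float = 100.0,
    expressed: Iterable[str] | None = None,
) -> pd.Series:
    """Percent of each category's expressed members induced from a low start.

    A member counts as induced if its mean normalized expression over the
    first-timepoint samples is below ``expr_ceiling`` *and* it is called up
    in the first-to-last contrast. Categories with zero expressed members
    are reported as NaN (undefined), not 0.
    """
    table = de_first_last.table
    first_mean = norm_values[list(first_timepoint_samples)].mean(axis=1)
    universe = set(table.index) & set(norm_values.index)
    if expressed is not None:
        universe &= set(expressed)
    out = {}
    for cat in EFFECTOR_CATEGORIES:
        members = [g for g in assignments.index[assignments == cat] if g in universe]
        if not members:
            out[cat] = np.nan
            continue
        low_start = first_mean.loc[members] < expr_ceiling
        called_up = table.loc[members, "call"] == "up"
        out[cat] = 100.0 * float((low_start & called_up).sum()) / len(members)
    return pd.Series(out, name="pct_induced")


def marker_timing(
    markers: Sequence[str], early_de: DEResult, late_de: DEResult
) -> tuple[float, float]:
    """Fractions of a marker list called up in an early vs a late contrast."""
    markers = list(markers)
    if not markers:
        raise InvalidArgumentError("marker list is empty")
    for name, de in (("early", early_de), ("late", late_de)):
        missing = [m for m in markers if m not in de.table.index]
        if missing:
            raise InvalidArgumentError(f"markers absent from {name} contrast: {missing[:5]}")
    frac_early = float((early_de.table.loc[markers, "call"] == "up").mean())
    frac_late = float((late_de.table.loc[markers, "call"] == "up").mean())
    return frac_early, frac_late


def round_half_up(value: float, digits: int = 0) -> float:
    """Display rounding: half-way cases round away from zero."""
    factor = 10**digits
    return np.floor(abs(value) * factor + 0.5) / factor * np.sign(value)
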