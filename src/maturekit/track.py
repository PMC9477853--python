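"""Piecewise-constant per-base score tracks (bedGraph-backed).

Used for conservation-style averaging over genomic regions. Bases not
covered by any segment score 0 by convention.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, ParseError


class ScoreTrack:
    """A per-base score function stored as sorted non-overlapping segments."""

    def __init__(self, segments: Mapping[str, pd.DataFrame]):
        self._segments: dict[str, pd.DataFrame] = {}
        for chrom, frame in segments.items():
            frame = frame[["start", "end", "value"]].sort_values("start").reset_index(drop=True)
            starts = frame["start"].to_numpy()
            ends = frame["end"].to_numpy()
            if (starts >= ends).any():
                raise InvalidArgumentError(f"empty segment on {chrom}")
            if (starts[1:] < ends[:-1]).any():
                raise InvalidArgumentError(f"overlapping segments on {chrom}")
            self._segments[chrom] = frame

    @property
    def chroms(self) -> list[str]:
        return list(self._segments)

    def segments(self, chrom: str) -> pd.DataFrame:
        return self._segments[chrom]

    def interval_mean(self, chrom: str, start: int, end: int) -> float:
        """Length-weighted mean score over [start, end); uncovered bases = 0."""
        if end <= start:
            raise InvalidArgumentError("interval must have positive length")
        frame = self._segments.get(chrom)
        if frame is None:
            return 0.0
        starts = frame["start"].to_numpy()
        ends = frame["end"].to_numpy()
        values = frame["value"].to_numpy()
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        if hi <= lo:
            return 0.0
        seg_start = np.maximum(starts[lo:hi], start)
        seg_end = np.minimum(ends[lo:hi], end)
        overlap = np.maximum(seg_end - seg_start, 0)
        return float((overlap * values[lo:hi]).sum() / (end - start))

    # -- bedGraph I/O ---------------------------------------------------------

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self._segments):
                for row in self._segments[chrom].itertuples(index=False):
                    fh.write(f"{chrom}\t{row.start}\t{row.end}\t{row.value:.6g}\n")

    @classmethod
    def from_bedgraph(cls, path) -> "ScoreTrack":
        rows: dict[str, list[tuple[int, int, float]]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise ParseError(f"{path}:{lineno}: expected 4 bedGraph columns")
                try:
                    chrom, start, end, value = (
                        parts[0],
                        int(parts[1]),
                        int(parts[2]),
                        float(parts[3]),
                    )
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: {exc}") from exc
                if start >= end:
                    raise ParseError(f"{path}:{lineno}: start >= end")
                rows.setdefault(chrom, []).append((start, end, value))
        segments = {
            chrom: pd.DataFrame(vals, columns=["start", "end", "value"])
            for chrom, vals in rows.items()
        }
        return cls(segments)
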