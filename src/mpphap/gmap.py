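"""Genetic-map input: convert marker positions to interval recombination
fractions.

The core API works directly in the recombination fraction r at meiosis
(transition probabilities are most naturally expressed in r, not genetic
distance); this module converts an ordered marker map (positions in cM) to
per-interval r values through a map function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = ["GeneticMap", "read_genetic_map", "haldane_r", "kosambi_r"]

REQUIRED_COLUMNS = ("marker", "chromosome", "position_cM")


def haldane_r(d_cM: float) -> float:
    """Haldane map function (no crossover interference):
    r = (1 - exp(-2 d))/2 with d in Morgans."""
    return 0.5 * (1.0 - math.exp(-2.0 * d_cM / 100.0))

def kosambi_r(d_cM: float) -> float:
    """Kosambi map function: r = tanh(2 d)/2 with d in Morgans."""
    return 0.5 * math.tanh(2.0 * d_cM / 100.0)


_MAP_FUNCTIONS = {"haldane": haldane_r, "kosambi": kosambi_r}


@dataclass(frozen=True)
class GeneticMap:
    """Markers with per-interval recombination fractions, per chromosome.

    ``intervals[chrom]`` is a list of (left marker, right marker, r).
    """

    markers: pd.DataFrame
    intervals: dict[str, list[tuple[str, str, float]]]

    def interval_r(self, chrom: str) -> list[float]:
        return [r for _, _, r in self.intervals[str(chrom)]]


def read_genetic_map(path, map_function: str = "haldane") -> GeneticMap:
    """Read a marker map CSV (columns marker, chromosome, position_cM) and
    convert adjacent intervals to recombination fractions.

    Positions must be non-decreasing within each chromosome and marker
    names unique; violations are reported with the offending line number
    (1-based, counting the header as line 1).
    """
    try:
        fn = _MAP_FUNCTIONS[map_function]
    except KeyError:
        raise ValueError(
            f"unknown map function {map_function!r}; choose from {sorted(_MAP_FUNCTIONS)}"
        ) from None
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"genetic map is missing required columns: {missing}")
    df = df.copy()
    df["chromosome"] = df["chromosome"].astype(str)
    dup = df["marker"].duplicated()
    if dup.any():
        i = int(df.index[dup][0])
        raise ValueError(
            f"duplicate marker {df['marker'][i]!r} at line {i + 2}"
        )
    intervals: dict[str, list[tuple[str, str, float]]] = {}
    for chrom, grp in df.groupby("chromosome", sort=False):
        pos = grp["position_cM"].to_numpy(dtype=float)
        diffs = pos[1:] - pos[:-1]
        bad = diffs < 0
        if bad.any():
            j = int(bad.argmax())
            marker = grp["marker"].iloc[j + 1]
            line = int(grp.index[j + 1]) + 2
            raise ValueError(
                f"positions must be non-decreasing within chromosome {chrom}: "
                f"marker {marker!r} at line {line} decreases"
            )
        names = grp["marker"].tolist()
        intervals[chrom] = [
            (names[j], names[j + 1], fn(float(d))) for j, d in enumerate(diffs)
        ]
    return GeneticMap(markers=df, intervals=intervals)
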