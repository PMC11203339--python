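"""T7 endonuclease I densitometry: band intensities to indel frequency.

T7EI cleaves heteroduplexes formed by re-annealing a mixed-allele PCR
product. With random re-annealing of two allele populations, the fraction
of cleaved molecules relates to the indel allele frequency p through
fcut = 1 - (1 - p)^2, giving the standard estimator

    indel% = 100 * (1 - sqrt(1 - fcut)),   fcut = cut / (cut + uncut).

This is the canonical correction used with the assay and is adopted here
as an explicit assumption.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

__all__ = ["LaneDensitometry", "t7ei_indel_percent", "read_lane_table"]


@dataclass(frozen=True)
class LaneDensitometry:
    """Band intensities (arbitrary units) from one gel lane."""

    uncut_intensity: float
    cut_intensities: tuple[float, ...]
    sample: str = ""

    def __post_init__(self) -> None:
        if self.uncut_intensity < 0 or any(c < 0 for c in self.cut_intensities):
            raise ValueError("band intensities must be non-negative")
        if not self.cut_intensities:
            raise ValueError("at least one cut band is required")
        if self.uncut_intensity + sum(self.cut_intensities) <= 0:
            raise ValueError("total lane intensity must be positive")


def t7ei_indel_percent(lane: LaneDensitometry) -> float:
    """Indel frequency (percent) from one lane's densitometry.

    Monotone in the cut fraction, invariant to uniform rescaling of the
    intensities, and bounded in [0, 100]. A lane with no uncut band is
    saturated; it returns 100 with a warning.
    """
    cut = sum(lane.cut_intensities)
    fcut = cut / (lane.uncut_intensity + cut)
    if fcut >= 1.0:
        warnings.warn(
            f"saturated T7EI lane {lane.sample!r}: no uncut band detected",
            stacklevel=2,
        )
        return 100.0
    return 100.0 * (1.0 - (1.0 - fcut) ** 0.5)


def read_lane_table(path) -> list[LaneDensitometry]:
    """Read lanes from a TSV: sample, uncut, cut1[, cut2, ...]."""
    df = pd.read_csv(path, sep="\t")
    lanes = []
    for _, row in df.iterrows():
        cuts = tuple(
            float(v)
            for col, v in row.items()
            if str(col).lower().startswith("cut") and pd.notna(v)
        )
        lanes.append(
            LaneDensitometry(
                uncut_intensity=float(row["uncut"]),
                cut_intensities=cuts,
                sample=str(row.iloc[0]),
            )
        )
    return lanes
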