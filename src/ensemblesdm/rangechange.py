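"""Range-change bookkeeping between current and future binary suitability maps.

Each valid pixel falls into one of four categories when a current binary map
is compared with a future one:

* loss    — suitable now, unsuitable in the future;
* stable  — suitable in both;
* gain    — unsuitable now, suitable in the future;
* absent  — unsuitable in both.

Percentages are relative to the current range: percent_loss =
100 * loss / (loss + stable), percent_gain = 100 * gain / (loss + stable),
and range_change = percent_gain - percent_loss (negative = net contraction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

LOSS, ABSENT, STABLE, GAIN = -2, -1, 1, 2


@dataclass
class BinaryMap:
    """0/1 grid (NaN = nodata) with the 0-1000 cutoff that produced it."""

    grid: np.ndarray
    threshold_used: float
    scenario: str = ""

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.grid)


@dataclass(frozen=True)
class RangeChangeStats:
    loss: int
    absent: int
    stable: int
    gain: int

    @property
    def percent_loss(self) -> float:
        base = self.loss + self.stable
        return 100.0 * self.loss / base if base else 0.0

    @property
    def percent_gain(self) -> float:
        base = self.loss + self.stable
        return 100.0 * self.gain / base if base else 0.0

    @property
    def range_change(self) -> float:
        return self.percent_gain - self.percent_loss

    def as_row(self, scenario: str = "", ensemble_type: str = "") -> dict:
        """Serialized row with percentages rounded to 3 decimals."""
        return {
            "Scenario": scenario, "EnsembleType": ensemble_type,
            "Loss": self.loss, "Absent": self.absent,
            "Stable": self.stable, "Gain": self.gain,
            "PercentLoss": round(self.percent_loss, 3),
            "PercentGain": round(self.percent_gain, 3),
            "RangeChange": round(self.range_change, 3),
        }


def binarize(suitability: np.ndarray, threshold: float,
             scenario: str = "") -> BinaryMap:
    """Cut a 0-1000 suitability grid at ``threshold`` (>= -> 1); NaN kept."""
    if not 0 <= threshold <= 1000:
        raise ValueError("threshold must be in [0, 1000]")
    suit = np.asarray(suitability, dtype=float)
    grid = np.where(np.isfinite(suit), (suit >= threshold).astype(float), np.nan)
    return BinaryMap(grid, threshold, scenario)


def range_change_stats(current: BinaryMap,
                       future: BinaryMap) -> tuple[RangeChangeStats, np.ndarray]:
    """Cross-tabulate two binary maps into counts and a categorical map.

    The change map codes loss = -2, absent = -1, stable = 1, gain = 2
    (NaN at nodata); counts and map categories agree by construction.
    """
    if current.grid.shape != future.grid.shape:
        raise ValueError("current and future grids differ in shape")
    cur, fut = current.grid, future.grid
    if not np.array_equal(current.valid_mask, future.valid_mask):
        raise ValueError("current and future nodata masks differ")
    valid = current.valid_mask
    change = np.full(cur.shape, np.nan)
    change[valid & (cur == 1) & (fut == 0)] = LOSS
    change[valid & (cur == 0) & (fut == 0)] = ABSENT
    change[valid & (cur == 1) & (fut == 1)] = STABLE
    change[valid & (cur == 0) & (fut == 1)] = GAIN
    stats = RangeChangeStats(
        loss=int((change == LOSS).sum()), absent=int((change == ABSENT).sum()),
        stable=int((change == STABLE).sum()), gain=int((change == GAIN).sum()))
    return stats, change


def stats_from_counts(loss: int, absent: int, stable: int,
                      gain: int) -> RangeChangeStats:
    """Range-change statistics directly from pixel counts (no maps needed)."""
    if min(loss, absent, stable, gain) < 0:
        raise ValueError("pixel counts must be non-negative")
    return RangeChangeStats(int(loss), int(absent), int(stable), int(gain))


def stats_table(rows: list[tuple[str, str, RangeChangeStats]]) -> pd.DataFrame:
    """Assemble (scenario, ensemble_type, stats) triples into a report table."""
    return pd.DataFrame([s.as_row(sc, et) for sc, et, s in rows])
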