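"""Per-cell fluorescence screening and damage classification.

Group-level calibration means are formed from per-cell total gamma-H2AX
fluorescence after editing out cells with very high signal (> 3000 AU,
fragmented nuclear DNA of advanced-apoptotic cells).  Cells below 500 AU
are counted as "healthy or newly formed", above 3000 AU as "highly
damaged/dying"; both cutoffs are strict, so a value exactly at a cutoff is
intermediate.  Group means and SEMs are computed over per-animal means
(n = animals, not pooled cells), matching the resolution of the study's
error bars.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .model import GroupMeasurement

__all__ = [
    "APOPTOTIC_CUTOFF_AU",
    "HEALTHY_CUTOFF_AU",
    "CellSample",
    "DamageCounts",
    "GroupSummary",
    "filter_high_fluorescence",
    "classify_damage",
    "group_summary",
    "percent_variation",
]

#: Editing cutoff: cells with total fluorescence strictly above this are
#: excluded from means (fragmented DNA / advanced apoptosis).
APOPTOTIC_CUTOFF_AU = 3000.0
#: Cells strictly below this are counted as healthy / newly formed.
HEALTHY_CUTOFF_AU = 500.0


@dataclass(frozen=True)
class CellSample:
    """Per-cell fluorescence values for one animal's scored sample."""

    tissue: str  # "blood" or "spleen"
    activity: float  # group injected activity, MBq
    day: float
    cell_fluorescence: np.ndarray
    animal_id: str = ""
    plausible_counts: tuple[int, int] = (50, 2000)

    def __post_init__(self) -> None:
        values = np.asarray(self.cell_fluorescence, dtype=float)
        object.__setattr__(self, "cell_fluorescence", values)
        if self.tissue not in ("blood", "spleen"):
            raise ValueError("tissue must be 'blood' or 'spleen'")
        if np.any(values < 0):
            raise ValueError("cell fluorescence values must be non-negative")
        lo, hi = self.plausible_counts
        if not lo <= values.size <= hi:
            warnings.warn(
                f"sample has {values.size} cells, outside the plausible "
                f"band [{lo}, {hi}] (study norm ~150-500)"
            )

    @property
    def n_cells(self) -> int:
        return self.cell_fluorescence.size


def filter_high_fluorescence(
    sample: CellSample, cutoff: float = APOPTOTIC_CUTOFF_AU
) -> tuple[CellSample, int]:
    """Remove cells with fluorescence strictly above ``cutoff``.

    Returns the edited sample and the number of removed cells.  An emptied
    sample is returned as-is (0 cells); downstream means are undefined.
    """
    keep = sample.cell_fluorescence <= cutoff
    n_removed = int((~keep).sum())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # count-band warning re-check not useful here
        kept = replace(sample, cell_fluorescence=sample.cell_fluorescence[keep])
    if kept.n_cells == 0:
        warnings.warn("all cells removed by the high-fluorescence filter")
    return kept, n_removed


@dataclass(frozen=True)
class DamageCounts:
    """Healthy / intermediate / damaged cell counts and their ratios."""

    healthy: int
    intermediate: int
    damaged: int
    damaged_to_healthy: float
    healthy_to_damaged: float


def classify_damage(
    sample: CellSample,
    low_cutoff: float = HEALTHY_CUTOFF_AU,
    high_cutoff: float = APOPTOTIC_CUTOFF_AU,
) -> DamageCounts:
    """Count healthy (< low), damaged (> high) and intermediate cells.

    Both cutoffs are strict; ratios with a zero denominator are NaN.
    """
    if not low_cutoff < high_cutoff:
        raise ValueError("low_cutoff must be below high_cutoff")
    v = sample.cell_fluorescence
    healthy = int(np.sum(v < low_cutoff))
    damaged = int(np.sum(v > high_cutoff))
    intermediate = v.size - healthy - damaged
    return DamageCounts(
        healthy=healthy,
        intermediate=intermediate,
        damaged=damaged,
        damaged_to_healthy=damaged / healthy if healthy else math.nan,
        healthy_to_damaged=healthy / damaged if damaged else math.nan,
    )


@dataclass(frozen=True)
class GroupSummary:
    """Group-level mean fluorescence over per-animal means.

    ``sem`` is NaN (flagged undefined) for a single-animal group; use
    :meth:`to_measurement` to obtain a valid calibration point.
    """

    activity: float
    day: float
    mean_fluorescence: float
    sem: float
    n_animals: int
    mean_median_ratio: float
    n_cells_removed: int
    sem_defined: bool

    def to_measurement(self) -> GroupMeasurement:
        if not self.sem_defined:
            raise ValueError("SEM undefined for a single-animal group")
        return GroupMeasurement(
            activity=self.activity,
            time=self.day,
            mean_fluorescence=self.mean_fluorescence,
            sem=self.sem,
            n_animals=self.n_animals,
        )


def group_summary(
    samples: Sequence[CellSample], cutoff: float = APOPTOTIC_CUTOFF_AU
) -> GroupSummary:
    """Aggregate one (activity, day) group of per-animal samples.

    The high-fluorescence filter is applied to every sample first (the only
    path from cells to a calibration point), then per-animal means are
    averaged; SEM = SD/sqrt(n) over animals.  Also reports the pooled
    mean:median ratio of the filtered cells.
    """
    if not samples:
        raise ValueError("need at least one sample")
    activity = samples[0].activity
    day = samples[0].day
    if any(s.activity != activity or s.day != day for s in samples):
        raise ValueError("all samples must share the group's activity and day")
    means = []
    pooled = []
    n_removed = 0
    for s in samples:
        kept, removed = filter_high_fluorescence(s, cutoff)
        n_removed += removed
        if kept.n_cells == 0:
            raise ValueError(f"sample {s.animal_id!r} emptied by filtering")
        means.append(float(kept.cell_fluorescence.mean()))
        pooled.append(kept.cell_fluorescence)
    means = np.array(means)
    pooled = np.concatenate(pooled)
    n = means.size
    sem = float(means.std(ddof=1) / math.sqrt(n)) if n > 1 else math.nan
    pooled_median = float(np.median(pooled))
    return GroupSummary(
        activity=activity,
        day=day,
        mean_fluorescence=float(means.mean()),
        sem=sem,
        n_animals=n,
        mean_median_ratio=float(pooled.mean() / pooled_median) if pooled_median else math.nan,
        n_cells_removed=n_removed,
        sem_defined=n > 1,
    )


def percent_variation(values: Sequence[float]) -> float:
    """Percent spread of a set of group means: (max - min) / max * 100.

    The convention used to report variability between control group means
    (e.g. means of 1026 and 972 AU vary by 5.3%).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values")
    if v.max() <= 0:
        raise ValueError("values must be positive")
    return float((v.max() - v.min()) / v.max() * 100.0)
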