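"""Seeded synthetic-data generator emulating the mouse study design.

Reproduces the statistical structure the analysis assumes, so every stage
of the pipeline is testable without the original measurements: five groups
(four Cs-137 activities plus vehicle control), five necropsy days, eight
animals per data point, 150-500 scored cells per sample.  Three layers:

* group-mean fluorescence: per-animal means Gaussian around the kinetic
  model prediction, with the group SEM anchored to the measured control
  variability (~36 AU);
* whole-body retention: per-animal biexponential curves with log-normal
  inter-animal variability on the half-times, sampled on the study's
  counting days (daily to day 7, then days 10 and 14);
* per-cell fluorescence: a log-normal bulk calibrated so its post-filter
  mean hits the animal's target, plus a heavy apoptotic tail above the
  3000 AU editing cutoff (a fixture choice, not a measured distribution).

All randomness flows through one seeded generator per call.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
from scipy import optimize, stats

from .biokinetics import RetentionParams, RetentionSeries
from .cells import APOPTOTIC_CUTOFF_AU, CellSample
from .kinetics import H2AXParams, predict_fluorescence
from .model import GroupMeasurement
from .presets import (
    ANIMALS_PER_POINT,
    BLOOD_BACKGROUND_SEM_AU,
    NECROPSY_DAYS,
    STUDY_ACTIVITIES_MBQ,
)

__all__ = [
    "StudyDesign",
    "NoiseConfig",
    "StudyBundle",
    "generate_group_means",
    "generate_retention_curves",
    "generate_cells",
    "generate_full_study",
]

#: whole-body counting schedule: daily for the first week, then days 10, 14
COUNTING_DAYS = (1, 2, 3, 4, 5, 6, 7, 10, 14)


@dataclass(frozen=True)
class StudyDesign:
    """The experimental design grid."""

    activities: tuple[float, ...] = STUDY_ACTIVITIES_MBQ
    control_activity: float = 0.0
    necropsy_days: tuple[float, ...] = NECROPSY_DAYS
    animals_per_point: int = ANIMALS_PER_POINT
    cells_per_sample: tuple[int, int] = (150, 500)

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.activities):
            raise ValueError("exposed activities must be positive")
        if any(d <= 0 for d in self.necropsy_days):
            raise ValueError("necropsy days must be positive")
        if self.animals_per_point < 1:
            raise ValueError("animals_per_point must be >= 1")
        lo, hi = self.cells_per_sample
        if not 1 <= lo <= hi:
            raise ValueError("cells_per_sample must be an increasing positive range")


@dataclass(frozen=True)
class NoiseConfig:
    """Noise levels of the generated data.

    ``group_sem_scale`` is the target SEM of a group mean (AU), anchored to
    the measured control SEM; per-animal SD is sqrt(n) times it.
    ``retention_cv`` is the fractional inter-animal variability of the
    biological half-times.  The cell mixture is a log-normal bulk
    (``cell_sigma`` on the log scale) with an apoptotic tail of weight
    ``apoptotic_weight`` shifted above the editing cutoff.
    """

    group_sem_scale: float = BLOOD_BACKGROUND_SEM_AU
    retention_cv: float = 0.15
    cell_sigma: float = 0.5
    apoptotic_weight: float = 0.05
    apoptotic_meanlog: float = 7.0
    apoptotic_sigma: float = 0.5
    sem_floor: float = 1.0

    def __post_init__(self) -> None:
        if self.group_sem_scale < 0 or self.retention_cv < 0:
            raise ValueError("noise scales must be non-negative")
        if not 0 <= self.apoptotic_weight < 1:
            raise ValueError("apoptotic_weight must be in [0, 1)")
        if self.cell_sigma <= 0 or self.apoptotic_sigma <= 0 or self.sem_floor <= 0:
            raise ValueError("cell_sigma, apoptotic_sigma and sem_floor must be positive")


def _animal_means(
    design: StudyDesign,
    truth: H2AXParams,
    noise: NoiseConfig,
    rng: np.random.Generator,
    include_control: bool,
) -> list[tuple[float, float, np.ndarray]]:
    """Per-animal mean fluorescence draws for each (activity, day) point."""
    activities = list(design.activities) + (
        [design.control_activity] if include_control else []
    )
    n = design.animals_per_point
    sd = math.sqrt(n) * noise.group_sem_scale
    out = []
    for a in activities:
        for d in design.necropsy_days:
            mu = predict_fluorescence(truth, activity=a, time=d)
            out.append((a, d, mu + sd * rng.standard_normal(n)))
    return out


def _group_table(
    points: list[tuple[float, float, np.ndarray]], sem_floor: float
) -> list[GroupMeasurement]:
    table = []
    for a, d, means in points:
        n = means.size
        sem = means.std(ddof=1) / math.sqrt(n) if n > 1 else 0.0
        table.append(
            GroupMeasurement(
                activity=a,
                time=d,
                mean_fluorescence=float(means.mean()),
                sem=float(max(sem, sem_floor)),
                n_animals=n,
            )
        )
    return table


def generate_group_means(
    design: StudyDesign,
    truth: H2AXParams,
    noise: NoiseConfig,
    seed: int | np.random.Generator = 0,
    include_control: bool = False,
) -> list[GroupMeasurement]:
    """Group-mean calibration table: one measurement per (activity, day).

    With ``group_sem_scale = 0`` the means equal the model predictions
    exactly (the SEM floor keeps weights finite).
    """
    rng = np.random.default_rng(seed)
    return _group_table(
        _animal_means(design, truth, noise, rng, include_control), noise.sem_floor
    )


def generate_retention_curves(
    design: StudyDesign,
    params: RetentionParams = RetentionParams(),
    cv: float = 0.15,
    seed: int | np.random.Generator = 0,
) -> list[tuple[float, RetentionSeries]]:
    """Per-animal whole-body retention series on the counting schedule.

    Half-times vary log-normally between animals with fractional CV ``cv``
    (cv = 0 reproduces the group curve exactly); the fast/slow fractions
    are shared.  Returns (group activity, series) pairs.
    """
    from .biokinetics import retention_fraction

    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log1p(cv**2))
    days = np.array(COUNTING_DAYS, dtype=float)
    out = []
    for a in design.activities:
        for i in range(design.animals_per_point):
            if cv > 0:
                t_fast = params.halftime_fast * math.exp(
                    rng.normal(-0.5 * sigma**2, sigma)
                )
                t_slow = params.halftime_slow * math.exp(
                    rng.normal(-0.5 * sigma**2, sigma)
                )
                if t_fast >= t_slow:  # rare under realistic cv; keep ordering
                    t_fast = 0.99 * t_slow
                animal = RetentionParams(
                    params.fraction_fast, t_fast, params.fraction_slow, t_slow
                )
            else:
                animal = params
            series = RetentionSeries(
                animal_id=f"A{a:g}-m{i + 1:02d}",
                times=days,
                fractions=retention_fraction(animal, days),
            )
            out.append((a, series))
    return out


def _truncated_lognormal_mean(mu: float, sigma: float, cutoff: float) -> float:
    """E[X | X <= cutoff] for X ~ LogNormal(mu, sigma)."""
    zc = (math.log(cutoff) - mu) / sigma
    denom = stats.norm.cdf(zc)
    if denom <= 0:
        return 0.0
    return math.exp(mu + sigma**2 / 2) * stats.norm.cdf(zc - sigma) / denom


def generate_cells(
    target_mean: float,
    n_cells: int,
    noise: NoiseConfig = NoiseConfig(),
    seed: int | np.random.Generator = 0,
    tissue: str = "blood",
    activity: float = 0.0,
    day: float = 1.0,
    animal_id: str = "",
) -> CellSample:
    """One animal's per-cell sample whose post-filter mean targets
    ``target_mean`` in expectation.

    The bulk log-normal location is solved (1-D root find) so that the mean
    of bulk cells surviving the > 3000 AU filter equals the target; the
    apoptotic tail sits entirely above the cutoff and is removed by the
    filter.  Targets at or above the cutoff (or <= 0) are unattainable.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if not 0 < target_mean < 0.98 * APOPTOTIC_CUTOFF_AU:
        raise ValueError(
            f"target mean {target_mean} AU unattainable for a post-filter mean "
            f"(must lie in (0, {0.98 * APOPTOTIC_CUTOFF_AU:g}))"
        )
    sigma = noise.cell_sigma
    mu = optimize.brentq(
        lambda m: _truncated_lognormal_mean(m, sigma, APOPTOTIC_CUTOFF_AU) - target_mean,
        math.log(target_mean) - 10.0,
        math.log(APOPTOTIC_CUTOFF_AU) + 10.0 * sigma,
        xtol=1e-10,
    )
    rng = np.random.default_rng(seed)
    n_tail = rng.binomial(n_cells, noise.apoptotic_weight)
    # bulk sampled from the log-normal truncated below the editing cutoff
    # (inverse CDF), so the filter removes exactly the apoptotic tail and
    # the post-filter mean is calibrated to the target
    u_max = stats.norm.cdf((math.log(APOPTOTIC_CUTOFF_AU) - mu) / sigma)
    u = rng.uniform(0.0, u_max, n_cells - n_tail)
    bulk = np.exp(mu + sigma * stats.norm.ppf(u))
    tail = APOPTOTIC_CUTOFF_AU + np.exp(
        rng.normal(noise.apoptotic_meanlog, noise.apoptotic_sigma, n_tail)
    )
    values = np.concatenate([bulk, tail])
    rng.shuffle(values)
    return CellSample(
        tissue=tissue,
        activity=activity,
        day=day,
        cell_fluorescence=values,
        animal_id=animal_id,
    )


@dataclass
class StudyBundle:
    """A self-consistent synthetic study: all three data layers + manifest."""

    group_means: list[GroupMeasurement]
    retention: list[tuple[float, RetentionSeries]]
    cell_samples: list[CellSample]
    manifest: dict = field(default_factory=dict)

    def group_means_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "activity_mbq": [m.activity for m in self.group_means],
                "day": [m.time for m in self.group_means],
                "mean_fluorescence": [m.mean_fluorescence for m in self.group_means],
                "sem": [m.sem for m in self.group_means],
                "n": [m.n_animals for m in self.group_means],
            }
        )

    def retention_frame(self) -> pd.DataFrame:
        rows = []
        for activity, series in self.retention:
            for t, f in zip(series.times, series.fractions):
                rows.append(
                    {
                        "animal_id": series.animal_id,
                        "group_activity_mbq": activity,
                        "day": t,
                        "fraction_retained": f,
                    }
                )
        return pd.DataFrame(rows)

    def cells_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.cell_samples:
            for v in s.cell_fluorescence:
                rows.append(
                    {
                        "tissue": s.tissue,
                        "animal_id": s.animal_id,
                        "activity_mbq": s.activity,
                        "day": s.day,
                        "cell_fluorescence": v,
                    }
                )
        return pd.DataFrame(rows)

    def to_csvs(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "group_means": outdir / "group_means.csv",
            "retention": outdir / "retention.csv",
            "cells": outdir / "cells.csv",
            "manifest": outdir / "manifest.json",
        }
        self.group_means_frame().to_csv(paths["group_means"], index=False)
        self.retention_frame().to_csv(paths["retention"], index=False)
        self.cells_frame().to_csv(paths["cells"], index=False)
        paths["manifest"].write_text(json.dumps(self.manifest, indent=2, sort_keys=True))
        return paths


def generate_full_study(
    design: StudyDesign = StudyDesign(),
    truth: H2AXParams | None = None,
    retention_params: RetentionParams = RetentionParams(),
    noise: NoiseConfig = NoiseConfig(),
    seed: int = 0,
    with_cells: bool = True,
    include_control: bool = True,
) -> StudyBundle:
    """Compose the three generators into one self-consistent bundle.

    The group-mean table is computed from the same per-animal means the
    cell samples are targeted at, so cell-level aggregation reproduces it
    up to per-cell Monte-Carlo error.
    """
    from .presets import BLOOD_BESTFIT

    if truth is None:
        truth = BLOOD_BESTFIT
    root = np.random.SeedSequence(seed)
    rng_means, rng_ret, rng_cells = (np.random.default_rng(s) for s in root.spawn(3))

    points = _animal_means(design, truth, noise, rng_means, include_control)
    group_means = _group_table(points, noise.sem_floor)
    retention = generate_retention_curves(design, retention_params, noise.retention_cv, rng_ret)

    cell_samples: list[CellSample] = []
    if with_cells:
        lo, hi = design.cells_per_sample
        for a, d, means in points:
            for i, m in enumerate(means):
                n_cells = int(rng_cells.integers(lo, hi + 1))
                target = float(np.clip(m, 1.0, 0.97 * APOPTOTIC_CUTOFF_AU))
                cell_samples.append(
                    generate_cells(
                        target,
                        n_cells,
                        noise,
                        seed=rng_cells,
                        tissue="blood",
                        activity=a,
                        day=d,
                        animal_id=f"A{a:g}-d{d:g}-m{i + 1:02d}",
                    )
                )

    manifest = {
        "seed": seed,
        "design": asdict(design),
        "truth": {n: getattr(truth, n) for n in ("b", "k", "alpha", "r", "p")},
        "retention_params": asdict(retention_params),
        "noise": asdict(noise),
        "include_control": include_control,
        "with_cells": with_cells,
    }
    return StudyBundle(
        group_means=group_means,
        retention=retention,
        cell_samples=cell_samples,
        manifest=manifest,
    )
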