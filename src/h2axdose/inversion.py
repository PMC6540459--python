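"""Monte-Carlo biodosimetry: inverting fluorescence into injected activity.

The fitted kinetic model serves as a calibration curve.  Uncertainty in the
calibration is propagated by drawing >= 5000 parameter combinations psi_i
from the joint 95% confidence region of the fit; for each draw and each
measured point (t_j, F_j) the injected activity A_ij is the minimiser of

    f_ij = [ F(psi_i, t_j, A_ij) - F_j ]^2 .

Because F - b = k*t*exp(1 - (1+rt)^p) * A*exp(-alpha*A) is separable, the
minimiser solves A*exp(-alpha*A) = C and has the closed form

    alpha*A = -W(-alpha*C)

with the principal Lambert-W branch giving the rising limb (A < 1/alpha)
and the W_{-1} branch the falling limb (A > 1/alpha), on which all study
activities lie.  Fluorescence above the model's ceiling (A = 1/alpha) is
flagged as saturated; fluorescence at/below background or beyond the search
interval is flagged out of range.  Per-point medians/ranges over the
ensemble are then scored against true activities by Pearson/Spearman
correlation over time windows, converted to dose via measured per-day
coefficients, and assessed as a low/high activity classifier by ROC
analysis with a DeLong AUC confidence interval.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.metrics import roc_curve

from .kinetics import H2AXParams
from .model import FREE_PARAM_NAMES, H2AXKineticsResults
from .presets import mean_dose_coefficients

__all__ = [
    "ParameterEnsemble",
    "ActivityEstimate",
    "ClassificationResult",
    "sample_confidence_region",
    "estimate_activity",
    "estimate_activity_batch",
    "summarize_estimates",
    "correlation_report",
    "activity_to_dose",
    "classify_and_roc",
    "delong_auc_variance",
]

DEFAULT_SEARCH_MBQ = (0.1, 20.0)

FLAG_OK = "ok"
FLAG_OUT_OF_RANGE = "out_of_range"
FLAG_SATURATED = "saturated"


@dataclass
class ParameterEnsemble:
    """Parameter combinations inside the joint confidence region.

    Stored column-wise for vectorised inversion; ``draw(i)`` materialises
    one :class:`H2AXParams`.
    """

    background: float
    k: np.ndarray
    alpha: np.ndarray
    r: np.ndarray
    p: np.ndarray
    seed: int | None
    proposal_scale: np.ndarray
    acceptance_rate: float
    level: float = 0.95
    df: int = 4

    @property
    def n_draws(self) -> int:
        return self.k.size

    def draw(self, i: int) -> H2AXParams:
        return H2AXParams(
            b=self.background,
            k=float(self.k[i]),
            alpha=float(self.alpha[i]),
            r=float(self.r[i]),
            p=float(self.p[i]),
        )

    def __iter__(self):
        return (self.draw(i) for i in range(self.n_draws))


def sample_confidence_region(
    fit: H2AXKineticsResults,
    n_min: int = 5000,
    seed: int | None = None,
    level: float = 0.95,
    df: int = 4,
    proposal_scale: np.ndarray | None = None,
    batch_size: int = 4000,
    min_acceptance: float = 1e-4,
) -> ParameterEnsemble:
    """Rejection-sample >= ``n_min`` parameter draws from the confidence region.

    Proposals perturb the best fit independently per parameter: log-normal
    for k, alpha, r and logit-normal for p (which must stay in (0,1)).  The
    proposal scale defaults to the profile-CI half-widths on the transformed
    scale, inflated to the joint-region radius; draws are accepted iff their
    deviance is within the chi-square(df) quantile.  Aborts if the
    acceptance rate falls below ``min_acceptance``.
    """
    if not fit.converged:
        raise RuntimeError("confidence-region sampling requires a converged fit")
    model = fit.model
    threshold = stats.chi2.ppf(level, df=df)
    if proposal_scale is None:
        inflate = math.sqrt(stats.chi2.ppf(level, df) / stats.chi2.ppf(level, 1))
        scales = []
        for name in FREE_PARAM_NAMES:
            ci = fit.profile_ci(name, level)
            if ci.open_low or ci.open_high:
                scales.append(0.5)  # fallback width for an unbounded profile
                continue
            if name == "p":
                z_lo, z_hi = (math.log(v / (1 - v)) for v in (ci.low, ci.high))
            else:
                z_lo, z_hi = math.log(ci.low), math.log(ci.high)
            scales.append(inflate * (z_hi - z_lo) / (2 * 1.96))
        proposal_scale = np.array(scales)
    proposal_scale = np.asarray(proposal_scale, dtype=float)

    rng = np.random.default_rng(seed)
    z0 = fit.z_opt
    accepted = [z0[None, :]]  # the best fit itself is trivially a member
    n_acc, n_prop = 1, 1
    while n_acc < n_min:
        z = z0[None, :] + rng.standard_normal((batch_size, 4)) * proposal_scale[None, :]
        k = np.exp(z[:, 0])
        alpha = np.exp(z[:, 1])
        r = np.exp(z[:, 2])
        p = 1.0 / (1.0 + np.exp(-z[:, 3]))
        dev = 2.0 * (model.nloglike_free(k, alpha, r, p) - fit.nll)
        keep = dev <= threshold
        accepted.append(z[keep])
        n_acc += int(keep.sum())
        n_prop += batch_size
        if n_prop > 10 * batch_size and n_acc / n_prop < min_acceptance:
            raise RuntimeError(
                f"confidence-region acceptance rate {n_acc / n_prop:.2e} below "
                f"{min_acceptance:.0e}; proposal scale {proposal_scale} is too wide"
            )
    z_all = np.concatenate(accepted, axis=0)[:n_min]
    return ParameterEnsemble(
        background=model.background,
        k=np.exp(z_all[:, 0]),
        alpha=np.exp(z_all[:, 1]),
        r=np.exp(z_all[:, 2]),
        p=1.0 / (1.0 + np.exp(-z_all[:, 3])),
        seed=seed,
        proposal_scale=proposal_scale,
        acceptance_rate=n_acc / n_prop,
        level=level,
        df=df,
    )


# ---------------------------------------------------------------------------
# Activity inversion
# ---------------------------------------------------------------------------


def _time_factor(k, r, p, time):
    """k * t * exp(1 - (1+rt)^p), the activity-independent signal factor."""
    with np.errstate(over="ignore", under="ignore"):
        return k * time * np.exp(1.0 - np.exp(p * np.log1p(r * time)))


def estimate_activity_batch(
    k: np.ndarray,
    alpha: np.ndarray,
    r: np.ndarray,
    p: np.ndarray,
    background: float,
    time: float,
    fluorescence: float,
    search: tuple[float, float] = DEFAULT_SEARCH_MBQ,
    branch: str = "high",
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised closed-form inversion for arrays of parameter draws.

    Returns ``(activities, flags)`` where flags take values "ok",
    "out_of_range" (target fluorescence unreachable inside the branch and
    search interval; boundary returned) and "saturated" (fluorescence above
    the response ceiling at A = 1/alpha; 1/alpha returned).
    """
    if branch not in ("low", "high", "global"):
        raise ValueError("branch must be 'low', 'high' or 'global'")
    lo, hi = search
    if not (0 < lo < hi):
        raise ValueError("search interval must be positive and increasing")
    if time <= 0:
        raise ValueError("time must be positive")
    k, alpha, r, p = np.broadcast_arrays(
        np.atleast_1d(np.asarray(k, dtype=float)),
        np.atleast_1d(np.asarray(alpha, dtype=float)),
        np.atleast_1d(np.asarray(r, dtype=float)),
        np.atleast_1d(np.asarray(p, dtype=float)),
    )
    n = k.size
    target = fluorescence - background
    flags = np.full(n, FLAG_OK, dtype=object)
    a_peak = 1.0 / alpha

    if target <= 0:
        # background-level signal: no positive activity reproduces it; the
        # squared deviation is minimised at the branch's far boundary
        out = np.full(n, hi if branch in ("high", "global") else lo)
        flags[:] = FLAG_OUT_OF_RANGE
        return out, flags

    c = target / _time_factor(k, r, p, time)  # solve A*exp(-alpha*A) = c
    arg = -alpha * c
    saturated = arg < -1.0 / math.e  # above the ceiling g(1/alpha)

    def _root(branch_id: int) -> np.ndarray:
        with np.errstate(all="ignore"):
            w = special.lambertw(np.where(saturated, -1.0 / math.e, arg), k=branch_id)
        return np.real(w) / -alpha

    def _clip_flag(a: np.ndarray, dom_lo: np.ndarray, dom_hi: np.ndarray, fl: np.ndarray):
        below, above = a < dom_lo, a > dom_hi
        a = np.clip(a, dom_lo, dom_hi)
        fl = fl.copy()
        fl[(below | above) & (fl == FLAG_OK)] = FLAG_OUT_OF_RANGE
        return a, fl

    base_flags = flags.copy()
    base_flags[saturated] = FLAG_SATURATED

    if branch in ("high", "global"):
        a_high = _root(-1)
        a_high = np.where(saturated, a_peak, a_high)
        dom_lo, dom_hi = np.maximum(lo, a_peak), np.full(n, hi)
        bad = dom_lo > dom_hi  # falling limb entirely outside search range
        a_high, fl_high = _clip_flag(a_high, np.minimum(dom_lo, dom_hi), dom_hi, base_flags)
        fl_high[bad] = FLAG_OUT_OF_RANGE
    if branch in ("low", "global"):
        a_low = _root(0)
        a_low = np.where(saturated, a_peak, a_low)
        dom_lo, dom_hi = np.full(n, lo), np.minimum(hi, a_peak)
        bad = dom_lo > dom_hi
        a_low, fl_low = _clip_flag(a_low, dom_lo, np.maximum(dom_lo, dom_hi), base_flags)
        fl_low[bad] = FLAG_OUT_OF_RANGE

    if branch == "high":
        return a_high, fl_high
    if branch == "low":
        return a_low, fl_low
    # global: smaller squared deviation wins, ties go to the high branch
    f_high = (_time_factor(k, r, p, time) * a_high * np.exp(-alpha * a_high) - target) ** 2
    f_low = (_time_factor(k, r, p, time) * a_low * np.exp(-alpha * a_low) - target) ** 2
    pick_low = f_low < f_high
    out = np.where(pick_low, a_low, a_high)
    flags = np.where(pick_low, fl_low, fl_high)
    return out, flags


def estimate_activity(
    psi: H2AXParams,
    time: float,
    fluorescence: float,
    search: tuple[float, float] = DEFAULT_SEARCH_MBQ,
    branch: str = "high",
) -> tuple[float, str]:
    """Injected activity (MBq) whose predicted fluorescence matches a
    measurement, for one parameter combination.  Returns (activity, flag)."""
    a, fl = estimate_activity_batch(
        psi.k, psi.alpha, psi.r, psi.p, psi.b, time, fluorescence, search, branch
    )
    return float(a[0]), str(fl[0])


@dataclass
class ActivityEstimate:
    """Reconstructed activity for one measured point, over the ensemble."""

    time: float
    measured_fluorescence: float
    median_activity: float
    min_activity: float
    max_activity: float
    true_activity: float | None = None
    n_used: int = 0
    n_flagged: int = 0
    undefined: bool = False
    draws: np.ndarray | None = field(default=None, repr=False)


def summarize_estimates(
    ensemble: ParameterEnsemble,
    points: Iterable,
    search: tuple[float, float] = DEFAULT_SEARCH_MBQ,
    branch: str = "high",
    keep_draws: bool = False,
) -> list[ActivityEstimate]:
    """Median/min/max reconstructed activity per measured point.

    ``points`` is an iterable of (time, fluorescence[, true_activity])
    tuples or a DataFrame with columns day, mean_fluorescence[,
    activity_mbq].  Flagged (out-of-range/saturated) draws are excluded
    from the summary; their count is reported.  A point where every draw is
    flagged is marked undefined.
    """
    if isinstance(points, pd.DataFrame):
        cols = ["day", "mean_fluorescence"]
        recs = []
        for row in points.itertuples():
            true_a = getattr(row, "activity_mbq", None)
            recs.append((float(row.day), float(row.mean_fluorescence), true_a))
        points = recs
    out = []
    for point in points:
        t, fl = float(point[0]), float(point[1])
        true_a = float(point[2]) if len(point) > 2 and point[2] is not None else None
        a, flags = estimate_activity_batch(
            ensemble.k,
            ensemble.alpha,
            ensemble.r,
            ensemble.p,
            ensemble.background,
            t,
            fl,
            search,
            branch,
        )
        ok = flags == FLAG_OK
        n_flagged = int((~ok).sum())
        if not np.any(ok):
            out.append(
                ActivityEstimate(
                    time=t,
                    measured_fluorescence=fl,
                    median_activity=math.nan,
                    min_activity=math.nan,
                    max_activity=math.nan,
                    true_activity=true_a,
                    n_used=0,
                    n_flagged=n_flagged,
                    undefined=True,
                    draws=a if keep_draws else None,
                )
            )
            continue
        used = a[ok]
        out.append(
            ActivityEstimate(
                time=t,
                measured_fluorescence=fl,
                median_activity=float(np.median(used)),
                min_activity=float(used.min()),
                max_activity=float(used.max()),
                true_activity=true_a,
                n_used=int(ok.sum()),
                n_flagged=n_flagged,
                draws=a if keep_draws else None,
            )
        )
    return out


def estimates_to_frame(estimates: Sequence[ActivityEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "day": [e.time for e in estimates],
            "mean_fluorescence": [e.measured_fluorescence for e in estimates],
            "median_activity_mbq": [e.median_activity for e in estimates],
            "min_activity_mbq": [e.min_activity for e in estimates],
            "max_activity_mbq": [e.max_activity for e in estimates],
            "true_activity_mbq": [e.true_activity for e in estimates],
            "n_used": [e.n_used for e in estimates],
            "n_flagged": [e.n_flagged for e in estimates],
            "undefined": [e.undefined for e in estimates],
        }
    )


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


def _spearman_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact permutation p-value for Spearman's rho (small n)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = x.size
    rho_obs = np.corrcoef(rx, ry)[0, 1]
    perms = np.array(list(itertools.permutations(range(n))))
    ry_perm = ry[perms]
    rx_c = rx - rx.mean()
    denom = math.sqrt(float(rx_c @ rx_c))
    ry_c = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    rho = (ry_c @ rx_c) / (denom * np.sqrt(np.sum(ry_c**2, axis=1)))
    return float(np.mean(np.abs(rho) >= abs(rho_obs) - 1e-12))


def correlation_report(
    estimates: Sequence[ActivityEstimate],
    time_ranges: Sequence[tuple[float, float]] = ((2, 3), (2, 5), (2, 7), (2, 14)),
    exact_spearman_max_n: int = 9,
) -> pd.DataFrame:
    """Pearson/Spearman correlation of true vs median-estimated activity
    within each time window (inclusive bounds).

    Pearson p-values come from the t distribution with n-2 df; Spearman
    p-values are exact (full permutation) for n <= ``exact_spearman_max_n``
    and t-approximate otherwise.  Windows with fewer than 3 usable points
    or zero variance are flagged undefined (NaN).
    """
    rows = []
    for d_lo, d_hi in time_ranges:
        pts = [
            e
            for e in estimates
            if d_lo <= e.time <= d_hi
            and not e.undefined
            and e.true_activity is not None
        ]
        label = f"{d_lo:g}-{d_hi:g} days"
        x = np.array([e.true_activity for e in pts])
        y = np.array([e.median_activity for e in pts])
        if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append(
                {
                    "time_range": label,
                    "n": x.size,
                    "pearson_r": np.nan,
                    "pearson_p": np.nan,
                    "spearman_rho": np.nan,
                    "spearman_p": np.nan,
                    "undefined": True,
                }
            )
            continue
        pr = stats.pearsonr(x, y)
        sr = stats.spearmanr(x, y)
        if x.size <= exact_spearman_max_n:
            sp = _spearman_exact_p(x, y)
        else:
            sp = float(sr.pvalue)
        rows.append(
            {
                "time_range": label,
                "n": x.size,
                "pearson_r": float(pr.statistic),
                "pearson_p": float(pr.pvalue),
                "spearman_rho": float(sr.statistic),
                "spearman_p": sp,
                "undefined": False,
            }
        )
    return pd.DataFrame(rows)


def activity_to_dose(
    activity_mbq,
    day,
    coefficient_table: dict[int, float] | None = None,
    interpolate: bool = False,
):
    """Whole-body committed dose (Gy) for an activity estimate at a given day.

    Uses the per-day mean dose coefficients derived from the measured
    committed doses (Gy per MBq injected).  Days outside the measurement
    grid raise unless ``interpolate=True`` (linear between grid days).
    """
    table = coefficient_table if coefficient_table is not None else mean_dose_coefficients()
    activity_mbq = np.asarray(activity_mbq, dtype=float)
    if np.any(activity_mbq < 0):
        raise ValueError("activity must be non-negative")
    if day in table:
        coeff = table[day]
    elif interpolate:
        days = np.array(sorted(table))
        if not days[0] <= day <= days[-1]:
            raise ValueError(f"day {day} outside the coefficient grid {days.tolist()}")
        coeff = float(np.interp(day, days, [table[d] for d in days]))
    else:
        raise ValueError(
            f"day {day} not in coefficient grid {sorted(table)}; "
            "pass interpolate=True to interpolate"
        )
    out = activity_mbq * coeff
    return out if out.ndim else float(out)


@dataclass
class ClassificationResult:
    """Low/high activity discrimination of normalised activity estimates."""

    scores: np.ndarray
    labels: np.ndarray  # 1 = high, 0 = low
    roc_points: np.ndarray  # (FPR, TPR) pairs
    auc: float
    auc_ci: tuple[float, float]


def delong_auc_variance(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """DeLong estimate of the AUC and its sampling variance.

    Uses the structural-components form: with midrank-based placement
    values V10 (positives) and V01 (negatives),
    var = var(V10)/m + var(V01)/n.
    """
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise ValueError("both classes must be non-empty")
    # placement values via midranks (ties count 1/2)
    v10 = np.empty(m)
    for i, s in enumerate(pos):
        v10[i] = (np.sum(s > neg) + 0.5 * np.sum(s == neg)) / n
    v01 = np.empty(n)
    for j, s in enumerate(neg):
        v01[j] = (np.sum(pos > s) + 0.5 * np.sum(pos == s)) / m
    auc = float(v10.mean())
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    return auc, float(var)


def classify_and_roc(
    estimates: Sequence[ActivityEstimate],
    low_set: Sequence[float] = (5.74, 6.66),
    high_set: Sequence[float] = (7.65, 9.28),
    level: float = 0.95,
) -> ClassificationResult:
    """ROC analysis of low vs high injected activity.

    Scores are the median activity estimates normalised to [0, 1] by the
    maximum over all points; labels come from the true activities.  The
    reported AUC uses the Mann-Whitney identity (ties counted 1/2); the ROC
    curve is the empirical threshold sweep; the CI is the DeLong normal
    approximation truncated to [0, 1].
    """
    pts = [e for e in estimates if not e.undefined and e.true_activity is not None]
    labels = []
    medians = []
    for e in pts:
        if any(np.isclose(e.true_activity, a) for a in high_set):
            labels.append(1)
        elif any(np.isclose(e.true_activity, a) for a in low_set):
            labels.append(0)
        else:
            continue
        medians.append(e.median_activity)
    labels = np.array(labels, dtype=int)
    medians = np.array(medians, dtype=float)
    if labels.size == 0 or labels.min() == labels.max():
        raise ValueError("need points from both the low and the high class")
    scores = medians / medians.max()
    auc, var = delong_auc_variance(scores, labels)
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * math.sqrt(var)
    ci = (max(0.0, auc - half), min(1.0, auc + half))
    fpr, tpr, _ = roc_curve(labels, scores)
    return ClassificationResult(
        scores=scores,
        labels=labels,
        roc_points=np.column_stack([fpr, tpr]),
        auc=auc,
        auc_ci=ci,
    )
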