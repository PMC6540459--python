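"""Weighted maximum-likelihood fitting of the fluorescence kinetics model.

The likelihood is defined at the group-mean level: each calibration point j
is the mean fluorescence F_j of one (activity, day) group of animals, with
standard error sem_j, modelled as Gaussian around the kinetic model
prediction with standard deviation sem_j (weights 1/sem_j^2):

    -log L = sum_j [ (F_j - Fhat_j)^2 / (2 sem_j^2) + log sem_j
                     + 0.5 log(2 pi) ]

The background ``b`` is fixed at the measured control level; the four free
parameters (k, alpha, r, p) are optimised on transformed scales (log for
the positive parameters, logit for p in (0,1)) with seeded multistart.
Parameter uncertainty uses profile likelihood: the 95% CI of one parameter
is where its profile deviance 2*(NLL_profile - NLL_best) crosses the
chi-square(1) quantile 3.841; the joint 95% region used for Monte-Carlo
uncertainty propagation uses the chi-square(4) quantile 9.488.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .kinetics import H2AXParams

__all__ = [
    "FREE_PARAM_NAMES",
    "GroupMeasurement",
    "ProfileCI",
    "H2AXKineticsModel",
    "H2AXKineticsResults",
    "measurements_from_dataframe",
    "fit_model",
]

FREE_PARAM_NAMES = ("k", "alpha", "r", "p")


@dataclass(frozen=True)
class GroupMeasurement:
    """One calibration data point: a group-mean fluorescence measurement."""

    activity: float  # injected activity, MBq
    time: float  # days post injection
    mean_fluorescence: float  # AU
    sem: float  # AU, standard error of the group mean
    n_animals: int

    def __post_init__(self) -> None:
        if not self.sem > 0:
            raise ValueError("sem must be positive")
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        if not self.time > 0:
            raise ValueError("time must be positive")
        if self.activity < 0:
            raise ValueError("activity must be non-negative")


def measurements_from_dataframe(df: pd.DataFrame) -> list[GroupMeasurement]:
    """Build measurements from a table with the calibration CSV schema.

    Expected columns: activity_mbq, day, mean_fluorescence, sem, n.
    """
    required = {"activity_mbq", "day", "mean_fluorescence", "sem", "n"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    return [
        GroupMeasurement(
            activity=float(row.activity_mbq),
            time=float(row.day),
            mean_fluorescence=float(row.mean_fluorescence),
            sem=float(row.sem),
            n_animals=int(row.n),
        )
        for row in df.itertuples()
    ]


class ProfileCI(NamedTuple):
    """A profile-likelihood confidence interval; open ends are flagged."""

    low: float
    high: float
    open_low: bool = False
    open_high: bool = False


def _logit(x: float) -> float:
    return math.log(x / (1.0 - x))


def _expit(x) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def _minimize_nm(fun, x0, **options):
    """Nelder-Mead with warnings from +inf simplex vertices silenced."""
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return optimize.minimize(fun, x0, method="Nelder-Mead", options=options)


#: default multistart sampling bounds on the natural scale
DEFAULT_START_BOUNDS = {
    "k": (1e3, 1e8),
    "alpha": (1e-3, 10.0),
    "r": (1e2, 1e10),
    "p": (0.03, 0.9),
}


class H2AXKineticsModel:
    """Kinetic fluorescence model bound to group-level calibration data.

    Parameters
    ----------
    data : sequence of GroupMeasurement or DataFrame
        Calibration measurements (a DataFrame must follow the CSV schema of
        :func:`measurements_from_dataframe`).
    background : float
        Fixed background fluorescence ``b`` (AU), the measured control
        level; not estimated.
    """

    def __init__(self, data, background: float):
        if isinstance(data, pd.DataFrame):
            data = measurements_from_dataframe(data)
        data = list(data)
        if not data:
            raise ValueError("no calibration data")
        if background <= 0:
            raise ValueError("background must be positive")
        self.data: list[GroupMeasurement] = data
        self.background = float(background)
        # sort once so the fit is invariant to input row order
        order = np.lexsort(
            (
                [m.mean_fluorescence for m in data],
                [m.time for m in data],
                [m.activity for m in data],
            )
        )
        self._activity = np.array([data[i].activity for i in order])
        self._time = np.array([data[i].time for i in order])
        self._fluor = np.array([data[i].mean_fluorescence for i in order])
        self._sem = np.array([data[i].sem for i in order])
        m = self._sem.size
        self._nll_const = float(np.sum(np.log(self._sem)) + 0.5 * m * math.log(2 * math.pi))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, background: float) -> "H2AXKineticsModel":
        return cls(df, background)

    @classmethod
    def from_csv(cls, path, background: float) -> "H2AXKineticsModel":
        return cls(pd.read_csv(path), background)

    # -- likelihood ---------------------------------------------------------

    def predictions_free(self, k, alpha, r, p) -> np.ndarray:
        """Model predictions for arrays of free parameters (vectorised).

        Each of k, alpha, r, p may be a scalar or a 1-D array of draws;
        returns shape (n_draws, n_points) (or (n_points,) for scalars).
        """
        k, alpha, r, p = np.broadcast_arrays(
            np.atleast_1d(np.asarray(k, dtype=float)),
            np.atleast_1d(np.asarray(alpha, dtype=float)),
            np.atleast_1d(np.asarray(r, dtype=float)),
            np.atleast_1d(np.asarray(p, dtype=float)),
        )
        A, t = self._activity[None, :], self._time[None, :]
        kk, aa = k[:, None], alpha[:, None]
        rr, pp = r[:, None], p[:, None]
        with np.errstate(over="ignore", under="ignore"):
            log_sig = (
                np.log(kk)
                + np.log(np.where(A > 0, A, 1.0))
                + np.log(t)
                - aa * A
                + 1.0
                - np.exp(pp * np.log1p(rr * t))
            )
            sig = np.where(A > 0, np.exp(log_sig), 0.0)
        return self.background + sig

    def nloglike_free(self, k, alpha, r, p) -> np.ndarray:
        """Negative log likelihood for (arrays of) free-parameter draws."""
        pred = self.predictions_free(k, alpha, r, p)
        resid = pred - self._fluor[None, :]
        nll = np.sum(resid**2 / (2.0 * self._sem[None, :] ** 2), axis=1) + self._nll_const
        nll = np.where(np.isfinite(nll), nll, np.inf)
        return nll

    def nloglike(self, params: H2AXParams) -> float:
        """Negative log likelihood of a full parameter set (b ignored if it
        differs from the model's fixed background only through rounding)."""
        return float(self.nloglike_free(params.k, params.alpha, params.r, params.p)[0])

    def weighted_ssr(self, params: H2AXParams) -> float:
        pred = self.predictions_free(params.k, params.alpha, params.r, params.p)[0]
        return float(np.sum((pred - self._fluor) ** 2 / self._sem**2))

    # -- transforms ---------------------------------------------------------

    @staticmethod
    def _z_from_free(k: float, alpha: float, r: float, p: float) -> np.ndarray:
        return np.array([math.log(k), math.log(alpha), math.log(r), _logit(p)])

    @staticmethod
    def _free_from_z(z: np.ndarray) -> tuple[float, float, float, float]:
        return (
            float(np.exp(z[0])),
            float(np.exp(z[1])),
            float(np.exp(z[2])),
            # keep p strictly inside (0, 1) even when the optimiser walks to
            # the logit boundary (expit would round to exactly 0 or 1)
            float(np.clip(_expit(z[3]), 1e-12, 1.0 - 1e-12)),
        )

    def _nll_z(self, z: np.ndarray) -> float:
        if not np.all(np.isfinite(z)) or np.any(np.abs(z) > 60):
            return np.inf
        return float(self.nloglike_free(*self._free_from_z(z))[0])

    # -- fitting ------------------------------------------------------------

    def _check_design(self) -> None:
        exposed = self._activity > 0
        if self._activity.size < 5:
            raise ValueError("need at least 5 calibration points")
        if np.unique(self._activity[exposed]).size < 2:
            raise ValueError(
                "calibration data span a single activity: k and alpha are not "
                "jointly identifiable (g(A) = k*A*exp(-alpha*A) collapses to "
                "one degree of freedom); provide at least two activities"
            )
        if np.unique(self._time).size < 2:
            raise ValueError(
                "calibration data span a single time: r and p are not "
                "identifiable; provide at least two times"
            )

    def fit(
        self,
        n_starts: int = 20,
        seed: int = 0,
        start_bounds: dict | None = None,
        x0: H2AXParams | None = None,
    ) -> "H2AXKineticsResults":
        """Maximum-likelihood fit of (k, alpha, r, p) with b fixed.

        Multistart: ``n_starts`` initial points drawn log-uniformly (p:
        uniform) within ``start_bounds``, each optimised by Nelder-Mead and
        polished by BFGS; the lowest NLL wins, ties broken by the
        lexicographically smaller parameter vector.  ``x0`` adds one
        user-chosen start.
        """
        self._check_design()
        bounds = dict(DEFAULT_START_BOUNDS)
        if start_bounds:
            bounds.update(start_bounds)
        rng = np.random.default_rng(seed)

        starts: list[np.ndarray] = []
        if x0 is not None:
            starts.append(self._z_from_free(x0.k, x0.alpha, x0.r, x0.p))
        for _ in range(n_starts):
            zk = rng.uniform(*np.log(bounds["k"]))
            za = rng.uniform(*np.log(bounds["alpha"]))
            p0 = rng.uniform(*bounds["p"])
            # sample the decay scale s = r**p (not r itself): most of the
            # (r, p) plane has r**p so large the signal underflows to zero
            # and the likelihood is flat there, which starves the multistart
            s0 = math.exp(rng.uniform(math.log(0.3), math.log(50.0)))
            zr = float(np.clip(math.log(s0) / p0, *np.log(bounds["r"])))
            starts.append(np.array([zk, za, zr, _logit(p0)]))

        best: tuple | None = None
        diagnostics = []
        for z0 in starts:
            nll0 = self._nll_z(z0)
            res = _minimize_nm(
                self._nll_z, z0,
                xatol=1e-10, fatol=1e-12, maxiter=4000, maxfev=6000,
            )
            cand, ok = res, bool(res.success)
            if np.isfinite(res.fun):
                with np.errstate(all="ignore"), warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    polish = optimize.minimize(self._nll_z, res.x, method="BFGS")
                if (
                    np.all(np.isfinite(polish.x))
                    and np.isfinite(polish.fun)
                    and polish.fun <= res.fun
                ):
                    cand, ok = polish, bool(res.success or polish.success)
            diagnostics.append(
                {"start_nll": nll0, "final_nll": float(cand.fun), "success": ok}
            )
            key = (float(cand.fun), tuple(np.round(cand.x, 12)))
            if best is None or key < best[0]:
                best = (key, cand, ok)
        if best is None or not np.isfinite(best[1].fun):
            raise RuntimeError(
                "all multistarts failed to produce a finite likelihood; "
                f"per-start diagnostics: {diagnostics}"
            )
        # final refinement from the winning start; convergence means this
        # polish terminates normally or can no longer improve the NLL
        final = _minimize_nm(
            self._nll_z, best[1].x,
            xatol=1e-10, fatol=1e-12, maxiter=4000, maxfev=6000,
        )
        sol = final if final.fun <= best[1].fun else best[1]
        sol_ok = bool(
            best[2] or final.success or (best[1].fun - final.fun) < 1e-8
        )
        k, alpha, r, p = self._free_from_z(sol.x)
        params = H2AXParams(b=self.background, k=k, alpha=alpha, r=r, p=p)
        hess = self._numeric_hessian(sol.x)
        with np.errstate(all="ignore"):
            cond = (
                float(np.linalg.cond(hess)) if np.all(np.isfinite(hess)) else math.inf
            )
        return H2AXKineticsResults(
            model=self,
            params=params,
            z_opt=np.asarray(sol.x, dtype=float),
            nll=float(sol.fun),
            converged=sol_ok,
            n_starts=len(starts),
            start_diagnostics=diagnostics,
            hessian_cond=cond,
        )

    def _numeric_hessian(self, z: np.ndarray, eps: float = 1e-4) -> np.ndarray:
        n = z.size
        hess = np.empty((n, n))
        f0 = self._nll_z(z)
        for i in range(n):
            for j in range(i, n):
                zi = z.copy()
                zi[i] += eps
                zi[j] += eps
                fpp = self._nll_z(zi)
                zi = z.copy()
                zi[i] += eps
                zi[j] -= eps
                fpm = self._nll_z(zi)
                zi = z.copy()
                zi[i] -= eps
                zi[j] += eps
                fmp = self._nll_z(zi)
                zi = z.copy()
                zi[i] -= eps
                zi[j] -= eps
                fmm = self._nll_z(zi)
                hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * eps * eps)
        return hess


@dataclass
class H2AXKineticsResults:
    """Results of a kinetic-model fit: estimates, uncertainty, diagnostics."""

    model: H2AXKineticsModel
    params: H2AXParams
    z_opt: np.ndarray
    nll: float
    converged: bool
    n_starts: int
    start_diagnostics: list = field(repr=False)
    hessian_cond: float = np.nan
    _ci_cache: dict = field(default_factory=dict, repr=False)

    @property
    def weighted_ssr(self) -> float:
        return self.model.weighted_ssr(self.params)

    @property
    def fixed_background(self) -> float:
        return self.model.background

    # -- profile likelihood -------------------------------------------------

    def _profile_starts(self, index: int, z_value: float, z_start: np.ndarray) -> list[np.ndarray]:
        """Starting points for the profile optimisation.

        The stretched-exponential scale r**p makes r and p strongly
        ridge-correlated: when one of them is fixed away from the optimum, a
        warm start at the unconstrained optimum can strand the nuisance
        optimiser on the wrong side of the ridge.  Add a structured start
        that keeps log(r**p) = p*log(r) at its fitted value, plus two small
        deterministic perturbations.
        """
        starts = [z_start.copy()]
        z_r, z_logit_p = z_start[2], z_start[3]
        p_fit = float(_expit(z_logit_p))
        log_scale = p_fit * z_r  # = log(r**p) at the warm start
        if index == 3:  # fixing p: move r to preserve r**p
            p_new = float(_expit(z_value))
            comp = z_start.copy()
            comp[2] = float(np.clip(log_scale / p_new, -50, 50))
            starts.append(comp)
        elif index == 2 and z_value > 0.1:  # fixing r: move p to preserve r**p
            p_new = float(np.clip(log_scale / z_value, 1e-6, 1 - 1e-6))
            comp = z_start.copy()
            comp[3] = _logit(p_new)
            starts.append(comp)
        for delta in (+1.5, -1.5):
            pert = z_start.copy()
            pert += delta * np.array([0.5, 0.2, 1.0, 0.8])
            starts.append(pert)
        return starts

    def _profile_nll(self, index: int, z_value: float, z_start: np.ndarray) -> tuple[float, np.ndarray]:
        """Minimise the NLL over the other parameters at a fixed z value."""
        free_idx = [i for i in range(4) if i != index]

        def obj(zf: np.ndarray) -> float:
            z = np.empty(4)
            z[index] = z_value
            z[free_idx] = zf
            return self.model._nll_z(z)

        best = None
        for z0 in self._profile_starts(index, z_value, z_start):
            res = _minimize_nm(
                obj, z0[free_idx], xatol=1e-9, fatol=1e-11, maxiter=3000,
            )
            if best is None or res.fun < best.fun:
                best = res
        z_full = np.empty(4)
        z_full[index] = z_value
        z_full[free_idx] = best.x
        return float(best.fun), z_full

    def profile_deviance(self, param_name: str, value: float) -> float:
        """Profile deviance 2*(NLL_profile(value) - NLL_best) for one parameter."""
        index = FREE_PARAM_NAMES.index(param_name)
        z_value = math.log(value) if param_name != "p" else _logit(value)
        nll, _ = self._profile_nll(index, z_value, self.z_opt)
        return 2.0 * (nll - self.nll)

    def profile_ci(
        self,
        param_name: str,
        level: float = 0.95,
        *,
        z_step: float = 0.15,
        max_steps: int = 120,
        rtol: float = 1e-3,
    ) -> ProfileCI:
        """Profile-likelihood CI for one free parameter.

        Walks outward from the best fit on the transformed scale with warm
        starts, brackets the deviance crossing of the chi-square(1 df)
        quantile, then refines by bisection to relative tolerance ``rtol``
        on the natural scale.  A bound not bracketed within the scan range
        is returned open-ended and flagged.
        """
        if not self.converged:
            raise RuntimeError("profile CI requires a converged fit")
        key = (param_name, level, z_step, max_steps, rtol)
        if key in self._ci_cache:
            return self._ci_cache[key]
        index = FREE_PARAM_NAMES.index(param_name)
        threshold = stats.chi2.ppf(level, df=1)

        def to_natural(z: float) -> float:
            return float(_expit(z)) if param_name == "p" else math.exp(z)

        bounds = []
        flags = []
        for direction in (-1.0, +1.0):
            z_prev = self.z_opt[index]
            dev_prev = 0.0
            warm = self.z_opt.copy()
            bracket = None
            for step in range(1, max_steps + 1):
                z_cur = self.z_opt[index] + direction * z_step * step
                nll, warm = self._profile_nll(index, z_cur, warm)
                dev = 2.0 * (nll - self.nll)
                if dev >= threshold:
                    bracket = (z_prev, z_cur, warm.copy())
                    break
                z_prev, dev_prev = z_cur, dev
            if bracket is None:
                bounds.append(0.0 if direction < 0 else math.inf)
                flags.append(True)
                continue
            z_lo, z_hi, warm_b = bracket

            def dev_fn(z: float) -> float:
                nll, _ = self._profile_nll(index, z, warm_b)
                return 2.0 * (nll - self.nll) - threshold

            z_root = optimize.brentq(dev_fn, z_lo, z_hi, xtol=rtol / 2.0)
            bounds.append(to_natural(z_root))
            flags.append(False)
        low, high = sorted(bounds[:2])
        ci = ProfileCI(low, high, open_low=flags[0], open_high=flags[1])
        self._ci_cache[key] = ci
        return ci

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        """Profile-likelihood CIs for all free parameters as a table."""
        rows = []
        for name in FREE_PARAM_NAMES:
            ci = self.profile_ci(name, level)
            rows.append(
                {
                    "param": name,
                    "estimate": getattr(self.params, name),
                    "low": ci.low,
                    "high": ci.high,
                    "open_low": ci.open_low,
                    "open_high": ci.open_high,
                }
            )
        return pd.DataFrame(rows).set_index("param")

    # -- confidence region --------------------------------------------------

    def in_confidence_region(
        self, candidate: H2AXParams, level: float = 0.95, df: int | None = None
    ) -> bool:
        """Whether a candidate parameter set lies in the joint confidence
        region: deviance 2*(NLL(candidate) - NLL_best) <= chi-square
        quantile with df = number of free parameters (default 4)."""
        if df is None:
            df = len(FREE_PARAM_NAMES)
        nll = self.model.nloglike(candidate)
        if not np.isfinite(nll):
            return False
        return 2.0 * (nll - self.nll) <= stats.chi2.ppf(level, df=df)

    def sample_confidence_region(self, n_min: int = 5000, seed: int | None = None, **kwargs):
        """Draw a parameter ensemble from the joint confidence region
        (see :func:`h2axdose.inversion.sample_confidence_region`)."""
        from .inversion import sample_confidence_region

        return sample_confidence_region(self, n_min=n_min, seed=seed, **kwargs)

    # -- reporting ----------------------------------------------------------

    def summary(self, level: float = 0.95, profile: bool = False) -> str:
        """Plain-text fit report; ``profile=True`` adds profile CIs."""
        p = self.params
        lines = [
            "gamma-H2AX kinetics model fit (weighted Gaussian ML)",
            "=" * 60,
            f"points: {len(self.model.data)}    fixed background b: "
            f"{self.model.background:g} AU",
            f"NLL: {self.nll:.6g}    weighted SSR: {self.weighted_ssr:.6g}",
            f"converged: {self.converged}    multistarts: {self.n_starts}    "
            f"Hessian cond: {self.hessian_cond:.3g}",
            "-" * 60,
        ]
        if profile:
            lines.append(f"{'param':>6} {'estimate':>12} {'low':>12} {'high':>12}")
            for name in FREE_PARAM_NAMES:
                ci = self.profile_ci(name, level)
                lines.append(
                    f"{name:>6} {getattr(p, name):>12.5g} {ci.low:>12.5g} {ci.high:>12.5g}"
                )
        else:
            lines.append(f"{'param':>6} {'estimate':>12}")
            for name in FREE_PARAM_NAMES:
                lines.append(f"{name:>6} {getattr(p, name):>12.5g}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "background": self.model.background,
            "params": {n: getattr(self.params, n) for n in FREE_PARAM_NAMES},
            "nll": self.nll,
            "weighted_ssr": self.weighted_ssr,
            "converged": self.converged,
            "n_starts": self.n_starts,
            "hessian_cond": self.hessian_cond,
        }


def fit_model(
    data, background: float, *, n_starts: int = 20, seed: int = 0, **kwargs
) -> H2AXKineticsResults:
    """Convenience wrapper: build the model and fit it."""
    return H2AXKineticsModel(data, background).fit(n_starts=n_starts, seed=seed, **kwargs)
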