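"""Rate-constant inference from observed subset counts.

Estimators follow the scikit-learn protocol (``fit`` / ``predict``,
``get_params`` / ``set_params``, trailing-underscore fitted attributes) so
they compose with sklearn tooling:

* :class:`TransientRateFitter` — fits differentiation/turnover rates to an
  anti-CD3 time course (influx-free transient model from a known DN3 pool).
* :class:`SteadyStateInfluxFitter` — fits progenitor influx K and/or DP
  turnover Kd4 to a steady-state cross-section with the remaining rates
  fixed.  The steady state exposes only four observable combinations, so
  no other parameter is identifiable from this design.

The declared estimator is least squares on log-transformed counts
(residuals on log(count + pseudocount), pseudocount 0.5 by default so
multinomially sampled zeros stay finite); no formal likelihood is claimed.
Free parameters are optimized on the log scale — positive by construction —
with multi-start restarts drawn log-uniformly within bounds to guard
against the shallow valley between K1 and Kd1.  Case-resampling bootstrap
(over mice within genotype x time strata) provides percentile intervals.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .analytic import solve_timecourse, steady_state_exact
from .exceptions import IdentifiabilityError, ValidationError
from .model import SUBSETS, CompartmentState, RateParameters
from .synthetic import ObservedDataset

__all__ = [
    "FitConfig",
    "FitResult",
    "BootstrapResult",
    "TransientRateFitter",
    "SteadyStateInfluxFitter",
    "fit_transient",
    "fit_influx_steady",
    "bootstrap_ci",
    "compare_genotype_fits",
]

_RATE_NAMES = ("K", "K1", "Kd1", "K2", "Kd2", "K3", "Kd3", "Kd4")

#: Default box bounds: rates in 1/day, influx in cells/day.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    **{name: (1e-6, 10.0) for name in _RATE_NAMES if name != "K"},
    "K": (1.0, 1e7),
}

# which observed subsets each parameter can influence in the transient model
_TRANSIENT_INFLUENCE = {
    "K1": {"DN3", "DN4", "ISP", "DP"},
    "Kd1": {"DN3", "DN4", "ISP", "DP"},
    "K2": {"DN4", "ISP", "DP"},
    "Kd2": {"DN4", "ISP", "DP"},
    "K3": {"ISP", "DP"},
    "Kd3": {"ISP", "DP"},
    "Kd4": {"DP"},
}

#: Restart optima closer than this (max pairwise relative difference) count
#: as the same optimum; convergence requires agreement at this level.
RESTART_DISPERSION_TOL = 1e-3


@dataclass(frozen=True)
class FitConfig:
    """Configuration of one fitting run (thin-wrapper interface)."""

    free: tuple[str, ...]
    fixed: Mapping[str, float] | RateParameters | None = None
    bounds: Mapping[str, tuple[float, float]] | None = None
    pseudocount: float = 0.5
    n_restarts: int = 8
    tol: float = 1e-8
    seed: int = 0
    c0_dn3: float = 3e8
    start: Mapping[str, float] | None = None


@dataclass
class FitResult:
    """Point estimates and convergence diagnostics of one fit."""

    estimates: dict[str, float]
    loss: float
    converged: bool
    restart_dispersion: float
    n_restarts: int
    n_success: int
    config: dict
    seed: int
    intervals: dict[str, tuple[float, float]] | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "FitResult":
        d = json.loads(Path(path).read_text())
        if d.get("intervals"):
            d["intervals"] = {k: tuple(v) for k, v in d["intervals"].items()}
        return cls(**d)


@dataclass
class BootstrapResult:
    """Percentile bootstrap intervals with the underlying replicate draws."""

    intervals: dict[str, tuple[float, float]]
    samples: dict[str, np.ndarray]
    failure_rate: float
    unstable: bool
    B: int
    seed: int


def _as_dataframe(data) -> pd.DataFrame:
    if isinstance(data, ObservedDataset):
        return data.df
    if isinstance(data, pd.DataFrame):
        return data
    raise ValidationError("data must be an ObservedDataset or a tidy DataFrame")


def _merge_fixed(free: Sequence[str], fixed, defaults: dict) -> dict[str, float]:
    """Full parameter dict = defaults <- fixed <- (free filled later)."""
    full = dict(defaults)
    if isinstance(fixed, RateParameters):
        full.update({k: v for k, v in fixed.to_dict().items() if k != "label"})
    elif fixed:
        unknown = set(fixed) - set(_RATE_NAMES)
        if unknown:
            raise ValidationError(f"unknown fixed parameters {sorted(unknown)}")
        full.update(fixed)
    missing = [p for p in _RATE_NAMES if p not in full and p not in free]
    if missing:
        raise ValidationError(
            f"parameters {missing} are neither free nor fixed; supply them via "
            f"`fixed`"
        )
    return full


class _LogLeastSquaresFitter(BaseEstimator):
    """Shared multi-start log-scale least-squares machinery."""

    # subclasses set these
    free: Sequence[str]
    _label = ""

    def _check_free(self, df: pd.DataFrame) -> None:
        raise NotImplementedError

    def _predict_counts(self, params: RateParameters, df: pd.DataFrame) -> np.ndarray:
        raise NotImplementedError

    def _full_params(self, free_values: np.ndarray) -> RateParameters:
        d = dict(self._fixed_full)
        for name, v in zip(self.free, free_values):
            d[name] = float(v)
        return RateParameters(**d, label=self._label)

    def _resolve_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        bounds = dict(DEFAULT_BOUNDS)
        if self.bounds:
            bounds.update(self.bounds)
        lo = np.array([bounds[p][0] for p in self.free])
        hi = np.array([bounds[p][1] for p in self.free])
        if np.any(lo <= 0) or np.any(lo >= hi):
            raise ValidationError("bounds must satisfy 0 < low < high")
        return lo, hi

    def fit(self, X, y=None):
        """Estimate the free rate constants from a tidy count table."""
        df = _as_dataframe(X)
        required = {"mouse_id", "time_days", "subset", "count"}
        if not required <= set(df.columns):
            raise ValidationError(f"data must have columns {sorted(required)}")
        if "genotype" in df.columns and df["genotype"].nunique() > 1:
            raise ValidationError(
                "data contains multiple genotypes; fit one at a time "
                "(ObservedDataset.filter)"
            )
        free = tuple(self.free)
        if len(free) == 0 or len(set(free)) != len(free):
            raise ValidationError("free must be a non-empty set of parameter names")
        unknown = set(free) - set(_RATE_NAMES)
        if unknown:
            raise ValidationError(f"unknown free parameters {sorted(unknown)}")
        self._check_free(df)

        lo, hi = self._resolve_bounds()
        log_lo, log_hi = np.log(lo), np.log(hi)
        obs = np.log(df["count"].to_numpy(dtype=float) + self.pseudocount)

        def residuals(log_theta: np.ndarray) -> np.ndarray:
            params = self._full_params(np.exp(log_theta))
            pred = self._predict_counts(params, df)
            return np.log(pred + self.pseudocount) - obs

        rng = np.random.default_rng(self.random_state)
        starts = [np.exp(rng.uniform(log_lo, log_hi)) for _ in range(self.n_restarts)]
        if self.start is not None:
            missing = set(free) - set(self.start)
            if missing:
                raise ValidationError(f"start is missing values for {sorted(missing)}")
            starts[0] = np.array([float(self.start[p]) for p in free])

        optima, losses, successes = [], [], []
        for x0 in starts:
            x0 = np.clip(x0, lo, hi)
            sol = least_squares(
                residuals,
                np.log(x0),
                bounds=(log_lo, log_hi),
                method="trf",
                xtol=self.tol,
                ftol=self.tol,
                gtol=self.tol,
            )
            optima.append(np.exp(sol.x))
            losses.append(float(np.sum(sol.fun**2)))
            successes.append(bool(sol.success))

        losses = np.asarray(losses)
        good = [i for i, s in enumerate(successes) if s]
        if not good:
            good = list(range(len(starts)))  # report best effort, unconverged
        best = min(good, key=lambda i: losses[i])

        dispersion = 0.0
        for i in good:
            for j in good:
                if i < j:
                    a, b = optima[i], optima[j]
                    denom = np.maximum(np.abs(a), np.abs(b))
                    denom = np.where(denom > 0, denom, 1.0)
                    dispersion = max(dispersion, float(np.max(np.abs(a - b) / denom)))

        estimates = {p: float(v) for p, v in zip(free, optima[best])}
        converged = bool(successes[best]) and dispersion <= RESTART_DISPERSION_TOL
        self.rates_ = self._full_params(optima[best])
        self.estimates_ = estimates
        self.loss_ = float(losses[best])
        self.converged_ = converged
        self.restart_dispersion_ = dispersion
        self.result_ = FitResult(
            estimates=estimates,
            loss=self.loss_,
            converged=converged,
            restart_dispersion=dispersion,
            n_restarts=self.n_restarts,
            n_success=len([s for s in successes if s]),
            config=self._config_echo(),
            seed=int(self.random_state),
        )
        return self

    def predict(self, X) -> np.ndarray:
        """Model-expected counts for each row of a tidy count table."""
        if not hasattr(self, "rates_"):
            raise ValidationError("estimator is not fitted")
        df = _as_dataframe(X)
        return self._predict_counts(self.rates_, df)

    def _config_echo(self) -> dict:
        cfg = {k: v for k, v in self.get_params().items()}
        for key, value in cfg.items():
            if isinstance(value, RateParameters):
                cfg[key] = value.to_dict()
            elif isinstance(value, tuple):
                cfg[key] = list(value)
            elif isinstance(value, Mapping):
                cfg[key] = {k: list(v) if isinstance(v, tuple) else v for k, v in value.items()}
        return cfg


class TransientRateFitter(_LogLeastSquaresFitter):
    """Fit rate constants to an anti-CD3 transient time course.

    The model is the influx-free cascade started from a known pure DN3 pool
    of size ``c0_dn3``.  By default K1, Kd1, K2 and K3 are free while Kd4 is
    held fixed: over a three-day window with Kd4 of order 1e-3/day the DP
    loss term is far below the noise floor, so freeing it is allowed but
    flagged as weakly identifiable.

    Parameters
    ----------
    free : sequence of str
        Names of the rate constants to estimate.
    fixed : mapping or RateParameters, optional
        Values for the non-free parameters.  K defaults to 0 and Kd2, Kd3
        to 0; everything else that is not free must be supplied here.
    c0_dn3 : float
        DN3 pool size at t = 0 (cells).
    bounds : mapping, optional
        Per-parameter (low, high) overrides of the default boxes.
    pseudocount : float
        Added inside both log terms of the loss, so zero counts are finite
        and a noiseless dataset has exactly zero loss at the truth.
    n_restarts : int
        Multi-start restarts, drawn log-uniformly within bounds.
    start : mapping, optional
        Replaces the first restart's initial point.
    random_state : int
        Seed for the restart draws.
    """

    _label = "fitted-transient"

    def __init__(
        self,
        free: Sequence[str] = ("K1", "Kd1", "K2", "K3"),
        fixed: Mapping[str, float] | RateParameters | None = None,
        c0_dn3: float = 3e8,
        bounds: Mapping[str, tuple[float, float]] | None = None,
        pseudocount: float = 0.5,
        n_restarts: int = 8,
        tol: float = 1e-8,
        start: Mapping[str, float] | None = None,
        random_state: int = 0,
    ):
        self.free = free
        self.fixed = fixed
        self.c0_dn3 = c0_dn3
        self.bounds = bounds
        self.pseudocount = pseudocount
        self.n_restarts = n_restarts
        self.tol = tol
        self.start = start
        self.random_state = random_state

    def _check_free(self, df: pd.DataFrame) -> None:
        free = set(self.free)
        if "K" in free:
            raise ValidationError(
                "K cannot be fitted from the transient design (influx is 0 "
                "by construction); use SteadyStateInfluxFitter"
            )
        self._fixed_full = _merge_fixed(
            self.free, self.fixed, {"K": 0.0, "Kd2": 0.0, "Kd3": 0.0}
        )
        if self._fixed_full.get("K", 0.0) > 0:
            raise ValidationError("transient fits require fixed K = 0")
        observed = set(df["subset"].unique())
        if {"K1", "Kd1"} <= free and observed <= {"DN3"}:
            raise IdentifiabilityError(
                "with only DN3 observed the transient decay identifies only "
                "K1 + Kd1, not K1 and Kd1 separately; observe a downstream "
                "subset or fix one of them"
            )
        for p in free:
            if not _TRANSIENT_INFLUENCE[p] & observed:
                raise IdentifiabilityError(
                    f"{p} does not influence any observed subset ({sorted(observed)})"
                )
        if "Kd4" in free:
            warnings.warn(
                "Kd4 is weakly identifiable from a short transient window",
                UserWarning,
                stacklevel=3,
            )
        if self.c0_dn3 <= 0:
            raise ValidationError("c0_dn3 must be > 0")

    def _predict_counts(self, params: RateParameters, df: pd.DataFrame) -> np.ndarray:
        times = np.asarray(sorted(df["time_days"].unique()), dtype=float)
        c0 = CompartmentState(0.0, float(self.c0_dn3), 0.0, 0.0, 0.0)
        tc = solve_timecourse(params, c0, times)
        t_index = {t: i for i, t in enumerate(times)}
        s_index = {s: j for j, s in enumerate(SUBSETS)}
        rows_t = df["time_days"].map(t_index).to_numpy()
        rows_s = df["subset"].map(s_index).to_numpy()
        return tc.counts[rows_t, rows_s]


class SteadyStateInfluxFitter(_LogLeastSquaresFitter):
    """Fit influx K and/or DP turnover Kd4 to a steady-state cross-section.

    The fixed point exposes exactly four observable combinations of the
    eight rates, and with the differentiation/turnover rates fixed only K
    (an overall scale) and Kd4 (the DP-specific scale) remain identifiable;
    requesting any other free parameter raises ``IdentifiabilityError``.
    """

    _label = "fitted-steady-state"

    def __init__(
        self,
        free: Sequence[str] = ("K",),
        fixed: Mapping[str, float] | RateParameters | None = None,
        bounds: Mapping[str, tuple[float, float]] | None = None,
        pseudocount: float = 0.5,
        n_restarts: int = 8,
        tol: float = 1e-8,
        start: Mapping[str, float] | None = None,
        random_state: int = 0,
    ):
        self.free = free
        self.fixed = fixed
        self.bounds = bounds
        self.pseudocount = pseudocount
        self.n_restarts = n_restarts
        self.tol = tol
        self.start = start
        self.random_state = random_state

    def _check_free(self, df: pd.DataFrame) -> None:
        free = set(self.free)
        if not free <= {"K", "Kd4"}:
            raise IdentifiabilityError(
                "the steady state observes only 4 combinations of the rates; "
                "with the differentiation rates fixed, only {K, Kd4} are "
                f"identifiable, not {sorted(free)}"
            )
        self._fixed_full = _merge_fixed(self.free, self.fixed, {"Kd2": 0.0, "Kd3": 0.0})
        observed = set(df["subset"].unique())
        if "Kd4" in free and "DP" not in observed:
            raise IdentifiabilityError("Kd4 requires the DP subset to be observed")

    def _predict_counts(self, params: RateParameters, df: pd.DataFrame) -> np.ndarray:
        ss = steady_state_exact(params).counts
        s_index = {s: j for j, s in enumerate(SUBSETS)}
        return ss[df["subset"].map(s_index).to_numpy()]


# ---------------------------------------------------------------------------
# Thin functional wrappers
# ---------------------------------------------------------------------------

def _estimator_from_config(scenario: str, config: FitConfig):
    common = dict(
        free=tuple(config.free),
        fixed=config.fixed,
        bounds=config.bounds,
        pseudocount=config.pseudocount,
        n_restarts=config.n_restarts,
        tol=config.tol,
        start=config.start,
        random_state=config.seed,
    )
    if scenario == "acd3_timecourse":
        return TransientRateFitter(c0_dn3=config.c0_dn3, **common)
    if scenario == "steady_state_crosssection":
        return SteadyStateInfluxFitter(**common)
    raise ValidationError(f"unknown scenario {scenario!r}")


def fit_transient(data, config: FitConfig) -> FitResult:
    """Fit transient rates (see :class:`TransientRateFitter`)."""
    return _estimator_from_config("acd3_timecourse", config).fit(data).result_


def fit_influx_steady(data, config: FitConfig) -> FitResult:
    """Fit K and/or Kd4 at steady state (see :class:`SteadyStateInfluxFitter`)."""
    return _estimator_from_config("steady_state_crosssection", config).fit(data).result_


def bootstrap_ci(
    data: ObservedDataset,
    config: FitConfig,
    B: int = 200,
    seed: int = 0,
    scenario: str | None = None,
) -> BootstrapResult:
    """Case-resampling percentile bootstrap for the free parameters.

    Mice are resampled with replacement within each (genotype, time)
    stratum; each replicate is refitted starting from the point estimate.
    A refit failure rate above 5% flags the result as unstable.
    Deterministic under ``seed``.
    """
    if B < 100:
        raise ValidationError("B must be >= 100 for percentile intervals")
    if scenario is None:
        if data.design is None:
            raise ValidationError("scenario not given and dataset has no design")
        scenario = data.design.scenario

    point = _estimator_from_config(scenario, config).fit(data)
    if not point.converged_:
        raise ValidationError("point fit did not converge; bootstrap aborted")

    df = data.df
    mice = df[["mouse_id", "genotype", "time_days"]].drop_duplicates()
    strata = [g for _, g in mice.groupby(["genotype", "time_days"], sort=False)]
    by_mouse = dict(tuple(df.groupby("mouse_id", sort=False)))

    rng = np.random.default_rng(seed)
    free = tuple(config.free)
    draws = {p: [] for p in free}
    failures = 0
    refit_cfg = dataclasses.replace(
        config, n_restarts=1, start=dict(point.estimates_), seed=seed
    )
    for b in range(B):
        parts = []
        for stratum in strata:
            ids = stratum["mouse_id"].to_numpy()
            picked = rng.choice(ids, size=ids.size, replace=True)
            for r, mid in enumerate(picked):
                part = by_mouse[mid].copy()
                part["mouse_id"] = f"bs{b}_{mid}_{r}"
                parts.append(part)
        boot_df = pd.concat(parts, ignore_index=True)
        boot = ObservedDataset(boot_df, data.design, data.noise, data.seed)
        est = _estimator_from_config(scenario, refit_cfg).fit(boot)
        if not est.converged_:
            failures += 1
        for p in free:
            draws[p].append(est.estimates_[p])

    samples = {p: np.asarray(v) for p, v in draws.items()}
    intervals = {
        p: (float(np.percentile(s, 2.5)), float(np.percentile(s, 97.5)))
        for p, s in samples.items()
    }
    failure_rate = failures / B
    return BootstrapResult(
        intervals=intervals,
        samples=samples,
        failure_rate=failure_rate,
        unstable=failure_rate > 0.05,
        B=B,
        seed=int(seed),
    )


def compare_genotype_fits(
    fit_wt: FitResult,
    fit_ko: FitResult,
    bootstrap_wt: BootstrapResult | None = None,
    bootstrap_ko: BootstrapResult | None = None,
) -> pd.DataFrame:
    """Fold-change table (KO / WT) over the shared fitted parameters.

    When bootstrap draws are supplied for both fits, a percentile interval
    for each fold change is computed from the ratio of (independent)
    replicate draws.
    """
    for name, fr in (("fit_wt", fit_wt), ("fit_ko", fit_ko)):
        if not fr.converged:
            raise ValidationError(f"{name} did not converge")
    shared = [p for p in fit_wt.estimates if p in fit_ko.estimates]
    if not shared:
        raise ValidationError("fits share no free parameters; nothing to compare")
    rows = []
    for p in shared:
        wt, ko = fit_wt.estimates[p], fit_ko.estimates[p]
        fold = ko / wt if wt > 0 else np.inf
        lo = hi = np.nan
        if (
            bootstrap_wt is not None
            and bootstrap_ko is not None
            and p in bootstrap_wt.samples
            and p in bootstrap_ko.samples
        ):
            ratios = bootstrap_ko.samples[p] / bootstrap_wt.samples[p]
            lo, hi = np.percentile(ratios, [2.5, 97.5])
        rows.append((p, wt, ko, fold, lo, hi))
    return pd.DataFrame(
        rows, columns=["parameter", "wt", "ko", "fold_change", "fold_lo", "fold_hi"]
    )
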