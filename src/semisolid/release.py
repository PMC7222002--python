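"""In-vitro release analysis: calibration, mass-balance correction, kinetics.

Timed UV absorbances from a stirred acceptor vessel are turned into a
cumulative-release profile per unit orifice area and fitted with five kinetic
models.  The measurement chain is:

1. absorbance -> concentration through a linear calibration (Beer-Lambert);
2. concentration -> cumulative released amount via the sampling-and-
   replacement mass balance.  With vessel volume V, aliquot volume V_s and
   orifice area A, the amount released per area up to the n-th sampling is

       Q_n = ( C_n * V + sum_{i<n} C_i * V_s ) / A        [mg/cm^2]

   which exactly inverts withdrawal of V_s (replaced with fresh medium) at
   each earlier time;
3. Q(t) -> kinetic fit: zero-order, first-order, Higuchi (fit through the
   origin on sqrt(t) over a 15-150 min window), Korsmeyer-Peppas (log-log,
   restricted to fractional release <= 0.6) or Weibull.

Model forms (q_inf = releasable amount per area, by default dose/area):

    zero              Q = k0 * t
    first             Q = q_inf * (1 - exp(-k1 * t))
    higuchi           Q = kH * sqrt(t)
    korsmeyer_peppas  Q/q_inf = kKP * t^n
    weibull           Q/q_inf = 1 - exp(-(t/tau_d)^beta)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize

from .exceptions import InsufficientDataError, InvalidInputError
from .stats import welch_t

ModelName = Literal["zero", "first", "higuchi", "korsmeyer_peppas", "weibull"]
MODEL_NAMES: tuple[str, ...] = (
    "zero",
    "first",
    "higuchi",
    "korsmeyer_peppas",
    "weibull",
)
#: fitting window for the Higuchi model [min]
HIGUCHI_WINDOW_MIN = (15.0, 150.0)
#: fractional-release ceiling for the Korsmeyer-Peppas log-log fit
KP_FRACTION_MAX = 0.6


# ---------------------------------------------------------------------------
# calibration


class CalibrationModel:
    """OLS of absorbance on concentration (linear Beer-Lambert calibration)."""

    def __init__(
        self,
        concentrations_mg_ml: Sequence[float],
        absorbances: Sequence[float],
        wavelength_nm: float = 276.5,
    ):
        conc = np.asarray(concentrations_mg_ml, dtype=float)
        absb = np.asarray(absorbances, dtype=float)
        if conc.shape != absb.shape or conc.ndim != 1:
            raise InvalidInputError("concentrations/absorbances must match, 1-D")
        if len(np.unique(conc)) < 3:
            raise InsufficientDataError(
                f"need >= 3 concentration levels, got {len(np.unique(conc))}"
            )
        self.conc = conc
        self.absb = absb
        self.wavelength_nm = wavelength_nm

    def fit(self) -> "CalibrationResults":
        res = sm.OLS(self.absb, sm.add_constant(self.conc)).fit()
        intercept, slope = res.params
        usable = slope > 0
        if not usable:
            warnings.warn(
                "calibration slope is not positive; curve flagged unusable",
                stacklevel=2,
            )
        return CalibrationResults(
            slope=float(slope),
            intercept=float(intercept),
            r_squared=float(res.rsquared),
            wavelength_nm=self.wavelength_nm,
            usable=bool(usable),
        )


@dataclass(frozen=True)
class CalibrationResults:
    """Fitted calibration line absorbance = slope*conc + intercept."""

    slope: float
    intercept: float
    r_squared: float
    wavelength_nm: float = 276.5
    usable: bool = True

    def to_concentration(self, absorbance) -> np.ndarray:
        return absorbance_to_conc(absorbance, self)

    def summary(self) -> str:
        return "\n".join(
            [
                f"UV calibration at {self.wavelength_nm} nm",
                "-" * 40,
                f"  slope (A per mg/mL) : {self.slope:10.4f}",
                f"  intercept (A)       : {self.intercept:10.4f}",
                f"  R^2                 : {self.r_squared:10.4f}",
                f"  usable              : {self.usable}",
            ]
        )


def fit_calibration(
    concentrations_mg_ml: Sequence[float],
    absorbances: Sequence[float],
    wavelength_nm: float = 276.5,
) -> CalibrationResults:
    """Convenience wrapper: ``CalibrationModel(...).fit()``."""
    return CalibrationModel(concentrations_mg_ml, absorbances, wavelength_nm).fit()


def absorbance_to_conc(absorbance, calib: CalibrationResults) -> np.ndarray:
    """Invert the calibration line; negative concentrations floor at 0."""
    if calib.slope <= 0:
        raise InvalidInputError("calibration slope must be positive")
    a = np.asarray(absorbance, dtype=float)
    conc = (a - calib.intercept) / calib.slope
    if np.any(conc < 0):
        warnings.warn(
            "absorbance below calibration intercept; concentration floored at 0",
            stacklevel=2,
        )
        conc = np.clip(conc, 0.0, None)
    return conc if conc.ndim else float(conc)


# ---------------------------------------------------------------------------
# experiment containers


@dataclass(frozen=True)
class ReleaseExperiment:
    """Timed absorbances measured through the acceptor vessel.

    ``absorbances`` has shape (n_replicates, n_times).
    """

    times_min: np.ndarray
    absorbances: np.ndarray
    vessel_volume_ml: float = 50.0
    sample_volume_ml: float = 3.0
    orifice_area_cm2: float = 3.8
    loaded_dose_mg: float = float("nan")
    temperature_C: float = 32.0
    formulation_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        a = np.atleast_2d(np.asarray(self.absorbances, dtype=float))
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError("times must be strictly increasing")
        if a.shape[1] != t.size:
            raise InvalidInputError("absorbance columns must match the schedule")
        if self.sample_volume_ml >= self.vessel_volume_ml:
            raise InvalidInputError("sample volume must be below vessel volume")
        if self.orifice_area_cm2 <= 0:
            raise InvalidInputError("orifice area must be positive")
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "absorbances", a)

    @property
    def n_replicates(self) -> int:
        return self.absorbances.shape[0]


@dataclass(frozen=True)
class ReleaseProfile:
    """Cumulative released amount per orifice area, Q(t) [mg/cm^2]."""

    times_min: np.ndarray
    q_mg_cm2: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        q = np.asarray(self.q_mg_cm2, dtype=float)
        if t.shape != q.shape or t.ndim != 1:
            raise InvalidInputError("times and Q must be 1-D and equal length")
        if np.any(q < 0):
            raise InvalidInputError("cumulative release cannot be negative")
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "q_mg_cm2", q)


def cumulative_release(
    concentrations_mg_ml: Sequence[float],
    exp: ReleaseExperiment,
    monotonicity_tol: float = 0.05,
) -> ReleaseProfile:
    """Withdrawal-corrected cumulative release per unit orifice area.

    ``concentrations_mg_ml`` are the vessel concentrations measured at
    ``exp.times_min`` (one replicate).  Applies the sampling-and-replacement
    mass balance Q_n = (C_n V + sum_{i<n} C_i V_s)/A.  Decreases of Q beyond
    ``monotonicity_tol`` (relative to the running maximum) are flagged with a
    warning — they indicate measurement error, not physics.
    """
    conc = np.asarray(concentrations_mg_ml, dtype=float)
    if conc.shape != exp.times_min.shape:
        raise InvalidInputError("concentration schedule mismatch")
    if np.any(conc < 0):
        raise InvalidInputError("concentrations must be >= 0")
    removed = np.concatenate([[0.0], np.cumsum(conc)[:-1]]) * exp.sample_volume_ml
    q = (conc * exp.vessel_volume_ml + removed) / exp.orifice_area_cm2
    running_max = np.maximum.accumulate(q)
    drop = running_max - q
    scale = max(running_max[-1], np.finfo(float).tiny)
    if np.any(drop / scale > monotonicity_tol):
        warnings.warn(
            "cumulative release decreases beyond tolerance; check measurements",
            stacklevel=2,
        )
    return ReleaseProfile(times_min=exp.times_min.copy(), q_mg_cm2=q)


# ---------------------------------------------------------------------------
# kinetic model forms


def release_law(model: str, params: dict[str, float], times_min) -> np.ndarray:
    """Evaluate a kinetic model Q(t) [mg/cm^2] at ``times_min``."""
    t = np.asarray(times_min, dtype=float)
    if model == "zero":
        return params["k0"] * t
    if model == "first":
        return params["q_inf"] * (1.0 - np.exp(-params["k1"] * t))
    if model == "higuchi":
        return params["kH"] * np.sqrt(t)
    if model == "korsmeyer_peppas":
        return params["q_inf"] * params["kKP"] * t ** params["n"]
    if model == "weibull":
        return params["q_inf"] * (1.0 - np.exp(-((t / params["tau_d"]) ** params["beta"])))
    raise InvalidInputError(f"unknown model {model!r}")


_NEEDS_QINF = {"first", "korsmeyer_peppas", "weibull"}


class ReleaseKineticsModel:
    """Fit one kinetic model to a cumulative-release profile.

    Parameters
    ----------
    profile : ReleaseProfile
    model : one of ``zero, first, higuchi, korsmeyer_peppas, weibull``
    q_inf : float, optional
        Releasable amount per area [mg/cm^2]; required by the first-order,
        Korsmeyer-Peppas and Weibull forms.  Use dose/area for a dose-based
        ceiling or ``max(Q)`` for a profile-based one.
    higuchi_window : (float, float)
        Time window for the Higuchi fit (default 15-150 min).
    higuchi_through_origin : bool
        The default Higuchi fit is constrained through the origin; disable to
        allow an intercept (burst/lag accommodation).
    """

    def __init__(
        self,
        profile: ReleaseProfile,
        model: ModelName,
        q_inf: float | None = None,
        higuchi_window: tuple[float, float] = HIGUCHI_WINDOW_MIN,
        higuchi_through_origin: bool = True,
    ):
        if model not in MODEL_NAMES:
            raise InvalidInputError(f"unknown model {model!r}")
        if model in _NEEDS_QINF and q_inf is None:
            raise InvalidInputError(f"model {model!r} requires q_inf")
        if q_inf is not None and q_inf <= 0:
            raise InvalidInputError("q_inf must be positive")
        self.profile = profile
        self.model = model
        self.q_inf = q_inf
        self.higuchi_window = higuchi_window
        self.higuchi_through_origin = higuchi_through_origin

    # -- fitting ------------------------------------------------------------
    def fit(self) -> "KineticResults":
        t = self.profile.times_min
        q = self.profile.q_mg_cm2
        fitter = getattr(self, f"_fit_{self.model}")
        params, t_fit, q_fit, q_hat = fitter(t, q)
        ss_res = float(np.sum((q_fit - q_hat) ** 2))
        ss_tot = float(np.sum((q_fit - q_fit.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
        if t_fit.size - len(params) <= 1:
            warnings.warn(
                f"{self.model}: {t_fit.size} points for {len(params)} "
                "parameter(s); almost no residual degrees of freedom",
                stacklevel=2,
            )
        return KineticResults(
            model=self.model,
            params=params,
            q_inf=self.q_inf,
            r_squared=r2,
            n_points=int(t_fit.size),
        )

    @staticmethod
    def _require(n: int, window_desc: str) -> None:
        if n < 3:
            raise InsufficientDataError(
                f"need >= 3 points in the {window_desc} (got {n})"
            )

    def _fit_zero(self, t, q):
        self._require(t.size, "profile")
        k0 = float(np.sum(q * t) / np.sum(t * t))
        return {"k0": k0}, t, q, k0 * t

    def _fit_higuchi(self, t, q):
        lo, hi = self.higuchi_window
        keep = (t >= lo) & (t <= hi)
        if not np.any(keep):
            raise InsufficientDataError("Higuchi fitting window is empty")
        self._require(int(keep.sum()), f"Higuchi window [{lo}, {hi}] min")
        ts, qs = t[keep], q[keep]
        root = np.sqrt(ts)
        if self.higuchi_through_origin:
            kH = float(np.sum(qs * root) / np.sum(ts))
            return {"kH": kH}, ts, qs, kH * root
        res = sm.OLS(qs, sm.add_constant(root)).fit()
        c, kH = (float(v) for v in res.params)
        return {"kH": kH, "intercept": c}, ts, qs, c + kH * root

    def _fit_first(self, t, q):
        self._require(t.size, "profile")
        qi = self.q_inf
        frac = np.clip(q / qi, None, 1.0 - 1e-12)
        # linearized start value, refined by nonlinear least squares
        k0 = max(-np.polyfit(t, np.log(1.0 - frac), 1)[0], 1e-8)
        (k1,), _ = optimize.curve_fit(
            lambda tt, k: qi * (1.0 - np.exp(-k * tt)), t, q, p0=[k0],
            bounds=(1e-12, np.inf), maxfev=10000,
        )
        k1 = float(k1)
        return {"k1": k1}, t, q, qi * (1.0 - np.exp(-k1 * t))

    def _fit_korsmeyer_peppas(self, t, q):
        qi = self.q_inf
        frac = q / qi
        keep = (frac > 0) & (frac <= KP_FRACTION_MAX)
        if not np.any(keep):
            raise InsufficientDataError(
                f"no points with fractional release in (0, {KP_FRACTION_MAX}]"
            )
        self._require(
            int(keep.sum()), f"Korsmeyer-Peppas window (Q/q_inf <= {KP_FRACTION_MAX})"
        )
        ts, fs = t[keep], frac[keep]
        res = sm.OLS(np.log(fs), sm.add_constant(np.log(ts))).fit()
        logk, n = (float(v) for v in res.params)
        kKP = float(np.exp(logk))
        q_hat = qi * kKP * ts ** n
        return {"kKP": kKP, "n": n}, ts, q[keep], q_hat

    def _fit_weibull(self, t, q):
        self._require(t.size, "profile")
        qi = self.q_inf
        frac = np.clip(q / qi, 1e-12, 1.0 - 1e-12)
        # linearized start values: log(-log(1-F)) = beta*log t - beta*log tau
        y = np.log(-np.log(1.0 - frac))
        beta0, c0 = np.polyfit(np.log(t), y, 1)
        beta0 = float(np.clip(beta0, 0.05, 20.0))
        tau0 = float(np.exp(-c0 / beta0)) if beta0 > 0 else float(np.median(t))
        (beta, tau), _ = optimize.curve_fit(
            lambda tt, b, td: qi * (1.0 - np.exp(-((tt / td) ** b))),
            t, q, p0=[beta0, max(tau0, 1e-6)],
            bounds=([1e-6, 1e-6], [50.0, np.inf]), maxfev=20000,
        )
        beta, tau = float(beta), float(tau)
        q_hat = qi * (1.0 - np.exp(-((t / tau) ** beta)))
        return {"beta": beta, "tau_d": tau}, t, q, q_hat


@dataclass(frozen=True)
class KineticResults:
    """Fitted kinetic-model parameters and goodness of fit."""

    model: str
    params: dict[str, float]
    q_inf: float | None
    r_squared: float
    n_points: int

    @property
    def rate(self) -> float:
        """The model's headline rate constant (kH, k0, k1, kKP or 1/tau_d)."""
        for key in ("kH", "k0", "k1", "kKP"):
            if key in self.params:
                return self.params[key]
        return 1.0 / self.params["tau_d"]

    def predict(self, times_min) -> np.ndarray:
        params = dict(self.params)
        if self.model in _NEEDS_QINF:
            params["q_inf"] = self.q_inf
        params.pop("intercept", None)
        q = release_law(self.model, params, times_min)
        if "intercept" in self.params:
            q = q + self.params["intercept"]
        return q

    def summary(self) -> str:
        lines = [f"Release kinetics: {self.model} model", "-" * 40]
        for k, v in self.params.items():
            lines.append(f"  {k:<10}: {v:12.6f}")
        if self.q_inf is not None:
            lines.append(f"  q_inf     : {self.q_inf:12.6f} mg/cm^2")
        lines.append(f"  R^2       : {self.r_squared:12.4f}")
        lines.append(f"  n points  : {self.n_points:12d}")
        return "\n".join(lines)


def fit_release_model(
    profile: ReleaseProfile,
    model: ModelName,
    q_inf: float | None = None,
    **kw,
) -> KineticResults:
    """Convenience wrapper: ``ReleaseKineticsModel(...).fit()``."""
    return ReleaseKineticsModel(profile, model, q_inf=q_inf, **kw).fit()


def compare_models(profile: ReleaseProfile, q_inf: float) -> pd.DataFrame:
    """Fit all five kinetic models and rank them by R^2.

    Models whose preconditions fail on this profile (e.g. an empty
    Korsmeyer-Peppas window) appear with NaN R^2 and the failure reason; the
    best-fitting model is flagged in the ``best`` column.
    """
    rows = []
    for model in MODEL_NAMES:
        try:
            res = fit_release_model(profile, model, q_inf=q_inf)
            rows.append(
                {
                    "model": model,
                    "r_squared": res.r_squared,
                    "params": res.params,
                    "rate": res.rate,
                    "note": "",
                }
            )
        except (InsufficientDataError, InvalidInputError, RuntimeError) as err:
            rows.append(
                {"model": model, "r_squared": np.nan, "params": {}, "rate": np.nan,
                 "note": str(err)}
            )
    df = pd.DataFrame(rows)
    df["rank"] = df["r_squared"].rank(ascending=False, method="min")
    df["best"] = df["rank"] == 1.0
    return df.sort_values("rank", ignore_index=True)


def release_rate_comparison(
    rates_by_formulation: dict[str, Sequence[float]]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean +/- SD release rate per formulation and pairwise Welch t-tests.

    ``rates_by_formulation`` maps formulation id -> replicate rate estimates
    (e.g. per-replicate Higuchi kH fits).  Groups with a single replicate are
    summarized descriptively and excluded from testing, with a warning.

    Returns (summary table, pairwise test table).
    """
    if any(len(v) == 0 for v in rates_by_formulation.values()):
        raise InvalidInputError("empty rate group")
    summary = []
    for fid, vals in rates_by_formulation.items():
        arr = np.asarray(vals, dtype=float)
        summary.append(
            {
                "formulation_id": fid,
                "mean": float(arr.mean()),
                "sd": float(arr.std(ddof=1)) if arr.size > 1 else np.nan,
                "n": int(arr.size),
            }
        )
    summary_df = pd.DataFrame(summary)
    testable = [f for f, v in rates_by_formulation.items() if len(v) >= 2]
    skipped = sorted(set(rates_by_formulation) - set(testable))
    if skipped:
        warnings.warn(
            f"single-replicate group(s) {skipped}: descriptive only, no test",
            stacklevel=2,
        )
    pairs = []
    for i, fa in enumerate(testable):
        for fb in testable[i + 1 :]:
            a = np.asarray(rates_by_formulation[fa], dtype=float)
            b = np.asarray(rates_by_formulation[fb], dtype=float)
            res = welch_t(a, b, label=f"{fa} vs {fb}")
            pairs.append(
                {
                    "a": fa,
                    "b": fb,
                    "mean_diff": res.mean,
                    "t": res.t,
                    "p": res.p,
                    "significant_0.05": bool(res.p < 0.05),
                }
            )
    return summary_df, pd.DataFrame(pairs)
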