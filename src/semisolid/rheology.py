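"""Rotational rheology: step-rate viscosity, yield-stress fits, thixotropy.

The flow test ramps the shear rate from 100 to 1100 1/s and back down while
recording shear stress.  Three quantities summarize a semi-solid:

* step viscosities at 300/700/1100 1/s (mean +/- SD over replicates), whose
  decrease with rate flags shear thinning;
* a yield-stress flow fit.  Two variants are offered: the *linear* form
  tau = tau_y + eta*gamma (mathematically the Bingham plastic law, and the
  default here), and the conventional *square-root* Casson form
  sqrt(tau) = sqrt(tau_y) + sqrt(eta*gamma);
* the hysteresis-loop area between the ascending and descending flow curves
  on the rate-stress plane.  A positive area (up-curve above down-curve)
  indicates thixotropy: shear-induced, recoverable structure breakdown.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import InsufficientDataError, InvalidInputError

STEP_RATES_S1 = (300.0, 700.0, 1100.0)


@dataclass(frozen=True)
class FlowCurve:
    """Shear-ramp record: rate [1/s], stress [Pa], phase ('up'|'down')."""

    shear_rate: np.ndarray
    shear_stress: np.ndarray
    phase: np.ndarray  # 'up' or 'down' per point
    temperature_C: float = 25.0
    formulation_id: str = ""

    def __post_init__(self) -> None:
        rate = np.asarray(self.shear_rate, dtype=float)
        stress = np.asarray(self.shear_stress, dtype=float)
        phase = np.asarray(self.phase, dtype=object)
        if not (rate.shape == stress.shape == phase.shape) or rate.ndim != 1:
            raise InvalidInputError("rate/stress/phase must be 1-D, equal length")
        if np.any(rate <= 0):
            raise InvalidInputError("shear rates must be positive")
        bad = set(np.unique(phase)) - {"up", "down"}
        if bad:
            raise InvalidInputError(f"unknown phase labels: {sorted(bad)}")
        up = rate[phase == "up"]
        down = rate[phase == "down"]
        if up.size and np.any(np.diff(up) < 0):
            raise InvalidInputError("ascending-phase rates must be non-decreasing")
        if down.size and np.any(np.diff(down) > 0):
            raise InvalidInputError("descending-phase rates must be non-increasing")
        object.__setattr__(self, "shear_rate", rate)
        object.__setattr__(self, "shear_stress", stress)
        object.__setattr__(self, "phase", phase)

    def ascending(self) -> tuple[np.ndarray, np.ndarray]:
        m = self.phase == "up"
        return self.shear_rate[m], self.shear_stress[m]

    def descending(self) -> tuple[np.ndarray, np.ndarray]:
        m = self.phase == "down"
        return self.shear_rate[m], self.shear_stress[m]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kw) -> "FlowCurve":
        """Build from columns ``phase, shear_rate_s1, shear_stress_Pa``
        (optionally ``temperature_C``, ``formulation_id``)."""
        required = {"phase", "shear_rate_s1", "shear_stress_Pa"}
        missing = required - set(df.columns)
        if missing:
            raise InvalidInputError(f"missing columns: {sorted(missing)}")
        if "temperature_C" in df.columns and "temperature_C" not in kw:
            kw["temperature_C"] = float(df["temperature_C"].iloc[0])
        if "formulation_id" in df.columns and "formulation_id" not in kw:
            kw["formulation_id"] = str(df["formulation_id"].iloc[0])
        return cls(
            df["shear_rate_s1"].to_numpy(),
            df["shear_stress_Pa"].to_numpy(),
            df["phase"].to_numpy(),
            **kw,
        )


# ---------------------------------------------------------------------------
# step-rate viscosity summaries


def summarize_step_viscosity(readings: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD viscosity per formulation x temperature x rate cell.

    ``readings`` is a long table with columns ``formulation_id,
    temperature_C, shear_rate_s1, replicate, viscosity_mPas``.  Cells with a
    single replicate raise (a lone reading has no SD); absent cells are simply
    absent from the output, never imputed.  The ``shear_thinning`` flag marks
    formulation/temperature groups whose mean viscosity strictly decreases
    with rate.
    """
    required = {"formulation_id", "temperature_C", "shear_rate_s1", "viscosity_mPas"}
    missing = required - set(readings.columns)
    if missing:
        raise InvalidInputError(f"missing columns: {sorted(missing)}")
    if np.any(readings["viscosity_mPas"].to_numpy(dtype=float) <= 0):
        raise InvalidInputError("viscosities must be positive")
    g = readings.groupby(["formulation_id", "temperature_C", "shear_rate_s1"])[
        "viscosity_mPas"
    ]
    out = g.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index()
    short = out[out["n"] < 2]
    if not short.empty:
        row = short.iloc[0]
        raise InsufficientDataError(
            f"cell ({row['formulation_id']}, {row['temperature_C']} C, "
            f"{row['shear_rate_s1']} 1/s) has {int(row['n'])} replicate(s); need >= 2"
        )
    flags = []
    for (fid, temp), grp in out.groupby(["formulation_id", "temperature_C"]):
        means = grp.sort_values("shear_rate_s1")["mean"].to_numpy()
        flags.append(((fid, temp), bool(np.all(np.diff(means) < 0))))
    flag_map = dict(flags)
    out["shear_thinning"] = [
        flag_map[(f, t)] for f, t in zip(out["formulation_id"], out["temperature_C"])
    ]
    return out


def temperature_ratio(
    table: pd.DataFrame,
    formulation: str,
    rate_s1: float,
    temp_hot_C: float = 32.0,
    temp_cold_C: float = 25.0,
) -> float:
    """Ratio of mean viscosity at the cold vs. hot temperature for one cell."""

    def cell(temp):
        sel = table[
            (table["formulation_id"] == formulation)
            & (table["temperature_C"] == temp)
            & (table["shear_rate_s1"] == rate_s1)
        ]
        if sel.empty:
            raise InvalidInputError(
                f"no cell for ({formulation}, {temp} C, {rate_s1} 1/s)"
            )
        return float(sel["mean"].iloc[0])

    return cell(temp_cold_C) / cell(temp_hot_C)


# ---------------------------------------------------------------------------
# yield-stress fits

CassonVariant = Literal["linear", "sqrt"]


class CassonModel:
    """Yield-stress flow model fit on the ascending branch of a flow curve.

    variant='linear' fits tau = tau_y + eta*gamma by OLS (slope = plastic
    viscosity eta, intercept = yield stress tau_y).  variant='sqrt' fits the
    conventional Casson form sqrt(tau) = sqrt(tau_y) + sqrt(eta*gamma) by OLS
    on square-root axes.  Negative intercepts are clipped so tau_y >= 0.
    """

    def __init__(self, curve: FlowCurve, variant: CassonVariant = "linear"):
        if variant not in ("linear", "sqrt"):
            raise InvalidInputError(f"unknown variant {variant!r}")
        rate, stress = curve.ascending()
        if rate.size < 3:
            raise InsufficientDataError(
                f"need >= 3 ascending-phase points, got {rate.size}"
            )
        if np.unique(rate).size < 2:
            raise InvalidInputError("singular design: all points at one shear rate")
        self.curve = curve
        self.variant = variant
        self._rate = rate
        self._stress = stress

    def fit(self) -> "CassonResults":
        if self.variant == "linear":
            x, y = self._rate, self._stress
        else:
            if np.any(self._stress < 0):
                raise InvalidInputError("negative stresses: sqrt variant undefined")
            x, y = np.sqrt(self._rate), np.sqrt(self._stress)
        res = sm.OLS(y, sm.add_constant(x)).fit()
        intercept, slope = res.params
        if self.variant == "linear":
            tau_y, eta = max(float(intercept), 0.0), float(slope)
        else:
            tau_y = max(float(intercept), 0.0) ** 2
            eta = max(float(slope), 0.0) ** 2
        return CassonResults(
            tau_y=tau_y,
            eta=eta,
            r_squared=float(res.rsquared),
            variant=self.variant,
            temperature_C=self.curve.temperature_C,
            formulation_id=self.curve.formulation_id,
            nobs=int(res.nobs),
        )


@dataclass(frozen=True)
class CassonResults:
    """Fitted yield stress tau_y [Pa] and consistency eta [Pa*s]."""

    tau_y: float
    eta: float
    r_squared: float
    variant: str
    temperature_C: float = float("nan")
    formulation_id: str = ""
    nobs: int = 0

    def predict(self, shear_rate):
        g = np.asarray(shear_rate, dtype=float)
        if self.variant == "linear":
            return self.tau_y + self.eta * g
        return (np.sqrt(self.tau_y) + np.sqrt(self.eta * g)) ** 2

    def summary(self) -> str:
        return "\n".join(
            [
                f"Yield-stress flow fit ({self.variant} variant)",
                "-" * 40,
                f"  tau_y (Pa)   : {self.tau_y:10.4f}",
                f"  eta (Pa*s)   : {self.eta:10.6f}",
                f"  R^2          : {self.r_squared:10.4f}",
                f"  n points     : {self.nobs:10d}",
            ]
        )


def fit_casson(curve: FlowCurve, variant: CassonVariant = "linear") -> CassonResults:
    """Convenience wrapper: ``CassonModel(curve, variant).fit()``."""
    return CassonModel(curve, variant).fit()


# ---------------------------------------------------------------------------
# thixotropy


def hysteresis_area(curve: FlowCurve) -> float:
    """Area of the up/down hysteresis loop on the rate-stress plane [Pa/s].

    The descending branch is linearly interpolated onto the ascending
    branch's rate grid over the shared rate interval and the trapezoid rule
    integrates (tau_up - tau_down).  Positive area means the up-curve lies
    above the down-curve (thixotropy); negative area is anti-thixotropic.
    """
    up_r, up_s = curve.ascending()
    down_r, down_s = curve.descending()
    if up_r.size < 2 or down_r.size < 2:
        raise InsufficientDataError("both phases need >= 2 points")
    lo = max(up_r.min(), down_r.min())
    hi = min(up_r.max(), down_r.max())
    if lo >= hi:
        raise InvalidInputError("ascending and descending rate ranges do not overlap")
    grid = up_r[(up_r >= lo) & (up_r <= hi)]
    grid = np.unique(np.concatenate([[lo], grid, [hi]]))
    # np.interp needs ascending x; the descending branch is stored high->low
    order = np.argsort(down_r)
    up_on = np.interp(grid, up_r, up_s)
    down_on = np.interp(grid, down_r[order], down_s[order])
    return float(np.trapezoid(up_on - down_on, grid))


def compare_thixotropy(
    areas_cold: dict[str, float], areas_hot: dict[str, float]
) -> pd.DataFrame:
    """Per-formulation hot/cold loop-area ratios and cold-area ordering.

    ``areas_cold``/``areas_hot`` map formulation id -> loop area at the lower
    (storage, e.g. 25 C) and higher (skin, e.g. 32 C) temperature.  A zero
    cold-temperature area leaves the ratio undefined (NaN).  ``rank`` orders
    formulations by decreasing cold-temperature area.
    """
    ids = sorted(set(areas_cold) & set(areas_hot))
    if not ids:
        raise InvalidInputError("no formulations common to both temperature sets")
    cold = np.array([areas_cold[i] for i in ids])
    hot = np.array([areas_hot[i] for i in ids])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(cold != 0, hot / cold, np.nan)
    if np.any(cold == 0):
        warnings.warn("zero cold-temperature loop area: ratio undefined", stacklevel=2)
    df = pd.DataFrame(
        {
            "formulation_id": ids,
            "area_cold": cold,
            "area_hot": hot,
            "ratio_hot_over_cold": ratio,
            "smaller_when_hot": hot < cold,
        }
    )
    df["rank_by_cold_area"] = (
        df["area_cold"].rank(ascending=False, method="min").astype(int)
    )
    return df
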