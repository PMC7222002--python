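"""Parallel-plate spreadability analysis.

An ointment aliquot is compressed between glass plates under increasing load
and the spread diameter is read after each load step.  Sample area grows with
the logarithm of the total applied mass, so the spreading curve is summarized
by an ordinary least-squares fit of

    area [cm^2] = a * ln(load [g]) + b

over the applied-load range.  The area under that curve (AUC) integrates
spreading capacity over the whole load programme, and the spreadability index
i(S) = AUC_test / AUC_reference compares a formulation against a reference
base: i(S) > 1 means the test formulation spreads better.

The abscissa is the TOTAL applied mass, i.e. the mass of the upper plate
(298.0 g by default) plus the added weights, so the default integration range
for a 20-500 g weight programme is [298, 798] g.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import InsufficientDataError, InvalidInputError

DEFAULT_PLATE_MASS_G = 298.0
#: total-load integration range for the standard 20-500 g weight programme
DEFAULT_LOAD_RANGE_G = (298.0, 798.0)


@dataclass(frozen=True)
class SpreadabilityCurve:
    """Load-diameter record of one spreadability test.

    Parameters
    ----------
    formulation_id : str
        Label of the formulation (e.g. ``"F-1"``).
    replicates : sequence of sequence of (float, float)
        One series per replicate; each element is ``(added_mass_g,
        diameter_cm)``.  Added mass 0.0 is the upper plate alone.
    plate_mass_g : float
        Baseline mass of the upper glass plate resting on the sample.
    """

    formulation_id: str
    replicates: tuple[tuple[tuple[float, float], ...], ...]
    plate_mass_g: float = DEFAULT_PLATE_MASS_G

    def __post_init__(self) -> None:
        if self.plate_mass_g <= 0:
            raise InvalidInputError("plate_mass_g must be positive")
        if not self.replicates:
            raise InvalidInputError("at least one replicate is required")
        object.__setattr__(
            self,
            "replicates",
            tuple(tuple((float(m), float(d)) for m, d in rep) for rep in self.replicates),
        )
        for r, rep in enumerate(self.replicates):
            if len(rep) < 3:
                raise InsufficientDataError(
                    f"replicate {r}: need >= 3 load steps, got {len(rep)}"
                )
            masses = [m for m, _ in rep]
            if any(m < 0 for m in masses):
                raise InvalidInputError(f"replicate {r}: negative added mass")
            if any(b <= a for a, b in zip(masses, masses[1:])):
                raise InvalidInputError(
                    f"replicate {r}: added masses must be strictly increasing"
                )
            for i, (m, d) in enumerate(rep):
                if d <= 0:
                    raise InvalidInputError(
                        f"replicate {r}, row {i} (added mass {m} g): "
                        f"non-positive diameter {d} cm"
                    )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        formulation_id: str | None = None,
        plate_mass_g: float = DEFAULT_PLATE_MASS_G,
    ) -> "SpreadabilityCurve":
        """Build from a long table with columns
        ``formulation_id, replicate, added_mass_g, diameter_cm``."""
        required = {"replicate", "added_mass_g", "diameter_cm"}
        missing = required - set(df.columns)
        if missing:
            raise InvalidInputError(f"missing columns: {sorted(missing)}")
        if formulation_id is None:
            ids = df["formulation_id"].unique()
            if len(ids) != 1:
                raise InvalidInputError(
                    "table holds several formulations; pass formulation_id"
                )
            formulation_id = str(ids[0])
        elif "formulation_id" in df.columns:
            df = df[df["formulation_id"] == formulation_id]
        reps = []
        for _, grp in df.sort_values("added_mass_g").groupby("replicate"):
            reps.append(tuple(zip(grp["added_mass_g"], grp["diameter_cm"])))
        return cls(formulation_id, tuple(reps), plate_mass_g)


def diameters_to_areas(curve: SpreadabilityCurve) -> pd.DataFrame:
    """Per-load mean sample area.

    Areas are computed per measurement as ``pi * (d/2)**2`` and averaged over
    replicates at each load step.  Loads are reported as total applied mass,
    ``plate_mass_g + added_mass_g``.

    Returns
    -------
    DataFrame with columns ``load_g`` (total), ``area_cm2`` (mean over
    replicates) and ``n`` (replicate count at that load).
    """
    rows: dict[float, list[float]] = {}
    for rep in curve.replicates:
        for added, d in rep:
            rows.setdefault(added, []).append(math.pi * (d / 2.0) ** 2)
    loads = sorted(rows)
    return pd.DataFrame(
        {
            "load_g": [curve.plate_mass_g + m for m in loads],
            "area_cm2": [float(np.mean(rows[m])) for m in loads],
            "n": [len(rows[m]) for m in loads],
        }
    )


class LogSpreadModel:
    """OLS model of sample area on the natural log of total applied load."""

    def __init__(self, loads_g: Sequence[float], areas_cm2: Sequence[float]):
        loads = np.asarray(loads_g, dtype=float)
        areas = np.asarray(areas_cm2, dtype=float)
        if loads.shape != areas.shape or loads.ndim != 1:
            raise InvalidInputError("loads and areas must be 1-D and equal length")
        if np.any(loads <= 0):
            raise InvalidInputError("loads must be positive (log abscissa)")
        if len(np.unique(loads)) < 3:
            raise InsufficientDataError(
                f"need >= 3 distinct loads, got {len(np.unique(loads))}"
            )
        self.loads = loads
        self.areas = areas

    def fit(self) -> "LogSpreadResults":
        X = sm.add_constant(np.log(self.loads))
        res = sm.OLS(self.areas, X).fit()
        b, a = res.params
        return LogSpreadResults(
            a=float(a),
            b=float(b),
            r_squared=float(res.rsquared),
            load_range=(float(self.loads.min()), float(self.loads.max())),
            a_se=float(res.bse[1]),
            b_se=float(res.bse[0]),
            nobs=int(res.nobs),
        )


@dataclass(frozen=True)
class LogSpreadResults:
    """Fitted log-law ``area = a*ln(load) + b`` with OLS diagnostics."""

    a: float
    b: float
    r_squared: float
    load_range: tuple[float, float]
    a_se: float = float("nan")
    b_se: float = float("nan")
    nobs: int = 0

    def predict(self, load_g):
        load = np.asarray(load_g, dtype=float)
        return self.a * np.log(load) + self.b

    def auc(self, load_range: tuple[float, float] | None = None) -> float:
        """Closed-form area under the fitted curve (see :func:`area_under_spread`)."""
        return area_under_spread(self, load_range)

    def equation(self) -> str:
        return f"y = {self.a:.3f}*ln(x) {'+' if self.b >= 0 else '-'} {abs(self.b):.3f}"

    def summary(self) -> str:
        lo, hi = self.load_range
        return "\n".join(
            [
                "Log-law spreadability fit",
                "-" * 40,
                f"  a (cm^2 per ln g) : {self.a:10.3f}  (se {self.a_se:.3f})",
                f"  b (cm^2)          : {self.b:10.3f}  (se {self.b_se:.3f})",
                f"  R^2               : {self.r_squared:10.3f}",
                f"  load range (g)    : [{lo:.0f}, {hi:.0f}]",
                f"  AUC (cm^2*g)      : {self.auc():10.1f}",
                f"  n                 : {self.nobs:10d}",
            ]
        )


def fit_log_spread(
    loads_g: Sequence[float],
    areas_cm2: Sequence[float],
    load_range: tuple[float, float] | None = None,
) -> LogSpreadResults:
    """Fit ``area = a*ln(load) + b`` by OLS, optionally restricted to a load window."""
    loads = np.asarray(loads_g, dtype=float)
    areas = np.asarray(areas_cm2, dtype=float)
    if load_range is not None:
        lo, hi = load_range
        keep = (loads >= lo) & (loads <= hi)
        loads, areas = loads[keep], areas[keep]
    return LogSpreadModel(loads, areas).fit()


def area_under_spread(
    fit: LogSpreadResults, load_range: tuple[float, float] | None = None
) -> float:
    """Closed-form AUC of the fitted log law.

    ``∫(a ln x + b) dx = a (x ln x − x) + b x`` evaluated over ``load_range``
    (default: the fit's own load range, [298, 798] g for the standard
    programme).
    """
    lo, hi = load_range if load_range is not None else fit.load_range
    if lo >= hi:
        raise InvalidInputError(f"degenerate load range [{lo}, {hi}]")
    if lo < 0:
        raise InvalidInputError("load range must be non-negative")

    def antider(x: float) -> float:
        if x == 0:  # x*ln(x) -> 0
            return 0.0
        return fit.a * (x * math.log(x) - x) + fit.b * x

    return antider(hi) - antider(lo)


def auc_trapezoid(loads_g: Sequence[float], areas_cm2: Sequence[float]) -> float:
    """Trapezoid-rule AUC on the raw per-load mean areas (numerical variant)."""
    loads = np.asarray(loads_g, dtype=float)
    areas = np.asarray(areas_cm2, dtype=float)
    if len(loads) < 2:
        raise InsufficientDataError("need >= 2 points for a trapezoid AUC")
    order = np.argsort(loads)
    return float(np.trapezoid(areas[order], loads[order]))


def spreadability_index(
    auc_test: float, auc_reference: float, ndigits: int | None = 3
) -> float:
    """Spreadability index i(S) = AUC_test / AUC_reference.

    Values above 1.0 mean the tested formulation spreads better than the
    reference.  Reported rounded to 3 decimals by default (``ndigits=None``
    disables rounding).
    """
    if auc_reference <= 0:
        raise InvalidInputError("reference AUC must be positive")
    if auc_test <= 0:
        raise InvalidInputError("test AUC must be positive")
    ratio = auc_test / auc_reference
    return round(ratio, ndigits) if ndigits is not None else ratio
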