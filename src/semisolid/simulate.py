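"""Synthetic instrument generators with known ground truth.

No raw instrument exports exist for this kind of bench study, so every
analysis stage is validated against simulated data: each generator draws an
instrument-realistic record from stated ground-truth parameters and returns
that ground truth alongside, enabling round-trip (parameter-recovery) tests.

Generators
----------
* :func:`gen_spreadability`  — log-law spreading with area-level noise,
  converted back to diameters (parallel-plate test, n=5 replicates).
* :func:`gen_flow_curve`     — shear-thinning thixotropic up/down ramp from a
  first-order structural-kinetics model.
* :func:`gen_tpa`            — piecewise-linear double-compression force-time
  trace realizing a prescribed texture profile exactly.
* :func:`gen_release_experiment` — timed absorbances from a chosen release
  law measured through a stirred vessel with aliquot withdrawal/replacement
  and photometric noise.

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .exceptions import InvalidInputError
from .release import ReleaseExperiment, ReleaseProfile, release_law
from .rheology import FlowCurve
from .spreadability import DEFAULT_PLATE_MASS_G, SpreadabilityCurve
from .texture import (
    ASCENT_SPEED_MM_S,
    DESCENT_SPEED_MM_S,
    TARGET_DEPTH_MM,
    TRIGGER_FORCE_N,
    TPAProfile,
    TPATrace,
)

#: added-weight programme of the parallel-plate test: plate alone, then
#: 20-500 g in 20 g steps
DEFAULT_ADDED_LOADS_G = tuple(float(m) for m in range(0, 501, 20))
#: release sampling schedule [min]
DEFAULT_RELEASE_TIMES_MIN = (15.0, 30.0, 60.0, 90.0, 120.0, 150.0)
#: printed UV calibration at 276.5 nm: absorbance = slope*conc + intercept
DEFAULT_CALIBRATION = (0.5831, -0.0169)
#: photometric accuracy bound of the spectrophotometer [A]
PHOTOMETRIC_NOISE_A = 0.005


@dataclass(frozen=True)
class GeneratorConfig:
    """Bundled noise levels and schedules for a whole synthetic study."""

    seed: int = 0
    spread_area_sd_cm2: float = 0.5
    stress_sd_Pa: float = 0.5
    force_sd_N: float = 0.0
    photometric_sd_A: float = PHOTOMETRIC_NOISE_A
    added_loads_g: tuple[float, ...] = DEFAULT_ADDED_LOADS_G
    release_times_min: tuple[float, ...] = DEFAULT_RELEASE_TIMES_MIN

    def __post_init__(self) -> None:
        for name in ("spread_area_sd_cm2", "stress_sd_Pa", "force_sd_N",
                     "photometric_sd_A"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be >= 0")


# ---------------------------------------------------------------------------
# spreadability


def gen_spreadability(
    a: float,
    b: float,
    added_loads_g: Sequence[float] = DEFAULT_ADDED_LOADS_G,
    n_reps: int = 5,
    noise_sd_cm2: float = 0.5,
    seed: int = 0,
    plate_mass_g: float = DEFAULT_PLATE_MASS_G,
    formulation_id: str = "SYN",
) -> SpreadabilityCurve:
    """Simulate a parallel-plate spreadability test from a log law.

    True areas follow ``a*ln(plate + added) + b``; Gaussian noise with SD
    ``noise_sd_cm2`` is added on the area scale and the noisy areas are
    converted back to the diameters the operator would read.
    """
    rng = np.random.default_rng(seed)
    loads = np.asarray(added_loads_g, dtype=float)
    total = plate_mass_g + loads
    true_areas = a * np.log(total) + b
    if np.any(true_areas <= 0):
        raise InvalidInputError(
            "log law implies non-positive area at the smallest load"
        )
    reps = []
    for _ in range(n_reps):
        areas = true_areas + rng.normal(0.0, noise_sd_cm2, size=total.size)
        if np.any(areas <= 0):
            raise InvalidInputError("noise drove a simulated area non-positive")
        diameters = 2.0 * np.sqrt(areas / math.pi)
        reps.append(tuple(zip(loads, diameters)))
    return SpreadabilityCurve(formulation_id, tuple(reps), plate_mass_g)


# ---------------------------------------------------------------------------
# thixotropic flow curves


def gen_flow_curve(
    tau_y: float,
    eta: float,
    breakdown_rate: float = 1e-4,
    recovery_rate: float = 0.05,
    rate_min_s1: float = 100.0,
    rate_max_s1: float = 1100.0,
    n_steps: int = 50,
    step_duration_s: float = 1.0,
    temperature_C: float = 25.0,
    noise_sd_Pa: float = 0.0,
    lambda_floor: float = 0.2,
    seed: int = 0,
    formulation_id: str = "SYN",
) -> FlowCurve:
    """Simulate an up/down shear ramp with first-order structural kinetics.

    A structure parameter ``lam`` in [0, 1] decays under shear and recovers at
    rest: ``dlam/dt = -k_b*rate*lam + k_r*(1-lam)``.  Measured stress is the
    yield-stress law scaled by the surviving structure,
    ``tau = (tau_y + eta*rate) * (floor + (1-floor)*lam)``, so a positive
    breakdown rate puts the ascending branch above the descending one (a
    thixotropic hysteresis loop); ``breakdown_rate=0`` gives a reversible
    curve with coincident branches.

    The piecewise-constant-rate structure ODE is advanced exactly per step
    (it is linear in ``lam`` at fixed rate).
    """
    if rate_min_s1 <= 0 or rate_max_s1 <= rate_min_s1:
        raise InvalidInputError("need 0 < rate_min < rate_max")
    if n_steps < 2 or step_duration_s <= 0:
        raise InvalidInputError("need >= 2 ramp steps of positive duration")
    if breakdown_rate < 0 or recovery_rate < 0:
        raise InvalidInputError("kinetic rates must be >= 0")
    if not 0 <= lambda_floor < 1:
        raise InvalidInputError("lambda_floor must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    up = np.linspace(rate_min_s1, rate_max_s1, n_steps)
    ramp = np.concatenate([up, up[::-1]])
    phases = ["up"] * n_steps + ["down"] * n_steps
    lam = 1.0
    stresses = np.empty(ramp.size)
    for i, rate in enumerate(ramp):
        r = breakdown_rate * rate + recovery_rate
        lam_inf = recovery_rate / r if r > 0 else 1.0
        lam = lam_inf + (lam - lam_inf) * math.exp(-r * step_duration_s)
        structure = lambda_floor + (1.0 - lambda_floor) * lam
        stresses[i] = (tau_y + eta * rate) * structure
    stresses = stresses + rng.normal(0.0, noise_sd_Pa, size=stresses.size)
    return FlowCurve(
        shear_rate=ramp,
        shear_stress=stresses,
        phase=np.array(phases, dtype=object),
        temperature_C=temperature_C,
        formulation_id=formulation_id,
    )


# ---------------------------------------------------------------------------
# TPA traces


def gen_tpa(
    profile: TPAProfile,
    descent_speed_mm_s: float = DESCENT_SPEED_MM_S,
    ascent_speed_mm_s: float = ASCENT_SPEED_MM_S,
    depth_mm: float = TARGET_DEPTH_MM,
    pause_s: float = 60.0,
    sample_rate_hz: float = 50.0,
    noise_sd_N: float = 0.0,
    seed: int = 0,
    formulation_id: str = "SYN",
) -> TPATrace:
    """Build a double-compression force-time trace realizing ``profile``.

    The trace is piecewise linear.  Episode 1 rises to ``hardness`` over the
    compression time ``depth/descent_speed``, falls symmetrically, then dips
    into a triangular detachment lobe whose minimum is ``adhesion_force`` and
    whose work (ascent speed times time-area) equals ``adhesiveness``.  After
    the pause, episode 2 is a time-scaled copy with scale ``elasticity`` and
    peak ``cohesiveness/elasticity * hardness``, so its area ratio A2/A1 is
    exactly ``cohesiveness`` and its travel ratio D2/D1 exactly
    ``elasticity``.

    Sampling uses a uniform grid with the piecewise-linear breakpoints
    injected, so trapezoid integrals of the noiseless trace are exact and the
    extraction round-trips to machine precision.
    """
    h = profile.hardness_N
    if profile.adhesiveness_mJ > 0 and profile.adhesion_force_N == 0:
        raise InvalidInputError(
            "inconsistent profile: positive adhesiveness with zero adhesion force"
        )
    if profile.adhesiveness_mJ == 0 and profile.adhesion_force_N < 0:
        raise InvalidInputError(
            "inconsistent profile: negative adhesion force with zero adhesiveness"
        )
    h2 = profile.cohesiveness / profile.elasticity * h
    if h2 <= 2 * TRIGGER_FORCE_N:
        raise InvalidInputError(
            "second-episode peak would sit at the trigger threshold; "
            "cohesiveness/elasticity ratio too small for this hardness"
        )
    t_c1 = depth_mm / descent_speed_mm_s
    t_f1 = t_c1  # symmetric release of the first compression
    t_c2 = profile.elasticity * t_c1
    t_f2 = profile.elasticity * t_f1
    lead = 1.0

    # breakpoints (time, force) of the piecewise-linear trace
    pts = [(0.0, 0.0), (lead, 0.0)]
    t = lead
    pts.append((t + t_c1, h))
    t += t_c1
    pts.append((t + t_f1, 0.0))
    t += t_f1
    if profile.adhesiveness_mJ > 0:
        # triangular lobe: work = ascent_speed * (1/2 * |Fmin| * T)
        t_lobe = 2.0 * profile.adhesiveness_mJ / (
            abs(profile.adhesion_force_N) * ascent_speed_mm_s
        )
        pts.append((t + t_lobe / 2.0, profile.adhesion_force_N))
        pts.append((t + t_lobe, 0.0))
        t += t_lobe
    pts.append((t + pause_s, 0.0))
    t += pause_s
    pts.append((t + t_c2, h2))
    t += t_c2
    pts.append((t + t_f2, 0.0))
    t += t_f2
    pts.append((t + lead, 0.0))
    t += lead

    bp_t = np.array([p[0] for p in pts])
    bp_f = np.array([p[1] for p in pts])
    grid = np.union1d(np.arange(0.0, t, 1.0 / sample_rate_hz), bp_t)
    force = np.interp(grid, bp_t, bp_f)
    if noise_sd_N > 0:
        rng = np.random.default_rng(seed)
        force = force + rng.normal(0.0, noise_sd_N, size=force.size)
    return TPATrace(
        time_s=grid,
        force_N=force,
        descent_speed_mm_s=descent_speed_mm_s,
        ascent_speed_mm_s=ascent_speed_mm_s,
        target_depth_mm=depth_mm,
        pause_s=pause_s,
        formulation_id=formulation_id,
    )


# ---------------------------------------------------------------------------
# release experiments


def gen_release_experiment(
    model: Literal["zero", "first", "higuchi", "korsmeyer_peppas", "weibull"],
    params: dict[str, float],
    loaded_dose_mg: float,
    orifice_area_cm2: float = 3.8,
    vessel_volume_ml: float = 50.0,
    sample_volume_ml: float = 3.0,
    times_min: Sequence[float] = DEFAULT_RELEASE_TIMES_MIN,
    calibration: tuple[float, float] = DEFAULT_CALIBRATION,
    noise_a: float = PHOTOMETRIC_NOISE_A,
    n_reps: int = 1,
    seed: int = 0,
    cap_at_dose: bool = True,
    formulation_id: str = "SYN",
) -> tuple[ReleaseExperiment, ReleaseProfile]:
    """Forward-simulate an in-vitro release run measured through a vessel.

    The chosen kinetic law gives the true cumulative release per area Q(t)
    [mg/cm^2].  Mass released into the vessel accumulates between sampling
    times; at each time an aliquot of ``sample_volume_ml`` is withdrawn
    (removing dissolved drug) and replaced with fresh medium, and the
    pre-withdrawal concentration is converted to an absorbance through the
    calibration line plus uniform photometric noise on +/- ``noise_a``.

    When ``cap_at_dose`` is set, Q(t) saturates at ``loaded_dose/area`` (with
    a warning); disable it to validate the measurement chain against the pure
    kinetic law.

    Returns the experiment record and the ground-truth profile.
    """
    times = np.asarray(times_min, dtype=float)
    if np.any(np.diff(times) <= 0) or np.any(times <= 0):
        raise InvalidInputError("sampling times must be positive and increasing")
    if sample_volume_ml >= vessel_volume_ml:
        raise InvalidInputError("sample volume must be below vessel volume")
    rng = np.random.default_rng(seed)
    slope, intercept = calibration

    q_true = release_law(model, params, times)
    q_max = loaded_dose_mg / orifice_area_cm2
    if np.any(q_true > q_max):
        if cap_at_dose:
            warnings.warn(
                f"{model} release exceeds the loaded dose; capped at "
                f"{q_max:.3f} mg/cm^2",
                stacklevel=2,
            )
            q_true = np.minimum(q_true, q_max)

    absorbances = np.empty((n_reps, times.size))
    for rep in range(n_reps):
        released_mass = q_true * orifice_area_cm2  # mg in vessel, cumulative
        withdrawn = 0.0
        conc = np.empty(times.size)
        for i, m in enumerate(released_mass):
            conc[i] = (m - withdrawn) / vessel_volume_ml
            withdrawn += sample_volume_ml * conc[i]
        a = slope * conc + intercept
        if noise_a > 0:
            a = a + rng.uniform(-noise_a, noise_a, size=a.size)
        absorbances[rep] = a

    exp = ReleaseExperiment(
        times_min=times,
        absorbances=absorbances,
        vessel_volume_ml=vessel_volume_ml,
        sample_volume_ml=sample_volume_ml,
        orifice_area_cm2=orifice_area_cm2,
        loaded_dose_mg=loaded_dose_mg,
        formulation_id=formulation_id,
    )
    truth = ReleaseProfile(times_min=times, q_mg_cm2=q_true)
    return exp, truth
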