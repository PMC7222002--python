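"""Texture profile analysis (TPA) of force-time traces.

A cylindrical probe compresses the sample twice with a pause in between; the
force-time record yields five texture parameters:

* hardness        — peak force of the first compression [N];
* cohesiveness    — A2/A1, ratio of positive force-time areas of the second
                    and first episodes (internal-structure recovery);
* adhesiveness    — work to detach the probe, the negative-force lobe after
                    the first episode converted to work via the ascent speed
                    (N * mm/s * s = mJ);
* elasticity      — D2/D1, ratio of the compression travel of the two
                    episodes (travel = descent speed x compression duration);
* adhesion force  — the most negative force reached [N].

Tensile strength F/A and Young's modulus (F/A)/(dl/l) summarize bulk
mechanical resistance from the same probe readings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError, SegmentationError

DESCENT_SPEED_MM_S = 5.0
ASCENT_SPEED_MM_S = 0.1
TARGET_DEPTH_MM = 10.0
TRIGGER_FORCE_N = 0.01
#: samples a force excursion must persist to count as a compression episode
DEBOUNCE_SAMPLES = 3


@dataclass(frozen=True)
class TPATrace:
    """Force-time record of a double-compression test."""

    time_s: np.ndarray
    force_N: np.ndarray
    descent_speed_mm_s: float = DESCENT_SPEED_MM_S
    ascent_speed_mm_s: float = ASCENT_SPEED_MM_S
    target_depth_mm: float = TARGET_DEPTH_MM
    trigger_force_N: float = TRIGGER_FORCE_N
    pause_s: float = 60.0
    formulation_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        f = np.asarray(self.force_N, dtype=float)
        if t.shape != f.shape or t.ndim != 1:
            raise InvalidInputError("time and force must be 1-D and equal length")
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError("time must be strictly increasing")
        for name, v in (
            ("descent_speed_mm_s", self.descent_speed_mm_s),
            ("ascent_speed_mm_s", self.ascent_speed_mm_s),
            ("target_depth_mm", self.target_depth_mm),
            ("trigger_force_N", self.trigger_force_N),
        ):
            if v <= 0:
                raise InvalidInputError(f"{name} must be positive")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "force_N", f)


@dataclass(frozen=True)
class TPAProfile:
    """The five extracted texture parameters."""

    hardness_N: float
    cohesiveness: float
    adhesiveness_mJ: float
    elasticity: float
    adhesion_force_N: float

    def __post_init__(self) -> None:
        if self.hardness_N <= 0:
            raise InvalidInputError("hardness must be positive")
        if self.cohesiveness <= 0:
            raise InvalidInputError("cohesiveness must be positive")
        if self.adhesiveness_mJ < 0:
            raise InvalidInputError("adhesiveness must be non-negative")
        if self.elasticity <= 0:
            raise InvalidInputError("elasticity must be positive")
        if self.adhesion_force_N > 0:
            raise InvalidInputError("adhesion force must be <= 0")

    def as_dict(self) -> dict[str, float]:
        return {
            "hardness_N": self.hardness_N,
            "cohesiveness": self.cohesiveness,
            "adhesiveness_mJ": self.adhesiveness_mJ,
            "elasticity": self.elasticity,
            "adhesion_force_N": self.adhesion_force_N,
        }


@dataclass(frozen=True)
class Segmentation:
    """Index ranges of the two compression episodes and the detachment lobe.

    ``episodes`` holds (start, peak, end) sample indices per episode, where
    start/end sit at the zero-force shoulders around the positive excursion.
    ``lobe`` is the (start, end) index range of the negative-force detachment
    lobe after episode 1 (None if the trace never goes negative there).
    """

    episodes: tuple[tuple[int, int, int], ...]
    lobe: tuple[int, int] | None


def segment_cycles(trace: TPATrace) -> Segmentation:
    """Locate the two compression episodes by trigger-force threshold crossing.

    Runs of force above the trigger threshold lasting at least
    :data:`DEBOUNCE_SAMPLES` samples are compression episodes; each run is
    extended backward/forward to the nearest non-positive-force sample so the
    episode covers the full positive excursion.  Exactly two episodes are
    required; any other count raises :class:`SegmentationError` naming the
    count found.
    """
    f = trace.force_N
    above = f > trace.trigger_force_N
    # run-length encode the boolean mask
    edges = np.flatnonzero(np.diff(above.astype(int)))
    starts = [0] if above[0] else []
    starts += [int(e) + 1 for e in edges if above[e + 1]]
    ends = [int(e) + 1 for e in edges if above[e]]  # exclusive
    if above[-1]:
        ends.append(len(f))
    runs = [(s, e) for s, e in zip(starts, ends) if e - s >= DEBOUNCE_SAMPLES]
    if len(runs) != 2:
        raise SegmentationError(
            f"expected 2 compression episodes, found {len(runs)}"
        )
    episodes = []
    prev_end = 0
    for s, e in runs:
        start = s
        while start > prev_end and f[start - 1] > 0:
            start -= 1
        if start > prev_end:  # include the zero-force shoulder sample
            start -= 1
        end = e - 1
        while end < len(f) - 1 and f[end + 1] > 0:
            end += 1
        if end < len(f) - 1:
            end += 1
        peak = start + int(np.argmax(f[start : end + 1]))
        episodes.append((start, peak, end))
        prev_end = end
    # negative detachment lobe between the first episode and the second
    e1_end = episodes[0][2]
    e2_start = episodes[1][0]
    neg = np.flatnonzero(f[e1_end : e2_start + 1] < 0) + e1_end
    lobe = (int(neg[0]), int(neg[-1])) if neg.size else None
    return Segmentation(episodes=tuple(episodes), lobe=lobe)


def _positive_area(t: np.ndarray, f: np.ndarray) -> float:
    return float(np.trapezoid(np.clip(f, 0.0, None), t))


def extract_tpa(trace: TPATrace) -> TPAProfile:
    """Extract the five TPA parameters from a segmented trace.

    Episode regions span from each episode's leading zero-force shoulder to
    the next episode's (or the trace's) start, so the positive-force areas A1
    and A2 are the full force-time integrals of each cycle.  Compression
    travel D uses the descent speed times the rise time from the episode
    start to its force peak.
    """
    t, f = trace.time_s, trace.force_N
    seg = segment_cycles(trace)
    (s1, p1, e1), (s2, p2, e2) = seg.episodes

    hardness = float(f[s1 : e1 + 1].max())
    a1 = _positive_area(t[s1 : s2 + 1], f[s1 : s2 + 1])
    a2 = _positive_area(t[s2:], f[s2:])
    if a1 <= 0:
        raise InvalidInputError("first-episode area A1 is zero; cohesiveness undefined")
    cohesiveness = a2 / a1

    d1 = trace.descent_speed_mm_s * (t[p1] - t[s1])
    d2 = trace.descent_speed_mm_s * (t[p2] - t[s2])
    if d1 <= 0:
        raise InvalidInputError("first compression has zero rise time")
    elasticity = d2 / d1

    adhesion_force = min(float(f.min()), 0.0)
    if seg.lobe is not None:
        lo, hi = seg.lobe
        # include the zero-crossing shoulders for an exact lobe integral
        lo = max(lo - 1, 0)
        hi = min(hi + 1, len(f) - 1)
        neg_area = float(np.trapezoid(np.clip(-f[lo : hi + 1], 0.0, None), t[lo : hi + 1]))
        adhesiveness = trace.ascent_speed_mm_s * neg_area  # N * mm = mJ
    else:
        adhesiveness = 0.0
        warnings.warn("no negative detachment lobe found; adhesiveness = 0",
                      stacklevel=2)
    return TPAProfile(
        hardness_N=hardness,
        cohesiveness=cohesiveness,
        adhesiveness_mJ=adhesiveness,
        elasticity=elasticity,
        adhesion_force_N=adhesion_force,
    )


def tensile_strength(force_N: float, area_m2: float) -> float:
    """Tensile strength F/A in Pa."""
    if area_m2 <= 0:
        raise InvalidInputError("probe cross-sectional area must be positive")
    if force_N <= 0:
        raise InvalidInputError("force must be positive")
    return force_N / area_m2


def youngs_modulus(force_N: float, area_m2: float, delta_l_m: float, l_m: float) -> float:
    """Young's modulus (F/A)/(dl/l) in Pa."""
    if delta_l_m <= 0:
        raise InvalidInputError("length deformation must be positive")
    if l_m <= 0:
        raise InvalidInputError("original length must be positive")
    if delta_l_m > l_m:
        raise InvalidInputError("deformation cannot exceed original length")
    return tensile_strength(force_N, area_m2) / (delta_l_m / l_m)


def texture_ratios(
    profiles: dict[str, TPAProfile], reference: str
) -> pd.DataFrame:
    """Per-parameter ratios and percent changes of each profile vs. a reference.

    Ratios are test/reference; percent change is 100*(test-reference)/|reference|.
    Zero reference entries yield NaN ratios.
    """
    if reference not in profiles:
        raise InvalidInputError(f"reference {reference!r} not among profiles")
    ref = profiles[reference].as_dict()
    rows = []
    for fid, prof in profiles.items():
        d = prof.as_dict()
        for param, val in d.items():
            rv = ref[param]
            rows.append(
                {
                    "formulation_id": fid,
                    "parameter": param,
                    "value": val,
                    "reference_value": rv,
                    "ratio": val / rv if rv != 0 else np.nan,
                    "percent_change": 100.0 * (val - rv) / abs(rv) if rv != 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)
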