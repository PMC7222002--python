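"""File I/O, study configuration and report generation.

All instrument files are plain delimited text (tab-separated by default)
with a one-line header; texture traces carry a small ``# key: value``
metadata block above the header.  :func:`run_study` drives a complete
synthetic study — generate instrument files with known ground truth, read
them back, run every analysis stage, and write report tables shaped like a
formulation-characterization writeup (pH summary, spreadability fits + index,
step viscosities, texture parameters, kinetic R^2 matrix, release-rate
table).

Statistical note written into the report header: pairwise tests are Welch t
at alpha = 0.05 with no multiple-testing correction.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import release as rel
from . import rheology as rheo
from . import simulate as sim
from . import spreadability as spread
from . import stats as st
from . import texture as tex
from .exceptions import InvalidInputError, SchemaError

log = logging.getLogger("semisolid")

SEP = "\t"
ALLOWED_CONC_MG_G = (0.0, 5.0, 10.0, 15.0, 20.0, 25.0)


@dataclass(frozen=True)
class FormulationSpec:
    """Identity and composition of one formulation (per 10 g batch)."""

    id: str
    drug_mg: float  # mg of drug per 10 g batch
    acid_ml: float  # mL of 1 mol/L acetic acid
    base: str = "to 10.0 g"

    def __post_init__(self) -> None:
        if self.drug_mg < 0 or self.acid_ml < 0:
            raise InvalidInputError("composition amounts must be >= 0")
        if self.conc_mg_g not in ALLOWED_CONC_MG_G:
            raise InvalidInputError(
                f"{self.id}: concentration {self.conc_mg_g} mg/g outside the "
                f"studied set {ALLOWED_CONC_MG_G}"
            )

    @property
    def conc_mg_g(self) -> float:
        """Drug concentration in mg per g of ointment."""
        return self.drug_mg / 10.0


#: the seven-formulation design: plain base, hydrated base, five drug loads
DEFAULT_FORMULATIONS: tuple[FormulationSpec, ...] = (
    FormulationSpec("F-1", 0.0, 0.0),
    FormulationSpec("F-2", 0.0, 1.0),
    FormulationSpec("F-3", 50.0, 1.0),
    FormulationSpec("F-4", 100.0, 1.0),
    FormulationSpec("F-5", 150.0, 1.0),
    FormulationSpec("F-6", 200.0, 1.0),
    FormulationSpec("F-7", 250.0, 1.0),
)


# ---------------------------------------------------------------------------
# delimited-text readers / writers


def _read_table(path: str | Path, required: set[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {sorted(missing)}")
    return df


def write_table(df: pd.DataFrame, path: str | Path, header_note: str = "") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header_note:
            for line in header_note.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep=SEP, index=False, lineterminator="\n")


def read_spreadability(
    path: str | Path, plate_mass_g: float = spread.DEFAULT_PLATE_MASS_G
) -> dict[str, spread.SpreadabilityCurve]:
    """Read a spreadability table into per-formulation curves."""
    df = _read_table(
        path, {"formulation_id", "replicate", "added_mass_g", "diameter_cm"}
    )
    return {
        str(fid): spread.SpreadabilityCurve.from_dataframe(
            grp, formulation_id=str(fid), plate_mass_g=plate_mass_g
        )
        for fid, grp in df.groupby("formulation_id")
    }


def read_flow_curves(path: str | Path) -> dict[tuple[str, float], rheo.FlowCurve]:
    """Read flow curves keyed by (formulation_id, temperature_C)."""
    df = _read_table(
        path,
        {"formulation_id", "temperature_C", "phase", "shear_rate_s1",
         "shear_stress_Pa"},
    )
    out = {}
    for (fid, temp), grp in df.groupby(["formulation_id", "temperature_C"]):
        out[(str(fid), float(temp))] = rheo.FlowCurve.from_dataframe(grp)
    return out


def read_viscosity_readings(path: str | Path) -> pd.DataFrame:
    return _read_table(
        path,
        {"formulation_id", "temperature_C", "shear_rate_s1", "replicate",
         "viscosity_mPas"},
    )


def read_tpa_trace(path: str | Path) -> tex.TPATrace:
    """Read a force-time trace with a ``# key: value`` metadata block."""
    meta: dict[str, str] = {}
    body = io.StringIO()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                if val:
                    meta[key.strip()] = val.strip()
            else:
                body.write(line)
    body.seek(0)
    df = pd.read_csv(body, sep=None, engine="python")
    missing = {"time_s", "force_N"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {sorted(missing)}")
    kw = {}
    for name, cast in (
        ("descent_speed_mm_s", float),
        ("ascent_speed_mm_s", float),
        ("target_depth_mm", float),
        ("trigger_force_N", float),
        ("pause_s", float),
        ("formulation_id", str),
    ):
        if name in meta:
            kw[name] = cast(meta[name])
    return tex.TPATrace(df["time_s"].to_numpy(), df["force_N"].to_numpy(), **kw)


def write_tpa_trace(trace: tex.TPATrace, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# formulation_id: {trace.formulation_id}\n")
        fh.write(f"# descent_speed_mm_s: {trace.descent_speed_mm_s}\n")
        fh.write(f"# ascent_speed_mm_s: {trace.ascent_speed_mm_s}\n")
        fh.write(f"# target_depth_mm: {trace.target_depth_mm}\n")
        fh.write(f"# trigger_force_N: {trace.trigger_force_N}\n")
        fh.write(f"# pause_s: {trace.pause_s}\n")
        pd.DataFrame({"time_s": trace.time_s, "force_N": trace.force_N}).to_csv(
            fh, sep=SEP, index=False, lineterminator="\n"
        )


def read_release(
    path: str | Path,
    vessel_volume_ml: float = 50.0,
    sample_volume_ml: float = 3.0,
    orifice_area_cm2: float = 3.8,
    loaded_dose_mg: dict[str, float] | None = None,
) -> dict[str, rel.ReleaseExperiment]:
    """Read timed absorbances into per-formulation release experiments."""
    df = _read_table(path, {"formulation_id", "replicate", "time_min", "absorbance"})
    out = {}
    for fid, grp in df.groupby("formulation_id"):
        wide = grp.pivot(index="replicate", columns="time_min", values="absorbance")
        wide = wide.sort_index(axis=1)
        out[str(fid)] = rel.ReleaseExperiment(
            times_min=wide.columns.to_numpy(dtype=float),
            absorbances=wide.to_numpy(dtype=float),
            vessel_volume_ml=vessel_volume_ml,
            sample_volume_ml=sample_volume_ml,
            orifice_area_cm2=orifice_area_cm2,
            loaded_dose_mg=(loaded_dose_mg or {}).get(str(fid), float("nan")),
            formulation_id=str(fid),
        )
    return out


# re-exported summary statistics so the report layer is one import
mean_sd = st.mean_sd
welch_t = st.welch_t
pearson_r = st.pearson_r


# ---------------------------------------------------------------------------
# study configuration


REQUIRED_CONFIG_KEYS = ("seed", "out_dir")


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of a full (synthetic) characterization study."""

    seed: int
    out_dir: Path
    plate_mass_g: float = spread.DEFAULT_PLATE_MASS_G
    vessel_volume_ml: float = 50.0
    sample_volume_ml: float = 3.0
    orifice_area_cm2: float = 3.8
    wavelength_nm: float = 276.5
    reference_id: str = "F-1"
    release_replicates: int = 3
    formulations: tuple[FormulationSpec, ...] = DEFAULT_FORMULATIONS

    def __post_init__(self) -> None:
        object.__setattr__(self, "out_dir", Path(self.out_dir))
        if self.sample_volume_ml >= self.vessel_volume_ml:
            raise InvalidInputError("sample volume must be below vessel volume")
        if self.reference_id not in {f.id for f in self.formulations}:
            raise InvalidInputError(
                f"reference {self.reference_id!r} not among formulations"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        missing = [k for k in REQUIRED_CONFIG_KEYS if k not in raw]
        if missing:
            raise InvalidInputError(
                f"config {path}: missing required key(s) {missing}; "
                f"required keys are {list(REQUIRED_CONFIG_KEYS)}"
            )
        known = {k: raw[k] for k in raw if k in cls.__dataclass_fields__}
        return cls(**known)


# ---------------------------------------------------------------------------
# default synthetic-study parameters
#
# These are the package's stated world for an end-to-end demonstration run:
# log-law spreading coefficients, step-viscosity levels, texture profiles
# and Higuchi release rates typical of a drug-loaded hydrophilic cream
# series on this instrument suite.

SPREAD_COEFFS: dict[str, tuple[float, float]] = {
    "F-1": (20.899, -92.743),
    "F-2": (21.851, -93.754),
    "F-3": (19.898, -82.552),
    "F-4": (16.791, -67.144),
    "F-5": (20.814, -89.592),
    "F-6": (20.474, -86.238),
    "F-7": (17.752, -80.112),
}

STEP_VISCOSITY_MPAS: dict[str, dict[float, tuple[float, float, float]]] = {
    # formulation -> temperature -> viscosities at (300, 700, 1100) 1/s
    "F-1": {25.0: (1907, 1257, 741), 32.0: (754, 528, 471)},
    "F-2": {25.0: (1019, 747, 611), 32.0: (597, 435, 407)},
    "F-3": {25.0: (1102, 738, 596), 32.0: (584, 423, 397)},
    "F-4": {25.0: (1408, 809, 651), 32.0: (606, 439, 401)},
    "F-5": {25.0: (1622, 1096, 877), 32.0: (1423, 984, 644)},
    "F-6": {25.0: (2749, 1295, 914), 32.0: (2272, 1148, 858)},
    "F-7": {25.0: (2071, 1364, 798), 32.0: (1853, 1236, 782)},
}

TPA_PROFILES: dict[str, tex.TPAProfile] = {
    "F-1": tex.TPAProfile(0.419, 1.107, 0.567, 1.130, -0.130),
    "F-2": tex.TPAProfile(0.205, 0.885, 0.325, 0.950, -0.053),
    "F-3": tex.TPAProfile(0.227, 0.869, 0.400, 0.947, -0.059),
    "F-6": tex.TPAProfile(0.801, 0.360, 1.683, 0.787, -0.260),
}

HIGUCHI_RATES: dict[str, tuple[float, float]] = {
    # formulation -> (kH [mg/cm^2/min^0.5], loaded dose [mg])
    "F-5": (0.41, 15.0),
    "F-6": (0.48, 20.0),
    "F-7": (0.52, 25.0),
}

PH_MEANS: dict[str, float] = {
    "F-1": 6.30, "F-2": 3.43, "F-3": 3.61, "F-4": 3.79, "F-5": 3.86,
    "F-6": 3.92, "F-7": 4.00,
}

REPORT_HEADER = (
    "semisolid characterization report\n"
    "pairwise comparisons: Welch two-sample t, alpha = 0.05, two-sided;\n"
    "no multiple-testing correction is applied."
)


# ---------------------------------------------------------------------------
# study driver


def _generate_inputs(cfg: StudyConfig, in_dir: Path) -> None:
    """Write the synthetic instrument files the analysis stages will read."""
    seed = int(cfg.seed)
    rng = np.random.default_rng(seed)

    rows = []
    for k, f in enumerate(cfg.formulations):
        a, b = SPREAD_COEFFS[f.id]
        curve = sim.gen_spreadability(
            a, b, n_reps=5, noise_sd_cm2=0.5, seed=seed + 11 + k,
            plate_mass_g=cfg.plate_mass_g, formulation_id=f.id,
        )
        for r, rep in enumerate(curve.replicates):
            for added, d in rep:
                rows.append(
                    {"formulation_id": f.id, "replicate": r,
                     "added_mass_g": added, "diameter_cm": round(d, 4)}
                )
    write_table(pd.DataFrame(rows), in_dir / "spreadability.tsv")

    visc_rows = []
    for f in cfg.formulations:
        for temp, means in STEP_VISCOSITY_MPAS[f.id].items():
            for rate, mean in zip(rheo.STEP_RATES_S1, means):
                vals = rng.normal(mean, 0.02 * mean, size=5)
                for r, v in enumerate(vals):
                    visc_rows.append(
                        {"formulation_id": f.id, "temperature_C": temp,
                         "shear_rate_s1": rate, "replicate": r,
                         "viscosity_mPas": round(float(v), 1)}
                    )
    write_table(pd.DataFrame(visc_rows), in_dir / "viscosity_steps.tsv")

    flow_rows = []
    for k, f in enumerate(cfg.formulations):
        for j, temp in enumerate((25.0, 32.0)):
            # apparent viscosity at the top rate anchors the consistency;
            # heating thins the stress scale while the structural kinetics
            # (breakdown/recovery) stay the same, so hot loops are smaller
            eta = STEP_VISCOSITY_MPAS[f.id][temp][2] / 1000.0 * 0.8
            tau_y = (30.0 + 4.0 * f.conc_mg_g) * (0.7 if temp > 30 else 1.0)
            curve = sim.gen_flow_curve(
                tau_y=tau_y, eta=eta,
                breakdown_rate=2e-5 * (1 + 0.05 * f.conc_mg_g),
                recovery_rate=0.05, temperature_C=temp, noise_sd_Pa=0.5,
                seed=seed + 37 + 2 * k + j, formulation_id=f.id,
            )
            for rate, stress, phase in zip(
                curve.shear_rate, curve.shear_stress, curve.phase
            ):
                flow_rows.append(
                    {"formulation_id": f.id, "temperature_C": temp,
                     "phase": phase, "shear_rate_s1": round(float(rate), 3),
                     "shear_stress_Pa": round(float(stress), 4)}
                )
    write_table(pd.DataFrame(flow_rows), in_dir / "flow_curves.tsv")

    for k, (fid, prof) in enumerate(sorted(TPA_PROFILES.items())):
        trace = sim.gen_tpa(prof, seed=seed + 71 + k, formulation_id=fid)
        write_tpa_trace(trace, in_dir / f"tpa_{fid}.tsv")

    rel_rows = []
    for k, (fid, (kH, dose)) in enumerate(sorted(HIGUCHI_RATES.items())):
        exp, _ = sim.gen_release_experiment(
            "higuchi", {"kH": kH}, loaded_dose_mg=dose,
            orifice_area_cm2=cfg.orifice_area_cm2,
            vessel_volume_ml=cfg.vessel_volume_ml,
            sample_volume_ml=cfg.sample_volume_ml,
            n_reps=cfg.release_replicates, seed=seed + 101 + k,
            formulation_id=fid,
        )
        for r in range(exp.n_replicates):
            for t, a in zip(exp.times_min, exp.absorbances[r]):
                rel_rows.append(
                    {"formulation_id": fid, "replicate": r, "time_min": t,
                     "absorbance": round(float(a), 5)}
                )
    write_table(pd.DataFrame(rel_rows), in_dir / "release.tsv")

    ph_rows = []
    for k, f in enumerate(cfg.formulations):
        prng = np.random.default_rng(seed + 131 + k)
        for r, v in enumerate(prng.normal(PH_MEANS[f.id], 0.02, size=5)):
            ph_rows.append(
                {"formulation_id": f.id, "replicate": r, "pH": round(float(v), 3)}
            )
    write_table(pd.DataFrame(ph_rows), in_dir / "ph.tsv")


def run_study(cfg: StudyConfig) -> dict[str, pd.DataFrame]:
    """Generate (if needed), analyze and report a full characterization study.

    Synthetic instrument files are written under ``out_dir/inputs`` unless
    already present, then every analysis stage runs and report tables are
    written under ``out_dir/report``.  Missing input files skip their stage
    with an explicit log entry rather than aborting the whole run.

    Returns the report tables keyed by name.
    """
    in_dir = cfg.out_dir / "inputs"
    report_dir = cfg.out_dir / "report"
    report_dir.mkdir(parents=True, exist_ok=True)
    if not (in_dir / "spreadability.tsv").exists():
        log.info("generating synthetic inputs under %s", in_dir)
        _generate_inputs(cfg, in_dir)

    tables: dict[str, pd.DataFrame] = {}

    def stage(name, filename, fn):
        path = in_dir / filename
        if not path.exists():
            log.warning("skipping %s stage: %s not found", name, path)
            return
        tables.update(fn(path))

    stage("pH", "ph.tsv", lambda p: _report_ph(p))
    stage("spreadability", "spreadability.tsv", lambda p: _report_spread(p, cfg))
    stage("viscosity", "viscosity_steps.tsv", lambda p: _report_viscosity(p))
    stage("rheology", "flow_curves.tsv", lambda p: _report_flow(p))
    if any(in_dir.glob("tpa_*.tsv")):
        tables.update(_report_tpa(sorted(in_dir.glob("tpa_*.tsv")), cfg))
    else:
        log.warning("skipping texture stage: no tpa_*.tsv found")
    stage("release", "release.tsv", lambda p: _report_release(p, cfg))

    for name, df in tables.items():
        write_table(df, report_dir / f"{name}.tsv", header_note=REPORT_HEADER)
    log.info("report written to %s (%d tables)", report_dir, len(tables))
    return tables


def _report_ph(path: Path) -> dict[str, pd.DataFrame]:
    df = _read_table(path, {"formulation_id", "pH"})
    rows = []
    for fid, grp in df.groupby("formulation_id"):
        s = st.mean_sd(grp["pH"].to_numpy(), label=str(fid))
        rows.append({"formulation_id": fid, "pH_mean": round(s.mean, 2),
                     "pH_sd": round(s.sd, 2), "n": s.n})
    return {"table_ph": pd.DataFrame(rows)}


def _report_spread(path: Path, cfg: StudyConfig) -> dict[str, pd.DataFrame]:
    curves = read_spreadability(path, cfg.plate_mass_g)
    fits = {}
    for fid, curve in curves.items():
        pts = spread.diameters_to_areas(curve)
        fits[fid] = spread.fit_log_spread(pts["load_g"], pts["area_cm2"])
    ref_auc = fits[cfg.reference_id].auc()
    rows = []
    for fid in sorted(fits):
        f = fits[fid]
        auc = f.auc()
        rows.append(
            {
                "formulation_id": fid,
                "equation": f.equation(),
                "r_squared": round(f.r_squared, 3),
                "auc_cm2_g": round(auc, 1),
                "i_s": "-" if fid == cfg.reference_id
                else f"{spread.spreadability_index(auc, ref_auc):.3f}",
            }
        )
    return {"table_spreadability": pd.DataFrame(rows)}


def _report_viscosity(path: Path) -> dict[str, pd.DataFrame]:
    readings = read_viscosity_readings(path)
    table = rheo.summarize_step_viscosity(readings)
    table = table.assign(
        mean=table["mean"].round(0), sd=table["sd"].round(1)
    )
    return {"table_viscosity": table}


def _report_flow(path: Path) -> dict[str, pd.DataFrame]:
    curves = read_flow_curves(path)
    rows = []
    areas: dict[float, dict[str, float]] = {}
    for (fid, temp), curve in sorted(curves.items()):
        fit = rheo.fit_casson(curve, variant="linear")
        area = rheo.hysteresis_area(curve)
        areas.setdefault(temp, {})[fid] = area
        rows.append(
            {
                "formulation_id": fid,
                "temperature_C": temp,
                "tau_y_Pa": round(fit.tau_y, 3),
                "eta_Pa_s": round(fit.eta, 5),
                "r_squared": round(fit.r_squared, 4),
                "loop_area_Pa_per_s": round(area, 1),
            }
        )
    out = {"table_flow": pd.DataFrame(rows)}
    temps = sorted(areas)
    if len(temps) == 2:
        out["table_thixotropy"] = rheo.compare_thixotropy(
            areas[temps[0]], areas[temps[1]]
        )
    return out


def _report_tpa(paths: Sequence[Path], cfg: StudyConfig) -> dict[str, pd.DataFrame]:
    profiles = {}
    for p in paths:
        trace = read_tpa_trace(p)
        fid = trace.formulation_id or p.stem.removeprefix("tpa_")
        profiles[fid] = tex.extract_tpa(trace)
    rows = [
        {"formulation_id": fid, **{k: round(v, 3) for k, v in prof.as_dict().items()}}
        for fid, prof in sorted(profiles.items())
    ]
    out = {"table_texture": pd.DataFrame(rows)}
    if cfg.reference_id in profiles:
        out["table_texture_ratios"] = tex.texture_ratios(
            profiles, cfg.reference_id
        ).round(3)
    return out


def _report_release(path: Path, cfg: StudyConfig) -> dict[str, pd.DataFrame]:
    doses = {fid: dose for fid, (_, dose) in HIGUCHI_RATES.items()}
    exps = read_release(
        path,
        vessel_volume_ml=cfg.vessel_volume_ml,
        sample_volume_ml=cfg.sample_volume_ml,
        orifice_area_cm2=cfg.orifice_area_cm2,
        loaded_dose_mg=doses,
    )
    calib = rel.CalibrationResults(
        slope=sim.DEFAULT_CALIBRATION[0], intercept=sim.DEFAULT_CALIBRATION[1],
        r_squared=1.0, wavelength_nm=cfg.wavelength_nm,
    )
    rates: dict[str, list[float]] = {}
    r2_rows = []
    for fid, exp in sorted(exps.items()):
        q_inf = exp.loaded_dose_mg / exp.orifice_area_cm2
        per_rep = []
        for r in range(exp.n_replicates):
            conc = rel.absorbance_to_conc(exp.absorbances[r], calib)
            profile = rel.cumulative_release(conc, exp)
            fit = rel.fit_release_model(profile, "higuchi")
            per_rep.append(fit.params["kH"])
        rates[fid] = per_rep
        mean_a = exp.absorbances.mean(axis=0)
        mean_profile = rel.cumulative_release(
            rel.absorbance_to_conc(mean_a, calib), exp
        )
        ranking = rel.compare_models(mean_profile, q_inf=q_inf)
        for _, row in ranking.iterrows():
            r2_rows.append(
                {"formulation_id": fid, "model": row["model"],
                 "r_squared": round(row["r_squared"], 3)
                 if np.isfinite(row["r_squared"]) else np.nan,
                 "best": bool(row["best"])}
            )
    summary, pairwise = rel.release_rate_comparison(rates)
    summary = summary.rename(columns={"mean": "kH_mean", "sd": "kH_sd"}).round(4)
    out = {
        "table_kinetics_r2": pd.DataFrame(r2_rows),
        "table_release_rates": summary,
    }
    if not pairwise.empty:
        out["table_release_tests"] = pairwise.round(5)
    return out
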