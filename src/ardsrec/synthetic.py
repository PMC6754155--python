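"""Synthetic cohort generator.

Emulates the statistical structure of the EHR-derived study population:

* gender-bimodal predicted body weight (PBW) from per-gender height normals;
* lowest PaO2/FiO2 drawn from a cohort-specific lognormal truncated at 300
  (the inclusion ceiling), so the ARDS cohort is more hypoxemic;
* a latent per-patient *recognition* state whose probability rises with
  hypoxemia severity; recognised patients (and documented controls) target
  ~6 mL/kg PBW, everyone else picks from a small quantized tidal-volume menu
  dominated by 450/500/600 mL;
* documentation only for recognised patients, with fixed probability.

The menu quantization is what makes standardized tidal volume fall with PBW
in *both* cohorts — the emergent behaviour the regression stage must detect.
"""
from __future__ import annotations

import io
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, InvalidInputError, NotInCohortError, SchemaError
from .types import (AnalysisConfig, Cohort, CohortConfig, Gender, PatientRecord,
                    Severity, severity_probs)

COHORT_CSV_COLUMNS = [
    "patient_id", "cohort", "gender", "height_in", "pbw_kg", "admit_weight_kg",
    "pf_first", "pf_lowest", "pplat_highest", "vt_lowest_ml", "vt_std",
    "documented", "bilateral_infiltrates", "admitting_icu", "study_duration_h",
    "latent_recognized",
]


def compute_pbw(height_in: float, gender: Gender | str) -> float:
    """Predicted body weight (kg) from height (inches) and gender.

    Male: 50 + 2.3*(height - 60); female: 45.5 + 2.3*(height - 60).
    """
    if not np.isfinite(height_in) or height_in <= 0:
        raise InvalidInputError(f"height must be positive, got {height_in}")
    gender = Gender(gender)
    base = 50.0 if gender is Gender.MALE else 45.5
    return base + 2.3 * (height_in - 60.0)


def standardize_vt(vt_ml: float, pbw_kg: float) -> float:
    """Standardized tidal volume V^T = V_T / PBW, in mL/kg PBW."""
    if vt_ml <= 0:
        raise InvalidInputError(f"tidal volume must be positive, got {vt_ml}")
    if pbw_kg < 25:
        raise InvalidInputError(
            f"PBW {pbw_kg} kg is below the 25 kg inclusion floor")
    return vt_ml / pbw_kg


def is_ltvv(vt_std: float, config: Optional[AnalysisConfig] = None) -> bool:
    """Low tidal volume ventilation: V^T <= 6.5 mL/kg PBW (inclusive)."""
    cfg = config or AnalysisConfig()
    return vt_std <= cfg.ltvv_threshold


def assign_severity(pf_lowest: float,
                    config: Optional[AnalysisConfig] = None) -> Severity:
    """Berlin stratum of the lowest P/F; boundaries go to the worse stratum."""
    cfg = config or AnalysisConfig()
    severe_cut, moderate_cut, mild_cut = cfg.severity_cutpoints
    if not np.isfinite(pf_lowest) or pf_lowest <= 0:
        raise InvalidInputError(f"P/F must be positive, got {pf_lowest}")
    if pf_lowest > mild_cut:
        raise NotInCohortError(
            f"P/F {pf_lowest} exceeds the {mild_cut} inclusion ceiling")
    if pf_lowest <= severe_cut:
        return Severity.SEVERE
    if pf_lowest <= moderate_cut:
        return Severity.MODERATE
    return Severity.MILD


def _truncated_lognormal(rng: np.random.Generator, median: float, sigma: float,
                         upper: float, size: int) -> np.ndarray:
    """Lognormal(median, sigma) truncated to (0, upper] via inverse CDF."""
    dist = stats.lognorm(s=sigma, scale=median)
    cap = dist.cdf(upper)
    u = rng.uniform(0.0, cap, size=size)
    return np.minimum(dist.ppf(u), upper)


def _round_to_menu(value_ml: float, menu: np.ndarray) -> float:
    return float(menu[np.argmin(np.abs(menu - value_ml))])


def generate_cohort(config: CohortConfig) -> list[PatientRecord]:
    """Draw a full two-cohort synthetic population. Deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    menu = np.asarray(config.vt_menu, dtype=float)
    w_male = np.asarray(config.vt_menu_weights_male, dtype=float)
    w_female = np.asarray(config.vt_menu_weights_female, dtype=float)
    w_male = w_male / w_male.sum()
    w_female = w_female / w_female.sum()
    recog_p = severity_probs(config)
    icu_w = np.asarray(config.admitting_icu_weights, dtype=float)
    icu_w = icu_w / icu_w.sum()

    records: list[PatientRecord] = []
    for cohort, n in ((Cohort.ARDS, config.n_ards),
                      (Cohort.CONTROL, config.n_control)):
        pf = _truncated_lognormal(rng, config.pf_median[cohort.value],
                                  config.pf_sigma[cohort.value], 300.0, n)
        for i in range(n):
            gender = Gender.MALE if rng.random() < config.gender_fraction_male \
                else Gender.FEMALE
            # redraw height until the 25 kg PBW inclusion floor is met
            while True:
                height = rng.normal(config.height_mean_in[gender.value],
                                    config.height_sd_in[gender.value])
                if height > 0 and compute_pbw(height, gender) >= 25.0:
                    break
            pbw = compute_pbw(height, gender)
            pf_lowest = float(pf[i])
            severity = assign_severity(pf_lowest)

            recognized: Optional[bool]
            documented = False
            if cohort is Cohort.ARDS:
                recognized = bool(rng.random() < recog_p[severity])
                if recognized:
                    documented = bool(
                        rng.random() < config.documentation_prob_given_recognized)
            else:
                recognized = None
                documented = bool(rng.random() < config.documentation_prob_control)

            behaves_recognized = (recognized is True) or \
                (cohort is Cohort.CONTROL and documented)
            if behaves_recognized:
                target = rng.normal(config.recognized_vt_target_mean,
                                    config.recognized_vt_target_sd)
                vt = _round_to_menu(max(target, 3.0) * pbw, menu)
            else:
                weights = w_male if gender is Gender.MALE else w_female
                vt = float(rng.choice(menu, p=weights))

            pf_first = float(min(
                pf_lowest * (1.0 + rng.exponential(config.pf_first_inflation_scale)),
                300.0))
            admit_weight = float(max(pbw * rng.normal(1.12, 0.22), 30.0))
            if rng.random() < config.pplat_missing_prob:
                pplat = None
            else:
                pplat = float(np.clip(30.0 - 0.03 * pf_lowest + rng.normal(0.0, 4.0),
                                      8.0, 50.0))
            duration = 5.67 + float(
                rng.lognormal(config.duration_log_mean, config.duration_log_sd))
            bilateral = bool(rng.random() < config.bilateral_infiltrate_prob) \
                if cohort is Cohort.CONTROL else None
            icu = str(rng.choice(config.admitting_icus, p=icu_w)) \
                if cohort is Cohort.ARDS else None

            records.append(PatientRecord(
                patient_id=f"{cohort.value[:1].upper()}{i:04d}",
                cohort=cohort,
                gender=gender,
                height_in=float(height),
                pbw_kg=float(pbw),
                admit_weight_kg=admit_weight,
                pf_first=pf_first,
                pf_lowest=pf_lowest,
                pplat_highest=pplat,
                vt_lowest_ml=vt,
                vt_std=vt / pbw,
                documented=documented,
                study_duration_h=duration,
                bilateral_infiltrates=bilateral,
                admitting_icu=icu,
                latent_recognized=recognized,
            ))
    return records


# --------------------------------------------------------------------------
# CSV serialization: empty field = missing, booleans as 0/1


def _bool_to_cell(value: Optional[bool]) -> str:
    return "" if value is None else str(int(value))


def records_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "patient_id": r.patient_id,
            "cohort": r.cohort.value,
            "gender": r.gender.value,
            "height_in": r.height_in,
            "pbw_kg": r.pbw_kg,
            "admit_weight_kg": r.admit_weight_kg,
            "pf_first": r.pf_first,
            "pf_lowest": r.pf_lowest,
            "pplat_highest": r.pplat_highest,
            "vt_lowest_ml": r.vt_lowest_ml,
            "vt_std": r.vt_std,
            "documented": int(r.documented),
            "bilateral_infiltrates": _bool_to_cell(r.bilateral_infiltrates),
            "admitting_icu": "" if r.admitting_icu is None else r.admitting_icu,
            "study_duration_h": r.study_duration_h,
            "latent_recognized": _bool_to_cell(r.latent_recognized),
        })
    return pd.DataFrame(rows, columns=COHORT_CSV_COLUMNS)


def write_cohort_csv(records: Sequence[PatientRecord], path) -> None:
    # default float repr round-trips exactly, keeping vt_std == vt/pbw to 1e-9
    records_to_frame(records).to_csv(path, index=False)


def _cell_to_bool(value) -> Optional[bool]:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return bool(int(float(value)))


def frame_to_records(frame: pd.DataFrame) -> list[PatientRecord]:
    missing = [c for c in COHORT_CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(missing)
    records = []
    for _, row in frame.iterrows():
        pplat = row["pplat_highest"]
        pplat = None if pd.isna(pplat) else float(pplat)
        icu = row["admitting_icu"]
        icu = None if (pd.isna(icu) or icu == "") else str(icu)
        records.append(PatientRecord(
            patient_id=str(row["patient_id"]),
            cohort=Cohort(row["cohort"]),
            gender=Gender(row["gender"]),
            height_in=float(row["height_in"]),
            pbw_kg=float(row["pbw_kg"]),
            admit_weight_kg=float(row["admit_weight_kg"]),
            pf_first=float(row["pf_first"]),
            pf_lowest=float(row["pf_lowest"]),
            pplat_highest=pplat,
            vt_lowest_ml=float(row["vt_lowest_ml"]),
            vt_std=float(row["vt_std"]),
            documented=bool(int(float(row["documented"]))),
            study_duration_h=float(row["study_duration_h"]),
            bilateral_infiltrates=_cell_to_bool(row["bilateral_infiltrates"]),
            admitting_icu=icu,
            latent_recognized=_cell_to_bool(row["latent_recognized"]),
        ))
    return records


def read_cohort_csv(path) -> list[PatientRecord]:
    frame = pd.read_csv(path, dtype={"patient_id": str, "admitting_icu": str},
                        float_precision="round_trip")
    return frame_to_records(frame)
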