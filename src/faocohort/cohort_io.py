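"""Cohort table I/O: one CSV row per pregnancy.

The schema below is the single exchange format between the generator, the
screening cascade and the analysis pipeline.  Units are fixed: ages in
years, weights in kg, heights in m, glucose in mg/dL, insulin in uU/mL,
biometry in mm, gestational ages in days since LMP, birth weight in g.
Optional fields are empty cells (NaN).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .growth import BiometrySnapshot
from .screening import OGTTPanel, PregnancyRecord

__all__ = ["COHORT_COLUMNS", "read_cohort_csv", "write_cohort_csv",
           "frame_to_records", "records_to_frame"]

COHORT_COLUMNS = [
    "id", "age_years", "prepreg_weight_kg", "height_m", "weight_at_dx_kg",
    "weight_near_term_kg", "gct_mgdl",
    "ogtt_fasting_mgdl", "ogtt_h1_mgdl", "ogtt_h2_mgdl", "ogtt_h3_mgdl",
    "hba1c_pct", "fasting_insulin_uUml",
    "ga_lmp_mid_days", "bpd_mid_mm", "ac_mid_mm", "fl_mid_mm",
    "ga_lmp_near_days", "bpd_near_mm", "ac_near_mm", "fl_near_mm",
    "parity", "pih_before_24gw", "delivered_elsewhere",
    "birth_weight_g", "ga_delivery_days", "infant_sex", "delivery_mode",
]

_REQUIRED = ["id", "age_years"]


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort table; schema violations name the row."""
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV missing columns: {missing}")
    for col in _REQUIRED:
        bad = df.index[df[col].isna()]
        if len(bad):
            raise ValueError(f"column {col!r} missing at row(s) {list(bad[:5])}")
    return df[COHORT_COLUMNS]


def write_cohort_csv(df: pd.DataFrame, path: str | Path) -> None:
    df[COHORT_COLUMNS].to_csv(path, index=False)


def _opt(value):
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    return value


def frame_to_records(df: pd.DataFrame) -> list[PregnancyRecord]:
    records = []
    for row in df.itertuples(index=False):
        ogtt = None
        if _opt(row.ogtt_fasting_mgdl) is not None:
            ogtt = OGTTPanel(row.ogtt_fasting_mgdl, row.ogtt_h1_mgdl,
                             row.ogtt_h2_mgdl, row.ogtt_h3_mgdl)
        bio_mid = bio_near = None
        if _opt(row.ac_mid_mm) is not None:
            bio_mid = BiometrySnapshot(row.ga_lmp_mid_days, row.bpd_mid_mm,
                                       row.ac_mid_mm, row.fl_mid_mm,
                                       "mid_gestation")
        if _opt(row.ac_near_mm) is not None:
            bio_near = BiometrySnapshot(row.ga_lmp_near_days, row.bpd_near_mm,
                                        row.ac_near_mm, row.fl_near_mm,
                                        "near_term")
        records.append(PregnancyRecord(
            id=str(row.id),
            age_years=float(row.age_years),
            prepreg_weight_kg=_opt(row.prepreg_weight_kg),
            height_m=_opt(row.height_m),
            weight_at_dx_kg=_opt(row.weight_at_dx_kg),
            weight_near_term_kg=_opt(row.weight_near_term_kg),
            gct_mgdl=_opt(row.gct_mgdl),
            ogtt=ogtt,
            hba1c_pct=_opt(row.hba1c_pct),
            fasting_insulin_uUml=_opt(row.fasting_insulin_uUml),
            biometry_mid=bio_mid,
            biometry_near=bio_near,
            parity=str(row.parity),
            pih_before_24gw=bool(row.pih_before_24gw),
            delivered_elsewhere=bool(row.delivered_elsewhere),
            birth_weight_g=_opt(row.birth_weight_g),
            ga_delivery_days=_opt(row.ga_delivery_days),
            infant_sex=str(row.infant_sex),
            delivery_mode=_opt(row.delivery_mode),
        ))
    return records


def records_to_frame(records: list[PregnancyRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "id": r.id, "age_years": r.age_years,
            "prepreg_weight_kg": r.prepreg_weight_kg, "height_m": r.height_m,
            "weight_at_dx_kg": r.weight_at_dx_kg,
            "weight_near_term_kg": r.weight_near_term_kg,
            "gct_mgdl": r.gct_mgdl,
            "ogtt_fasting_mgdl": r.ogtt.fasting_mgdl if r.ogtt else None,
            "ogtt_h1_mgdl": r.ogtt.h1_mgdl if r.ogtt else None,
            "ogtt_h2_mgdl": r.ogtt.h2_mgdl if r.ogtt else None,
            "ogtt_h3_mgdl": r.ogtt.h3_mgdl if r.ogtt else None,
            "hba1c_pct": r.hba1c_pct,
            "fasting_insulin_uUml": r.fasting_insulin_uUml,
            "ga_lmp_mid_days": r.biometry_mid.ga_lmp_days if r.biometry_mid else None,
            "bpd_mid_mm": r.biometry_mid.bpd_mm if r.biometry_mid else None,
            "ac_mid_mm": r.biometry_mid.ac_mm if r.biometry_mid else None,
            "fl_mid_mm": r.biometry_mid.fl_mm if r.biometry_mid else None,
            "ga_lmp_near_days": r.biometry_near.ga_lmp_days if r.biometry_near else None,
            "bpd_near_mm": r.biometry_near.bpd_mm if r.biometry_near else None,
            "ac_near_mm": r.biometry_near.ac_mm if r.biometry_near else None,
            "fl_near_mm": r.biometry_near.fl_mm if r.biometry_near else None,
            "parity": r.parity,
            "pih_before_24gw": r.pih_before_24gw,
            "delivered_elsewhere": r.delivered_elsewhere,
            "birth_weight_g": r.birth_weight_g,
            "ga_delivery_days": r.ga_delivery_days,
            "infant_sex": r.infant_sex,
            "delivery_mode": r.delivery_mode,
        }
        rows.append(row)
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)
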