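"""Glycemic screening cascade, cohort exclusions, subgrouping and outcome labels.

The study design is the classical two-step screen for gestational diabetes:
every pregnancy gets a 50-g glucose challenge test (GCT) at 24-28 gestational
weeks, and only GCT >= 140 mg/dL proceeds to a 3-h 100-g oral glucose
tolerance test (OGTT) read against the Carpenter-Coustan thresholds
(fasting/1h/2h/3h, defaults 95/180/155/140 mg/dL, inclusive).  Two or more
exceedances diagnose GDM; exactly one is a "one-value abnormality"; zero is
OGTT-confirmed normal glucose tolerance (NGT).  A screen-negative GCT is NGT
without an OGTT.

The exclusion cascade that defines the analysis cohort removes, in order:
pregnancy-induced hypertension before 24 weeks, missing maternal weight,
missing GCT, GCT-positive without OGTT (unclassifiable), one-value
abnormality, GDM, and delivery elsewhere.  Every stage logs its counts so
the cohort flow is fully auditable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .growth import BiometrySnapshot

__all__ = [
    "GlycemicStatus",
    "OGTTPanel",
    "ScreeningResult",
    "PregnancyRecord",
    "ExclusionLog",
    "LgaReference",
    "default_lga_reference",
    "classify_glycemic_status",
    "apply_exclusions",
    "assign_subgroup",
    "homa_indices",
    "label_outcomes",
]


class GlycemicStatus(str, Enum):
    NGT_SCREEN_NEGATIVE = "NGT_screen_negative"
    NGT_OGTT = "NGT_ogtt"
    ONE_VALUE_ABNORMALITY = "one_value_abnormality"
    GDM = "GDM"
    UNCLASSIFIABLE = "unclassifiable"


@dataclass(frozen=True)
class OGTTPanel:
    """3-h 100-g OGTT plasma glucose panel (mg/dL)."""

    fasting_mgdl: float
    h1_mgdl: float
    h2_mgdl: float
    h3_mgdl: float

    def __post_init__(self) -> None:
        for v in (self.fasting_mgdl, self.h1_mgdl, self.h2_mgdl, self.h3_mgdl):
            if not v > 0:
                raise ValueError("OGTT glucose values must be positive")

    def values(self) -> tuple[float, float, float, float]:
        return (self.fasting_mgdl, self.h1_mgdl, self.h2_mgdl, self.h3_mgdl)


@dataclass(frozen=True)
class ScreeningResult:
    status: GlycemicStatus
    n_abnormal: int = 0


@dataclass
class PregnancyRecord:
    """One singleton pregnancy: maternal covariates, glycemic panel, up to two
    biometry snapshots, and delivery outcomes.  Optional fields are ``None``
    when not recorded, mirroring real chart review."""

    id: str
    age_years: float
    prepreg_weight_kg: Optional[float] = None
    height_m: Optional[float] = None
    weight_at_dx_kg: Optional[float] = None
    weight_near_term_kg: Optional[float] = None
    gct_mgdl: Optional[float] = None
    ogtt: Optional[OGTTPanel] = None
    hba1c_pct: Optional[float] = None
    fasting_insulin_uUml: Optional[float] = None
    biometry_mid: Optional[BiometrySnapshot] = None
    biometry_near: Optional[BiometrySnapshot] = None
    parity: str = "primipara"                  # primipara | multipara
    pih_before_24gw: bool = False
    delivered_elsewhere: bool = False
    birth_weight_g: Optional[float] = None
    ga_delivery_days: Optional[float] = None
    infant_sex: str = "female"                 # male | female
    delivery_mode: Optional[str] = None        # vaginal | primary_cesarean | repeat_cesarean

    @property
    def prepreg_bmi(self) -> Optional[float]:
        if self.prepreg_weight_kg is None or not self.height_m:
            return None
        return self.prepreg_weight_kg / self.height_m**2

    @property
    def weight_gain_to_dx(self) -> Optional[float]:
        if self.weight_at_dx_kg is None or self.prepreg_weight_kg is None:
            return None
        return self.weight_at_dx_kg - self.prepreg_weight_kg

    @property
    def weight_gain_to_term(self) -> Optional[float]:
        if self.weight_near_term_kg is None or self.prepreg_weight_kg is None:
            return None
        return self.weight_near_term_kg - self.prepreg_weight_kg


@dataclass
class ExclusionLog:
    """Ordered stage ledger; each stage consumes the previous stage's survivors."""

    stages: list[tuple[str, int, int, str]] = field(default_factory=list)
    # (stage_name, n_in, n_excluded, reason)

    def add(self, stage_name: str, n_in: int, n_excluded: int, reason: str) -> None:
        if self.stages:
            prev_name, prev_in, prev_excl, _ = self.stages[-1]
            if n_in != prev_in - prev_excl:
                raise ValueError(
                    f"stage '{stage_name}' n_in={n_in} does not telescope from "
                    f"'{prev_name}' ({prev_in}-{prev_excl})"
                )
        if n_excluded < 0 or n_excluded > n_in:
            raise ValueError("n_excluded out of range")
        self.stages.append((stage_name, n_in, n_excluded, reason))

    @property
    def final_n(self) -> int:
        if not self.stages:
            return 0
        _, n_in, n_excl, _ = self.stages[-1]
        return n_in - n_excl

    def count_after(self, stage_name: str) -> int:
        for name, n_in, n_excl, _ in self.stages:
            if name == stage_name:
                return n_in - n_excl
        raise KeyError(stage_name)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.stages, columns=["stage", "n_in", "n_excluded", "reason"]
        )


# Carpenter-Coustan defaults, mg/dL, inclusive thresholds (fasting, 1h, 2h, 3h)
CC_DEFAULTS = (95.0, 180.0, 155.0, 140.0)
GCT_THRESHOLD_DEFAULT = 140.0


def classify_glycemic_status(
    record: PregnancyRecord,
    cc_thresholds: Sequence[float] = CC_DEFAULTS,
    gct_threshold: float = GCT_THRESHOLD_DEFAULT,
) -> ScreeningResult:
    """Two-step GCT -> OGTT classification.

    GCT < threshold is screen-negative NGT (no OGTT required); GCT-positive
    without an OGTT is unclassifiable; otherwise the Carpenter-Coustan
    exceedance count maps 0 -> NGT, 1 -> one-value abnormality, >= 2 -> GDM.
    """
    if record.gct_mgdl is None or (isinstance(record.gct_mgdl, float) and math.isnan(record.gct_mgdl)):
        raise ValueError("missing GCT: record belongs in the exclusion cascade")
    if record.gct_mgdl < gct_threshold:
        return ScreeningResult(GlycemicStatus.NGT_SCREEN_NEGATIVE, 0)
    if record.ogtt is None:
        return ScreeningResult(GlycemicStatus.UNCLASSIFIABLE, 0)
    n_abn = sum(
        v >= t for v, t in zip(record.ogtt.values(), cc_thresholds, strict=True)
    )
    if n_abn == 0:
        return ScreeningResult(GlycemicStatus.NGT_OGTT, 0)
    if n_abn == 1:
        return ScreeningResult(GlycemicStatus.ONE_VALUE_ABNORMALITY, 1)
    return ScreeningResult(GlycemicStatus.GDM, n_abn)


def _has(value) -> bool:
    if value is None:
        return False
    if isinstance(value, float) and math.isnan(value):
        return False
    return True


def apply_exclusions(
    cohort: Sequence[PregnancyRecord],
    cc_thresholds: Sequence[float] = CC_DEFAULTS,
    gct_threshold: float = GCT_THRESHOLD_DEFAULT,
) -> tuple[list[PregnancyRecord], ExclusionLog]:
    """Apply the cohort-defining exclusion cascade, logging every stage.

    Order: PIH before 24 GW; missing maternal weight; missing GCT;
    GCT-positive without OGTT (unclassifiable); one-value abnormality; GDM;
    delivered elsewhere.  The survivors are the included NGT cohort.
    """
    log = ExclusionLog()
    current = list(cohort)

    def stage(name: str, keep_fn, reason: str) -> None:
        nonlocal current
        kept = [r for r in current if keep_fn(r)]
        log.add(name, len(current), len(current) - len(kept), reason)
        current = kept

    stage("pih_before_24gw", lambda r: not r.pih_before_24gw,
          "pregnancy-induced hypertension before 24 GW")
    stage("missing_weight", lambda r: _has(r.prepreg_weight_kg),
          "no maternal weight record")
    stage("missing_gct", lambda r: _has(r.gct_mgdl), "no result of 50-g GCT")

    status = {
        id(r): classify_glycemic_status(r, cc_thresholds, gct_threshold).status
        for r in current
    }
    stage("unclassifiable", lambda r: status[id(r)] != GlycemicStatus.UNCLASSIFIABLE,
          "GCT-positive without OGTT")
    stage("one_value_abnormality",
          lambda r: status[id(r)] != GlycemicStatus.ONE_VALUE_ABNORMALITY,
          "one OGTT value at/above threshold")
    stage("gdm", lambda r: status[id(r)] != GlycemicStatus.GDM,
          ">= 2 OGTT values at/above threshold (GDM)")
    stage("delivered_elsewhere", lambda r: not r.delivered_elsewhere,
          "delivered at another hospital")
    return current, log


def assign_subgroup(age_years: float, prepreg_bmi: float) -> str:
    """Four age x BMI strata: G1 young/non-obese, G2 young/obese,
    G3 older/non-obese, G4 older/obese.  Boundaries inclusive at age >= 35
    years and BMI >= 25 kg/m^2."""
    if not _has(age_years) or not _has(prepreg_bmi):
        raise ValueError("age and BMI required for subgrouping")
    older = age_years >= 35.0
    obese = prepreg_bmi >= 25.0
    return ("G4" if obese else "G3") if older else ("G2" if obese else "G1")


def homa_indices(
    fasting_glucose_mgdl: float, fasting_insulin_uUml: float
) -> tuple[float, Optional[float]]:
    """HOMA1 insulin-resistance and beta-cell indices from fasting glucose
    (mg/dL) and insulin (uU/mL).

    HOMA-IR = G*I/405; HOMA-beta = 360*I/(G-63), undefined (None) for
    G <= 63 mg/dL where the denominator degenerates.
    """
    if fasting_glucose_mgdl <= 0 or fasting_insulin_uUml <= 0:
        raise ValueError("glucose and insulin must be positive")
    homa_ir = fasting_glucose_mgdl * fasting_insulin_uUml / 405.0
    if fasting_glucose_mgdl <= 63.0:
        return homa_ir, None
    homa_beta = 360.0 * fasting_insulin_uUml / (fasting_glucose_mgdl - 63.0)
    return homa_ir, homa_beta


class LgaReference:
    """GA-week- and sex-specific 90th-percentile birth-weight table (g)."""

    def __init__(self, table: pd.DataFrame):
        req = {"ga_week", "sex", "p90_g"}
        if not req <= set(table.columns):
            raise ValueError(f"LGA reference needs columns {sorted(req)}")
        self._table = table
        self._lookup = {
            (int(r.ga_week), str(r.sex)): float(r.p90_g)
            for r in table.itertuples()
        }

    @classmethod
    def from_csv(cls, path: str | Path) -> "LgaReference":
        return cls(pd.read_csv(path))

    def p90(self, ga_week: int, sex: str) -> Optional[float]:
        return self._lookup.get((int(ga_week), sex))

    def as_frame(self) -> pd.DataFrame:
        return self._table.copy()


def default_lga_reference(week_min: int = 34, week_max: int = 40) -> LgaReference:
    """Synthetic sex- and GA-matched p90 birth-weight reference.

    Median curve is a smooth concave function of GA week with a +55 g male
    shift and SD 330 g; p90 = median + 1.2816*SD.  Magnitudes are typical of
    East-Asian term references but the table is synthetic, not any published
    standard.
    """
    rows = []
    for w in range(week_min, week_max + 1):
        mbw = 3480.0 - 130.0 * (40 - w) - 6.0 * (40 - w) ** 2
        for sex, shift in (("male", 55.0), ("female", 0.0)):
            rows.append({"ga_week": w, "sex": sex,
                         "p90_g": round(mbw + shift + 1.2816 * 330.0, 1)})
    return LgaReference(pd.DataFrame(rows))


def label_outcomes(
    record: PregnancyRecord,
    lga_reference: LgaReference,
    macrosomia_cutoff_g: float = 4000.0,
) -> dict:
    """Delivery outcome flags.

    LGA: birth weight at/above the sex- and GA-week-matched 90th percentile
    (``None`` when the delivery GA is outside the reference).  Macrosomia:
    birth weight >= 4000 g, computable regardless of the reference.
    """
    if not _has(record.birth_weight_g):
        raise ValueError("birth weight required for outcome labels")
    macro = record.birth_weight_g >= macrosomia_cutoff_g
    lga = None
    if _has(record.ga_delivery_days):
        p90 = lga_reference.p90(int(record.ga_delivery_days // 7), record.infant_sex)
        if p90 is not None:
            lga = record.birth_weight_g >= p90
    return {"lga": lga, "macrosomia": macro}
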