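"""Configuration for the analysis pipeline and the cohort generator.

Everything tunable lives here as plain dataclasses with documented defaults;
a YAML file with the same nesting overrides any subset of keys
(``load_config("study.yaml")``).  Dotted key names from the docs map onto
the nesting, e.g. ``efw.coef_bpd3`` -> ``config.efw.coef_bpd3``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

__all__ = [
    "EfwConfig", "ChartPathsConfig", "ScreeningConfig", "FaoConfig",
    "StatsConfig", "OutcomeLink", "GeneratorConfig", "StudyConfig",
    "load_config",
]


@dataclass
class EfwConfig:
    """Estimated-fetal-weight polynomial EFW = coef_bpd3*BPD^3 + coef_ac2fl*AC^2*FL
    (cm in, grams out)."""
    coef_bpd3: float = 1.07
    coef_ac2fl: float = 0.30


@dataclass
class ChartPathsConfig:
    """Optional CSV paths per measurement; ``None`` falls back to the shipped
    synthetic default curves."""
    bpd: Optional[str] = None
    ac: Optional[str] = None
    fl: Optional[str] = None


@dataclass
class ScreeningConfig:
    # Carpenter-Coustan OGTT thresholds, mg/dL, inclusive
    cc_fasting: float = 95.0
    cc_h1: float = 180.0
    cc_h2: float = 155.0
    cc_h3: float = 140.0
    gct_threshold: float = 140.0
    macrosomia_cutoff_g: float = 4000.0

    @property
    def cc_thresholds(self) -> tuple[float, float, float, float]:
        return (self.cc_fasting, self.cc_h1, self.cc_h2, self.cc_h3)


@dataclass
class FaoConfig:
    level: float = 0.90
    headline: str = "lmp"          # lmp | bpd | fl | union
    use_fixed_cutoffs: bool = False
    fixed_cutoffs: dict = field(
        default_factory=lambda: {"lmp": 1.080, "bpd": 1.071, "fl": 1.069})
    rederive_near_term: bool = False   # default: carry mid-gestation cutoffs


@dataclass
class StatsConfig:
    welch: bool = True
    pairwise_family_size: int = 6      # all pairs of 4 subgroups
    # Adjusted-OR covariates; variables that define the exposure are dropped
    # automatically at fit time.
    adjustment: tuple = ("age_years", "prepreg_bmi", "weight_gain_dx", "gct_mgdl")


@dataclass
class OutcomeLink:
    """Logistic link: logit P = logit(base_rate) + log(group_or[g]) + log(fao_or)*FAO."""
    base_rate: float
    group_or: tuple      # (G1, G2, G3, G4); G1 must be 1.0
    fao_or: float


@dataclass
class GeneratorConfig:
    """Synthetic-cohort generator settings.

    Defaults emulate the study conditions of a large single-centre
    normal-glucose-tolerance pregnancy cohort: four age x BMI strata with
    realistic mixing, per-stratum maternal moments, a linear model for the
    abdominal overgrowth ratio on maternal covariates, and logistic links
    from stratum and fetal-abdominal-obesity status to delivery outcomes.
    """
    n: int = 20000
    seed: int = 1
    # (young/non-obese, young/obese, older/non-obese, older/obese)
    group_mix: tuple = (0.63, 0.03, 0.31, 0.03)
    age_dist: tuple = ((31.0, 2.4), (31.2, 2.4), (37.2, 2.2), (37.5, 2.3))
    bmi_dist: tuple = ((20.0, 1.9), (27.5, 2.6), (20.5, 1.9), (27.4, 2.4))
    gct_dist: tuple = ((109.9, 21.0), (116.2, 19.6), (114.3, 20.9), (118.9, 23.1))
    gain_dx_dist: tuple = ((7.7, 3.1), (5.8, 4.9), (7.6, 3.2), (5.3, 4.2))
    gain_term_dist: tuple = ((13.3, 4.0), (11.0, 5.9), (12.7, 3.9), (10.1, 5.0))
    height_mean_m: float = 1.61
    height_sd_m: float = 0.05
    # planted linear model of the GA-AC/GA-LMP ratio
    faor_intercept: float = 0.9489
    faor_age: float = 0.0010          # per year
    faor_bmi: float = 0.0015          # per kg/m^2
    faor_gain: float = 0.0008         # per kg gained to diagnosis
    faor_gct: float = 0.00008         # per mg/dL on 50-g GCT
    faor_resid_sd: float = 0.036
    faor_level: float = 0.90          # latent FAO = planted ratio in top decile
    # persistence of mid-gestation overgrowth to the near-term scan
    faor_near_persistence: float = 0.7
    faor_near_sd: float = 0.02
    biometry_noise_sd_mm: float = 2.0
    fao_outcome_links: dict = field(default_factory=lambda: {
        "lga": OutcomeLink(0.035, (1.0, 3.0, 1.5, 2.8), 4.0),
        "macrosomia": OutcomeLink(0.014, (1.0, 2.5, 0.95, 1.05), 4.0),
        "primary_cesarean": OutcomeLink(0.19, (1.0, 1.3, 1.35, 1.3), 1.35),
    })
    exclusion_rates: dict = field(default_factory=lambda: {
        "pih": 0.0032, "missing_weight": 0.0036, "missing_gct": 0.0253,
        "elsewhere": 0.024,
        # conditional on a positive 50-g GCT:
        "no_ogtt_given_positive": 0.038,
        "gdm_given_positive": 0.31,
        "one_value_given_positive": 0.20,
    })
    p_mid_biometry: float = 0.76
    p_near_biometry: float = 0.90
    p_repeat_cesarean: float = 0.14   # among non-primary-cesarean deliveries
    primipara_prob: tuple = (0.776, 0.67, 0.584, 0.504)
    male_prob: float = 0.515
    ga_delivery_mean_days: float = 273.0
    ga_delivery_sd_days: float = 10.0
    birth_weight_mean_g: float = 3200.0
    birth_weight_sd_g: float = 330.0


@dataclass
class StudyConfig:
    efw: EfwConfig = field(default_factory=EfwConfig)
    chart: ChartPathsConfig = field(default_factory=ChartPathsConfig)
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    fao: FaoConfig = field(default_factory=FaoConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    lga_reference_path: Optional[str] = None


def _update_dataclass(obj, overrides: dict):
    names = {f.name for f in dataclasses.fields(obj)}
    for key, val in overrides.items():
        if key not in names:
            raise KeyError(f"unknown config key {key!r} for {type(obj).__name__}")
        cur = getattr(obj, key)
        if dataclasses.is_dataclass(cur) and isinstance(val, dict):
            _update_dataclass(cur, val)
        elif isinstance(cur, dict) and isinstance(val, dict):
            cur.update(val)
        elif isinstance(cur, tuple) and isinstance(val, (list, tuple)):
            setattr(obj, key, tuple(tuple(v) if isinstance(v, list) else v for v in val))
        else:
            setattr(obj, key, val)
    return obj


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> StudyConfig:
    """Defaults, optionally overridden by a YAML file and/or a dict."""
    cfg = StudyConfig()
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        _update_dataclass(cfg, data)
    if overrides:
        _update_dataclass(cfg, overrides)
    return cfg
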