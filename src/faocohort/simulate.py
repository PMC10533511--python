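"""Synthetic pregnancy-cohort generator with planted, retrievable truth.

The generator emulates the structure the analysis assumes so every pipeline
stage is testable without real patient data:

* four maternal age x BMI strata with configurable mixing and per-stratum
  moments for age, BMI, weight gain and 50-g GCT glucose;
* a planted linear model for the abdominal overgrowth ratio
  (GA-AC/GA-LMP) on age, BMI, weight gain to diagnosis and GCT glucose;
* forward growth-chart biometry: the abdominal circumference is evaluated
  at GA-LMP times the planted ratio (an overgrown abdomen "reads" older),
  head and femur at GA-LMP itself, all plus Gaussian measurement noise in mm;
* logistic links from stratum and latent fetal-abdominal-obesity status
  (planted ratio in the top decile) to LGA, macrosomia and primary cesarean
  delivery, with birth weights drawn consistent with those flags;
* exclusion conditions (PIH, missing weight/GCT, GDM-spectrum OGTT results,
  delivery elsewhere) planted at configured rates.

:func:`planted_truth` returns the closed-form quantities the configuration
implies, the oracle for parameter-recovery tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import GeneratorConfig
from .cohort_io import COHORT_COLUMNS, frame_to_records
from .growth import MeasurementKind, default_chart
from .screening import PregnancyRecord, default_lga_reference

__all__ = ["generate_frame", "generate_cohort", "planted_truth", "PlantedTruth"]

_CC = (95.0, 180.0, 155.0, 140.0)   # abnormal-value targets for planted OGTTs


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth implied by a GeneratorConfig."""

    faor_coefficients: dict          # intercept + slopes + residual sd
    group_or: dict                   # outcome -> (G1..G4) odds ratios
    fao_or: dict                     # outcome -> OR for latent FAO status
    expected_exclusions: dict        # cascade stage -> expected count
    expected_included: float
    fao_prevalence: float            # 1 - quantile level, by construction


def _truncnorm(rng, mean, sd, lo, hi, size):
    if sd <= 0:
        return np.full(size, float(mean))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _per_group(rng, group, dist, lo, hi):
    out = np.empty(group.size)
    for g in range(4):
        mask = group == g
        if mask.any():
            mean, sd = dist[g]
            out[mask] = _truncnorm(rng, mean, sd, lo[g] if isinstance(lo, (list, tuple)) else lo,
                                   hi[g] if isinstance(hi, (list, tuple)) else hi,
                                   int(mask.sum()))
    return out


def generate_frame(config: GeneratorConfig | None = None,
                   include_truth_columns: bool = False) -> pd.DataFrame:
    """Generate a cohort table (the CSV schema the pipeline reads).

    Deterministic given ``config.seed``.  With ``include_truth_columns`` the
    frame carries the latent per-record truth (``_faor_true``,
    ``_fao_latent``) for recovery diagnostics; these columns are not part of
    the CSV schema and are dropped by :func:`faocohort.cohort_io.write_cohort_csv`.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return pd.DataFrame(columns=COHORT_COLUMNS)
    mix = np.asarray(cfg.group_mix, float)
    if mix.size != 4 or abs(mix.sum() - 1.0) > 1e-9 or np.any(mix < 0):
        raise ValueError("group_mix must be 4 probabilities summing to 1")

    group = rng.choice(4, size=n, p=mix)
    age = _per_group(rng, group, cfg.age_dist, (18, 18, 35, 35), (34.999, 34.999, 48, 48))
    bmi = _per_group(rng, group, cfg.bmi_dist, (14, 25, 14, 25), (24.999, 45, 24.999, 45))
    gct = _per_group(rng, group, cfg.gct_dist, 50, 260)
    gain_dx = _per_group(rng, group, cfg.gain_dx_dist, -3, 25)
    gain_term = _per_group(rng, group, cfg.gain_term_dist, -2, 32)
    height = _truncnorm(rng, cfg.height_mean_m, cfg.height_sd_m, 1.40, 1.85, n)
    prepreg_weight = bmi * height**2
    weight_dx = prepreg_weight + gain_dx
    weight_term = prepreg_weight + gain_term

    # planted overgrowth-ratio model (clipped to a physiologic band)
    noise = rng.normal(0.0, cfg.faor_resid_sd, n) if cfg.faor_resid_sd > 0 else 0.0
    faor = (cfg.faor_intercept + cfg.faor_age * age + cfg.faor_bmi * bmi
            + cfg.faor_gain * gain_dx + cfg.faor_gct * gct + noise)
    faor = np.clip(faor, 0.85, 1.18)
    fao_latent = faor >= np.quantile(faor, cfg.faor_level)

    # mid-gestation scan
    charts = {k: default_chart(k) for k in MeasurementKind}
    ga_mid = rng.uniform(24 * 7.0, 28 * 7.0, n)
    sd_mm = cfg.biometry_noise_sd_mm

    def measure(chart, ga):
        med = chart.value(np.clip(ga, *chart.valid_range))
        if sd_mm > 0:
            med = med + rng.normal(0.0, sd_mm, ga.size)
        return med

    ac_mid = measure(charts[MeasurementKind.AC], ga_mid * faor)
    bpd_mid = measure(charts[MeasurementKind.BPD], ga_mid)
    fl_mid = measure(charts[MeasurementKind.FL], ga_mid)

    # near-term scan: mid-gestation overgrowth partially persists
    ga_near = rng.uniform(36 * 7.0, 38 * 7.0, n)
    faor_near = 1.0 + cfg.faor_near_persistence * (faor - 1.0)
    if cfg.faor_near_sd > 0:
        faor_near = faor_near + rng.normal(0.0, cfg.faor_near_sd, n)
    ac_near = measure(charts[MeasurementKind.AC], np.clip(ga_near * faor_near, 98.0, 299.0))
    bpd_near = measure(charts[MeasurementKind.BPD], ga_near)
    fl_near = measure(charts[MeasurementKind.FL], ga_near)

    # glycemic screening results
    rates = cfg.exclusion_rates
    positive = gct >= 140.0
    cat = np.full(n, "ngt", object)    # conditional category for GCT positives
    u = rng.uniform(size=n)
    p_no, p_gdm, p_one = (rates["no_ogtt_given_positive"],
                          rates["gdm_given_positive"],
                          rates["one_value_given_positive"])
    cat[positive & (u < p_no)] = "no_ogtt"
    cat[positive & (u >= p_no) & (u < p_no + p_gdm)] = "gdm"
    cat[positive & (u >= p_no + p_gdm) & (u < p_no + p_gdm + p_one)] = "one_value"

    ogtt = np.full((n, 4), np.nan)
    has_ogtt = positive & (cat != "no_ogtt")
    idx = np.flatnonzero(has_ogtt)
    lo_normal = (65.0, 100.0, 85.0, 60.0)
    for i in idx:
        vals = [rng.uniform(lo_normal[j], _CC[j] - 0.5) for j in range(4)]
        if cat[i] == "one_value":
            j = rng.integers(4)
            vals[j] = _CC[j] + rng.uniform(0.0, 25.0)
        elif cat[i] == "gdm":
            k = rng.choice([2, 3, 4], p=[0.70, 0.25, 0.05])
            for j in rng.choice(4, size=k, replace=False):
                vals[j] = _CC[j] + rng.uniform(0.0, 30.0)
        ogtt[i] = vals
    insulin = np.where(has_ogtt, np.exp(rng.normal(np.log(7.0), 0.4, n)), np.nan)
    hba1c = np.where(has_ogtt, np.clip(rng.normal(5.0, 0.3, n), 4.0, 6.5), np.nan)

    # outcomes from logistic links; macrosomia coupled inside LGA so birth
    # weights can satisfy both labels exactly
    base = {}
    for name, link in cfg.fao_outcome_links.items():
        lor = np.log(np.asarray(link.group_or, float))[group]
        lp = np.log(link.base_rate / (1 - link.base_rate)) + lor \
            + np.log(link.fao_or) * fao_latent
        base[name] = 1.0 / (1.0 + np.exp(-lp))
    u_bw = rng.uniform(size=n)
    p_lga = base.get("lga", np.zeros(n))
    p_mac = np.minimum(base.get("macrosomia", np.zeros(n)), p_lga)
    lga = u_bw < p_lga
    macro = u_bw < p_mac
    p_ces = base.get("primary_cesarean", np.zeros(n))
    primary_ces = rng.uniform(size=n) < p_ces

    ga_delivery = np.clip(rng.normal(cfg.ga_delivery_mean_days,
                                     cfg.ga_delivery_sd_days, n), 238.0, 286.0)
    sex = np.where(rng.uniform(size=n) < cfg.male_prob, "male", "female")
    ref = default_lga_reference()
    p90 = np.array([ref.p90(int(g // 7), s) for g, s in zip(ga_delivery, sex)])

    bw = np.minimum(rng.normal(cfg.birth_weight_mean_g, cfg.birth_weight_sd_g, n),
                    p90 - 10.0)
    bw = np.where(lga & ~macro,
                  rng.uniform(p90 + 1.0, np.maximum(p90 + 2.0, 3995.0)), bw)
    bw = np.where(macro, rng.uniform(4005.0, 4600.0, n), bw)

    primipara = rng.uniform(size=n) < np.asarray(cfg.primipara_prob)[group]
    mode = np.where(primary_ces, "primary_cesarean",
                    np.where(rng.uniform(size=n) < cfg.p_repeat_cesarean,
                             "repeat_cesarean", "vaginal"))

    # planted exclusions and missingness
    pih = rng.uniform(size=n) < rates["pih"]
    missing_weight = rng.uniform(size=n) < rates["missing_weight"]
    missing_gct = rng.uniform(size=n) < rates["missing_gct"]
    elsewhere = rng.uniform(size=n) < rates["elsewhere"]
    has_mid = rng.uniform(size=n) < cfg.p_mid_biometry
    has_near = (rng.uniform(size=n) < cfg.p_near_biometry) & ~elsewhere

    def masked(arr, keep, fill=np.nan):
        out = np.asarray(arr, object if isinstance(fill, str) else float).copy()
        out[~keep] = fill
        return out

    df = pd.DataFrame({
        "id": [f"S{i:06d}" for i in range(n)],
        "age_years": np.round(age, 3),
        "prepreg_weight_kg": masked(np.round(prepreg_weight, 2), ~missing_weight),
        "height_m": np.round(height, 3),
        "weight_at_dx_kg": masked(np.round(weight_dx, 2), ~missing_weight),
        "weight_near_term_kg": masked(np.round(weight_term, 2), ~missing_weight),
        "gct_mgdl": masked(np.round(gct, 1), ~missing_gct),
        "ogtt_fasting_mgdl": masked(np.round(ogtt[:, 0], 1), ~missing_gct),
        "ogtt_h1_mgdl": masked(np.round(ogtt[:, 1], 1), ~missing_gct),
        "ogtt_h2_mgdl": masked(np.round(ogtt[:, 2], 1), ~missing_gct),
        "ogtt_h3_mgdl": masked(np.round(ogtt[:, 3], 1), ~missing_gct),
        "hba1c_pct": np.round(hba1c, 2),
        "fasting_insulin_uUml": np.round(insulin, 2),
        "ga_lmp_mid_days": masked(np.round(ga_mid, 2), has_mid),
        "bpd_mid_mm": masked(np.round(bpd_mid, 2), has_mid),
        "ac_mid_mm": masked(np.round(ac_mid, 2), has_mid),
        "fl_mid_mm": masked(np.round(fl_mid, 2), has_mid),
        "ga_lmp_near_days": masked(np.round(ga_near, 2), has_near),
        "bpd_near_mm": masked(np.round(bpd_near, 2), has_near),
        "ac_near_mm": masked(np.round(ac_near, 2), has_near),
        "fl_near_mm": masked(np.round(fl_near, 2), has_near),
        "parity": np.where(primipara, "primipara", "multipara"),
        "pih_before_24gw": pih,
        "delivered_elsewhere": elsewhere,
        "birth_weight_g": masked(np.round(bw, 0), ~elsewhere),
        "ga_delivery_days": masked(np.round(ga_delivery, 1), ~elsewhere),
        "infant_sex": sex,
        "delivery_mode": masked(mode, ~elsewhere, fill=""),
    }, columns=COHORT_COLUMNS)
    df["delivery_mode"] = df["delivery_mode"].replace("", np.nan)
    if include_truth_columns:
        df["_faor_true"] = faor
        df["_fao_latent"] = fao_latent
    return df


def generate_cohort(config: GeneratorConfig | None = None) -> list[PregnancyRecord]:
    """Records view of :func:`generate_frame`."""
    return frame_to_records(generate_frame(config))


def planted_truth(config: GeneratorConfig | None = None) -> PlantedTruth:
    """Closed-form expectations implied by a generator configuration."""
    cfg = config or GeneratorConfig()
    mix = np.asarray(cfg.group_mix, float)
    rates = cfg.exclusion_rates
    n = cfg.n

    # probability of a positive 50-g GCT under the per-stratum mixture
    p_pos = float(sum(m * sps.norm.sf(140.0, loc=mu, scale=sd)
                      for m, (mu, sd) in zip(mix, cfg.gct_dist)))

    e = {}
    remaining = float(n)
    for stage, p in (("pih_before_24gw", rates["pih"]),
                     ("missing_weight", rates["missing_weight"]),
                     ("missing_gct", rates["missing_gct"])):
        e[stage] = remaining * p
        remaining -= e[stage]
    for stage, p in (("unclassifiable", rates["no_ogtt_given_positive"]),
                     ("one_value_abnormality", rates["one_value_given_positive"]),
                     ("gdm", rates["gdm_given_positive"])):
        e[stage] = remaining * p_pos * p
    remaining -= e["unclassifiable"] + e["one_value_abnormality"] + e["gdm"]
    e["delivered_elsewhere"] = remaining * rates["elsewhere"]
    remaining -= e["delivered_elsewhere"]

    return PlantedTruth(
        faor_coefficients={
            "intercept": cfg.faor_intercept, "age_years": cfg.faor_age,
            "prepreg_bmi": cfg.faor_bmi, "weight_gain_dx": cfg.faor_gain,
            "gct_mgdl": cfg.faor_gct, "resid_sd": cfg.faor_resid_sd,
        },
        group_or={k: tuple(v.group_or) for k, v in cfg.fao_outcome_links.items()},
        fao_or={k: v.fao_or for k, v in cfg.fao_outcome_links.items()},
        expected_exclusions=e,
        expected_included=remaining,
        fao_prevalence=1.0 - cfg.faor_level,
    )


def truth_as_dict(truth: PlantedTruth) -> dict:
    return dataclasses.asdict(truth)
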