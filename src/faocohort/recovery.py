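"""Pipeline-level parameter recovery on synthetic cohorts.

Runs the full chain — generation, exclusion cascade, growth-chart GA
estimation, overgrowth ratios, empirical thresholds, outcome labelling,
logistic fits — and checks that each planted per-group odds ratio falls
inside its fitted 95% CI.  The outcome fits adjust for the pipeline's own
(observed) FAO flag, matching how the generator links outcomes to group and
latent FAO status.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .config import GeneratorConfig, StudyConfig
from .cohort_io import frame_to_records
from .growth import MeasurementKind, default_chart
from .pipeline import _build_analysis_frame, _classify_frame, _derive_thresholds
from .screening import apply_exclusions, default_lga_reference
from .simulate import generate_frame, planted_truth
from .stats import RegressionSpec, fit_logistic_or

__all__ = ["fit_group_ors", "planted_or_recovery"]

_LEVELS = ("G2", "G3", "G4")


def fit_group_ors(cohort_frame, study_config: StudyConfig | None = None) -> dict:
    """Fitted per-group ORs (vs G1) for each linked outcome, adjusted for the
    observed headline FAO flag."""
    cfg = study_config or StudyConfig()
    records, _ = apply_exclusions(frame_to_records(cohort_frame),
                                  cfg.screening.cc_thresholds,
                                  cfg.screening.gct_threshold)
    charts = {k: default_chart(k) for k in MeasurementKind}
    df, _ = _build_analysis_frame(records, cfg, charts, default_lga_reference())
    thresholds = _derive_thresholds(df, cfg)
    _classify_frame(df, thresholds, cfg.fao.headline)
    sub = df[df["fao_mid"].notna()].copy()
    sub["fao_flag"] = sub["fao_mid"].astype(float)
    out = {}
    for outcome in ("lga", "macrosomia", "primary_cesarean"):
        d = sub[sub[outcome].notna()].copy()
        d[outcome] = d[outcome].astype(float)
        results = fit_logistic_or(
            d, RegressionSpec(outcome, "subgroup", ("fao_flag",), "G1"))
        out[outcome] = {r.label: r for r in results}
    return out


def planted_or_recovery(config: GeneratorConfig | None = None,
                        n_replicates: int = 20,
                        base_seed: int = 1) -> dict:
    """Fraction of replicates in which each planted group OR lies inside its
    fitted 95% CI.  Returns ``{outcome: {level: fraction}}``."""
    cfg = config or GeneratorConfig()
    truth = planted_truth(cfg)
    hits = {o: {lev: 0 for lev in _LEVELS} for o in truth.group_or}
    for rep in range(n_replicates):
        rep_cfg = dataclasses.replace(cfg, seed=(base_seed + 1000 * rep) % 2**31)
        frame = generate_frame(rep_cfg)
        fitted = fit_group_ors(frame)
        for outcome, planted in truth.group_or.items():
            for j, lev in enumerate(_LEVELS):
                res = fitted[outcome][lev]
                if res.estimate is not None and \
                        res.ci_low <= planted[j + 1] <= res.ci_high:
                    hits[outcome][lev] += 1
    return {o: {lev: hits[o][lev] / n_replicates for lev in _LEVELS}
            for o in hits}
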