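"""End-to-end study orchestration and paper-style report rendering.

:func:`run_study` executes the stages in protocol order — exclusion cascade,
glycemic classification, age x BMI subgrouping, growth-chart GA estimation,
overgrowth ratios and FAO thresholds, outcome labelling, and the statistical
battery — and returns an :class:`AnalysisReport` whose six tables mirror the
usual presentation of such cohorts: per-group clinical summaries, biometry
and ratio summaries, outcome prevalences with explicit numerators and
denominators, odds-ratio blocks, and the FAO-present vs FAO-absent
comparison.  Every percentage cell carries its numerator and denominator so
each printed number is auditable; every stage logs its counts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import faor as faor_mod
from . import stats as st
from .config import StudyConfig
from .cohort_io import frame_to_records, read_cohort_csv
from .growth import (MeasurementKind, UnconvertibleMeasurement, default_chart,
                     estimate_fetal_weight, load_growth_chart)
from .screening import (LgaReference, apply_exclusions, assign_subgroup,
                        default_lga_reference, homa_indices, label_outcomes)

__all__ = ["AnalysisReport", "run_study", "render_report",
           "format_or_ci", "format_pct"]

GROUPS = ("G1", "G2", "G3", "G4")
PAIRS = [("G1", "G2"), ("G1", "G3"), ("G1", "G4"),
         ("G2", "G3"), ("G2", "G4"), ("G3", "G4")]


@dataclass
class AnalysisReport:
    table1: dict = field(default_factory=dict)
    table2: dict = field(default_factory=dict)
    table3: dict = field(default_factory=dict)
    table4: dict = field(default_factory=dict)
    table5: dict = field(default_factory=dict)
    table6: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    exclusion_log: list = field(default_factory=list)
    flagged: dict = field(default_factory=dict)
    config_echo: dict = field(default_factory=dict)
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(_jsonable(self.to_dict()), sort_keys=True,
                          indent=2, **kwargs)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if np.isnan(f) else f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def format_pct(value: float) -> str:
    """One-decimal percentage, half-up: 9.594 -> '9.6'."""
    return str(Decimal(repr(float(value))).quantize(Decimal("0.1"), ROUND_HALF_UP))


def format_or_ci(or_: float, lo: float, hi: float) -> str:
    """Two-decimal odds ratio with CI: '1.42 (1.17, 1.73)'."""
    q = lambda v: Decimal(repr(float(v))).quantize(Decimal("0.01"), ROUND_HALF_UP)
    return f"{q(or_)} ({q(lo)}, {q(hi)})"


def _cr_dict(res: st.ComparisonResult) -> dict:
    return {"estimate": res.estimate, "ci_low": res.ci_low, "ci_high": res.ci_high,
            "p_raw": res.p_raw, "p_adjusted": res.p_adjusted,
            "family_size": res.family_size, "method": res.method,
            "label": res.label, "flags": list(res.flags)}


def _pct_cell(num: int, den: int) -> dict:
    return {"n": int(num), "d": int(den),
            "pct": 100.0 * num / den if den else np.nan}


def _mean_sd(series: pd.Series) -> dict:
    x = series.dropna()
    return {"mean": float(x.mean()) if len(x) else np.nan,
            "sd": float(x.std(ddof=1)) if len(x) > 1 else np.nan,
            "n": int(len(x))}


def _estimate_ga_batch(chart, mm: np.ndarray) -> tuple[np.ndarray, int]:
    """Invert a chart for an array of measurements; out-of-range values are
    flagged (NaN) rather than dropped."""
    out = np.full(mm.shape, np.nan)
    vlo, vhi = chart.value_range
    ok = np.isfinite(mm) & (mm >= vlo) & (mm <= vhi)
    if ok.any():
        out[ok] = chart.invert(mm[ok])
    n_flagged = int(np.sum(np.isfinite(mm) & ~ok))
    return out, n_flagged


def _build_analysis_frame(records, config: StudyConfig, charts, lga_ref):
    rows = []
    for r in records:
        bmi = r.prepreg_bmi
        row = {
            "id": r.id, "age_years": r.age_years, "prepreg_bmi": bmi,
            "weight_gain_dx": r.weight_gain_to_dx,
            "weight_gain_term": r.weight_gain_to_term,
            "gct_mgdl": r.gct_mgdl,
            "ogtt_fasting": r.ogtt.fasting_mgdl if r.ogtt else np.nan,
            "hba1c_pct": r.hba1c_pct if r.hba1c_pct is not None else np.nan,
            "subgroup": assign_subgroup(r.age_years, bmi),
            "primipara": r.parity == "primipara",
            "male": r.infant_sex == "male",
            "delivered_elsewhere": r.delivered_elsewhere,
            "birth_weight_g": r.birth_weight_g if r.birth_weight_g is not None else np.nan,
            "ga_delivery_days": r.ga_delivery_days if r.ga_delivery_days is not None else np.nan,
            "delivery_mode": r.delivery_mode,
        }
        homa_ir = homa_beta = np.nan
        if r.ogtt is not None and r.fasting_insulin_uUml:
            ir, beta = homa_indices(r.ogtt.fasting_mgdl, r.fasting_insulin_uUml)
            homa_ir, homa_beta = ir, beta if beta is not None else np.nan
        row["homa_ir"], row["homa_beta"] = homa_ir, homa_beta
        for ctx, bio in (("mid", r.biometry_mid), ("near", r.biometry_near)):
            row[f"ga_lmp_{ctx}"] = bio.ga_lmp_days if bio else np.nan
            for m in ("bpd", "ac", "fl"):
                row[f"{m}_{ctx}_mm"] = getattr(bio, f"{m}_mm") if bio else np.nan
        if r.birth_weight_g is not None:
            lab = label_outcomes(r, lga_ref, config.screening.macrosomia_cutoff_g)
            row["lga"] = lab["lga"]
            row["macrosomia"] = lab["macrosomia"]
        else:
            row["lga"] = row["macrosomia"] = None
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        return df, {}

    flagged = {}
    for ctx in ("mid", "near"):
        for m, kind in (("bpd", MeasurementKind.BPD), ("ac", MeasurementKind.AC),
                        ("fl", MeasurementKind.FL)):
            ga, n_flag = _estimate_ga_batch(charts[kind],
                                            df[f"{m}_{ctx}_mm"].to_numpy(float))
            df[f"ga_{m}_{ctx}"] = ga
            if n_flag:
                flagged[f"unconvertible_{m}_{ctx}"] = n_flag
    efw_cfg = config.efw
    df["efw_g"] = [
        estimate_fetal_weight(b / 10.0, a / 10.0, f / 10.0,
                              efw_cfg.coef_bpd3, efw_cfg.coef_ac2fl).efw_g
        if np.isfinite(b) and np.isfinite(a) and np.isfinite(f) else np.nan
        for b, a, f in zip(df["bpd_mid_mm"], df["ac_mid_mm"], df["fl_mid_mm"])
    ]
    for ctx in ("mid", "near"):
        df[f"faor_lmp_{ctx}"] = df[f"ga_ac_{ctx}"] / df[f"ga_lmp_{ctx}"]
        df[f"faor_bpd_{ctx}"] = df[f"ga_ac_{ctx}"] / df[f"ga_bpd_{ctx}"]
        df[f"faor_fl_{ctx}"] = df[f"ga_ac_{ctx}"] / df[f"ga_fl_{ctx}"]
    df["cesarean"] = df["delivery_mode"].isin(
        ["primary_cesarean", "repeat_cesarean"]).astype(object)
    df.loc[df["delivery_mode"].isna(), "cesarean"] = None
    df["primary_cesarean"] = (df["delivery_mode"] == "primary_cesarean").astype(object)
    df.loc[df["delivery_mode"].isna(), "primary_cesarean"] = None
    return df, flagged


def _derive_thresholds(df: pd.DataFrame, config: StudyConfig):
    fao_cfg = config.fao
    if fao_cfg.use_fixed_cutoffs:
        return faor_mod.fixed_thresholds(fao_cfg.fixed_cutoffs, fao_cfg.level)
    sets = [faor_mod.FaorSet(l, b, f) for l, b, f in
            zip(df["faor_lmp_mid"], df["faor_bpd_mid"], df["faor_fl_mid"])
            if np.isfinite(l) and np.isfinite(b) and np.isfinite(f)]
    return faor_mod.empirical_thresholds(sets, fao_cfg.level)


def _classify_frame(df: pd.DataFrame, thresholds, headline: str) -> None:
    for ctx in ("mid", "near"):
        for name in ("lmp", "bpd", "fl"):
            df[f"fao_{name}_{ctx}"] = (
                df[f"faor_{name}_{ctx}"] >= thresholds.cut(name)).astype(object)
            df.loc[df[f"faor_{name}_{ctx}"].isna(), f"fao_{name}_{ctx}"] = None
        if headline == "union":
            head = df[[f"fao_lmp_{ctx}", f"fao_bpd_{ctx}", f"fao_fl_{ctx}"]].apply(
                lambda r: None if any(v is None for v in r) else bool(any(r)), axis=1)
            df[f"fao_{ctx}"] = head
        else:
            df[f"fao_{ctx}"] = df[f"fao_{headline}_{ctx}"]


def _group_frames(df: pd.DataFrame) -> dict:
    out = {"total": df}
    for g in GROUPS:
        out[g] = df[df["subgroup"] == g]
    return out


def _pairwise_t(groups: dict, var: str, family: int, welch: bool) -> dict:
    out = {}
    for ga, gb in PAIRS:
        x = groups[ga][var].dropna()
        y = groups[gb][var].dropna()
        if len(x) < 2 or len(y) < 2 or (x.std() == 0 and y.std() == 0 and x.mean() != y.mean()):
            continue
        try:
            res = st.two_sample_t(x, y, pooled=not welch).adjust(family)
        except ValueError:
            continue
        out[f"{ga}_vs_{gb}"] = _cr_dict(res)
    return out


def _pairwise_prop(groups: dict, var: str, family: int) -> dict:
    out = {}
    for ga, gb in PAIRS:
        a = groups[ga][var].dropna()
        b = groups[gb][var].dropna()
        if len(a) == 0 or len(b) == 0:
            continue
        res = st.proportion_test(int(a.sum()), len(a), int(b.sum()), len(b))
        out[f"{ga}_vs_{gb}"] = _cr_dict(res.adjust(family))
    return out


def _or_block(df: pd.DataFrame, outcome: str, covariates: tuple) -> dict:
    """Adjusted ORs of ``outcome`` for G2-G4 vs G1 with the given covariates;
    crude ORs alongside as the closed-form check."""
    block = {"adjusted": {}, "crude": {}, "covariates": list(covariates)}
    sub = df[df[outcome].notna()].copy()
    sub[outcome] = sub[outcome].astype(float)
    try:
        spec = st.RegressionSpec(outcome, "subgroup", tuple(covariates), "G1")
        for res in st.fit_logistic_or(sub, spec):
            block["adjusted"][res.label] = _cr_dict(res)
    except ValueError as exc:
        block["adjusted"] = {"error": str(exc)}
    for g in GROUPS[1:]:
        a = sub[sub["subgroup"] == g]
        c = sub[sub["subgroup"] == "G1"]
        if len(a) == 0 or len(c) == 0:
            continue
        tab = st.ContingencyTable2x2(int(a[outcome].sum()), int((1 - a[outcome]).sum()),
                                     int(c[outcome].sum()), int((1 - c[outcome]).sum()))
        block["crude"][g] = _cr_dict(st.crude_or(tab))
    return block


def run_study(cohort, config: StudyConfig | None = None,
              seed: Optional[int] = None) -> AnalysisReport:
    """Run the full analysis on a cohort CSV path or DataFrame."""
    config = config or StudyConfig()
    df_in = read_cohort_csv(cohort) if isinstance(cohort, (str, Path)) else cohort
    records = frame_to_records(df_in)

    included, log = apply_exclusions(records, config.screening.cc_thresholds,
                                     config.screening.gct_threshold)

    charts = {}
    for kind, path in ((MeasurementKind.BPD, config.chart.bpd),
                       (MeasurementKind.AC, config.chart.ac),
                       (MeasurementKind.FL, config.chart.fl)):
        charts[kind] = load_growth_chart(path, kind) if path else default_chart(kind)
    lga_ref = (LgaReference.from_csv(config.lga_reference_path)
               if config.lga_reference_path else default_lga_reference())

    report = AnalysisReport(
        exclusion_log=[{"stage": s, "n_in": n_in, "n_excluded": n_ex, "reason": r}
                       for s, n_in, n_ex, r in log.stages],
        config_echo=_jsonable(dataclasses.asdict(config)),
        seed=seed,
    )
    df, flagged = _build_analysis_frame(included, config, charts, lga_ref)
    report.flagged = flagged
    if df.empty:
        return report

    try:
        thresholds = _derive_thresholds(df, config)
    except ValueError:
        thresholds = faor_mod.fixed_thresholds(config.fao.fixed_cutoffs,
                                               config.fao.level)
        report.flagged["thresholds_fallback_fixed"] = 1
    _classify_frame(df, thresholds, config.fao.headline)
    report.thresholds = {"level": thresholds.level, "lmp": thresholds.cut_lmp,
                         "bpd": thresholds.cut_bpd, "fl": thresholds.cut_fl,
                         "n_reference": thresholds.n_reference,
                         "headline": config.fao.headline}

    groups = _group_frames(df)
    family = config.stats.pairwise_family_size
    welch = config.stats.welch

    t1_vars = ["age_years", "prepreg_bmi", "weight_gain_dx", "weight_gain_term",
               "gct_mgdl", "ogtt_fasting", "hba1c_pct", "homa_ir", "homa_beta"]
    report.table1 = {
        "summary": {g: {v: _mean_sd(sub[v]) for v in t1_vars}
                    for g, sub in groups.items()},
        "comparisons": {v: _pairwise_t(groups, v, family, welch) for v in t1_vars},
    }

    df["ga_lmp_mid_wk"] = df["ga_lmp_mid"] / 7.0
    for m in ("ac", "bpd", "fl"):
        df[f"ga_{m}_mid_wk"] = df[f"ga_{m}_mid"] / 7.0
    groups = _group_frames(df)
    t2_vars = ["ga_lmp_mid_wk", "ga_ac_mid_wk", "ga_bpd_mid_wk", "ga_fl_mid_wk",
               "efw_g", "faor_lmp_mid", "faor_bpd_mid", "faor_fl_mid"]
    report.table2 = {
        "summary": {g: {v: _mean_sd(sub[v]) for v in t2_vars}
                    for g, sub in groups.items()},
        "comparisons": {v: _pairwise_t(groups, v, family, welch) for v in t2_vars},
    }

    t3_flags = ["fao_mid", "primipara", "cesarean", "primary_cesarean",
                "lga", "macrosomia"]
    t3 = {"prevalence": {}, "continuous": {}, "comparisons": {}}
    for g, sub in groups.items():
        t3["prevalence"][g] = {}
        for v in t3_flags:
            obs = sub[v].dropna()
            t3["prevalence"][g][v] = _pct_cell(int(obs.sum()), len(obs))
        t3["continuous"][g] = {v: _mean_sd(sub[v])
                               for v in ("birth_weight_g", "ga_delivery_days")}
    t3["comparisons"] = {v: _pairwise_prop(groups, v, family) for v in t3_flags}
    report.table3 = t3

    # adjusted ORs: drop covariates that define the subgroup exposure
    adj = tuple(c for c in config.stats.adjustment
                if c not in ("age_years", "prepreg_bmi"))
    report.table4 = {f"fao_{name}": _or_block(df, f"fao_{name}_mid", adj)
                     for name in ("lmp", "bpd", "fl")}
    report.table5 = {out: _or_block(df, out, adj)
                     for out in ("lga", "macrosomia", "primary_cesarean")}

    # FAO-present vs FAO-absent (headline flag at mid-gestation)
    fao_df = df[df["fao_mid"].notna()]
    pos = fao_df[fao_df["fao_mid"] == True]   # noqa: E712
    neg = fao_df[fao_df["fao_mid"] == False]  # noqa: E712
    t6 = {"n": {"fao_pos": len(pos), "fao_neg": len(neg), "total": len(fao_df)},
          "continuous": {}, "prevalence": {}}
    for v in ["age_years", "prepreg_bmi", "weight_gain_dx", "weight_gain_term",
              "hba1c_pct", "gct_mgdl", "ogtt_fasting", "homa_ir", "homa_beta"]:
        cell = {"fao_neg": _mean_sd(neg[v]), "fao_pos": _mean_sd(pos[v])}
        x, y = pos[v].dropna(), neg[v].dropna()
        if len(x) >= 2 and len(y) >= 2:
            try:
                cell["test"] = _cr_dict(st.two_sample_t(x, y, pooled=not welch))
            except ValueError:
                pass
        t6["continuous"][v] = cell
    for v in ["fao_near", "primipara", "male", "lga", "macrosomia",
              "primary_cesarean"]:
        xp, xn = pos[v].dropna(), neg[v].dropna()
        cell = {"fao_neg": _pct_cell(int(xn.sum()), len(xn)),
                "fao_pos": _pct_cell(int(xp.sum()), len(xp))}
        if len(xp) and len(xn):
            cell["test"] = _cr_dict(st.proportion_test(int(xp.sum()), len(xp),
                                                       int(xn.sum()), len(xn)))
        t6["prevalence"][v] = cell
    report.table6 = t6
    return report


def render_report(report: AnalysisReport, fmt: str = "text",
                  out_dir: str | Path = ".") -> list[Path]:
    """Write the report as text (paper-style rounding), JSON (full precision)
    or CSV (one file per table).  Returns written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    if fmt == "json":
        path = out_dir / "report.json"
        path.write_text(report.to_json())
        written.append(path)
    elif fmt == "text":
        path = out_dir / "report.txt"
        path.write_text(_render_text(report))
        written.append(path)
    elif fmt == "csv":
        for name in ("table1", "table2", "table3", "table4", "table5", "table6"):
            tab = getattr(report, name)
            path = out_dir / f"{name}.csv"
            pd.json_normalize(_jsonable(tab), sep=".").T.to_csv(
                path, header=["value"])
            written.append(path)
        path = out_dir / "exclusion_log.csv"
        pd.DataFrame(report.exclusion_log).to_csv(path, index=False)
        written.append(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return written


def _render_text(report: AnalysisReport) -> str:
    lines = ["FAO cohort analysis report", "=" * 60, "", "Exclusion cascade:"]
    for stage in report.exclusion_log:
        lines.append(f"  {stage['stage']:<24s} in={stage['n_in']:>6d} "
                     f"excluded={stage['n_excluded']:>5d}  ({stage['reason']})")
    if report.thresholds:
        th = report.thresholds
        lines += ["", f"FAO thresholds (level {th['level']:g}, "
                  f"n_ref={th['n_reference']}, headline={th['headline']}): "
                  f"lmp {th['lmp']:.3f}  bpd {th['bpd']:.3f}  fl {th['fl']:.3f}"]
    if report.table3:
        lines += ["", "Outcome prevalences (% [n/d]):"]
        for g, cells in report.table3["prevalence"].items():
            parts = []
            for v, cell in cells.items():
                if cell["d"]:
                    parts.append(f"{v} {format_pct(cell['pct'])} "
                                 f"[{cell['n']}/{cell['d']}]")
            lines.append(f"  {g:<6s} " + "; ".join(parts))
    for name, title in (("table4", "Odds ratios for FAO (vs G1)"),
                        ("table5", "Odds ratios for outcomes (vs G1)")):
        tab = getattr(report, name)
        if not tab:
            continue
        lines += ["", title + ":"]
        for outcome, block in tab.items():
            adj = block.get("adjusted", {})
            if "error" in adj:
                lines.append(f"  {outcome}: not estimable ({adj['error']})")
                continue
            parts = []
            for lev, res in adj.items():
                if res["estimate"] is None:
                    parts.append(f"{lev} n/e")
                else:
                    parts.append(f"{lev} " + format_or_ci(
                        res["estimate"], res["ci_low"], res["ci_high"]))
            lines.append(f"  {outcome}: " + "; ".join(parts))
    if report.table6 and report.table6.get("n", {}).get("total"):
        n = report.table6["n"]
        lines += ["", f"FAO(+) vs FAO(-): n={n['fao_pos']}/{n['fao_neg']} "
                  f"of {n['total']}"]
        for v, cell in report.table6["prevalence"].items():
            if cell["fao_pos"]["d"] and cell["fao_neg"]["d"]:
                lines.append(f"  {v:<18s} FAO(+) {format_pct(cell['fao_pos']['pct'])}%"
                             f"  FAO(-) {format_pct(cell['fao_neg']['pct'])}%")
    lines.append("")
    return "\n".join(lines)
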