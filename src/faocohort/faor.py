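"""Fetal abdominal overgrowth ratios (FAORs) and FAO classification.

The three ratios divide the ultrasound gestational age implied by the
abdominal circumference (GA-AC) by, respectively, the actual LMP-based
gestational age (GA-LMP, correcting for scan-timing variation) and the
ultrasound GAs of head and femur (GA-BPD, GA-FL, detecting abdominal
overgrowth relative to the rest of the fetus).  Ratios are unit-invariant:
days or decimal weeks give identical values.

Fetal abdominal obesity (FAO) is an empirical-quantile call: a ratio at or
above the 90th percentile of the reference cohort's ratios.  Thresholds can
be re-derived from any cohort (linear interpolation between order
statistics) or fixed as configuration constants; the shipped fixed defaults
are 1.080 / 1.071 / 1.069 for the LMP / BPD / FL ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

__all__ = [
    "FaorSet",
    "FaoThresholds",
    "FaoFlags",
    "DEFAULT_FIXED_CUTOFFS",
    "compute_faors",
    "empirical_thresholds",
    "classify_fao",
]

RATIO_NAMES = ("lmp", "bpd", "fl")

#: Published-style default cutoffs for classifying external records without a
#: reference cohort (GA-AC/GA-LMP, GA-AC/GA-BPD, GA-AC/GA-FL).
DEFAULT_FIXED_CUTOFFS = {"lmp": 1.080, "bpd": 1.071, "fl": 1.069}


@dataclass(frozen=True)
class FaorSet:
    faor_lmp: float   # GA-AC / GA-LMP
    faor_bpd: float   # GA-AC / GA-BPD
    faor_fl: float    # GA-AC / GA-FL

    def ratio(self, name: str) -> float:
        return getattr(self, f"faor_{name}")


@dataclass(frozen=True)
class FaoThresholds:
    """Empirical per-ratio cutoffs at a given percentile level."""

    level: float
    cut_lmp: float
    cut_bpd: float
    cut_fl: float
    n_reference: int

    def cut(self, name: str) -> float:
        return getattr(self, f"cut_{name}")


@dataclass(frozen=True)
class FaoFlags:
    fao_lmp: bool
    fao_bpd: bool
    fao_fl: bool
    fao_headline: bool

    def flag(self, name: str) -> bool:
        return getattr(self, f"fao_{name}")


def compute_faors(ga_ac_days: float, ga_lmp_days: float,
                  ga_bpd_days: float, ga_fl_days: float) -> FaorSet:
    """The three overgrowth ratios from four gestational ages on a common
    unit (the ratios are scale-invariant)."""
    for name, v in (("ga_ac", ga_ac_days), ("ga_lmp", ga_lmp_days),
                    ("ga_bpd", ga_bpd_days), ("ga_fl", ga_fl_days)):
        if not v > 0:
            raise ValueError(f"{name} must be positive")
    return FaorSet(ga_ac_days / ga_lmp_days,
                   ga_ac_days / ga_bpd_days,
                   ga_ac_days / ga_fl_days)


def empirical_thresholds(faors: Iterable[FaorSet], level: float = 0.90,
                         min_n: int = 10) -> FaoThresholds:
    """Per-ratio empirical quantile at ``level``, linear interpolation
    between order statistics; non-finite values are dropped (count logged in
    the exception message if too few remain)."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    faors = list(faors)
    cuts = {}
    n_ref = None
    for name in RATIO_NAMES:
        vals = np.asarray([f.ratio(name) for f in faors], dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size < min_n:
            raise ValueError(
                f"need >= {min_n} finite {name} ratios, got {finite.size} "
                f"({vals.size - finite.size} non-finite dropped)"
            )
        cuts[name] = float(np.quantile(finite, level, method="linear"))
        n_ref = finite.size if n_ref is None else min(n_ref, finite.size)
    return FaoThresholds(level, cuts["lmp"], cuts["bpd"], cuts["fl"], n_ref)


def fixed_thresholds(cutoffs: Optional[dict] = None, level: float = 0.90) -> FaoThresholds:
    """Thresholds from configured constants (no reference cohort)."""
    c = dict(DEFAULT_FIXED_CUTOFFS)
    if cutoffs:
        c.update(cutoffs)
    return FaoThresholds(level, c["lmp"], c["bpd"], c["fl"], 0)


def classify_fao(faors: FaorSet, thresholds: FaoThresholds,
                 headline: str = "lmp") -> FaoFlags:
    """Per-ratio flags (inclusive >=) plus the single headline flag used in
    prevalence and outcome analyses.

    ``headline`` is ``"lmp"``, ``"bpd"``, ``"fl"`` or ``"union"`` (any
    ratio at/above its cutoff).
    """
    flags = {name: faors.ratio(name) >= thresholds.cut(name) for name in RATIO_NAMES}
    if headline == "union":
        head = any(flags.values())
    elif headline in flags:
        head = flags[headline]
    else:
        raise ValueError(f"unknown headline criterion {headline!r}")
    return FaoFlags(flags["lmp"], flags["bpd"], flags["fl"], head)
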