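"""Worked-example cohort-flow and outcome count tables.

The screening cascade can be audited from published stage counts alone:
given how many pregnancies entered screening and how many were removed at
each stage, the cascade must reproduce the reported NGT pool and final
included cohort.  :func:`build_flow_cohort` materialises a minimal record
list with exactly a given set of stage counts so the cascade arithmetic is
exercised through the real classification code, not recomputed by hand.

``REFERENCE_FLOW_COUNTS`` and ``REFERENCE_OUTCOME_CELLS`` carry the counts
of the large single-centre cohort that motivates this package's defaults
(7820 screened pregnancies; 6721 included with normal glucose tolerance,
5097 of them with mid-gestation biometry).
"""

from __future__ import annotations

from dataclasses import dataclass

from .screening import OGTTPanel, PregnancyRecord

__all__ = ["FlowCounts", "REFERENCE_FLOW_COUNTS", "REFERENCE_OUTCOME_CELLS",
           "build_flow_cohort"]


@dataclass(frozen=True)
class FlowCounts:
    """Stage counts of a two-step screening cascade."""

    n_total: int
    pih_before_24gw: int
    missing_weight: int
    missing_gct: int
    gct_positive: int          # among those screened with a GCT
    no_ogtt: int               # GCT-positive without an OGTT
    one_value_abnormality: int
    gdm: int
    delivered_elsewhere: int   # among the NGT pool


#: Stage counts of the motivating cohort: 7820 screened; 251 excluded up
#: front (25 PIH, 28 no weight, 198 no GCT); 1233 of 7569 GCT-positive, 47
#: without OGTT; 250 one-value abnormalities and 384 GDM diagnoses.
REFERENCE_FLOW_COUNTS = FlowCounts(
    n_total=7820, pih_before_24gw=25, missing_weight=28, missing_gct=198,
    gct_positive=1233, no_ogtt=47, one_value_abnormality=250, gdm=384,
    delivered_elsewhere=167,
)

#: Outcome prevalence cells (numerator, denominator) of the included cohort:
#: totals over n=6721 except the group-1 primipara cell (n=4226) and the
#: mid-gestation FAO cell (n=5097 with biometry).
REFERENCE_OUTCOME_CELLS = {
    "lga_total": (342, 6721),
    "macrosomia_total": (127, 6721),
    "primipara_group1": (3279, 4226),
    "cesarean_total": (2426, 6721),
    "primary_cesarean_total": (1512, 6721),
    "fao_at_diagnosis": (489, 5097),
}

# OGTT panels with 0, 1 and >= 2 Carpenter-Coustan exceedances
_PANEL_NGT = OGTTPanel(80.0, 150.0, 120.0, 100.0)
_PANEL_ONE = OGTTPanel(90.0, 185.0, 150.0, 135.0)
_PANEL_GDM = OGTTPanel(100.0, 190.0, 160.0, 120.0)


def build_flow_cohort(counts: FlowCounts = REFERENCE_FLOW_COUNTS) -> list[PregnancyRecord]:
    """Minimal synthetic cohort whose exclusion cascade reproduces ``counts``."""
    def rec(i, **kw):
        base = dict(id=f"f{i}", age_years=30.0, prepreg_weight_kg=55.0,
                    height_m=1.62, gct_mgdl=110.0)
        base.update(kw)
        return PregnancyRecord(**base)

    c = counts
    screened = c.n_total - c.pih_before_24gw - c.missing_weight - c.missing_gct
    ogtt_done = c.gct_positive - c.no_ogtt
    ngt_ogtt = ogtt_done - c.one_value_abnormality - c.gdm
    screen_negative = screened - c.gct_positive
    if min(screened, ogtt_done, ngt_ogtt, screen_negative) < 0:
        raise ValueError("inconsistent flow counts")
    ngt_pool = screen_negative + ngt_ogtt
    if c.delivered_elsewhere > ngt_pool:
        raise ValueError("delivered_elsewhere exceeds the NGT pool")

    cohort: list[PregnancyRecord] = []
    i = 0

    def extend(n, **kw):
        nonlocal i
        for _ in range(n):
            cohort.append(rec(i, **kw))
            i += 1

    extend(c.pih_before_24gw, pih_before_24gw=True)
    extend(c.missing_weight, prepreg_weight_kg=None)
    extend(c.missing_gct, gct_mgdl=None)
    extend(c.no_ogtt, gct_mgdl=150.0)
    extend(c.one_value_abnormality, gct_mgdl=150.0, ogtt=_PANEL_ONE)
    extend(c.gdm, gct_mgdl=150.0, ogtt=_PANEL_GDM)
    extend(ngt_ogtt, gct_mgdl=150.0, ogtt=_PANEL_NGT)
    extend(c.delivered_elsewhere, delivered_elsewhere=True)
    extend(screen_negative - c.delivered_elsewhere)
    assert len(cohort) == c.n_total
    return cohort
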