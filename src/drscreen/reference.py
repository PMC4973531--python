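"""Published aggregate results of the screening programme the package models.

An eight-year (2007-2014) population-based telemedicine screening programme
for diabetic retinopathy in a Spanish health-care area of 15,396 diabetes
patients reported its results only in aggregate: yearly screened counts and
incident cases, yearly screening and treatment cost totals, the cost
components of macular-oedema (DMO) care, and the inputs of its
cost-effectiveness comparisons.  Those printed aggregates are bundled here
as plain data so the package's examples, tests and reproduction script can
recompute the derived quantities (rates, means, per-patient costs, ICERs)
from the same inputs.

Known internal inconsistencies of the published tables are preserved as
printed; see ``docs/methods.md`` for which component rows do not reconcile
with their printed totals.
"""

from __future__ import annotations

import pandas as pd

from .registry import CostLineItem

YEARS = (2007, 2008, 2009, 2010, 2011, 2012, 2013, 2014)

#: Patients screened per year (denominator of the annual incidences).
SCREENED = {
    2007: 5027, 2008: 4989, 2009: 5312, 2010: 5367,
    2011: 5276, 2012: 6337, 2013: 5623, 2014: 6125,
}

#: Incident any-DR cases among screened patients, per year.
ANY_DR_CASES = {
    2007: 407, 2008: 402, 2009: 428, 2010: 432,
    2011: 426, 2012: 556, 2013: 502, 2014: 551,
}

#: Incident sight-threatening DR cases, per year.
STDR_CASES = {
    2007: 131, 2008: 125, 2009: 132, 2010: 134,
    2011: 141, 2012: 170, 2013: 162, 2014: 174,
}

#: Incident DMO cases (extrafoveal + clinically significant), per year.
DMO_CASES = {
    2007: 104, 2008: 101, 2009: 112, 2010: 114,
    2011: 110, 2012: 150, 2013: 135, 2014: 153,
}

#: Total screening cost per year (EUR).
SCREENING_TOTALS = {
    2007: 203_240, 2008: 201_840, 2009: 214_640, 2010: 217_080,
    2011: 213_480, 2012: 258_480, 2013: 229_560, 2014: 250_224,
}

#: Total yearly cost of DR diagnosis and treatment (EUR).
DIAGNOSIS_TREATMENT_TOTALS = {
    2007: 81_262, 2008: 79_886, 2009: 82_334, 2010: 77_995,
    2011: 85_598, 2012: 107_209, 2013: 116_574, 2014: 128_359,
}

#: Patients with DMO per year, as counted in the DMO cost table.
DMO_PATIENTS = {
    2007: 103, 2008: 101, 2009: 112, 2010: 114,
    2011: 110, 2012: 150, 2013: 135, 2014: 153,
}

#: Yearly DMO cost components (EUR): diagnosis, treatment and follow-up
#: lines.  Laser era 2007-2010; anti-VEGF era 2011-2014.
DMO_COMPONENTS: dict[int, list[CostLineItem]] = {
    2007: [
        CostLineItem(2007, "diagnosis", 15_686),
        CostLineItem(2007, "laser", 12_750),
        CostLineItem(2007, "follow_up", 51_680),
        CostLineItem(2007, "vitrectomy", 5_996),
        CostLineItem(2007, "follow_up", 2_140),
    ],
    2008: [
        CostLineItem(2008, "diagnosis", 15_382),
        CostLineItem(2008, "laser", 11_250),
        CostLineItem(2008, "follow_up", 48_120),
        CostLineItem(2008, "vitrectomy", 3_669),
        CostLineItem(2008, "follow_up", 1_480),
    ],
    2009: [
        CostLineItem(2009, "diagnosis", 17_024),
        CostLineItem(2009, "laser", 12_600),
        CostLineItem(2009, "follow_up", 51_072),
        CostLineItem(2009, "vitrectomy", 5_628),
        CostLineItem(2009, "follow_up", 2_080),
    ],
    2010: [
        CostLineItem(2010, "diagnosis", 17_328),
        CostLineItem(2010, "laser", 13_050),
        CostLineItem(2010, "follow_up", 52_896),
        CostLineItem(2010, "vitrectomy", 6_851),
        CostLineItem(2010, "follow_up", 2_520),
    ],
    2011: [
        CostLineItem(2011, "diagnosis", 16_720),
        CostLineItem(2011, "anti_vegf", 389_327),
        CostLineItem(2011, "follow_up", 39_510),
        CostLineItem(2011, "vitrectomy", 4_037),
        CostLineItem(2011, "follow_up", 1_490),
    ],
    2012: [
        CostLineItem(2012, "diagnosis", 16_752),
        CostLineItem(2012, "anti_vegf", 437_250),
        CostLineItem(2012, "follow_up", 47_040),
        CostLineItem(2012, "vitrectomy", 6_851),
        CostLineItem(2012, "follow_up", 2_480),
    ],
    2013: [
        CostLineItem(2013, "diagnosis", 14_328),
        CostLineItem(2013, "anti_vegf", 472_929),
        CostLineItem(2013, "follow_up", 48_048),
        CostLineItem(2013, "vitrectomy", 3_315),
        CostLineItem(2013, "follow_up", 1_664),
    ],
    2014: [
        CostLineItem(2014, "diagnosis", 16_238),
        CostLineItem(2014, "anti_vegf", 518_870),
        CostLineItem(2014, "follow_up", 54_824),
        CostLineItem(2014, "vitrectomy", 8_442),
        CostLineItem(2014, "follow_up", 3_328),
    ],
}

#: Printed yearly DMO treatment totals (EUR).  For 2007 and 2011-2014 these
#: do not equal the component sums above; they are carried as printed because
#: the era means and per-patient figures derive from them.
DMO_TREATMENT_TOTALS = {
    2007: 56_880, 2008: 64_519, 2009: 71_380, 2010: 75_317,
    2011: 459_384, 2012: 534_251, 2013: 561_956, 2014: 626_264,
}

#: Printed yearly DMO grand totals (diagnosis + treatment, EUR).
DMO_GRAND_TOTALS = {
    2007: 72_566, 2008: 79_901, 2009: 88_404, 2010: 92_645,
    2011: 476_104, 2012: 551_003, 2013: 576_284, 2014: 642_503,
}

#: Per-arm per-patient cost (EUR) and QALY inputs of the screening-interval
#: comparison: annual screening ("hi") vs the programme's 2.5-year interval
#: ("lo"), per patient diagnosed, by disease category.
SCREENING_CEA_INPUTS = {
    "any_dr": {"cost_hi": 1347.89, "qaly_hi": 12.05, "cost_lo": 482.32, "qaly_lo": 11.28},
    "stdr": {"cost_hi": 4270.98, "qaly_hi": 11.27, "cost_lo": 1528.26, "qaly_lo": 10.67},
    "dmo": {"cost_hi": 5099.91, "qaly_hi": 11.87, "cost_lo": 1824.82, "qaly_lo": 11.43},
}

#: Yearly per-patient DMO treatment cost (EUR) by era, and the first-year
#: QALY gain of anti-VEGF over laser.
LASER_COST_PER_PATIENT = 777.09
ANTI_VEGF_COST_PER_PATIENT = 7153.62
ANTI_VEGF_QALY_GAIN = 0.21

#: Cohort characteristics used by the cost-utility analysis.
LIFE_EXPECTANCY = 78.0
MEAN_AGE_DMO = 60.67
DISCOUNT_RATE = 0.03
SENSITIVITY = 0.902
SPECIFICITY = 0.986
SCREENING_INTERVAL_YEARS = 2.5

LASER_ERA_YEARS = (2007, 2008, 2009, 2010)
ANTI_VEGF_ERA_YEARS = (2011, 2012, 2013, 2014)


def dmo_ledger_frame(year: int) -> pd.DataFrame:
    """One year's DMO cost components as a cost-ledger DataFrame."""
    rows = [
        {"year": c.year, "category": c.category, "amount": c.amount}
        for c in DMO_COMPONENTS[year]
    ]
    return pd.DataFrame(rows, columns=["year", "category", "amount"])
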