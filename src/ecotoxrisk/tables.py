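"""Bundled reference tables for the worked example.

Acute EC/LC50s and release-medium analyte concentrations for six
nano-enabled products — three sunscreens (SUN1-3), a body cream (CA1), a
sanitiser (SAN1) and a sock textile (SK1) — whose released nanomaterials
and ions were tested on the three-species battery (*P. subcapitata* 72 h
growth, *S. polyrhiza* 72 h frond growth, *D. magna* 24/48 h
immobilisation).  Values are transcribed digit-for-digit from the published
determinations; EC50s recorded as "not determined" are NaN with status
``nd``.  EC/LC50s are in µg/L of the target analyte.  Concentrations are in
the unit printed for each product: mg/L except CA1, reported in µg/L.

These records are inputs for the risk-characterisation chain (they are not
recomputable here, since the underlying replicate data are unpublished).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["reference_toxicity", "reference_concentrations", "PRODUCTS"]

PRODUCTS = ("SUN1", "SUN2", "SUN3", "CA1", "SAN1", "SK1")

_ORGANISM_SLOTS = (
    ("P_subcapitata", 72),
    ("S_polyrhiza", 72),
    ("D_magna", 24),
    ("D_magna", 48),
)

# product, toxicant_form, analyte, condition ->
#   ((P.sub 72), (S.poly 72), (D.magna 24), (D.magna 48)) as (ec50, sd)
_TOXICITY = {
    ("SUN1", "ion", "Zn_ion", "light"): (
        (173.1, 2.5), (239.1, 68), (376.4, 16), (167.0, 9.1)),
    ("SUN1", "ion", "Zn_ion", "dark"): (
        (177.8, 20), (292.1, 40), (301.9, 37), (109.1, 6.0)),
    ("SUN2", "pr_enm", "Ti", "light"): (
        (99.50, 5.1), (173.0, 6.6), (26.03, 5.8), (4.205, 1.9)),
    ("SUN2", "pr_enm", "Ti", "dark"): (
        (93.20, 15), (189.0, 3.4), (64.59, 2.1), (7.856, 1.9)),
    ("SUN3", "pr_enm", "Ti", "light"): (
        (153.5, 1.4), (167.5, 22), (23.18, 1.0), (6.453, 0.12)),
    ("SUN3", "pr_enm", "Ti", "dark"): (
        (157.7, 2.2), (161.1, 31), (14.01, 2.4), (7.243, 0.57)),
    ("CA1", "ion", "Ag_ion", "light"): (
        (np.nan, np.nan), (33.94, 1.2), (15.50, 0.7), (17.9, 3.0)),
    ("CA1", "ion", "Ag_ion", "dark"): (
        (np.nan, np.nan), (32.25, 4.0), (15.80, 3.5), (15.89, 0.36)),
    ("SK1", "ion", "Ag_ion", "na"): (
        (663.5, 39), (2494, 397), (206.2, 29), (236.9, 34)),
    ("SAN1", "pr_enm", "Ag", "na"): (
        (1.315, 0.45), (108.2, 3.1), (5.367, 0.17), (1.110, 0.08)),
    ("SAN1", "ion", "Ag_ion", "na"): (
        (9.387, 0.26), (71.74, 5.0), (2.089, 0.65), (1.065, 0.31)),
}

# product, enm_type, analyte, condition -> (value, sd, unit)
_CONCENTRATIONS = {
    ("SUN1", "nTiO2+nZnO", "Ti", "light"): (6.99, 0.06, "mg_per_L"),
    ("SUN1", "nTiO2+nZnO", "Ti", "dark"): (8.51, 0.209, "mg_per_L"),
    ("SUN1", "nTiO2+nZnO", "Zn", "light"): (26.8, 0.39, "mg_per_L"),
    ("SUN1", "nTiO2+nZnO", "Zn", "dark"): (27.00, 0.84, "mg_per_L"),
    ("SUN1", "nTiO2+nZnO", "Zn_ion", "light"): (13.7, 0.42, "mg_per_L"),
    ("SUN1", "nTiO2+nZnO", "Zn_ion", "dark"): (13.84, 0.55, "mg_per_L"),
    ("SUN2", "nTiO2", "Ti", "light"): (0.68, 0.03, "mg_per_L"),
    ("SUN2", "nTiO2", "Ti", "dark"): (0.78, 0.02, "mg_per_L"),
    ("SUN3", "nTiO2", "Ti", "light"): (0.96, 0.02, "mg_per_L"),
    ("SUN3", "nTiO2", "Ti", "dark"): (0.93, 0.009, "mg_per_L"),
    ("CA1", "nTiO2+nAg", "Ti", "light"): (39.52, 0.82, "ug_per_L"),
    ("CA1", "nTiO2+nAg", "Ti", "dark"): (30.71, 0.71, "ug_per_L"),
    ("CA1", "nTiO2+nAg", "Ag", "light"): (56.19, 3.0, "ug_per_L"),
    ("CA1", "nTiO2+nAg", "Ag", "dark"): (52.38, 0.8, "ug_per_L"),
    ("CA1", "nTiO2+nAg", "Ag_ion", "light"): (39.05, 1.6, "ug_per_L"),
    ("CA1", "nTiO2+nAg", "Ag_ion", "dark"): (33.33, 6.4, "ug_per_L"),
    ("SAN1", "nAg", "Ag", "na"): (0.95, 0.03, "mg_per_L"),
    ("SAN1", "nAg", "Ag_ion", "na"): (0.82, 0.01, "mg_per_L"),
    ("SK1", "nTiO2+nAg", "Ti", "na"): (5.73, 0.23, "mg_per_L"),
    ("SK1", "nTiO2+nAg", "Ag", "na"): (6.00, 0.4, "mg_per_L"),
    ("SK1", "nTiO2+nAg", "Ag_ion", "na"): (6.40, 0.4, "mg_per_L"),
}


def reference_toxicity() -> pd.DataFrame:
    """Reference EC/LC50 records (µg/L of target analyte).

    Columns: product, toxicant_form (pr_enm | ion), analyte, condition,
    organism, duration_h, ec50_ugL (NaN where not determined), sd_ugL,
    status (ok | nd), record_id.
    """
    rows = []
    for (product, form, analyte, condition), slots in _TOXICITY.items():
        for (organism, duration), (ec50, sd) in zip(_ORGANISM_SLOTS, slots):
            rows.append(
                {
                    "product": product,
                    "toxicant_form": form,
                    "analyte": analyte,
                    "condition": condition,
                    "organism": organism,
                    "duration_h": duration,
                    "ec50_ugL": ec50,
                    "sd_ugL": sd,
                    "status": "nd" if np.isnan(ec50) else "ok",
                    "record_id": f"ec50/{product}/{analyte}/{condition}/"
                    f"{organism}/{duration}h",
                }
            )
    return pd.DataFrame(rows)


def reference_concentrations() -> pd.DataFrame:
    """Reference release-medium analyte concentrations (the MECs).

    Columns: product, enm_type, analyte, condition, value, sd, unit,
    record_id.  Units are as printed per product (mg/L except CA1, µg/L).
    """
    rows = []
    for (product, enm_type, analyte, condition), (value, sd, unit) in (
        _CONCENTRATIONS.items()
    ):
        rows.append(
            {
                "product": product,
                "enm_type": enm_type,
                "analyte": analyte,
                "condition": condition,
                "value": value,
                "sd": sd,
                "unit": unit,
                "record_id": f"mec/{product}/{analyte}/{condition}",
            }
        )
    return pd.DataFrame(rows)
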