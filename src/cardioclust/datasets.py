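"""Published reference measurements used as worked-example inputs.

These small tables are the printed per-case measurements of the two rare
clusters identified in a 3,822-case population cardiac-MRI study — an
11-case cluster with exceptionally large right ventricles and a 4-case
cluster with dilated, poorly-contracting left ventricles — plus the study's
cohort-level LV summary statistics.  They serve as fixed inputs for the
threshold rule engine and for arithmetic checks; they are not simulator
output.

Ejection fractions are converted from the printed percent scale to fractions.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "load_rva_cluster_cases",
    "load_dcm_cluster_cases",
    "REFERENCE_LV_SUMMARY",
]

# case id, RV EDV index (mL/m²), RV EF (%)
_RVA_ROWS = [
    ("2512949", 133.13, 63.61),
    ("2628396", 175.77, 43.91),
    ("3423847", 140.50, 65.24),
    ("3713328", 169.65, 71.59),
    ("3874816", 183.96, 56.22),
    ("4366978", 134.68, 52.53),
    ("4681487", 139.82, 54.39),
    ("4710306", 144.86, 29.69),
    ("5101726", 145.93, 43.82),
    ("5319688", 151.30, 51.93),
    ("5561149", 180.48, 41.88),
]

# case id, LV EDV index (mL/m²), LV EF (%), reference EDV, reference EF (%)
_DCM_ROWS = [
    ("2432774", 189.28, 19.74, 208.24, 20.0),
    ("3378112", 213.28, 18.75, 213.03, 15.0),
    ("4879002", 133.09, 27.03, 144.59, 29.0),
    ("5618713", 192.87, 26.74, 192.43, 27.0),
]

#: cohort-level LV measures: automatic pipeline vs reference channel
#: (volumes mL/m², EF as fraction)
REFERENCE_LV_SUMMARY = {
    "LV_EDV": {"pipeline_mean": 70.56, "pipeline_sd": 13.91, "gt_mean": 75.48, "gt_sd": 28.62},
    "LV_ESV": {"pipeline_mean": 24.06, "pipeline_sd": 9.02, "gt_mean": 33.87, "gt_sd": 22.82},
    "LV_EF": {"pipeline_mean": 0.6641, "pipeline_sd": 0.0733, "gt_mean": 0.5604, "gt_sd": 0.0653},
}


def load_rva_cluster_cases() -> pd.DataFrame:
    """The 11 printed cases of the RV-dilation cluster (RV EDV, RV EF)."""
    df = pd.DataFrame(_RVA_ROWS, columns=["case_id", "V_RV_ED", "EF_RV_pct"])
    df["EF_RV"] = df["EF_RV_pct"] / 100.0
    return df[["case_id", "V_RV_ED", "EF_RV"]]


def load_dcm_cluster_cases() -> pd.DataFrame:
    """The 4 printed cases of the dilated-LV cluster (LV EDV, LV EF, reference)."""
    df = pd.DataFrame(
        _DCM_ROWS,
        columns=["case_id", "V_LV_ED", "EF_LV_pct", "gt_V_LV_ED", "gt_EF_LV_pct"],
    )
    df["EF_LV"] = df["EF_LV_pct"] / 100.0
    df["gt_EF_LV"] = df["gt_EF_LV_pct"] / 100.0
    return df[["case_id", "V_LV_ED", "EF_LV", "gt_V_LV_ED", "gt_EF_LV"]]
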