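"""Published summary results of the islatravir thorough QT study.

These are the study's printed geometric-mean PK summaries and predicted
ddQTcP table, kept as reference values for cross-study arithmetic (dose
ratios, parent/metabolite exposure ratios) and for comparing simulated
output to the reported scale.  Individual-level study data are not public;
everything an analysis computes here is derived from these printed
summaries or from synthetic trials.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "PK_GM_SUMMARY",
    "DDQTCP_AT_CMAX",
    "QTCP_EXPONENT",
    "dose_ratios",
]

#: Geometric-mean PK summaries (single oral dose, healthy adults).
#: Cmax in uM for islatravir/M4 and ng/mL for moxifloxacin; AUC in h*uM.
#: NaN marks parameters not reported (terminal phase not characterizable).
PK_GM_SUMMARY = pd.DataFrame(
    [
        ("islatravir", 0.75, 28, 0.0250, 33.8, 0.50, 0.0989, 0.0641, 0.0903),
        ("islatravir", 240.0, 26, 3.83, 35.5, 1.08, 29.8, 21.2, 28.2),
        ("M4", 0.75, 28, 0.0223, 31.9, 0.52, None, None, None),
        ("M4", 240.0, 26, 2.07, 44.5, 1.15, 8.52, 7.18, 8.34),
        ("moxifloxacin", 400.0, 28, 1830.0, 24.6, None, None, None, None),
    ],
    columns=[
        "analyte", "dose_mg", "n", "cmax_gm", "cmax_gcv_pct",
        "tmax_median_h", "auc_0_inf_gm", "auc_0_24_gm", "auc_0_168_gm",
    ],
)

#: Model-predicted placebo-corrected QTcP change at the observed GM Cmax
#: (least-squares mean with two-sided 90% CI, ms).
DDQTCP_AT_CMAX = pd.DataFrame(
    [
        ("islatravir", 0.75, 28, -0.73, -3.19, 1.73),
        ("islatravir", 240.0, 26, 0.03, -2.89, 2.96),
        ("moxifloxacin", 400.0, 28, 13.84, 12.10, 15.58),
    ],
    columns=["analyte", "dose_mg", "n", "lsm_ms", "lo90_ms", "hi90_ms"],
)

#: The study's population-specific QT correction exponent.
QTCP_EXPONENT = 0.3754


def _gm(analyte: str, dose: float, col: str) -> float:
    sel = (PK_GM_SUMMARY["analyte"] == analyte) & (
        PK_GM_SUMMARY["dose_mg"] == dose)
    return float(PK_GM_SUMMARY.loc[sel, col].iloc[0])


def dose_ratios() -> dict[str, float]:
    """Exposure-ratio arithmetic on the published geometric means.

    Returns the 240 mg : 0.75 mg AUC0-24 and Cmax ratios (dose ratio 320;
    observed exposures scale ~330- and ~150-fold) and the islatravir:M4
    AUC0-inf ratio at 240 mg (~threefold).
    """
    return {
        "auc_0_24_ratio_240_vs_0p75": _gm("islatravir", 240, "auc_0_24_gm")
        / _gm("islatravir", 0.75, "auc_0_24_gm"),
        "cmax_ratio_240_vs_0p75": _gm("islatravir", 240, "cmax_gm")
        / _gm("islatravir", 0.75, "cmax_gm"),
        "islatravir_m4_auc_0_inf_ratio_240": _gm("islatravir", 240,
                                                 "auc_0_inf_gm")
        / _gm("M4", 240, "auc_0_inf_gm"),
    }
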