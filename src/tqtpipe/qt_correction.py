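"""Heart-rate correction of the QT interval and adequacy assessment.

Workflow: triplicate ECG extractions are averaged per time point; the
population-specific correction exponent is the OLS slope of log QT on
log RR over drug-free data (all placebo observations plus all pre-dose
observations); QTcF (Fridericia, exponent 1/3) and QTcP (population
exponent) are computed as QT / (RR in s)**exponent; adequacy of a
correction is judged by regressing the corrected interval on RR — the
correction is adequate when the two-sided 95% CI of that slope contains
zero.  Baselines are period-specific means of the pre-dose values and
changes from baseline are taken against the own-period baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FRIDERICIA_EXPONENT",
    "CorrectionFit",
    "aggregate_triplicates",
    "qtcf",
    "qtcp",
    "drug_free_subset",
    "derive_population_exponent",
    "assess_adequacy",
    "fit_correction",
    "baseline_and_delta",
]

FRIDERICIA_EXPONENT = 1.0 / 3.0
BAZETT_EXPONENT = 0.5  # offered as an extra only

_GROUP_KEYS = ["subject", "sequence", "period", "treatment", "time_h"]
_INTERVALS = ["qt_ms", "rr_ms", "pr_ms", "qrs_ms", "hr_bpm"]


@dataclass(frozen=True)
class CorrectionFit:
    """Estimated correction exponent plus the adequacy regression result."""

    exponent: float
    exponent_se: float
    adequacy_slope: float  # ms of QTc per ms of RR
    adequacy_slope_ci95: tuple[float, float]
    adequate: bool
    n_points: int


def aggregate_triplicates(obs: pd.DataFrame) -> pd.DataFrame:
    """Average replicate ECG extractions per subject/period/time.

    Returns one row per (subject, sequence, period, treatment, time_h) with
    the arithmetic mean of each available interval and the replicate count.
    """
    if obs.empty:
        raise ValueError("no ECG observations to aggregate")
    cols = [c for c in _INTERVALS if c in obs.columns]
    g = obs.groupby(_GROUP_KEYS, sort=True)
    out = g[cols].mean()
    out["n_replicates"] = g["replicate"].count()
    return out.reset_index()


def _check_positive(qt_ms, rr_ms) -> tuple[np.ndarray, np.ndarray]:
    qt = np.asarray(qt_ms, dtype=float)
    rr = np.asarray(rr_ms, dtype=float)
    if np.any(qt <= 0) or np.any(rr <= 0):
        raise ValueError("QT and RR intervals must be positive")
    return qt, rr


def qtcf(qt_ms, rr_ms):
    """Fridericia-corrected QT: QT / (RR in s)**(1/3), in ms."""
    return qtcp(qt_ms, rr_ms, FRIDERICIA_EXPONENT)


def qtcp(qt_ms, rr_ms, exponent: float):
    """Power-law heart-rate-corrected QT: QT / (RR in s)**exponent, in ms."""
    qt, rr = _check_positive(qt_ms, rr_ms)
    out = qt / (rr / 1000.0) ** exponent
    return out if out.ndim else float(out)


def qtcb(qt_ms, rr_ms):
    """Bazett-corrected QT (exponent 1/2); offered as an extra only."""
    return qtcp(qt_ms, rr_ms, BAZETT_EXPONENT)


def drug_free_subset(agg: pd.DataFrame, include_predose: bool = True,
                     placebo: str = "placebo") -> pd.DataFrame:
    """Drug-free rows: every placebo observation plus (optionally) every
    pre-dose observation regardless of arm."""
    mask = agg["treatment"] == placebo
    if include_predose:
        mask = mask | (agg["time_h"] < 0)
    return agg.loc[mask]


def derive_population_exponent(drug_free: pd.DataFrame) -> tuple[float, float]:
    """OLS slope of ln(QT) on ln(RR in s) over drug-free aggregated data.

    Returns (exponent, standard error).  Pooled across subjects: each
    aggregated observation is one regression point.
    """
    qt, rr = _check_positive(drug_free["qt_ms"], drug_free["rr_ms"])
    if qt.size < 3:
        raise ValueError("need at least 3 drug-free points")
    x = np.log(rr / 1000.0)
    if np.ptp(x) == 0:
        raise ValueError("RR has zero variance; exponent not identifiable")
    res = stats.linregress(x, np.log(qt))
    return float(res.slope), float(res.stderr)


def derive_population_exponent_mixed(drug_free: pd.DataFrame) -> tuple[float, float]:
    """Per-subject random-intercept variant of the exponent regression.

    Optional alternative to the pooled OLS default; requires statsmodels.
    """
    import statsmodels.formula.api as smf

    df = drug_free.copy()
    qt, rr = _check_positive(df["qt_ms"], df["rr_ms"])
    df["log_qt"] = np.log(qt)
    df["log_rr"] = np.log(rr / 1000.0)
    fit = smf.mixedlm("log_qt ~ log_rr", df, groups=df["subject"]).fit(reml=True)
    return float(fit.params["log_rr"]), float(fit.bse["log_rr"])


def assess_adequacy(qtc_ms, rr_ms, alpha: float = 0.05):
    """Regress QTc (ms) on RR (ms); the correction is adequate when the
    two-sided 95% CI of the slope (t distribution, n-2 df) contains zero.

    Returns (slope, (lo, hi), adequate).
    """
    qtc = np.asarray(qtc_ms, dtype=float)
    rr = np.asarray(rr_ms, dtype=float)
    if qtc.size < 3:
        raise ValueError("need at least 3 points for the adequacy regression")
    res = stats.linregress(rr, qtc)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, qtc.size - 2)
    se = res.stderr if np.isfinite(res.stderr) else 0.0  # constant QTc
    lo = res.slope - tcrit * se
    hi = res.slope + tcrit * se
    # guard the degenerate zero-residual fit, where the CI collapses to a
    # point and floating-point noise in the slope would decide adequacy
    atol = 1e-10 * max(1.0, float(np.mean(np.abs(qtc))) / float(np.mean(rr)))
    adequate = bool(lo - atol <= 0.0 <= hi + atol)
    return float(res.slope), (float(lo), float(hi)), adequate


def fit_correction(agg: pd.DataFrame, include_predose: bool = True,
                   fixed_exponent: float | None = None) -> CorrectionFit:
    """Derive (or accept) the population exponent and assess its adequacy.

    ``agg`` is the triplicate-aggregated ECG table.  When ``fixed_exponent``
    is given, the derivation is skipped and only adequacy is assessed.
    """
    df = drug_free_subset(agg, include_predose=include_predose)
    if fixed_exponent is None:
        exponent, se = derive_population_exponent(df)
    else:
        exponent, se = float(fixed_exponent), float("nan")
    qtc = qtcp(df["qt_ms"], df["rr_ms"], exponent)
    slope, ci, adequate = assess_adequacy(qtc, df["rr_ms"])
    return CorrectionFit(
        exponent=exponent, exponent_se=se, adequacy_slope=slope,
        adequacy_slope_ci95=ci, adequate=adequate, n_points=len(df),
    )


def baseline_and_delta(agg: pd.DataFrame, exponent: float) -> pd.DataFrame:
    """Attach QTcF/QTcP, the period-specific baseline, and change from baseline.

    Baseline is the mean of that subject/period's pre-dose (time < 0)
    aggregated QTc values; dQTcP = post-dose QTcP - own-period baseline.
    Baseline (pre-dose) rows carry dQTcP = 0 by convention.
    """
    out = agg.copy()
    out["qtcf_ms"] = qtcf(out["qt_ms"], out["rr_ms"])
    out["qtcp_ms"] = qtcp(out["qt_ms"], out["rr_ms"], exponent)
    pre = out.loc[out["time_h"] < 0]
    base = (
        pre.groupby(["subject", "period"])["qtcp_ms"].mean()
        .rename("baseline_qtcp_ms").reset_index()
    )
    missing = (
        out[["subject", "period"]].drop_duplicates().merge(base, how="left")
    )
    if missing["baseline_qtcp_ms"].isna().any():
        bad = missing.loc[missing["baseline_qtcp_ms"].isna(),
                          ["subject", "period"]].to_records(index=False)
        raise ValueError(f"no pre-dose records for subject/period: {list(bad)}")
    out = out.merge(base, on=["subject", "period"], how="left")
    out["delta_qtcp_ms"] = np.where(
        out["time_h"] < 0, 0.0, out["qtcp_ms"] - out["baseline_qtcp_ms"]
    )
    return out
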