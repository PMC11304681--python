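"""Noncompartmental pharmacokinetics.

Cmax/Tmax from observed quantifiable concentrations, linear-up/log-down
trapezoidal AUC over the study windows (0-24 h, 0-168 h, 0-last), terminal
rate constant (lambda_z) by log-linear regression over the best terminal
point set (maximum adjusted R-squared), extrapolation to infinity via the
regression-predicted concentration at the last quantifiable time, and
geometric-mean summaries.

BLQ convention: below-LLOQ samples before the first quantifiable
concentration are set to 0; embedded or terminal BLQ samples are treated
as missing (excluded from trapezoids and lambda_z).  A concentration equal
to the LLOQ is quantifiable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NcaResult",
    "GeometricSummary",
    "prepare_profile",
    "cmax_tmax",
    "auc_linuplogdown",
    "fit_lambda_z",
    "auc_to_inf",
    "geometric_summary",
    "run_nca",
    "summarize_nca",
]


@dataclass(frozen=True)
class NcaResult:
    """Per subject/period/analyte noncompartmental parameters."""

    cmax: float
    tmax_h: float
    lambda_z: float  # nan when not calculable ("NR")
    lambda_z_n_points: int
    lambda_z_r2_adj: float
    auc_0_24: float
    auc_0_168: float
    auc_0_last: float
    auc_0_inf: float
    pct_extrapolated: float


@dataclass(frozen=True)
class GeometricSummary:
    n: int
    geometric_mean: float
    geometric_cv_pct: float


def prepare_profile(times_h, conc, blq=None) -> tuple[np.ndarray, np.ndarray]:
    """Apply the BLQ convention; returns clean (times, conc) for analysis.

    Leading BLQ values (before the first quantifiable sample) become 0;
    later BLQ values are dropped.
    """
    t = np.asarray(times_h, dtype=float)
    c = np.asarray(conc, dtype=float)
    if t.size and np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if blq is None:
        blq = np.isnan(c)
    blq = np.asarray(blq, dtype=bool) | np.isnan(c)
    quant = ~blq
    if not quant.any():
        raise ValueError("profile has no quantifiable concentrations")
    first = np.argmax(quant)
    keep = quant.copy()
    lead = np.arange(t.size) < first
    keep |= lead
    c = np.where(lead, 0.0, c)
    if np.any(c[keep] < 0):
        raise ValueError("concentrations must be >= 0")
    return t[keep], c[keep]


def cmax_tmax(times_h, conc) -> tuple[float, float]:
    """Maximum observed concentration and its time (earliest on ties)."""
    t = np.asarray(times_h, dtype=float)
    c = np.asarray(conc, dtype=float)
    if c.size == 0:
        raise ValueError("empty profile")
    i = int(np.argmax(c))  # argmax returns the first maximum
    return float(c[i]), float(t[i])


def _segment_area(t1, t2, c1, c2) -> float:
    """Linear-up/log-down area of one segment."""
    dt = t2 - t1
    if c2 >= c1 or c1 <= 0.0 or c2 <= 0.0:
        return 0.5 * (c1 + c2) * dt
    return (c1 - c2) / np.log(c1 / c2) * dt


def _interp_conc(t, t1, t2, c1, c2) -> float:
    """Concentration at t within [t1, t2], consistent with the segment rule."""
    f = (t - t1) / (t2 - t1)
    if c2 >= c1 or c1 <= 0.0 or c2 <= 0.0:
        return c1 + f * (c2 - c1)
    return float(c1 * (c2 / c1) ** f)


def auc_linuplogdown(times_h, conc, t_start: float, t_end: float) -> float:
    """Linear-up/log-down trapezoidal AUC over [t_start, t_end].

    Ascending (or tied) segments use the linear trapezoid, descending
    segments with positive endpoints the log trapezoid.  Window endpoints
    off the sampling grid are interpolated with the same segment rule.
    The window is clipped to the observed range; nothing is added beyond
    the last quantifiable sample.
    """
    t = np.asarray(times_h, dtype=float)
    c = np.asarray(conc, dtype=float)
    if t_start >= t_end:
        raise ValueError("t_start must be < t_end")
    lo = max(t_start, float(t[0]))
    hi = min(t_end, float(t[-1]))
    if lo >= hi:
        raise ValueError("window does not overlap the sampled range")
    total = 0.0
    for i in range(t.size - 1):
        t1, t2, c1, c2 = t[i], t[i + 1], c[i], c[i + 1]
        if t2 <= lo or t1 >= hi:
            continue
        a, b = max(t1, lo), min(t2, hi)
        ca = _interp_conc(a, t1, t2, c1, c2) if a > t1 else c1
        cb = _interp_conc(b, t1, t2, c1, c2) if b < t2 else c2
        total += _segment_area(a, b, ca, cb)
    return float(total)


def fit_lambda_z(times_h, conc):
    """Terminal log-linear regression with automatic point selection.

    Candidate sets are all runs of >=3 consecutive points from strictly
    after Tmax through the last quantifiable sample; the set maximizing
    adjusted R-squared wins, ties going to the larger set.  Only positive
    concentrations are eligible.

    Returns (lambda_z, n_points, r2_adj, c_est_last); all-nan/0 when no
    eligible set exists (terminal parameters not calculable).
    """
    t = np.asarray(times_h, dtype=float)
    c = np.asarray(conc, dtype=float)
    _, tmax = cmax_tmax(t, c)
    mask = (t > tmax) & (c > 0.0)
    tt, cc = t[mask], c[mask]
    nr = (float("nan"), 0, float("nan"), float("nan"))
    if tt.size < 3:
        return nr
    log_c = np.log(cc)
    best = None  # (r2_adj, n, slope, intercept)
    for start in range(tt.size - 2):
        x, y = tt[start:], log_c[start:]
        n = x.size
        res = stats.linregress(x, y)
        if res.slope >= 0:
            continue
        r2 = res.rvalue**2
        r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        cand = (r2_adj, n, res.slope, res.intercept)
        if best is None or cand[0] > best[0] + 1e-12 or (
            abs(cand[0] - best[0]) <= 1e-12 and n > best[1]
        ):
            best = cand
    if best is None:
        return nr
    r2_adj, n, slope, intercept = best
    c_est_last = float(np.exp(intercept + slope * t[-1]))
    return float(-slope), int(n), float(r2_adj), c_est_last


def auc_to_inf(auc_0_last: float, c_est_last: float, lambda_z: float):
    """AUC0-inf = AUC0-last + Cest,last/lambda_z, with percent extrapolated."""
    if not lambda_z > 0.0:
        raise ValueError("lambda_z must be positive")
    tail = c_est_last / lambda_z
    auc_inf = auc_0_last + tail
    pct = 100.0 * tail / auc_inf if auc_inf > 0 else float("nan")
    return float(auc_inf), float(pct)


def geometric_summary(values) -> GeometricSummary:
    """Geometric mean and geometric %CV = 100*sqrt(exp(s2_ln) - 1)."""
    x = np.asarray(values, dtype=float)
    if x.size == 0 or np.any(x <= 0):
        raise ValueError("geometric summary requires positive values")
    ln = np.log(x)
    gm = float(np.exp(ln.mean()))
    s2 = float(np.var(ln, ddof=1)) if x.size > 1 else 0.0
    return GeometricSummary(n=int(x.size), geometric_mean=gm,
                            geometric_cv_pct=100.0 * np.sqrt(np.expm1(s2)))


def nca_profile(times_h, conc, blq=None) -> NcaResult:
    """Full NCA for one concentration-time profile."""
    t, c = prepare_profile(times_h, conc, blq)
    cmax, tmax = cmax_tmax(t, c)
    auc24 = auc_linuplogdown(t, c, 0.0, 24.0)
    auc168 = auc_linuplogdown(t, c, 0.0, 168.0) if t[-1] > 24.0 else auc24
    auc_last = auc_linuplogdown(t, c, 0.0, float(t[-1]))
    lz, n_pts, r2, c_est = fit_lambda_z(t, c)
    if np.isfinite(lz) and lz > 0:
        auc_inf, pct = auc_to_inf(auc_last, c_est, lz)
    else:
        auc_inf, pct = float("nan"), float("nan")
    return NcaResult(
        cmax=cmax, tmax_h=tmax, lambda_z=lz, lambda_z_n_points=n_pts,
        lambda_z_r2_adj=r2, auc_0_24=auc24, auc_0_168=auc168,
        auc_0_last=auc_last, auc_0_inf=auc_inf, pct_extrapolated=pct,
    )


def run_nca(pk: pd.DataFrame) -> pd.DataFrame:
    """NCA over a PK long table; one row per subject/period/analyte.

    Expects columns subject, period, treatment, analyte, dose_mg, time_h,
    conc, blq (as written by the trial simulator or an equivalent source).
    """
    rows = []
    keys = ["subject", "period", "treatment", "analyte", "dose_mg"]
    for key, grp in pk.groupby(keys, sort=True):
        grp = grp.sort_values("time_h")
        try:
            res = nca_profile(grp["time_h"], grp["conc"],
                              grp["blq"] if "blq" in grp else None)
        except ValueError:
            continue  # all-BLQ profile: nothing to report
        row = dict(zip(keys, key))
        if "conc_unit" in grp:
            row["conc_unit"] = grp["conc_unit"].iloc[0]
        row.update(res.__dict__)
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_nca(nca_table: pd.DataFrame) -> pd.DataFrame:
    """Treatment-level geometric summaries shaped like a PK summary table.

    Geometric mean (%CV) for Cmax and the AUCs, median (range) for Tmax;
    parameters that are not calculable for a subject are dropped from that
    parameter's summary.
    """
    out = []
    for (analyte, dose), grp in nca_table.groupby(["analyte", "dose_mg"],
                                                  sort=True):
        row: dict = {"analyte": analyte, "dose_mg": dose, "n": len(grp)}
        for par in ("cmax", "auc_0_24", "auc_0_168", "auc_0_inf"):
            vals = grp[par].dropna()
            vals = vals[vals > 0]
            if len(vals) >= 1:
                s = geometric_summary(vals)
                row[f"{par}_gm"] = s.geometric_mean
                row[f"{par}_gcv_pct"] = s.geometric_cv_pct
                row[f"{par}_n"] = s.n
            else:
                row[f"{par}_gm"] = float("nan")
                row[f"{par}_gcv_pct"] = float("nan")
                row[f"{par}_n"] = 0
        row["tmax_median_h"] = float(grp["tmax_h"].median())
        row["tmax_min_h"] = float(grp["tmax_h"].min())
        row["tmax_max_h"] = float(grp["tmax_h"].max())
        out.append(row)
    return pd.DataFrame(out)
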