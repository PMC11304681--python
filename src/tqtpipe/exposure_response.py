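"""Concentration-QTc mixed-effects modelling and regulatory decisions.

The primary analysis models the change from baseline in population-corrected
QT (dQTcP) with fixed effects for treatment and time point, continuous
effects for each analyte's time-matched plasma concentration and for the
centered baseline QTcP, and a double-compound-symmetry covariance: a
subject-level exchangeable component, a subject-by-period exchangeable
component, and an independent residual,

    V_subject = s2_subject * J + s2_subject_period * blockdiag_p(J_p)
                + s2_residual * I.

Variance components are estimated by REML (quasi-Newton on the
log-variance scale with dispersed restarts); fixed effects are the GLS
solution at the converged components.  The placebo-corrected effect at a
reference concentration (the observed geometric-mean Cmax) is

    ddQTc(c_ref) = beta_treatment + beta_conc * c_ref,

with a two-sided 90% CI whose limits equal the one-sided 95% confidence
bounds used by the regulatory decision rules: a drug is QT-negative when
the upper bound is < 10 ms, and assay sensitivity is confirmed when the
positive control's lower bound is > 5 ms (both strict).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .synthetic_trial import (
    ISLATRAVIR_HIGH,
    ISLATRAVIR_LOW,
    MOXIFLOXACIN,
    PLACEBO,
)

__all__ = [
    "DEFAULT_ANALYTE_FOR_TREATMENT",
    "CqtFit",
    "DeltaDeltaPrediction",
    "build_cqt_dataset",
    "fit_cqt",
    "predict_ddqtc",
    "decision_rules",
    "timepoint_analysis",
    "reml_neg2loglik",
    "gls_solution",
]

logger = logging.getLogger("tqtpipe")

#: Which measured analyte carries each arm's concentration effect.
DEFAULT_ANALYTE_FOR_TREATMENT: dict[str, str] = {
    ISLATRAVIR_LOW: "islatravir",
    ISLATRAVIR_HIGH: "islatravir",
    MOXIFLOXACIN: "moxifloxacin",
}

QT_NEGATIVE_THRESHOLD_MS = 10.0
ASSAY_SENSITIVITY_THRESHOLD_MS = 5.0


# ---------------------------------------------------------------------------
# Dataset assembly


def build_cqt_dataset(
    qtc_series: pd.DataFrame,
    pk: pd.DataFrame,
    analyte_for_treatment: dict[str, str] | None = None,
    placebo: str = PLACEBO,
    max_time_h: float = 24.0,
) -> pd.DataFrame:
    """Join post-dose dQTcP values with time-matched concentrations.

    One row per subject/period/post-dose time through ``max_time_h``; each
    analyte named in ``analyte_for_treatment`` gets its own concentration
    column ``conc_<analyte>`` (zero off-drug).  BLQ concentrations count as
    zero; a missing concentration at a matched time drops the row (logged).
    Placebo rows carry zero in every concentration column.
    """
    mapping = dict(DEFAULT_ANALYTE_FOR_TREATMENT
                   if analyte_for_treatment is None else analyte_for_treatment)
    rows = qtc_series.loc[
        (qtc_series["time_h"] > 0) & (qtc_series["time_h"] <= max_time_h)
    ].copy()
    if rows.empty:
        raise ValueError("no post-dose QTc rows in the analysis window")
    analytes = sorted(set(mapping.values()))
    for a in analytes:
        rows[f"conc_{a}"] = 0.0

    pk_q = pk.copy()
    pk_q["conc_filled"] = np.where(pk_q["blq"], 0.0, pk_q["conc"])
    drop_mask = np.zeros(len(rows), dtype=bool)
    for trt, analyte in mapping.items():
        sel = rows["treatment"] == trt
        if not sel.any():
            continue
        sub = pk_q.loc[pk_q["analyte"] == analyte,
                       ["subject", "period", "time_h", "conc_filled"]]
        merged = rows.loc[sel, ["subject", "period", "time_h"]].merge(
            sub, on=["subject", "period", "time_h"], how="left"
        )
        vals = merged["conc_filled"].to_numpy()
        missing = np.isnan(vals)
        rows.loc[sel, f"conc_{analyte}"] = np.where(missing, 0.0, vals)
        drop_mask[np.flatnonzero(sel.to_numpy())[missing]] = True
    if drop_mask.any():
        logger.info("dropping %d QTc rows without a matched concentration",
                    int(drop_mask.sum()))
        rows = rows.loc[~drop_mask]
    overlap = set()
    for trt, analyte in mapping.items():
        overlap |= set(rows.loc[rows["treatment"] == trt, "time_h"])
    if mapping and not overlap:
        raise ValueError("ECG and PK schedules share no time points")

    rows["baseline_centered"] = (
        rows["baseline_qtcp_ms"] - rows["baseline_qtcp_ms"].mean()
    )
    keep = (["subject", "sequence", "period", "treatment", "time_h",
             "delta_qtcp_ms", "baseline_qtcp_ms", "baseline_centered"]
            + [f"conc_{a}" for a in analytes])
    out = rows[keep].sort_values(
        ["subject", "period", "time_h", "treatment"]
    ).reset_index(drop=True)
    out.attrs["analyte_for_treatment"] = mapping
    out.attrs["placebo"] = placebo
    return out


# ---------------------------------------------------------------------------
# REML machinery for the double-compound-symmetry model

_VC_NAMES = ("sigma2_subject", "sigma2_subject_period", "sigma2_residual")


def _block_patterns(subject: np.ndarray, period: np.ndarray):
    """Group subjects by their (period run-length) pattern.

    Rows must be sorted by subject then period.  Returns
    {pattern: list of row-index arrays}, one entry per subject.
    """
    patterns: dict[tuple, list[np.ndarray]] = {}
    for s in pd.unique(subject):
        idx = np.flatnonzero(subject == s)
        per = period[idx]
        _, counts = np.unique(per, return_counts=True)
        patterns.setdefault(tuple(counts), []).append(idx)
    return patterns


def _pattern_cov(pattern: tuple, vc: np.ndarray) -> np.ndarray:
    n = int(sum(pattern))
    v = vc[2] * np.eye(n) + vc[0] * np.ones((n, n))
    off = 0
    for size in pattern:
        v[off:off + size, off:off + size] += vc[1]
        off += size
    return v


class _RemlProblem:
    """Precomputed structures for one model fit."""

    def __init__(self, X: np.ndarray, y: np.ndarray,
                 subject: np.ndarray, period: np.ndarray):
        order = np.lexsort((period, subject))
        self.X, self.y = X[order], y[order]
        self.n, self.p = X.shape
        self.rank = np.linalg.matrix_rank(X)
        if self.rank < self.p:
            raise ValueError("design matrix is rank deficient")
        pats = _block_patterns(subject[order], period[order])
        self.groups = []
        for pattern, idx_list in pats.items():
            Xg = np.stack([self.X[i] for i in idx_list])
            yg = np.stack([self.y[i] for i in idx_list])
            self.groups.append((pattern, Xg, yg))

    def assemble(self, vc: np.ndarray):
        """X'V^-1 X, X'V^-1 y, y'V^-1 y and sum log|V_i| at components vc."""
        p = self.p
        xtvx = np.zeros((p, p))
        xtvy = np.zeros(p)
        ytvy = 0.0
        logdet = 0.0
        for pattern, Xg, yg in self.groups:
            V = _pattern_cov(pattern, vc)
            sign, ld = np.linalg.slogdet(V)
            if sign <= 0:
                raise np.linalg.LinAlgError("non-PD block covariance")
            vinv = np.linalg.inv(V)
            logdet += Xg.shape[0] * ld
            WX = np.einsum("ij,ajk->aik", vinv, Xg)
            xtvx += np.einsum("aip,aiq->pq", Xg, WX)
            Wy = yg @ vinv
            xtvy += np.einsum("aip,ai->p", Xg, Wy)
            ytvy += float(np.einsum("ai,ai->", yg, Wy))
        return xtvx, xtvy, ytvy, logdet

    def neg2ll(self, log_vc: np.ndarray) -> float:
        vc = np.exp(np.clip(log_vc, -40.0, 40.0))
        try:
            xtvx, xtvy, ytvy, logdet = self.assemble(vc)
            sign, ld_x = np.linalg.slogdet(xtvx)
            if sign <= 0:
                return 1e12
            beta = np.linalg.solve(xtvx, xtvy)
        except np.linalg.LinAlgError:
            return 1e12
        quad = ytvy - beta @ xtvy
        if not np.isfinite(quad) or quad < 0:
            return 1e12
        return logdet + ld_x + quad


def reml_neg2loglik(log_vc, X, y, subject, period) -> float:
    """-2 x restricted log-likelihood (up to an additive constant) at the
    given log variance components (subject, subject-by-period, residual).

    Exposed so the REML surface can be examined or maximized independently.
    """
    prob = _RemlProblem(np.asarray(X, float), np.asarray(y, float),
                        np.asarray(subject), np.asarray(period))
    return prob.neg2ll(np.asarray(log_vc, float))


def gls_solution(X, y, subject, period, vc):
    """Closed-form GLS fixed effects and covariance at fixed components.

    ``vc`` is (sigma2_subject, sigma2_subject_period, sigma2_residual).
    Returns (beta, cov_beta).
    """
    prob = _RemlProblem(np.asarray(X, float), np.asarray(y, float),
                        np.asarray(subject), np.asarray(period))
    xtvx, xtvy, _, _ = prob.assemble(np.asarray(vc, float))
    beta = np.linalg.solve(xtvx, xtvy)
    return beta, np.linalg.inv(xtvx)


def _optimize_reml(prob: _RemlProblem, n_restarts: int = 3,
                   tol: float = 1e-8):
    """Bounded quasi-Newton on the log-variance scale, dispersed restarts."""
    resid = prob.y - prob.X @ np.linalg.lstsq(prob.X, prob.y, rcond=None)[0]
    var0 = max(float(np.var(resid)), 1e-8)
    base = math.log(var0)
    starts = [
        np.array([base - 1.6, base - 1.6, base - 0.5]),
        np.array([base - 3.0, base - 0.7, base - 0.7]),
        np.array([base - 0.7, base - 3.0, base - 0.7]),
    ][:max(1, n_restarts)]
    bounds = [(base - 30.0, base + 6.0)] * 3
    best = None
    for x0 in starts:
        res = optimize.minimize(prob.neg2ll, x0, method="L-BFGS-B",
                                bounds=bounds,
                                options={"ftol": tol, "gtol": 1e-7,
                                         "maxiter": 200})
        if best is None or res.fun < best.fun:
            best = res
    return best


# ---------------------------------------------------------------------------
# Model fitting


@dataclass
class CqtFit:
    """Fitted concentration-QTc mixed model."""

    params: pd.Series
    cov_params: pd.DataFrame
    vc: dict[str, float]
    reml_loglik: float
    converged: bool
    df_resid: int
    n_obs: int
    treatment_cols: dict[str, str]
    conc_cols: dict[str, str]
    analyte_for_treatment: dict[str, str]
    time_cols: dict[float, str] = field(default_factory=dict)
    interaction_cols: dict[tuple[str, float], str] = field(default_factory=dict)

    def contrast(self, c: np.ndarray) -> tuple[float, float]:
        est = float(c @ self.params.to_numpy())
        se = float(np.sqrt(c @ self.cov_params.to_numpy() @ c))
        return est, se


def _build_design(data: pd.DataFrame, include_interaction: bool,
                  placebo: str, include_concentration: bool = True):
    treatments = [t for t in pd.unique(data["treatment"]) if t != placebo]
    treatments.sort()
    times = sorted(pd.unique(data["time_h"]))
    ref_time = times[0]
    cols: dict[str, np.ndarray] = {"(Intercept)": np.ones(len(data))}
    trt_cols, time_cols, inter_cols = {}, {}, {}
    for t in treatments:
        name = f"trt[{t}]"
        cols[name] = (data["treatment"] == t).to_numpy(float)
        trt_cols[t] = name
    for tp in times[1:]:
        name = f"time[{tp:g}]"
        cols[name] = (data["time_h"] == tp).to_numpy(float)
        time_cols[tp] = name
    if include_interaction:
        for t in treatments:
            for tp in times[1:]:
                name = f"trt[{t}]:time[{tp:g}]"
                cols[name] = (
                    ((data["treatment"] == t) & (data["time_h"] == tp))
                    .to_numpy(float)
                )
                inter_cols[(t, tp)] = name
    conc_cols = {}
    mapping = data.attrs.get("analyte_for_treatment",
                             DEFAULT_ANALYTE_FOR_TREATMENT)
    if include_concentration:
        for a in sorted(set(mapping.values())):
            col = f"conc_{a}"
            if col in data.columns and np.any(data[col].to_numpy() != 0.0):
                cols[col] = data[col].to_numpy(float)
                conc_cols[a] = col
    cols["baseline_centered"] = data["baseline_centered"].to_numpy(float)
    X = np.column_stack(list(cols.values()))
    return X, list(cols), trt_cols, time_cols, inter_cols, conc_cols, mapping


def fit_cqt(data: pd.DataFrame, include_interaction: bool = False,
            include_concentration: bool = True,
            n_restarts: int = 3) -> CqtFit:
    """REML fit of the concentration-QTc model on a built dataset.

    Fixed effects: intercept, treatment (placebo reference), time point
    (first post-dose time reference), one concentration slope per analyte,
    and centered baseline QTcP; optional treatment-by-time interaction for
    the by-time-point analysis.  Degrees of freedom for t intervals are
    residual: N - rank(X).
    """
    placebo = data.attrs.get("placebo", PLACEBO)
    n_trt = data.groupby("treatment")["subject"].nunique()
    if (n_trt < 2).any():
        raise ValueError("need at least 2 subjects per treatment")
    (X, names, trt_cols, time_cols,
     inter_cols, conc_cols, mapping) = _build_design(
        data, include_interaction, placebo, include_concentration)
    y = data["delta_qtcp_ms"].to_numpy(float)
    prob = _RemlProblem(X, y, data["subject"].to_numpy(),
                        data["period"].to_numpy())
    res = _optimize_reml(prob, n_restarts=n_restarts)
    vc = np.exp(res.x)
    xtvx, xtvy, _, _ = prob.assemble(vc)
    beta = np.linalg.solve(xtvx, xtvy)
    cov = np.linalg.inv(xtvx)
    n, p = prob.n, prob.rank
    # variances that collapsed to the lower optimizer bound are zero
    floor = math.exp(res.x[2]) * 1e-10
    vc_rep = {k: (0.0 if v < floor else float(v))
              for k, v in zip(_VC_NAMES, vc)}
    loglik = -0.5 * (res.fun + (n - p) * math.log(2.0 * math.pi))
    return CqtFit(
        params=pd.Series(beta, index=names),
        cov_params=pd.DataFrame(cov, index=names, columns=names),
        vc=vc_rep,
        reml_loglik=float(loglik),
        converged=bool(res.success),
        df_resid=int(n - p),
        n_obs=int(n),
        treatment_cols=trt_cols,
        conc_cols=conc_cols,
        analyte_for_treatment=dict(mapping),
        time_cols=time_cols,
        interaction_cols=inter_cols,
    )


# ---------------------------------------------------------------------------
# Predictions and decisions


@dataclass(frozen=True)
class DeltaDeltaPrediction:
    """Placebo-corrected QTc effect at a reference concentration."""

    treatment: str
    c_ref: float
    estimate: float
    ci90: tuple[float, float]  # two-sided 90% CI
    side: str  # "upper" (test drug) or "lower" (positive control)

    @property
    def bound(self) -> float:
        """The one-sided 95% confidence limit used for the decision."""
        return self.ci90[1] if self.side == "upper" else self.ci90[0]


def predict_ddqtc(fit: CqtFit, treatment: str, c_ref: float,
                  side: str = "upper") -> DeltaDeltaPrediction:
    """ddQTc at ``c_ref``: treatment contrast plus concentration effect.

    The two-sided 90% CI uses a t quantile at the residual df; its upper
    (lower) limit is the one-sided 95% upper (lower) confidence bound.
    """
    if not fit.converged:
        raise RuntimeError("model fit did not converge")
    if treatment not in fit.treatment_cols:
        raise ValueError(f"unknown treatment {treatment!r}")
    if side not in ("upper", "lower"):
        raise ValueError("side must be 'upper' or 'lower'")
    c = np.zeros(len(fit.params))
    c[fit.params.index.get_loc(fit.treatment_cols[treatment])] = 1.0
    analyte = fit.analyte_for_treatment.get(treatment)
    if analyte is not None and analyte in fit.conc_cols:
        c[fit.params.index.get_loc(fit.conc_cols[analyte])] = c_ref
    est, se = fit.contrast(c)
    tcrit = stats.t.ppf(0.95, fit.df_resid)
    return DeltaDeltaPrediction(
        treatment=treatment, c_ref=float(c_ref), estimate=est,
        ci90=(est - tcrit * se, est + tcrit * se), side=side,
    )


def decision_rules(predictions: list[DeltaDeltaPrediction]) -> dict:
    """Apply the regulatory thresholds (strict inequalities).

    QT-negative: every test drug's upper one-sided 95% bound < 10 ms.
    Assay sensitivity: every positive control's lower bound > 5 ms.
    """
    test = [p for p in predictions if p.side == "upper"]
    control = [p for p in predictions if p.side == "lower"]
    out = {
        "per_treatment": {
            p.treatment: (
                p.bound < QT_NEGATIVE_THRESHOLD_MS if p.side == "upper"
                else p.bound > ASSAY_SENSITIVITY_THRESHOLD_MS
            )
            for p in predictions
        },
    }
    out["qt_negative"] = bool(test) and all(
        p.bound < QT_NEGATIVE_THRESHOLD_MS for p in test)
    out["assay_sensitivity"] = bool(control) and all(
        p.bound > ASSAY_SENSITIVITY_THRESHOLD_MS for p in control)
    return out


def timepoint_analysis(data: pd.DataFrame,
                       n_restarts: int = 3) -> pd.DataFrame:
    """By-time-point least-squares-mean differences from placebo.

    Fits the same model plus treatment-by-time interaction and returns one
    row per (treatment, time point): estimated dQTcP difference vs placebo
    with a two-sided 90% CI.
    """
    placebo = data.attrs.get("placebo", PLACEBO)
    shared = data.groupby("time_h")["treatment"].nunique()
    if (shared < 2).any():
        bad = shared.index[shared < 2].tolist()
        raise ValueError(f"time points with a single arm: {bad}")
    fit = fit_cqt(data, include_interaction=True,
                  include_concentration=False, n_restarts=n_restarts)
    tcrit = stats.t.ppf(0.95, fit.df_resid)
    rows = []
    times = sorted(pd.unique(data["time_h"]))
    for trt, trt_col in fit.treatment_cols.items():
        for tp in times:
            c = np.zeros(len(fit.params))
            c[fit.params.index.get_loc(trt_col)] = 1.0
            key = (trt, tp)
            if key in fit.interaction_cols:
                c[fit.params.index.get_loc(fit.interaction_cols[key])] = 1.0
            est, se = fit.contrast(c)
            rows.append({
                "treatment": trt, "time_h": tp, "estimate_ms": est,
                "se_ms": se, "lo90_ms": est - tcrit * se,
                "hi90_ms": est + tcrit * se,
            })
    return pd.DataFrame(rows)
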