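"""End-to-end orchestration: simulate -> correct -> NCA -> C-QTc -> safety.

One reproducible run driven by a single config (a YAML key-value file or
the equivalent dict): either input ECG/PK long tables or a simulation
section, the correction method and exponent source, model options, the
seed, and the output directory.  Every run writes delimited-text tables
shaped like a TQT study report (correction report, predicted ddQTcP table,
by-time-point table, PK summary, categorical counts) plus one structured
summary file with the headline decisions.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import categorical_safety as safety
from . import exposure_response as er
from . import nca as nca_mod
from . import qt_correction as qtc
from . import synthetic_trial as sim
from .qt_correction import FRIDERICIA_EXPONENT

__all__ = ["RunConfig", "run_pipeline", "load_table"]

logger = logging.getLogger("tqtpipe")


@dataclass
class RunConfig:
    """Everything one pipeline run depends on; no hidden defaults elsewhere."""

    seed: int = 0
    out_dir: str | None = None
    ecg_path: str | None = None
    pk_path: str | None = None
    simulate: dict[str, Any] | None = None
    correction_method: str = "qtcp"  # "qtcp" or "qtcf"
    exponent: float | str = "derived"  # fixed value or "derived"
    include_predose_drug_free: bool = True
    control_treatments: tuple[str, ...] = (sim.MOXIFLOXACIN,)
    model: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        has_files = self.ecg_path is not None and self.pk_path is not None
        if not has_files and self.simulate is None:
            # default: simulate under the standard study conditions
            self.simulate = {}
        if self.correction_method not in ("qtcp", "qtcf"):
            raise ValueError("correction_method must be 'qtcp' or 'qtcf'")

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "control_treatments" in d:
            d["control_treatments"] = tuple(d["control_treatments"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def load_table(path) -> pd.DataFrame:
    """Read a pipeline-format delimited table (``#`` lines are comments)."""
    return pd.read_csv(path, comment="#")


def _write(df: pd.DataFrame, path: pathlib.Path, seed: int) -> None:
    with open(path, "w") as fh:
        fh.write(f"# tqtpipe {__version__} seed={seed}\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def _simulated_trial(cfg: RunConfig) -> sim.SimulatedTrial:
    opts = dict(cfg.simulate or {})
    design_keys = {f.name for f in dataclasses.fields(sim.TrialDesign)}
    design_opts = {k: opts.pop(k) for k in list(opts) if k in design_keys}
    design = sim.TrialDesign(**{
        k: tuple(v) if isinstance(v, list) else v
        for k, v in design_opts.items()
    })
    pk_over = opts.pop("pk", None)
    if pk_over is None:
        return sim.simulate_default_trial(cfg.seed, design=design, **opts)
    pk_params = sim.default_pk_params()
    for trt, fields in pk_over.items():
        pk_params[trt] = dataclasses.replace(pk_params[trt], **fields)
    qt_params = sim.default_qt_params(**opts)
    return sim.simulate_trial(design, pk_params, qt_params, seed=cfg.seed)


def run_pipeline(config: RunConfig | dict) -> dict[str, Any]:
    """Run the full analysis chain; returns the report bundle as a dict.

    When ``config.out_dir`` is set, all tables and the structured summary
    are also written there.  Any stage failure raises with a stage label.
    """
    cfg = config if isinstance(config, RunConfig) else RunConfig.from_dict(config)
    bundle: dict[str, Any] = {}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as e:  # re-raise with the failing stage labelled
                raise RuntimeError(f"pipeline stage '{name}' failed: {e}") from e
        return wrap

    # --- inputs -----------------------------------------------------------
    if cfg.ecg_path is not None and cfg.pk_path is not None:
        ecg = stage("load")(lambda: load_table(cfg.ecg_path))
        pk = stage("load")(lambda: load_table(cfg.pk_path))
    else:
        trial = stage("simulate")(lambda: _simulated_trial(cfg))
        ecg, pk = trial.ecg, trial.pk
        bundle["trial"] = trial

    # --- QT correction ----------------------------------------------------
    agg = stage("aggregate")(lambda: qtc.aggregate_triplicates(ecg))
    fixed = None if cfg.exponent == "derived" else float(cfg.exponent)
    if fixed is not None:
        logger.info("correction derivation skipped: fixed exponent %.4f", fixed)
    correction = stage("correction")(lambda: qtc.fit_correction(
        agg, include_predose=cfg.include_predose_drug_free,
        fixed_exponent=fixed))
    exponent = (FRIDERICIA_EXPONENT if cfg.correction_method == "qtcf"
                else correction.exponent)
    series = stage("correction")(lambda: qtc.baseline_and_delta(agg, exponent))

    # --- NCA --------------------------------------------------------------
    nca_table = stage("nca")(lambda: nca_mod.run_nca(pk))
    pk_summary = stage("nca")(lambda: nca_mod.summarize_nca(nca_table))

    # --- exposure-response -------------------------------------------------
    dataset = stage("cqt")(lambda: er.build_cqt_dataset(series, pk))
    fit = stage("cqt")(lambda: er.fit_cqt(dataset, **cfg.model))
    mapping = fit.analyte_for_treatment
    predictions = []
    for trt in fit.treatment_cols:
        analyte = mapping.get(trt)
        sel = (nca_table["treatment"] == trt) & (
            nca_table["analyte"] == analyte)
        cmax = nca_table.loc[sel, "cmax"].dropna()
        if analyte is None or cmax.empty:
            continue
        gm_cmax = nca_mod.geometric_summary(cmax).geometric_mean
        side = "lower" if trt in cfg.control_treatments else "upper"
        predictions.append(stage("cqt")(
            lambda t=trt, c=gm_cmax, s=side: er.predict_ddqtc(fit, t, c, s)))
    decisions = er.decision_rules(predictions)
    ddqtc_table = pd.DataFrame([
        {"treatment": p.treatment, "gm_cmax": p.c_ref,
         "lsm_ms": p.estimate, "lo90_ms": p.ci90[0], "hi90_ms": p.ci90[1],
         "one_sided_95_bound": p.bound, "side": p.side}
        for p in predictions
    ])
    timepoints = stage("cqt")(lambda: er.timepoint_analysis(dataset))

    # --- categorical safety -------------------------------------------------
    flags = stage("safety")(lambda: safety.flag_observations(ecg))
    counts = stage("safety")(lambda: safety.count_table(flags))

    summary = {
        "tqtpipe_version": __version__,
        "seed": cfg.seed,
        "correction_method": cfg.correction_method,
        "qtcp_exponent": round(correction.exponent, 6),
        "adequacy_slope": float(f"{correction.adequacy_slope:.6g}"),
        "adequacy_adequate": bool(correction.adequate),
        "model_converged": bool(fit.converged),
        "variance_components": {k: float(f"{v:.6g}")
                                for k, v in fit.vc.items()},
        "negative_qt_signal": decisions["qt_negative"],
        "assay_sensitivity_confirmed": decisions["assay_sensitivity"],
        "ddqtcp_at_gm_cmax": {
            p.treatment: {
                "gm_cmax": float(f"{p.c_ref:.6g}"),
                "estimate_ms": float(f"{p.estimate:.4f}"),
                "lo90_ms": float(f"{p.ci90[0]:.4f}"),
                "hi90_ms": float(f"{p.ci90[1]:.4f}"),
                "side": p.side,
            } for p in predictions
        },
    }

    bundle.update({
        "config": cfg, "aggregated_ecg": agg, "correction": correction,
        "qtc_series": series, "nca": nca_table, "pk_summary": pk_summary,
        "cqt_dataset": dataset, "cqt_fit": fit, "predictions": predictions,
        "ddqtcp_table": ddqtc_table, "timepoint_table": timepoints,
        "decisions": decisions, "safety_counts": counts, "summary": summary,
    })

    if cfg.out_dir is not None:
        out = pathlib.Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write(series, out / "qtc_series.csv", cfg.seed)
        _write(nca_table, out / "nca_subject.csv", cfg.seed)
        _write(pk_summary, out / "pk_summary.csv", cfg.seed)
        _write(ddqtc_table, out / "ddqtcp_at_cmax.csv", cfg.seed)
        _write(timepoints, out / "ddqtcp_by_timepoint.csv", cfg.seed)
        _write(counts, out / "safety_counts.csv", cfg.seed)
        correction_report = {
            "exponent": correction.exponent,
            "exponent_se": correction.exponent_se,
            "adequacy_slope": correction.adequacy_slope,
            "adequacy_slope_ci95": list(correction.adequacy_slope_ci95),
            "adequate": correction.adequate,
            "n_points": correction.n_points,
        }
        with open(out / "correction_report.json", "w") as fh:
            json.dump(correction_report, fh, indent=2, sort_keys=True,
                      allow_nan=True)
            fh.write("\n")
        with open(out / "summary.yaml", "w") as fh:
            yaml.safe_dump(summary, fh, sort_keys=True)
        with open(out / "run.log", "w") as fh:
            fh.write(f"tqtpipe {__version__}\nseed {cfg.seed}\n"
                     f"numpy {np.__version__}\npandas {pd.__version__}\n")
    return bundle
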