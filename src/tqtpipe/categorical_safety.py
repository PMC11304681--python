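"""Descriptive categorical ECG flagging and count tables.

Flags use strict comparisons on the conventional thresholds: heart rate
> 100 bpm, PR interval > 220 ms, QRS duration > 110 ms.  T- and U-wave
morphology abnormalities are carried through as boolean inputs, not
derived here.  Missing interval values leave the flag undefined and are
excluded from that flag's denominator.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = ["FLAG_THRESHOLDS", "flag_observations", "count_table"]

logger = logging.getLogger("tqtpipe")

FLAG_THRESHOLDS = {"hr_gt_100": ("hr_bpm", 100.0),
                   "pr_gt_220": ("pr_ms", 220.0),
                   "qrs_gt_110": ("qrs_ms", 110.0)}
_MORPHOLOGY = {"abnormal_t_wave": "t_wave_abnormal",
               "abnormal_u_wave": "u_wave_abnormal"}


def flag_observations(obs: pd.DataFrame,
                      hr_consistency_bpm: float = 2.0) -> pd.DataFrame:
    """Per-observation boolean flags (nullable: missing input -> missing flag).

    Heart rate is taken from the recorded HR field, not recomputed from RR;
    recorded HR deviating from 60000/RR by more than ``hr_consistency_bpm``
    is logged as a warning.
    """
    out = obs[["subject", "period", "treatment", "time_h"]].copy()
    if "replicate" in obs:
        out["replicate"] = obs["replicate"]
    if {"hr_bpm", "rr_ms"} <= set(obs.columns):
        implied = 60000.0 / obs["rr_ms"]
        n_bad = int((np.abs(obs["hr_bpm"] - implied) > hr_consistency_bpm)
                    .sum())
        if n_bad:
            logger.warning(
                "%d observations with recorded HR inconsistent with RR "
                "(>%g bpm apart)", n_bad, hr_consistency_bpm)
    for flag, (col, thr) in FLAG_THRESHOLDS.items():
        vals = pd.to_numeric(obs[col], errors="coerce") if col in obs else (
            pd.Series(np.nan, index=obs.index))
        out[flag] = pd.array(vals > thr, dtype="boolean")
        out.loc[vals.isna(), flag] = pd.NA
    for flag, col in _MORPHOLOGY.items():
        if col in obs:
            out[flag] = pd.array(obs[col], dtype="boolean")
        else:
            out[flag] = pd.NA
    return out


def count_table(flags: pd.DataFrame,
                by: tuple[str, ...] = ("treatment", "time_h")) -> pd.DataFrame:
    """Counts and denominators per cell for each flag.

    The denominator is the number of non-missing flag values in the cell;
    missing observations count toward neither.
    """
    flag_cols = [c for c in flags.columns
                 if c in FLAG_THRESHOLDS or c in _MORPHOLOGY]
    rows = []
    for key, grp in flags.groupby(list(by), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        row = dict(zip(by, key))
        for f in flag_cols:
            col = grp[f]
            row[f"{f}_count"] = int(col.sum(skipna=True))
            row[f"{f}_denom"] = int(col.notna().sum())
        rows.append(row)
    return pd.DataFrame(rows)
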