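"""Synthetic nested-crossover TQT trial generator.

Emulates the structure of a single-dose thorough QT study of islatravir:
four treatment sequences randomized 2:2:1:4 over two periods, triplicate
12-lead ECG extractions at three pre-dose and nine post-dose time points,
PK sampling to 168 h, one-compartment oral absorption PK, and a linear
concentration-QTc effect on top of a power-law QT/RR relationship.

The generator's defaults are calibrated so that a 240-mg islatravir dose
reproduces the published geometric-mean exposure scale (Cmax ~3.8 uM,
AUC0-inf ~30 h*uM, Tmax ~1 h) and a 400-mg moxifloxacin dose the expected
~14 ms QTc prolongation at its geometric-mean Cmax (~1,830 ng/mL).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PLACEBO",
    "ISLATRAVIR_LOW",
    "ISLATRAVIR_HIGH",
    "MOXIFLOXACIN",
    "SEQUENCE_TREATMENTS",
    "TrialDesign",
    "PkParams",
    "MetaboliteSpec",
    "QtModelParams",
    "SimulatedTrial",
    "randomize",
    "pk_profile",
    "simulate_trial",
    "default_design",
    "default_pk_params",
    "default_qt_params",
    "simulate_default_trial",
    "write_trial_tables",
]

# ---------------------------------------------------------------------------
# Treatments and design constants

PLACEBO = "placebo"
ISLATRAVIR_LOW = "islatravir_0.75mg"
ISLATRAVIR_HIGH = "islatravir_240mg"
MOXIFLOXACIN = "moxifloxacin_400mg"

#: Treatment administered in (period 1, period 2) for each sequence.
#: Sequences 1/2 are the moxifloxacin/placebo crossover pair, sequence 3 is
#: placebo in both periods, and sequence 4 doses islatravir 0.75 mg first and
#: the supratherapeutic 240 mg dose second (after the washout).
SEQUENCE_TREATMENTS: dict[int, tuple[str, str]] = {
    1: (MOXIFLOXACIN, PLACEBO),
    2: (PLACEBO, MOXIFLOXACIN),
    3: (PLACEBO, PLACEBO),
    4: (ISLATRAVIR_LOW, ISLATRAVIR_HIGH),
}

ISLATRAVIR_MW = 293.26  # g/mol, 4'-ethynyl-2-fluoro-2'-deoxyadenosine
M4_MW = 294.24  # g/mol, 4'-ethynyl-2-fluoro-2'-deoxyinosine

#: Assay lower limits of quantification, in each analyte's reporting unit.
ISLATRAVIR_LLOQ_UM = 0.020 / ISLATRAVIR_MW  # 20.0 pg/mL -> ~6.8e-5 uM
M4_LLOQ_UM = 0.5 / M4_MW  # 0.5 ng/mL -> ~1.7e-3 uM
MOXIFLOXACIN_LLOQ_NGML = 10.0

# RR truncation keeps simulated heart rate within 40-100 bpm, the healthy
# resting range, so descriptive HR>100 flags stay empty by construction.
RR_TRUNCATION_S = (0.6, 1.5)


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class TrialDesign:
    """Schedule and allocation structure of the nested-crossover trial."""

    n_per_sequence: tuple[int, int, int, int] = (14, 14, 7, 28)
    ecg_times_h: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 8.0, 12.0, 24.0)
    predose_ecg_times_h: tuple[float, ...] = (-1 / 3, -1 / 6, -1 / 12)
    pk_times_h: tuple[float, ...] = (
        0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 8.0, 12.0, 24.0, 96.0, 168.0,
    )
    n_replicates: int = 3
    washout_days: int = 7

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_per_sequence):
            raise ValueError("sequence counts must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("replicate count must be >= 1")
        for name in ("ecg_times_h", "predose_ecg_times_h", "pk_times_h"):
            t = np.asarray(getattr(self, name), dtype=float)
            if t.size and np.any(np.diff(t) <= 0):
                raise ValueError(f"{name} must be strictly increasing")
        if any(t >= 0 for t in self.predose_ecg_times_h):
            raise ValueError("pre-dose ECG times must be negative")

    @property
    def n_total(self) -> int:
        return int(sum(self.n_per_sequence))

    @property
    def all_ecg_times_h(self) -> tuple[float, ...]:
        return tuple(self.predose_ecg_times_h) + tuple(self.ecg_times_h)


@dataclass(frozen=True)
class MetaboliteSpec:
    """A metabolite generated as a fixed fraction of the parent concentration."""

    name: str
    fraction: float
    lloq: float
    mol_weight: float | None = None


@dataclass(frozen=True)
class PkParams:
    """One-compartment oral absorption PK for one analyte.

    Concentrations are reported in uM when ``mol_weight`` is given
    (dose mg / V L -> mg/L -> uM), otherwise in ng/mL.
    """

    analyte: str
    dose: float  # mg
    ka: float  # 1/h
    ke: float  # 1/h
    v_over_f: float  # L
    mol_weight: float | None = None
    lloq: float = 0.0  # in reporting units
    between_subject_cv: float = 0.35  # log-normal CV on CL and V
    residual_cv: float = 0.10  # proportional assay error
    metabolite: MetaboliteSpec | None = None

    def __post_init__(self) -> None:
        if not (self.ka > 0 and self.ke > 0):
            raise ValueError("ka and ke must be positive")
        if self.v_over_f <= 0:
            raise ValueError("V/F must be positive")
        if self.dose < 0:
            raise ValueError("dose must be >= 0")
        if self.between_subject_cv < 0 or self.residual_cv < 0:
            raise ValueError("CVs must be >= 0")

    @property
    def conc_unit(self) -> str:
        return "uM" if self.mol_weight is not None else "ng/mL"

    def _scale(self) -> float:
        # mg/L -> uM (x1000/MW) or mg/L -> ng/mL (x1e6/1e3)
        if self.mol_weight is not None:
            return 1000.0 / self.mol_weight
        return 1000.0


@dataclass(frozen=True)
class QtModelParams:
    """Data-generating QT model: power-law QT/RR plus additive effects.

    QT(subject, period, time, replicate) =
        qt_pop_mean * RR_s**alpha_true
        + subject effect + period effect
        + circadian_amplitude * cos(2*pi*t/24)
        + conc_slope * C(t) + residual.

    ``conc_slope`` is in ms per concentration unit of the arm's analyte
    (ms/uM for islatravir, ms/(ng/mL) for moxifloxacin).
    """

    qt_pop_mean: float = 400.0  # ms at RR = 1 s
    alpha_true: float = 0.3754
    conc_slope: float = 0.0
    between_subject_sd: float = 12.0  # ms
    between_period_sd: float = 5.0  # ms
    residual_sd: float = 6.0  # ms, per replicate
    circadian_amplitude: float = 3.0  # ms
    rr_mean_s: float = 0.9
    rr_sd_s: float = 0.09
    t_wave_abnormal_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("between_subject_sd", "between_period_sd", "residual_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.alpha_true <= 1.0):
            raise ValueError("alpha_true must be in [0, 1]")
        if self.rr_mean_s <= 0:
            raise ValueError("rr_mean_s must be positive")

    def physiology_key(self) -> tuple:
        """Treatment-independent fields; must agree across arms of one trial."""
        return (
            self.qt_pop_mean, self.alpha_true, self.between_subject_sd,
            self.between_period_sd, self.residual_sd, self.circadian_amplitude,
            self.rr_mean_s, self.rr_sd_s,
        )


@dataclass
class SimulatedTrial:
    """A complete simulated trial: allocation, ECG and PK long tables, truth."""

    assignments: pd.DataFrame  # subject, sequence, period, treatment
    ecg: pd.DataFrame
    pk: pd.DataFrame
    design: TrialDesign
    pk_params: dict[str, PkParams]
    qt_params: dict[str, QtModelParams]
    subject_effects: pd.DataFrame  # subject, effect_ms (realized draws)
    seed: int


# ---------------------------------------------------------------------------
# Operations


def randomize(
    n_total: int,
    ratios: Sequence[int] = (2, 2, 1, 4),
    seed: int = 0,
) -> pd.DataFrame:
    """Allocate ``n_total`` subjects to sequences in the given ratios.

    Whole blocks are filled first; any remainder is allocated by a seeded
    draw with probabilities proportional to the ratios.  The subject-to-
    sequence permutation is a deterministic function of the seed.

    Returns a DataFrame with columns ``subject`` (1..n) and ``sequence``.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    ratios = tuple(int(r) for r in ratios)
    if any(r < 0 for r in ratios) or sum(ratios) == 0:
        raise ValueError("ratios must be non-negative with a positive sum")
    rng = np.random.default_rng(seed)
    block = sum(ratios)
    n_blocks, remainder = divmod(n_total, block)
    counts = np.array(ratios, dtype=int) * n_blocks
    if remainder:
        p = np.array(ratios, dtype=float) / block
        extra = rng.choice(len(ratios), size=remainder, p=p)
        for s in extra:
            counts[s] += 1
    labels = np.repeat(np.arange(1, len(ratios) + 1), counts)
    labels = rng.permutation(labels)
    return pd.DataFrame({"subject": np.arange(1, n_total + 1), "sequence": labels})


def pk_profile(params: PkParams, times_h: Sequence[float]) -> np.ndarray:
    """Noise-free one-compartment oral concentration-time profile.

    C(t) = (F*D/V) * ka/(ka-ke) * (exp(-ke*t) - exp(-ka*t)), converted to the
    analyte's reporting unit.  A coincident ka == ke is a removable
    singularity and is handled by an epsilon perturbation of ke.
    """
    t = np.asarray(times_h, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    ka, ke = params.ka, params.ke
    if math.isclose(ka, ke, rel_tol=1e-9, abs_tol=0.0):
        ke = ke * (1.0 - 1e-8)
    amp = (params.dose / params.v_over_f) * ka / (ka - ke)
    conc_mg_l = amp * (np.exp(-ke * t) - np.exp(-ka * t))
    return conc_mg_l * params._scale()


def _individual_pk(params: PkParams, eta_cl: float, eta_v: float) -> PkParams:
    """Apply log-normal between-subject variability to CL and V."""
    cl = params.ke * params.v_over_f * math.exp(eta_cl)
    v = params.v_over_f * math.exp(eta_v)
    return replace(params, ke=cl / v, v_over_f=v, between_subject_cv=0.0)


def _common_physiology(qt: Mapping[str, QtModelParams]) -> QtModelParams:
    keys = {p.physiology_key() for p in qt.values()}
    if len(keys) != 1:
        raise ValueError(
            "treatment-independent QT physiology (population mean, alpha, "
            "variances, circadian, RR distribution) must agree across arms"
        )
    return next(iter(qt.values()))


def simulate_trial(
    design: TrialDesign,
    pk: Mapping[str, PkParams],
    qt: Mapping[str, QtModelParams],
    seed: int = 0,
) -> SimulatedTrial:
    """Simulate one complete trial.

    ``pk`` maps each active treatment to its analyte's PK parameters
    (placebo needs no entry; its concentrations are identically zero).
    ``qt`` maps every treatment used by the design to its QT model; only
    ``conc_slope`` and ``t_wave_abnormal_rate`` may differ between arms.
    """
    used_treatments = sorted(
        {t for s, n in zip(SEQUENCE_TREATMENTS, design.n_per_sequence)
         for t in SEQUENCE_TREATMENTS[s] if n > 0}
    )
    for trt in used_treatments:
        if trt not in qt:
            raise ValueError(f"missing QT model parameters for treatment {trt!r}")
        if trt != PLACEBO and trt not in pk:
            raise ValueError(f"missing PK parameters for treatment {trt!r}")
    phys = _common_physiology({t: qt[t] for t in used_treatments})
    if not design.all_ecg_times_h or not design.pk_times_h:
        raise ValueError("ECG and PK schedules must be non-empty")

    rng = np.random.default_rng(seed)
    # the design fixes the per-sequence counts; the permutation is seeded
    labels = np.repeat(np.arange(1, 5), design.n_per_sequence)
    labels = rng.permutation(labels)
    assignments = pd.DataFrame(
        {"subject": np.arange(1, design.n_total + 1), "sequence": labels}
    )
    n = design.n_total
    n_periods = 2
    times = np.asarray(design.all_ecg_times_h, dtype=float)
    n_times = times.size
    n_rep = design.n_replicates

    seq = assignments["sequence"].to_numpy()
    treatments = np.empty((n, n_periods), dtype=object)
    for i, s in enumerate(seq):
        treatments[i] = SEQUENCE_TREATMENTS[int(s)]

    # --- random draws, fixed order for reproducibility -------------------
    b_subj = rng.normal(0.0, phys.between_subject_sd, size=n)
    b_per = rng.normal(0.0, phys.between_period_sd, size=(n, n_periods))
    sigma_cv = {
        trt: math.sqrt(math.log(1.0 + p.between_subject_cv**2))
        for trt, p in pk.items()
    }
    # PK variability is a subject property, shared across periods
    eta_cl = rng.normal(0.0, 1.0, size=n)
    eta_v = rng.normal(0.0, 1.0, size=n)
    ln_rr_sigma = phys.rr_sd_s / phys.rr_mean_s
    rr_s = np.exp(rng.normal(math.log(phys.rr_mean_s), ln_rr_sigma,
                             size=(n, n_periods, n_times)))
    rr_s = np.clip(rr_s, *RR_TRUNCATION_S)
    resid = rng.normal(0.0, phys.residual_sd, size=(n, n_periods, n_times, n_rep))
    pr_subj = np.clip(rng.normal(160.0, 12.0, size=n), 120.0, 205.0)
    qrs_subj = np.clip(rng.normal(95.0, 5.0, size=n), 80.0, 105.0)
    pr_noise = rng.normal(0.0, 3.0, size=(n, n_periods, n_times, n_rep))
    qrs_noise = rng.normal(0.0, 2.0, size=(n, n_periods, n_times, n_rep))
    t_wave_u = rng.random(size=(n, n_periods, n_times, n_rep))

    # --- concentrations at ECG times (true, for the QT effect) -----------
    conc_ecg = np.zeros((n, n_periods, n_times))
    post_mask = times >= 0
    indiv_params: dict[tuple[int, int], PkParams] = {}
    for i in range(n):
        for p in range(n_periods):
            trt = treatments[i, p]
            if trt == PLACEBO:
                continue
            base = pk[trt]
            s = sigma_cv[trt]
            ip = _individual_pk(base, eta_cl[i] * s, eta_v[i] * s)
            indiv_params[(i, p)] = ip
            conc_ecg[i, p, post_mask] = pk_profile(ip, times[post_mask])

    slope = np.zeros((n, n_periods))
    t_rate = np.zeros((n, n_periods))
    for i in range(n):
        for p in range(n_periods):
            slope[i, p] = qt[treatments[i, p]].conc_slope
            t_rate[i, p] = qt[treatments[i, p]].t_wave_abnormal_rate

    circadian = phys.circadian_amplitude * np.cos(2.0 * math.pi * times / 24.0)
    qt_mean = (
        phys.qt_pop_mean * rr_s**phys.alpha_true
        + b_subj[:, None, None]
        + b_per[:, :, None]
        + circadian[None, None, :]
        + slope[:, :, None] * conc_ecg
    )
    qt_ms = qt_mean[..., None] + resid  # (n, periods, times, reps)
    rr_ms = rr_s * 1000.0

    # --- assemble ECG long table -----------------------------------------
    idx_s, idx_p, idx_t, idx_r = np.meshgrid(
        np.arange(n), np.arange(n_periods), np.arange(n_times), np.arange(n_rep),
        indexing="ij",
    )
    flat = lambda a: a.reshape(-1)
    pr_ms = np.clip(pr_subj[:, None, None, None] + pr_noise, 100.0, 215.0)
    qrs_ms = np.clip(qrs_subj[:, None, None, None] + qrs_noise, 70.0, 108.0)
    ecg = pd.DataFrame({
        "subject": flat(idx_s) + 1,
        "sequence": seq[flat(idx_s)],
        "period": flat(idx_p) + 1,
        "treatment": treatments[flat(idx_s), flat(idx_p)],
        "time_h": times[flat(idx_t)],
        "replicate": flat(idx_r) + 1,
        "qt_ms": flat(qt_ms),
        "rr_ms": rr_ms[flat(idx_s), flat(idx_p), flat(idx_t)],
        "pr_ms": flat(pr_ms),
        "qrs_ms": flat(qrs_ms),
        "t_wave_abnormal": flat(t_wave_u) < t_rate[flat(idx_s), flat(idx_p)],
        "u_wave_abnormal": False,
    })
    ecg["hr_bpm"] = 60000.0 / ecg["rr_ms"]
    ecg = ecg[[
        "subject", "sequence", "period", "treatment", "time_h", "replicate",
        "qt_ms", "rr_ms", "pr_ms", "qrs_ms", "hr_bpm",
        "t_wave_abnormal", "u_wave_abnormal",
    ]]

    # --- PK long table -----------------------------------------------------
    pk_times = np.concatenate([[0.0], np.asarray(design.pk_times_h, dtype=float)])
    pk_rows: list[pd.DataFrame] = []
    active = sorted(indiv_params)  # deterministic (subject, period) order
    for (i, p) in active:
        ip = indiv_params[(i, p)]
        true_parent = pk_profile(ip, pk_times)
        analytes = [(ip.analyte, true_parent, ip.lloq, ip.conc_unit)]
        if ip.metabolite is not None:
            met = ip.metabolite
            analytes.append((met.name, true_parent * met.fraction, met.lloq,
                             ip.conc_unit))
        for name, true_c, lloq, unit in analytes:
            noise = rng.lognormal(
                mean=-0.5 * math.log(1.0 + ip.residual_cv**2),
                sigma=math.sqrt(math.log(1.0 + ip.residual_cv**2)),
                size=pk_times.size,
            )
            measured = true_c * noise
            blq = measured < lloq
            pk_rows.append(pd.DataFrame({
                "subject": i + 1,
                "sequence": int(seq[i]),
                "period": p + 1,
                "treatment": treatments[i, p],
                "analyte": name,
                "dose_mg": ip.dose,
                "time_h": pk_times,
                "conc": np.where(blq, np.nan, measured),
                "conc_unit": unit,
                "lloq": lloq,
                "blq": blq,
            }))
    pk_table = (
        pd.concat(pk_rows, ignore_index=True)
        if pk_rows
        else pd.DataFrame(columns=[
            "subject", "sequence", "period", "treatment", "analyte", "dose_mg",
            "time_h", "conc", "conc_unit", "lloq", "blq",
        ])
    )

    assign_long = pd.DataFrame({
        "subject": np.repeat(np.arange(1, n + 1), n_periods),
        "sequence": np.repeat(seq, n_periods),
        "period": np.tile([1, 2], n),
        "treatment": treatments.reshape(-1),
    })
    subject_effects = pd.DataFrame(
        {"subject": np.arange(1, n + 1), "effect_ms": b_subj}
    )
    return SimulatedTrial(
        assignments=assign_long,
        ecg=ecg,
        pk=pk_table,
        design=design,
        pk_params=dict(pk),
        qt_params=dict(qt),
        subject_effects=subject_effects,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Study-condition defaults


def default_design() -> TrialDesign:
    return TrialDesign()


def default_pk_params() -> dict[str, PkParams]:
    """PK parameter sets calibrated to the study's exposure scale.

    Islatravir: ka 3.2/h, ke 0.15/h, V/F 184 L give, for 240 mg, Cmax ~3.8 uM
    at Tmax ~1 h and AUC0-inf ~30 h*uM.  The 0.75-mg arm shares the kinetics
    (dose-linear).  M4 is a fixed 0.29 fraction of parent with its own LLOQ,
    so the 0.75-mg M4 profile is quantifiable only through ~4 h.
    Moxifloxacin: ka 1.4/h, ke 0.058/h, V/F 191 L give Cmax ~1,830 ng/mL.
    """
    m4 = MetaboliteSpec(name="M4", fraction=0.29, lloq=M4_LLOQ_UM,
                        mol_weight=M4_MW)
    isl = dict(ka=3.2, ke=0.15, v_over_f=184.0, mol_weight=ISLATRAVIR_MW,
               lloq=ISLATRAVIR_LLOQ_UM, metabolite=m4)
    return {
        ISLATRAVIR_LOW: PkParams(analyte="islatravir", dose=0.75, **isl),
        ISLATRAVIR_HIGH: PkParams(analyte="islatravir", dose=240.0, **isl),
        MOXIFLOXACIN: PkParams(
            analyte="moxifloxacin", dose=400.0, ka=1.4, ke=0.058,
            v_over_f=191.0, mol_weight=None, lloq=MOXIFLOXACIN_LLOQ_NGML,
        ),
    }


#: Typical moxifloxacin geometric-mean Cmax (ng/mL) used to set the default
#: concentration-QTc slope so the positive-control effect is ~14 ms at Cmax.
MOXIFLOXACIN_TYPICAL_GM_CMAX = 1830.0


def default_qt_params(
    islatravir_slope: float = 0.0,
    moxifloxacin_effect_at_cmax: float = 14.0,
    alpha_true: float = 0.3754,
    **overrides,
) -> dict[str, QtModelParams]:
    base = QtModelParams(alpha_true=alpha_true, **overrides)
    moxi_slope = moxifloxacin_effect_at_cmax / MOXIFLOXACIN_TYPICAL_GM_CMAX
    return {
        PLACEBO: base,
        ISLATRAVIR_LOW: replace(base, conc_slope=islatravir_slope),
        ISLATRAVIR_HIGH: replace(base, conc_slope=islatravir_slope,
                                 t_wave_abnormal_rate=0.002),
        MOXIFLOXACIN: replace(base, conc_slope=moxi_slope),
    }


def simulate_default_trial(
    seed: int,
    islatravir_slope: float = 0.0,
    moxifloxacin_effect_at_cmax: float = 14.0,
    alpha_true: float = 0.3754,
    design: TrialDesign | None = None,
    **qt_overrides,
) -> SimulatedTrial:
    """One call producing a trial under the default study conditions."""
    return simulate_trial(
        design or default_design(),
        default_pk_params(),
        default_qt_params(
            islatravir_slope=islatravir_slope,
            moxifloxacin_effect_at_cmax=moxifloxacin_effect_at_cmax,
            alpha_true=alpha_true,
            **qt_overrides,
        ),
        seed=seed,
    )


def write_trial_tables(trial: SimulatedTrial, outdir, seed_note: bool = True):
    """Write the ECG and PK long tables as CSV; returns the two paths."""
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in (("ecg.csv", trial.ecg), ("pk.csv", trial.pk)):
        path = outdir / name
        with open(path, "w") as fh:
            if seed_note:
                fh.write(f"# seed={trial.seed}\n")
            df.to_csv(fh, index=False, float_format="%.10g")
        paths.append(path)
    return tuple(paths)
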