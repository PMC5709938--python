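"""Simulated study datasets in NONMEM-style long format.

The base study design mirrors a small-N single-dose PK study: 6 subjects,
one oral dose each, 8 post-dose sampling times within 24 h, lognormal
inter-individual variability (IIV) on Vd/F and CL/F at CV levels
{5, 10, 20, 30, 50, 80}%, proportional residual error, and 100 simulation
replicates per IIV level (600 datasets in total).

IIV magnitude is specified as a coefficient of variation of the lognormal
individual parameters and converted to the log-scale variance via

    CV(%) = sqrt(exp(omega2) - 1) * 100  <=>  omega2 = log(1 + (CV/100)**2).

Datasets are plain pandas DataFrames with the NONMEM-style columns
ID, TIME, AMT, EVID, MDV, DV: one dosing record per subject (EVID=1, MDV=1,
DV empty) at t=0 and one observation record (EVID=0, MDV=0, AMT empty) per
sampling time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import PopulationParameters, concentration_curve

__all__ = [
    "StudyDesign",
    "PKDataset",
    "cv_to_omega2",
    "omega2_to_cv",
    "simulate_dataset",
    "generate_study",
    "write_dataset",
    "read_dataset",
    "write_study",
    "read_study",
    "base_truth",
    "base_design",
    "theo_truth",
    "theo_design",
    "load_config",
    "save_config",
]

#: default sampling schedule (h): 8 points within 24 h post dose
DEFAULT_TIMES = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0)
#: default single oral dose (mg)
DEFAULT_DOSE = 320.0
#: IIV levels of the simulation sweep, as CV%
DEFAULT_IIV_LEVELS = (5.0, 10.0, 20.0, 30.0, 50.0, 80.0)

COLUMNS = ["ID", "TIME", "AMT", "EVID", "MDV", "DV"]


def cv_to_omega2(cv_percent: float) -> float:
    """Log-scale variance omega2 for a lognormal CV given in percent."""
    if cv_percent < 0:
        raise ValueError("cv_percent must be non-negative")
    return math.log1p((cv_percent / 100.0) ** 2)


def omega2_to_cv(omega2: float) -> float:
    """Lognormal CV% for a log-scale variance: sqrt(exp(omega2) - 1) * 100."""
    if omega2 < 0:
        raise ValueError("omega2 must be non-negative")
    return math.sqrt(math.expm1(omega2)) * 100.0


@dataclass(frozen=True)
class StudyDesign:
    """Design of the simulation study."""

    n_subjects: int = 6
    dose: float = DEFAULT_DOSE
    sampling_times: tuple = DEFAULT_TIMES
    iiv_levels: tuple = DEFAULT_IIV_LEVELS
    n_replicates: int = 100
    seed: int = 20260926

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        t = np.asarray(self.sampling_times, dtype=float)
        if t.size < 1 or np.any(np.diff(t) <= 0) or np.any(t <= 0):
            raise ValueError("sampling_times must be strictly increasing and > 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass(frozen=True)
class PKDataset:
    """One simulated dataset plus its generating truth and provenance."""

    records: pd.DataFrame
    truth: PopulationParameters
    replicate_id: int = 0
    iiv_level: float | None = None
    label: str = "simulated"

    @property
    def observations(self) -> pd.DataFrame:
        return self.records[self.records["EVID"] == 0]

    @property
    def n_subjects(self) -> int:
        return self.records["ID"].nunique()


def _subject_rng_effects(truth: PopulationParameters, n_subjects: int, rng):
    """Draw (eta_ka, eta_v, eta_cl) rows; inactive effects are exactly 0."""
    etas = np.zeros((n_subjects, 3))
    for k, om2 in enumerate(
        (truth.omega2_ka, truth.omega2_v, truth.omega2_cl)
    ):
        if om2 > 0:
            etas[:, k] = rng.normal(0.0, math.sqrt(om2), size=n_subjects)
    return etas


def simulate_dataset(
    design: StudyDesign,
    truth: PopulationParameters,
    replicate_id: int = 0,
    rng: np.random.Generator | None = None,
    iiv_level: float | None = None,
) -> PKDataset:
    """Simulate one replicate dataset from the hierarchical model.

    Per subject, eta ~ N(0, omega2) independently for each parameter with
    IIV; predictions come from the closed-form concentration curve; DV =
    C_pred * (1 + eps) with eps ~ N(0, sigma2) i.i.d.  Negative DVs (possible
    under proportional normal error) are kept as-is — truncation would bias
    the generative model.
    """
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence(
                (design.seed, 0 if iiv_level is None else int(iiv_level * 100), replicate_id)
            )
        )
    times = np.asarray(design.sampling_times, dtype=float)
    n, nt = design.n_subjects, times.size
    etas = _subject_rng_effects(truth, n, rng)
    ka_i = truth.ka * np.exp(etas[:, 0:1])
    v_i = truth.v_f * np.exp(etas[:, 1:2])
    cl_i = truth.cl_f * np.exp(etas[:, 2:3])
    c_pred = concentration_curve(ka_i, v_i, cl_i, design.dose, times)
    eps = rng.normal(0.0, math.sqrt(truth.sigma2), size=(n, nt)) if truth.sigma2 > 0 else 0.0
    dv = c_pred * (1.0 + eps)

    rows = []
    for i in range(n):
        rows.append((i + 1, 0.0, design.dose, 1, 1, np.nan))
        for j in range(nt):
            rows.append((i + 1, times[j], np.nan, 0, 0, dv[i, j]))
    records = pd.DataFrame(rows, columns=COLUMNS)
    return PKDataset(
        records=records,
        truth=truth,
        replicate_id=replicate_id,
        iiv_level=iiv_level,
    )


def generate_study(design: StudyDesign, truth_base: PopulationParameters):
    """Generate the full sweep: ``n_replicates`` datasets at each IIV level.

    At each level the IIV variances on Vd/F and CL/F are both set to
    ``cv_to_omega2(level)`` (the sweep assumes equal IIV on all parameters
    with IIV).  Deterministic given ``design.seed``; each (level, replicate)
    has its own independent RNG stream, so any subset can be regenerated in
    isolation.
    """
    out = []
    for level in design.iiv_levels:
        om2 = cv_to_omega2(level)
        truth = replace(truth_base, omega2_v=om2, omega2_cl=om2)
        for rep in range(design.n_replicates):
            out.append(
                simulate_dataset(design, truth, replicate_id=rep, iiv_level=level)
            )
    return out


# ---------------------------------------------------------------------------
# presets

def base_truth(
    iiv_cv: float = 30.0, sigma2: float = 0.01
) -> PopulationParameters:
    """Truth of the base simulation model: Ka=2/h, Vd/F=40 L, CL/F=10 L/h."""
    om2 = cv_to_omega2(iiv_cv)
    return PopulationParameters(
        ka=2.0, v_f=40.0, cl_f=10.0, omega2_v=om2, omega2_cl=om2, sigma2=sigma2
    )


def base_design(**overrides) -> StudyDesign:
    """The 6-subject, 8-sample, 6-level x 100-replicate base design."""
    return StudyDesign(**overrides)


#: sampling schedule used for the theophylline-like case study (h)
THEO_TIMES = (0.25, 0.5, 1.0, 2.0, 3.5, 5.0, 7.0, 9.0, 12.0, 24.0, 24.3)


def theo_truth(sigma2: float = 0.01) -> PopulationParameters:
    """Case-study truth re-parameterized from a theophylline population fit.

    CL/F = 2.88 L/h, Vd/F = 33.01 L, Ka = 1.46 1/h, with IIV CVs of 25.69%
    on CL/F, 13.48% on Vd/F and 65.39% on Ka.  Unlike the base simulation
    model this places a random effect on Ka.  The residual variance is not
    part of the printed parameterization; the package default is used.
    """
    return PopulationParameters(
        ka=1.46,
        v_f=33.01,
        cl_f=2.88,
        omega2_v=cv_to_omega2(13.48),
        omega2_cl=cv_to_omega2(25.69),
        omega2_ka=cv_to_omega2(65.39),
        sigma2=sigma2,
    )


def theo_design(n_replicates: int = 100, seed: int = 20260926) -> StudyDesign:
    """6 subjects, 320 mg oral dose, 11 samples to 24.3 h, one IIV level."""
    return StudyDesign(
        n_subjects=6,
        dose=320.0,
        sampling_times=THEO_TIMES,
        iiv_levels=(0.0,),
        n_replicates=n_replicates,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# NONMEM-style CSV I/O

def write_dataset(dataset: PKDataset, path) -> None:
    """Write one dataset as NONMEM-style CSV (ID,TIME,AMT,EVID,MDV,DV)."""
    dataset.records.to_csv(path, index=False, na_rep="")


def read_dataset(path, truth: PopulationParameters | None = None) -> PKDataset:
    """Read a single-replicate NONMEM-style CSV written by :func:`write_dataset`."""
    df = pd.read_csv(path)
    df.columns = [c.upper() for c in df.columns]
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset file missing columns: {missing}")
    df = df[COLUMNS].astype(
        {"ID": int, "TIME": float, "EVID": int, "MDV": int, "DV": float, "AMT": float}
    )
    truth = truth if truth is not None else PopulationParameters(1.0, 1.0, 1.0)
    return PKDataset(records=df, truth=truth)


def write_study(datasets, path) -> None:
    """Write many replicates to one long CSV with a leading REP column."""
    frames = []
    for ds in datasets:
        df = ds.records.copy()
        df.insert(0, "REP", ds.replicate_id)
        if ds.iiv_level is not None:
            df.insert(1, "IIV", ds.iiv_level)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, na_rep="")


def read_study(path, truth: PopulationParameters | None = None):
    """Read a long REP-column CSV back into a list of datasets."""
    df = pd.read_csv(path)
    df.columns = [c.upper() for c in df.columns]
    if "REP" not in df.columns:
        raise ValueError("long-format study file requires a REP column")
    truth = truth if truth is not None else PopulationParameters(1.0, 1.0, 1.0)
    keys = ["REP", "IIV"] if "IIV" in df.columns else ["REP"]
    out = []
    for key, grp in df.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        out.append(
            PKDataset(
                records=grp[COLUMNS].reset_index(drop=True).astype(
                    {"ID": int, "TIME": float, "EVID": int, "MDV": int}
                ),
                truth=truth,
                replicate_id=int(key[0]),
                iiv_level=float(key[1]) if len(key) > 1 else None,
            )
        )
    return out


# ---------------------------------------------------------------------------
# key-value configuration

def save_config(design: StudyDesign, truth: PopulationParameters, path) -> None:
    """Persist a design + truth as a YAML key-value config."""
    cfg = {
        "design": {
            "n_subjects": design.n_subjects,
            "dose": design.dose,
            "sampling_times": list(design.sampling_times),
            "iiv_levels": list(design.iiv_levels),
            "n_replicates": design.n_replicates,
            "seed": design.seed,
        },
        "truth": {
            "ka": truth.ka,
            "v_f": truth.v_f,
            "cl_f": truth.cl_f,
            "omega2_v": truth.omega2_v,
            "omega2_cl": truth.omega2_cl,
            "omega2_ka": truth.omega2_ka,
            "sigma2": truth.sigma2,
        },
    }
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


def load_config(path):
    """Load a YAML config into a (StudyDesign, PopulationParameters) pair."""
    cfg = yaml.safe_load(Path(path).read_text())
    d = cfg.get("design", {})
    if "sampling_times" in d:
        d["sampling_times"] = tuple(d["sampling_times"])
    if "iiv_levels" in d:
        d["iiv_levels"] = tuple(d["iiv_levels"])
    return StudyDesign(**d), PopulationParameters(**cfg.get("truth", {}))
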