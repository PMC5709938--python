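"""Internal: dataset -> padded per-subject arrays for the estimators."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import PKDataset
from .model import concentration_curve


@dataclass(frozen=True)
class SubjectArrays:
    """Rectangularized observation data: one row per subject, NaN-padded."""

    ids: np.ndarray          # (n,)
    dose: np.ndarray         # (n,) single oral bolus at t=0 per subject
    times: np.ndarray        # (n, T) padded with 1.0 where masked
    y: np.ndarray            # (n, T) padded with 0.0 where masked
    mask: np.ndarray         # (n, T) True where a real observation exists

    @property
    def n_subjects(self) -> int:
        return self.ids.size

    @property
    def n_obs(self) -> int:
        return int(self.mask.sum())


def extract_subjects(dataset: PKDataset) -> SubjectArrays:
    """Build padded arrays from a NONMEM-style records frame.

    Requires exactly one dosing record (EVID=1) at t=0 per subject and at
    least one observation record per subject.
    """
    df = dataset.records
    ids = np.sort(df["ID"].unique())
    doses, t_rows, y_rows = [], [], []
    for sid in ids:
        sub = df[df["ID"] == sid]
        dose_rows = sub[sub["EVID"] == 1]
        if len(dose_rows) != 1 or dose_rows["TIME"].iloc[0] != 0.0:
            raise ValueError(f"subject {sid}: need exactly one EVID=1 record at t=0")
        obs = sub[sub["EVID"] == 0]
        if len(obs) == 0:
            raise ValueError(f"subject {sid}: no observations")
        doses.append(float(dose_rows["AMT"].iloc[0]))
        t_rows.append(obs["TIME"].to_numpy(dtype=float))
        y_rows.append(obs["DV"].to_numpy(dtype=float))
    width = max(len(t) for t in t_rows)
    n = len(ids)
    times = np.ones((n, width))
    y = np.zeros((n, width))
    mask = np.zeros((n, width), dtype=bool)
    for i, (t, v) in enumerate(zip(t_rows, y_rows)):
        times[i, : len(t)] = t
        y[i, : len(t)] = v
        mask[i, : len(t)] = True
    return SubjectArrays(
        ids=ids, dose=np.asarray(doses), times=times, y=y, mask=mask
    )


# eta column order used throughout the estimators
ETA_ORDER = ("ka", "v_f", "cl_f")


def predict_all(theta: np.ndarray, etas: np.ndarray, sub: SubjectArrays) -> np.ndarray:
    """Batched predictions (..., n, T) for theta=(ka,v,cl) and etas (..., n, 3).

    Eta columns follow :data:`ETA_ORDER`; masked cells get the prediction at
    the pad time and must be ignored by callers via ``sub.mask``.  Leading
    batch dimensions on ``etas`` broadcast through (used to evaluate whole
    finite-difference stencils in one call).
    """
    ka = theta[0] * np.exp(etas[..., 0:1])
    v = theta[1] * np.exp(etas[..., 1:2])
    cl = theta[2] * np.exp(etas[..., 2:3])
    return concentration_curve(ka, v, cl, sub.dose[:, None], sub.times)
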