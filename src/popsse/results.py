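"""Shared result containers for the estimation methods."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FitResult"]


@dataclass
class FitResult:
    """Outcome of one estimation run on one dataset.

    ``theta_hat`` is (Ka, Vd/F, CL/F); ``omega2_hat`` maps parameter name
    ("v_f", "cl_f", optionally "ka") to its estimated IIV variance.  For
    maximum-likelihood fits ``ofv`` is the -2 log-likelihood objective up to
    its additive constant; for MCMC fits it is the mean log-posterior of the
    stationary phase.  ``minimization_success`` and ``covariance_success``
    record the convergence and curvature checks, mirroring the bookkeeping of
    estimation-method comparison studies.
    """

    method: str
    theta_hat: np.ndarray
    omega2_hat: dict
    sigma2_hat: float
    ofv: float
    minimization_success: bool
    covariance_success: bool
    eta_hat: np.ndarray | None = None
    n_func_evals: int = 0
    runtime_s: float = 0.0
    settings: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def estimates(self) -> dict:
        """Flat {parameter_name: estimate} mapping used by the SSE table."""
        out = {
            "ka": float(self.theta_hat[0]),
            "v_f": float(self.theta_hat[1]),
            "cl_f": float(self.theta_hat[2]),
        }
        for name, val in self.omega2_hat.items():
            out[f"omega2_{'v' if name == 'v_f' else 'cl' if name == 'cl_f' else 'ka'}"] = float(val)
        return out
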