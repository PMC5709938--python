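"""One-compartment oral-absorption population PK model.

Structural model: first-order absorption from a depot compartment into a
central compartment with first-order elimination,

    dA_d/dt = -Ka * A_d,
    dA_c/dt =  Ka * A_d - (CL/V) * A_c,

with concentration C(t) = A_c(t) / V.  For a single oral bolus ``dose`` given
at t = 0 the closed-form solution is

    C(t) = dose * Ka / (V * (Ka - ke)) * (exp(-ke t) - exp(-Ka t)),
    ke = CL / V,

with the L'Hopital limit ``C(t) = dose * Ka * t / V * exp(-Ka t)`` when
Ka == ke (flip-flop tie).

Statistical model: population fixed effects theta = (Ka, Vd/F, CL/F) with
lognormal inter-individual variability on Vd/F and CL/F (and optionally Ka,
used by the theophylline case-study parameterization),

    V_i  = theta_V  * exp(eta_V),   eta_V  ~ N(0, omega2_V),
    CL_i = theta_CL * exp(eta_CL),  eta_CL ~ N(0, omega2_CL),

and a proportional residual-error model

    DV_ij = C_pred,ij * (1 + eps_ij),  eps_ij ~ N(0, sigma2),

so that Var(DV_ij | eta_i) = C_pred,ij**2 * sigma2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "PopulationParameters",
    "SubjectEffects",
    "predict_concentration",
    "residual_variance",
    "ode_concentration",
]

#: relative |Ka - ke| / Ka below which the flip-flop limit branch is used
FLIP_FLOP_RTOL = 1e-8


@dataclass(frozen=True)
class PopulationParameters:
    """Population ("true" or estimated) parameters of the hierarchical model.

    Parameters
    ----------
    ka : float
        First-order absorption rate constant, 1/h.
    v_f : float
        Apparent volume of distribution Vd/F, L.
    cl_f : float
        Apparent clearance CL/F, L/h.
    omega2_v, omega2_cl : float
        Variances (log scale) of the subject random effects on Vd/F and CL/F.
    sigma2 : float
        Proportional residual-error variance (dimensionless).
    omega2_ka : float
        Variance of an optional random effect on Ka; 0 (the default) means no
        eta on Ka, matching the base simulation model.  The theophylline
        case-study model sets it > 0.
    """

    ka: float
    v_f: float
    cl_f: float
    omega2_v: float = 0.0
    omega2_cl: float = 0.0
    sigma2: float = 0.0
    omega2_ka: float = 0.0

    def __post_init__(self) -> None:
        if not (self.ka > 0 and self.v_f > 0 and self.cl_f > 0):
            raise ValueError("ka, v_f and cl_f must be strictly positive")
        for name in ("omega2_v", "omega2_cl", "sigma2", "omega2_ka"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def theta(self) -> np.ndarray:
        return np.array([self.ka, self.v_f, self.cl_f])

    def active_omegas(self) -> list[str]:
        """Names of the parameters carrying a random effect (variance > 0)."""
        out = []
        if self.omega2_v > 0:
            out.append("v_f")
        if self.omega2_cl > 0:
            out.append("cl_f")
        if self.omega2_ka > 0:
            out.append("ka")
        return out


@dataclass(frozen=True)
class SubjectEffects:
    """Subject-level random effects (log scale)."""

    eta_v: float = 0.0
    eta_cl: float = 0.0
    eta_ka: float = 0.0


def _individual_params(params: PopulationParameters, effects: SubjectEffects):
    ka = params.ka * np.exp(effects.eta_ka)
    v = params.v_f * np.exp(effects.eta_v)
    cl = params.cl_f * np.exp(effects.eta_cl)
    return ka, v, cl


def concentration_curve(ka, v, cl, dose, times):
    """Closed-form concentration for individual parameters, broadcasting.

    ``ka``, ``v``, ``cl`` and ``dose`` broadcast against each other and
    against ``times``; all must be strictly positive (dose >= 0).
    Shapes: with per-subject columns ``(n_sub, 1)`` and ``times`` of shape
    ``(n_times,)`` the result is ``(n_sub, n_times)``.
    """
    ka = np.asarray(ka, dtype=float)
    v = np.asarray(v, dtype=float)
    cl = np.asarray(cl, dtype=float)
    t = np.asarray(times, dtype=float)
    ke = cl / v
    diff = ka - ke
    tie = np.abs(diff) < FLIP_FLOP_RTOL * ka
    # regular branch; guard the tie denominator to avoid 0/0 warnings
    safe = np.where(tie, 1.0, diff)
    regular = dose * ka / (v * safe) * (np.exp(-ke * t) - np.exp(-ka * t))
    limit = dose * ka * t / v * np.exp(-ka * t)
    return np.where(np.broadcast_to(tie, regular.shape), limit, regular)


def predict_concentration(
    params: PopulationParameters,
    effects: SubjectEffects,
    dose: float,
    times,
) -> np.ndarray:
    """Predicted concentration (mg/L) at ``times`` (h) after an oral ``dose`` (mg).

    Uses the closed-form one-compartment solution with the subject's
    eta-scaled individual parameters; switches to the L'Hopital limit form
    when Ka and ke coincide to within ``FLIP_FLOP_RTOL``.
    """
    if dose < 0:
        raise ValueError("dose must be non-negative")
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    ka, v, cl = _individual_params(params, effects)
    if not (np.isfinite(v) and np.isfinite(cl) and v > 0 and cl > 0):
        raise ValueError("individual V and CL must be positive and finite")
    return concentration_curve(ka, v, cl, dose, times)


def residual_variance(c_pred, sigma2: float):
    """Observation variance under the proportional error model.

    Var(DV) = c_pred**2 * sigma2 for DV = c_pred * (1 + eps), eps ~ N(0, sigma2).
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    return np.square(np.asarray(c_pred, dtype=float)) * sigma2


def ode_concentration(
    params: PopulationParameters,
    effects: SubjectEffects,
    dose: float,
    times,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> np.ndarray:
    """Concentration by direct numerical integration of the compartment ODEs.

    Independent verification oracle for :func:`predict_concentration`; uses an
    explicit high-order Runge-Kutta integration of the depot/central system.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    ka, v, cl = _individual_params(params, effects)
    ke = cl / v

    def rhs(t, a):
        return [-ka * a[0], ka * a[0] - ke * a[1]]

    t_end = float(times.max()) if times.size else 0.0
    nonzero = times > 0
    out = np.zeros_like(times)
    if t_end > 0 and dose > 0:
        sol = solve_ivp(
            rhs,
            (0.0, t_end),
            [dose, 0.0],
            t_eval=np.sort(times[nonzero]),
            rtol=rtol,
            atol=atol,
            method="DOP853",
        )
        order = np.argsort(times[nonzero])
        central = np.empty_like(sol.y[1])
        central[order] = sol.y[1]
        out[nonzero] = central / v
    return out
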