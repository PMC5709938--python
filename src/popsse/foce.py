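"""First-order conditional estimation with interaction (FOCE-I).

Maximum-likelihood estimation of the nonlinear mixed-effects model by the
classical conditional linearization: for each subject the empirical-Bayes
conditional mode eta_hat_i is found by an inner Newton optimization of

    g_i(eta) = sum_j [ log(sigma2 f_ij(eta)^2)
                       + (y_ij - f_ij(eta))^2 / (sigma2 f_ij(eta)^2) ]
               + eta' Omega^{-1} eta,

then the model is linearized about eta_hat_i and the -2 log marginal
likelihood is approximated (2*pi constants omitted, as is conventional for
NLME objective values) by

    OFV = sum_i [ log det C_i + r_i' C_i^{-1} r_i ],
    C_i = G_i Omega G_i' + diag(sigma2 f_i(eta_hat_i)^2),
    r_i = y_i - f_i(eta_hat_i) + G_i eta_hat_i,

with G_i = df_i/deta at eta_hat_i.  Evaluating the residual-error variance at
the conditional mode (rather than at eta = 0) is the "interaction" between
the subject random effects and the proportional residual error.  The outer
problem minimizes OFV over (theta, omega2, sigma2) on the log scale.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np

from ._subjects import ETA_ORDER, SubjectArrays, extract_subjects, predict_all
from .datasets import PKDataset
from .model import PopulationParameters
from .results import FitResult

__all__ = ["FOCESettings", "conditional_mode", "foce_objective", "fit_foce"]

_INNER_FD_STEP = 1e-4  # step for the inner Newton's FD gradient/Hessian


@dataclass(frozen=True)
class FOCESettings:
    """Tuning knobs of the FOCE-I fit.

    ``sig_digits`` is the parameter-stability convergence criterion (the
    estimates must be stable to this many significant digits across the final
    outer iterations); ``fd_step`` is the relative central-difference step for
    the sensitivity matrix G.
    """

    sig_digits: int = 3
    inner_tol: float = 1e-6
    max_outer_iter: int = 200
    fd_step: float = 1e-5
    transform: bool = True
    inner_max_iter: int = 100

    def __post_init__(self) -> None:
        if self.sig_digits < 1:
            raise ValueError("sig_digits must be >= 1")
        if self.inner_tol <= 0 or self.fd_step <= 0:
            raise ValueError("tolerances must be positive")


def _active_indices(active: list[str]) -> np.ndarray:
    return np.array([ETA_ORDER.index(name) for name in active], dtype=int)


def _expand_etas(etas_active: np.ndarray, idx: np.ndarray, n: int) -> np.ndarray:
    etas = np.zeros((n, 3))
    if idx.size:
        etas[:, idx] = etas_active
    return etas


def _subject_objectives(
    etas_active: np.ndarray,
    theta: np.ndarray,
    omega2_vec: np.ndarray,
    sigma2: float,
    sub: SubjectArrays,
    idx: np.ndarray,
) -> np.ndarray:
    """Per-subject conditional objectives g_i; shape (..., n) for
    ``etas_active`` of shape (..., n, p) (leading dims broadcast)."""
    etas = np.zeros(etas_active.shape[:-1] + (3,))
    if idx.size:
        etas[..., idx] = etas_active
    # floor predictions so the proportional-error variance never underflows;
    # keeps the objective finite when the outer search probes extreme regions
    f = np.maximum(predict_all(theta, etas, sub), 1e-10)
    with np.errstate(over="ignore"):
        var = sigma2 * f * f
        term = np.log(var) + np.minimum((sub.y - f) ** 2 / var, 1e30)
    term = np.where(sub.mask, term, 0.0)
    out = term.sum(axis=-1)
    if idx.size:
        out = out + (etas_active**2 / omega2_vec).sum(axis=-1)
    return out


def _stencil_offsets(p: int, h: float) -> np.ndarray:
    """Central-difference stencil: f0, +/- h e_k, and the 4-point crosses."""
    pts = [np.zeros(p)]
    for k in range(p):
        e = np.zeros(p)
        e[k] = h
        pts.extend([e, -e])
    for k in range(p):
        for l in range(k + 1, p):
            ek = np.zeros(p)
            el = np.zeros(p)
            ek[k] = h
            el[l] = h
            pts.extend([ek + el, ek - el, -ek + el, -ek - el])
    return np.asarray(pts)


def _grad_hess(obj, eta, h=_INNER_FD_STEP):
    """Batched central-difference gradient and Hessian of per-subject obj.

    The whole stencil is evaluated in one vectorized objective call
    (shape (P, n, p) -> (P, n)), which amortizes the numpy dispatch cost.
    """
    n, p = eta.shape
    offsets = _stencil_offsets(p, h)                       # (P, p)
    vals = obj(eta[None, :, :] + offsets[:, None, :])       # (P, n)
    f0 = vals[0]
    g = np.empty((n, p))
    H = np.empty((n, p, p))
    for k in range(p):
        fp, fm = vals[1 + 2 * k], vals[2 + 2 * k]
        g[:, k] = (fp - fm) / (2 * h)
        H[:, k, k] = (fp - 2 * f0 + fm) / h**2
    pos = 1 + 2 * p
    for k in range(p):
        for l in range(k + 1, p):
            fpp, fpm, fmp, fmm = vals[pos : pos + 4]
            pos += 4
            H[:, k, l] = H[:, l, k] = (fpp - fpm - fmp + fmm) / (4 * h**2)
    return f0, g, H


def _conditional_modes(
    sub: SubjectArrays,
    theta: np.ndarray,
    omega2_vec: np.ndarray,
    sigma2: float,
    idx: np.ndarray,
    eta0: np.ndarray | None,
    tol: float,
    max_iter: int,
):
    """Batched damped-Newton search for all subjects' conditional modes."""
    n, p = sub.n_subjects, idx.size
    if p == 0:
        return np.zeros((n, 0)), True
    eta = np.zeros((n, p)) if eta0 is None else eta0.copy()

    def obj(e):
        return _subject_objectives(e, theta, omega2_vec, sigma2, sub, idx)

    # ``done`` subjects are left alone: either their gradient met tol or no
    # further descent is possible at finite-difference noise level
    done = np.zeros(n, dtype=bool)
    grad_ok = np.zeros(n, dtype=bool)
    for _ in range(max_iter):
        f0, g, H = _grad_hess(obj, eta)
        bad = ~np.isfinite(g).all(axis=1) | ~np.isfinite(H).reshape(n, -1).all(axis=1)
        if bad.any():
            g[bad] = 0.0
            H[bad] = np.eye(p)
        grad_ok = (np.abs(g).max(axis=1) < tol) & ~bad
        done |= grad_ok
        if done.all():
            break
        # positive-definite safeguard: shift eigenvalues up where needed
        eig = np.linalg.eigvalsh(H)
        lo = eig[:, 0]
        bump = np.where(lo < 1e-8, 1e-6 - np.minimum(lo, 0.0), 0.0)
        H = H + bump[:, None, None] * np.eye(p)
        try:
            delta = np.linalg.solve(H, g[..., None])[..., 0]
        except np.linalg.LinAlgError:
            delta = g / np.maximum(
                np.abs(np.diagonal(H, axis1=1, axis2=2)), 1e-8
            )
        # trust cap against wild steps far from the optimum
        norms = np.linalg.norm(delta, axis=1)
        shrink = np.ones_like(norms)
        np.divide(4.0, norms, out=shrink, where=norms > 4.0)
        delta *= shrink[:, None]
        done |= ~done & (norms < 1e-9)  # step at machine-noise scale
        step = np.where(done, 0.0, 1.0)
        new_eta = eta.copy()
        accepted = done.copy()
        for _bt in range(20):
            trial = eta - step[:, None] * delta
            ft = obj(trial)
            ok = ~accepted & (ft <= f0 - 1e-13 * np.abs(f0))
            new_eta[ok] = trial[ok]
            accepted |= ok
            if accepted.all():
                break
            step = np.where(accepted, step, step / 2.0)
        # a subject whose line search found no descent sits at the finite-
        # difference noise floor: treat as converged
        done |= ~accepted
        eta = new_eta
    return eta, bool((grad_ok | done).all())


def conditional_mode(
    dataset: PKDataset,
    theta,
    omega2: dict,
    sigma2: float,
    inner_tol: float = 1e-6,
) -> np.ndarray:
    """Per-subject empirical-Bayes conditional modes.

    Returns an (n_subjects, 3) array of etas in the (ka, v_f, cl_f) column
    order; columns without a random effect (variance absent or 0) are 0.
    ``omega2`` maps parameter name ("v_f", "cl_f", "ka") to its variance; all
    supplied variances must be strictly positive.
    """
    sub = extract_subjects(dataset)
    active = [name for name in ETA_ORDER if omega2.get(name, 0.0) != 0.0]
    vec = np.array([omega2[name] for name in active])
    if np.any(vec <= 0):
        raise ValueError("omega2 entries must be strictly positive")
    idx = _active_indices(active)
    eta, ok = _conditional_modes(
        sub, np.asarray(theta, dtype=float), vec, sigma2, idx, None, inner_tol, 100
    )
    if not ok:
        raise RuntimeError("conditional-mode search did not converge")
    return _expand_etas(eta, idx, sub.n_subjects)


def _ofv_from_modes(
    sub: SubjectArrays,
    theta: np.ndarray,
    omega2_vec: np.ndarray,
    sigma2: float,
    idx: np.ndarray,
    eta: np.ndarray,
    fd_step: float,
) -> float:
    """Linearized -2 log-likelihood given the conditional modes."""
    n, T = sub.times.shape
    p = idx.size
    etas_full = _expand_etas(eta, idx, n)
    f = np.maximum(predict_all(theta, etas_full, sub), 1e-10)
    h_diag = np.where(sub.mask, sigma2 * f * f, 1.0)
    if p:
        hs = fd_step * np.maximum(1.0, np.abs(eta))          # (n, p)
        pts = np.repeat(eta[None], 2 * p, axis=0)            # (2p, n, p)
        for k in range(p):
            pts[2 * k, :, k] += hs[:, k]
            pts[2 * k + 1, :, k] -= hs[:, k]
        full = np.zeros((2 * p, n, 3))
        full[..., idx] = pts
        F = predict_all(theta, full, sub)                    # (2p, n, T)
        G = np.empty((n, T, p))
        for k in range(p):
            G[:, :, k] = (F[2 * k] - F[2 * k + 1]) / (2 * hs[:, k][:, None])
        G = np.where(sub.mask[:, :, None], G, 0.0)
        C = np.einsum("ntk,nsk->nts", G * omega2_vec, G)
        r = np.where(sub.mask, sub.y - f, 0.0) + np.einsum("ntk,nk->nt", G, eta)
    else:
        C = np.zeros((n, T, T))
        r = np.where(sub.mask, sub.y - f, 0.0)
    C[:, np.arange(T), np.arange(T)] += h_diag
    try:
        chol = np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        C[:, np.arange(T), np.arange(T)] += 1e-10 * h_diag.mean()
        try:
            chol = np.linalg.cholesky(C)
        except np.linalg.LinAlgError:
            return np.inf
    logdet = 2.0 * np.log(np.diagonal(chol, axis1=1, axis2=2)).sum()
    sol = np.linalg.solve(C, r[..., None])[..., 0]
    return float(logdet + (r * sol).sum())


def foce_objective(
    dataset: PKDataset,
    theta,
    omega2: dict,
    sigma2: float,
    settings: FOCESettings | None = None,
) -> float:
    """FOCE-I objective function value at the given population parameters.

    Conditional modes are re-solved from scratch; use :func:`fit_foce` for
    warm-started repeated evaluation.
    """
    settings = settings or FOCESettings()
    sub = extract_subjects(dataset)
    active = [name for name in ETA_ORDER if omega2.get(name, 0.0) > 0.0]
    vec = np.array([omega2[name] for name in active])
    idx = _active_indices(active)
    theta = np.asarray(theta, dtype=float)
    eta, _ = _conditional_modes(
        sub, theta, vec, sigma2, idx, None, settings.inner_tol, settings.inner_max_iter
    )
    return _ofv_from_modes(sub, theta, vec, sigma2, idx, eta, settings.fd_step)


_LOG_BOUNDS = (np.log(1e-8), np.log(1e8))


def _fd_gradient(fun, x, f0, step=1e-5):
    g = np.empty(x.size)
    for k in range(x.size):
        e = np.zeros(x.size)
        e[k] = step
        g[k] = (fun(x + e) - f0) / step
    return g


def _minimize_bfgs_armijo(
    fun,
    x0: np.ndarray,
    bounds,
    max_iter: int,
    gtol: float = 3e-3,
    step_cap: float = 2.0,
):
    """Damped quasi-Newton minimizer with geometric (Armijo) backtracking.

    The proportional-error OFV surface has near-vertical cliffs where
    predictions underflow; interpolation-based line searches (Wolfe) stall
    against them, while plain step-halving crosses them in a few halvings.
    Inverse-Hessian is built by BFGS updates; steps are capped in norm and
    iterates clipped to ``bounds``.  Returns (x, f, iterates, converged).
    """
    lo, hi = bounds
    x = np.clip(x0.astype(float), lo, hi)
    f = fun(x)
    g = _fd_gradient(fun, x, f)
    n = x.size
    Binv = np.eye(n)
    iterates = [x.copy()]
    converged = False
    for _ in range(max_iter):
        if not np.all(np.isfinite(g)):
            break
        if np.abs(g).max() < gtol:
            converged = True
            break
        d = -Binv @ g
        if d @ g >= 0:  # lost positive-definiteness: reset to steepest descent
            Binv = np.eye(n)
            d = -g

        def _armijo(direction):
            norm = np.linalg.norm(direction)
            if norm > step_cap:
                direction = direction * (step_cap / norm)
            gd = g @ direction
            alpha = 1.0
            for _bt in range(40):
                x_try = np.clip(x + alpha * direction, lo, hi)
                f_try = fun(x_try)
                if np.isfinite(f_try) and f_try <= f + 1e-4 * alpha * gd:
                    return x_try, f_try
                alpha *= 0.5
            return None

        hit = _armijo(d)
        if hit is None and not np.allclose(d, -g):
            # stale curvature: retry along steepest descent before giving up
            Binv = np.eye(n)
            hit = _armijo(-g / max(1.0, np.linalg.norm(g)))
        if hit is None:  # no descent at noise level: converged in practice
            converged = True
            break
        x_new, f_new = hit
        g_new = _fd_gradient(fun, x_new, f_new)
        s = x_new - x
        yv = g_new - g
        sy = s @ yv
        if np.isfinite(sy) and sy > 1e-10 * np.linalg.norm(s) * np.linalg.norm(yv):
            rho = 1.0 / sy
            I = np.eye(n)
            V = I - rho * np.outer(s, yv)
            Binv = V @ Binv @ V.T + rho * np.outer(s, s)
        small_step = np.abs(s).max() < 1e-6
        small_df = abs(f - f_new) < 1e-10 * (abs(f) + 1.0)
        x, f, g = x_new, f_new, g_new
        iterates.append(x.copy())
        if small_step and small_df:
            converged = True
            break
    return x, f, iterates, converged


def fit_foce(
    dataset: PKDataset,
    initials: PopulationParameters,
    settings: FOCESettings | None = None,
) -> FitResult:
    """Fit the population model by FOCE-I starting from ``initials``.

    The IIV structure is taken from the initials: every omega2 that is > 0 is
    estimated (log scale), the rest are structurally absent.  Returns a
    :class:`FitResult`; optimizer failure is reported through
    ``minimization_success=False`` with the last iterate recorded, never as
    an exception.
    """
    settings = settings or FOCESettings()
    t0 = time.perf_counter()
    sub = extract_subjects(dataset)
    active = initials.active_omegas()
    idx = _active_indices(active)
    p = idx.size
    omega0 = np.array(
        [getattr(initials, f"omega2_{'v' if a == 'v_f' else 'cl' if a == 'cl_f' else 'ka'}") for a in active]
    )
    x0 = np.log(np.concatenate([initials.theta, omega0, [initials.sigma2]]))

    warm = {"eta": np.zeros((sub.n_subjects, p))}
    n_evals = {"n": 0}

    def unpack(x):
        vals = np.exp(x)
        return vals[:3], vals[3 : 3 + p], vals[3 + p]

    def objective(x):
        n_evals["n"] += 1
        theta, om2, s2 = unpack(x)
        eta, _ = _conditional_modes(
            sub, theta, om2, s2, idx, warm["eta"], settings.inner_tol,
            settings.inner_max_iter,
        )
        warm["eta"] = eta
        return _ofv_from_modes(sub, theta, om2, s2, idx, eta, settings.fd_step)

    x_hat, ofv, iterates, opt_converged = _minimize_bfgs_armijo(
        objective, x0, _LOG_BOUNDS, settings.max_outer_iter
    )
    theta_hat, om2_hat, s2_hat = unpack(x_hat)
    ofv = float(ofv)

    # SIG-style stability: estimates unchanged to sig_digits significant
    # digits across the final outer iterations (log-scale change ~ relative)
    stable = True
    if len(iterates) >= 2:
        stable = bool(
            np.abs(iterates[-1] - iterates[-2]).max() < 0.5 * 10.0 ** (-settings.sig_digits)
        )
    minimization_success = bool(opt_converged and np.isfinite(ofv) and stable)

    # covariance step: central-difference Hessian of the OFV (log scale) must
    # be positive definite
    covariance_success = False
    if np.isfinite(ofv):
        covariance_success = _covariance_step(objective, x_hat)

    eta_full = _expand_etas(warm["eta"], idx, sub.n_subjects)
    omega2_hat = {name: float(v) for name, v in zip(active, om2_hat)}
    return FitResult(
        method="FOCE-I",
        theta_hat=theta_hat,
        omega2_hat=omega2_hat,
        sigma2_hat=float(s2_hat),
        ofv=ofv,
        minimization_success=minimization_success,
        covariance_success=covariance_success,
        eta_hat=eta_full,
        n_func_evals=n_evals["n"],
        runtime_s=time.perf_counter() - t0,
        settings={
            "sig_digits": settings.sig_digits,
            "inner_tol": settings.inner_tol,
            "fd_step": settings.fd_step,
            "optimizer": "damped-BFGS/Armijo(log-scale)",
        },
        extra={"outer_iterations": len(iterates) - 1},
    )


def _covariance_step(objective, x_hat: np.ndarray, h: float = 1e-4) -> bool:
    """PD check of the finite-difference Hessian of the OFV at the optimum."""
    m = x_hat.size
    H = np.empty((m, m))
    f0 = objective(x_hat)
    fp = np.empty(m)
    fm = np.empty(m)
    for k in range(m):
        e = np.zeros(m)
        e[k] = h
        fp[k] = objective(x_hat + e)
        fm[k] = objective(x_hat - e)
        H[k, k] = (fp[k] - 2 * f0 + fm[k]) / h**2
    for k in range(m):
        for l in range(k + 1, m):
            ek = np.zeros(m)
            el = np.zeros(m)
            ek[k] = h
            el[l] = h
            H[k, l] = H[l, k] = (
                objective(x_hat + ek + el)
                - objective(x_hat + ek - el)
                - objective(x_hat - ek + el)
                + objective(x_hat - ek - el)
            ) / (4 * h**2)
    if not np.all(np.isfinite(H)):
        return False
    try:
        eig = np.linalg.eigvalsh(0.5 * (H + H.T))
    except np.linalg.LinAlgError:
        return False
    return bool(eig.min() > 0)
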