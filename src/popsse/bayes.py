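"""Markov chain Monte Carlo Bayesian estimation (Metropolis-within-Gibbs).

The hierarchical posterior is sampled with a fixed scan per iteration:

1. random-walk Metropolis update of each subject's eta vector (all subjects
   in parallel — given theta they are conditionally independent), with
   per-subject proposal scales adapted during burn-in toward a target
   acceptance rate;
2. conjugate inverse-gamma draw of each IIV variance omega2_k given the
   current etas (skipped when the variances are fixed — the "fixed omega"
   variant);
3. component-wise random-walk Metropolis update of log theta, followed by
   an interweaving Gibbs shift along the theta/eta ridge (the shift leaves
   the likelihood invariant and decorrelates theta from the eta means);
4. conjugate inverse-gamma draw of sigma2 given the scaled residuals
   (y - f)/f, which are N(0, sigma2) under the proportional error model.

Priors (the sampler's own, reported in the result metadata): flat improper
prior on log theta; inverse-gamma(a0, b0) with a0 = b0 = 0.01 on each
omega2 and on sigma2 — weakly informative and conjugate for the Gibbs steps.

Burn-in ends early when a stationarity check passes: every ``test_interval``
iterations, each monitored series (log posterior, thetas, omega2s, sigma2)
over the most recent half of the burn-in so far is regressed on iteration
and burn-in is declared converged when no series shows a significant linear
trend (slope t-test, alpha = 0.01).  Point estimates are posterior means
over the stationary samples; posterior medians are stored alongside.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._subjects import ETA_ORDER, SubjectArrays, extract_subjects, predict_all
from .datasets import PKDataset
from .foce import FOCESettings, _active_indices, _expand_etas, fit_foce
from .model import PopulationParameters
from .results import FitResult

__all__ = [
    "MCMCSettings",
    "PosteriorChain",
    "log_posterior",
    "fit_bayes",
    "fit_bayes_composite",
    "mcse",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class MCMCSettings:
    """Sampler configuration.

    ``n_burn_max`` and ``n_stationary`` default to 4000 and 10,000 — the
    conventional burn-in cap and stationary-sample count for this kind of
    single-chain population-PK analysis.  ``ctype`` selects the burn-in
    stationarity check (3 = test objective, thetas, omega2s and sigma2);
    ``sigl`` is retained for provenance only and has no MCMC role here.
    """

    n_burn_max: int = 4000
    n_stationary: int = 10_000
    ctype: int = 3
    test_interval: int = 500
    proposal_adapt_target: float = 0.3
    seed: int | None = None
    prior_a: float = 0.01
    prior_b: float = 0.01
    sigl: int = 8
    store_etas: bool = False

    def __post_init__(self) -> None:
        if self.n_burn_max < 0 or self.n_stationary < 1:
            raise ValueError("invalid iteration counts")


@dataclass
class PosteriorChain:
    """Stored stationary-phase samples and sampler diagnostics."""

    samples: dict            # name -> (n_stationary,) array
    burn_in_used: int
    converged_burn_in: bool
    acceptance_rates: dict   # block -> rate over the stationary phase
    param_names: list = field(default_factory=list)
    eta_samples: np.ndarray | None = None  # (n_stationary, n_sub, p) if stored

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.samples)


def _loglik_rows(theta, etas_full, sigma2, sub: SubjectArrays) -> np.ndarray:
    """Per-subject observation log-likelihood, proportional error model."""
    f = predict_all(theta, etas_full, sub)
    with np.errstate(divide="ignore", invalid="ignore"):
        var = sigma2 * f * f
        term = -0.5 * (_LOG2PI + np.log(var) + (sub.y - f) ** 2 / var)
    return np.where(sub.mask, term, 0.0).sum(axis=1)


def _eta_prior_rows(etas_active, omega2_vec) -> np.ndarray:
    return -0.5 * (
        _LOG2PI * etas_active.shape[1]
        + np.log(omega2_vec).sum()
        + (etas_active**2 / omega2_vec).sum(axis=1)
    )


def _log_ig(x, a, b) -> float:
    return float(-(a + 1.0) * np.log(x) - b / x)


def log_posterior(
    dataset: PKDataset,
    theta,
    omega2: dict,
    sigma2: float,
    etas,
    prior_a: float = 0.01,
    prior_b: float = 0.01,
) -> float:
    """Unnormalized log posterior density of the hierarchical model.

    ``etas`` is (n_subjects, 3) in (ka, v_f, cl_f) column order.  Flat prior
    on log theta; inverse-gamma(prior_a, prior_b) on each variance.  Returns
    -inf for non-finite configurations (rejected in Metropolis steps).
    """
    sub = extract_subjects(dataset)
    active = [name for name in ETA_ORDER if omega2.get(name, 0.0) > 0.0]
    idx = _active_indices(active)
    vec = np.array([omega2[name] for name in active])
    theta = np.asarray(theta, dtype=float)
    etas = np.asarray(etas, dtype=float)
    if sigma2 <= 0 or np.any(vec <= 0) or np.any(theta <= 0):
        return -np.inf
    lp = _loglik_rows(theta, etas, sigma2, sub).sum()
    if idx.size:
        lp += _eta_prior_rows(etas[:, idx], vec).sum()
        lp += sum(_log_ig(v, prior_a, prior_b) for v in vec)
    lp += _log_ig(sigma2, prior_a, prior_b)
    out = float(lp)
    return out if np.isfinite(out) else -np.inf


def _trend_free(series: np.ndarray, alpha: float, n_batches: int = 20) -> bool:
    """True when the series shows no significant linear trend.

    The slope t-test is run on non-overlapping batch means rather than raw
    iterations: MCMC series are autocorrelated, and a naive OLS test would
    flag a trend in almost any stationary chain.
    """
    n = series.size
    if n < 2 * n_batches or np.allclose(series, series[0]):
        return True
    b = n // n_batches
    means = series[: n_batches * b].reshape(n_batches, b).mean(axis=1)
    if np.allclose(means, means[0]):
        return True
    x = np.arange(n_batches, dtype=float)
    res = stats.linregress(x, means)
    resid = means - (res.intercept + res.slope * x)
    denom = (resid * resid).sum()
    r1 = float((resid[:-1] * resid[1:]).sum() / denom) if denom > 0 else 0.0
    r1 = min(max(r1, 0.0), 0.95)
    # AR(1) inflation of the slope SE for residual batch-mean correlation
    t_corr = res.slope / (res.stderr * np.sqrt((1 + r1) / (1 - r1)))
    pval = 2.0 * stats.t.sf(abs(t_corr), n_batches - 2)
    return bool(pval > alpha)


def fit_bayes(
    dataset: PKDataset,
    initials: PopulationParameters,
    settings: MCMCSettings | None = None,
    fix_omega: bool = False,
    method_label: str | None = None,
    fix_theta: bool = False,
    fix_sigma: bool = False,
) -> tuple[FitResult, PosteriorChain]:
    """Sample the posterior and return posterior-mean point estimates.

    With ``fix_omega=True`` the IIV variances are held at their initial
    values for the whole chain (the fixed-omega variant).  The burn-in
    convergence flag becomes ``minimization_success``; ``covariance_success``
    is always True for MCMC (posterior spread is always available).
    ``fix_theta`` / ``fix_sigma`` hold those blocks at their initial values
    (useful for conditional-posterior verification).
    """
    settings = settings or MCMCSettings()
    t0 = time.perf_counter()
    rng = np.random.default_rng(settings.seed)
    sub = extract_subjects(dataset)
    n = sub.n_subjects
    active = initials.active_omegas()
    idx = _active_indices(active)
    p = idx.size
    a0, b0 = settings.prior_a, settings.prior_b

    log_theta = np.log(initials.theta.copy())
    om2 = np.array(
        [getattr(initials, f"omega2_{'v' if a == 'v_f' else 'cl' if a == 'cl_f' else 'ka'}") for a in active]
    )
    sigma2 = float(initials.sigma2) if initials.sigma2 > 0 else 0.01
    etas = np.zeros((n, p))

    s_eta = np.full(n, 0.3)
    s_theta = np.full(3, 0.05)
    target = settings.proposal_adapt_target

    ll_rows = _loglik_rows(np.exp(log_theta), _expand_etas(etas, idx, n), sigma2, sub)

    def scaled_resid_ss(theta, etas_active):
        f = predict_all(theta, _expand_etas(etas_active, idx, n), sub)
        z = np.where(sub.mask, (sub.y - f) / f, 0.0)
        return float((z * z).sum())

    n_obs = sub.n_obs
    monitors: dict[str, list] = {}
    acc_eta = acc_theta = prop_count = 0

    def one_iteration(adapting: bool):
        nonlocal etas, om2, sigma2, log_theta, ll_rows, s_eta, s_theta
        nonlocal acc_eta, acc_theta, prop_count
        theta = np.exp(log_theta)
        # (1) per-subject eta random-walk MH, vectorized across subjects
        if p:
            prop = etas + s_eta[:, None] * rng.standard_normal((n, p))
            ll_prop = _loglik_rows(theta, _expand_etas(prop, idx, n), sigma2, sub)
            log_r = (
                ll_prop
                - ll_rows
                + _eta_prior_rows(prop, om2)
                - _eta_prior_rows(etas, om2)
            )
            accept = np.log(rng.random(n)) < log_r
            etas = np.where(accept[:, None], prop, etas)
            ll_rows = np.where(accept, ll_prop, ll_rows)
            acc_eta += accept.sum()
            if adapting:
                s_eta = s_eta * np.exp(0.05 * (accept - target))
            # (2) conjugate inverse-gamma draw for each omega2
            if not fix_omega:
                shape = a0 + 0.5 * n
                rate_ig = b0 + 0.5 * (etas**2).sum(axis=0)
                om2 = rate_ig / rng.gamma(shape, 1.0, size=p)
        # (3) component-wise random-walk MH on log theta (flat prior there)
        etas_full = _expand_etas(etas, idx, n)
        for k in range(3) if not fix_theta else ():
            prop_lt = log_theta.copy()
            prop_lt[k] += s_theta[k] * rng.standard_normal()
            ll_prop_rows = _loglik_rows(np.exp(prop_lt), etas_full, sigma2, sub)
            acc = np.log(rng.random()) < ll_prop_rows.sum() - ll_rows.sum()
            if acc:
                log_theta = prop_lt
                ll_rows = ll_prop_rows
                acc_theta += 1
            prop_count += 1
            if adapting:
                s_theta[k] *= np.exp(0.05 * ((1.0 if acc else 0.0) - target))
        # (3b) interweaving Gibbs shift along the theta/eta ridge: moving a
        # common shift delta from the etas into log theta leaves every
        # individual parameter theta_k*exp(eta_ik) — hence the likelihood —
        # unchanged, and its full conditional is N(mean(eta), omega2/n).
        # Without it the centered hierarchical parameterization makes
        # theta mix at random-walk speed along this ridge.
        if p and not fix_theta:
            for j, col in enumerate(idx):
                delta = rng.normal(etas[:, j].mean(), np.sqrt(om2[j] / n))
                etas[:, j] -= delta
                log_theta[col] += delta
        # (4) conjugate inverse-gamma draw of sigma2
        if not fix_sigma:
            ss = scaled_resid_ss(np.exp(log_theta), etas)
            sigma2 = (b0 + 0.5 * ss) / rng.gamma(a0 + 0.5 * n_obs, 1.0)
        ll_rows = _loglik_rows(np.exp(log_theta), _expand_etas(etas, idx, n), sigma2, sub)

    def log_post_now():
        lp = ll_rows.sum()
        if p:
            lp += _eta_prior_rows(etas, om2).sum()
            lp += sum(_log_ig(v, a0, b0) for v in om2)
        lp += _log_ig(sigma2, a0, b0)
        return float(lp)

    # ---- burn-in with stationarity testing (ctype-3 style)
    converged = settings.n_burn_max == 0
    burn_used = 0
    history: list[np.ndarray] = []
    for it in range(settings.n_burn_max):
        one_iteration(adapting=True)
        burn_used = it + 1
        row = np.concatenate(
            [[log_post_now()], np.exp(log_theta), om2, [sigma2]]
        )
        history.append(row)
        if settings.ctype == 3 and burn_used % settings.test_interval == 0:
            win = np.asarray(history[burn_used // 2 :])
            if all(_trend_free(win[:, j], 0.01) for j in range(win.shape[1])):
                converged = True
                break
    else:
        if settings.n_burn_max > 0:
            win = np.asarray(history[len(history) // 2 :])
            converged = all(_trend_free(win[:, j], 0.01) for j in range(win.shape[1]))

    # ---- stationary phase: no adaptation, store everything
    acc_eta = acc_theta = prop_count = 0
    m = settings.n_stationary
    theta_s = np.empty((m, 3))
    om2_s = np.empty((m, p))
    sig_s = np.empty(m)
    lp_s = np.empty(m)
    eta_s = np.empty((m, n, p)) if settings.store_etas else None
    for it in range(m):
        one_iteration(adapting=False)
        theta_s[it] = np.exp(log_theta)
        om2_s[it] = om2
        sig_s[it] = sigma2
        lp_s[it] = log_post_now()
        if eta_s is not None:
            eta_s[it] = etas

    samples = {"log_posterior": lp_s, "ka": theta_s[:, 0], "v_f": theta_s[:, 1], "cl_f": theta_s[:, 2]}
    for j, name in enumerate(active):
        samples[f"omega2_{'v' if name == 'v_f' else 'cl' if name == 'cl_f' else 'ka'}"] = om2_s[:, j]
    samples["sigma2"] = sig_s
    chain = PosteriorChain(
        samples=samples,
        burn_in_used=burn_used,
        converged_burn_in=converged,
        acceptance_rates={
            "eta": float(acc_eta) / (m * n) if p else float("nan"),
            "theta": float(acc_theta) / max(prop_count, 1),
        },
        param_names=["ka", "v_f", "cl_f", *active, "sigma2"],
        eta_samples=eta_s,
    )
    label = method_label or ("BAYES(F)" if fix_omega else "BAYES")
    result = FitResult(
        method=label,
        theta_hat=theta_s.mean(axis=0),
        omega2_hat={name: float(om2_s[:, j].mean()) for j, name in enumerate(active)},
        sigma2_hat=float(sig_s.mean()),
        ofv=float(lp_s.mean()),
        minimization_success=bool(converged),
        covariance_success=True,
        eta_hat=_expand_etas(etas, idx, n),
        n_func_evals=burn_used + m,
        runtime_s=time.perf_counter() - t0,
        settings={
            "n_burn_max": settings.n_burn_max,
            "n_stationary": m,
            "ctype": settings.ctype,
            "sigl": settings.sigl,
            "priors": f"log-theta flat; omega2,sigma2 ~ InvGamma({a0},{b0})",
            "fix_omega": fix_omega,
        },
        extra={
            "posterior_median_theta": np.median(theta_s, axis=0),
            "posterior_median_omega2": {
                name: float(np.median(om2_s[:, j])) for j, name in enumerate(active)
            },
            "burn_in_used": burn_used,
        },
    )
    return result, chain


def fit_bayes_composite(
    dataset: PKDataset,
    initials: PopulationParameters,
    foce_settings: FOCESettings | None = None,
    mcmc_settings: MCMCSettings | None = None,
) -> tuple[FitResult, PosteriorChain]:
    """Composite method: FOCE-I first, its estimates seed the MCMC chain.

    On FOCE-I non-convergence the last iterate still seeds the chain; on a
    hard failure (non-finite estimates) the user initials are used and the
    fallback is flagged in the result metadata.  The FOCE-I stage result is
    attached under ``extra['foce_stage']`` for audit.
    """
    foce_res = fit_foce(dataset, initials, foce_settings)
    est = foce_res.estimates()
    fell_back = not all(np.isfinite(v) and v > 0 for v in est.values())
    if fell_back:
        seed_params = initials
    else:
        seed_params = PopulationParameters(
            ka=est["ka"],
            v_f=est["v_f"],
            cl_f=est["cl_f"],
            omega2_v=est.get("omega2_v", 0.0),
            omega2_cl=est.get("omega2_cl", 0.0),
            omega2_ka=est.get("omega2_ka", 0.0),
            sigma2=foce_res.sigma2_hat,
        )
    result, chain = fit_bayes(
        dataset, seed_params, mcmc_settings, fix_omega=False, method_label="BAYES(C)"
    )
    result.extra["foce_stage"] = foce_res
    result.extra["foce_fallback_to_initials"] = fell_back
    return result, chain


def mcse(x: np.ndarray, n_batches: int = 50) -> float:
    """Monte-Carlo standard error of a chain mean by non-overlapping batch means."""
    x = np.asarray(x, dtype=float)
    b = max(len(x) // n_batches, 2)
    k = len(x) // b
    means = x[: k * b].reshape(k, b).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(k))
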