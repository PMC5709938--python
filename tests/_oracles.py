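"""Independent oracles used by the test suite.

These deliberately avoid the package's estimation code paths: the marginal
likelihood is computed by adaptive Gauss-Hermite quadrature over the exact
hierarchical density, and conditional modes by exhaustive grid search, so
they can arbitrate the FOCE-I linearization and inner optimizer.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import logsumexp

from popsse._subjects import extract_subjects
from popsse.model import concentration_curve

_LOG2PI = np.log(2.0 * np.pi)


def _subject_loglik(theta, eta, sigma2, dose, times, y, eta_idx):
    """Exact log p(y | eta) for one subject; eta over the active indices."""
    full = np.zeros(3)
    full[eta_idx] = eta
    ka = theta[0] * np.exp(full[0])
    v = theta[1] * np.exp(full[1])
    cl = theta[2] * np.exp(full[2])
    f = concentration_curve(ka, v, cl, dose, times)
    var = sigma2 * f * f
    return float(-0.5 * (_LOG2PI + np.log(var) + (y - f) ** 2 / var).sum())


def _neg_log_joint(theta, eta, omega2_vec, sigma2, dose, times, y, eta_idx):
    lp = _subject_loglik(theta, eta, sigma2, dose, times, y, eta_idx)
    lp += float(
        -0.5 * (eta_idx.size * _LOG2PI + np.log(omega2_vec).sum()
                + (eta**2 / omega2_vec).sum())
    )
    return -lp


def aghq_minus2ll(dataset, theta, omega2: dict, sigma2, n_nodes: int = 41):
    """-2 log marginal likelihood by adaptive Gauss-Hermite quadrature.

    Per subject the integrand is re-centered at its mode and rescaled by the
    mode Hessian (finite differences), then integrated on a tensor grid of
    ``n_nodes`` per eta dimension.  Exact up to quadrature error, which at
    41+ nodes is far below the tolerances it arbitrates.
    """
    from popsse._subjects import ETA_ORDER

    sub = extract_subjects(dataset)
    active = [nm for nm in ETA_ORDER if omega2.get(nm, 0.0) > 0.0]
    eta_idx = np.array([ETA_ORDER.index(nm) for nm in active], dtype=int)
    om2 = np.array([omega2[nm] for nm in active])
    theta = np.asarray(theta, dtype=float)
    d = eta_idx.size
    z, w = hermgauss(n_nodes)
    grids = np.meshgrid(*([z] * d), indexing="ij")
    zmat = np.stack([g.ravel() for g in grids], axis=1)          # (M, d)
    if d == 1:
        logw = np.log(w)
    else:
        logw = sum(np.log(m).ravel() for m in np.meshgrid(*([w] * d), indexing="ij"))
    total = 0.0
    for i in range(sub.n_subjects):
        times = sub.times[i][sub.mask[i]]
        y = sub.y[i][sub.mask[i]]
        dose = sub.dose[i]
        nlj = lambda e: _neg_log_joint(theta, e, om2, sigma2, dose, times, y, eta_idx)
        res = minimize(nlj, np.zeros(d), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000})
        mode = res.x
        # FD Hessian of the negative log joint at the mode
        h = 1e-4
        H = np.empty((d, d))
        f0 = nlj(mode)
        for a in range(d):
            ea = np.zeros(d); ea[a] = h
            H[a, a] = (nlj(mode + ea) - 2 * f0 + nlj(mode - ea)) / h**2
            for b in range(a + 1, d):
                eb = np.zeros(d); eb[b] = h
                H[a, b] = H[b, a] = (
                    nlj(mode + ea + eb) - nlj(mode + ea - eb)
                    - nlj(mode - ea + eb) + nlj(mode - ea - eb)
                ) / (4 * h**2)
        A = np.linalg.cholesky(np.linalg.inv(H))
        pts = mode + np.sqrt(2.0) * zmat @ A.T                  # (M, d)
        logf = np.array([-nlj(e) for e in pts])
        _, logdetA = np.linalg.slogdet(A)
        log_int = (
            0.5 * d * np.log(2.0) + logdetA
            + logsumexp(logw + (zmat**2).sum(axis=1) + logf)
        )
        total += log_int
    return -2.0 * total


def grid_conditional_mode(theta, omega2_vec, sigma2, dose, times, y,
                          lo=-2.0, hi=2.0, fine_step=1e-3):
    """Two-stage exhaustive grid search for a single subject's 2-D mode.

    Coarse pass at step 0.05 over [lo, hi]^2, then a fine pass at
    ``fine_step`` in a +/-0.06 window around the coarse optimum; resolves
    the mode of the conditional objective to the fine-step resolution.
    """

    def g(ev, ecl):
        ka = theta[0]
        v = theta[1] * np.exp(ev)
        cl = theta[2] * np.exp(ecl)
        f = concentration_curve(ka, v[..., None], cl[..., None], dose, times)
        var = sigma2 * f * f
        ll = (np.log(var) + (y - f) ** 2 / var).sum(axis=-1)
        return ll + ev**2 / omega2_vec[0] + ecl**2 / omega2_vec[1]

    coarse = np.arange(lo, hi + 1e-12, 0.05)
    EV, ECL = np.meshgrid(coarse, coarse, indexing="ij")
    vals = g(EV, ECL)
    i, j = np.unravel_index(np.argmin(vals), vals.shape)
    c_ev, c_ecl = coarse[i], coarse[j]
    fine = np.arange(-0.06, 0.06 + 1e-12, fine_step)
    EV, ECL = np.meshgrid(c_ev + fine, c_ecl + fine, indexing="ij")
    vals = g(EV, ECL)
    i, j = np.unravel_index(np.argmin(vals), vals.shape)
    return np.array([EV[i, j], ECL[i, j]])
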