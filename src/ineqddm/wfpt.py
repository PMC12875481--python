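"""Wiener first-passage-time density, choice probabilities, and a simulator.

Conventions (unit diffusion coefficient throughout):

* boundary separation ``alpha`` > 0; evidence lives on (0, alpha);
* relative starting point ``z`` in (0, 1), measured toward the **upper**
  boundary, which codes *rejection*; the lower boundary codes *acceptance*;
* drift ``v`` > 0 pushes toward rejection;
* observed response time = nondecision time ``tau`` + first-passage time.

The density is evaluated with the classical dual series: a small-time
expansion in image terms and a large-time eigenfunction expansion, switching
per evaluation point to whichever needs fewer terms at the requested
truncation tolerance.
"""

from __future__ import annotations

import numpy as np

_TWO_PI = 2.0 * np.pi

DEADLINE_S = 10.0


def _log_f1(u, w, tol: float = 1e-7):
    """log density of lower-boundary first passage at normalized time ``u``.

    ``u = t / alpha**2`` is decision time rescaled to a unit boundary with
    zero drift; ``w`` is the relative start.  Vectorized; returns -inf where
    ``u <= 0`` or the density underflows.
    """
    u = np.asarray(u, dtype=float)
    w = np.asarray(w, dtype=float)
    u, w = np.broadcast_arrays(u, w)
    out = np.full(u.shape, -np.inf)
    ok = u > 0
    if not ok.any():
        return out
    uu = u[ok].ravel()
    ww = w[ok].ravel()

    # terms needed for each expansion (Navarro & Fuss style bounds)
    with np.errstate(invalid="ignore"):
        ks = np.where(
            2.0 * np.sqrt(_TWO_PI * uu) * tol < 1.0,
            2.0 + np.sqrt(np.maximum(-2.0 * uu * np.log(2.0 * tol * np.sqrt(_TWO_PI * uu)), 0.0)),
            2.0,
        )
        ks = np.maximum(ks, np.sqrt(uu) + 1.0)
        kl = np.where(
            np.pi * uu * tol < 1.0,
            np.sqrt(np.maximum(-2.0 * np.log(np.pi * uu * tol), 0.0) / (np.pi**2 * uu)),
            1.0 / (np.pi * np.sqrt(uu)),
        )
    small = ks < kl
    f = np.empty_like(uu)

    if small.any():
        us, wsm = uu[small], ww[small]
        half = int(min(np.ceil(ks[small].max() / 2.0) + 1, 64))
        k = np.arange(-half, half + 1)[:, None]
        arg = wsm[None, :] + 2.0 * k
        dens = (arg * np.exp(-(arg**2) / (2.0 * us[None, :]))).sum(axis=0)
        f[small] = dens / np.sqrt(_TWO_PI * us**3)
    large = ~small
    if large.any():
        ul, wl = uu[large], ww[large]
        K = int(min(np.ceil(kl[large].max()) + 1, 128))
        k = np.arange(1, K + 1)[:, None]
        dens = (
            k * np.exp(-(k**2) * np.pi**2 * ul[None, :] / 2.0) * np.sin(k * np.pi * wl[None, :])
        ).sum(axis=0)
        f[large] = np.pi * dens

    with np.errstate(divide="ignore", invalid="ignore"):
        logf = np.where(f > 0, np.log(np.maximum(f, 1e-300)), -np.inf)
    out[ok] = logf
    return out


def wfpt_logdensity(t, boundary, alpha, z, tau, drift, tol: float = 1e-7):
    """Log first-passage density at the named boundary at observed RT ``t``.

    ``boundary`` is ``"upper"``/``"lower"`` or an integer array (1 = upper =
    rejection, 0 = lower = acceptance).  Density is over decision time
    ``t - tau``; the result is -inf for ``t <= tau``.
    """
    alpha = np.asarray(alpha, dtype=float)
    z = np.asarray(z, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("boundary separation alpha must be positive")
    if np.any((z <= 0) | (z >= 1)):
        raise ValueError("relative starting point z must lie in (0, 1)")
    drift = np.asarray(drift, dtype=float)
    if not np.all(np.isfinite(drift)):
        raise ValueError("drift must be finite")

    if isinstance(boundary, str):
        upper = boundary == "upper"
        if boundary not in ("upper", "lower"):
            raise ValueError("boundary must be 'upper' or 'lower'")
    else:
        upper = np.asarray(boundary).astype(bool)
    v = np.where(upper, -drift, drift)
    w = np.where(upper, 1.0 - z, z)
    tdec = np.asarray(t, dtype=float) - np.asarray(tau, dtype=float)
    v, w, tdec, alpha = np.broadcast_arrays(v, w, tdec, alpha)

    logf = _log_f1(tdec / alpha**2, w, tol=tol)
    with np.errstate(invalid="ignore"):
        logf = logf - 2.0 * np.log(alpha) - v * alpha * w - v**2 * np.maximum(tdec, 0.0) / 2.0
    return np.where(tdec > 0, logf, -np.inf)


def prob_upper(alpha, z, drift):
    """Analytic probability of absorption at the upper (rejection) boundary.

    Equals ``z`` at zero drift, is strictly increasing in drift, and lies in
    (0, 1).
    """
    alpha = np.asarray(alpha, dtype=float)
    z = np.asarray(z, dtype=float)
    drift = np.asarray(drift, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("alpha must be positive")
    if np.any((z <= 0) | (z >= 1)):
        raise ValueError("z must lie in (0, 1)")
    if not np.all(np.isfinite(drift)):
        raise ValueError("drift must be finite")
    x = -2.0 * drift * alpha  # log-slope of the scale function
    x, z = np.broadcast_arrays(x, z)
    small = np.abs(x) < 1e-9
    big = x > 700.0  # expm1(x) would overflow; use asymptotic ratio
    with np.errstate(over="ignore", invalid="ignore"):
        core = np.where(small | big, 1.0, np.expm1(x * z) / np.expm1(np.where(big, 0.0, x)))
    p = np.where(small, z, np.where(big, np.exp(x * (z - 1.0)), core))
    return p if p.shape else float(p)


def mean_decision_time(alpha, z, drift):
    """Unconditional mean first-passage (decision) time.

    Closed form for a unit-diffusion process on (0, alpha) started at
    ``z * alpha``: ``E[T] = (alpha/v) P_upper - z*alpha/v`` for drift v != 0
    and ``z*alpha*(alpha - z*alpha)`` at zero drift.
    """
    alpha = np.asarray(alpha, dtype=float)
    z = np.asarray(z, dtype=float)
    drift = np.asarray(drift, dtype=float)
    x0 = z * alpha
    small = np.abs(drift) < 1e-7
    p_up = prob_upper(alpha, z, np.where(small, 1.0, drift))
    with np.errstate(divide="ignore", invalid="ignore"):
        et = (alpha * np.asarray(p_up) - x0) / np.where(small, 1.0, drift)
    et = np.where(small, x0 * (alpha - x0), et)
    return et if et.shape else float(et)


def simulate_paths(
    alpha,
    z,
    tau,
    drift,
    rng: np.random.Generator,
    deadline_s: float = DEADLINE_S,
    dt: float = 1e-3,
    bridge: bool = True,
):
    """Simulate first-passage trials by Euler–Maruyama with bridge crossing.

    All parameters broadcast; one path is run per element of the broadcast
    shape.  Within each step the probability that the Brownian bridge between
    the two endpoints crossed a boundary is sampled exactly, which removes
    the O(sqrt(dt)) absorption bias of the plain Euler scheme.

    Returns ``(choice, rt)`` arrays where choice is 1 = reject (upper),
    0 = accept (lower), -1 = timeout (no absorption before the deadline),
    and rt = tau + first-passage time (NaN for timeouts).
    """
    alpha, z, tau, drift = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (alpha, z, tau, drift))
    )
    shape = alpha.shape
    n = int(np.prod(shape)) if shape else 1
    a = alpha.ravel().astype(float)
    x = (z.ravel() * a).copy()
    mu = drift.ravel()
    t0 = tau.ravel()
    budget = deadline_s - t0  # decision-time budget per path

    choice = np.full(n, -1, dtype=int)
    rt = np.full(n, np.nan)
    active = np.flatnonzero(budget > 0)
    t = np.zeros(n)
    sqdt = np.sqrt(dt)

    while active.size:
        xa = x[active]
        step = mu[active] * dt + sqdt * rng.standard_normal(active.size)
        xn = xa + step
        t[active] += dt

        hit_up = xn >= a[active]
        hit_lo = xn <= 0.0
        if bridge:
            interior = ~(hit_up | hit_lo)
            if interior.any():
                ii = np.flatnonzero(interior)
                au = a[active][ii]
                p_up = np.exp(-2.0 * (au - xa[ii]) * (au - xn[ii]) / dt)
                p_lo = np.exp(-2.0 * xa[ii] * xn[ii] / dt)
                u = rng.random(ii.size)
                cross_up = u < p_up
                cross_lo = ~cross_up & (u < p_up + p_lo)
                hit_up[ii[cross_up]] = True
                hit_lo[ii[cross_lo]] = True

        absorbed = hit_up | hit_lo
        over = t[active] > budget[active]
        done_idx = active[absorbed & ~over]
        if done_idx.size:
            choice[done_idx] = np.where(hit_up[absorbed & ~over], 1, 0)
            rt[done_idx] = t0[done_idx] + t[done_idx]
        # paths that ran out of time stay choice=-1 / rt=NaN
        keep = ~(absorbed | over)
        x[active] = xn
        active = active[keep]

    return choice.reshape(shape), rt.reshape(shape)


def quantile_decision_time(alpha, z, tau, drift, q, t_max: float = 60.0, n_grid: int = 4096):
    """Numeric inverse-CDF of the unconditional decision-time distribution.

    Used by the optional exact sampling backend; builds the CDF from the
    summed upper+lower densities on a log-spaced grid and interpolates.
    """
    grid = np.linspace(1e-5, t_max, n_grid)
    dens = np.exp(wfpt_logdensity(grid, "upper", alpha, z, 0.0, drift)) + np.exp(
        wfpt_logdensity(grid, "lower", alpha, z, 0.0, drift)
    )
    cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2.0 * np.diff(grid))])
    cdf /= cdf[-1]
    return tau + np.interp(q, cdf, grid)
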