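"""Vectorized least-squares refinement of many 2-D Gaussian spots at once.

Single-molecule movies at the study's densities yield 10^4–10^5 candidate
spots; fitting them one scipy call at a time dominates runtime.  This
module runs a damped Gauss-Newton iteration on the whole batch with stacked
(n, 5, 5) normal equations.  Model per spot:

    f(x, y) = b + A · exp(−((x−x0)² + (y−y0)²) / (2 σ²))

Cross-checked against scipy.optimize.curve_fit on single spots in the test
suite.
"""

from __future__ import annotations

import numpy as np

PARAM_NAMES = ("amplitude", "x0", "y0", "sigma", "background")


def _model_and_jac(p, X, Y):
    A, x0, y0, s, b = (p[:, i][:, None, None] for i in range(5))
    dx = X - x0
    dy = Y - y0
    r2 = dx * dx + dy * dy
    g = np.exp(-r2 / (2 * s * s))
    f = b + A * g
    J = np.stack(
        [
            g,
            A * g * dx / (s * s),
            A * g * dy / (s * s),
            A * g * r2 / (s * s * s),
            np.ones_like(g),
        ],
        axis=-1,
    )  # (n, h, w, 5)
    return f, J


def fit_gaussians_batch(
    windows: np.ndarray,
    sigma0: float,
    sigma_bounds: tuple[float, float] | None = None,
    max_iter: int = 30,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit one symmetric Gaussian + constant background per window.

    Parameters
    ----------
    windows : (n, h, w) array of pixel counts, one candidate spot each.
    sigma0 : initial PSF width (pixels).
    sigma_bounds : (lo, hi) clamp for sigma; fits ending on a bound are
        flagged (column ``at_bound``) — typically aggregates or noise.

    Returns
    -------
    params : (n, 5) array ordered (amplitude, x0, y0, sigma, background),
        x0/y0 in window pixel coordinates.
    at_bound : (n,) bool, True where sigma ended clamped at a bound.
    """
    W = np.asarray(windows, dtype=np.float64)
    n, h, w = W.shape
    Y, X = np.mgrid[0:h, 0:w].astype(np.float64)
    X = X[None]
    Y = Y[None]
    lo, hi = sigma_bounds if sigma_bounds is not None else (0.25 * sigma0, 4.0 * sigma0)

    # initialization: background from window border, centroid of excess mass
    border = np.concatenate(
        [W[:, 0, :], W[:, -1, :], W[:, :, 0], W[:, :, -1]], axis=1
    )
    b0 = np.median(border, axis=1)
    A0 = np.maximum(W.reshape(n, -1).max(axis=1) - b0, 1.0)
    excess = np.clip(W - b0[:, None, None], 0, None)
    mass = excess.sum(axis=(1, 2)) + 1e-12
    x0 = (excess * X).sum(axis=(1, 2)) / mass
    y0 = (excess * Y).sum(axis=(1, 2)) / mass
    p = np.column_stack([A0, x0, y0, np.full(n, float(sigma0)), b0])

    lam = np.full(n, 1e-3)
    f, J = _model_and_jac(p, X, Y)
    r = W - f
    cost = (r * r).sum(axis=(1, 2))
    for _ in range(max_iter):
        Jf = J.reshape(n, -1, 5)
        rf = r.reshape(n, -1)
        JTJ = np.einsum("nij,nik->njk", Jf, Jf)
        JTr = np.einsum("nij,ni->nj", Jf, rf)
        # Levenberg damping scaled by the diagonal of JTJ
        Aug = JTJ + lam[:, None, None] * np.eye(5)[None] * np.maximum(
            np.einsum("njj->nj", JTJ), 1e-12
        )[:, None, :]
        try:
            step = np.linalg.solve(Aug, JTr[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.stack(
                [np.linalg.lstsq(a, b, rcond=None)[0] for a, b in zip(Aug, JTr)]
            )
        p_new = p + step
        p_new[:, 0] = np.clip(p_new[:, 0], 1e-6, None)   # amplitude > 0
        p_new[:, 1] = np.clip(p_new[:, 1], -1.0, w)      # center near window
        p_new[:, 2] = np.clip(p_new[:, 2], -1.0, h)
        p_new[:, 3] = np.clip(p_new[:, 3], lo, hi)
        f_new, J_new = _model_and_jac(p_new, X, Y)
        r_new = W - f_new
        cost_new = (r_new * r_new).sum(axis=(1, 2))
        better = cost_new < cost
        p = np.where(better[:, None], p_new, p)
        lam = np.where(better, lam * 0.3, lam * 5.0)
        lam = np.clip(lam, 1e-8, 1e6)
        improved = better & (cost - cost_new > 1e-10 * (cost + 1e-12))
        f = np.where(better[:, None, None], f_new, f)
        J = np.where(better[:, None, None, None], J_new, J)
        r = np.where(better[:, None, None], r_new, r)
        cost = np.where(better, cost_new, cost)
        if not improved.any():
            break
    at_bound = (p[:, 3] <= lo + 1e-9) | (p[:, 3] >= hi - 1e-9)
    return p, at_bound


def fit_two_gaussians_batch(
    windows: np.ndarray,
    sigma: float,
    max_iter: int = 40,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit two fixed-width Gaussians + shared background per window.

    Used to split candidate spots whose single-Gaussian fit came out wide —
    at single-molecule densities those are usually two just-overlapping
    emitters, not one big one.  Parameters per window:
    (A1, x1, y1, A2, x2, y2, b), sigma held at the PSF width.

    Returns (params (n, 7), rss (n,)).
    """
    W = np.asarray(windows, dtype=np.float64)
    n, h, w = W.shape
    Y, X = np.mgrid[0:h, 0:w].astype(np.float64)
    X = X[None]
    Y = Y[None]

    border = np.concatenate([W[:, 0, :], W[:, -1, :], W[:, :, 0], W[:, :, -1]],
                            axis=1)
    b0 = np.median(border, axis=1)
    excess = np.clip(W - b0[:, None, None], 0, None)
    mass = excess.sum(axis=(1, 2)) + 1e-12
    cx = (excess * X).sum(axis=(1, 2)) / mass
    cy = (excess * Y).sum(axis=(1, 2)) / mass
    # split along the principal axis of the excess-intensity distribution
    dx = X - cx[:, None, None]
    dy = Y - cy[:, None, None]
    sxx = (excess * dx * dx).sum(axis=(1, 2)) / mass
    syy = (excess * dy * dy).sum(axis=(1, 2)) / mass
    sxy = (excess * dx * dy).sum(axis=(1, 2)) / mass
    theta = 0.5 * np.arctan2(2 * sxy, sxx - syy)
    ux, uy = np.cos(theta), np.sin(theta)
    amp0 = np.maximum(W.reshape(n, -1).max(axis=1) - b0, 1.0)
    off = max(sigma, 1.0)
    p = np.column_stack([
        amp0, cx + off * ux, cy + off * uy,
        amp0, cx - off * ux, cy - off * uy, b0,
    ])

    s2 = sigma * sigma

    def model_jac(p):
        A1, x1, y1, A2, x2, y2, b = (p[:, i][:, None, None] for i in range(7))
        g1 = np.exp(-((X - x1) ** 2 + (Y - y1) ** 2) / (2 * s2))
        g2 = np.exp(-((X - x2) ** 2 + (Y - y2) ** 2) / (2 * s2))
        f = b + A1 * g1 + A2 * g2
        J = np.stack([
            g1, A1 * g1 * (X - x1) / s2, A1 * g1 * (Y - y1) / s2,
            g2, A2 * g2 * (X - x2) / s2, A2 * g2 * (Y - y2) / s2,
            np.ones_like(g1),
        ], axis=-1)
        return f, J

    lam = np.full(n, 1e-3)
    f, J = model_jac(p)
    r = W - f
    cost = (r * r).sum(axis=(1, 2))
    for _ in range(max_iter):
        Jf = J.reshape(n, -1, 7)
        rf = r.reshape(n, -1)
        JTJ = np.einsum("nij,nik->njk", Jf, Jf)
        JTr = np.einsum("nij,ni->nj", Jf, rf)
        Aug = JTJ + lam[:, None, None] * np.eye(7)[None] * np.maximum(
            np.einsum("njj->nj", JTJ), 1e-12
        )[:, None, :]
        try:
            step = np.linalg.solve(Aug, JTr[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.stack(
                [np.linalg.lstsq(a, b, rcond=None)[0] for a, b in zip(Aug, JTr)]
            )
        p_new = p + step
        p_new[:, 0] = np.clip(p_new[:, 0], 1e-6, None)
        p_new[:, 3] = np.clip(p_new[:, 3], 1e-6, None)
        for c in (1, 4):
            p_new[:, c] = np.clip(p_new[:, c], -1.0, w)
        for c in (2, 5):
            p_new[:, c] = np.clip(p_new[:, c], -1.0, h)
        f_new, J_new = model_jac(p_new)
        r_new = W - f_new
        cost_new = (r_new * r_new).sum(axis=(1, 2))
        better = cost_new < cost
        p = np.where(better[:, None], p_new, p)
        lam = np.where(better, lam * 0.3, lam * 5.0)
        lam = np.clip(lam, 1e-8, 1e6)
        improved = better & (cost - cost_new > 1e-10 * (cost + 1e-12))
        f = np.where(better[:, None, None], f_new, f)
        J = np.where(better[:, None, None, None], J_new, J)
        r = np.where(better[:, None, None], r_new, r)
        cost = np.where(better, cost_new, cost)
        if not improved.any():
            break
    return p, cost
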