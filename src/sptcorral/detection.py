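"""Single-molecule spot detection and single-molecule validation diagnostics.

Detection is a matched-filter reconstruction of the cross-correlation
approach: candidate pixels are local maxima of the cross-correlation
between the frame and a normalized (zero-mean, unit-norm) Gaussian
template of the PSF width;
candidates above a robust noise threshold are refined to subpixel position
by least-squares fitting of a 2-D Gaussian with constant background.  The
module also provides the two standard single-molecule sanity checks —
unimodality of the spot intensity distribution and single-step
photobleaching of intensity traces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi, stats
from skimage.feature import peak_local_max

from ._gaussfit import fit_gaussians_batch, fit_two_gaussians_batch

LOC_COLUMNS = ["frame", "x", "y", "amplitude", "background", "sigma"]


@dataclass
class Localization:
    """One subpixel localization; x = column, y = row, in pixels."""

    frame_index: int
    x: float
    y: float
    amplitude: float
    background: float
    fit_sigma: float


def _gaussian_kernel(sigma: float) -> np.ndarray:
    half = int(math.ceil(3 * sigma))
    ax = np.arange(-half, half + 1)
    g = np.exp(-(ax**2) / (2 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


def detect_spots(
    frame: np.ndarray,
    psf_sigma: float,
    snr_threshold: float = 5.0,
    frame_index: int = 0,
    sigma_bounds_factor: tuple[float, float] = (0.5, 2.0),
) -> pd.DataFrame:
    """Detect and localize spots in one frame.

    Candidates are local maxima of the cross-correlation with a normalized
    Gaussian template; the detection threshold is ``snr_threshold`` times a
    robust (median-absolute-deviation) estimate of the correlation-response
    noise, which makes the detector invariant to constant offsets and sparse
    bright spots.  Surviving candidates are refined in a (4·σ+1)² window by
    a least-squares Gaussian fit with free width.  Fits pinned at the lower
    [0.5, 2]·σ_psf width bound are discarded as noise; wide fits are handed
    to a two-emitter refit (overlapping molecules) and discarded as likely
    aggregates only when the split does not explain them either.

    Returns a table with columns (frame, x, y, amplitude, background, sigma).
    """
    if psf_sigma <= 0:
        raise ValueError("psf_sigma must be positive")
    frame = np.asarray(frame, dtype=np.float64)
    win_half = max(int(math.ceil(2 * psf_sigma)), 2)
    win = 2 * win_half + 1
    if frame.shape[0] < win or frame.shape[1] < win:
        raise ValueError(
            f"frame {frame.shape} smaller than the {win}×{win} fit window"
        )
    kernel = _gaussian_kernel(psf_sigma)
    # matched filter: correlate with the zero-mean, unit-norm template, so
    # the response is in amplitude units and constant offsets cancel
    kz = kernel - kernel.mean()
    kz /= np.sqrt((kz**2).sum())
    resp = ndi.correlate(frame, kz, mode="reflect")
    # one-sided MAD from negative deviations: emitters only push the
    # response up, so the negative side stays uncontaminated even when
    # spots cover a sizable fraction of the frame
    med = np.median(resp)
    neg = med - resp[resp < med]
    noise_sd = 1.4826 * (np.median(neg) if len(neg) else 0.0)
    thr = snr_threshold * max(noise_sd, 1e-12)
    # min_distance=1 keeps just-resolved neighbors (two Gaussians develop
    # separate maxima from ~2σ apart); duplicates are merged after the fit
    peaks = peak_local_max(
        resp,
        min_distance=1,
        threshold_abs=thr,
        exclude_border=win_half,
    )
    if len(peaks) == 0:
        return pd.DataFrame(columns=LOC_COLUMNS)
    windows = np.stack(
        [
            frame[r - win_half:r + win_half + 1, c - win_half:c + win_half + 1]
            for r, c in peaks
        ]
    )
    lo = sigma_bounds_factor[0] * psf_sigma
    hi = sigma_bounds_factor[1] * psf_sigma
    params, at_bound = fit_gaussians_batch(windows, psf_sigma, (lo, hi))
    amp, x0, y0, sig, bg = params.T
    x = peaks[:, 1] - win_half + x0
    y = peaks[:, 0] - win_half + y0
    in_frame = (
        (amp > 0)
        & (x >= 0) & (x < frame.shape[1])
        & (y >= 0) & (y < frame.shape[0])
        # center must stay inside its window, else the fit chased a neighbor
        & (np.abs(x0 - win_half) <= win_half)
        & (np.abs(y0 - win_half) <= win_half)
    )
    at_low = at_bound & (sig <= lo + 1e-6)
    # wide fits are two overlapping emitters more often than aggregates at
    # single-molecule densities: try a two-emitter refit before deciding
    wide = in_frame & ~at_low & (sig >= 1.25 * psf_sigma)
    keep = in_frame & ~at_bound & ~wide
    rows = [
        pd.DataFrame(
            {
                "frame": frame_index, "x": x[keep], "y": y[keep],
                "amplitude": amp[keep], "background": bg[keep],
                "sigma": sig[keep],
            }
        )
    ]
    if np.any(wide):
        rows.append(
            _split_wide(
                frame, frame_index, windows[wide], peaks[wide], params[wide],
                at_bound[wide], psf_sigma, win_half,
            )
        )
    rows = [t for t in rows if len(t)]
    if not rows:
        return pd.DataFrame(columns=LOC_COLUMNS)
    out = pd.concat(rows, ignore_index=True)[LOC_COLUMNS]
    return _dedupe(out, min_sep=max(psf_sigma, 1.0))


def _split_wide(frame, frame_index, windows, peaks, params, at_hi_bound,
                psf_sigma, win_half):
    """Two-emitter refit of wide single-Gaussian candidates.

    A split is accepted when the two-emitter model explains the window
    substantially better (RSS halved), the emitters are resolved (≥ 1 px
    apart) and neither is a minor artifact of the other.  Rejected splits
    fall back to the single fit, except fits pinned at the upper sigma
    bound, which are discarded as likely aggregates.
    """
    h_img, w_img = frame.shape
    win = 2 * win_half + 1
    Y, X = np.mgrid[0:win, 0:win].astype(float)
    amp, x0, y0, sig, bg = params.T
    model1 = bg[:, None, None] + amp[:, None, None] * np.exp(
        -((X[None] - x0[:, None, None]) ** 2 + (Y[None] - y0[:, None, None]) ** 2)
        / (2 * sig[:, None, None] ** 2)
    )
    rss1 = ((windows - model1) ** 2).sum(axis=(1, 2))
    p2, rss2 = fit_two_gaussians_batch(windows, psf_sigma)
    A1, x1, y1, A2, x2, y2, b2 = p2.T
    sep = np.hypot(x1 - x2, y1 - y2)
    amp_ratio = np.minimum(A1, A2) / np.maximum(A1, A2)
    ok = (rss2 <= 0.5 * rss1) & (sep >= 1.0) & (sep <= win) & (amp_ratio >= 0.2)
    rows = []
    for i in range(len(windows)):
        px_off = peaks[i, 1] - win_half
        py_off = peaks[i, 0] - win_half
        if ok[i]:
            for a, xx, yy in ((A1[i], x1[i], y1[i]), (A2[i], x2[i], y2[i])):
                gx, gy = px_off + xx, py_off + yy
                if 0 <= gx < w_img and 0 <= gy < h_img:
                    rows.append((frame_index, gx, gy, a, b2[i], psf_sigma))
        elif not at_hi_bound[i]:
            rows.append((frame_index, px_off + x0[i], py_off + y0[i],
                         amp[i], bg[i], sig[i]))
    return pd.DataFrame(rows, columns=LOC_COLUMNS)


def _dedupe(locs: pd.DataFrame, min_sep: float) -> pd.DataFrame:
    """Collapse refined detections closer than ``min_sep`` px (same emitter)."""
    if len(locs) < 2:
        return locs.reset_index(drop=True)
    order = np.argsort(-locs["amplitude"].to_numpy())
    xs = locs["x"].to_numpy()
    ys = locs["y"].to_numpy()
    kept: list[int] = []
    for i in order:
        if all(np.hypot(xs[i] - xs[j], ys[i] - ys[j]) >= min_sep for j in kept):
            kept.append(i)
    return locs.iloc[sorted(kept)].reset_index(drop=True)


def detect_movie(
    stack,
    psf_sigma: float,
    snr_threshold: float = 5.0,
) -> pd.DataFrame:
    """Run :func:`detect_spots` on every frame of a movie.

    ``stack`` may be a (T, H, W) array or a FrameStack.
    """
    data = getattr(stack, "data", stack)
    tables = [
        detect_spots(data[f], psf_sigma, snr_threshold, frame_index=f)
        for f in range(data.shape[0])
    ]
    out = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame(
        columns=LOC_COLUMNS
    )
    return out


def check_intensity_unimodality(
    amplitudes, min_n: int = 50, grid_size: int = 512
) -> dict:
    """Mode count of the spot-amplitude distribution.

    Single fluorophores give a unimodal amplitude distribution; dimers or
    aggregates add modes.  A Gaussian kernel-density estimate with
    Silverman's bandwidth rule is evaluated on a regular grid and its local
    maxima counted.  Fewer than ``min_n`` amplitudes flags the diagnostic as
    underpowered instead of raising.
    """
    a = np.asarray(
        amplitudes["amplitude"] if isinstance(amplitudes, pd.DataFrame) else amplitudes,
        dtype=float,
    )
    a = a[np.isfinite(a)]
    if len(a) < min_n:
        return {
            "underpowered": True,
            "n": int(len(a)),
            "mode_count": None,
            "quartiles": None,
        }
    kde = stats.gaussian_kde(a, bw_method="silverman")
    pad = 2 * a.std() / max(len(a) ** 0.2, 1)
    grid = np.linspace(a.min() - pad, a.max() + pad, grid_size)
    dens = kde(grid)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    mode_count = int(interior.sum())
    return {
        "underpowered": False,
        "n": int(len(a)),
        "mode_count": max(mode_count, 1),
        "quartiles": tuple(np.percentile(a, [25, 50, 75])),
    }


def _piecewise_rss(csum, csum2, bounds):
    """RSS of a piecewise-constant fit with segment boundaries ``bounds``."""
    rss = 0.0
    edges = [0, *bounds, len(csum) - 1]
    for a, b in zip(edges[:-1], edges[1:]):
        n = b - a
        if n <= 0:
            return np.inf
        s = csum[b] - csum[a]
        s2 = csum2[b] - csum2[a]
        rss += s2 - s * s / n
    return rss


def count_photobleach_steps(trace, max_steps: int = 2) -> tuple[int, list[int]]:
    """Select the number of downward intensity steps (0, 1 or 2) in a trace.

    Piecewise-constant models with 0–2 change points are scored by residual
    sum of squares plus a BIC-style penalty of 6·ln(n)·σ̂² per step, with σ̂
    the robust noise level from the median absolute successive difference.
    The per-step cost is deliberately stiffer than the classical 2·ln(n)
    because the change point is optimized over all positions, which inflates
    the best chance RSS reduction on stepless traces well beyond a single
    χ²₁; genuine bleach steps dwarf the penalty either way.
    Returns (step_count, change-point frame indices); single fluorophores
    bleach in one step.
    """
    y = np.asarray(trace, dtype=float)
    n = len(y)
    if n < 4:
        raise ValueError("trace must have at least 4 frames")
    csum = np.concatenate([[0.0], np.cumsum(y)])
    csum2 = np.concatenate([[0.0], np.cumsum(y * y)])
    diffs = np.diff(y)
    sigma = 1.4826 * np.median(np.abs(diffs - np.median(diffs))) / math.sqrt(2)
    penalty = 6.0 * math.log(n) * sigma**2

    def seg(a, b):
        # vectorized RSS of segments [a, b) given by broadcastable indices
        nn = b - a
        s = csum[b] - csum[a]
        s2 = csum2[b] - csum2[a]
        return s2 - s * s / nn

    best = (_piecewise_rss(csum, csum2, []), 0, [])
    c = np.arange(1, n)
    if max_steps >= 1:
        rss1 = seg(0, c) + seg(c, n)
        j = int(np.argmin(rss1))
        if rss1[j] + penalty < best[0] - 1e-12:
            best = (rss1[j] + penalty, 1, [int(c[j])])
    if max_steps >= 2 and n >= 4:
        tail = seg(c, n)                       # S(c2, n) for c2 = 1..n-1
        rss2_best, cp_best = np.inf, None
        for c1 in range(1, n - 1):
            c2 = np.arange(c1 + 1, n)
            tot = seg(0, c1) + seg(c1, c2) + tail[c2 - 1]
            j = int(np.argmin(tot))
            if tot[j] < rss2_best:
                rss2_best, cp_best = float(tot[j]), [c1, int(c2[j])]
        if cp_best is not None and rss2_best + 2 * penalty < best[0] - 1e-12:
            best = (rss2_best + 2 * penalty, 2, cp_best)
    return best[1], best[2]
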