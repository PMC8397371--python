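"""Ground-truthed synthetic experiments on micropatterned corral substrates.

The generator emulates the measurement geometry of a hybrid substrate in
which micron-scale circular corrals present ligand either on a fluid
supported membrane ("mobile", clusterable by the cell) or grafted to a
polymer ("immobile").  Single molecules arrive in each corral as a Poisson
process, dwell for a two-component exponential mixture of residence times,
photobleach independently, and move by reflected Brownian motion inside a
confinement disk.  Everything is generated in continuous time; frame
quantization is applied only at analysis time, so the generative truth is
independent of acquisition settings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import erf

REGION_CLASSES = ("mobile", "immobile")


def _per_region(value) -> dict:
    """Normalize a scalar or {region: value} mapping to a full region dict."""
    if isinstance(value, Mapping):
        out = dict(value)
        for k in out:
            if k not in REGION_CLASSES:
                raise ValueError(f"unknown region class {k!r}")
        for k in REGION_CLASSES:
            if k not in out:
                raise ValueError(f"missing region class {k!r}")
        return out
    return {k: value for k in REGION_CLASSES}


# ---------------------------------------------------------------------------
# Pattern layout
# ---------------------------------------------------------------------------

@dataclass
class PatternLayout:
    """Geometric ground truth of corral centers, radii and region classes.

    Coordinates and sizes are in micrometers; ``pixel_size`` converts to the
    camera pixel grid (x = column, y = row).
    """

    corral_id: np.ndarray          # (N,) int
    centers: np.ndarray            # (N, 2) µm, columns (x, y)
    radii: np.ndarray              # (N,) µm
    region_class: np.ndarray       # (N,) str, "mobile" | "immobile"
    field_size: tuple[float, float]   # (width, height) µm
    pixel_size: float              # µm / pixel
    puncta: np.ndarray | None = None  # (N, 2) µm cluster centers, NaN if none

    def __post_init__(self):
        self.corral_id = np.asarray(self.corral_id, dtype=int)
        self.centers = np.asarray(self.centers, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        self.region_class = np.asarray(self.region_class, dtype=object)
        if np.any(self.radii <= 0):
            raise ValueError("corral radius must be positive")
        bad = set(self.region_class) - set(REGION_CLASSES)
        if bad:
            raise ValueError(f"invalid region classes: {bad}")
        # pairwise disjoint disks
        n = len(self.corral_id)
        for i in range(n):
            for j in range(i + 1, n):
                d = np.hypot(*(self.centers[i] - self.centers[j]))
                if d <= self.radii[i] + self.radii[j]:
                    raise ValueError(
                        "corral disks overlap: corrals "
                        f"{self.corral_id[i]} and {self.corral_id[j]} at "
                        f"center distance {d:.3g} µm ≤ sum of radii"
                    )
        w, h = self.field_size
        if np.any(self.centers[:, 0] - self.radii < 0) or np.any(
            self.centers[:, 0] + self.radii > w
        ) or np.any(self.centers[:, 1] - self.radii < 0) or np.any(
            self.centers[:, 1] + self.radii > h
        ):
            raise ValueError("every corral must lie fully inside the field")

    @property
    def n_corrals(self) -> int:
        return len(self.corral_id)

    @property
    def shape_px(self) -> tuple[int, int]:
        """Image shape (rows, cols) of the camera field."""
        w, h = self.field_size
        return (int(round(h / self.pixel_size)), int(round(w / self.pixel_size)))

    def areas(self) -> np.ndarray:
        return np.pi * self.radii**2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "corral_id": self.corral_id,
                "x_um": self.centers[:, 0],
                "y_um": self.centers[:, 1],
                "radius_um": self.radii,
                "region_class": self.region_class,
            }
        )


def make_pattern_layout(
    n_rows: int,
    n_cols: int,
    radius: float,
    spacing: float,
    pixel_size: float = 0.1,
    alternating: bool = True,
) -> PatternLayout:
    """Lay out ``n_rows × n_cols`` corrals of ``radius`` µm on a square grid.

    ``spacing`` is the center-to-center distance (µm) and must exceed twice
    the radius so disks stay disjoint.  With ``alternating`` the region class
    follows a checkerboard starting with "mobile" at grid position (0, 0);
    otherwise every corral is mobile.
    """
    if spacing <= 2 * radius:
        raise ValueError(
            f"corral disks would overlap: spacing {spacing} µm ≤ 2·radius "
            f"{2 * radius} µm violates pairwise disjointness"
        )
    ids, centers, classes = [], [], []
    k = 0
    for i in range(n_rows):
        for j in range(n_cols):
            ids.append(k)
            centers.append(((j + 0.5) * spacing, (i + 0.5) * spacing))
            if alternating:
                classes.append("mobile" if (i + j) % 2 == 0 else "immobile")
            else:
                classes.append("mobile")
            k += 1
    return PatternLayout(
        corral_id=np.array(ids),
        centers=np.array(centers),
        radii=np.full(len(ids), float(radius)),
        region_class=np.array(classes, dtype=object),
        field_size=(n_cols * spacing, n_rows * spacing),
        pixel_size=pixel_size,
    )


def assign_puncta(
    layout: PatternLayout,
    rng: np.random.Generator,
    radial_frac: float = 0.7,
) -> PatternLayout:
    """Place one cluster punctum per mobile corral at a random rim angle.

    The punctum sits at ``radial_frac`` of the corral radius from the center
    (clusters tend to be trapped near the corral periphery).  Immobile
    corrals get NaN.  Returns a new layout with ``puncta`` set.
    """
    pts = np.full((layout.n_corrals, 2), np.nan)
    for i in range(layout.n_corrals):
        if layout.region_class[i] == "mobile":
            theta = rng.uniform(0, 2 * np.pi)
            r = radial_frac * layout.radii[i]
            pts[i] = layout.centers[i] + r * np.array([np.cos(theta), np.sin(theta)])
    return replace(layout, puncta=pts)


# ---------------------------------------------------------------------------
# Simulation configuration
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Acquisition and kinetic parameters of a simulated experiment.

    Defaults are the study conditions: 20 frames/s over 1000 frames, a
    two-component dwell mixture with a fast ~80 ms component, and a
    single-molecule channel sparse enough for tracking (~0.5 active
    molecules/µm² inside corrals).  Per-region parameters accept either a
    scalar (applied to both classes) or a ``{"mobile": .., "immobile": ..}``
    mapping.
    """

    dt: float = 0.05                     # frame interval, s
    n_frames: int = 1000
    k_on: Mapping | float = 2.0          # arrival rate, events/µm²/s
    dwell_f1: Mapping | float = 0.55     # fast-component fraction
    dwell_tau1: Mapping | float = 0.08   # fast time constant, s
    dwell_tau2: Mapping | float = 0.508  # slow time constant, s
    k_bleach: float = 0.2                # photobleach rate, 1/s
    diffusion: Mapping | float = field(
        default_factory=lambda: {"mobile": 0.01, "immobile": 0.0}
    )                                    # µm²/s
    confinement_radius: float = 0.15     # µm
    psf_sigma: float = 1.0               # pixels
    photons_per_frame: float = 500.0
    background: float = 20.0             # camera counts / pixel
    read_noise: float = 3.0              # counts (sd)
    ligand_density: Mapping | float = 100.0  # molecules/µm²
    binding_cluster_fraction: float = 0.0    # fraction of arrivals at punctum
    punctum_radius: float = 0.25         # µm
    emccd_excess_noise: bool = False     # double the shot-noise variance
    rng_seed: int = 0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("frame interval dt must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be ≥ 1")
        if self.k_bleach < 0:
            raise ValueError("photobleach rate must be ≥ 0")
        for name in ("k_on", "dwell_f1", "dwell_tau1", "dwell_tau2",
                     "diffusion", "ligand_density"):
            setattr(self, name, _per_region(getattr(self, name)))
        for r in REGION_CLASSES:
            f1 = self.k_on[r]
            if f1 < 0:
                raise ValueError("arrival rate must be ≥ 0")
            if not 0 <= self.dwell_f1[r] <= 1:
                raise ValueError("dwell fraction f1 must lie in [0, 1]")
            if not 0 < self.dwell_tau1[r] <= self.dwell_tau2[r]:
                raise ValueError("need 0 < τ1 ≤ τ2")
            if self.diffusion[r] < 0:
                raise ValueError("diffusion coefficient must be ≥ 0")
        if not 0 <= self.binding_cluster_fraction <= 1:
            raise ValueError("binding_cluster_fraction must lie in [0, 1]")

    @property
    def movie_length(self) -> float:
        return self.n_frames * self.dt


# ---------------------------------------------------------------------------
# Dwell-time primitives
# ---------------------------------------------------------------------------

def sample_dwell_times(
    n: int, f1: float, tau1: float, tau2: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` continuous dwell times from f1·Exp(τ1) + (1−f1)·Exp(τ2)."""
    fast = rng.random(n) < f1
    t = np.empty(n)
    t[fast] = rng.exponential(tau1, fast.sum())
    t[~fast] = rng.exponential(tau2, (~fast).sum())
    return t


def quantize_dwells(t: np.ndarray, dt: float) -> np.ndarray:
    """Frame-quantize continuous dwell times: ceil(t/dt)·dt, minimum one frame.

    A molecule visible for any part of a frame counts that frame, so a
    single-frame appearance has dwell = dt.
    """
    t = np.asarray(t, dtype=float)
    k = np.maximum(np.ceil(t / dt - 1e-12), 1.0)
    return k * dt


def mixture_mean_observed_dwell(
    f1: float, tau1: float, tau2: float, k_bleach: float = 0.0
) -> float:
    """Closed-form mean of min(T, B): T the dwell mixture, B ~ Exp(1/k_bleach).

    min of independent exponentials with rates 1/τ and k_b is exponential
    with rate 1/τ + k_b, so the mixture mean is
    f1/(1/τ1 + k_b) + (1−f1)/(1/τ2 + k_b).
    """
    return f1 / (1.0 / tau1 + k_bleach) + (1.0 - f1) / (1.0 / tau2 + k_bleach)


def kon_for_active_density(
    target_density: float, f1: float, tau1: float, tau2: float,
    k_bleach: float, dt: float | None = None,
) -> float:
    """Arrival rate (events/µm²/s) yielding a steady-state active density.

    At stationarity the density of visible molecules is k_on · E[observed
    dwell]; invert for the arrival rate giving ``target_density`` (µm⁻²).
    With ``dt`` the camera quantization is included: a molecule visible for
    any part of a frame occupies the whole frame, so the expected number of
    visible frames is E[ceil(T/dt)] = Σ_k S((k−1)·dt), evaluated in closed
    form for the bleach-competed mixture.
    """
    if dt is None:
        mean_visible = mixture_mean_observed_dwell(f1, tau1, tau2, k_bleach)
    else:
        r1 = 1.0 / tau1 + k_bleach
        r2 = 1.0 / tau2 + k_bleach
        mean_frames = f1 / (1 - math.exp(-dt * r1)) + (1 - f1) / (
            1 - math.exp(-dt * r2)
        )
        mean_visible = mean_frames * dt
    return target_density / mean_visible


# ---------------------------------------------------------------------------
# Binding events
# ---------------------------------------------------------------------------

@dataclass
class BindingEvent:
    """Ground-truth record of one molecule's visit to the substrate."""

    event_id: int
    corral_id: int
    region_class: str
    arrival_time: float      # s
    true_dwell: float        # s
    bleach_time: float       # s (inf if no bleaching)
    observed_dwell: float    # s: min(true_dwell, bleach_time, movie_end − arrival)
    first_frame: int
    positions: np.ndarray    # (n_visible_frames, 2) µm

    @property
    def n_visible_frames(self) -> int:
        return len(self.positions)


def _uniform_in_disk(rng, center, radius, n=1):
    r = radius * np.sqrt(rng.random(n))
    th = rng.uniform(0, 2 * np.pi, n)
    return center + np.column_stack([r * np.cos(th), r * np.sin(th)])


def _reflect_radial(pos, center, radius):
    """Mirror a point across the circle |p − c| = radius if it lies outside."""
    d = pos - center
    rho = np.hypot(d[0], d[1])
    if rho > radius and rho > 0:
        pos = center + d * ((2 * radius - rho) / rho)
        # a huge step could over-reflect; clamp to the boundary then
        d = pos - center
        rho = np.hypot(d[0], d[1])
        if rho > radius:
            pos = center + d * (radius / rho)
    return pos


def simulate_binding_events(
    layout: PatternLayout,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[BindingEvent]:
    """Simulate arrivals, dwells, bleaching and motion for every corral.

    Arrivals in corral *c* are a homogeneous Poisson process with rate
    k_on[class(c)] · area(c); each dwell is drawn from the two-exponential
    mixture of its region, truncated by an independent exponential bleach
    time and by the movie end.  Motion is reflected Brownian inside a
    confinement disk (D = 0 in immobile regions).  Positions never leave the
    corral disk.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    T = cfg.movie_length
    events: list[BindingEvent] = []
    eid = 0
    for i in range(layout.n_corrals):
        region = layout.region_class[i]
        center = layout.centers[i]
        radius = layout.radii[i]
        rate = cfg.k_on[region] * np.pi * radius**2
        n = rng.poisson(rate * T)
        if n == 0:
            continue
        arrivals = np.sort(rng.uniform(0, T, n))
        dwells = sample_dwell_times(
            n, cfg.dwell_f1[region], cfg.dwell_tau1[region],
            cfg.dwell_tau2[region], rng,
        )
        if cfg.k_bleach > 0:
            bleach = rng.exponential(1.0 / cfg.k_bleach, n)
        else:
            bleach = np.full(n, np.inf)
        r_conf = min(cfg.confinement_radius, radius)
        d_coef = cfg.diffusion[region]
        punctum = None
        if (
            region == "mobile"
            and cfg.binding_cluster_fraction > 0
            and layout.puncta is not None
            and np.isfinite(layout.puncta[i]).all()
        ):
            punctum = layout.puncta[i]
        for j in range(n):
            obs = min(dwells[j], bleach[j], T - arrivals[j])
            first = int(arrivals[j] / cfg.dt)
            n_vis = max(int(math.ceil(obs / cfg.dt - 1e-12)), 1)
            n_vis = min(n_vis, cfg.n_frames - first)
            if n_vis < 1:
                continue
            # binding site: inside the corral, optionally at the punctum
            if punctum is not None and rng.random() < cfg.binding_cluster_fraction:
                site = _uniform_in_disk(rng, punctum, cfg.punctum_radius)[0]
            else:
                site = _uniform_in_disk(rng, center, max(radius - r_conf, 1e-9))[0]
            # keep the whole confinement disk inside the corral
            dc = site - center
            rho = np.hypot(dc[0], dc[1])
            if rho > radius - r_conf:
                site = center + dc * ((radius - r_conf) / max(rho, 1e-12))
            pos = np.empty((n_vis, 2))
            pos[0] = site
            if d_coef > 0 and n_vis > 1:
                step_sd = math.sqrt(2 * d_coef * cfg.dt)
                steps = rng.normal(0, step_sd, (n_vis - 1, 2))
                p = site.copy()
                for s in range(1, n_vis):
                    p = _reflect_radial(p + steps[s - 1], site, r_conf)
                    pos[s] = p
            else:
                pos[1:] = site
            events.append(
                BindingEvent(
                    event_id=eid,
                    corral_id=int(layout.corral_id[i]),
                    region_class=str(region),
                    arrival_time=float(arrivals[j]),
                    true_dwell=float(dwells[j]),
                    bleach_time=float(bleach[j]),
                    observed_dwell=float(obs),
                    first_frame=first,
                    positions=pos,
                )
            )
            eid += 1
    return events


def events_to_frame(events: Sequence[BindingEvent]) -> pd.DataFrame:
    """Flatten events into a ground-truth localization table (µm)."""
    rows = []
    for ev in events:
        for k in range(ev.n_visible_frames):
            rows.append(
                (
                    ev.event_id, ev.corral_id, ev.region_class,
                    ev.first_frame + k, ev.positions[k, 0], ev.positions[k, 1],
                )
            )
    return pd.DataFrame(
        rows,
        columns=["event_id", "corral_id", "region_class", "frame", "x_um", "y_um"],
    )


# ---------------------------------------------------------------------------
# Forward imaging model
# ---------------------------------------------------------------------------

@dataclass
class FrameStack:
    """A rendered movie: (frame, row, col) pixel counts plus acquisition metadata."""

    data: np.ndarray        # (T, H, W) float counts, ≥ 0
    dt: float               # s
    pixel_size: float       # µm / pixel

    def __post_init__(self):
        if self.data.ndim != 3 or self.data.shape[0] < 1:
            raise ValueError("frame stack must be (T, H, W) with T ≥ 1")
        if np.any(self.data < 0):
            raise ValueError("pixel intensities must be ≥ 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


def _stamp_integrated_gaussian(img, x_px, y_px, photons, sigma):
    """Add a pixel-integrated 2-D Gaussian (total mass ≈ photons) to img."""
    h, w = img.shape
    half = int(math.ceil(4 * sigma)) + 1
    cx, cy = int(round(x_px)), int(round(y_px))
    x0, x1 = max(cx - half, 0), min(cx + half + 1, w)
    y0, y1 = max(cy - half, 0), min(cy + half + 1, h)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1)
    ys = np.arange(y0, y1)
    s = sigma * math.sqrt(2)
    fx = 0.5 * (erf((xs + 0.5 - x_px) / s) - erf((xs - 0.5 - x_px) / s))
    fy = 0.5 * (erf((ys + 0.5 - y_px) / s) - erf((ys - 0.5 - y_px) / s))
    img[y0:y1, x0:x1] += photons * np.outer(fy, fx)


def render_movie(
    events: Sequence[BindingEvent],
    layout: PatternLayout,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    noise: bool = True,
) -> FrameStack:
    """Render binding events into a camera movie.

    Each visible molecule contributes a pixel-integrated Gaussian of width
    ``cfg.psf_sigma`` carrying ``cfg.photons_per_frame`` counts; shot noise
    is Poisson on signal + background, and the camera adds Gaussian read
    noise.  Pixel values are clipped at zero.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed + 1)
    shape = layout.shape_px
    w_um, h_um = layout.field_size
    signal = np.zeros((cfg.n_frames,) + shape, dtype=np.float64)
    for ev in events:
        if np.any(ev.positions[:, 0] < 0) or np.any(ev.positions[:, 0] > w_um) or \
           np.any(ev.positions[:, 1] < 0) or np.any(ev.positions[:, 1] > h_um):
            raise ValueError(f"event {ev.event_id} leaves the field")
        for k in range(ev.n_visible_frames):
            f = ev.first_frame + k
            if f >= cfg.n_frames:
                break
            x_px = ev.positions[k, 0] / layout.pixel_size
            y_px = ev.positions[k, 1] / layout.pixel_size
            _stamp_integrated_gaussian(
                signal[f], x_px, y_px, cfg.photons_per_frame, cfg.psf_sigma
            )
    if noise:
        lam = signal + cfg.background
        if cfg.emccd_excess_noise:
            # EMCCD multiplication roughly doubles shot-noise variance
            data = 2.0 * rng.poisson(lam / 2.0).astype(np.float64)
        else:
            data = rng.poisson(lam).astype(np.float64)
        if cfg.read_noise > 0:
            data += rng.normal(0, cfg.read_noise, data.shape)
        data = np.clip(data, 0, None)
    else:
        data = signal + cfg.background
    return FrameStack(data=data, dt=cfg.dt, pixel_size=layout.pixel_size)


def render_ligand_channel(
    layout: PatternLayout,
    densities: Mapping | float,
    clustered_fraction: float,
    rng: np.random.Generator | None = None,
    noise_sd: float = 0.0,
    punctum_radius: float = 0.25,
) -> np.ndarray:
    """Render the ligand reference channel used for region masking.

    Immobile corrals are uniform disks.  Mobile corrals place
    ``clustered_fraction`` of their total intensity into one punctum near
    the rim (the cell has dragged the mobile ligand into a cluster) and
    spread the remainder uniformly.  The summed intensity of a corral is
    density · area in calibrated units regardless of class, reflecting
    ligand conservation inside each corral.
    """
    if not 0 <= clustered_fraction <= 1:
        raise ValueError("clustered_fraction must lie in [0, 1]")
    densities = _per_region(densities)
    for v in densities.values():
        if v < 0:
            raise ValueError("ligand densities must be ≥ 0")
    if rng is None:
        rng = np.random.default_rng(0)
    if layout.puncta is None:
        layout = assign_puncta(layout, rng)
    shape = layout.shape_px
    img = np.zeros(shape)
    px = layout.pixel_size
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    xum = (xx + 0.5) * px
    yum = (yy + 0.5) * px
    for i in range(layout.n_corrals):
        cx, cy = layout.centers[i]
        r = layout.radii[i]
        disk = (xum - cx) ** 2 + (yum - cy) ** 2 <= r**2
        npix = disk.sum()
        if npix == 0:
            continue
        total = densities[layout.region_class[i]] * np.pi * r**2
        cf = clustered_fraction if layout.region_class[i] == "mobile" else 0.0
        img[disk] += total * (1 - cf) / npix
        if cf > 0:
            pxc, pyc = layout.puncta[i]
            pdisk = (xum - pxc) ** 2 + (yum - pyc) ** 2 <= punctum_radius**2
            pdisk &= disk
            if pdisk.sum() == 0:  # punctum smaller than a pixel
                j = np.unravel_index(
                    np.argmin((xum - pxc) ** 2 + (yum - pyc) ** 2), shape
                )
                img[j] += total * cf
            else:
                img[pdisk] += total * cf / pdisk.sum()
    if noise_sd > 0:
        img = np.clip(img + rng.normal(0, noise_sd, shape), 0, None)
    return img


# ---------------------------------------------------------------------------
# Corral ratio datasets (two-channel intensity tables)
# ---------------------------------------------------------------------------

def simulate_corral_ratio_dataset(
    n_mobile: int,
    n_immobile: int,
    fold_change: float,
    cv: float,
    rng_seed: int | np.random.Generator = 0,
    n_cells: int = 1,
    base_intensity: float = 100.0,
) -> pd.DataFrame:
    """Per-corral two-channel intensities with a configured fold-change.

    Each corral carries a denominator (ligand-like) intensity and a
    numerator (signal-like) intensity; the per-corral numerator/denominator
    ratio is lognormal with mean ``fold_change`` (mobile) or 1 (immobile)
    and coefficient of variation ``cv``.  Returns a long table with one row
    per corral and channel, ready for :func:`sptcorral.quantify.
    channel_ratio_per_cell` after splitting by channel.
    """
    if n_mobile <= 0 or n_immobile <= 0:
        raise ValueError("corral counts must be positive")
    if fold_change <= 0:
        raise ValueError("fold_change must be positive")
    if cv < 0:
        raise ValueError("cv must be ≥ 0")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )

    def _ln(mean, n):
        if cv == 0:
            return np.full(n, mean)
        sig2 = math.log(1 + cv**2)
        return rng.lognormal(math.log(mean) - sig2 / 2, math.sqrt(sig2), n)

    rows = []
    for cell in range(n_cells):
        cid = 0
        for region, n_c, r_mean in (
            ("mobile", n_mobile, fold_change),
            ("immobile", n_immobile, 1.0),
        ):
            denom = _ln(base_intensity, n_c)
            ratio = _ln(r_mean, n_c)
            numer = denom * ratio
            for k in range(n_c):
                rows.append((cell, cid, region, 0.0, "numerator", numer[k]))
                rows.append((cell, cid, region, 0.0, "denominator", denom[k]))
                cid += 1
    return pd.DataFrame(
        rows,
        columns=["cell_id", "corral_id", "region_class", "timepoint",
                 "channel", "net_intensity"],
    )


def simulate_recruitment_series(
    n_cells: int,
    n_mobile: int,
    n_immobile: int,
    fold_change: float,
    cv: float,
    rng_seed: int | np.random.Generator = 0,
    duration: float = 1800.0,
    sampling: float = 30.0,
    rise_time: float = 300.0,
    ligand_intensity: float = 100.0,
) -> tuple[pd.DataFrame, dict]:
    """Synthetic corral recruitment time series (saturating rise to a plateau).

    Mobile-corral plateaus exceed immobile ones by ``fold_change`` on
    average, with per-corral lognormal variation of coefficient ``cv``.
    Default timing matches a 30 min acquisition at 30 s/frame (61 samples).
    Returns (long intensity table, {(cell, corral): ligand intensity}).
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    tgrid = np.arange(0.0, duration + sampling / 2, sampling)
    sig2 = math.log(1 + cv**2) if cv > 0 else 0.0

    def _plateau(mean, n):
        if cv == 0:
            return np.full(n, mean)
        return rng.lognormal(math.log(mean) - sig2 / 2, math.sqrt(sig2), n)

    rows, ligand = [], {}
    for cell in range(n_cells):
        cid = 0
        for region, n_c, mean in (
            ("mobile", n_mobile, 100.0 * fold_change),
            ("immobile", n_immobile, 100.0),
        ):
            plat = _plateau(mean, n_c)
            for k in range(n_c):
                lig = ligand_intensity
                ligand[(cell, cid)] = lig
                trace = plat[k] * (1 - np.exp(-tgrid / rise_time))
                for t, v in zip(tgrid, trace):
                    rows.append((cell, cid, region, t, "signal", v))
                cid += 1
    table = pd.DataFrame(
        rows,
        columns=["cell_id", "corral_id", "region_class", "timepoint",
                 "channel", "net_intensity"],
    )
    return table, ligand


def render_nucleus_image(
    mean_signal: float,
    shape: tuple[int, int] = (64, 64),
    nucleus_radius: int = 18,
    background: float = 50.0,
    noise_sd: float = 2.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One synthetic cell: a nuclear blob of ``mean_signal`` over background.

    Returns (image, boolean nuclear mask); used to exercise nuclear
    intensity quantification with a known ground-truth signal.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    mask = (xx - w / 2) ** 2 + (yy - h / 2) ** 2 <= nucleus_radius**2
    img = np.full(shape, background, dtype=float)
    img[mask] += mean_signal
    if noise_sd > 0:
        img = np.clip(img + rng.normal(0, noise_sd, shape), 0, None)
    return img, mask
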