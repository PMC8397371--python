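"""Trajectory linking, dwell times, localization images and MSD diagnostics.

Localizations are linked frame-to-frame by greedy nearest-neighbor
assignment; a molecule's dwell time is the number of frames over which its
trajectory is observed times the frame interval.  First-appearance
positions assembled into a 2-D histogram give the sptPALM-style
localization image.  Mean-squared-displacement curves with a confinement
ratio distinguish confined from free diffusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

TRACK_COLUMNS = ["track_id", "frame", "x", "y", "region"]


@dataclass
class Trajectory:
    """Linked subpixel localizations of one molecule.

    Positions are in pixels (x = column, y = row).  ``censored_start`` /
    ``censored_end`` mark tracks touching the first or last movie frame,
    whose dwell times are lower bounds only.
    """

    track_id: int
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    loc_indices: np.ndarray = None  # rows of the source localization table
    region_class: str = "unassigned"
    corral_id: int = -1
    censored_start: bool = False
    censored_end: bool = False

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("trajectory frames must be strictly increasing")

    @property
    def start_frame(self) -> int:
        return int(self.frames[0])

    @property
    def end_frame(self) -> int:
        return int(self.frames[-1])

    @property
    def n_frames_observed(self) -> int:
        """Frames from first to last appearance inclusive (gaps counted)."""
        return self.end_frame - self.start_frame + 1

    def first_position(self) -> tuple[float, float]:
        return float(self.x[0]), float(self.y[0])


@dataclass
class DwellTimeSample:
    """Frame-quantized residence times for one (cell, region, species) group."""

    dwells: np.ndarray           # s, positive multiples of dt
    dt: float                    # s
    censored_start: np.ndarray = None
    censored_end: np.ndarray = None
    cell_id: int = 0
    region_class: str = "unassigned"
    species: str = ""

    def __post_init__(self):
        self.dwells = np.asarray(self.dwells, dtype=float)
        if self.censored_start is None:
            self.censored_start = np.zeros(len(self.dwells), dtype=bool)
        if self.censored_end is None:
            self.censored_end = np.zeros(len(self.dwells), dtype=bool)
        self.censored_start = np.asarray(self.censored_start, dtype=bool)
        self.censored_end = np.asarray(self.censored_end, dtype=bool)
        if np.any(self.dwells <= 0):
            raise ValueError("dwell times must be positive")
        k = self.dwells / self.dt
        if np.any(np.abs(k - np.round(k)) > 1e-6):
            raise ValueError("dwell times must be integer multiples of dt")

    @property
    def censored(self) -> np.ndarray:
        return self.censored_start | self.censored_end

    def uncensored(self) -> np.ndarray:
        """Dwells eligible for fitting (tracks not touching movie edges)."""
        return self.dwells[~self.censored]

    def __len__(self) -> int:
        return len(self.dwells)


def link_trajectories(
    localizations: pd.DataFrame,
    max_disp: float,
    gap_max: int = 0,
    n_frames: int | None = None,
) -> list[Trajectory]:
    """Link a localization table into trajectories by greedy nearest neighbor.

    For each frame, candidate (track, localization) pairs within
    ``max_disp`` pixels are sorted by ascending distance (ties broken by
    lower localization row index, then track id) and accepted greedily when
    both members are still unassigned.  Unmatched localizations seed new
    tracks; a track unmatched for ``gap_max``+1 consecutive frames is
    terminated.  At unambiguous densities this equals the optimal bipartite
    assignment (property-tested against the Hungarian algorithm).
    """
    if max_disp <= 0:
        raise ValueError("max_disp must be positive")
    if gap_max < 0:
        raise ValueError("gap_max must be ≥ 0")
    if len(localizations) == 0:
        return []
    loc = localizations.reset_index(drop=True)
    frames = loc["frame"].to_numpy(dtype=int)
    xs = loc["x"].to_numpy(dtype=float)
    ys = loc["y"].to_numpy(dtype=float)
    order = np.argsort(frames, kind="stable")
    last_frame = int(frames.max())
    if n_frames is None:
        n_frames = last_frame + 1

    # active track state: id -> (last_frame, last_x, last_y, member rows)
    active: dict[int, list] = {}
    finished: list[list] = []
    next_id = 0
    by_frame: dict[int, np.ndarray] = {
        f: order[frames[order] == f] for f in np.unique(frames)
    }
    for f in range(int(frames.min()), last_frame + 1):
        rows = by_frame.get(f, np.array([], dtype=int))
        # expire tracks that exceeded the allowed gap
        for tid in [t for t, st in active.items() if f - st[0] > gap_max + 1]:
            finished.append(active.pop(tid)[3])
        pairs = []
        tids = list(active.keys())
        if tids and len(rows):
            tx = np.array([active[t][1] for t in tids])
            ty = np.array([active[t][2] for t in tids])
            d = np.hypot(
                tx[:, None] - xs[rows][None, :], ty[:, None] - ys[rows][None, :]
            )
            ti, li = np.nonzero(d <= max_disp)
            pairs = sorted(
                zip(d[ti, li], rows[li], np.array(tids)[ti]),
                key=lambda t: (t[0], t[1], t[2]),
            )
        used_tracks: set = set()
        used_locs: set = set()
        for dist, row, tid in pairs:
            if tid in used_tracks or row in used_locs:
                continue
            used_tracks.add(tid)
            used_locs.add(row)
            st = active[tid]
            st[0], st[1], st[2] = f, xs[row], ys[row]
            st[3].append(row)
        for row in rows:
            if row not in used_locs:
                active[next_id] = [f, xs[row], ys[row], [int(row)]]
                next_id += 1
    finished.extend(st[3] for st in active.values())

    tracks = []
    for tid, members in enumerate(finished):
        members = sorted(members, key=lambda r: frames[r])
        fr = frames[members]
        tr = Trajectory(
            track_id=tid,
            frames=fr,
            x=xs[members],
            y=ys[members],
            loc_indices=np.array(members, dtype=int),
            censored_start=bool(fr[0] == 0),
            censored_end=bool(fr[-1] == n_frames - 1),
        )
        tracks.append(tr)
    tracks.sort(key=lambda t: (t.start_frame, t.track_id))
    for i, t in enumerate(tracks):
        t.track_id = i
    return tracks


def compute_dwell_times(
    tracks: list[Trajectory],
    dt: float,
    cell_id: int = 0,
    region_class: str = "unassigned",
    species: str = "",
) -> DwellTimeSample:
    """Dwell time per trajectory: observed frame span × frame interval.

    Gap frames inside a track count as observed, so a track spanning frames
    10–19 at dt = 50 ms dwells 0.5 s and a single-frame appearance dwells
    one frame interval.  Censoring flags are carried along; censored tracks
    are excluded from fitting downstream by default.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    dwells = np.array([t.n_frames_observed * dt for t in tracks])
    return DwellTimeSample(
        dwells=dwells,
        dt=dt,
        censored_start=np.array([t.censored_start for t in tracks], dtype=bool),
        censored_end=np.array([t.censored_end for t in tracks], dtype=bool),
        cell_id=cell_id,
        region_class=region_class,
        species=species,
    )


def localization_image(
    tracks: list[Trajectory],
    render_pixel: float,
    pixel_size: float,
    field_size: tuple[float, float],
) -> np.ndarray:
    """Assemble first-appearance positions into a localization image.

    ``render_pixel`` is the rendering pixel size in µm; track coordinates
    (camera pixels) are converted with ``pixel_size``.  The image is a plain
    2-D histogram, so its sum equals the number of tracks.
    """
    if render_pixel <= 0:
        raise ValueError("render_pixel must be positive")
    w_um, h_um = field_size
    nx = max(int(np.ceil(w_um / render_pixel)), 1)
    ny = max(int(np.ceil(h_um / render_pixel)), 1)
    img = np.zeros((ny, nx))
    if not tracks:
        return img
    fx = np.array([t.first_position()[0] for t in tracks]) * pixel_size
    fy = np.array([t.first_position()[1] for t in tracks]) * pixel_size
    img, _, _ = np.histogram2d(
        fy, fx, bins=(ny, nx), range=((0, ny * render_pixel), (0, nx * render_pixel))
    )
    return img


def compute_msd(
    track: Trajectory, max_lag: int, pixel_size: float = 1.0
) -> tuple[np.ndarray, np.ndarray, float]:
    """Time-averaged MSD of one trajectory and its confinement ratio.

    MSD(ℓ) averages squared displacements over all frame pairs separated by
    ℓ frames.  The confinement ratio MSD(max_lag) / (max_lag · MSD(1)) is
    ≈ 1 for free Brownian motion and ≪ 1 for confined motion.  Units are
    µm² when ``pixel_size`` is given, else px².
    """
    if len(track.frames) < max_lag + 1:
        raise ValueError("track shorter than max_lag + 1 frames")
    fr = track.frames
    x = track.x * pixel_size
    y = track.y * pixel_size
    lags = np.arange(1, max_lag + 1)
    msd = np.full(max_lag, np.nan)
    for i, lag in enumerate(lags):
        # pair positions exactly `lag` frames apart (gap-aware)
        idx = {f: j for j, f in enumerate(fr)}
        d2 = [
            (x[idx[f + lag]] - x[j]) ** 2 + (y[idx[f + lag]] - y[j]) ** 2
            for j, f in enumerate(fr)
            if f + lag in idx
        ]
        if d2:
            msd[i] = float(np.mean(d2))
    ratio = float(msd[-1] / (max_lag * msd[0])) if msd[0] > 0 else np.nan
    return lags, msd, ratio


def tracks_to_frame(tracks: list[Trajectory]) -> pd.DataFrame:
    """Long-format trajectory table (track_id, frame, x, y, region)."""
    rows = []
    for t in tracks:
        for f, xx, yy in zip(t.frames, t.x, t.y):
            rows.append((t.track_id, int(f), float(xx), float(yy), t.region_class))
    return pd.DataFrame(rows, columns=TRACK_COLUMNS)


def frame_to_tracks(table: pd.DataFrame, n_frames: int | None = None) -> list[Trajectory]:
    """Rebuild Trajectory objects from a long-format table."""
    if n_frames is None:
        n_frames = int(table["frame"].max()) + 1 if len(table) else 0
    tracks = []
    for tid, g in table.sort_values("frame").groupby("track_id"):
        region = g["region"].iloc[0] if "region" in g else "unassigned"
        fr = g["frame"].to_numpy(dtype=int)
        tracks.append(
            Trajectory(
                track_id=int(tid),
                frames=fr,
                x=g["x"].to_numpy(dtype=float),
                y=g["y"].to_numpy(dtype=float),
                region_class=str(region),
                censored_start=bool(fr[0] == 0),
                censored_end=bool(fr[-1] == n_frames - 1),
            )
        )
    return tracks
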