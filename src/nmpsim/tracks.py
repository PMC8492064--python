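"""Trajectory statistics: reference subtraction, tissue-motion correction,
motility and directionality distributions, time-averaged MSD.

Conventions follow the live-imaging analysis they emulate: positions in µm,
the posterior direction is +y, and angles are measured relative to posterior
(0 deg = posterior, in (-180, 180]). "Raw" tracks are positions relative to a
reference point (e.g. the last-formed somite); "corrected" tracks have the
mean motion of a region of interest subtracted, isolating local cell motion
from bulk tissue drift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

TRACK_COLUMNS = ["track_id", "frame", "t_hours", "x_um", "y_um", "tissue"]


class TrackError(ValueError):
    pass


@dataclass
class TrackTable:
    """Uniformly sampled 2D trajectories with tissue labels.

    ``df`` holds one row per (track, frame) with columns
    track_id, frame, t_hours, x_um, y_um, tissue. Frames within a track are
    strictly increasing and consecutive; every track has at least 2 points.
    """

    df: pd.DataFrame
    frame_interval: float  # hours

    def __post_init__(self) -> None:
        missing = [c for c in TRACK_COLUMNS if c not in self.df.columns]
        if missing:
            raise TrackError(f"track table missing columns: {missing}")
        if self.frame_interval <= 0:
            raise TrackError("frame_interval must be positive")
        self.df = self.df.sort_values(["track_id", "frame"]).reset_index(drop=True)
        sizes = self.df.groupby("track_id", sort=False).size()
        if (sizes < 2).any():
            bad = sizes[sizes < 2].index.tolist()
            raise TrackError(f"tracks with < 2 points: {bad}")
        gaps = self.df.groupby("track_id", sort=False)["frame"].diff().dropna()
        if not (gaps == 1).all():
            raise TrackError("tracks must be sampled at every frame (no gaps)")

    @property
    def track_ids(self) -> np.ndarray:
        return self.df["track_id"].unique()

    def positions(self, track_id) -> np.ndarray:
        sub = self.df[self.df["track_id"] == track_id]
        return sub[["x_um", "y_um"]].to_numpy()

    def select_tissue(self, tissue: str) -> "TrackTable":
        sub = self.df[self.df["tissue"] == tissue].reset_index(drop=True)
        return TrackTable(sub, self.frame_interval)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, frame_interval: float | None = None) -> "TrackTable":
        df = pd.read_csv(path)
        if frame_interval is None:
            t = df.sort_values(["track_id", "frame"]).groupby("track_id")["t_hours"]
            dt = t.diff().dropna()
            if dt.empty:
                raise TrackError("cannot infer frame interval from file")
            frame_interval = float(dt.iloc[0])
        return cls(df, frame_interval)

    # steps as wide arrays -------------------------------------------------
    def _step_vectors(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(track_id, frame-of-arrival, dxy) for every consecutive step."""
        df = self.df
        tid = df["track_id"].to_numpy()
        xy = df[["x_um", "y_um"]].to_numpy()
        same = tid[1:] == tid[:-1]
        d = xy[1:] - xy[:-1]
        return tid[1:][same], df["frame"].to_numpy()[1:][same], d[same]


@dataclass
class MsdCurve:
    """Time-averaged mean squared displacement versus lag time."""

    lag_hours: np.ndarray
    msd_um2: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.lag_hours <= 0) or np.any(np.diff(self.lag_hours) <= 0):
            raise TrackError("lags must be positive and increasing")
        if np.any(self.n_pairs <= 0):
            raise TrackError("each lag needs at least one displacement pair")


# ---------------------------------------------------------------------------


def subtract_reference(tracks: TrackTable, reference: np.ndarray) -> TrackTable:
    """Express every position relative to a per-frame reference point.

    ``reference`` is an (n_frames, 2) array indexed by frame number; it must
    cover every frame present in the table.
    """
    reference = np.asarray(reference, dtype=float)
    frames = tracks.df["frame"].to_numpy()
    if frames.max() >= len(reference):
        raise TrackError(
            f"reference track missing frame {int(frames.max())} "
            f"(covers 0..{len(reference) - 1})")
    out = tracks.df.copy()
    out["x_um"] = out["x_um"].to_numpy() - reference[frames, 0]
    out["y_um"] = out["y_um"].to_numpy() - reference[frames, 1]
    return TrackTable(out, tracks.frame_interval)


def correct_tissue_motion(tracks: TrackTable, roi_members) -> TrackTable:
    """Subtract the cumulative mean motion of an ROI from every track.

    For each frame transition the mean displacement vector of the ROI member
    tracks is computed; its cumulative sum is subtracted from all positions.
    In the output, the mean per-step displacement of ROI members is exactly
    zero (to floating tolerance) at every transition.
    """
    roi_members = set(roi_members)
    df = tracks.df
    frames = np.arange(df["frame"].min(), df["frame"].max() + 1)
    roi = df[df["track_id"].isin(roi_members)]
    if roi.empty:
        raise TrackError("no ROI member tracks present")

    mean_step = np.zeros((len(frames), 2))
    roi_tid = roi["track_id"].to_numpy()
    roi_frame = roi["frame"].to_numpy()
    roi_xy = roi[["x_um", "y_um"]].to_numpy()
    same = roi_tid[1:] == roi_tid[:-1]
    step_frame = roi_frame[1:][same]  # frame of arrival
    steps = (roi_xy[1:] - roi_xy[:-1])[same]
    for k, f in enumerate(frames[1:], start=1):
        sel = step_frame == f
        if not sel.any():
            raise TrackError(f"no ROI member spans the transition into frame {f}")
        mean_step[k] = steps[sel].mean(axis=0)
    cum = np.cumsum(mean_step, axis=0)

    out = df.copy()
    fidx = out["frame"].to_numpy() - frames[0]
    out["x_um"] = out["x_um"].to_numpy() - cum[fidx, 0]
    out["y_um"] = out["y_um"].to_numpy() - cum[fidx, 1]
    return TrackTable(out, tracks.frame_interval)


def motility_distribution(tracks: TrackTable, mode: str = "mean_step_speed"
                          ) -> pd.Series:
    """Per-track motility in µm/h.

    ``mean_step_speed`` (default) averages step length / frame interval over
    the track; ``net_displacement`` divides the start-to-end distance by the
    track duration.
    """
    tid, _, d = tracks._step_vectors()
    step_len = np.hypot(d[:, 0], d[:, 1])
    if mode == "mean_step_speed":
        s = pd.Series(step_len).groupby(pd.Series(tid)).mean() / tracks.frame_interval
    elif mode == "net_displacement":
        g = tracks.df.groupby("track_id", sort=False)
        net = np.hypot(g["x_um"].last() - g["x_um"].first(),
                       g["y_um"].last() - g["y_um"].first())
        dur = (g["frame"].last() - g["frame"].first()) * tracks.frame_interval
        s = net / dur
    else:
        raise ValueError(f"unknown motility mode {mode!r}")
    s.index.name = "track_id"
    s.name = "motility_um_per_h"
    return s


def angle_distribution(tracks: TrackTable, n_bins: int = 16
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Velocity-weighted angular histogram of step directions.

    Angles are measured from the posterior (+y) axis, in (-180, 180] deg.
    Each step's weight is proportional to its speed, so fast directed
    movement dominates the rose plot; zero-length steps contribute nothing.
    Returns (bin_edges_deg, weights) with weights summing to 1.
    """
    if n_bins < 4:
        raise ValueError("n_bins must be >= 4")
    _, _, d = tracks._step_vectors()
    speed = np.hypot(d[:, 0], d[:, 1])
    keep = speed > 0
    d, speed = d[keep], speed[keep]
    if len(d) == 0:
        raise TrackError("no non-zero steps to bin")
    # angle from +y axis: atan2(x, y) so that (0, +1) -> 0 deg
    ang = np.degrees(np.arctan2(d[:, 0], d[:, 1]))
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    # map +180 into the last bin rather than creating an overflow
    ang = np.where(ang <= -180.0 + 1e-12, 180.0, ang)
    hist, _ = np.histogram(ang, bins=edges, weights=speed)
    return edges, hist / hist.sum()


def time_averaged_msd(tracks: TrackTable, max_lag_frames: int) -> MsdCurve:
    """Time-and-ensemble-averaged MSD over all overlapping windows.

    For lag k the squared displacements |r(t + k) - r(t)|^2 of every window
    of every track are pooled; the ensemble average weights each track by
    its number of windows (pair-count weighting).
    """
    if max_lag_frames < 1:
        raise TrackError("max_lag_frames must be >= 1")
    sums = np.zeros(max_lag_frames)
    counts = np.zeros(max_lag_frames, dtype=np.int64)
    any_long_enough = False
    for tid, sub in tracks.df.groupby("track_id", sort=False):
        xy = sub[["x_um", "y_um"]].to_numpy()
        n = len(xy)
        if n <= max_lag_frames:
            continue
        any_long_enough = True
        for k in range(1, max_lag_frames + 1):
            d = xy[k:] - xy[:-k]
            sums[k - 1] += np.einsum("ij,ij->", d, d)
            counts[k - 1] += n - k
    if not any_long_enough:
        raise TrackError(
            f"no track longer than max_lag_frames = {max_lag_frames}")
    lags = np.arange(1, max_lag_frames + 1) * tracks.frame_interval
    return MsdCurve(lag_hours=lags, msd_um2=sums / counts, n_pairs=counts)


def fit_diffusion(msd: MsdCurve) -> tuple[float, float]:
    """Fit MSD = 4 D tau through the origin; returns (D in µm²/h, R²).

    The linearity score is the coefficient of determination of the origin-
    constrained linear fit; a diffusive walk scores near 1, ballistic motion
    (quadratic MSD) materially below 1. A degenerate all-zero curve returns
    (0.0, nan).
    """
    tau = msd.lag_hours
    y = msd.msd_um2
    if len(tau) < 3:
        raise TrackError("need at least 3 lags to fit a diffusion coefficient")
    if np.allclose(y, 0.0):
        return 0.0, float("nan")
    slope = float(np.dot(tau, y) / np.dot(tau, tau))
    ss_res = float(np.sum((y - slope * tau) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    score = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return slope / 4.0, score
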