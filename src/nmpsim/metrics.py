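"""Tissue-scale readouts: elongation, resident-progenitor displacement,
progenitor-zone shape conservation, count series and doubling-time fits.

All distances are reported in µm. The posterior edge of the progenitor zone
is taken as the 95th percentile of progenitor y (robust to stray cells), and
shape extents as 5th-95th percentile spans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import FATES
from .simulator import SimResult


class MetricError(ValueError):
    pass


@dataclass(frozen=True)
class ShapeDescriptor:
    """Robust extents of the progenitor population."""

    length_um: float  # antero-posterior (y)
    width_um: float   # medio-lateral (x)

    def __post_init__(self) -> None:
        if self.length_um <= 0 or self.width_um <= 0:
            raise MetricError("shape extents must be positive")

    @property
    def aspect(self) -> float:
        return self.length_um / self.width_um


def _progenitor_xy(snapshot: pd.DataFrame, unit_scale: float):
    sel = snapshot[snapshot["state"] == "progenitor"]
    return (sel["x_unit"].to_numpy() * unit_scale,
            sel["y_unit"].to_numpy() * unit_scale)


def progenitor_shape(result: SimResult, snapshot_index: int) -> ShapeDescriptor:
    x, y = _progenitor_xy(result.snapshots[snapshot_index],
                          result.layout.unit_scale)
    if len(x) == 0:
        raise MetricError("no progenitors in snapshot")
    return ShapeDescriptor(
        length_um=float(np.percentile(y, 95) - np.percentile(y, 5)),
        width_um=float(np.percentile(x, 95) - np.percentile(x, 5)),
    )


def posterior_edge_um(result: SimResult, snapshot_index: int) -> float:
    """95th percentile of progenitor y, in µm."""
    _, y = _progenitor_xy(result.snapshots[snapshot_index],
                          result.layout.unit_scale)
    if len(y) == 0:
        raise MetricError("no progenitors in snapshot")
    return float(np.percentile(y, 95))


def elongation_rate(result: SimResult, window_hours: float = 10.0
                    ) -> tuple[float, float]:
    """Posterior travel of the PZ edge over the window: (µm, µm/h)."""
    times = np.asarray(result.snapshot_times)
    if times[-1] - times[0] + 1e-9 < window_hours:
        raise MetricError("snapshots do not span the requested window")
    i1 = int(np.argmin(np.abs(times - (times[0] + window_hours))))
    dist = posterior_edge_um(result, i1) - posterior_edge_um(result, 0)
    return dist, dist / (times[i1] - times[0])


def resident_y_displacement(result: SimResult, central_third: bool = True
                            ) -> pd.Series:
    """Net posterior displacement (µm) of resident progenitors.

    Residents are cells present in every snapshot that keep the progenitor
    state throughout. With ``central_third`` they are further restricted to
    cells starting in the central antero-posterior third of the initial
    progenitor span. Returns an empty series (with a warning attribute) if
    no cell qualifies.
    """
    first, last = result.snapshots[0], result.snapshots[-1]
    prog_always = None
    for snap in result.snapshots:
        ids = set(snap.loc[snap["state"] == "progenitor", "cell_id"])
        prog_always = ids if prog_always is None else (prog_always & ids)
    resident = prog_always or set()

    f = first[first["cell_id"].isin(resident)].set_index("cell_id")
    if central_third and len(f):
        y = f["y_unit"]
        lo, hi = y.quantile(1 / 3), y.quantile(2 / 3)
        f = f[(y >= lo) & (y <= hi)]
    l = last.set_index("cell_id").loc[f.index]
    out = (l["y_unit"] - f["y_unit"]) * result.layout.unit_scale
    out.name = "y_displacement_um"
    out.attrs["no_residents"] = len(out) == 0
    return out


def shape_conservation(shape_t0: ShapeDescriptor, shape_t1: ShapeDescriptor
                       ) -> float:
    """Percent conservation of the length/width aspect between two times.

    100 means an unchanged aspect; halving or doubling the aspect both give
    50 (the measure is symmetric in its arguments).
    """
    a0, a1 = shape_t0.aspect, shape_t1.aspect
    return 100.0 * min(a1 / a0, a0 / a1)


def count_timeseries(result: SimResult) -> pd.DataFrame:
    """Per-fate cell counts per snapshot (columns: time_h + fates)."""
    return result.counts.copy()


def measure_doubling_time(counts, times=None) -> float:
    """Doubling time (h) from a least-squares fit of ln(count) vs time.

    ``counts`` may be a pandas Series indexed by time or an array with an
    explicit ``times`` vector. A non-growing series yields inf (flat) or a
    negative value (shrinking), which callers should treat as flagged.
    """
    if isinstance(counts, pd.Series):
        times = counts.index.to_numpy(dtype=float)
        counts = counts.to_numpy(dtype=float)
    else:
        counts = np.asarray(counts, dtype=float)
        times = np.asarray(times, dtype=float)
    if len(counts) < 3:
        raise MetricError("need >= 3 time points")
    if np.any(counts <= 0):
        raise MetricError("counts must be positive for a log fit")
    slope = np.polyfit(times, np.log(counts), 1)[0]
    if abs(slope) < 1e-9:  # flat series: no growth to measure
        return float("inf")
    return float(np.log(2.0) / slope)


def tissue_integrity(result: SimResult, snapshot_index: int = -1,
                     radius_um: float = 30.0, fate: str | None = None) -> float:
    """Fraction of cells whose neighbours are mostly of their own fate.

    A cell counts as 'integrated' when more than half of its neighbours
    within ``radius_um`` share its fate; isolated cells count as integrated.
    Well-separated tissues score near 1; mixed ones drop toward the fate
    frequencies. With ``fate`` the score is restricted to cells of that
    fate — ``fate='progenitor'`` measures the coherence of the progenitor
    zone specifically, the most sensitive readout of tissue organisation
    because newly committed cells must leave it.
    """
    from scipy.spatial import cKDTree

    snap = result.snapshots[snapshot_index]
    pts = snap[["x_unit", "y_unit"]].to_numpy() * result.layout.unit_scale
    states = snap["state"].cat.codes.to_numpy()
    tree = cKDTree(pts)
    pairs = tree.query_pairs(radius_um, output_type="ndarray")
    n = len(snap)
    same = np.zeros(n)
    total = np.zeros(n)
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        eq = (states[i] == states[j]).astype(float)
        np.add.at(same, i, eq)
        np.add.at(same, j, eq)
        np.add.at(total, i, 1)
        np.add.at(total, j, 1)
    good = np.where(total > 0, same > total / 2.0, True)
    if fate is not None:
        sel = snap["state"].astype(str).to_numpy() == fate
        if not sel.any():
            raise MetricError(f"no cells of fate {fate!r} in snapshot")
        return float(np.mean(good[sel]))
    return float(np.mean(good))


def cohort_mean_speed(result: SimResult, t_max: float | None = None) -> float:
    """Mean realised step speed (µm/h) of the t = 0 progenitor cohort.

    The cohort keeps its identity after commitment, so this is the readout
    for deregulation experiments: forcing Bra-high values speeds the cohort
    up, forcing Sox2-high slows it down. ``t_max`` restricts the window
    (the early hours, while deregulated cells are still transiting, carry
    most of the signal).
    """
    first = result.snapshots[0]
    cohort = set(first.loc[first["state"] == "progenitor", "cell_id"])
    if not cohort:
        raise MetricError("no progenitors at t = 0")
    tracks = result.to_tracks()
    sub = tracks.df[tracks.df["track_id"].isin(cohort)]
    if t_max is not None:
        sub = sub[sub["t_hours"] <= t_max + 1e-9]
    sub = sub.sort_values(["track_id", "frame"])
    xy = sub[["x_um", "y_um"]].to_numpy()
    tid = sub["track_id"].to_numpy()
    same = tid[1:] == tid[:-1]
    steps = np.hypot(*(xy[1:] - xy[:-1])[same].T)
    return float(steps.mean() / tracks.frame_interval)


def progenitor_msd(result: SimResult, max_lag_frames: int = 8):
    """Time-averaged MSD of resident-progenitor tracks (µm² vs hours).

    Residents (cells in the progenitor state throughout the run) are
    tracked in the simulation frame; returns an MsdCurve.
    """
    from .tracks import TrackTable, time_averaged_msd

    ids = set(resident_y_displacement(result, central_third=False).index)
    if not ids:
        raise MetricError("no resident progenitors")
    tracks = result.to_tracks()
    sub = tracks.df[tracks.df["track_id"].isin(ids)].reset_index(drop=True)
    return time_averaged_msd(TrackTable(sub, tracks.frame_interval),
                             max_lag_frames)
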