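"""Per-nucleus Sox2 / Bra quantification.

Works on tables of nuclear fluorescence intensities (Sox2, Bra, DAPI) with
3D positions and tissue labels. DAPI normalisation compensates the loss of
signal with imaging depth; the per-nucleus Sox2/Bra ratio is the
heterogeneity readout; path profiles average expression along a
posterior-to-anterior series of sampling volumes; digital transverse
sections slice the tissue in y for ratio maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

NUCLEUS_COLUMNS = ["id", "x_um", "y_um", "z_um", "sox2", "bra", "dapi", "tissue"]


class QuantError(ValueError):
    pass


def read_nucleus_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in NUCLEUS_COLUMNS if c not in df.columns]
    if missing:
        raise QuantError(f"nucleus table missing columns: {missing}")
    return df


def normalize_to_dapi(records: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Divide sox2 and bra by the per-nucleus DAPI signal.

    Returns (table with ``sox2_norm``/``bra_norm`` columns, number of
    records excluded for dapi <= 0).
    """
    ok = records["dapi"] > 0
    n_excluded = int((~ok).sum())
    out = records[ok].copy()
    out["sox2_norm"] = out["sox2"] / out["dapi"]
    out["bra_norm"] = out["bra"] / out["dapi"]
    return out, n_excluded


def sox2_bra_ratio(records: pd.DataFrame) -> tuple[pd.Series, int]:
    """Per-nucleus Sox2/Bra ratio on DAPI-normalised values.

    Zero-Bra nuclei are excluded (no pseudocount) and counted; the exclusion
    count is always reported alongside the ratios.
    """
    if "sox2_norm" not in records.columns:
        records, _ = normalize_to_dapi(records)
    ok = records["bra_norm"] > 0
    n_excluded = int((~ok).sum())
    ratio = records.loc[ok, "sox2_norm"] / records.loc[ok, "bra_norm"]
    ratio.name = "sox2_bra_ratio"
    return ratio, n_excluded


def coefficient_of_variation(values) -> float:
    """CV in percent: 100 * sample standard deviation / mean."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise QuantError("need at least 2 values")
    mean = values.mean()
    if mean == 0:
        raise QuantError("CV undefined for zero mean")
    return float(100.0 * values.std(ddof=1) / mean)


@dataclass
class PathProfile:
    """Mean expression along an ordered series of sampling volumes."""

    centers: np.ndarray       # (n_volumes, ndim) volume centres, posterior first
    sox2_mean: np.ndarray
    bra_mean: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.counts <= 0):
            empty = int(np.argmin(self.counts))
            raise QuantError(f"sampling volume {empty} contains no nuclei")


def _polyline_arclength(path: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def path_profile(records: pd.DataFrame, path, volume_size: float,
                 n_volumes: int = 7) -> PathProfile:
    """Average normalised Sox2 and Bra in volumes spaced along a path.

    ``path`` is an ordered polyline (posterior first) in 2D or 3D, µm. The
    path is divided into ``n_volumes`` equal-arclength segments; each
    segment's midpoint is a volume centre. Every nucleus within
    ``volume_size`` (µm, a radius) of its nearest centre is assigned to that
    volume. Volumes are equal-geometry, so per-volume counts reflect the
    local cell density, not a balancing rule.
    """
    path = np.asarray(path, dtype=float)
    if path.ndim != 2 or len(path) < 2:
        raise QuantError("path must be a polyline of >= 2 points")
    ndim = path.shape[1]
    if "sox2_norm" not in records.columns:
        records, _ = normalize_to_dapi(records)

    s = _polyline_arclength(path)
    total = s[-1]
    mid_s = (np.arange(n_volumes) + 0.5) * total / n_volumes
    centers = np.column_stack(
        [np.interp(mid_s, s, path[:, d]) for d in range(ndim)])

    cols = ["x_um", "y_um", "z_um"][:ndim]
    pts = records[cols].to_numpy()
    d2 = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    nearest = np.argmin(d2, axis=1)
    within = np.sqrt(d2[np.arange(len(pts)), nearest]) <= volume_size

    sox2 = np.zeros(n_volumes)
    bra = np.zeros(n_volumes)
    counts = np.zeros(n_volumes, dtype=int)
    for v in range(n_volumes):
        sel = within & (nearest == v)
        counts[v] = int(sel.sum())
        if counts[v]:
            sox2[v] = records.loc[sel, "sox2_norm"].mean()
            bra[v] = records.loc[sel, "bra_norm"].mean()
    return PathProfile(centers=centers, sox2_mean=sox2, bra_mean=bra,
                       counts=counts)


def signed_fold_change(profile_means, from_index: int, to_index: int) -> float:
    """Fold change with the +f / -1/f sign convention.

    The plain ratio f = mean[to] / mean[from] is reported as +f when the
    level rises (f >= 1) and as -1/f when it falls, so a halving reads -2.0
    and signed_fold_change(a, b) == -signed_fold_change(b, a) off unity.
    """
    means = np.asarray(profile_means, dtype=float)
    a, b = means[from_index], means[to_index]
    if a <= 0 or b <= 0:
        raise QuantError("fold change requires positive means")
    f = b / a
    return float(f if f >= 1.0 else -1.0 / f)


def transverse_section_map(records: pd.DataFrame, y_center: float,
                           thickness: float = 40.0) -> pd.DataFrame:
    """Digital transverse section: nuclei with |y - y_center| <= thickness/2.

    Returns (x_um, z_um, ratio) per in-slab nucleus for section rendering;
    an empty slab returns an empty frame with ``attrs['empty'] = True``.
    """
    if thickness <= 0:
        raise QuantError("thickness must be positive")
    if "sox2_norm" not in records.columns:
        records, _ = normalize_to_dapi(records)
    sel = (records["y_um"] - y_center).abs() <= thickness / 2.0
    slab = records[sel]
    ratio, _ = sox2_bra_ratio(slab) if len(slab) else (pd.Series(dtype=float), 0)
    out = slab.loc[ratio.index, ["x_um", "z_um"]].copy()
    out["ratio"] = ratio
    out.attrs["empty"] = len(out) == 0
    return out.reset_index(drop=True)
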