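"""Synthetic inputs for the analysis stages.

Two generators, both fully deterministic under a fixed seed:

* nucleus tables — per-tissue Sox2 / Bra / DAPI intensities with
  configurable cell-to-cell variability. The progenitor zone (PZ) is highly
  heterogeneous with an anterior-Sox2 / posterior-Bra enrichment; NT and
  PSM are homogeneous and polarised (Sox2-high resp. Bra-high). Intensities
  are log-normal (fluorescence is positive and right-skewed) and all
  channels share an exponential depth attenuation in z, so DAPI
  normalisation has real work to do.

* trajectory tables — per-tissue drift + diffusion random walks emulating a
  common posterior tissue flow with tissue-specific local motility.

CV targets are in percent and refer to the DAPI-normalised channel. The
generator discounts the variance contributed by the spatial gradient and by
DAPI noise (the (1 + cv^2) factors of independent log-normals multiply
exactly), so the configured target is what the analysis pipeline measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tracks import TrackTable

TISSUES = ("PZ", "NT", "PSM")


class GeneratorError(ValueError):
    pass


def _default_nucleus_params() -> dict:
    return {
        # means are arbitrary fluorescence units; cv in percent
        "PZ": dict(n=1000, sox2_mean=1.0, bra_mean=1.0, dapi_mean=1.0,
                   sox2_cv=41.8, bra_cv=30.75, dapi_cv=10.0),
        # means put the tissue ratios on the depicted 0-2 scale:
        # NT ~ 1.8 (Sox2-high), PSM ~ 0.11 (Bra-high), PZ ~ 1 and broad
        "NT": dict(n=600, sox2_mean=1.8, bra_mean=1.0, dapi_mean=1.0,
                   sox2_cv=10.0, bra_cv=10.0, dapi_cv=5.0),
        "PSM": dict(n=800, sox2_mean=0.2, bra_mean=1.8, dapi_mean=1.0,
                    sox2_cv=10.0, bra_cv=10.0, dapi_cv=5.0),
    }


def _default_regions() -> dict:
    # ((x0,x1),(y0,y1),(z0,z1)) in µm; y increases posteriorly
    return {
        "NT": ((-75.0, 75.0), (0.0, 600.0), (0.0, 60.0)),
        "PSM": ((75.0, 270.0), (0.0, 600.0), (0.0, 60.0)),
        "PZ": ((-270.0, 270.0), (600.0, 825.0), (0.0, 60.0)),
    }


def _default_track_params() -> dict:
    # drift in µm/h (posterior = +y), diffusion in µm²/h
    return {
        "PZ": dict(n_tracks=100, drift=(0.0, 30.0), diffusion=50.0),
        "NT": dict(n_tracks=100, drift=(0.0, 10.0), diffusion=10.0),
        "PSM": dict(n_tracks=100, drift=(0.0, 15.0), diffusion=45.0),
    }


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic nucleus and track generators.

    ``pz_sox2_gradient`` / ``pz_bra_gradient`` are fractional amplitudes of
    the linear antero-posterior modulation of the PZ means: amplitude a
    scales the mean by (1 + a) at the anterior PZ edge down to (1 - a) at
    the posterior edge (so Sox2 uses a > 0, Bra a < 0).
    """

    seed: int = 0
    nucleus_params: dict = field(default_factory=_default_nucleus_params)
    regions: dict = field(default_factory=_default_regions)
    pz_sox2_gradient: float = 0.25
    pz_bra_gradient: float = -0.25
    depth_attenuation_um: float = 120.0  # e-folding depth of all channels
    track_params: dict = field(default_factory=_default_track_params)
    n_frames: int = 100
    frame_interval: float = 0.1  # hours

    def validate(self) -> None:
        for tis, p in self.nucleus_params.items():
            if p["n"] <= 0:
                raise GeneratorError(f"{tis}: nucleus count must be positive")
            for k in ("sox2_cv", "bra_cv", "dapi_cv"):
                if p[k] < 0:
                    raise GeneratorError(f"{tis}: {k} must be >= 0")
        for tis, p in self.track_params.items():
            if p["n_tracks"] <= 0 or p["diffusion"] < 0:
                raise GeneratorError(f"{tis}: bad track parameters")
        if self.frame_interval <= 0:
            raise GeneratorError("frame_interval must be positive")
        if self.n_frames < 2:
            raise GeneratorError("need at least 2 frames")


def _lognormal(rng, mean: float, cv_frac: float, n: int) -> np.ndarray:
    """Log-normal samples with exact mean and coefficient of variation."""
    if cv_frac <= 0:
        return np.full(n, mean)
    s2 = np.log1p(cv_frac ** 2)
    mu = np.log(mean) - s2 / 2.0
    return rng.lognormal(mu, np.sqrt(s2), n)


def _discounted_cv(target_pct: float, *other_cv_fracs: float) -> float:
    """Per-cell CV (fraction) so the product's CV hits the target.

    For independent positive factors the (1 + cv^2) terms multiply; the
    per-cell term absorbs whatever the other factors do not contribute.
    Returns 0 when the other factors already exceed the target.
    """
    target = target_pct / 100.0
    budget = (1.0 + target ** 2)
    for cv in other_cv_fracs:
        budget /= (1.0 + cv ** 2)
    return float(np.sqrt(max(budget - 1.0, 0.0)))


def generate_nucleus_table(config: GeneratorConfig,
                           rng: np.random.Generator | None = None
                           ) -> pd.DataFrame:
    """Synthetic per-nucleus intensity table for all three tissues."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    frames = []
    next_id = 0
    for tissue in TISSUES:
        p = config.nucleus_params[tissue]
        (x0, x1), (y0, y1), (z0, z1) = config.regions[tissue]
        n = p["n"]
        x = rng.uniform(x0, x1, n)
        y = rng.uniform(y0, y1, n)
        z = rng.uniform(z0, z1, n)

        g_sox2 = np.ones(n)
        g_bra = np.ones(n)
        if tissue == "PZ":
            frac = (y - y0) / max(y1 - y0, 1e-12)  # 0 anterior -> 1 posterior
            g_sox2 = 1.0 + config.pz_sox2_gradient * (1.0 - 2.0 * frac)
            g_bra = 1.0 + config.pz_bra_gradient * (1.0 - 2.0 * frac)
        cv_d = p["dapi_cv"] / 100.0
        cv_sox2 = _discounted_cv(p["sox2_cv"], _cv_of(g_sox2), cv_d)
        cv_bra = _discounted_cv(p["bra_cv"], _cv_of(g_bra), cv_d)

        sox2 = g_sox2 * _lognormal(rng, p["sox2_mean"], cv_sox2, n)
        bra = g_bra * _lognormal(rng, p["bra_mean"], cv_bra, n)
        dapi = _lognormal(rng, p["dapi_mean"], cv_d, n)
        atten = np.exp(-z / config.depth_attenuation_um)

        frames.append(pd.DataFrame({
            "id": np.arange(next_id, next_id + n),
            "x_um": x, "y_um": y, "z_um": z,
            "sox2": sox2 * atten, "bra": bra * atten, "dapi": dapi * atten,
            "tissue": tissue,
        }))
        next_id += n
    return pd.concat(frames, ignore_index=True)


def _cv_of(values: np.ndarray) -> float:
    m = values.mean()
    return float(values.std() / m) if m > 0 and len(values) > 1 else 0.0


def generate_tracks(config: GeneratorConfig,
                    rng: np.random.Generator | None = None) -> TrackTable:
    """Synthetic drift + diffusion trajectories per tissue.

    Each step is drift * dt plus a Gaussian with per-axis variance 2 D dt,
    so the time-averaged MSD of a drift-free tissue recovers 4 D tau.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    dt = config.frame_interval
    rows = []
    next_id = 0
    for tissue in TISSUES:
        p = config.track_params[tissue]
        (x0, x1), (y0, y1), _ = config.regions[tissue]
        n, nf = p["n_tracks"], config.n_frames
        start = np.column_stack(
            [rng.uniform(x0, x1, n), rng.uniform(y0, y1, n)])
        drift = np.asarray(p["drift"], dtype=float) * dt
        noise = rng.normal(0.0, np.sqrt(2.0 * p["diffusion"] * dt),
                           size=(n, nf - 1, 2))
        steps = noise + drift
        pos = np.concatenate(
            [start[:, None, :], start[:, None, :] + np.cumsum(steps, axis=1)],
            axis=1)
        tids = np.repeat(np.arange(next_id, next_id + n), nf)
        frames = np.tile(np.arange(nf), n)
        rows.append(pd.DataFrame({
            "track_id": tids,
            "frame": frames,
            "t_hours": frames * dt,
            "x_um": pos[:, :, 0].ravel(),
            "y_um": pos[:, :, 1].ravel(),
            "tissue": tissue,
        }))
        next_id += n
    return TrackTable(pd.concat(rows, ignore_index=True), frame_interval=dt)
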