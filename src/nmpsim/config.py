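"""Simulation configuration.

All model parameters live in :class:`SimConfig`. Speeds and interaction radii
are expressed in micrometres (per hour), positions in model units
(1 unit = ``unit_scale_um`` µm, 150 µm by default); times in hours.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import yaml

FATES = ("progenitor", "NT", "PSM")
REGIMES = ("random", "gradient", "mixed")
DEREGULATIONS = ("none", "bra_high", "sox2_high")


class ConfigError(ValueError):
    """Raised when a configuration violates a model constraint."""


def _default_adhesion() -> dict[str, float]:
    # Only the NT-NT > PSM-PSM ordering is biologically constrained;
    # cross-fate attraction is zero (non-mixing handled by cross repulsion).
    return {
        "progenitor-progenitor": 0.5,
        "NT-NT": 1.0,
        "PSM-PSM": 0.4,
        "progenitor-NT": 0.0,
        "progenitor-PSM": 0.0,
        "NT-PSM": 0.0,
    }


@dataclass
class SimConfig:
    """Parameters of the posterior-body agent model.

    Attributes
    ----------
    dt : float
        Integration step in hours (default 0.1 h = 6 min, the live-imaging
        cadence).
    total_time : float
        Simulated duration in hours.
    theta_low, theta_high : float
        Sox2/Bra ratio thresholds on the 0-2 scale: a progenitor crossing
        below ``theta_low`` commits to PSM, above ``theta_high`` to NT.
    ratio_noise_sigma : float
        Noise amplitude of the ratio SDE, per sqrt(hour).
    ratio_relaxation_kappa : float
        Drift (mean-reversion) rate of the ratio SDE, per hour.
    v_high, v_mid, v_low : float
        Motility speeds in µm/h for Bra-high / undetermined / Sox2-high
        cells respectively.
    adhesion : dict
        Symmetric fate-pair attraction strengths (dimensionless weights).
    cross_repulsion : float
        Weight of the cross-fate repulsive term implementing non-mixing.
    adhesion_speed, core_repulsion_speed : float
        Velocity scales (µm/h) of the attraction and hard-core bias terms.
    r_core, r_adh, r_pack : float
        Interaction radii in µm: hard-core exclusion, adhesion range,
        packing (density-count) range.
    n_max : int
        Maximum neighbour count within ``r_pack`` tolerated after a move.
    doubling_times : dict
        Per-fate population doubling times in hours.
    initial_counts : dict
        Cells per fate at t = 0 (before ``population_scale``).
    initial_ratio_range : tuple
        Interval of initial progenitor ratios in the random regime, on the
        0-2 scale.
    regime : str
        Spatial organisation of progenitor ratios: ``random`` (no spatial
        structure), ``gradient`` (strict anterior-Sox2 / posterior-Bra
        grading), ``mixed`` (gradient plus per-cell randomness).
    deregulation : str
        ``none``, ``bra_high`` or ``sox2_high``: forces the SDE anchor of a
        fraction of progenitors across the corresponding threshold.
    population_scale : float
        Scales initial counts and region areas together, preserving number
        density, for cheap replicate runs.
    """

    dt: float = 0.1
    total_time: float = 10.0
    theta_low: float = 0.4
    theta_high: float = 1.6
    ratio_noise_sigma: float = 0.25
    ratio_relaxation_kappa: float = 1.0
    v_high: float = 60.0
    v_mid: float = 36.0
    v_low: float = 12.0
    # "linear": speed falls linearly from v_high at theta_low to v_low at
    # theta_high (v_mid at the band centre); "step": flat v_mid in the band.
    motility_profile: str = "linear"
    adhesion: dict[str, float] = field(default_factory=_default_adhesion)
    cross_repulsion: float = 8.0
    adhesion_speed: float = 5.0
    core_repulsion_speed: float = 240.0
    r_core: float = 10.0
    r_adh: float = 30.0
    r_pack: float = 20.0
    n_max: int = 18
    doubling_times: dict[str, float] = field(
        default_factory=lambda: {"progenitor": 11.49, "NT": 10.83, "PSM": 8.75}
    )
    initial_counts: dict[str, int] = field(
        default_factory=lambda: {"progenitor": 1100, "NT": 1200, "PSM": 3200}
    )
    initial_ratio_range: tuple[float, float] = (0.3, 1.7)
    regime: str = "mixed"
    deregulation: str = "none"
    deregulated_fraction: float = 1.0
    deregulated_anchor_low: float = 0.2
    deregulated_anchor_high: float = 1.8
    gradient_mu_anterior: float = 1.7
    gradient_mu_posterior: float = 0.3
    mixed_offset: float = 0.35
    # Regime anchors are clipped to [theta_low + margin, theta_high - margin]
    # so commitment is always noise-driven threshold crossing, never a
    # deterministic drift across the threshold (deregulation excepted).
    anchor_margin: float = 0.05
    # The random regime draws anchors uniformly over the whole band, so its
    # edge-anchored cells sit permanently near a threshold; a deeper buffer
    # keeps its progenitor pool stable under the same noise calibration.
    anchor_margin_random: float = 0.15
    motility_enabled: bool = True
    interactions_enabled: bool = True
    ratio_updates_enabled: bool = True
    proliferation_enabled: bool = True
    seed: int = 0
    snapshot_interval: float = 0.1
    population_scale: float = 1.0
    # Geometry (model units). The PZ sits centred posterior to NT and PSM,
    # narrower than the full body width so it can remodel medio-laterally.
    unit_scale_um: float = 150.0
    nt_width: float = 1.0
    nt_length: float = 4.0
    psm_width: float = 1.3
    psm_length: float = 4.0
    pz_width: float = 2.4
    pz_length: float = 2.25

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.theta_low < self.theta_high:
            raise ConfigError("theta_low must be < theta_high")
        if not self.v_low <= self.v_mid <= self.v_high:
            raise ConfigError("motility speeds must satisfy v_low <= v_mid <= v_high")
        if self.adhesion["NT-NT"] <= self.adhesion["PSM-PSM"]:
            raise ConfigError("NT-NT adhesion must exceed PSM-PSM adhesion")
        for name in ("dt", "total_time", "r_core", "r_adh", "r_pack",
                     "unit_scale_um", "nt_width", "nt_length", "psm_width",
                     "psm_length", "pz_width", "pz_length", "population_scale"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for fate, t in self.doubling_times.items():
            if t <= 0:
                raise ConfigError(f"doubling time for {fate} must be positive")
        for fate, n in self.initial_counts.items():
            if n < 0:
                raise ConfigError(f"initial count for {fate} must be >= 0")
        if self.regime not in REGIMES:
            raise ConfigError(f"unknown regime {self.regime!r}")
        if self.deregulation not in DEREGULATIONS:
            raise ConfigError(f"unknown deregulation {self.deregulation!r}")
        if not 0.0 <= self.deregulated_fraction <= 1.0:
            raise ConfigError("deregulated_fraction must lie in [0, 1]")
        lo, hi = self.initial_ratio_range
        if not (0.0 <= lo <= hi <= 2.0):
            raise ConfigError("initial_ratio_range must lie within [0, 2]")

    # -- fate-pair helpers -------------------------------------------------
    def adhesion_value(self, fate_a: str, fate_b: str) -> float:
        key = f"{fate_a}-{fate_b}"
        if key in self.adhesion:
            return self.adhesion[key]
        return self.adhesion[f"{fate_b}-{fate_a}"]

    def adhesion_matrix(self) -> np.ndarray:
        """3x3 symmetric attraction matrix indexed by FATES order."""
        m = np.zeros((3, 3))
        for i, a in enumerate(FATES):
            for j, b in enumerate(FATES):
                m[i, j] = self.adhesion_value(a, b)
        return m

    def scaled_counts(self) -> dict[str, int]:
        return {f: int(round(n * self.population_scale))
                for f, n in self.initial_counts.items()}

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["initial_ratio_range"] = list(self.initial_ratio_range)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimConfig":
        d = dict(d)
        if "initial_ratio_range" in d:
            d["initial_ratio_range"] = tuple(d["initial_ratio_range"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)
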