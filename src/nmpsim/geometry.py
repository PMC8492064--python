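"""Domain layout of the 2D posterior body.

Coordinate convention: the origin sits at the medial point of the anterior
wall, x increases rightward (medio-lateral), y increases posteriorly, so a
posterior displacement is a positive y increment. The neural tube (NT) runs
medially, flanked by two presomitic-mesoderm (PSM) columns; the progenitor
zone (PZ) caps them posteriorly. The anterior boundary (dense somitic /
neuroepithelial tissue) and the lateral boundaries (lateral plate) are
blocked; the posterior edge is open, which is where the tissue elongates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ConfigError, SimConfig


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle (model units): [x0, x1] x [y0, y1]."""

    x0: float
    x1: float
    y0: float
    y1: float

    def contains(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= self.x0) & (x <= self.x1) & (y >= self.y0) & (y <= self.y1)

    @property
    def width(self) -> float:
        return self.x1 - self.x0

    @property
    def height(self) -> float:
        return self.y1 - self.y0

    @property
    def area(self) -> float:
        return self.width * self.height


@dataclass(frozen=True)
class DomainLayout:
    """Static geometry of the simulated posterior body.

    Region rectangles describe tissue extents at t = 0 only; as the tissue
    elongates, region membership follows the cells (their fate labels), not
    these rectangles.
    """

    unit_scale: float  # µm per model unit
    anterior_wall_y: float
    lateral_wall_x_left: float
    lateral_wall_x_right: float
    nt: Rect
    psm_left: Rect
    psm_right: Rect
    pz: Rect
    posterior_open: bool = True
    regions: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "regions",
            {"NT": self.nt, "PSM_left": self.psm_left,
             "PSM_right": self.psm_right, "PZ": self.pz},
        )
        self._check()

    def _check(self) -> None:
        if self.unit_scale <= 0:
            raise ConfigError("unit_scale must be positive")
        if not (self.psm_left.x1 <= self.nt.x0 and self.nt.x1 <= self.psm_right.x0):
            raise ConfigError("NT must lie strictly between the PSM columns")
        for name, r in self.regions.items():
            if r.x0 < self.lateral_wall_x_left - 1e-9 or r.x1 > self.lateral_wall_x_right + 1e-9:
                raise ConfigError(f"region {name} exceeds the lateral walls")
            if r.y0 < self.anterior_wall_y - 1e-9:
                raise ConfigError(f"region {name} crosses the anterior wall")
        for name in ("NT", "PSM_left", "PSM_right"):
            if self.pz.y0 < self.regions[name].y1 - 1e-9:
                raise ConfigError("PZ must be posterior to NT and PSM")

    # -- unit conversion ---------------------------------------------------
    def to_um(self, value_units):
        """Convert model-unit lengths/coordinates to µm (exactly linear)."""
        return np.asarray(value_units, dtype=float) * self.unit_scale

    def to_units(self, value_um):
        return np.asarray(value_um, dtype=float) / self.unit_scale

    def region_rect(self, fate: str, side: str | None = None) -> Rect:
        if fate == "PSM":
            return self.psm_left if side == "left" else self.psm_right
        return self.regions["NT" if fate == "NT" else "PZ"]


def build_default_layout(config: SimConfig) -> DomainLayout:
    """Construct the t = 0 layout from the configured dimensions.

    ``population_scale`` shrinks both axes of every region by sqrt(scale) so
    number densities are preserved when initial counts are scaled down.
    """
    s = float(np.sqrt(config.population_scale))
    nt_w = config.nt_width * s
    nt_l = config.nt_length * s
    psm_w = config.psm_width * s
    psm_l = config.psm_length * s
    pz_w = config.pz_width * s
    pz_l = config.pz_length * s

    half_nt = nt_w / 2.0
    wall = half_nt + psm_w
    nt = Rect(-half_nt, half_nt, 0.0, nt_l)
    psm_left = Rect(-wall, -half_nt, 0.0, psm_l)
    psm_right = Rect(half_nt, wall, 0.0, psm_l)
    pz_y0 = max(nt_l, psm_l)
    half_pz = min(pz_w / 2.0, wall)
    pz = Rect(-half_pz, half_pz, pz_y0, pz_y0 + pz_l)
    return DomainLayout(
        unit_scale=config.unit_scale_um,
        anterior_wall_y=0.0,
        lateral_wall_x_left=-wall,
        lateral_wall_x_right=wall,
        nt=nt,
        psm_left=psm_left,
        psm_right=psm_right,
        pz=pz,
    )


def region_of(point, layout: DomainLayout, tissue_state_map=None) -> str:
    """Label a point as NT | PSM | PZ | anterior_block | outside.

    With no occupancy information the t = 0 rectangles are used. A
    ``tissue_state_map`` of ``(x, y, fate_label)`` arrays reassigns the
    moving tissue fronts: the label of the nearest cell wins, so regions
    follow the cells as the body elongates.
    """
    x, y = float(point[0]), float(point[1])
    if y < layout.anterior_wall_y:
        return "anterior_block"
    if x < layout.lateral_wall_x_left or x > layout.lateral_wall_x_right:
        return "outside"
    if tissue_state_map is not None:
        cx, cy, labels = tissue_state_map
        cx = np.asarray(cx, dtype=float)
        if cx.size:
            d2 = (cx - x) ** 2 + (np.asarray(cy, dtype=float) - y) ** 2
            lab = str(np.asarray(labels)[np.argmin(d2)])
            return {"progenitor": "PZ"}.get(lab, lab)
    # t=0 rectangles; precedence is irrelevant because interiors are disjoint
    if layout.pz.contains(x, y):
        return "PZ"
    if layout.nt.contains(x, y):
        return "NT"
    if layout.psm_left.contains(x, y) or layout.psm_right.contains(x, y):
        return "PSM"
    return "outside"
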