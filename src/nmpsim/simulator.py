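"""Agent-based model of posterior body elongation.

Each cell carries a Sox2-to-Bra ratio R(t) on a 0-2 scale, a fate state
(progenitor / NT / PSM) and a 2D position. Progenitor ratios follow a
mean-reverting stochastic differential equation; noise drives some cells
below 0.4 (irreversible commitment to PSM) or above 1.6 (commitment to NT).
The ratio sets motility (Bra-high fast, Sox2-high slow); positions evolve by
a biased random walk whose bias encodes adhesion, hard-core exclusion,
cross-fate repulsion (non-mixing) and a local density cap. Each fate divides
with its own doubling time. The anterior and lateral boundaries are blocked,
so proliferation can only push tissue posteriorly — the elongation readout.

The per-step ratio update is an Euler-Maruyama discretisation of an
Ornstein-Uhlenbeck process, dR = -kappa (R - mu) dt + sigma dW, clipped to
[0, 2]. The anchor mu encodes the regime: a per-cell value drawn uniformly
at birth with no spatial structure (random), a linear anterior-to-posterior
gradient from 1.7 to 0.3 across the current progenitor span (gradient), or
that gradient plus a per-cell offset drawn uniformly in +-0.35 at birth
(mixed). Anchors are compressed to sit strictly inside the undetermined
band, so commitment is always a noise-driven threshold crossing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .config import FATES, ConfigError, SimConfig
from .geometry import DomainLayout, build_default_layout

PROG, NT, PSM = 0, 1, 2
FATE_CODES = {"progenitor": PROG, "NT": NT, "PSM": PSM}
FATE_NAMES = {v: k for k, v in FATE_CODES.items()}


class Population:
    """Vectorised cell state: one row per cell, numpy columns."""

    __slots__ = ("ids", "parent", "state", "ratio", "x", "y", "birth_time",
                 "anchor_offset", "deregulated", "_next_id")

    def __init__(self, ids, parent, state, ratio, x, y, birth_time,
                 anchor_offset, deregulated):
        self.ids = np.asarray(ids, dtype=np.int64)
        self.parent = np.asarray(parent, dtype=np.int64)
        self.state = np.asarray(state, dtype=np.int8)
        self.ratio = np.asarray(ratio, dtype=float)
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.birth_time = np.asarray(birth_time, dtype=float)
        self.anchor_offset = np.asarray(anchor_offset, dtype=float)
        self.deregulated = np.asarray(deregulated, dtype=bool)
        self._next_id = int(self.ids.max()) + 1 if len(self.ids) else 0

    def __len__(self) -> int:
        return len(self.ids)

    def append(self, **cols) -> None:
        n = len(cols["x"])
        new_ids = np.arange(self._next_id, self._next_id + n, dtype=np.int64)
        self._next_id += n
        self.ids = np.concatenate([self.ids, new_ids])
        for name in ("parent", "state", "ratio", "x", "y", "birth_time",
                     "anchor_offset", "deregulated"):
            setattr(self, name, np.concatenate([getattr(self, name), cols[name]]))

    def snapshot(self, time: float) -> pd.DataFrame:
        return pd.DataFrame({
            "time_h": np.full(len(self), time),
            "cell_id": self.ids.copy(),
            "parent_id": self.parent.copy(),
            "state": pd.Categorical.from_codes(self.state, list(FATES)),
            "ratio": self.ratio.copy(),
            "x_unit": self.x.copy(),
            "y_unit": self.y.copy(),
        })


@dataclass
class SwitchEvent:
    """Record of one irreversible fate commitment."""

    time: float
    cell_id: int
    new_state: str
    ratio_at_switch: float


@dataclass
class SimResult:
    """Output of one simulation run."""

    config: SimConfig
    layout: DomainLayout
    snapshots: list[pd.DataFrame]
    snapshot_times: list[float]
    switch_events: list[SwitchEvent]
    rng_seed: int
    counts: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        rows = []
        for t, snap in zip(self.snapshot_times, self.snapshots):
            c = snap["state"].value_counts()
            rows.append({"time_h": t, **{f: int(c.get(f, 0)) for f in FATES}})
        self.counts = pd.DataFrame(rows)

    def to_tracks(self):
        """Flatten snapshots into a TrackTable (positions in µm)."""
        from .tracks import TrackTable

        frames = []
        for i, (t, snap) in enumerate(zip(self.snapshot_times, self.snapshots)):
            frames.append(pd.DataFrame({
                "track_id": snap["cell_id"].to_numpy(),
                "frame": i,
                "t_hours": t,
                "x_um": snap["x_unit"].to_numpy() * self.layout.unit_scale,
                "y_um": snap["y_unit"].to_numpy() * self.layout.unit_scale,
                "tissue": snap["state"].astype(str).to_numpy(),
            }))
        df = pd.concat(frames, ignore_index=True)
        interval = (self.snapshot_times[1] - self.snapshot_times[0]
                    if len(self.snapshot_times) > 1 else self.config.dt)
        # keep only cells present from the first snapshot so tracks are gap-free
        first = set(self.snapshots[0]["cell_id"])
        df = df[df["track_id"].isin(first)].reset_index(drop=True)
        return TrackTable(df, frame_interval=interval)


# ---------------------------------------------------------------------------
# initialization


def _anchor_band_scale(config: SimConfig) -> float:
    """Factor squeezing the natural anchor range into the undetermined band.

    Nominal anchors span the gradient from ``gradient_mu_anterior`` to
    ``gradient_mu_posterior`` (plus the per-cell offset in the mixed
    regime), or the configured initial ratio range in the random regime.
    Anchors are compressed about the band centre so they stay at least
    ``anchor_margin`` inside the thresholds: commitment is then always a
    noise-driven threshold crossing, never deterministic drift across it.
    """
    if config.regime == "random":
        lo, hi = config.initial_ratio_range
        half_nat = (hi - lo) / 2.0
        margin = config.anchor_margin_random
    else:
        half_nat = abs(config.gradient_mu_anterior
                       - config.gradient_mu_posterior) / 2.0
        if config.regime == "mixed":
            half_nat += config.mixed_offset
        margin = config.anchor_margin
    half_band = (config.theta_high - config.theta_low) / 2.0 - margin
    if half_nat <= half_band or half_nat == 0.0:
        return 1.0
    return half_band / half_nat


def _offset_half_width(config: SimConfig) -> float:
    """Half-width of the per-cell anchor offset drawn at birth (natural scale).

    The random regime gives every cell its own anchor spanning the whole
    configured ratio range — spatial randomness with no positional
    structure — while the mixed regime adds a bounded offset on top of the
    positional gradient. The gradient regime is purely positional.
    """
    if config.regime == "random":
        lo, hi = config.initial_ratio_range
        return (hi - lo) / 2.0
    if config.regime == "mixed":
        return config.mixed_offset
    return 0.0


def _anchor_mu(pop: Population, config: SimConfig) -> np.ndarray:
    """Per-progenitor SDE anchor for the active regime and deregulation."""
    prog = pop.state == PROG
    mu = np.full(len(pop), 1.0)
    center = (config.theta_low + config.theta_high) / 2.0
    if prog.any():
        if config.regime == "random":
            nat = center + pop.anchor_offset[prog]
        else:
            ys = pop.y[prog]
            y_lo, y_hi = np.percentile(ys, [5.0, 95.0])
            if y_hi - y_lo < 1e-9:
                frac = np.full(ys.shape, 0.5)
            else:
                frac = np.clip((ys - y_lo) / (y_hi - y_lo), 0.0, 1.0)
            nat = config.gradient_mu_anterior + frac * (
                config.gradient_mu_posterior - config.gradient_mu_anterior)
            if config.regime == "mixed":
                nat = nat + pop.anchor_offset[prog]
        mu[prog] = center + (nat - center) * _anchor_band_scale(config)
    if config.deregulation != "none":
        target = (config.deregulated_anchor_low if config.deregulation == "bra_high"
                  else config.deregulated_anchor_high)
        sel = prog & pop.deregulated
        mu[sel] = target
    return np.clip(mu, 0.0, 2.0)


def initialize_population(config: SimConfig, layout: DomainLayout,
                          rng: np.random.Generator) -> Population:
    """Place the initial cells uniformly in their t = 0 regions.

    Progenitor ratios are drawn per regime; NT and PSM cells start at fixed
    ratios 1.9 and 0.1 (beyond their thresholds). The PSM count is split
    evenly between the two columns.
    """
    counts = config.scaled_counts()
    area_per_cell = {}
    for fate, rect_names in (("progenitor", ["PZ"]), ("NT", ["NT"]),
                             ("PSM", ["PSM_left", "PSM_right"])):
        area = sum(layout.regions[r].area for r in rect_names)
        n = counts[fate]
        if n > 0:
            density_um2 = n / (area * layout.unit_scale ** 2)
            expected_neighbors = density_um2 * np.pi * config.r_pack ** 2
            # the cap may bind at t=0 (growth pressure is the point), but a
            # region far beyond it cannot be initialised sensibly
            if expected_neighbors > 1.5 * config.n_max:
                raise ConfigError(
                    f"{fate} region too small: initial density exceeds the "
                    f"n_max/r_pack packing cap")
        area_per_cell[fate] = area

    xs, ys, states, ratios, offsets = [], [], [], [], []

    def _uniform(rect, n):
        return (rng.uniform(rect.x0, rect.x1, n), rng.uniform(rect.y0, rect.y1, n))

    # progenitors in the PZ
    n_p = counts["progenitor"]
    px, py = _uniform(layout.pz, n_p)
    lo, hi = config.initial_ratio_range
    center = (config.theta_low + config.theta_high) / 2.0
    if config.regime == "random":
        r = rng.uniform(lo, hi, n_p)
        off = r - center  # each cell's anchor IS its randomly drawn value
    else:
        frac = (py - layout.pz.y0) / max(layout.pz.height, 1e-12)
        r = config.gradient_mu_anterior + frac * (
            config.gradient_mu_posterior - config.gradient_mu_anterior)
        off = np.zeros(n_p)
        if config.regime == "mixed":
            off = rng.uniform(-config.mixed_offset, config.mixed_offset, n_p)
            r = r + off
    # every progenitor starts at its own anchor, compressed into the
    # undetermined band exactly like the SDE drift anchor
    r = center + (r - center) * _anchor_band_scale(config)
    xs.append(px); ys.append(py)
    states.append(np.full(n_p, PROG, dtype=np.int8))
    ratios.append(np.clip(r, 0.0, 2.0))
    offsets.append(off)

    # NT
    n_nt = counts["NT"]
    tx, ty = _uniform(layout.nt, n_nt)
    xs.append(tx); ys.append(ty)
    states.append(np.full(n_nt, NT, dtype=np.int8))
    ratios.append(np.full(n_nt, 1.9))
    offsets.append(np.zeros(n_nt))

    # PSM, half per column
    n_m = counts["PSM"]
    n_left = n_m // 2
    for rect, n in ((layout.psm_left, n_left), (layout.psm_right, n_m - n_left)):
        mx, my = _uniform(rect, n)
        xs.append(mx); ys.append(my)
        states.append(np.full(n, PSM, dtype=np.int8))
        ratios.append(np.full(n, 0.1))
        offsets.append(np.zeros(n))

    n_total = sum(len(a) for a in xs)
    pop = Population(
        ids=np.arange(n_total),
        parent=np.full(n_total, -1),
        state=np.concatenate(states),
        ratio=np.concatenate(ratios),
        x=np.concatenate(xs),
        y=np.concatenate(ys),
        birth_time=np.zeros(n_total),
        anchor_offset=np.concatenate(offsets),
        deregulated=np.zeros(n_total, dtype=bool),
    )
    if config.deregulation != "none" and config.deregulated_fraction > 0:
        prog_idx = np.flatnonzero(pop.state == PROG)
        k = int(round(config.deregulated_fraction * len(prog_idx)))
        chosen = rng.choice(prog_idx, size=k, replace=False)
        pop.deregulated[chosen] = True
    return pop


# ---------------------------------------------------------------------------
# per-step operations


def update_ratio(pop: Population, config: SimConfig, dt: float,
                 rng: np.random.Generator) -> None:
    """One Euler-Maruyama step of the ratio SDE, in place.

    Progenitors revert to their regime anchor with additive noise; committed
    NT / PSM cells relax deterministically toward 2 / 0 at the same rate.
    """
    kappa = config.ratio_relaxation_kappa
    sigma = config.ratio_noise_sigma
    mu = _anchor_mu(pop, config)
    prog = pop.state == PROG
    noise = np.zeros(len(pop))
    noise[prog] = sigma * np.sqrt(dt) * rng.standard_normal(int(prog.sum()))
    target = np.where(prog, mu, np.where(pop.state == NT, 2.0, 0.0))
    pop.ratio += -kappa * (pop.ratio - target) * dt + noise
    np.clip(pop.ratio, 0.0, 2.0, out=pop.ratio)


def specify_state(pop: Population, config: SimConfig, time: float,
                  events: list[SwitchEvent] | None = None) -> int:
    """Commit progenitors that crossed a threshold; returns number switched.

    Commitment is irreversible: only progenitors are examined, and the new
    state is PSM below ``theta_low``, NT above ``theta_high``.
    """
    prog = pop.state == PROG
    to_psm = prog & (pop.ratio < config.theta_low)
    to_nt = prog & (pop.ratio > config.theta_high)
    if events is not None:
        for idx in np.flatnonzero(to_psm):
            events.append(SwitchEvent(time, int(pop.ids[idx]), "PSM",
                                      float(pop.ratio[idx])))
        for idx in np.flatnonzero(to_nt):
            events.append(SwitchEvent(time, int(pop.ids[idx]), "NT",
                                      float(pop.ratio[idx])))
    pop.state[to_psm] = PSM
    pop.state[to_nt] = NT
    return int(to_psm.sum() + to_nt.sum())


def motility_of(ratio, state, config: SimConfig) -> np.ndarray:
    """Speed in µm/h as a non-increasing function of the Sox2/Bra ratio.

    Committed PSM cells and sub-threshold ratios move at ``v_high``,
    committed NT cells and supra-threshold ratios at ``v_low``. Inside the
    undetermined band the default ``linear`` profile interpolates from
    ``v_high`` down to ``v_low`` (passing through ``v_mid`` at the band
    centre), so heterogeneous ratios translate into heterogeneous speeds;
    the ``step`` profile returns a flat ``v_mid`` instead.
    """
    ratio = np.asarray(ratio, dtype=float)
    state = np.asarray(state)
    if config.motility_profile == "step":
        speed = np.full(ratio.shape, config.v_mid)
    else:
        frac = (ratio - config.theta_low) / (config.theta_high - config.theta_low)
        half = np.clip(frac, 0.0, 1.0)
        # two half-band segments: v_high -> v_mid -> v_low
        speed = np.where(
            half <= 0.5,
            config.v_high + (config.v_mid - config.v_high) * 2.0 * half,
            config.v_mid + (config.v_low - config.v_mid) * 2.0 * (half - 0.5))
    fast = (state == PSM) | (ratio < config.theta_low)
    slow = ((state == NT) | (ratio > config.theta_high)) & ~fast
    speed[fast] = config.v_high
    speed[slow] = config.v_low
    return speed


def _interaction_bias(pop: Population, config: SimConfig,
                      layout: DomainLayout) -> np.ndarray:
    """Per-cell bias velocity (model units / h) from pairwise interactions.

    Three terms, all pairwise and radially symmetric:
    hard-core repulsion inside r_core; linear spring attraction in
    (r_core, r_adh] weighted by the fate-pair adhesion matrix; and a
    cross-fate repulsion of the same range that keeps tissues from
    interpenetrating (non-mixing).
    """
    n = len(pop)
    bias = np.zeros((n, 2))
    if n < 2:
        return bias
    u = layout.unit_scale
    r_core = config.r_core / u
    r_adh = config.r_adh / u
    pts = np.column_stack([pop.x, pop.y])
    tree = cKDTree(pts)
    pairs = tree.query_pairs(r_adh, output_type="ndarray")
    if len(pairs) == 0:
        return bias
    i, j = pairs[:, 0], pairs[:, 1]
    dvec = pts[j] - pts[i]
    dist = np.hypot(dvec[:, 0], dvec[:, 1])
    dist = np.maximum(dist, 1e-9)
    unit = dvec / dist[:, None]

    adh = config.adhesion_matrix()
    same = pop.state[i] == pop.state[j]
    a_ij = adh[pop.state[i], pop.state[j]]

    # signed radial speed on i toward j (µm/h); negative = repulsion
    core = dist < r_core
    shell = ~core
    speed = np.zeros(len(pairs))
    speed[core] = -config.core_repulsion_speed * (1.0 - dist[core] / r_core)
    frac = (dist[shell] - r_core) / max(r_adh - r_core, 1e-12)
    attract = config.adhesion_speed * a_ij[shell] * frac
    repel = config.adhesion_speed * config.cross_repulsion * (1.0 - frac)
    speed[shell] = np.where(same[shell], attract, attract - repel)

    contrib = (speed / u)[:, None] * unit
    np.add.at(bias, i, contrib)
    np.add.at(bias, j, -contrib)
    return bias


def step_positions(pop: Population, layout: DomainLayout, config: SimConfig,
                   dt: float, rng: np.random.Generator) -> None:
    """Biased-random-motion position update with move rejection, in place.

    Candidate displacement = motility * dt * (random unit vector) + bias.
    The interaction terms are a bias OF the random motion: with motility
    disabled cells make no move attempt at all (the tissue can then only
    grow in place). A candidate is rejected — the cell stays put — if it
    crosses the anterior or a lateral wall, or if it would raise the cell's
    neighbour count within ``r_pack`` above ``n_max`` (and above its current
    count, so an over-packed region can still relax).
    """
    n = len(pop)
    if n == 0 or not config.motility_enabled:
        return
    u = layout.unit_scale
    theta = rng.uniform(0.0, 2.0 * np.pi, n)
    speed_units = motility_of(pop.ratio, pop.state, config) / u
    disp = (speed_units * dt)[:, None] * np.column_stack(
        [np.cos(theta), np.sin(theta)])
    if config.interactions_enabled:
        disp += _interaction_bias(pop, config, layout) * dt

    cand_x = pop.x + disp[:, 0]
    cand_y = pop.y + disp[:, 1]
    ok = ((cand_y >= layout.anterior_wall_y)
          & (cand_x >= layout.lateral_wall_x_left)
          & (cand_x <= layout.lateral_wall_x_right))

    if config.interactions_enabled:
        r_pack = config.r_pack / u
        pts = np.column_stack([pop.x, pop.y])
        tree = cKDTree(pts)
        cur = tree.query_ball_point(pts, r_pack, return_length=True) - 1
        cand = tree.query_ball_point(
            np.column_stack([cand_x, cand_y]), r_pack, return_length=True)
        # candidate count vs *current* tree: subtract self if still in range
        moved = np.hypot(disp[:, 0], disp[:, 1])
        cand = cand - (moved <= r_pack).astype(int)
        ok &= (cand <= config.n_max) | (cand <= cur)

    pop.x[ok] = cand_x[ok]
    pop.y[ok] = cand_y[ok]


def proliferate(pop: Population, config: SimConfig, dt: float, time: float,
                rng: np.random.Generator,
                layout: DomainLayout | None = None) -> int:
    """Stochastic division; returns the number of daughters added.

    Each cell divides with probability dt * ln2 / T_fate this step. The
    daughter inherits state and ratio, sits at distance r_core / 2 from the
    mother at a random angle (clamped inside the walls when a layout is
    given), and draws a fresh anchor offset in the mixed regime / inherits
    the mother's in the random regime.
    """
    if not config.proliferation_enabled or len(pop) == 0:
        return 0
    t_by_code = np.array([config.doubling_times[FATE_NAMES[c]] for c in range(3)])
    p = dt * np.log(2.0) / t_by_code[pop.state]
    divides = rng.random(len(pop)) < p
    k = int(divides.sum())
    if k == 0:
        return 0
    idx = np.flatnonzero(divides)
    ang = rng.uniform(0.0, 2.0 * np.pi, k)
    d = (config.r_core / config.unit_scale_um) / 2.0
    if config.regime == "random":
        # the anchor IS the cell's heritable identity in the random regime
        off = pop.anchor_offset[idx].copy()
    else:
        hw = _offset_half_width(config)
        off = rng.uniform(-hw, hw, k) if hw > 0 else np.zeros(k)
    new_x = pop.x[idx] + d * np.cos(ang)
    new_y = pop.y[idx] + d * np.sin(ang)
    if layout is not None:
        new_x = np.clip(new_x, layout.lateral_wall_x_left,
                        layout.lateral_wall_x_right)
        new_y = np.maximum(new_y, layout.anterior_wall_y)
    pop.append(
        parent=pop.ids[idx],
        state=pop.state[idx].copy(),
        ratio=pop.ratio[idx].copy(),
        x=new_x,
        y=np.maximum(new_y, 0.0),
        birth_time=np.full(k, time),
        anchor_offset=np.where(pop.state[idx] == PROG, off, 0.0),
        deregulated=pop.deregulated[idx].copy(),
    )
    return k


def apply_deregulation(config: SimConfig) -> SimConfig:
    """Validate and return the config for a deregulation experiment.

    The actual anchor shift happens inside the ratio update for flagged
    cells; this operation only checks the mode and is the hook point for
    callers that build experiment configs programmatically.
    """
    if config.deregulation not in ("none", "bra_high", "sox2_high"):
        raise ConfigError(f"unknown deregulation {config.deregulation!r}")
    return config


# ---------------------------------------------------------------------------
# driver


def run_simulation(config: SimConfig, seed: int | None = None) -> SimResult:
    """Run the model for ``total_time`` hours and collect snapshots.

    The same seed and config always reproduce the identical result: all
    randomness flows through one ``numpy.random.Generator``.
    """
    config = apply_deregulation(config)
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    layout = build_default_layout(config)
    pop = initialize_population(config, layout, rng)

    events: list[SwitchEvent] = []
    snapshots = [pop.snapshot(0.0)]
    snap_times = [0.0]
    n_steps = int(round(config.total_time / config.dt))
    snap_every = max(1, int(round(config.snapshot_interval / config.dt)))

    for step in range(1, n_steps + 1):
        t = step * config.dt
        if config.ratio_updates_enabled:
            update_ratio(pop, config, config.dt, rng)
            specify_state(pop, config, t, events)
        step_positions(pop, layout, config, config.dt, rng)
        proliferate(pop, config, config.dt, t, rng, layout)
        if step % snap_every == 0 or step == n_steps:
            snapshots.append(pop.snapshot(t))
            snap_times.append(t)

    return SimResult(config=config, layout=layout, snapshots=snapshots,
                     snapshot_times=snap_times, switch_events=events,
                     rng_seed=seed)
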