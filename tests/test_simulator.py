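import numpy as np
import pytest
from scipy import stats

from nmpsim import (ConfigError, SimConfig, build_default_layout,
                    initialize_population, motility_of, proliferate,
                    run_simulation, specify_state, step_positions, update_ratio)
from nmpsim.simulator import NT, PROG, PSM, Population


def _single_cell(state=PROG, ratio=1.0, x=0.0, y=5.0):
    return Population(ids=[0], parent=[-1], state=[state], ratio=[ratio],
                      x=[x], y=[y], birth_time=[0.0], anchor_offset=[0.0],
                      deregulated=[False])


class TestInitialization:
    def test_default_counts(self, rng):
        cfg = SimConfig()
        pop = initialize_population(cfg, build_default_layout(cfg), rng)
        counts = np.bincount(pop.state, minlength=3)
        assert counts[PROG] == 1100
        assert counts[NT] == 1200
        assert counts[PSM] == 3200

    def test_random_regime_ratio_interval(self, rng):
        cfg = SimConfig(regime="random")
        pop = initialize_population(cfg, build_default_layout(cfg), rng)
        r = pop.ratio[pop.state == PROG]
        lo, hi = cfg.initial_ratio_range
        assert r.min() >= lo and r.max() <= hi

    def test_gradient_regime_anticorrelates_ratio_with_y(self, rng):
        cfg = SimConfig(regime="gradient")
        pop = initialize_population(cfg, build_default_layout(cfg), rng)
        sel = pop.state == PROG
        rho = stats.spearmanr(pop.ratio[sel], pop.y[sel]).statistic
        assert rho < -0.9  # anterior Sox2-high, posterior Bra-high

    def test_overdense_region_rejected(self, rng):
        cfg = SimConfig(n_max=1)
        with pytest.raises(ConfigError):
            initialize_population(cfg, build_default_layout(cfg), rng)


class TestRatioDynamics:
    def test_drift_fixed_point(self, rng):
        cfg = SimConfig(ratio_noise_sigma=0.0, regime="random",
                        initial_ratio_range=(1.0, 1.0))
        pop = _single_cell(ratio=1.0)
        update_ratio(pop, cfg, 0.1, rng)
        assert pop.ratio[0] == pytest.approx(1.0)

    def test_pure_relaxation_moves_toward_anchor(self, rng):
        cfg = SimConfig(ratio_noise_sigma=0.0, regime="random",
                        initial_ratio_range=(1.0, 1.0))
        pop = _single_cell(ratio=1.4)
        update_ratio(pop, cfg, 0.1, rng)
        assert 1.0 < pop.ratio[0] < 1.4

    def test_ou_stationary_standard_deviation(self, rng):
        # thresholds pushed out so no cell commits: pure OU in the interior
        kappa, sigma, dt = 1.0, 0.2, 0.05
        cfg = SimConfig(regime="random", initial_ratio_range=(1.0, 1.0),
                        theta_low=0.01, theta_high=1.99,
                        ratio_relaxation_kappa=kappa, ratio_noise_sigma=sigma)
        n = 4000
        pop = Population(ids=np.arange(n), parent=np.full(n, -1),
                         state=np.full(n, PROG), ratio=np.ones(n),
                         x=np.zeros(n), y=np.full(n, 5.0),
                         birth_time=np.zeros(n), anchor_offset=np.zeros(n),
                         deregulated=np.zeros(n, bool))
        for _ in range(200):  # 10 relaxation times: well past burn-in
            update_ratio(pop, cfg, dt, rng)
        expected = sigma / np.sqrt(2.0 * kappa)
        assert pop.ratio.std() == pytest.approx(expected, rel=0.10)

    def test_committed_cells_relax_to_poles(self, rng):
        cfg = SimConfig(ratio_noise_sigma=0.0)
        pop = Population(ids=[0, 1], parent=[-1, -1], state=[NT, PSM],
                         ratio=[1.7, 0.3], x=[0, 0], y=[5, 5],
                         birth_time=[0, 0], anchor_offset=[0, 0],
                         deregulated=[False, False])
        for _ in range(100):
            update_ratio(pop, cfg, 0.1, rng)
        assert pop.ratio[0] == pytest.approx(2.0, abs=1e-3)
        assert pop.ratio[1] == pytest.approx(0.0, abs=1e-3)


class TestFateCommitment:
    @pytest.mark.parametrize("state,ratio,expected", [
        (PROG, 0.39, PSM),   # below 0.4: mesodermal commitment
        (PROG, 1.0, PROG),   # inside the band: undetermined
        (PROG, 1.61, NT),    # above 1.6: neural commitment
        (NT, 0.2, NT),       # committed cells never revert
        (PSM, 1.9, PSM),
    ])
    def test_threshold_semantics(self, state, ratio, expected):
        pop = _single_cell(state=state, ratio=ratio)
        specify_state(pop, SimConfig(), time=1.0)
        assert pop.state[0] == expected


class TestMotility:
    @pytest.mark.parametrize("profile", ["linear", "step"])
    def test_anchor_speeds(self, profile):
        cfg = SimConfig(motility_profile=profile)
        assert motility_of(0.2, PROG, cfg) == cfg.v_high
        assert motility_of(1.8, PROG, cfg) == cfg.v_low
        assert motility_of(1.0, PROG, cfg) == pytest.approx(cfg.v_mid)
        assert motility_of(0.5, NT, cfg) == cfg.v_low
        assert motility_of(1.5, PSM, cfg) == cfg.v_high

    @pytest.mark.parametrize("profile", ["linear", "step"])
    def test_non_increasing_in_ratio(self, profile):
        cfg = SimConfig(motility_profile=profile)
        grid = np.linspace(0.0, 2.0, 201)
        speeds = motility_of(grid, np.full(201, PROG), cfg)
        assert np.all(np.diff(speeds) <= 1e-12)


class TestPositions:
    def test_no_motility_means_no_movement(self, rng):
        cfg = SimConfig(motility_enabled=False, population_scale=0.1)
        layout = build_default_layout(cfg)
        pop = initialize_population(cfg, layout, rng)
        x0, y0 = pop.x.copy(), pop.y.copy()
        step_positions(pop, layout, cfg, 0.1, rng)
        np.testing.assert_array_equal(pop.x, x0)
        np.testing.assert_array_equal(pop.y, y0)

    def test_isolated_cell_step_length_and_isotropy(self, rng):
        cfg = SimConfig(interactions_enabled=False)
        layout = build_default_layout(cfg)
        angles, lengths = [], []
        pop = _single_cell(ratio=1.0, y=20.0)
        for _ in range(3000):
            x0, y0 = pop.x[0], pop.y[0]
            step_positions(pop, layout, cfg, 0.1, rng)
            dx, dy = pop.x[0] - x0, pop.y[0] - y0
            lengths.append(np.hypot(dx, dy))
            angles.append(np.arctan2(dy, dx))
            pop.x[0], pop.y[0] = 0.0, 20.0
        expected = cfg.v_mid / cfg.unit_scale_um * 0.1
        assert np.mean(lengths) == pytest.approx(expected, rel=1e-6)
        counts, _ = np.histogram(angles, bins=8, range=(-np.pi, np.pi))
        assert stats.chisquare(counts).pvalue > 0.01

    def test_anterior_wall_blocks_movement(self, rng):
        cfg = SimConfig(interactions_enabled=False)
        layout = build_default_layout(cfg)
        pop = _single_cell(ratio=1.0, y=1e-6)  # hugging the wall
        crossings = 0
        for _ in range(500):
            step_positions(pop, layout, cfg, 0.1, rng)
            if pop.y[0] < layout.anterior_wall_y:
                crossings += 1
            pop.y[0] = 1e-6
        assert crossings == 0


class TestProliferation:
    def test_infinite_doubling_time_is_static(self, rng):
        cfg = SimConfig(doubling_times={"progenitor": 1e12, "NT": 1e12,
                                        "PSM": 1e12})
        layout = build_default_layout(cfg)
        pop = initialize_population(cfg.replace(population_scale=0.1),
                                    build_default_layout(cfg.replace(population_scale=0.1)), rng)
        n0 = len(pop)
        proliferate(pop, cfg, 0.1, 0.1, rng)
        assert len(pop) == n0

    def test_psm_population_doubles_in_one_doubling_time(self, rng):
        cfg = SimConfig()
        n = 3200
        pop = Population(ids=np.arange(n), parent=np.full(n, -1),
                         state=np.full(n, PSM), ratio=np.zeros(n),
                         x=np.zeros(n), y=np.full(n, 5.0),
                         birth_time=np.zeros(n), anchor_offset=np.zeros(n),
                         deregulated=np.zeros(n, bool))
        t, dt = 0.0, 0.1
        while t < 8.75 - 1e-9:
            t += dt
            proliferate(pop, cfg, dt, t, rng)
        # binomial branching: expect x2 within a few percent at n = 3200
        assert len(pop) / n == pytest.approx(2.0, rel=0.05)

    def test_daughters_inherit_state_and_ratio(self, rng):
        cfg = SimConfig(doubling_times={"progenitor": 0.15, "NT": 0.15,
                                        "PSM": 0.15})
        pop = _single_cell(state=NT, ratio=1.8)
        for _ in range(50):
            proliferate(pop, cfg, 0.1, 0.1, rng)
            if len(pop) > 1:
                break
        assert len(pop) > 1
        assert np.all(pop.state == NT)
        assert np.all(pop.ratio == 1.8)
        assert pop.parent[-1] in pop.ids


class TestRunSimulation:
    def test_zero_time_returns_initial_snapshot_only(self):
        cfg = SimConfig(total_time=1e-9, population_scale=0.1)
        res = run_simulation(cfg, seed=1)
        assert len(res.snapshots) == 1
        counts = res.counts.iloc[0]
        assert counts["progenitor"] == 110
        assert counts["NT"] == 120
        assert counts["PSM"] == 320

    def test_same_seed_is_bit_identical(self):
        cfg = SimConfig(total_time=1.0, population_scale=0.05,
                        snapshot_interval=0.5)
        a = run_simulation(cfg, seed=42)
        b = run_simulation(cfg, seed=42)
        for sa, sb in zip(a.snapshots, b.snapshots):
            np.testing.assert_array_equal(sa["x_unit"], sb["x_unit"])
            np.testing.assert_array_equal(sa["ratio"], sb["ratio"])
            np.testing.assert_array_equal(sa["state"].cat.codes,
                                          sb["state"].cat.codes)

    def test_run_invariants(self, small_run):
        res = small_run
        totals = res.counts[["progenitor", "NT", "PSM"]].sum(axis=1)
        assert (totals.diff().dropna() >= 0).all()  # no cell death
        layout = res.layout
        final_states = {}
        for snap in res.snapshots:
            assert snap["ratio"].between(0.0, 2.0).all()
            assert (snap["y_unit"] >= layout.anterior_wall_y).all()
            assert snap["x_unit"].between(layout.lateral_wall_x_left,
                                          layout.lateral_wall_x_right).all()
            for cid, state in zip(snap["cell_id"], snap["state"].astype(str)):
                prev = final_states.get(cid)
                if prev in ("NT", "PSM"):
                    assert state == prev  # fate irreversibility
                final_states[cid] = state


class TestDeregulation:
    def test_unknown_mode_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(deregulation="wnt_high")

    def test_none_is_identity(self):
        cfg = SimConfig(deregulation="none")
        from nmpsim import apply_deregulation
        assert apply_deregulation(cfg) is cfg

    def test_bra_high_drives_cells_into_psm(self):
        cfg = SimConfig(deregulation="bra_high", deregulated_fraction=1.0,
                        population_scale=0.1, total_time=4.0,
                        snapshot_interval=1.0)
        res = run_simulation(cfg, seed=5)
        base = run_simulation(cfg.replace(deregulation="none"), seed=5)
        assert (res.counts["progenitor"].iloc[-1]
                < base.counts["progenitor"].iloc[-1])
        assert res.counts["PSM"].iloc[-1] > base.counts["PSM"].iloc[-1]
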