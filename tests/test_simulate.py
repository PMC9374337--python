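import numpy as np
import pandas as pd
import pytest
from scipy import stats

from smdmap.geometry import Spherocylinder
from smdmap.simulate import (
    ConfigurationError,
    SimulationConfig,
    StreamConfig,
    extract_lag_displacements,
    generate_cell_population,
    generate_protein_panel,
    simulate_confined_walk,
    synthesize_localization_stream,
)
from smdmap.scaling import fit_power_law

CELL = Spherocylinder(radius=0.45, total_length=2.25)


def small_config(**kw):
    defaults = dict(d_sim=5.0, dt_sim=1e-4, total_time=0.05, n_particles=10, seed=3)
    defaults.update(kw)
    return SimulationConfig(**defaults)


def test_config_validation():
    with pytest.raises(ConfigurationError):
        SimulationConfig(d_sim=-1.0)
    with pytest.raises(ConfigurationError):
        SimulationConfig(d_sim=1.0, dt_sim=3e-4, total_time=1e-3)  # not integer steps
    with pytest.raises(ConfigurationError):
        SimulationConfig(d_sim=1.0, n_particles=0)


def test_zero_diffusion_keeps_particles_still():
    traj = simulate_confined_walk(small_config(d_sim=0.0), CELL)
    for _, group in traj.groupby("particle"):
        assert group[["x", "y", "z"]].nunique().max() == 1


def test_row_and_lag_counts_for_reference_protocol():
    """2 s of 0.1-ms steps gives 20,000 rows and 19,985 lag-15 pairs each."""
    config = SimulationConfig(d_sim=1.0, dt_sim=1e-4, total_time=2.0,
                              n_particles=2, seed=0)
    traj = simulate_confined_walk(config, CELL)
    assert config.n_steps == 20000
    assert (traj.groupby("particle").size() == 20000).all()
    disp = extract_lag_displacements(traj, 15)
    assert (disp.groupby("particle").size() == 19985).all()


def test_lag_boundary_case_single_displacement():
    config = small_config(total_time=16e-4, n_particles=4)
    traj = simulate_confined_walk(config, CELL)
    disp = extract_lag_displacements(traj, 15)
    assert (disp.groupby("particle").size() == 1).all()
    with pytest.raises(ValueError):
        extract_lag_displacements(traj, 16)


def test_lag_displacement_is_sum_of_per_step_vectors():
    config = small_config(n_particles=3, total_time=0.01)
    traj = simulate_confined_walk(config, CELL)
    disp = extract_lag_displacements(traj, 7)
    one = traj[traj.particle == 1].sort_values("step")
    xy = one[["x", "y"]].to_numpy() * 1000.0
    steps = np.diff(xy, axis=0)
    row = disp[(disp.particle == 1) & (disp.couple == 2)].iloc[0]
    # origin = position after step 2 (row 1), end = after step 9 (row 8)
    expected = steps[1:8].sum(axis=0)
    assert row.dx_nm == pytest.approx(expected[0], abs=1e-9)
    assert row.dy_nm == pytest.approx(expected[1], abs=1e-9)


def test_containment_invariant():
    traj = simulate_confined_walk(small_config(d_sim=20.0, total_time=0.2), CELL)
    pts = traj[["x", "y", "z"]].to_numpy()
    assert CELL.contains(pts, atol=1e-9).all()


def test_free_diffusion_msd_matches_analytic_value():
    """In an effectively unconfined compartment, planar MSD = 4 D dt."""
    big = Spherocylinder(radius=100.0, total_length=300.0)
    config = SimulationConfig(d_sim=5.0, dt_sim=1.5e-3, total_time=0.3,
                              n_particles=100, seed=5)
    traj = simulate_confined_walk(config, big)
    disp = extract_lag_displacements(traj, 1)
    r2_um2 = (disp["r_nm"].to_numpy() / 1000.0) ** 2
    expected = 4 * 5.0 * 1.5e-3
    se = r2_um2.std(ddof=1) / np.sqrt(len(r2_um2))
    assert abs(r2_um2.mean() - expected) < 3 * se


def test_free_diffusion_displacements_are_rayleigh():
    big = Spherocylinder(radius=20.0, total_length=60.0)
    config = SimulationConfig(d_sim=5.0, dt_sim=1.5e-3, total_time=0.15,
                              n_particles=200, seed=6)
    disp = extract_lag_displacements(simulate_confined_walk(config, big), 1)
    s = 4 * 5.0 * 1.5e-3 * 1e6  # nm^2
    p = stats.kstest(disp["r_nm"], lambda r: 1 - np.exp(-(r**2) / s)).pvalue
    assert p > 0.01


def test_stationary_distribution_is_uniform_over_compartment():
    """Post-burn-in positions follow the uniform density (chi-square, 8 x-bins).

    Independence matters more than trajectory length here: positions
    decorrelate only on the L^2/2D time scale, so the check uses the final
    position of many short independent walks (uniform is the stationary
    law, preserved by the reflected dynamics from the uniform start).
    """
    config = SimulationConfig(d_sim=5.0, dt_sim=1e-4, total_time=2e-3,
                              n_particles=100_000, seed=7)
    traj = simulate_confined_walk(config, CELL)
    x = traj.loc[traj.step == config.n_steps, "x"].to_numpy()
    assert x.size >= 1e5
    edges = np.linspace(-CELL.total_length / 2, CELL.total_length / 2, 9)
    grid = np.linspace(edges[0], edges[-1], 4001)
    h = CELL.half_cylinder_length
    area = np.pi * (CELL.radius**2 - np.clip(np.abs(grid) - h, 0, None) ** 2)
    probs = np.array([
        np.trapezoid(area[(grid >= lo) & (grid <= hi)], grid[(grid >= lo) & (grid <= hi)])
        for lo, hi in zip(edges[:-1], edges[1:])
    ])
    probs /= probs.sum()
    counts, _ = np.histogram(x, edges)
    p = stats.chisquare(counts, counts.sum() * probs).pvalue
    assert p > 0.01


def test_markov_subsampling_matches_direct_coarse_steps():
    """Lag-15 displacements at 0.1-ms steps match direct 1.5-ms steps."""
    fine = SimulationConfig(d_sim=5.0, dt_sim=1e-4, total_time=0.75,
                            n_particles=20, seed=8)
    coarse = SimulationConfig(d_sim=5.0, dt_sim=1.5e-3, total_time=0.75,
                              n_particles=20, seed=9)
    r_fine = extract_lag_displacements(simulate_confined_walk(fine, CELL), 15)["r_nm"]
    r_coarse = extract_lag_displacements(simulate_confined_walk(coarse, CELL), 1)["r_nm"]
    # non-overlapping windows only, for independence
    p = stats.ks_2samp(r_fine[::15], r_coarse).pvalue
    assert p > 0.01


class TestStream:
    def test_noise_free_stream_reproduces_true_displacements(self):
        cfg = StreamConfig(loc_noise_sd=0.0, false_pair_rate=0.0,
                           frames_per_cell=400, seed=1)
        locs = synthesize_localization_stream([(CELL, 5.0)], cfg)
        assert set(locs.columns) >= {"frame", "x_nm", "y_nm", "truth_id", "cell_id"}
        # every truth id appears exactly twice, in consecutive odd/even frames
        by_id = locs[locs.truth_id >= 0].groupby("truth_id")
        assert (by_id.size() == 2).all()
        frames = by_id["frame"].agg(["min", "max"])
        assert ((frames["max"] - frames["min"]) == 1).all()
        assert (frames["min"] % 2 == 0).all()

    def test_displacement_count_in_qc_range(self):
        cfg = StreamConfig(frames_per_cell=8000, seed=2)
        locs = synthesize_localization_stream([(CELL, 5.0)], cfg)
        n = (locs.truth_id >= 0).sum() / 2
        assert 2000 <= n <= 20000

    def test_false_pairs_are_labelled(self):
        cfg = StreamConfig(false_pair_rate=2.0, frames_per_cell=200, seed=3)
        locs = synthesize_localization_stream([(CELL, 5.0)], cfg)
        assert (locs.truth_id == -1).sum() > 0


class TestPopulation:
    def test_point_ranges_give_exact_geometry(self):
        cells = generate_cell_population((0.9, 0.9), (2.25, 2.25), (5.0, 5.0),
                                         n_cells=1, seed=0)
        (geom, d), = cells
        assert geom.radius == pytest.approx(0.45)
        assert geom.total_length == pytest.approx(2.25)
        assert d == pytest.approx(5.0)

    def test_sampled_geometries_are_valid_and_in_range(self):
        cells = generate_cell_population(n_cells=200, seed=1)
        for geom, d in cells:
            assert geom.total_length >= 2 * geom.radius
            assert 0.2 <= 2 * geom.radius <= 2.34
            assert 1.1 <= geom.total_length <= 3.64
            assert 0.5 <= d <= 20.0

    def test_infeasible_range_raises(self):
        with pytest.raises(ConfigurationError):
            generate_cell_population((3.0, 4.0), (1.0, 2.0), (1.0, 2.0), 5, 0)

    def test_reproducible(self):
        a = generate_cell_population(n_cells=5, seed=9)
        b = generate_cell_population(n_cells=5, seed=9)
        assert [(g.radius, g.total_length, d) for g, d in a] == \
           [(g.radius, g.total_length, d) for g, d in b]


class TestProteinPanel:
    def test_noiseless_panel_recovers_generating_law(self):
        panel = generate_protein_panel(alpha=50.0, beta=-0.54, n=12,
                                       rel_noise=0.0, seed=0)
        fit = fit_power_law(panel["complex_mass_kda"], panel["d_um2s"])
        assert fit.alpha == pytest.approx(50.0, rel=1e-6)
        assert fit.beta == pytest.approx(-0.54, abs=1e-7)

    def test_masses_within_range(self):
        panel = generate_protein_panel(n=200, seed=1)
        assert panel["complex_mass_kda"].between(25.0, 320.0).all()

    def test_positive_exponent_warns_but_is_allowed(self):
        with pytest.warns(UserWarning):
            generate_protein_panel(beta=0.2, n=5, rel_noise=0.0, seed=2)
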