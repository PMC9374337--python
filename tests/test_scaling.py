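import numpy as np
import pytest
from scipy import stats

from smdmap.scaling import (
    PoleCenterEnsemble,
    ProteinRecord,
    ViscosityModel,
    complex_mass,
    f_test_nested,
    fit_power_law,
    interactors_per_molecule,
    loneliness,
    normality_test,
    pole_center_ratio,
    perceived_viscosity,
    spearman,
    two_sample_rank_test,
)


class TestComplexMass:
    def test_homodimer(self):
        rec = ProteinRecord(name="Icd", monomer_mw=45.7, oligomeric_state=2)
        assert complex_mass(rec) == pytest.approx(142.8)

    def test_free_tag(self):
        rec = ProteinRecord(name="tag", monomer_mw=0.0, oligomeric_state=1)
        assert complex_mass(rec) == pytest.approx(25.7)

    def test_untagged_monomer_identity(self):
        rec = ProteinRecord(name="x", monomer_mw=50.0, tag_mw=0.0)
        assert complex_mass(rec) == pytest.approx(50.0)

    def test_invalid_state(self):
        with pytest.raises(ValueError):
            complex_mass(ProteinRecord(name="x", monomer_mw=1.0, oligomeric_state=0))


class TestLoneliness:
    def test_reciprocal_reading(self):
        assert interactors_per_molecule(0.025) == pytest.approx(40.0)

    def test_equal_abundances(self):
        assert loneliness(500.0, 500.0) == 1.0

    def test_worked_example(self):
        assert loneliness(1000.0, 100.0) == pytest.approx(10.0)

    def test_no_interactors_is_undefined_not_infinite(self):
        assert np.isnan(loneliness(1000.0, 0.0))

    def test_invalid_abundance(self):
        with pytest.raises(ValueError):
            loneliness(0.0, 10.0)


def brute_force_spearman(x, y):
    """Textbook definition: Pearson correlation of mean ranks."""
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    return np.corrcoef(rx, ry)[0, 1]


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        assert spearman(x, x)[0] == pytest.approx(1.0)
        assert spearman(x, -x)[0] == pytest.approx(-1.0)

    def test_matches_brute_force_with_ties(self):
        x = [1.0, 2.0, 2.0, 4.0, 5.0, 6.0]
        y = [3.0, 1.0, 4.0, 4.0, 6.0, 5.0]
        assert spearman(x, y)[0] == pytest.approx(brute_force_spearman(x, y))

    def test_invariant_under_monotone_transform(self, rng):
        x = rng.uniform(1, 10, 30)
        y = rng.uniform(1, 10, 30)
        assert spearman(np.exp(x), y)[0] == pytest.approx(spearman(x, y)[0])
        assert spearman(x, y**3)[0] == pytest.approx(spearman(x, y)[0])

    def test_constant_input_flagged(self):
        r, p = spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(r)

    def test_permutation_p_value_reasonable(self):
        x = np.arange(8.0)
        r, p = spearman(x, x, n_perm=500, seed=1)
        assert p < 0.01


class TestPowerLaw:
    def test_exact_recovery(self):
        m = np.array([30.0, 60.0, 120.0, 240.0])
        fit = fit_power_law(m, 10.0 * m**-0.5)
        assert fit.alpha == pytest.approx(10.0, abs=1e-8)
        assert fit.beta == pytest.approx(-0.5, abs=1e-8)
        assert np.allclose(fit.residuals, 0.0, atol=1e-10)

    def test_loglog_start_matches_linear_regression(self, rng):
        m = np.exp(rng.uniform(np.log(25), np.log(320), 20))
        d = 50 * m**-0.6 * np.exp(rng.normal(0, 0.05, 20))
        from smdmap.scaling import PowerLawModel
        alpha0, beta0 = PowerLawModel(m, d).loglog_start()
        slope, intercept = np.polyfit(np.log(m), np.log(d), 1)
        assert beta0 == pytest.approx(slope, abs=1e-8)
        assert np.log(alpha0) == pytest.approx(intercept, abs=1e-8)

    def test_requires_positive_data(self):
        with pytest.raises(ValueError):
            fit_power_law([1.0, -2.0, 3.0], [1.0, 2.0, 3.0])

    def test_summary_smoke(self):
        m = np.array([30.0, 60.0, 120.0, 240.0])
        text = fit_power_law(m, 10.0 * m**-0.5).summary()
        assert "beta" in text


class TestPoleCenterRatio:
    def test_identical_regions_give_unit_ratio(self):
        ens = pole_center_ratio([1.0, 1.0, 1.0])
        assert ens.mean == 1.0 and ens.sd == 0.0

    def test_invalid_cells_are_skipped_with_count(self):
        ens = pole_center_ratio([0.9, float("nan"), 1.1])
        assert ens.skipped == 1
        assert ens.mean == pytest.approx(1.0)

    def test_kde_summary(self, rng):
        ens = PoleCenterEnsemble(ratios=rng.normal(0.9, 0.05, 50))
        grid, dens = ens.kde()
        assert len(grid) == len(dens)
        assert dens.min() >= 0


class TestViscosity:
    def test_round_trip_identity(self):
        model = ViscosityModel()
        eta = model.eta_cp(5.0, 142.8)
        assert model.d_um2s(eta, 142.8) == pytest.approx(5.0, rel=1e-12)

    def test_radius_grows_with_cube_root_of_mass(self):
        model = ViscosityModel()
        r1 = model.hydrodynamic_radius_nm(40.0)
        r8 = model.hydrodynamic_radius_nm(320.0)
        assert r8 / r1 == pytest.approx(2.0, rel=1e-12)

    def test_exponent_on_exact_power_law_panel(self):
        """For D = a*M^-0.54 exactly, eta scales as M^(0.54 - 1/3)."""
        m = np.exp(np.linspace(np.log(25), np.log(320), 12))
        d = 70.0 * m**-0.54
        _, fit = perceived_viscosity(d, m)
        assert fit.beta == pytest.approx(0.54 - 1.0 / 3.0, abs=1e-6)

    def test_positive_inputs_required(self):
        with pytest.raises(ValueError):
            ViscosityModel().eta_cp(-1.0, 100.0)


class TestRankTest:
    def test_full_separation_exact_p(self):
        u, p = two_sample_rank_test([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 / C(6,3)

    def test_identical_samples(self):
        a = np.arange(10.0)
        u, p = two_sample_rank_test(a, a)
        assert u == pytest.approx(50.0)  # n^2 / 2
        assert p > 0.9

    def test_antisymmetry(self):
        a, b = [1.0, 5.0, 9.0, 12.0], [2.0, 3.0, 11.0]
        u_ab, p_ab = two_sample_rank_test(a, b)
        u_ba, p_ba = two_sample_rank_test(b, a)
        assert u_ab + u_ba == len(a) * len(b)
        assert p_ab == pytest.approx(p_ba)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            two_sample_rank_test([], [1.0])


class TestNormality:
    def test_affine_invariance(self, rng):
        x = rng.normal(0, 1, 50)
        w1, _ = normality_test(x)
        w2, _ = normality_test(5.0 * x - 3.0)
        assert w1 == pytest.approx(w2, abs=1e-10)

    def test_small_and_constant_samples_rejected(self):
        with pytest.raises(ValueError):
            normality_test([1.0, 2.0])
        with pytest.raises(ValueError):
            normality_test([2.0, 2.0, 2.0, 2.0])

    def test_detects_uniform_at_moderate_n(self, rng):
        rejections = sum(
            normality_test(rng.uniform(0, 1, 50))[1] < 0.01 for _ in range(100)
        )
        assert rejections > 10


class TestFTest:
    def test_nested_comparison(self):
        f, p = f_test_nested(rss_restricted=12.0, rss_full=10.0, n=12,
                             p_full=2, p_restricted=1)
        assert f == pytest.approx((2.0 / 1) / (10.0 / 10))
        assert 0.0 <= p <= 1.0

    def test_requires_nesting(self):
        with pytest.raises(ValueError):
            f_test_nested(1.0, 1.0, 10, 1, 2)


class TestPlantedPoleSlowdown:
    """A pole slowdown built into the stream generator must be recovered
    on top of the confinement-only baseline."""

    @staticmethod
    def cell_ratio(pole_slowdown, seed):
        from smdmap.confinement import REFERENCE_CELL
        from smdmap.displacements import extract_displacements, filter_displacements
        from smdmap.mapping import fit_regions
        from smdmap.segmentation import CellRecord, measure_geometry, partition_regions
        from smdmap.simulate import StreamConfig, synthesize_localization_stream

        cfg = StreamConfig(loc_noise_sd=10.0, frames_per_cell=6000,
                           pole_slowdown=pole_slowdown, seed=seed)
        stream = synthesize_localization_stream([(REFERENCE_CELL, 5.0)], cfg)
        disp = filter_displacements(extract_displacements(stream), 600.0)
        length, width = measure_geometry(disp)
        cell = CellRecord(id=0, displacements=disp, rotation_angle=0.0,
                          length_um=length, width_um=width)
        fits = fit_regions(partition_regions(cell), background=True)
        return fits.pole_center_ratio()

    def test_slowdown_recovered_relative_to_baseline(self):
        seeds = range(10)
        base = np.array([self.cell_ratio(1.0, 700 + s) for s in seeds])
        slow = np.array([self.cell_ratio(0.7, 800 + s) for s in seeds])
        assert base.mean() < 1.0
        assert slow.mean() < base.mean()  # planted slowdown is visible
        # quantitative recovery: planted factor times the confinement baseline
        assert slow.mean() == pytest.approx(0.7 * base.mean(), abs=0.05)
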