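"""Dynamics estimators: diffusion, Arrhenius, jumps, rotation, orientation,
pair structure, layer occupancy and dipole density."""

import numpy as np
import pytest
from scipy import stats

import adlayers as al
from adlayers import synthetic as syn
from adlayers.dynamics import (
    OrientationSeries,
    R_KJ_PER_MOL_K,
    Trajectory2D,
    adlayer_dipole,
    arrhenius_barrier,
    detect_jumps,
    displacement_anisotropy,
    layer_occupancy,
    molecule_centers,
    msd_and_diffusion,
    orientation_histogram,
    pair_distribution_2d,
    rotational_relaxation,
)
from adlayers.errors import ValidationError
from adlayers.structures import AtomConfiguration


class TestMSD:
    def test_static_track_gives_zero(self):
        traj = Trajectory2D(times=np.arange(200.0), tracks=np.zeros((200, 1, 2)))
        curve = msd_and_diffusion(traj)
        assert curve.diffusion == pytest.approx(0.0, abs=1e-12)
        assert np.all(curve.msd == 0.0)

    def test_recovery_at_reference_value(self):
        # D = 0.088 A^2/ps corresponds to 0.88e-5 cm^2/s
        traj = syn.make_brownian_walk(syn.WalkSpec(D=0.088, dt=1.0, n_steps=100_000,
                                                   seed=0))
        curve = msd_and_diffusion(traj)
        assert abs(curve.diffusion - 0.088) < 3 * curve.diffusion_se
        assert curve.diffusion_cm2_s == pytest.approx(0.88e-5, rel=0.15)

    def test_two_seeds_consistent(self):
        a = msd_and_diffusion(syn.make_brownian_walk(
            syn.WalkSpec(D=0.05, dt=1.0, n_steps=50_000, seed=1)))
        b = msd_and_diffusion(syn.make_brownian_walk(
            syn.WalkSpec(D=0.05, dt=1.0, n_steps=50_000, seed=2)))
        joint = np.hypot(a.diffusion_se, b.diffusion_se)
        assert abs(a.diffusion - b.diffusion) < 3 * joint

    def test_estimator_unbiased_over_seeds(self):
        Ds = [
            msd_and_diffusion(syn.make_brownian_walk(
                syn.WalkSpec(D=0.1, dt=1.0, n_steps=20_000, seed=s))).diffusion
            for s in range(20)
        ]
        se_of_mean = np.std(Ds, ddof=1) / np.sqrt(len(Ds))
        assert abs(np.mean(Ds) - 0.1) < se_of_mean

    def test_msd_zero_at_lag_zero_and_nonnegative(self):
        traj = syn.make_brownian_walk(syn.WalkSpec(D=0.2, dt=0.5, n_steps=5000, seed=4))
        curve = msd_and_diffusion(traj)
        assert curve.msd[0] == 0.0
        assert np.all(curve.msd >= 0.0)

    def test_short_trajectory_rejected(self):
        with pytest.raises(ValidationError):
            msd_and_diffusion(Trajectory2D(times=np.arange(50.0),
                                           tracks=np.zeros((50, 1, 2))))


class TestArrhenius:
    def test_equal_diffusion_zero_barrier(self):
        assert arrhenius_barrier(1e-5, 300, 1e-5, 340).activation_energy == 0.0

    def test_printed_diffusion_pair(self):
        # the two reported diffusion constants evaluate to ~3.1 kJ/mol
        res = arrhenius_barrier(0.88e-5, 300.0, 1.02e-5, 340.0)
        expected = R_KJ_PER_MOL_K * np.log(1.02 / 0.88) / (1 / 300 - 1 / 340)
        assert res.activation_energy == pytest.approx(expected, rel=1e-12)
        assert res.activation_energy == pytest.approx(3.14, abs=0.05)
        assert res.note == "two-point estimate"

    def test_e_fold_unit_check(self):
        # D2 = e D1 and 1/T1 - 1/T2 = 1/1000 -> E_a = 1000 R
        T1 = 500.0
        T2 = 1.0 / (1.0 / T1 - 1e-3)
        res = arrhenius_barrier(1e-5, T1, np.e * 1e-5, T2)
        assert res.activation_energy == pytest.approx(1000 * R_KJ_PER_MOL_K, rel=1e-9)

    def test_domain_errors(self):
        with pytest.raises(ValidationError):
            arrhenius_barrier(-1e-5, 300, 1e-5, 340)
        with pytest.raises(ValidationError):
            arrhenius_barrier(1e-5, 300, 1e-5, 300)


class TestJumps:
    def test_pure_brownian_has_no_jumps(self):
        traj = syn.make_brownian_walk(syn.WalkSpec(D=0.05, dt=1.0, n_steps=10_000,
                                                   seed=3))
        # step sd ~ 0.45 A << 5 A threshold
        assert detect_jumps(traj, threshold=5.0).n_events == 0

    def test_event_count_matches_binomial(self):
        p, n = 0.01, 10_000
        traj = syn.make_brownian_walk(
            syn.WalkSpec(D=0.01, dt=1.0, n_steps=n, jump_probability=p,
                         jump_length=8.0, seed=5)
        )
        ev = detect_jumps(traj, threshold=5.0)
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(ev.n_events - n * p) < 3 * sigma
        assert 0 < ev.jump_fraction < 1

    def test_zero_threshold_flags_every_step(self):
        traj = syn.make_brownian_walk(syn.WalkSpec(D=0.1, dt=1.0, n_steps=500, seed=6))
        ev = detect_jumps(traj, threshold=0.0)
        assert ev.n_events == ev.n_steps == 500


class TestRotation:
    def test_fixed_vector_reports_lower_bound(self):
        n = 2000
        series = OrientationSeries(times=np.arange(float(n)),
                                   vectors=np.tile([1.0, 0.0], (n, 1)))
        res = rotational_relaxation(series)
        assert res.bound == "lower"

    def test_recovery_at_reference_value(self):
        series = syn.make_rotor_series(tau=37.0, dt=1.0, n=100_000, seed=1)
        res = rotational_relaxation(series)
        assert res.bound is None
        assert res.tau == pytest.approx(37.0, rel=0.10)

    def test_white_noise_decorelates_within_one_frame(self):
        rng = np.random.default_rng(2)
        theta = rng.uniform(0, 2 * np.pi, size=5000)
        series = OrientationSeries(
            times=np.arange(5000.0),
            vectors=np.column_stack([np.cos(theta), np.sin(theta)]),
        )
        res = rotational_relaxation(series)
        assert res.bound == "upper"
        assert res.tau <= series.dt


class TestOrientationHistogram:
    def test_delta_distribution(self):
        v = np.tile([np.cos(np.radians(45)), np.sin(np.radians(45))], (1000, 1))
        series = OrientationSeries(times=np.arange(1000.0), vectors=v)
        hist = orientation_histogram(series, bin_width=10.0)
        # all mass in one bin; density integrates to 1
        assert np.sum(hist.density > 0) == 1
        assert np.sum(hist.density * np.diff(hist.edges)) == pytest.approx(1.0)
        assert len(hist.peaks) == 1 and hist.peaks[0] == pytest.approx(45.0)

    def test_uniform_angles_pass_chi_square(self):
        rng = np.random.default_rng(8)
        theta = rng.uniform(0, 2 * np.pi, size=20_000)
        series = OrientationSeries(
            times=np.arange(20_000.0),
            vectors=np.column_stack([np.cos(theta), np.sin(theta)]),
        )
        hist = orientation_histogram(series, bin_width=10.0)
        counts = hist.density * np.diff(hist.edges) * 20_000
        chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
        p = stats.chi2.sf(chi2, df=len(counts) - 1)
        assert p > 0.01
        assert len(hist.peaks) == 0

    def test_four_well_bias_reports_four_peaks(self):
        rng = np.random.default_rng(9)
        wells = np.array([45.0, 135.0, 225.0, 315.0])
        theta = np.radians(rng.choice(wells, size=8000) + rng.normal(0, 8, 8000))
        series = OrientationSeries(
            times=np.arange(8000.0),
            vectors=np.column_stack([np.cos(theta), np.sin(theta)]),
        )
        hist = orientation_histogram(series, bin_width=5.0, excess_factor=1.5)
        assert len(hist.peaks) == 4
        assert np.allclose(sorted(hist.peaks), wells, atol=5.0)


class TestPairDistribution:
    def test_two_pinned_molecules_single_bin(self):
        centers = np.tile(np.array([[5.0, 5.0], [15.0, 5.0]]), (4, 1, 1))
        curve = pair_distribution_2d(centers, (40.0, 40.0),
                                     bins=np.linspace(0, 20, 21))
        assert np.sum(curve.counts > 0) == 1
        assert curve.first_peak == pytest.approx(10.5)  # the bin containing 10 A

    def test_poisson_centers_flat_and_normalized(self):
        rng = np.random.default_rng(10)
        N, L = 64, 50.0
        centers = rng.uniform(0, L, size=(150, N, 2))
        curve = pair_distribution_2d(centers, (L, L), bins=80)
        mid = slice(5, 50)
        assert np.mean(curve.g[mid]) == pytest.approx(1.0, abs=0.03)
        # density-weighted integral over the cell returns N - 1
        from adlayers.dynamics import _annulus_arc_length

        dr = curve.r[1] - curve.r[0]
        integral = np.sum(curve.g * _annulus_arc_length(curve.r, L, L) * dr) * (N - 1) / L**2
        assert integral == pytest.approx(N - 1, rel=0.02)

    def test_hexagonal_lattice_peaks(self):
        a = 10.0
        nx, ny = 6, 4
        pts = []
        for i in range(nx):
            for j in range(ny):
                pts.append([i * a + (j % 2) * a / 2, j * a * np.sqrt(3) / 2])
        pts = np.array(pts)
        box = (nx * a, ny * a * np.sqrt(3) / 2)
        curve = pair_distribution_2d(pts[None], box, bins=np.linspace(0.1, 22, 120))
        peaks = curve.r[(curve.g > 2.0)]
        assert np.any(np.abs(peaks - a) < 0.5)
        assert np.any(np.abs(peaks - np.sqrt(3) * a) < 0.5)

    def test_single_molecule_error(self):
        with pytest.raises(ValidationError):
            pair_distribution_2d(np.zeros((1, 1, 2)), (10, 10))


class TestLayerOccupancy:
    def disk_config(self, layer_counts, box=(64.92, 64.92)):
        """Point molecules arranged with given per-layer counts."""
        rng = np.random.default_rng(0)
        pos, mol = [], []
        m = 1
        for layer, count in enumerate(layer_counts):
            for _ in range(count):
                pos.append([rng.uniform(0, box[0]), rng.uniform(0, box[1]),
                            10.0 + 1.7 + layer * 3.4])
                mol.append(m)
                m += 1
        return AtomConfiguration(np.array(pos), ["N"] * len(pos),
                                 [box[0], box[1], 60.0],
                                 molecule_id=np.array(mol, int))

    def test_single_layer_is_layer_by_layer(self):
        cfg = self.disk_config([10])
        prof = layer_occupancy(cfg, substrate_top_z=10.0, layer_thickness=3.4,
                               molecule_area=100.0)
        assert list(prof.counts) == [10]
        assert prof.verdict == "layer_by_layer"

    def test_24_disk_scenario_is_stranski_krastanov(self):
        # 24 disks of 100 A^2 on a 4215 A^2 cell with one second-layer molecule
        cfg = self.disk_config([24, 1])
        prof = layer_occupancy(cfg, substrate_top_z=10.0, layer_thickness=3.4,
                               molecule_area=100.0, area=4215.0)
        assert prof.coverages[0] == pytest.approx(0.569, abs=0.001)
        assert prof.verdict == "stranski_krastanov"

    def test_generator_modes_classify_as_expected(self):
        surface = syn.make_crystal_slab(syn.SlabSpec(box=(60, 60), spacing=1.0,
                                                     layers=1))
        top = surface.positions[:, 2].max()
        common = dict(disk_radius=5.0, seed=2)
        expected = {"flat2d": "layer_by_layer", "stacked": "layer_by_layer"}
        for mode, want in expected.items():
            cfg = syn.make_adlayer(surface, 40 if mode == "stacked" else 12,
                                   mode, **common)
            prof = layer_occupancy(
                cfg, substrate_top_z=top + 1.7, layer_thickness=3.4,
                molecule_area=100.0,
                adlayer=lambda c: np.asarray(c.chain_id) == "A",
            )
            assert prof.verdict == want, mode
        cluster = syn.make_adlayer(surface, 30, "cluster3d", **common)
        prof = layer_occupancy(
            cluster, substrate_top_z=top + 1.7, layer_thickness=3.4,
            molecule_area=100.0,
            adlayer=lambda c: np.asarray(c.chain_id) == "A",
        )
        assert prof.verdict != "layer_by_layer"

    def test_z_translation_invariance(self):
        cfg = self.disk_config([24, 1])
        a = layer_occupancy(cfg, 10.0, 3.4, 100.0, area=4215.0)
        shifted = cfg.translated((0, 0, 12.3))
        b = layer_occupancy(shifted, 22.3, 3.4, 100.0, area=4215.0)
        assert a.verdict == b.verdict
        assert np.array_equal(a.counts, b.counts)

    def test_empty_profile(self):
        cfg = AtomConfiguration([[0, 0, 0]], ["C"], [10, 10, 10])
        prof = layer_occupancy(cfg, 0.0, 3.4, 100.0,
                               adlayer=np.array([False]))
        assert prof.verdict == "empty"


class TestDipole:
    def test_conversion_constant(self):
        cfg = AtomConfiguration([[0, 0, 1.0], [0, 0, 0.0]], ["N", "N"],
                                [10.0, 10.0, 20.0], charges=[1.0, -1.0])
        prof = adlayer_dipole(cfg, area_nm2=1.0)
        assert prof.dipole_per_area == pytest.approx(4.8032)
        assert not prof.origin_dependent

    def test_overlapping_charges_cancel(self):
        cfg = AtomConfiguration([[1, 1, 3.0], [1, 1, 3.0]], ["N", "N"],
                                [10, 10, 20], charges=[0.5, -0.5])
        assert adlayer_dipole(cfg).dipole_per_area == 0.0

    def test_linearity_in_charge(self):
        rng = np.random.default_rng(11)
        pos = rng.uniform(0, 10, size=(6, 3))
        q = rng.normal(size=6)
        q -= q.mean()  # neutral
        a = adlayer_dipole(AtomConfiguration(pos, ["N"] * 6, [10, 10, 20], charges=q))
        b = adlayer_dipole(AtomConfiguration(pos, ["N"] * 6, [10, 10, 20], charges=2 * q))
        assert b.dipole_per_area == pytest.approx(2 * a.dipole_per_area)

    def test_origin_invariance_for_neutral_region(self):
        rng = np.random.default_rng(12)
        pos = rng.uniform(0, 10, size=(8, 3))
        q = rng.normal(size=8)
        q -= q.mean()
        cfg = AtomConfiguration(pos, ["N"] * 8, [10, 10, 30], charges=q)
        shifted = cfg.translated((0, 0, 5.0))
        a, b = adlayer_dipole(cfg), adlayer_dipole(shifted)
        assert a.dipole_e_angstrom == pytest.approx(b.dipole_e_angstrom, abs=1e-10)

    def test_non_neutral_region_flagged(self):
        cfg = AtomConfiguration([[0, 0, 1.0]], ["N"], [10, 10, 20], charges=[1.0])
        assert adlayer_dipole(cfg).origin_dependent

    def test_missing_charges_error(self):
        cfg = AtomConfiguration([[0, 0, 0]], ["N"], [10, 10, 20])
        with pytest.raises(ValidationError):
            adlayer_dipole(cfg)


class TestAnisotropy:
    def test_isotropic_ratio_near_one(self):
        traj = syn.make_brownian_walk(
            syn.WalkSpec(D=0.1, dt=1.0, n_steps=50_000, n_walkers=4, seed=13)
        )
        res = displacement_anisotropy(traj)
        assert abs(res.ratio - 1.0) < 3 * res.ratio_se

    def test_two_to_one_ratio_recovered(self):
        traj = syn.make_brownian_walk(
            syn.WalkSpec(D=0.1, D_y=0.05, dt=1.0, n_steps=50_000, n_walkers=4, seed=14)
        )
        res = displacement_anisotropy(traj)
        assert abs(res.ratio - 2.0) < 3 * res.ratio_se

    def test_static_track_zero_slopes(self):
        traj = Trajectory2D(times=np.arange(200.0), tracks=np.zeros((200, 1, 2)))
        res = displacement_anisotropy(traj)
        assert res.axis_curves[0].slope == 0.0
        assert res.axis_curves[1].slope == 0.0


def test_molecule_centers_reassembles_split_molecules():
    # a 2-atom molecule straddling the periodic boundary
    cfg = AtomConfiguration(
        [[9.8, 5.0, 5.0], [0.2, 5.0, 5.0]], ["C", "C"], [10.0, 10.0, 20.0],
        molecule_id=[1, 1],
    )
    _, centers = molecule_centers(cfg)
    assert centers[0, 0] == pytest.approx(10.0, abs=1e-9) or \
           centers[0, 0] == pytest.approx(0.0, abs=1e-9)
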