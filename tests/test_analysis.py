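"""Analysis metrics: RMSD/RMSF, SASA, contacts, capture radius."""

import numpy as np
import pytest

from flycast.analysis import (ContactCriterion, capture_radius_series,
                              contact_count, normalized_complex_sasa,
                              rmsd_by_segments, rmsd_series, rmsf, sasa)
from flycast.errors import FlycastError, SelectionError
from flycast.structure_io import Selection
from flycast.synthetic_data import (make_breathing_helix,
                                    make_jitter_trajectory,
                                    make_synthetic_phospho_pocket)

from conftest import ideal_helix, make_structure


def static_trajectory(base, frames=5, transform=None):
    from flycast.dynamics import Trajectory

    coords = np.repeat(base.coord[None], frames, axis=0)
    if transform is not None:
        for f in range(frames):
            coords[f] = transform(coords[f], f)
    return Trajectory(
        template=base,
        step_index=np.arange(1, frames + 1),
        region=np.full(frames, "II"),
        coords=coords,
        bias_energy=np.zeros(frames),
        potential_energy=np.zeros(frames),
    )


def rot_z(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])


CAL = Selection("A", None, "calpha")


class TestRmsd:
    def test_reference_copies_give_zero(self):
        base = ideal_helix(12)
        series = rmsd_series(static_trajectory(base), base, CAL, CAL)
        assert np.allclose(series.values, 0.0, atol=1e-10)

    def test_rigid_motion_is_removed_by_superposition(self):
        base = ideal_helix(12)
        traj = static_trajectory(
            base, transform=lambda c, f: c @ rot_z(0.3 * f).T + f)
        series = rmsd_series(traj, base, CAL, CAL)
        assert np.allclose(series.values, 0.0, atol=1e-8)

    def test_matches_independent_scipy_kabsch_oracle(self):
        """Per-frame RMSD equals scipy Rotation.align_vectors residual."""
        from scipy.spatial.transform import Rotation

        base = ideal_helix(10)
        traj = make_jitter_trajectory(base, sigma=0.8, frames=10, seed=4)
        series = rmsd_series(traj, base, CAL, CAL)
        for f in range(10):
            mob = traj.coords[f] - traj.coords[f].mean(axis=0)
            ref = base.coord - base.coord.mean(axis=0)
            _, rssd = Rotation.align_vectors(ref, mob)
            assert series.values[f] == pytest.approx(
                rssd / np.sqrt(len(ref)), abs=1e-9)

    def test_invariant_to_rigid_transform_of_every_frame(self):
        base = ideal_helix(14)
        traj = make_jitter_trajectory(base, sigma=0.5, frames=6, seed=9)
        s0 = rmsd_series(traj, base, CAL, CAL)
        moved = static_trajectory(base, frames=6)
        moved.coords = traj.coords @ rot_z(1.0).T + np.array([5.0, -2.0, 1.0])
        s1 = rmsd_series(moved, base, CAL, CAL)
        assert np.allclose(s0.values, s1.values, atol=1e-9)


class TestRmsdSegments:
    def test_whole_selection_rmsd_recovered_from_segments(self):
        """Atom-count-weighted mean of segment RMSD² equals whole RMSD²."""
        base = ideal_helix(30)
        traj = make_jitter_trajectory(base, sigma=1.0, frames=5, seed=2)
        segments = [(1, 10), (11, 18), (19, 30)]
        by_seg = rmsd_by_segments(traj, base, CAL, segments, "A")
        counts = np.array([10, 8, 12])
        whole = rmsd_series(traj, base, CAL, CAL)
        seg_sq = np.array([by_seg[k].values ** 2 for k in by_seg])
        combined = np.sqrt((counts[:, None] * seg_sq).sum(axis=0)
                           / counts.sum())
        assert np.allclose(combined, whole.values, atol=1e-9)

    def test_static_single_residue_segment_is_zero(self):
        base = ideal_helix(10)
        by_seg = rmsd_by_segments(static_trajectory(base), base, CAL,
                                  [(5, 5)], "A")
        assert np.allclose(by_seg["5-5"].values, 0.0, atol=1e-10)

    def test_default_study_segments_resolve_on_long_chain(self):
        """The three default AANAT-style windows (1–25, 30–57, 141–198)
        resolve to three series on a 1–200 numbered chain."""
        base = ideal_helix(200)
        traj = static_trajectory(base, frames=2)
        by_seg = rmsd_by_segments(traj, base, CAL,
                                  [(1, 25), (30, 57), (141, 198)], "A")
        assert len(by_seg) == 3

    def test_overlapping_segments_rejected(self):
        base = ideal_helix(20)
        with pytest.raises(ValueError):
            rmsd_by_segments(static_trajectory(base), base, CAL,
                             [(1, 10), (10, 20)], "A")


class TestRmsf:
    def test_static_trajectory_gives_zeros(self):
        base = ideal_helix(10)
        series = rmsf(static_trajectory(base), CAL, CAL)
        assert np.allclose(series.values, 0.0, atol=1e-10)

    def test_isotropic_jitter_converges_to_sigma_sqrt3(self):
        """No-fit RMSF of iid Gaussian jitter is σ√3 (σ = 0.5 → 0.866)."""
        base = ideal_helix(8)
        traj = make_jitter_trajectory(base, sigma=0.5, frames=4000, seed=7)
        series = rmsf(traj, None, CAL)
        assert np.allclose(series.values, 0.5 * np.sqrt(3), rtol=0.05)

    def test_frame_order_invariance(self):
        base = ideal_helix(8)
        traj = make_jitter_trajectory(base, sigma=0.4, frames=50, seed=3)
        fwd = rmsf(traj, None, CAL)
        traj.coords = traj.coords[::-1].copy()
        rev = rmsf(traj, None, CAL)
        assert np.allclose(fwd.values, rev.values)

    def test_empty_window_rejected(self):
        base = ideal_helix(8)
        traj = make_jitter_trajectory(base, sigma=0.1, frames=10, seed=1)
        with pytest.raises(FlycastError):
            rmsf(traj, None, CAL, window=(100, 200))


class TestSasa:
    def test_single_carbon_is_analytic_sphere(self):
        """Isolated C atom: 4π(1.7+1.4)² ≈ 120.76 Ų, exact at any
        point count (no neighbor can bury a point)."""
        s = make_structure([[0.0, 0.0, 0.0]])
        total, per_atom = sasa(s)
        assert total == pytest.approx(4 * np.pi * 3.1 ** 2, rel=1e-12)

    def test_distant_atoms_are_additive(self):
        s = make_structure([[0.0, 0, 0], [100.0, 0, 0]], res_per_atom=[1, 2])
        total, _ = sasa(s)
        assert total == pytest.approx(2 * 4 * np.pi * 3.1 ** 2, rel=1e-12)

    def test_overlapping_spheres_match_monte_carlo_oracle(self):
        """Two C spheres 2 Å apart vs 10⁶-point MC surface integration."""
        s = make_structure([[0.0, 0, 0], [2.0, 0, 0]], res_per_atom=[1, 2])
        total, _ = sasa(s, sphere_points=960)
        rng = np.random.default_rng(123)
        R = 1.7 + 1.4
        centers = s.coord
        mc_total = 0.0
        for i in range(2):
            pts = rng.standard_normal((1_000_000, 3))
            pts /= np.linalg.norm(pts, axis=1)[:, None]
            pts = centers[i] + R * pts
            other = centers[1 - i]
            exposed = np.sum(np.sum((pts - other) ** 2, axis=1) > R * R)
            mc_total += exposed / 1_000_000 * 4 * np.pi * R * R
        assert total == pytest.approx(mc_total, rel=0.01)

    def test_rigid_motion_invariance_below_point_noise(self):
        """Total SASA is rotation/translation invariant up to the point
        sampling: ~0.3% worst-case at 960 points (the same scale biotite's
        independent implementation shows), shrinking with point count."""
        base = ideal_helix(15)
        t0, _ = sasa(base)
        moved = base.with_coord(base.coord @ rot_z(0.77).T + 11.0)
        t1, _ = sasa(moved)
        assert abs(t1 - t0) / t0 < 5e-3
        t0f, _ = sasa(base, sphere_points=7680)
        t1f, _ = sasa(moved, sphere_points=7680)
        assert abs(t1f - t0f) / t0f < 1e-3

    def test_agrees_with_biotite_oracle(self):
        """Independent Shrake–Rupley implementation (biotite) on the same
        radii set agrees within discretization error."""
        import biotite.structure as bts

        base = ideal_helix(15)
        total, _ = sasa(base, sphere_points=2000)
        arr = bts.AtomArray(base.n_atoms)
        arr.chain_id = base.chain_id
        arr.res_id = base.res_id
        arr.res_name = base.res_name
        arr.atom_name = base.atom_name
        arr.element = base.element
        arr.coord = base.coord.astype(np.float32)
        oracle = bts.sasa(arr, vdw_radii="Single", point_number=2000).sum()
        assert total == pytest.approx(oracle, rel=0.02)

    def test_unknown_element_rejected_listing_atom(self):
        s = make_structure([[0.0, 0, 0]], elements=["XX"], masses=[1.0])
        with pytest.raises(FlycastError, match="XX"):
            sasa(s)


class TestNormalizedSasa:
    def test_distant_chains_give_100_percent(self):
        coords = np.vstack([np.zeros((3, 3)) + np.arange(3)[:, None] * 4,
                            np.zeros((3, 3)) + np.arange(3)[:, None] * 4
                            + np.array([200.0, 0, 0])])
        s = make_structure(coords, chain=["A"] * 3 + ["B"] * 3,
                           res_per_atom=[1, 2, 3, 1, 2, 3])
        val = normalized_complex_sasa(s, (Selection("A"), Selection("B")))
        assert val == pytest.approx(100.0, abs=1e-9)

    def test_bounded_and_symmetric_on_toy_complex(self, toy_dimer):
        _, _, native, _ = toy_dimer
        a, b = Selection("A"), Selection("B")
        v1 = normalized_complex_sasa(native, (a, b), radius_override=3.0)
        v2 = normalized_complex_sasa(native, (b, a), radius_override=3.0)
        assert v1 == pytest.approx(v2, abs=1e-9)
        assert 0.0 < v1 < 100.0  # real burial at the interface

    def test_overlapping_partition_rejected(self, toy_dimer):
        _, _, native, _ = toy_dimer
        with pytest.raises(FlycastError):
            normalized_complex_sasa(
                native, (Selection("A"), Selection("A")),
                radius_override=3.0)


class TestContacts:
    def test_no_matching_atoms_gives_zero(self):
        s = make_structure([[0.0, 0, 0], [3.0, 0, 0]], chain=["A", "B"],
                           res_per_atom=[1, 1])  # carbons only
        assert contact_count(s, Selection("A"), Selection("B")) == 0

    def test_crafted_n_o_pair_within_cutoff(self):
        s = make_structure([[0.0, 0, 0], [3.0, 0, 0]], chain=["A", "B"],
                           res_per_atom=[1, 1], atom_names=["N", "O"],
                           elements=["N", "O"])
        assert contact_count(s, Selection("A"), Selection("B")) == 1
        crit = ContactCriterion(cutoff=2.5)
        assert contact_count(s, Selection("A"), Selection("B"), crit) == 0

    def test_symmetric_at_atom_pair_level(self):
        s = make_synthetic_phospho_pocket()
        a, b = Selection("A"), Selection("B")
        assert contact_count(s, a, b) == contact_count(s, b, a)

    def test_phospho_pocket_residue_level_count_is_three(self):
        """Three basic residues contact the phosphate within 3.5 Å; the
        decoy residue beyond the cutoff is not counted."""
        s = make_synthetic_phospho_pocket()
        phosphate = Selection("B", frozenset([31]),
                              ("P", "O1P", "O2P", "O3P"))
        basics = Selection("A", frozenset([49, 56, 127, 173]), "sidechain")
        crit = ContactCriterion(cutoff=3.5, level="residue")
        assert contact_count(s, phosphate, basics, crit) == 3


class TestCaptureRadius:
    def test_rigid_selection_is_constant(self):
        base = ideal_helix(29)
        traj = static_trajectory(
            base, transform=lambda c, f: c @ rot_z(0.2 * f).T + 2 * f)
        series = capture_radius_series(traj, CAL)
        assert np.allclose(series.values, series.values[0], atol=1e-9)

    def test_breathing_helix_amplitude_scaling(self):
        """Max−min of the capture-radius series doubles when the imposed
        breathing amplitude doubles (29 residues, helix-9-like length)."""
        t1 = make_breathing_helix(29, amplitude=0.4, period=50)
        t2 = make_breathing_helix(29, amplitude=0.8, period=50)
        e1 = np.ptp(capture_radius_series(t1, CAL).values)
        e2 = np.ptp(capture_radius_series(t2, CAL).values)
        assert e2 == pytest.approx(2 * e1, rel=0.01)
        assert e1 > 0

    def test_uniform_doubling_doubles_series(self):
        base = ideal_helix(10)
        traj = static_trajectory(base, frames=2,
                                 transform=lambda c, f: c * (1 + f))
        series = capture_radius_series(traj, CAL)
        assert series.values[1] == pytest.approx(2 * series.values[0])

    def test_single_point_selection_rejected(self):
        base = ideal_helix(10)
        traj = static_trajectory(base)
        with pytest.raises(SelectionError, match="window"):
            capture_radius_series(
                traj, Selection("A", frozenset([5]), "calpha"))
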