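import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from il18design import (
    ContactCriteria, Frame, GeneratorConfig, HBondCriteria, Trajectory,
    align_trajectory, detect_hbonds, distance_pattern, gen_toy_structure,
    gen_trajectory, mean_hbond_count, per_residue_rmsd, read_frame,
    read_trajectory, rmsd_series, rmsd_summary, rmsf, superpose,
    write_frame, write_trajectory, contact_timeseries,
)
from il18design.trajectory import (
    TrajectoryError, analysis_window, dha_angle, donor_hydrogen_pairs,
    hbond_count_series, kabsch,
)


def make_frame(coords, atom_names=None, elements=None, res_ids=None,
               res_names=None, chains=None):
    coords = np.asarray(coords, float)
    n = len(coords)
    return Frame(
        atom_name=np.array(atom_names or ["CA"] * n, dtype="U6"),
        res_name=np.array(res_names or ["GLY"] * n, dtype="U4"),
        res_id=np.array(res_ids if res_ids is not None else np.arange(1, n + 1), dtype=int),
        chain_id=np.array(chains or ["A"] * n, dtype="U4"),
        element=np.array(elements or ["C"] * n, dtype="U2"),
        coords=coords,
    )


def rigid_copy(frame, rng):
    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.uniform(-10, 10, 3)
    out = frame.copy()
    out.coords = frame.coords @ R.T + t
    return out


class TestSuperpose:
    def test_identity(self, toy):
        _, r = superpose(toy.frame, toy.frame)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_rigid_copy_recovers_zero_rmsd(self, toy, rng):
        moved = rigid_copy(toy.frame, rng)
        fitted, r = superpose(moved, toy.frame)
        assert r < 1e-6
        assert np.abs(fitted.coords - toy.frame.coords).max() < 1e-6

    def test_matches_rotation_grid_oracle(self, rng):
        # 4-atom toy, one atom displaced: seeded random-rotation search with
        # shrinking perturbations approximates the global minimum
        ref = np.array([[0, 0, 0], [1.5, 0, 0], [0, 1.5, 0], [0, 0, 1.5]], float)
        mob = ref.copy()
        mob[3] += [0.4, -0.3, 0.2]
        mob = mob @ Rotation.random(random_state=rng).as_matrix().T + [3, -2, 1]

        def grid_rmsd(R):
            rot = mob @ R.T
            rot = rot - rot.mean(0) + ref.mean(0)
            return np.sqrt(np.mean(np.sum((rot - ref) ** 2, axis=1)))

        best_R, best = None, np.inf
        for R in Rotation.random(4000, random_state=rng):
            r = grid_rmsd(R.as_matrix())
            if r < best:
                best, best_R = r, R
        for scale in (0.3, 0.1, 0.03, 0.01, 0.003):
            for vec in rng.normal(0, scale, (2000, 3)):
                R = Rotation.from_rotvec(vec) * best_R
                r = grid_rmsd(R.as_matrix())
                if r < best:
                    best, best_R = r, R

        R, t = kabsch(mob, ref)
        kabsch_rmsd = np.sqrt(np.mean(np.sum((mob @ R.T + t - ref) ** 2, axis=1)))
        assert kabsch_rmsd <= best + 1e-3
        assert abs(kabsch_rmsd - best) < 1e-3

    def test_proper_rotation_enforced(self, rng):
        pts = rng.normal(0, 2, (6, 3))
        mirrored = pts * np.array([1, 1, -1])
        R, _ = kabsch(mirrored, pts)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_inputs_rejected(self, toy):
        line = make_frame([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(TrajectoryError):
            superpose(line, line, selection=np.ones(4, bool))
        small = make_frame([[0, 0, 0], [1, 0, 0]])
        with pytest.raises(TrajectoryError):
            superpose(small, small, selection=np.ones(2, bool))
        with pytest.raises(TrajectoryError):
            superpose(toy.frame, small)


class TestRmsd:
    def test_static_trajectory_is_zero(self, toy):
        traj = Trajectory(toy.frame.atom_name, toy.frame.res_name, toy.frame.res_id,
                          toy.frame.chain_id, toy.frame.element,
                          np.repeat(toy.frame.coords[None], 5, axis=0))
        assert rmsd_series(traj, toy.frame) == pytest.approx(np.zeros(5), abs=1e-12)

    def test_translated_copies_align_to_zero(self, toy, rng):
        coords = np.stack([toy.frame.coords + rng.uniform(-8, 8, 3) for _ in range(6)])
        traj = Trajectory(toy.frame.atom_name, toy.frame.res_name, toy.frame.res_id,
                          toy.frame.chain_id, toy.frame.element, coords)
        assert rmsd_series(traj, toy.frame).max() < 1e-9

    def test_gaussian_jitter_matches_sqrt3_sigma(self, toy, jitter_traj):
        series = rmsd_series(jitter_traj, toy.frame)
        assert np.mean(series) == pytest.approx(math.sqrt(3) * 0.5, rel=0.10)

    def test_summary_window_and_quality_flag(self):
        series = np.concatenate([np.full(1500, 9.0), np.full(1000, 1.5)])
        s = rmsd_summary(series, discard_frac=0.6)
        assert (s.window.start, s.window.stop) == (1500, 2500)
        assert s.mean == pytest.approx(1.5) and s.acceptable
        assert not rmsd_summary(np.full(10, 5.0)).acceptable


class TestPerResidueRmsd:
    def test_static_gives_zero_matrix(self, toy):
        traj = gen_trajectory(toy.frame, GeneratorConfig(
            seed=0, n_frames=4, base_amplitude=0.0))
        _, mat = per_residue_rmsd(traj, toy.frame)
        assert np.abs(mat).max() < 1e-9

    def test_planted_loop_rows_dominate(self, toy):
        cfg = GeneratorConfig(seed=9, n_frames=60, base_amplitude=0.05,
                              loop_region=(8, 12), loop_amplitude_factor=10.0)
        traj = gen_trajectory(toy.frame, cfg)
        keys, mat = per_residue_rmsd(traj, toy.frame)
        mean_per_res = mat.mean(axis=1)
        loop = np.array([8 <= r <= 12 for _, r in keys])
        assert mean_per_res[loop].min() > 3 * mean_per_res[~loop].max()

    def test_single_frame_consistent_with_global_rmsd(self, toy, rng):
        coords = toy.frame.coords + rng.normal(0, 0.3, toy.frame.coords.shape)
        traj = Trajectory(toy.frame.atom_name, toy.frame.res_name, toy.frame.res_id,
                          toy.frame.chain_id, toy.frame.element, coords[None])
        keys, mat = per_residue_rmsd(traj, toy.frame)
        # backbone atoms split evenly (4 per residue): the global backbone RMSD
        # is the quadratic mean of the per-residue values
        global_rmsd = rmsd_series(traj, toy.frame)[0]
        assert math.sqrt(np.mean(mat[:, 0] ** 2)) == pytest.approx(global_rmsd, abs=1e-9)


class TestRmsf:
    def test_static_gives_zero(self, toy):
        traj = gen_trajectory(toy.frame, GeneratorConfig(
            seed=0, n_frames=5, base_amplitude=0.0))
        _, vals = rmsf(traj, toy.frame)
        assert np.abs(vals).max() < 1e-9

    def test_isotropic_sigma_half_matches_analytic(self, toy, jitter_traj):
        _, vals = rmsf(jitter_traj, toy.frame)
        expected = math.sqrt(3) * 0.5
        assert np.abs(vals - expected).max() < 0.05 * expected * 2.5  # 300 frames
        assert vals.mean() == pytest.approx(expected, rel=0.05)

    def test_planted_loop_amplitude_recovered_as_argmax(self, toy):
        cfg = GeneratorConfig(seed=21, n_frames=200, base_amplitude=0.3,
                              loop_region=(8, 12), loop_amplitude_factor=3.0)
        traj = gen_trajectory(toy.frame, cfg)
        keys, vals = rmsf(traj, toy.frame)
        chain, res = keys[int(np.argmax(vals))]
        assert 8 <= res <= 12

    def test_parseval_consistency_with_trace(self, toy, jitter_traj):
        # sum over CA atoms of rmsf^2 equals the total fluctuation trace
        keys, vals = rmsf(jitter_traj, toy.frame)
        aligned = align_trajectory(jitter_traj, toy.frame)
        ca = toy.frame.ca_mask()
        coords = aligned.coords[:, ca, :]
        total = np.sum(np.var(coords, axis=0))
        assert np.sum(vals ** 2) == pytest.approx(total, rel=1e-9)

    def test_empty_window_rejected(self, toy, jitter_traj):
        with pytest.raises(TrajectoryError):
            rmsf(jitter_traj, toy.frame, discard_frac=1.0)

    def test_invariant_under_global_rigid_motion(self, toy):
        base_cfg = dict(n_frames=80, base_amplitude=0.4,
                        loop_region=(8, 12), loop_amplitude_factor=2.0)
        plain = gen_trajectory(toy.frame, GeneratorConfig(seed=33, **base_cfg))
        moved = gen_trajectory(toy.frame, GeneratorConfig(
            seed=33, rigid_transforms=True, **base_cfg))
        # same seed: identical jitter, then extra rigid motion per frame
        _, v1 = rmsf(plain, toy.frame)
        _, v2 = rmsf(moved, toy.frame)
        assert np.abs(v1 - v2).max() < 1e-6


class TestDistancePattern:
    def test_three_four_five_centroid(self):
        # backbone atoms symmetric about (3,4,0): centroid distance is 5
        offsets = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0]], float)
        coords = offsets + [3, 4, 0]
        frame = make_frame(coords, atom_names=["N", "CA", "C", "O"],
                           elements=["N", "C", "C", "O"], res_ids=[1, 1, 1, 1])
        traj = Trajectory(frame.atom_name, frame.res_name, frame.res_id,
                          frame.chain_id, frame.element, frame.coords[None])
        keys, vals = distance_pattern(traj, frame)
        assert keys == [("A", 1)]
        assert vals[0] == pytest.approx(5.0, abs=1e-12)

    def test_static_equals_single_frame(self, toy):
        static = Trajectory(toy.frame.atom_name, toy.frame.res_name, toy.frame.res_id,
                            toy.frame.chain_id, toy.frame.element,
                            np.repeat(toy.frame.coords[None], 7, axis=0))
        single = Trajectory(toy.frame.atom_name, toy.frame.res_name, toy.frame.res_id,
                            toy.frame.chain_id, toy.frame.element,
                            toy.frame.coords[None])
        _, v_static = distance_pattern(static, toy.frame)
        _, v_single = distance_pattern(single, toy.frame)
        assert v_static == pytest.approx(v_single, abs=1e-12)

    def test_matches_two_loop_oracle(self, rng):
        toy10 = gen_toy_structure(10, with_acceptor=False)
        traj = gen_trajectory(toy10.frame, GeneratorConfig(
            seed=17, n_frames=50, base_amplitude=0.4, loop_region=(0, 0)))
        keys, vals = distance_pattern(traj, toy10.frame)
        aligned = align_trajectory(traj, toy10.frame)
        ref = toy10.frame
        for (chain, rid), value in zip(keys, vals):
            mask = ref.residue_mask(chain, rid) & ref.backbone_mask()
            acc = []
            for f in range(aligned.n_frames):
                center = aligned.coords[f][mask].mean(axis=0)
                acc.append(math.sqrt(float(center @ center)))
            assert value == pytest.approx(np.mean(acc), abs=1e-9)

    def test_incomplete_backbone_residue_excluded(self, toy):
        # the engineered water (chain W) lacks N/CA/C: never reported
        traj = Trajectory(toy.frame.atom_name, toy.frame.res_name, toy.frame.res_id,
                          toy.frame.chain_id, toy.frame.element,
                          toy.frame.coords[None])
        keys, _ = distance_pattern(traj, toy.frame)
        assert ("W", 1) not in keys


class TestHbonds:
    def hb_frame(self, d_no, angle):
        n = np.array([0.0, 0.0, 0.0])
        h = np.array([0.0, -1.0, 0.0])
        theta = math.radians(angle)
        c = math.cos(theta)
        h_a = c + math.sqrt(c * c - 1 + d_no ** 2)
        a = h + h_a * np.array([math.sin(theta), c, 0.0])
        return make_frame([n, h, a], atom_names=["N", "H", "O"],
                          elements=["N", "H", "O"], res_ids=[1, 1, 2])

    @pytest.mark.parametrize("d,angle,expected", [
        (2.9, 175.0, 1),   # classic strong bond
        (3.6, 180.0, 0),   # distance boundary violated
        (3.0, 149.0, 0),   # angle boundary violated
        (3.5, 150.0, 1),   # both criteria inclusive
    ])
    def test_geometric_criteria(self, d, angle, expected):
        frame = self.hb_frame(d, angle)
        found = detect_hbonds(frame)
        assert len(found) == expected
        if expected:
            assert found == [(0, 1, 2)]
            assert dha_angle(*frame.coords) == pytest.approx(angle, abs=1e-6)

    def test_engineered_toy_bond_detected(self, toy):
        assert detect_hbonds(toy.frame) == [toy.hbond_triple]

    def test_engineered_near_miss_not_detected(self):
        miss = gen_toy_structure(20, hbond_distance=3.6)
        assert detect_hbonds(miss.frame) == []

    def test_no_hydrogens_instructs_protonation(self):
        frame = make_frame([[0, 0, 0], [3, 0, 0]], atom_names=["N", "O"],
                           elements=["N", "O"])
        with pytest.raises(TrajectoryError, match="protonate"):
            detect_hbonds(frame)

    def test_matches_all_triples_oracle_over_seeds(self):
        criteria = HBondCriteria()
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = 30
            elements = rng.choice(["N", "O", "C", "H"], size=n, p=[0.2, 0.2, 0.3, 0.3])
            coords = rng.uniform(0, 8, (n, 3))
            frame = make_frame(coords, atom_names=list(elements),
                               elements=list(elements),
                               res_ids=list(range(1, n + 1)))
            if not (elements == "H").any():
                continue
            # independent oracle: plain loops over every (donor, H, acceptor)
            expected = set()
            no_idx = [i for i in range(n) if elements[i] in "NO"]
            for h in range(n):
                if elements[h] != "H":
                    continue
                dists = {i: np.linalg.norm(coords[i] - coords[h]) for i in no_idx}
                if not dists:
                    continue
                d = min(dists, key=dists.get)
                if dists[d] > 1.2:
                    continue
                for a in no_idx:
                    if a == d:
                        continue
                    if np.linalg.norm(coords[d] - coords[a]) > 3.5:
                        continue
                    v1, v2 = coords[d] - coords[h], coords[a] - coords[h]
                    cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    if math.degrees(math.acos(max(-1, min(1, cosang)))) >= 150:
                        expected.add((d, h, a))
            assert set(detect_hbonds(frame, criteria)) == expected

    def test_chain_restriction(self, toy):
        # the only bond is A-donor to W-acceptor: vanishes when restricted to A
        assert detect_hbonds(toy.frame, chains=["A"]) == []

    def test_donor_pairs_require_covalent_hydrogen(self, toy):
        pairs = donor_hydrogen_pairs(toy.frame)
        for d, h in pairs:
            assert toy.frame.element[d] in ("N", "O")
            assert np.linalg.norm(toy.frame.coords[d] - toy.frame.coords[h]) < 1.2


class TestMeanHbondCount:
    def make_static_traj(self, frame, n_frames):
        return Trajectory(frame.atom_name, frame.res_name, frame.res_id,
                          frame.chain_id, frame.element,
                          np.repeat(frame.coords[None], n_frames, axis=0))

    def test_static_count_exact(self, toy):
        traj = self.make_static_traj(toy.frame, 10)
        assert mean_hbond_count(traj, discard_frac=0.0) == pytest.approx(1.0)

    def test_window_arithmetic_honored(self):
        assert analysis_window(2500, 0.6) == slice(1500, 2500)
        assert analysis_window(10, 0.0) == slice(0, 10)

    def test_toggled_bond_adds_half(self, toy):
        on = gen_toy_structure(20, hbond_distance=2.9)
        off = gen_toy_structure(20, hbond_distance=3.6)
        coords = np.stack([on.frame.coords if i % 2 == 0 else off.frame.coords
                           for i in range(10)])
        traj = Trajectory(on.frame.atom_name, on.frame.res_name, on.frame.res_id,
                          on.frame.chain_id, on.frame.element, coords)
        assert mean_hbond_count(traj, discard_frac=0.0) == pytest.approx(0.5)
        series = hbond_count_series(traj)
        assert list(series) == [1, 0] * 5


class TestContacts:
    def two_group_frame(self, distance):
        # ASP carboxylate midpoint at origin; LYS NZ at the given distance
        coords = [[0.5, 0, 0], [-0.5, 0, 0],       # OD1, OD2 -> midpoint (0,0,0)
                  [distance, 0, 0]]                # NZ
        return make_frame(coords, atom_names=["OD1", "OD2", "NZ"],
                          elements=["O", "O", "N"],
                          res_names=["ASP", "ASP", "LYS"],
                          res_ids=[37, 37, 25])

    @pytest.mark.parametrize("d,expected", [
        (3.5, "strong"), (4.5, "within"), (7.0, "long_range"), (5.5, "neither")])
    def test_electrostatic_classes(self, d, expected):
        frame = self.two_group_frame(d)
        traj = Trajectory(frame.atom_name, frame.res_name, frame.res_id,
                          frame.chain_id, frame.element, frame.coords[None])
        dists, labels = contact_timeseries(
            traj, (("A", 37), ("A", 25), "electrostatic"))
        assert dists[0] == pytest.approx(d, abs=1e-12)
        assert labels == [expected]

    def test_ring_centroid_is_vertex_mean(self):
        ring_names = ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]
        angles = np.linspace(0, 2 * math.pi, 6, endpoint=False)
        ring = np.c_[1.4 * np.cos(angles), 1.4 * np.sin(angles), np.zeros(6)] + [2, 1, -1]
        coords = np.vstack([ring, [[8, 1, -1], [9, 1, -1]]])
        frame = make_frame(coords, atom_names=ring_names + ["OD1", "OD2"],
                           elements=["C"] * 6 + ["O", "O"],
                           res_names=["PHE"] * 6 + ["ASP"] * 2,
                           res_ids=[10] * 6 + [20] * 2)
        traj = Trajectory(frame.atom_name, frame.res_name, frame.res_id,
                          frame.chain_id, frame.element, frame.coords[None])
        dists, labels = contact_timeseries(traj, (("A", 20), ("A", 10), "anion_pi"))
        assert dists[0] == pytest.approx(np.linalg.norm(
            ring.mean(axis=0) - [8.5, 1, -1]), abs=1e-9)

    def test_cation_pi_requires_aromatic_partner(self):
        frame = self.two_group_frame(4.0)
        traj = Trajectory(frame.atom_name, frame.res_name, frame.res_id,
                          frame.chain_id, frame.element, frame.coords[None])
        with pytest.raises(TrajectoryError):
            contact_timeseries(traj, (("A", 25), ("A", 37), "cation_pi"))

    def test_criteria_ordering_enforced(self):
        with pytest.raises(ValueError):
            ContactCriteria(electro_pi_max=7.0, longrange_min=6.0)


class TestPdbIO:
    def test_frame_roundtrip_to_pdb_precision(self, toy, tmp_path):
        path = tmp_path / "toy.pdb"
        write_frame(path, toy.frame)
        back = read_frame(path)
        assert np.abs(back.coords - toy.frame.coords).max() < 1e-3
        assert list(back.atom_name) == list(toy.frame.atom_name)
        assert list(back.res_id) == list(toy.frame.res_id)

    def test_trajectory_roundtrip(self, toy, tmp_path):
        traj = gen_trajectory(toy.frame, GeneratorConfig(seed=5, n_frames=3))
        path = tmp_path / "traj.pdb"
        write_trajectory(path, traj)
        back = read_trajectory(path)
        assert back.n_frames == 3
        assert np.abs(back.coords - traj.coords).max() < 1e-3

    def test_single_model_read_as_one_frame(self, toy, tmp_path):
        path = tmp_path / "one.pdb"
        write_frame(path, toy.frame)
        traj = read_trajectory(path)
        assert traj.n_frames == 1
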