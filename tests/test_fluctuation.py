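"""RMSD primitives, score matrix, motif selection and RMSF baseline."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from flexmotif.fluctuation import (
    ScoreMatrix,
    kabsch_rmsd,
    raw_rmsd,
    rmsf_baseline,
    score_transitions,
    select_high_fluctuation,
)
from flexmotif.neighborhood import ConfigError, SphereParams, build_spheres
from flexmotif.structure_io import ResidueId
from flexmotif.synthetic import SynthSpec, make_trajectory
from flexmotif.trajectory import Trajectory

from _oracles import direct_rmsd, grid_search_min_rmsd


class TestRawRmsd:
    def test_identity_is_zero(self, rng):
        a = rng.normal(size=(7, 3))
        assert raw_rmsd(a, a) == 0.0

    def test_pure_translation_gives_norm(self, rng):
        a = rng.normal(size=(6, 3))
        assert raw_rmsd(a, a + np.array([3.0, 4.0, 0.0])) == pytest.approx(5.0, abs=1e-12)

    def test_matches_direct_loop_oracle(self, rng):
        a = rng.normal(size=(4, 3)) * 3
        b = rng.normal(size=(4, 3)) * 3
        assert raw_rmsd(a, b) == pytest.approx(direct_rmsd(a, b), abs=1e-12)

    def test_length_mismatch_and_empty_rejected(self):
        with pytest.raises(ValueError):
            raw_rmsd(np.zeros((3, 3)), np.zeros((4, 3)))
        with pytest.raises(ValueError):
            raw_rmsd(np.zeros((0, 3)), np.zeros((0, 3)))


class TestKabschRmsd:
    def test_rigid_motion_invisible(self, rng):
        a = rng.normal(size=(10, 3)) * 4
        rot = Rotation.from_euler("xyz", [0.4, -1.1, 2.2]).as_matrix()
        b = a @ rot.T + np.array([5.0, -2.0, 7.0])
        assert kabsch_rmsd(a, b) <= 1e-8

    def test_matches_grid_search_oracle_on_fixed_point_sets(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            a = rng.normal(size=(4, 3)) * 2
            b = rng.normal(size=(4, 3)) * 2
            assert kabsch_rmsd(a, b) == pytest.approx(grid_search_min_rmsd(a, b), abs=1e-3)

    def test_matches_scipy_align_vectors(self, rng):
        a = rng.normal(size=(12, 3)) * 3
        b = rng.normal(size=(12, 3)) * 3
        ac, bc = a - a.mean(0), b - b.mean(0)
        _, rssd = Rotation.align_vectors(ac, bc)
        assert kabsch_rmsd(a, b) == pytest.approx(rssd / np.sqrt(len(a)), abs=1e-9)

    def test_no_reflection_allowed(self):
        # a mirror image must NOT score zero: only proper rotations
        rng = np.random.default_rng(3)
        a = rng.normal(size=(6, 3)) * 2
        b = a * np.array([1.0, 1.0, -1.0])
        assert kabsch_rmsd(a, b) > 0.1

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_superposed_never_exceeds_raw(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 20))
        a = rng.normal(size=(n, 3)) * 5
        b = rng.normal(size=(n, 3)) * 5
        assert kabsch_rmsd(a, b) <= raw_rmsd(a, b) + 1e-9

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        st.integers(min_value=0, max_value=10_000),
        st.floats(min_value=0.1, max_value=10.0),
    )
    def test_both_modes_scale_linearly_with_coordinates(self, seed, k):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(8, 3)) * 3
        b = rng.normal(size=(8, 3)) * 3
        assert raw_rmsd(k * a, k * b) == pytest.approx(k * raw_rmsd(a, b), rel=1e-9)
        assert kabsch_rmsd(k * a, k * b) == pytest.approx(k * kabsch_rmsd(a, b), rel=1e-7, abs=1e-9)

    def test_permutation_invariance(self, rng):
        a = rng.normal(size=(9, 3))
        b = rng.normal(size=(9, 3))
        perm = rng.permutation(9)
        assert raw_rmsd(a[perm], b[perm]) == pytest.approx(raw_rmsd(a, b), abs=1e-12)
        assert kabsch_rmsd(a[perm], b[perm]) == pytest.approx(kabsch_rmsd(a, b), abs=1e-9)


def _score_setup(spec: SynthSpec, d: float = 5.0):
    traj = make_trajectory(spec)
    spheres = build_spheres(traj, SphereParams(radius_d=d))
    return traj, spheres


class TestScoreTransitions:
    def test_static_trajectory_scores_all_zero(self):
        traj, spheres = _score_setup(SynthSpec(n_residues=8, n_frames=5))
        for mode in ("raw", "superposed"):
            m = score_transitions(traj, spheres, mode)
            assert m.scores.shape == (8, 4)
            assert np.all(m.scores == 0.0)

    def test_global_translation_contract(self):
        traj, spheres = _score_setup(
            SynthSpec(n_residues=10, n_frames=4, translation=(3.0, 4.0, 0.0))
        )
        raw = score_transitions(traj, spheres, "raw")
        sup = score_transitions(traj, spheres, "superposed")
        assert np.allclose(raw.scores, 5.0, atol=1e-9)
        assert np.all(sup.scores <= 1e-8)

    def test_global_rotation_invisible_to_superposed(self):
        traj, spheres = _score_setup(
            SynthSpec(n_residues=10, n_frames=3, rotation_angle=0.3)
        )
        sup = score_transitions(traj, spheres, "superposed")
        raw = score_transitions(traj, spheres, "raw")
        assert np.all(sup.scores <= 1e-8)
        assert np.all(raw.scores > 0.01)

    def test_perturbed_window_dominates_its_column(self):
        spec = SynthSpec(n_residues=30, n_frames=5, perturbed_window=(10, 12),
                         perturbation_sigma=1.5, seed=42)
        traj, spheres = _score_setup(spec)
        m = score_transitions(traj, spheres, "superposed")
        window = set(range(9, 12))  # 0-based residues 10-12
        for t in range(m.n_transitions):
            top_row = int(np.argmax(m.scores[:, t]))
            members = set(spheres[top_row].member_residues.tolist())
            assert members & window

    def test_matrix_matches_per_sphere_loop_oracle(self):
        spec = SynthSpec(n_residues=12, n_frames=4, perturbed_window=(4, 6),
                         perturbation_sigma=1.0, seed=9)
        traj, spheres = _score_setup(spec)
        m = score_transitions(traj, spheres, "raw")
        for i, sph in enumerate(spheres):
            for t in range(traj.n_frames - 1):
                a = traj.frames[t, sph.member_atom_indices]
                b = traj.frames[t + 1, sph.member_atom_indices]
                assert m.scores[i, t] == pytest.approx(direct_rmsd(a, b), abs=1e-9)

    def test_too_short_trajectory_rejected(self):
        traj, spheres = _score_setup(SynthSpec(n_residues=5, n_frames=2))
        short = Trajectory(topology=traj.topology, frames=traj.frames[:1])
        with pytest.raises(ValueError, match="too short"):
            score_transitions(short, spheres)

    def test_invalid_mode_rejected(self, static_trajectory):
        spheres = build_spheres(static_trajectory, SphereParams())
        with pytest.raises(ConfigError, match="rmsd_mode"):
            score_transitions(static_trajectory, spheres, "weighted")


def _matrix(scores: np.ndarray) -> ScoreMatrix:
    ids = [ResidueId("A", i + 1) for i in range(scores.shape[0])]
    return ScoreMatrix(scores=scores, residue_ids=ids, rmsd_mode="raw")


class TestSelectHighFluctuation:
    def test_p100_selects_every_cell(self, rng):
        m = _matrix(rng.uniform(0, 2, size=(4, 6)))
        sel = select_high_fluctuation(m, 100.0)
        assert sel.selected_count == sel.candidate_count == 24

    def test_ceiling_forces_single_global_maximum(self, rng):
        scores = rng.uniform(0, 1, size=(3, 3))  # R=3, F=4
        scores[1, 2] = 5.0
        sel = select_high_fluctuation(_matrix(scores), 10.0)
        assert sel.selected_count == 1  # ceil(0.9)
        assert sel.motifs[0].residue_index == 1
        assert sel.motifs[0].transition == 2
        assert sel.motifs[0].score == pytest.approx(5.0)

    def test_all_equal_scores_use_documented_tie_break(self):
        sel = select_high_fluctuation(_matrix(np.ones((2, 3))), 50.0)
        # ceil(3) = 3 cells; order: earlier transition, then lower residue
        picked = [(m.transition, m.residue_index) for m in sel.motifs]
        assert picked == [(0, 0), (0, 1), (1, 0)]

    def test_ranks_descend_with_score(self, rng):
        m = _matrix(rng.uniform(0, 3, size=(6, 5)))
        sel = select_high_fluctuation(m, 40.0)
        scores = [mo.score for mo in sel.motifs]
        assert scores == sorted(scores, reverse=True)
        assert [mo.rank for mo in sel.motifs] == list(range(1, len(scores) + 1))

    def test_deterministic_repeat_calls(self, rng):
        m = _matrix(rng.uniform(0, 3, size=(5, 5)))
        a = select_high_fluctuation(m, 33.0)
        b = select_high_fluctuation(m, 33.0)
        assert [(x.rank, x.residue_index, x.transition, x.score) for x in a.motifs] == \
               [(x.rank, x.residue_index, x.transition, x.score) for x in b.motifs]

    @pytest.mark.parametrize("p", [0.0, -1.0, 100.1])
    def test_invalid_percentage_rejected(self, p, rng):
        with pytest.raises(ConfigError):
            select_high_fluctuation(_matrix(rng.uniform(size=(2, 2))), p)


class TestRmsfBaseline:
    def test_static_trajectory_rmsf_zero(self, static_trajectory):
        assert np.all(rmsf_baseline(static_trajectory) == 0.0)

    def test_alternating_ca_gives_unit_rmsf(self):
        # one residue, CA alternating between x=0 and x=2: mean x=1, dev 1
        traj = make_trajectory(SynthSpec(n_residues=1, n_frames=4))
        frames = traj.frames.copy()
        ca_idx = 1
        for f in range(4):
            frames[f, ca_idx, 0] = 0.0 if f % 2 == 0 else 2.0
        assert rmsf_baseline(Trajectory(topology=traj.topology, frames=frames))[0] == \
               pytest.approx(1.0, abs=1e-12)

    def test_matches_two_pass_oracle_on_random_walk(self, rng):
        from _oracles import two_pass_rmsf

        traj = make_trajectory(SynthSpec(n_residues=6, n_frames=8))
        steps = rng.normal(0, 0.5, size=traj.frames.shape)
        frames = traj.frames + np.cumsum(steps, axis=0)
        traj = Trajectory(topology=traj.topology, frames=frames)
        ca_idx = [idx[r.ca_index] for r, idx in zip(
            traj.topology.residues, traj.topology.residue_atom_indices())]
        expected = two_pass_rmsf(traj.frames[:, ca_idx, :])
        assert np.allclose(rmsf_baseline(traj), expected, atol=1e-10)

    def test_single_frame_rejected(self):
        traj = make_trajectory(SynthSpec(n_residues=3, n_frames=1))
        with pytest.raises(ValueError, match="too short"):
            rmsf_baseline(traj)


def test_signal_recovery_across_seeds():
    """With a >= 1 A perturbation window and no drift, the top-ranked
    motif's sphere must contain a perturbed residue in >= 19/20 runs."""
    hits = 0
    window = set(range(11, 14))  # 0-based residues 12-14
    for seed in range(20):
        spec = SynthSpec(n_residues=30, n_frames=5, perturbed_window=(12, 14),
                         perturbation_sigma=1.0, seed=seed)
        traj = make_trajectory(spec)
        spheres = build_spheres(traj, SphereParams(radius_d=5.0))
        matrix = score_transitions(traj, spheres, "superposed")
        top = select_high_fluctuation(matrix, 0.1).motifs[0]
        if set(spheres[top.residue_index].member_residues.tolist()) & window:
            hits += 1
    assert hits >= 19
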