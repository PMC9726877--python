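"""Trajectory statistics: distances, conformer classes, populations, RMSF."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from helioproton.structure import Selection, write_pdb
from helioproton.synthetic import TrajectorySpec, gen_trajectory_set, markov_stationary
from helioproton.trajectory import (
    ConformerLabels,
    DistanceSeries,
    Trajectory,
    classify_gate,
    classify_trp246,
    distance_series,
    populations,
    rmsf,
    rmsf_table,
    trajectory_from_pdb,
    trajectory_from_xyz,
)

TRP_PAIR = (("A", 26, "OE1"), ("A", 246, "NE1"))


def _static_spec(**kw):
    base = dict(
        seed=1, n_frames=10, noise_sigma=0.0,
        transition=((1.0, 0.0), (0.0, 1.0)), start="state:0",
        distance_means=((3.0,), (7.5,)), distance_sds=((0.0,), (0.0,)),
    )
    base.update(kw)
    return TrajectorySpec(**base)


class TestDistanceSeries:
    def test_constant_trajectory_gives_constant_series(self):
        trajs, _ = gen_trajectory_set(_static_spec(distance_means=((4.2,), (7.5,))))
        d = distance_series(trajs[0], *TRP_PAIR)
        np.testing.assert_allclose(d.values, 4.2)

    def test_swap_endpoints_identical(self):
        trajs, _ = gen_trajectory_set(TrajectorySpec(seed=2, n_frames=50))
        a = distance_series(trajs[0], *TRP_PAIR)
        b = distance_series(trajs[0], *TRP_PAIR[::-1])
        np.testing.assert_array_equal(a.values, b.values)

    def test_noiseless_generator_distances_recovered_exactly(self):
        trajs, truth = gen_trajectory_set(TrajectorySpec(seed=3, n_frames=200,
                                                         noise_sigma=0.0))
        d = distance_series(trajs[0], *TRP_PAIR)
        np.testing.assert_allclose(d.values, truth.drawn_distances[0, :, 0], atol=1e-12)

    def test_missing_atom_names_address(self):
        trajs, _ = gen_trajectory_set(TrajectorySpec(seed=2, n_frames=2))
        with pytest.raises(ValueError, match="A/26/XX"):
            distance_series(trajs[0], ("A", 26, "XX"), ("A", 246, "NE1"))


class TestClassification:
    @pytest.mark.parametrize(
        "d,label",
        [(3.4, "in_hb"), (3.5, "in_nohb"), (4.7, "in_nohb"),
         (6.0, "in_nohb"), (6.5, "out")],
    )
    def test_trp246_thresholds(self, d, label):
        """d < 3.5: Trp-in with H-bond; 3.5 <= d <= 6.0: Trp-in without;
        d > 6.0: Trp-out (boundaries inclusive on the in/no-H-bond side)."""
        labels = classify_trp246(DistanceSeries(np.array([d]), pair="t"))
        assert labels.labels[0] == label

    @pytest.mark.parametrize(
        "d1,d2,label",
        [(3.0, 3.2, "closed"), (4.0, 3.8, "open"), (3.0, 4.2, "mixed"),
         (3.5, 3.5, "open"), (3.49, 3.5, "mixed")],
    )
    def test_gate_rule(self, d1, d2, label):
        """Closed needs both H-bond distances < 3.5 A; open needs both >= 3.5;
        anything else is outside both pure classes."""
        out = classify_gate(
            DistanceSeries(np.array([d1]), pair="a"),
            DistanceSeries(np.array([d2]), pair="b"),
        )
        assert out.labels[0] == label

    def test_every_frame_gets_exactly_one_label(self):
        trajs, _ = gen_trajectory_set(TrajectorySpec(seed=5, n_frames=300))
        labels = classify_trp246(distance_series(trajs[0], *TRP_PAIR))
        assert len(labels) == 300

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            classify_gate(DistanceSeries(np.array([3.0]), "a"),
                          DistanceSeries(np.array([3.0, 3.1]), "b"))


class TestPopulations:
    def test_single_replicate_all_out(self):
        labels = ConformerLabels(np.array(["out"] * 8), scheme="trp246", replicate="r1")
        pop = populations([labels])
        assert pop.fractions.loc["r1", "out"] == 1.0
        assert pop.fractions.loc["pooled", "out"] == 1.0

    def test_fractions_normalize_per_row(self):
        trajs, _ = gen_trajectory_set(TrajectorySpec(seed=6, n_frames=400))
        pop = populations([classify_trp246(distance_series(t, *TRP_PAIR))
                           for t in trajs])
        np.testing.assert_allclose(pop.fractions.sum(axis=1), 1.0, atol=1e-12)

    def test_pooled_matches_markov_stationary_within_3se(self):
        """Five replicates of a symmetric two-state chain: pooled 'out'
        fraction agrees with the stationary probability 0.5."""
        spec = TrajectorySpec(seed=7, n_replicates=5, n_frames=1000,
                              transition=((0.9, 0.1), (0.1, 0.9)))
        trajs, truth = gen_trajectory_set(spec)
        pop = populations([classify_trp246(distance_series(t, *TRP_PAIR))
                           for t in trajs])
        p = truth.stationary[1]
        # effective sample size shrinks by the chain's autocorrelation time
        rho = 0.9 - 0.1  # lambda_2 of the symmetric chain
        n_eff = 5000 * (1 - rho) / (1 + rho)
        se = np.sqrt(p * (1 - p) / n_eff)
        assert abs(pop.fractions.loc["pooled", "out"] - p) <= 3 * se

    def test_dwell_times_match_transition_matrix(self):
        """Mean dwell length in a state is 1/(1-P_ss)."""
        spec = TrajectorySpec(seed=8, n_replicates=5, n_frames=1000,
                              transition=((0.95, 0.05), (0.8, 0.2)))
        trajs, truth = gen_trajectory_set(spec)
        states = truth.hidden_states
        dwells = []
        for r in range(states.shape[0]):
            run = 1
            for f in range(1, states.shape[1]):
                if states[r, f] == states[r, f - 1] and states[r, f] == 0:
                    run += 1
                elif states[r, f - 1] == 0:
                    dwells.append(run)
                    run = 1
                else:
                    run = 1
        mean_dwell = np.mean(dwells)
        expect = 1.0 / 0.05
        se = np.std(dwells, ddof=1) / np.sqrt(len(dwells))
        assert abs(mean_dwell - expect) <= 3 * se

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            populations([])


class TestRMSF:
    def test_static_trajectory_zero_everywhere(self):
        trajs, _ = gen_trajectory_set(_static_spec())
        r = rmsf(trajs[0])
        np.testing.assert_allclose(r.values, 0.0, atol=1e-12)

    def test_gaussian_noise_approaches_sigma_sqrt3(self):
        """iid isotropic noise with per-coordinate sigma gives per-atom RMSF
        -> sigma*sqrt(3) (no alignment, 1000 frames, 5% band)."""
        sigma = 0.2
        trajs, _ = gen_trajectory_set(_static_spec(n_frames=1000, noise_sigma=sigma))
        r = rmsf(trajs[0], align=None)
        np.testing.assert_allclose(r.values, sigma * np.sqrt(3.0), rtol=0.05)

    def test_identical_replicates_have_zero_sd(self):
        trajs, _ = gen_trajectory_set(_static_spec(n_frames=20, noise_sigma=0.1))
        clones = [Trajectory(trajs[0].template, trajs[0].frames, replicate=f"c{i}")
                  for i in range(5)]
        table = rmsf_table(clones)
        np.testing.assert_allclose(table.sd.values, 0.0, atol=1e-12)

    def test_rigid_motion_invariance_with_alignment(self):
        trajs, _ = gen_trajectory_set(_static_spec(n_frames=50, noise_sigma=0.15))
        t = trajs[0]
        rot = Rotation.from_euler("xyz", [20, -35, 70], degrees=True).as_matrix()
        moved = Trajectory(t.template, t.frames @ rot.T + np.array([3.0, -1.0, 9.0]),
                           replicate=t.replicate)
        a = rmsf(t)
        b = rmsf(moved)
        np.testing.assert_allclose(b.values, a.values, atol=1e-8)

    def test_delta_rmsf_of_identical_states_is_zero(self):
        trajs, _ = gen_trajectory_set(_static_spec(n_frames=30, noise_sigma=0.1))
        table = rmsf_table(trajs)
        np.testing.assert_allclose(table.delta(table).values, 0.0, atol=1e-15)

    def test_single_frame_errors(self):
        trajs, _ = gen_trajectory_set(_static_spec(n_frames=2))
        t = Trajectory(trajs[0].template, trajs[0].frames[:1])
        with pytest.raises(ValueError, match="2 frames"):
            rmsf(t)

    def test_rmsf_cross_checked_against_mdanalysis(self):
        """Independent oracle: MDAnalysis RMSF on the same multi-model PDB
        (no alignment, so both packages measure raw fluctuations)."""
        mda = pytest.importorskip("MDAnalysis")
        from MDAnalysis.analysis.rms import RMSF as MDARMSF

        trajs, _ = gen_trajectory_set(_static_spec(n_frames=40, noise_sigma=0.2))
        t = trajs[0]
        import io, warnings

        pdb_text = write_pdb([t.template.with_coords(f) for f in t.frames])
        import tempfile, os

        with tempfile.NamedTemporaryFile("w", suffix=".pdb", delete=False) as fh:
            fh.write(pdb_text)
            path = fh.name
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                u = mda.Universe(path)
                ref = MDARMSF(u.atoms).run().results.rmsf
            mean = t.frames.mean(axis=0)
            ours = np.sqrt(np.mean(np.sum((t.frames - mean) ** 2, axis=2), axis=0))
            np.testing.assert_allclose(ours, ref, atol=2e-3)  # PDB has 3 decimals
        finally:
            os.unlink(path)


class TestTrajectoryIO:
    def test_multi_model_pdb_roundtrip(self):
        trajs, _ = gen_trajectory_set(_static_spec(n_frames=5, noise_sigma=0.05))
        t = trajs[0]
        text = write_pdb([t.template.with_coords(f) for f in t.frames])
        again = trajectory_from_pdb(text)
        assert again.n_frames == 5
        np.testing.assert_allclose(again.frames, t.frames, atol=5e-4)

    def test_xyz_with_roster_sidecar(self):
        trajs, _ = gen_trajectory_set(_static_spec(n_frames=3))
        t = trajs[0]
        lines = []
        for f in t.frames:
            lines.append(str(len(t.template)))
            lines.append("frame")
            for a, p in zip(t.template.atoms, f):
                lines.append(f"{a.element} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}")
        again = trajectory_from_xyz("\n".join(lines), t.template)
        np.testing.assert_allclose(again.frames, t.frames, atol=1e-6)

    def test_mismatched_rosters_error(self):
        trajs, _ = gen_trajectory_set(_static_spec(n_frames=2))
        t = trajs[0]
        text = write_pdb([t.template.with_coords(t.frames[0])])
        other = write_pdb([t.template.with_coords(t.frames[1])])
        other = other.replace("NE1", "NE2")
        merged = "MODEL 1\n" + text.replace("END\n", "") + "ENDMDL\nMODEL 2\n" \
            + other.replace("END\n", "") + "ENDMDL\n"
        with pytest.raises(ValueError, match="roster"):
            trajectory_from_pdb(merged)
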