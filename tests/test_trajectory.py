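"""Gating metrics, stability filtering, densities and frame selection."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from eaatkit.errors import DomainError, SelectionError
from eaatkit.structure import Atom, StructureModel, Trajectory
from eaatkit.trajectory import (
    ANCHOR_PRESETS,
    compute_chain_metrics,
    fit_trajectory,
    flag_unstable,
    ligand_rmsd,
    metrics_to_frame,
    pair_distance,
    pool_metric,
    protein_rmsd,
    rmsf,
    sampling_density,
    select_representative_frames,
)


def _toy_topology(n_res: int = 8) -> StructureModel:
    """Chain A: n_res CA atoms on a non-collinear path, a 2-atom ligand and
    one Na+ ion."""
    rng = np.random.default_rng(7)
    atoms = [Atom("A", 100 + i, "ALA", "CA", rng.uniform(-5, 5, 3))
             for i in range(n_res)]
    atoms += [Atom("A", 500, "ASP", "C1", [8.0, 0.0, 0.0], hetero=True),
              Atom("A", 500, "ASP", "C2", [9.4, 0.0, 0.0], hetero=True),
              Atom("A", 601, "NA", "NA", [0.0, 8.0, 0.0], hetero=True)]
    return StructureModel.from_atoms(atoms)


def _static_traj(top: StructureModel, n_frames: int = 5) -> Trajectory:
    return Trajectory(topology=top,
                      frames=np.repeat(top.coords[None], n_frames, axis=0))


def _tumbling_frames(coords: np.ndarray, n_frames: int,
                     rng: np.random.Generator) -> np.ndarray:
    frames = np.empty((n_frames, len(coords), 3))
    frames[0] = coords
    for f in range(1, n_frames):
        rot = Rotation.random(rng=rng).as_matrix()
        frames[f] = coords @ rot.T + rng.normal(0, 10, 3)
    return frames


class TestFitTrajectory:
    def test_static_trajectory_unchanged(self):
        top = _toy_topology()
        fitted = fit_trajectory(_static_traj(top), chain="A")
        assert np.allclose(fitted.frames, _static_traj(top).frames, atol=1e-9)

    def test_rigid_tumbling_collapses_to_frame0(self, rng):
        top = _toy_topology()
        traj = Trajectory(topology=top,
                          frames=_tumbling_frames(top.coords, 6, rng))
        fitted = fit_trajectory(traj, chain="A")
        for f in range(fitted.n_frames):
            assert np.allclose(fitted.frames[f], fitted.frames[0], atol=1e-8)

    def test_internal_motion_rmsd_matches_bruteforce_oracle(self, rng):
        """Post-fit RMSD equals independent per-frame optimal superposition
        computed with an explicit Kabsch re-derivation."""
        top = _toy_topology()
        base = top.coords
        ca = top.protein_ca_indices("A")
        frames = _tumbling_frames(base, 5, rng)
        internal = rng.normal(0, 0.4, frames.shape)
        frames = frames + internal
        traj = Trajectory(topology=top, frames=frames)
        series = protein_rmsd(fit_trajectory(traj, chain="A"), "A")

        ref = frames[0][ca]
        for f in range(5):
            mob = frames[f][ca]
            # independent oracle: textbook Kabsch, written without the
            # package's batched code path
            p = mob - mob.mean(0)
            q = ref - ref.mean(0)
            u, s, vt = np.linalg.svd(p.T @ q)
            d = np.sign(np.linalg.det(vt.T @ u.T))
            r = vt.T @ np.diag([1, 1, d]) @ u.T
            moved = p @ r.T + ref.mean(0)
            oracle = np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1)))
            assert series.values[f] == pytest.approx(oracle, abs=1e-9)


class TestProteinRmsd:
    def test_frame0_is_exactly_zero(self, small_traj_set):
        series = protein_rmsd(fit_trajectory(small_traj_set[0], chain="A"), "A")
        assert series.values[0] == 0.0
        assert np.all(series.values >= 0)

    def test_uniform_displacement_gives_displacement(self):
        top = _toy_topology()
        frames = np.repeat(top.coords[None], 2, axis=0)
        ca = top.protein_ca_indices("A")
        frames[1, ca] += np.array([1.0, 0.0, 0.0])
        # no fitting: direct RMSD semantics
        series = protein_rmsd(Trajectory(topology=top, frames=frames), "A")
        assert series.values[1] == pytest.approx(1.0, abs=1e-12)

    def test_formula_oracle_on_random_frame(self, rng):
        top = _toy_topology()
        frames = np.repeat(top.coords[None], 2, axis=0)
        ca = top.protein_ca_indices("A")
        delta = rng.normal(0, 1, (len(ca), 3))
        frames[1, ca] += delta
        series = protein_rmsd(Trajectory(topology=top, frames=frames), "A")
        oracle = np.sqrt(np.mean(np.sum(delta ** 2, axis=1)))
        assert series.values[1] == pytest.approx(oracle, abs=1e-12)

    def test_missing_chain_raises(self):
        with pytest.raises(SelectionError):
            protein_rmsd(_static_traj(_toy_topology()), "Z")


class TestLigandRmsd:
    def test_comoving_ligand_is_zero(self, rng):
        top = _toy_topology()
        traj = Trajectory(topology=top,
                          frames=_tumbling_frames(top.coords, 4, rng))
        series = ligand_rmsd(fit_trajectory(traj, chain="A"), "A")
        assert np.allclose(series.values, 0.0, atol=1e-8)

    def test_translated_ligand_measures_translation(self):
        top = _toy_topology()
        frames = np.repeat(top.coords[None], 2, axis=0)
        lig = top.indices_where(residue_number=500)
        frames[1, lig] += np.array([0.0, 2.0, 0.0])
        series = ligand_rmsd(Trajectory(topology=top, frames=frames), "A")
        assert series.values[1] == pytest.approx(2.0, abs=1e-12)

    def test_empty_selector_raises(self):
        with pytest.raises(SelectionError):
            ligand_rmsd(_static_traj(_toy_topology()), "A", residue_name="XYZ")


class TestRmsf:
    def test_static_is_zero(self):
        vals = rmsf(_static_traj(_toy_topology(), 4), "A")
        assert np.allclose(vals["rmsf_A"], 0.0)

    def test_fewer_than_two_frames_rejected(self):
        with pytest.raises(DomainError):
            rmsf(_static_traj(_toy_topology(), 1), "A")

    def test_sinusoidal_oscillation_closed_form(self):
        """One atom oscillating with amplitude a has RMSF a/sqrt(2)."""
        top = _toy_topology()
        n = 4000
        frames = np.repeat(top.coords[None], n, axis=0)
        a = 1.7
        phases = 2 * np.pi * np.arange(n) / 100.0  # many full periods
        frames[:, 0, 0] += a * np.sin(phases)
        vals = rmsf(Trajectory(topology=top, frames=frames), "A")
        assert vals["rmsf_A"].iloc[0] == pytest.approx(a / np.sqrt(2), rel=0.02)

    def test_isotropic_noise_closed_form(self, rng):
        """White-noise positions with sd sigma per axis give RMSF sqrt(3)·sigma."""
        top = _toy_topology()
        n, sigma = 1000, 0.8
        frames = np.repeat(top.coords[None], n, axis=0)
        frames[:, 1, :] += rng.normal(0, sigma, (n, 3))
        vals = rmsf(Trajectory(topology=top, frames=frames), "A")
        assert vals["rmsf_A"].iloc[1] == pytest.approx(np.sqrt(3) * sigma, rel=0.05)


class TestPairDistance:
    def test_coincident_and_pythagoras(self):
        atoms = [Atom("A", 1, "ALA", "CA", [0, 0, 0]),
                 Atom("A", 2, "ALA", "CA", [3, 4, 0]),
                 Atom("A", 3, "ALA", "CA", [0, 0, 0])]
        top = StructureModel.from_atoms(atoms)
        traj = _static_traj(top, 2)
        d12 = pair_distance(traj, "A", (1, "CA"), (2, "CA"))
        d13 = pair_distance(traj, "A", (1, "CA"), (3, "CA"))
        assert np.allclose(d12.values, 5.0)
        assert np.allclose(d13.values, 0.0)

    def test_preset_anchors_resolve_on_toy_trimer(self, small_traj_set):
        traj = small_traj_set[0]
        for name in ("hp2_opening", "na1_dist", "na2_dist", "na3_dist"):
            series = pair_distance(traj, "A", *ANCHOR_PRESETS[name],
                                   metric_name=name)
            assert np.all(series.values >= 0)

    def test_planted_gate_mean_recovered(self, small_traj_set):
        pooled = np.concatenate([
            pair_distance(t, "A", *ANCHOR_PRESETS["hp2_opening"]).values
            for t in small_traj_set])
        assert pooled.mean() == pytest.approx(6.0, abs=0.1)

    def test_unresolvable_anchor_named_in_error(self, small_traj_set):
        with pytest.raises(SelectionError, match="999"):
            pair_distance(small_traj_set[0], "A", (999, "CA"), (366, "CA"))


class TestFlagUnstable:
    @pytest.mark.parametrize("peak,expected", [
        (9.9, False),   # keep
        (10.0, True),   # "reaching" the threshold excludes
        (12.5, True),
    ])
    def test_boundary(self, peak, expected):
        series = np.concatenate([np.linspace(0, peak, 50), [1.0]])
        assert flag_unstable(series) is expected

    def test_monotone_in_threshold(self, rng):
        series = rng.uniform(0, 12, 200)
        excluded = [flag_unstable(series, thr) for thr in (8.0, 10.0, 12.5)]
        # raising the threshold never excludes more
        assert excluded == sorted(excluded, reverse=True)

    def test_planted_drifting_replicate_is_the_only_flagged(self):
        from eaatkit import synth
        spec = synth.TrajectoryGenSpec(n_frames=50, n_replicates=4,
                                       unstable_replicates=frozenset({3}),
                                       seed=9)
        flagged = set()
        for traj in synth.gen_trajectory(spec):
            for chain in ("A", "B", "C"):
                m = compute_chain_metrics(traj, chain, include_ions=False)
                if flag_unstable(m["protein_rmsd"]):
                    flagged.add((traj.replicate_id, chain))
        assert flagged == {(3, "A"), (3, "B"), (3, "C")}


class TestSamplingDensity:
    def test_single_point_mass_in_one_bin(self):
        dm = sampling_density(np.array([1.0, 1.0]), np.array([2.0, 2.0]), bins=5)
        areas = np.outer(np.diff(dm.x_edges), np.diff(dm.y_edges))
        assert (dm.density > 0).sum() == 1
        assert float((dm.density * areas).sum()) == pytest.approx(1.0, abs=1e-9)

    def test_total_mass_one_and_marginals_normalized(self, rng):
        x, y = rng.normal(0, 1, 5000), rng.normal(5, 2, 5000)
        dm = sampling_density(x, y)
        areas = np.outer(np.diff(dm.x_edges), np.diff(dm.y_edges))
        assert float((dm.density * areas).sum()) == pytest.approx(1.0, abs=1e-6)
        assert float((dm.marginal_x * np.diff(dm.x_edges)).sum()) == pytest.approx(1.0, abs=1e-6)
        assert float((dm.marginal_y * np.diff(dm.y_edges)).sum()) == pytest.approx(1.0, abs=1e-6)

    def test_two_planted_clusters_yield_two_local_maxima(self, rng):
        n = 4000
        x = np.concatenate([rng.normal(5, 0.3, n), rng.normal(10, 0.3, n)])
        y = np.concatenate([rng.normal(1, 0.2, n), rng.normal(3, 0.2, n)])
        dm = sampling_density(x, y, bins=40)
        flat = np.argsort(dm.density, axis=None)[-2:]
        peaks = set()
        for idx in flat:
            i, j = np.unravel_index(idx, dm.density.shape)
            cx = 0.5 * (dm.x_edges[i] + dm.x_edges[i + 1])
            cy = 0.5 * (dm.y_edges[j] + dm.y_edges[j + 1])
            peaks.add((round(cx), round(cy)))
        assert peaks == {(5, 1), (10, 3)}

    def test_empty_pool_is_an_error(self):
        with pytest.raises(DomainError, match="threshold"):
            sampling_density(np.array([]), np.array([]))


def _pool_from(values: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame({"replicate": 1, "chain": "A",
                         "frame": np.arange(len(values)), "value": values})


class TestFrameSelection:
    def test_constant_distribution_mean_exact_sd_zero(self):
        sel = select_representative_frames(_pool_from(np.full(50, 7.25)),
                                           k=5, seed=3)
        assert len(sel.frames) == 5
        assert sel.mean_A == pytest.approx(7.25)
        assert sel.sd_A == pytest.approx(0.0)

    def test_same_seed_same_selection(self, rng):
        pool = _pool_from(rng.normal(6.0, 0.3, 500))
        a = select_representative_frames(pool, seed=11)
        b = select_representative_frames(pool, seed=11)
        assert a.frames == b.frames
        assert np.array_equal(a.values_A, b.values_A)

    def test_unimodal_mode_recovered(self, rng):
        pool = _pool_from(rng.normal(10.5, 0.2, 3000))
        sel = select_representative_frames(pool, k=5, seed=2)
        assert sel.mean_A == pytest.approx(10.5, abs=0.2)

    def test_selected_values_inside_reported_window(self, rng):
        pool = _pool_from(rng.normal(6.0, 0.5, 2000))
        sel = select_representative_frames(pool, k=5, seed=4)
        lo, hi = sel.window_A
        assert np.all((sel.values_A >= lo) & (sel.values_A <= hi))

    def test_window_widened_once_when_sparse(self):
        # mode bin holds 6 frames; k=7 forces a one-step widening
        values = np.array([5.0, 5.02, 8.0, 8.1, 7.9, 2.0, 2.1, 1.9, 5.04])
        sel = select_representative_frames(_pool_from(values), k=7, seed=0)
        assert sel.widened
        assert len(sel.frames) == 7

    def test_impossible_k_raises(self):
        with pytest.raises(DomainError):
            select_representative_frames(_pool_from(np.array([1.0, 2.0])), k=5)


class TestRigidInvariance:
    def test_all_metrics_invariant_under_global_rigid_transform(self, rng,
                                                                small_traj_set):
        traj = small_traj_set[0]
        rot = Rotation.random(rng=rng).as_matrix()
        shift = np.array([12.0, -4.0, 9.0])
        moved = Trajectory(topology=traj.topology,
                           frames=traj.frames @ rot.T + shift,
                           dt_ps=traj.dt_ps, replicate_id=traj.replicate_id,
                           system_label=traj.system_label)
        m0 = compute_chain_metrics(traj, "A")
        m1 = compute_chain_metrics(moved, "A")
        for name in m0:
            assert np.allclose(m0[name].values, m1[name].values, atol=1e-8), name


def test_pool_metric_excludes_flagged_chains(small_traj_set):
    series = []
    for traj in small_traj_set:
        series.append(protein_rmsd(fit_trajectory(traj, chain="A"), "A"))
    df = metrics_to_frame(series)
    full = pool_metric(df, "protein_rmsd", chain="A")
    partial = pool_metric(df, "protein_rmsd", chain="A", excluded={(2, "A")})
    assert len(full) == 3 * small_traj_set[0].n_frames
    assert len(partial) == 2 * small_traj_set[0].n_frames
    assert 2 not in set(partial["replicate"])
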