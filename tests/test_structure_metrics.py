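"""Kabsch superposition, ensemble precision and RDC Q-factor."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from halfcam import structure_metrics as sm
from halfcam.synthetic_data import gen_ensemble


def toy_model(coords, offset=0):
    n = len(coords)
    return sm.Model(np.arange(1, n + 1) + offset, ["CA"] * n, np.asarray(coords, float))


class TestKabsch:
    def test_identical_models_zero_rmsd(self):
        c = np.random.default_rng(0).normal(size=(6, 3))
        _, _, rmsd = sm.kabsch(c, c)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_rotation_recovered(self):
        rng = np.random.default_rng(1)
        c = rng.normal(size=(8, 3))
        rot = Rotation.from_euler("zyx", [0.4, -1.1, 0.7]).as_matrix()
        moved = c @ rot.T + np.array([1.0, -2.0, 3.0])
        _, _, rmsd = sm.kabsch(moved, c)
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_four_atom_toy_matches_rotation_grid_oracle(self):
        # brute-force search over rotations (coarse-to-fine grid) must not
        # beat the closed-form Kabsch optimum by more than 1e-3 A
        rng = np.random.default_rng(2)
        p = rng.normal(size=(4, 3))
        q = rng.normal(size=(4, 3))
        _, _, rmsd = sm.kabsch(p, q)
        p0 = p - p.mean(axis=0)
        q0 = q - q.mean(axis=0)
        best = np.inf
        center = np.zeros(3)
        for step in (0.4, 0.05, 0.01):
            grid = np.arange(-4 * step, 4.01 * step, step)
            for ax in grid:
                for ay in grid:
                    for az in grid:
                        r = Rotation.from_rotvec(center + [ax, ay, az]).as_matrix()
                        val = np.sqrt(np.mean(np.sum((p0 @ r.T - q0) ** 2, axis=1)))
                        if val < best:
                            best, argbest = val, center + [ax, ay, az]
            center = argbest
        assert rmsd <= best + 1e-9
        assert best - rmsd < 1e-3

    def test_symmetry_of_rmsd(self):
        rng = np.random.default_rng(3)
        p, q = rng.normal(size=(5, 3)), rng.normal(size=(5, 3))
        assert sm.kabsch(p, q)[2] == pytest.approx(sm.kabsch(q, p)[2], rel=1e-12)

    def test_collinear_selection_rejected(self):
        line = np.outer(np.arange(4), [1.0, 0.0, 0.0])
        with pytest.raises(ValueError):
            sm.kabsch(line, line + 0.1)

    def test_superpose_matches_by_residue_and_atom(self):
        rng = np.random.default_rng(4)
        c = rng.normal(size=(10, 3))
        ref = toy_model(c)
        rot = Rotation.from_euler("xyz", [0.2, 0.3, -0.1]).as_matrix()
        mob = toy_model(c @ rot.T + 5.0)
        moved, rmsd = sm.superpose(mob, ref)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(moved.coords, ref.coords, atol=1e-10)


class TestEnsembleRmsd:
    def test_identical_models(self):
        ens = gen_ensemble(n_models=4, jitter_sd=0.0, seed=0)
        pair, to_mean = sm.ensemble_rmsd(ens, residues=(1, 30))
        assert pair == pytest.approx(0.0, abs=1e-12)
        assert to_mean == pytest.approx(0.0, abs=1e-12)

    def test_single_displaced_atom_analytic_case(self):
        # two models identical except one atom moved radially by d: the
        # optimal rotation stays the identity (symmetric cross-covariance),
        # only the centroid shift d/N is absorbed
        tet = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float)
        d = 1.0
        m1 = toy_model(tet)
        moved = tet.copy()
        moved[0] += d * tet[0] / np.linalg.norm(tet[0])
        m2 = toy_model(moved)
        pair, to_mean = sm.ensemble_rmsd(sm.Ensemble([m1, m2]), residues=(1, 4),
                                         atoms=("CA",))
        n = 4
        expected_pair = d * np.sqrt(((1 - 1 / n) ** 2 + (n - 1) / n**2) / n)
        assert pair == pytest.approx(expected_pair, abs=1e-9)
        assert to_mean == pytest.approx(expected_pair / 2, abs=1e-9)

    def test_jittered_ensemble_matches_monte_carlo_expectation(self):
        sd = 0.5
        ens = gen_ensemble(n_models=10, jitter_sd=sd, seed=5)
        pair, to_mean = sm.ensemble_rmsd(ens, residues=(1, 30))
        # E[RMSD to mean] ~ sd * sqrt(3 * (M-1)/M) for isotropic jitter
        expected = sd * np.sqrt(3 * 9 / 10)
        assert to_mean == pytest.approx(expected, abs=0.05)
        assert to_mean <= pair  # Jensen-type inequality

    def test_backbone_selection_variants(self):
        ens = gen_ensemble(n_models=5, jitter_sd=0.3, seed=6)
        full = sm.ensemble_rmsd(ens, residues=(5, 25), atoms=sm.BACKBONE_ATOMS)
        no_o = sm.ensemble_rmsd(ens, residues=(5, 25), atoms=sm.BACKBONE_ATOMS_NO_O)
        assert full[1] > 0 and no_o[1] > 0

    def test_empty_selection_rejected(self):
        ens = gen_ensemble(n_models=3, jitter_sd=0.1, seed=7)
        with pytest.raises(ValueError):
            sm.ensemble_rmsd(ens, residues=(200, 300))


def random_rdc(seed, n=20, noise=0.0):
    rng = np.random.default_rng(seed)
    vecs = rng.normal(size=(n, 3))
    saupe5 = rng.normal(size=5)
    a = sm._design_matrix(vecs / np.linalg.norm(vecs, axis=1)[:, None])
    d = a @ saupe5 + (rng.normal(0, noise, n) if noise else 0.0)
    return sm.RDCSet(vectors=vecs, d_meas=d), saupe5


class TestAlignmentTensor:
    def test_exact_recovery_noise_free(self):
        rdc, truth = random_rdc(0)
        saupe, d_calc = sm.fit_alignment_tensor(rdc)
        assert np.allclose(d_calc, rdc.d_meas, atol=1e-10)
        assert np.trace(saupe) == pytest.approx(0.0, abs=1e-12)
        assert saupe[0, 0] == pytest.approx(truth[0], abs=1e-10)

    def test_matches_normal_equations_oracle(self):
        rdc, _ = random_rdc(1, noise=1.0)
        _, d_calc = sm.fit_alignment_tensor(rdc)
        a = sm._design_matrix(rdc.vectors)
        x_oracle = np.linalg.solve(a.T @ a, a.T @ rdc.d_meas)
        assert np.allclose(d_calc, a @ x_oracle, atol=1e-10)

    def test_isotropic_zero_couplings(self):
        rdc = sm.RDCSet(np.random.default_rng(2).normal(size=(10, 3)), np.zeros(10))
        saupe, d_calc = sm.fit_alignment_tensor(rdc)
        assert np.allclose(saupe, 0.0)
        assert np.allclose(d_calc, 0.0)

    def test_too_few_or_degenerate_restraints_rejected(self):
        with pytest.raises(ValueError):
            sm.fit_alignment_tensor(sm.RDCSet(np.eye(3), np.ones(3)))
        same = np.tile([1.0, 0.0, 0.0], (8, 1))
        with pytest.raises(ValueError):
            sm.fit_alignment_tensor(sm.RDCSet(same, np.ones(8)))


class TestQFactor:
    @pytest.mark.parametrize(
        "d_meas, d_calc, expected",
        [
            ([5.0, -5.0], [5.0, -5.0], 0.0),
            ([5.0, -5.0], [0.0, 0.0], 1.0),
            ([5.0, -5.0], [4.0, -4.0], 0.2),
        ],
    )
    def test_values(self, d_meas, d_calc, expected):
        rdc = sm.RDCSet(np.tile([0.0, 0.0, 1.0], (2, 1)), np.array(d_meas),
                        d_calc=np.array(d_calc))
        assert sm.q_factor(rdc) == pytest.approx(expected)

    def test_scale_invariance(self):
        rdc, _ = random_rdc(3, noise=0.5)
        sm.fit_alignment_tensor(rdc)
        q1 = sm.q_factor(rdc)
        scaled = sm.RDCSet(rdc.vectors, 7.0 * rdc.d_meas, d_calc=7.0 * rdc.d_calc)
        assert sm.q_factor(scaled) == pytest.approx(q1, rel=1e-12)

    def test_zero_measured_rejected(self):
        rdc = sm.RDCSet(np.tile([0.0, 0.0, 1.0], (2, 1)), np.zeros(2), d_calc=np.ones(2))
        with pytest.raises(ValueError):
            sm.q_factor(rdc)


class TestPdbIO:
    def test_ensemble_roundtrip_through_pdb(self, tmp_path):
        ens = gen_ensemble(n_models=3, jitter_sd=0.2, seed=8)
        path = tmp_path / "synthetic_ensemble.pdb"
        lines = []
        for i, model in enumerate(ens.models, start=1):
            lines.append(f"MODEL     {i:4d}")
            for serial, (res, name, xyz) in enumerate(
                zip(model.res_ids, model.atom_names, model.coords), start=1
            ):
                lines.append(
                    f"ATOM  {serial:5d} {name:^4s}ALA A{res:4d}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           "
                    f"{name[0]:>2s}"
                )
            lines.append("ENDMDL")
        lines.append("END")
        path.write_text("\n".join(lines) + "\n")

        back = sm.read_pdb_ensemble(path)
        assert len(back.models) == 3
        pair0, mean0 = sm.ensemble_rmsd(ens, residues=(1, 30))
        pair1, mean1 = sm.ensemble_rmsd(back, residues=(1, 30))
        assert mean1 == pytest.approx(mean0, abs=2e-3)  # 3-decimal PDB precision
        assert pair1 == pytest.approx(pair0, abs=2e-3)
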