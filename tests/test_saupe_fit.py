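import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import rdctensor as rt
from rdctensor.couplings import dipolar_prefactor
from rdctensor.saupe_fit import FitError, matrix_to_s, s_to_matrix

from conftest import random_traceless


class TestQFactor:
    def test_perfect_agreement_is_zero(self):
        assert rt.qfactor([10.0, -5.0, 8.0], [10.0, -5.0, 8.0]) == 0.0

    def test_hand_computed_case(self):
        # residuals (1, -1, 1): sqrt(3 / (100 + 25 + 64)) = sqrt(3/189)
        q = rt.qfactor([10.0, -5.0, 8.0], [9.0, -4.0, 7.0])
        assert q == pytest.approx(math.sqrt(3 / 189), abs=1e-12)
        assert q == pytest.approx(0.1260, abs=1e-4)

    @pytest.mark.parametrize("c", [2.0, -1.0, 1e-3])
    def test_scale_invariance(self, c):
        d_exp = np.array([10.0, -5.0, 8.0])
        d_calc = np.array([9.0, -4.0, 7.0])
        assert rt.qfactor(c * d_exp, c * d_calc) == pytest.approx(
            rt.qfactor(d_exp, d_calc), rel=1e-12
        )

    def test_all_zero_experimental_undefined(self):
        with pytest.raises(ValueError, match="zero"):
            rt.qfactor([0.0, 0.0], [1.0, 2.0])


class TestTensorParams:
    def test_axial_tensor_descriptors(self):
        S = np.diag([-0.5, -0.5, 1.0]) * 1e-3
        t = rt.tensor_params(S)
        # gdo = sqrt(2/3 * (0.25 + 0.25 + 1) * 1e-6) = 1e-3 (max 1 for full order)
        assert t.gdo == pytest.approx(1.0e-3, rel=1e-12)
        assert t.rhombicity == pytest.approx(0.0, abs=1e-12)
        assert t.da == pytest.approx(0.5e-3, rel=1e-12)

    def test_zero_tensor(self):
        t = rt.tensor_params(np.zeros((3, 3)))
        assert t.gdo == 0.0
        np.testing.assert_allclose(t.eigvals, 0.0)

    def test_spectral_invariance_under_rotation(self):
        rng = np.random.default_rng(5)
        S = random_traceless(rng)
        R = Rotation.random(rng=rng).as_matrix()
        t1, t2 = rt.tensor_params(S), rt.tensor_params(R @ S @ R.T)
        np.testing.assert_allclose(t1.eigvals, t2.eigvals, atol=1e-15)
        assert t2.gdo == pytest.approx(t1.gdo, rel=1e-12)

    def test_eigvecs_proper_rotation(self):
        S = random_traceless(np.random.default_rng(8))
        t = rt.tensor_params(S)
        assert np.linalg.det(t.eigvecs) == pytest.approx(1.0, abs=1e-12)
        assert abs(t.eigvals[0]) >= abs(t.eigvals[1]) >= abs(t.eigvals[2])

    def test_rejects_non_traceless(self):
        with pytest.raises(ValueError, match="traceless"):
            rt.tensor_params(np.eye(3))

    def test_five_vector_roundtrip(self):
        S = random_traceless(np.random.default_rng(9))
        np.testing.assert_allclose(s_to_matrix(matrix_to_s(S)), S, atol=1e-18)


class TestDesignMatrix:
    def test_axis_aligned_closed_form(self):
        """A bond along z with axial S = diag(-1/2,-1/2,1)*s0 predicts kappa*s0."""
        conf = rt.Conformer(
            id="p",
            atoms=(
                rt.Atom("C1", "C", 12.011, np.zeros(3)),
                rt.Atom("H1", "H", 1.008, np.array([0.0, 0.0, 1.09])),
            ),
        )
        recs = [rt.CouplingRecord("C1", "H1", "CH", D=1.0, sigD=0.1)] * 5
        ds = rt.RDCDataset(records=list(recs))
        A, d, w = rt.build_design_matrix(conf, ds)
        s0 = 1e-3
        s = matrix_to_s(np.diag([-0.5, -0.5, 1.0]) * s0)
        kappa = dipolar_prefactor("CH", 1.09)
        np.testing.assert_allclose(A @ s, kappa * s0 * np.ones(5), rtol=1e-12)

    def test_single_direction_is_rank_one(self):
        conf = rt.Conformer(
            id="p",
            atoms=(
                rt.Atom("C1", "C", 12.011, np.zeros(3)),
                rt.Atom("H1", "H", 1.008, np.array([0.0, 0.0, 1.09])),
            ),
        )
        ds = rt.RDCDataset(
            records=[rt.CouplingRecord("C1", "H1", "CH", D=1.0, sigD=0.1)] * 6
        )
        A, _, _ = rt.build_design_matrix(conf, ds)
        assert np.linalg.matrix_rank(A) == 1

    def test_reproduces_simulator_forward_model(self, rigid_system):
        conf, S, ds = rigid_system
        A, d, _ = rt.build_design_matrix(conf, ds)
        np.testing.assert_allclose(A @ matrix_to_s(S.S), d, atol=1e-12)

    def test_too_few_records(self, rigid_system):
        conf, _, ds = rigid_system
        small = rt.RDCDataset(records=ds.records[:4])
        with pytest.raises(FitError, match=">= 5"):
            rt.build_design_matrix(conf, small)

    def test_excluded_records_leave_design(self, rigid_system):
        conf, _, ds = rigid_system
        flagged = [
            rt.CouplingRecord(r.atom1, r.atom2, r.ctype, D=r.D, sigD=r.sigD,
                              include=(i < 6))
            for i, r in enumerate(ds.records)
        ]
        A, _, _ = rt.build_design_matrix(conf, rt.RDCDataset(records=flagged))
        assert A.shape == (6, 5)


class TestFitSCST:
    def test_exact_recovery_from_noiseless_data(self, rigid_system):
        conf, S, ds = rigid_system
        fit = rt.fit_scst(conf, ds)
        assert np.abs(fit.tensor.S - S.S).max() < 1e-10 * np.linalg.norm(S.S)
        assert fit.q < 1e-10

    def test_matches_normal_equations_oracle(self, rigid_system):
        """SVD pseudo-inverse equals brute-force (A'W^2A)^-1 A'W^2 d."""
        conf, _, ds = rigid_system
        noisy = rt.RDCDataset(
            records=[
                rt.CouplingRecord(r.atom1, r.atom2, r.ctype, D=r.D + 0.1 * i,
                                  sigD=0.1 + 0.05 * i)
                for i, r in enumerate(ds.records)
            ]
        )
        A, d, w = rt.build_design_matrix(conf, noisy)
        W2 = np.diag(w**2)
        s_ref = np.linalg.solve(A.T @ W2 @ A, A.T @ W2 @ d)
        fit = rt.fit_scst(conf, noisy)
        np.testing.assert_allclose(matrix_to_s(fit.tensor.S), s_ref, rtol=1e-9)

    def test_rotation_equivariance(self, rigid_system):
        conf, _, ds = rigid_system
        R = Rotation.from_euler("zyz", [30, 45, 60], degrees=True).as_matrix()
        rotated = conf.with_coords(conf.coords @ R.T)
        f1, f2 = rt.fit_scst(conf, ds), rt.fit_scst(rotated, ds)
        np.testing.assert_allclose(f2.tensor.S, R @ f1.tensor.S @ R.T, atol=1e-9 * f1.tensor.gdo)
        assert f2.q == pytest.approx(f1.q, abs=1e-9)

    def test_equal_sigmas_match_unweighted(self, rigid_system):
        conf, _, ds = rigid_system
        equal = rt.RDCDataset(
            records=[rt.CouplingRecord(r.atom1, r.atom2, r.ctype, D=r.D, sigD=0.25)
                     for r in ds.records]
        )
        fw = rt.fit_scst(conf, equal, weighted=True)
        fu = rt.fit_scst(conf, equal, weighted=False)
        np.testing.assert_allclose(fw.tensor.S, fu.tensor.S, rtol=1e-12)

    def test_scaling_data_scales_tensor_not_q(self, rigid_system):
        conf, _, ds = rigid_system
        c = 3.7
        scaled = rt.RDCDataset(
            records=[rt.CouplingRecord(r.atom1, r.atom2, r.ctype, D=c * r.D,
                                       sigD=c * r.sigD)
                     for r in ds.records]
        )
        f1, f2 = rt.fit_scst(conf, ds), rt.fit_scst(conf, scaled)
        assert f2.q == pytest.approx(f1.q, abs=1e-9)
        np.testing.assert_allclose(f2.tensor.S, c * f1.tensor.S, rtol=1e-9)

    def test_noise_monotonicity_of_median_q(self):
        """Median Q over replicates does not decrease with the noise level."""
        medians = []
        for sigma in (0.0, 0.3, 1.0):
            qs = []
            for rep in range(100):
                spec = rt.SimulationSpec(n_vectors=10, gdo_target=5e-4,
                                         noise_sigma=sigma, seed=1000 + rep)
                conf, _ = rt.make_rigid_molecule(spec)
                S = rt.random_saupe(5e-4, 1000 + rep)
                ds = rt.simulate_rdcs([conf], S, [1.0], spec)
                qs.append(rt.fit_scst(conf, ds).q)
            medians.append(np.median(qs))
        assert medians[0] <= medians[1] <= medians[2]

    def test_rank_deficient_geometry_flagged(self):
        conf = rt.Conformer(
            id="p",
            atoms=(
                rt.Atom("C1", "C", 12.011, np.zeros(3)),
                rt.Atom("H1", "H", 1.008, np.array([0.0, 0.0, 1.09])),
            ),
        )
        ds = rt.RDCDataset(
            records=[rt.CouplingRecord("C1", "H1", "CH", D=5.0, sigD=0.1)] * 6
        )
        with pytest.warns(UserWarning, match="rank-deficient"):
            fit = rt.fit_scst(conf, ds)
        assert fit.rank_deficient and fit.condition == math.inf

    def test_json_report_schema(self, rigid_system):
        import json

        conf, _, ds = rigid_system
        report = json.loads(rt.fit_scst(conf, ds).to_json())
        assert set(report) >= {"tensor", "records", "q", "rmsd", "singvals", "condition"}
        assert len(report["records"]) == len(ds.records)
        assert set(report["records"][0]) == {"atom1", "atom2", "d_exp", "sigD", "d_calc", "residual"}
        assert len(report["singvals"]) == 5
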