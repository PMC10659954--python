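"""Seminario constants, RESP charges, torsion fits, evaluation and itp I/O."""

import numpy as np
import pytest

from ptmforge.ff import (AngleTerm, BondTerm, DegenerateHessianError,
                         HessianBundle, TorsionSeries, TorsionTerm,
                         bundled_snc_parameters, eval_angle, eval_bond,
                         eval_torsion, fit_torsion_series,
                         read_parameter_files, resp_fit, seminario_angle,
                         seminario_bond, write_parameter_files)
from ptmforge.fixtures import (make_harmonic_hessian, make_point_charge_esp,
                               make_torsion_profile)


class TestSeminarioBond:
    def test_diatomic_recovers_exactly(self):
        h = make_harmonic_hessian(["C", "C"], [[0, 0, 0], [1.5, 0, 0]],
                                  bonds=[(0, 1, 1000.0)])
        term = seminario_bond(h, 0, 1)
        assert term.kb == pytest.approx(1000.0, abs=1e-6)
        assert term.req == pytest.approx(0.15)

    def test_zero_block_is_degenerate(self):
        h = HessianBundle("alpha", ["C", "C"],
                          np.array([[0.0, 0, 0], [1.5, 0, 0]]), np.zeros((6, 6)))
        with pytest.raises(DegenerateHessianError):
            seminario_bond(h, 0, 1)

    def test_waterlike_bonds_within_one_percent(self):
        pos = np.array([[0.96, 0, 0], [0, 0, 0], [0, 0.96, 0]])
        h = make_harmonic_hessian(["H", "O", "H"], pos,
                                  bonds=[(0, 1, 500000.0), (1, 2, 480000.0)],
                                  angles=[(0, 1, 2, 400.0)])
        assert seminario_bond(h, 0, 1).kb == pytest.approx(500000.0, rel=0.01)
        assert seminario_bond(h, 1, 2).kb == pytest.approx(480000.0, rel=0.01)

    def test_conformer_average_is_order_independent(self):
        h1 = make_harmonic_hessian(["C", "C"], [[0, 0, 0], [1.50, 0, 0]],
                                   bonds=[(0, 1, 1000.0)], conformer="alpha")
        h2 = make_harmonic_hessian(["C", "C"], [[0, 0, 0], [1.54, 0, 0]],
                                   bonds=[(0, 1, 900.0)], conformer="beta")
        a = seminario_bond([h1, h2], 0, 1)
        b = seminario_bond([h2, h1], 0, 1)
        assert a.kb == pytest.approx(b.kb) == pytest.approx(950.0)
        assert a.req == pytest.approx(b.req) == pytest.approx(0.152)


class TestSeminarioAngle:
    def test_pure_bend_recovered_within_one_percent(self):
        pos = np.array([[1.0, 0, 0], [0, 0, 0], [0, 1.0, 0]])
        h = make_harmonic_hessian(["H", "O", "H"], pos,
                                  angles=[(0, 1, 2, 500.0)])
        term = seminario_angle(h, 0, 1, 2)
        assert term.k_theta == pytest.approx(500.0, rel=0.01)
        assert not term.corrected

    def test_theta_eq_equals_measured_angle(self):
        theta = np.deg2rad(104.5)
        pos = np.array([[0.96, 0, 0], [0, 0, 0],
                        [0.96 * np.cos(theta), 0.96 * np.sin(theta), 0]])
        h = make_harmonic_hessian(["H", "O", "H"], pos,
                                  bonds=[(0, 1, 500000.0), (1, 2, 500000.0)],
                                  angles=[(0, 1, 2, 400.0)])
        assert seminario_angle(h, 0, 1, 2).theta_eq == pytest.approx(104.5)

    def test_collinear_rejected(self):
        pos = np.array([[1.0, 0, 0], [0, 0, 0], [-1.0, 0, 0]])
        h = make_harmonic_hessian(["C", "C", "C"], pos,
                                  bonds=[(0, 1, 1000.0), (1, 2, 1000.0)])
        with pytest.raises(ValueError, match="collinear"):
            seminario_angle(h, 0, 1, 2)

    def test_shared_center_correction_reduces_stiffness(self):
        """Angles sharing a central atom are softened toward the true value;
        an angle without siblings keeps the plain (stiffer) estimate."""
        pos = np.array([[0, 0, 0], [1.0, 0, 0], [-0.5, 0.866, 0],
                        [-0.5, -0.5, 0.7]])
        angles = [(1, 0, 2, 450.0), (1, 0, 3, 450.0), (2, 0, 3, 450.0)]
        h = make_harmonic_hessian(["N", "H", "H", "H"], pos,
                                  bonds=[(0, i, 300000.0) for i in (1, 2, 3)],
                                  angles=angles)
        siblings = [(a, b, c) for a, b, c, _ in angles]
        for a, b, c, true_k in angles:
            plain = seminario_angle(h, a, b, c)
            corrected = seminario_angle(h, a, b, c, siblings=siblings)
            assert corrected.corrected and not plain.corrected
            assert corrected.k_theta < plain.k_theta
            assert abs(corrected.k_theta - true_k) < abs(plain.k_theta - true_k)


class TestRespFit:
    def test_single_charge_exact(self):
        esp = make_point_charge_esp([0.5], [[0.0, 0, 0]], 200, seed=11)
        charges = resp_fit([esp], restraint=0.0, formal_charge=0.5)
        assert charges["X1"] == pytest.approx(0.5, abs=1e-6)

    def test_charge_pair_recovered(self):
        esp = make_point_charge_esp([0.3, -0.3], [[0, 0, 0], [2.0, 0, 0]],
                                    400, seed=12)
        charges = resp_fit([esp], restraint=0.0, formal_charge=0.0)
        assert charges["X1"] == pytest.approx(0.3, abs=1e-4)
        assert charges["X2"] == pytest.approx(-0.3, abs=1e-4)

    def test_group_constraint_exact(self):
        esp = make_point_charge_esp([0.2, -0.1, -0.1],
                                    [[0, 0, 0], [1.6, 0, 0], [0, 1.6, 0]],
                                    600, seed=13)
        charges = resp_fit([esp], constraints=[(["X2", "X3"], 0.0)],
                           restraint=0.0, formal_charge=0.0)
        assert charges["X2"] + charges["X3"] == pytest.approx(0.0, abs=1e-12)

    def test_total_charge_constraint_holds_to_machine(self):
        esp = make_point_charge_esp([0.25, -0.05], [[0, 0, 0], [2.0, 0, 0]],
                                    300, seed=14)
        charges = resp_fit([esp], restraint=0.001, formal_charge=0.2)
        assert sum(charges.charges.values()) == pytest.approx(0.2, abs=1e-10)

    def test_multiconformer_fit_uses_all_samples(self):
        e1 = make_point_charge_esp([0.3, -0.3], [[0, 0, 0], [2.0, 0, 0]],
                                   300, seed=15, conformer="alpha")
        e2 = make_point_charge_esp([0.3, -0.3], [[0, 0, 0], [0, 2.0, 0]],
                                   300, seed=16, conformer="beta")
        charges = resp_fit([e1, e2], restraint=0.0, formal_charge=0.0)
        assert charges["X1"] == pytest.approx(0.3, abs=1e-4)

    def test_two_stage_equivalence_makes_charges_equal(self):
        pos = [[0, 0, 0], [1.6, 0, 0], [-1.6, 0.2, 0]]
        esp = make_point_charge_esp([0.2, -0.12, -0.08], pos, 600, seed=17)
        charges = resp_fit([esp], formal_charge=0.0,
                           methyl_equivalences=[["X2", "X3"]])
        assert charges["X2"] == pytest.approx(charges["X3"], abs=1e-12)

    def test_infeasible_constraints_rejected(self):
        esp = make_point_charge_esp([0.0], [[0.0, 0, 0]], 100, seed=18)
        with pytest.raises(ValueError, match="infeasible"):
            resp_fit([esp], constraints=[(["X1"], 1.0), (["X1"], 2.0)],
                     restraint=0.0, formal_charge=1.0)


class TestTorsionFit:
    def test_single_term_recovered(self):
        gen = TorsionSeries(("C", "S", "N", "O"), (TorsionTerm(2.0, 1, 0.0),))
        prof = make_torsion_profile(gen, np.arange(-180.0, 180.0, 15.0))
        series, rms = fit_torsion_series([prof], multiplicities=(1, 2, 3))
        by_n = {t.n: t for t in series.terms}
        assert by_n[1].k_phi == pytest.approx(2.0, abs=1e-6)
        assert by_n[1].phi_s == 0.0
        assert by_n[2].k_phi == pytest.approx(0.0, abs=1e-6)
        assert by_n[3].k_phi == pytest.approx(0.0, abs=1e-6)
        assert rms < 1e-6

    def test_flat_profile_gives_zeros(self):
        gen = TorsionSeries(("A", "B", "C", "D"), ())
        prof = make_torsion_profile(gen)
        series, rms = fit_torsion_series([prof], multiplicities=(1, 2, 3))
        assert all(t.k_phi == pytest.approx(0.0, abs=1e-12)
                   for t in series.terms)

    def test_bundled_series_refits_to_itself(self):
        snc = bundled_snc_parameters()
        gen = snc.torsion("CB", "SG", "ND", "OE")
        prof = make_torsion_profile(gen, np.arange(-180.0, 180.0, 10.0))
        series, rms = fit_torsion_series([prof], multiplicities=(1, 2, 3, 4))
        got = {(t.n): (t.k_phi, t.phi_s) for t in series.terms}
        for t in gen.terms:
            assert got[t.n][0] == pytest.approx(t.k_phi, abs=1e-3)
            assert got[t.n][1] == t.phi_s
        assert rms < 1e-6

    def test_underdetermined_rejected(self):
        gen = TorsionSeries(("A", "B", "C", "D"), (TorsionTerm(1.0, 1, 0.0),))
        prof = make_torsion_profile(gen, np.arange(-180.0, 180.0, 30.0))
        with pytest.raises(ValueError, match="grid points"):
            fit_torsion_series([prof], multiplicities=range(1, 13))

    def test_fit_then_evaluate_reproduces_generator_curve(self):
        gen = TorsionSeries(("C", "S", "N", "O"),
                            (TorsionTerm(1.1, 1, 0.0), TorsionTerm(27.3, 2, 180.0),
                             TorsionTerm(2.7, 3, 180.0)))
        prof = make_torsion_profile(gen, np.arange(-180.0, 180.0, 15.0))
        series, _ = fit_torsion_series([prof], multiplicities=(1, 2, 3))
        grid = np.arange(-180.0, 180.0, 5.0)
        err = [eval_torsion(series, p) - eval_torsion(gen, p) for p in grid]
        assert np.sqrt(np.mean(np.square(err))) < 1e-6


class TestEvaluation:
    def test_bond_zero_at_equilibrium(self):
        term = BondTerm(("C", "S"), 0.1803, 129555.1)
        assert eval_bond(term, 0.1803) == 0.0

    def test_no_bond_displacement_energy(self):
        snc = bundled_snc_parameters()
        term = snc.bond("ND", "OE")
        assert eval_bond(term, 0.1270) == pytest.approx(34.788, abs=1e-3)

    def test_angle_harmonic_in_radians(self):
        term = AngleTerm(("S", "N", "O"), 117.2, 1283.1)
        expected = 0.5 * 1283.1 * np.deg2rad(5.0) ** 2
        assert eval_angle(term, 122.2) == pytest.approx(expected)

    def test_csno_series_at_zero(self):
        snc = bundled_snc_parameters()
        series = snc.torsion("CB", "SG", "ND", "OE")
        assert eval_torsion(series, 0.0) == pytest.approx(2.1538, abs=1e-4)

    def test_torsion_periodic_and_nonnegative(self):
        snc = bundled_snc_parameters()
        series = snc.torsion("CB", "SG", "ND", "OE")
        for phi in np.arange(-180.0, 180.0, 7.0):
            v = eval_torsion(series, phi)
            assert v >= 0.0
            assert eval_torsion(series, phi + 360.0) == pytest.approx(v)


class TestBundledSet:
    def test_sg_charge(self):
        assert bundled_snc_parameters().charges["SG"] == -0.1959

    def test_sn_bond(self):
        term = bundled_snc_parameters().bond("SG", "ND")
        assert term.req == 0.1918
        assert term.kb == 79743.2

    def test_csno_term_count(self):
        snc = bundled_snc_parameters()
        assert len(snc.torsion("CB", "SG", "ND", "OE").terms) == 4

    def test_uncorrected_angles_flagged(self):
        snc = bundled_snc_parameters()
        assert not snc.angle("CB", "SG", "ND").corrected
        assert not snc.angle("SG", "ND", "OE").corrected
        assert snc.angle("CA", "CB", "SG").corrected


class TestParameterFiles:
    def test_snc_bond_line_present(self):
        files = write_parameter_files(bundled_snc_parameters())
        assert any("SG" in line and "0.191800" in line
                   for line in files["ffbonded.itp"].splitlines())

    def test_round_trip_equality(self):
        pset = bundled_snc_parameters()
        back = read_parameter_files(write_parameter_files(pset))
        assert back.residue == pset.residue
        assert back.charges.charges == pytest.approx(pset.charges.charges)
        assert back.atom_types == pset.atom_types
        assert {t.atoms: (t.req, t.kb) for t in back.bonds} == \
            {t.atoms: (t.req, t.kb) for t in pset.bonds}
        assert {t.atoms: (t.theta_eq, t.k_theta, t.corrected)
                for t in back.angles} == \
            {t.atoms: (t.theta_eq, t.k_theta, t.corrected)
             for t in pset.angles}
        assert {s.atoms: s.terms for s in back.torsions} == \
            {s.atoms: s.terms for s in pset.torsions}

    def test_empty_torsions_omit_dihedral_section(self):
        pset = bundled_snc_parameters()
        pset.torsions = []
        files = write_parameter_files(pset)
        assert "dihedraltypes" not in files["ffbonded.itp"]

    def test_unmapped_atom_type_rejected(self):
        pset = bundled_snc_parameters()
        pset.atom_types.pop("SG")
        with pytest.raises(ValueError, match="SG"):
            write_parameter_files(pset)
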