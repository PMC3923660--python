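import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import oracles
from tcrdesign import (
    InterfaceDefinition,
    Role,
    buried_sasa,
    crossing_angle,
    hydrogen_bonds,
    interface_residues,
    make_synthetic_complex,
    residue_contacts,
    superpose_and_rmsd,
)
from tcrdesign.geometry import sasa
from tcrdesign.structure import (
    Atom,
    Residue,
    StructureError,
    StructureModel,
    TCR_SIDE,
    PMHC_SIDE,
)


def _single_atom_res(chain, seq, name, element, pos, aa="GLY"):
    return Residue(chain, seq, aa, [Atom(name, element, np.asarray(pos, float))])


class TestInterfaceResidues:
    def test_gap_beyond_cutoff_is_empty(self, complex_apart):
        assert interface_residues(complex_apart) == []

    def test_matches_brute_force(self, complex_touching):
        got = [r.key for r in interface_residues(complex_touching)]
        tcr = [(r, a) for r in complex_touching.side_residues(TCR_SIDE)
               for a in r.heavy_atoms()]
        pmhc = [(r, a) for r in complex_touching.side_residues(PMHC_SIDE)
                for a in r.heavy_atoms()]
        brute = sorted({r.key for r, a in tcr for _, b in pmhc
                        if np.linalg.norm(a.position - b.position) <= 5.5})
        assert got == brute

    def test_missing_roles_raises(self, complex_touching):
        complex_touching.roles = {}
        with pytest.raises(StructureError):
            interface_residues(complex_touching)


class TestResidueContacts:
    def test_glycine_query_is_empty(self):
        gly = Residue("A", 1, "GLY", [Atom("CA", "C", np.zeros(3))])
        pep = _single_atom_res("B", 1, "CA", "C", [1.0, 0, 0])
        m = StructureModel(chains={"A": [gly], "B": [pep]},
                           roles={"A": Role.TCR_ALPHA, "B": Role.PEPTIDE})
        assert residue_contacts(m, gly) == []

    @pytest.mark.parametrize("dist,expected", [(5.9, 1), (6.1, 0)])
    def test_contact_cutoff_boundary(self, dist, expected):
        query = Residue("A", 1, "ALA", [
            Atom("CA", "C", np.zeros(3)),
            Atom("CB", "C", np.array([1.5, 0.0, 0.0]))])
        pep = _single_atom_res("B", 1, "CA", "C", [1.5 + dist, 0, 0])
        m = StructureModel(chains={"A": [query], "B": [pep]},
                           roles={"A": Role.TCR_ALPHA, "B": Role.PEPTIDE})
        assert len(residue_contacts(m, query)) == expected

    def test_absent_residue_raises(self, complex_touching):
        ghost = Residue("Z", 99, "ALA", [])
        with pytest.raises(StructureError):
            residue_contacts(complex_touching, ghost)


class TestSasa:
    def test_single_atom_closed_form(self):
        atom = Atom("O", "O", np.zeros(3))
        area = sasa([atom])[0]
        exact = 4 * np.pi * (1.52 + 1.4) ** 2
        assert area == pytest.approx(exact, rel=0.01)

    def test_far_atoms_additive(self):
        a = Atom("C", "C", np.zeros(3))
        b = Atom("C", "C", np.array([40.0, 0, 0]))
        exact = 2 * 4 * np.pi * (1.70 + 1.4) ** 2
        assert sasa([a, b]).sum() == pytest.approx(exact, rel=0.01)

    def test_buried_equals_free_minus_bound(self, complex_touching):
        res = buried_sasa(complex_touching)
        assert res["pmhc_buried"] > 0
        # recompute directly from the definition
        pmhc_atoms = [a for r in complex_touching.side_residues(PMHC_SIDE)
                      for a in r.heavy_atoms()]
        tcr_atoms = [a for r in complex_touching.side_residues(TCR_SIDE)
                     for a in r.heavy_atoms()]
        per_atom = sasa(tcr_atoms + pmhc_atoms)
        in_complex = per_atom[len(tcr_atoms):].sum()
        assert res["pmhc_buried"] == pytest.approx(
            res["pmhc_free_sasa"] - in_complex, abs=1e-9)

    def test_complex_not_larger_than_free_sum(self, complex_touching):
        res = buried_sasa(complex_touching)
        assert res["complex_sasa"] <= res["tcr_free_sasa"] + \
            res["pmhc_free_sasa"] + 1e-9

    def test_separated_chains_bury_nothing(self):
        m = make_synthetic_complex(seed=5, gap=15.0)
        res = buried_sasa(m)
        assert res["pmhc_buried"] == pytest.approx(0.0, abs=1e-6)


class TestHydrogenBonds:
    def _donor(self):
        return Residue("A", 1, "GLY", [
            Atom("N", "N", np.zeros(3)),
            Atom("H", "H", np.array([1.0, 0.0, 0.0]), is_hydrogen=True)])

    def _model(self, acceptor_x, waters=None):
        acc = _single_atom_res("B", 1, "O", "O", [acceptor_x, 0, 0])
        return StructureModel(chains={"A": [self._donor()], "B": [acc]},
                              roles={"A": Role.TCR_ALPHA, "B": Role.PEPTIDE},
                              waters=waters or [])

    def test_inside_both_cutoffs_reported(self):
        bonds = hydrogen_bonds(self._model(2.9))  # H..A 1.9, D..A 2.9
        assert len(bonds) == 1
        assert bonds[0].donor_atom == "N"
        assert not bonds[0].water_mediated

    def test_outside_ha_cutoff_not_reported(self):
        assert hydrogen_bonds(self._model(3.8)) == []  # H..A 2.8 > 2.7

    def test_da_cutoff_enforced(self):
        defn = InterfaceDefinition(hbond_ha_max=2.7, hbond_da_max=3.6)
        # H..A = 2.65 ok but D..A = 3.65 fails
        assert hydrogen_bonds(self._model(3.65), defn) == []

    def test_water_bridge_reported_once(self):
        wat = Residue("W", 1, "HOH",
                      [Atom("O", "O", np.array([2.8, 0.8, 0.0]), is_water=True)])
        m = self._model(20.0, waters=[wat])
        m.chains["B"] = [_single_atom_res("B", 1, "O", "O", [5.5, 1.6, 0])]
        bonds = hydrogen_bonds(m)
        mediated = [b for b in bonds if b.water_mediated]
        assert len(mediated) == 1
        assert mediated[0].donor_atom == "N"
        assert mediated[0].acceptor_atom == "O"


class TestSuperposition:
    def test_identity_is_zero(self, complex_touching):
        assert superpose_and_rmsd(complex_touching,
                                  complex_touching)["rmsd"] < 1e-12

    def test_rigid_motion_invariance(self, complex_touching):
        rotated = complex_touching.copy()
        rot = Rotation.from_rotvec(np.deg2rad(37) * np.array([1.0, 2, 3])
                                   / np.sqrt(14)).as_matrix()
        for _, a in rotated.atoms():
            a.position = rot @ a.position + np.array([4.0, -7.0, 2.0])
        assert superpose_and_rmsd(complex_touching, rotated)["rmsd"] < 1e-6

    def test_symmetric(self, complex_touching):
        perturbed = complex_touching.copy()
        rng = np.random.default_rng(0)
        for _, a in perturbed.atoms():
            a.position = a.position + rng.normal(0, 0.3, 3)
        r_ab = superpose_and_rmsd(complex_touching, perturbed)["rmsd"]
        r_ba = superpose_and_rmsd(perturbed, complex_touching)["rmsd"]
        assert r_ab == pytest.approx(r_ba, abs=1e-9)

    def test_matches_independent_solver_on_toy_points(self):
        rng = np.random.default_rng(42)
        p = rng.normal(size=(4, 3)) * 3
        q = rng.normal(size=(4, 3)) * 3
        ra = [Residue("A", i, "GLY", [Atom("CA", "C", p[i])]) for i in range(4)]
        rb = [Residue("A", i, "GLY", [Atom("CA", "C", q[i])]) for i in range(4)]
        ma = StructureModel(chains={"A": ra})
        mb = StructureModel(chains={"A": rb})
        got = superpose_and_rmsd(ma, mb)["rmsd"]
        assert got == pytest.approx(oracles.rmsd_align_oracle(p, q), abs=1e-9)

    def test_selection_mismatch_raises(self, complex_touching, complex_apart):
        bigger = make_synthetic_complex(seed=1, n_receptor=6, n_ligand=3)
        with pytest.raises(StructureError, match="mismatch"):
            superpose_and_rmsd(complex_touching, bigger)


class TestCrossingAngle:
    @staticmethod
    def _model(beta_offset, pep_dir=(1.0, 0.0)):
        def ca_res(cid, i, p):
            p = np.asarray(p, float)
            return Residue(cid, i, "ALA", [
                Atom("N", "N", p + [0, 0, 0.1]),
                Atom("CA", "C", p),
                Atom("C", "C", p + [0.1, 0, 0])])
        pep = [ca_res("C", i + 1, [i * pep_dir[0], i * pep_dir[1], 2.0])
               for i in range(9)]
        alpha = [ca_res("A", i + 1, [i * 0.5, 0.0, 8.0]) for i in range(5)]
        beta = [ca_res("B", i + 1,
                       np.array([i * 0.5, 0.0, 8.0]) +
                       np.array([beta_offset[0], beta_offset[1], 0.0]))
                for i in range(5)]
        # MHC platform: a grid of CA atoms spanning the z=0 plane
        mhc = [ca_res("M", 20 * j + k + 1, [k * 2.0 - 8, j * 2.0 - 8, 0.0])
               for j in range(5) for k in range(5)]
        return StructureModel(
            chains={"A": alpha, "B": beta, "C": pep, "M": mhc},
            roles={"A": Role.TCR_ALPHA, "B": Role.TCR_BETA,
                   "C": Role.PEPTIDE, "M": Role.MHC_HEAVY})

    def test_parallel_construction_is_zero(self):
        m = self._model(beta_offset=(6.0, 0.0))
        assert crossing_angle(m, v_domain_length=5) == pytest.approx(0.0, abs=0.5)

    def test_perpendicular_construction_is_ninety(self):
        m = self._model(beta_offset=(0.0, 6.0))
        assert crossing_angle(m, v_domain_length=5) == pytest.approx(90.0, abs=0.5)

    def test_oblique_angle(self):
        m = self._model(beta_offset=(6.0, 6.0))
        assert crossing_angle(m, v_domain_length=5) == pytest.approx(45.0, abs=1.0)

    def test_missing_peptide_raises(self):
        m = self._model(beta_offset=(6.0, 0.0))
        del m.chains["C"]
        m.roles.pop("C")
        with pytest.raises(StructureError):
            crossing_angle(m, v_domain_length=5)
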