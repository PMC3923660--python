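import numpy as np
import pytest

import oracles
from tcrdesign import (
    MutationSpec,
    PackingMode,
    Role,
    make_synthetic_complex,
    minimize_interface,
    mutate_and_pack,
    sidechain_rmsd,
)
from tcrdesign.energy import ZAFFI_1_1
from tcrdesign.packing import (
    RotamerLibrary,
    _build_rotamer,
    default_rotamer_library,
    minimize_torsions,
    packing_energy,
)
from tcrdesign.structure import StructureError, load_parameter_table
from tcrdesign.energy import score


class TestMutationSpec:
    @pytest.mark.parametrize("text,role,pos,wt,mut", [
        ("αD26Y", Role.TCR_ALPHA, 26, "D", "Y"),
        ("aD26Y", Role.TCR_ALPHA, 26, "D", "Y"),
        ("βL98W", Role.TCR_BETA, 98, "L", "W"),
        ("bL98W", Role.TCR_BETA, 98, "L", "W"),
    ])
    def test_parse(self, text, role, pos, wt, mut):
        spec = MutationSpec.parse(text)
        assert (spec.chain_role, spec.position, spec.wt_aa, spec.mut_aa) == \
            (role, pos, wt, mut)

    def test_render_uses_greek(self):
        assert str(MutationSpec.parse("aD26Y")) == "αD26Y"
        assert str(MutationSpec.parse("bL98W")) == "βL98W"

    def test_identity_mutation_rejected(self):
        with pytest.raises(ValueError):
            MutationSpec(Role.TCR_ALPHA, 26, "D", "D")

    def test_garbage_rejected(self):
        with pytest.raises(ValueError):
            MutationSpec.parse("x26Y")


class TestRotamerLibrary:
    def test_every_rotatable_aa_has_rotamers(self):
        lib = default_rotamer_library()
        from tcrdesign.templates import CHI_ATOMS
        for aa in CHI_ATOMS:
            assert len(lib.base_rotamers(aa)) >= 1

    def test_gly_ala_have_no_chi(self):
        lib = default_rotamer_library()
        assert lib.base_rotamers("GLY") == [()]
        assert lib.base_rotamers("ALA") == [()]

    def test_expansion_is_three_per_chi_up_to_three(self):
        lib = default_rotamer_library()
        assert len(lib.expanded_rotamers("SER")) == \
            3 * len(lib.base_rotamers("SER"))
        assert len(lib.expanded_rotamers("MET")) == \
            27 * len(lib.base_rotamers("MET"))
        # chi4 is not expanded
        assert len(lib.expanded_rotamers("LYS")) == \
            27 * len(lib.base_rotamers("LYS"))


class TestMutateAndPack:
    def test_glycine_mutation_has_bare_sidechain(self, complex_touching):
        mut = mutate_and_pack(complex_touching,
                              MutationSpec(Role.TCR_ALPHA, 3, "A", "G"))
        res = mut.find_residue("A", 3)
        assert res.aa == "GLY"
        assert res.sidechain_heavy_atoms() == []

    def test_backbone_fixed_in_nomin(self, complex_touching):
        mut = mutate_and_pack(complex_touching,
                              MutationSpec(Role.TCR_ALPHA, 3, "A", "W"))
        for r1, r2 in zip(complex_touching.chains["A"], mut.chains["A"]):
            for name in ("N", "CA", "C", "O"):
                assert np.allclose(r1.atom(name).position,
                                   r2.atom(name).position, atol=1e-9)

    def test_deterministic(self, complex_touching):
        spec = MutationSpec(Role.TCR_ALPHA, 3, "A", "F")
        m1 = mutate_and_pack(complex_touching, spec)
        m2 = mutate_and_pack(complex_touching, spec)
        p1 = np.array([a.position for _, a in m1.atoms()])
        p2 = np.array([a.position for _, a in m2.atoms()])
        assert np.array_equal(p1, p2)

    def test_equals_bruteforce_enumeration(self, complex_touching):
        """NOMIN packing picks the argmin over explicit per-rotamer energies
        computed by an independent direct-sum implementation."""
        lib = RotamerLibrary({"SER": [(-65.0,), (180.0,), (62.0,)]}, sigma=9.0)
        spec = MutationSpec(Role.TCR_ALPHA, 3, "A", "S")
        packed = mutate_and_pack(complex_touching, spec, lib=lib)
        table = load_parameter_table()
        w = ZAFFI_1_1
        best = None
        for chis in lib.expanded_rotamers("SER"):
            trial = complex_touching.copy()
            res = trial.find_residue("A", 3)
            _build_rotamer(res, "SER", chis, table)
            env = [(r, a) for r in trial.residues() if r.key != res.key
                   for a in r.atoms]
            side = [(res, a) for a in res.atoms
                    if a.name not in ("N", "CA", "C", "O", "OXT", "H")]
            t = oracles.cross_terms_oracle(side, env)
            e = (w.w_vdw_attr * t["vdw_attr"] + w.w_vdw_rep * t["vdw_rep"]
                 + w.w_solvation * t["solvation"] + w.w_hbond * t["hbond"]
                 + w.w_elec * t["electrostatics"]
                 + w.w_intra_rep * oracles.intra_rep_oracle(res))
            if best is None or e < best[0] - 1e-12:
                best = (e, chis, trial)
        ref_res = best[2].find_residue("A", 3)
        got_res = packed.find_residue("A", 3)
        assert [a.name for a in got_res.atoms] == [a.name for a in ref_res.atoms]
        for a, b in zip(got_res.atoms, ref_res.atoms):
            assert np.allclose(a.position, b.position, atol=1e-9)

    def test_position_absent_raises(self, complex_touching):
        with pytest.raises(StructureError, match="no residue"):
            mutate_and_pack(complex_touching,
                            MutationSpec(Role.TCR_ALPHA, 99, "A", "W"))

    def test_wildtype_mismatch_cites_observed(self, complex_touching):
        with pytest.raises(StructureError, match="structure has A"):
            mutate_and_pack(complex_touching,
                            MutationSpec(Role.TCR_ALPHA, 3, "S", "W"))


class TestMinimization:
    def test_quadratic_toy_reaches_analytic_minimum(self):
        target = np.array([12.0, -34.0, 56.0])

        def energy(x):
            return float(((x - target) ** 2).sum())

        x, e, ok = minimize_torsions(np.zeros(3), energy, tol=1e-6)
        assert ok
        assert np.abs(np.deg2rad(x - target)).max() < 1e-3

    def test_already_minimal_unchanged(self):
        def energy(x):
            return float((x ** 2).sum())

        x, e, _ = minimize_torsions(np.zeros(2), energy)
        assert np.allclose(x, 0.0, atol=1e-8)

    def test_minimization_never_raises_energy(self, complex_touching):
        spec = MutationSpec(Role.TCR_ALPHA, 3, "A", "S")
        packed = mutate_and_pack(complex_touching, spec)
        e_before = score(packed, intra_residues=packed.repacked)
        minimized = minimize_interface(packed, mode=PackingMode.MIN)
        e_after = score(minimized, intra_residues=packed.repacked)
        assert e_after <= e_before + 1e-9

    def test_min_sc_leaves_backbone_untouched(self, complex_touching):
        spec = MutationSpec(Role.TCR_ALPHA, 3, "A", "S")
        packed = mutate_and_pack(complex_touching, spec)
        minimized = minimize_interface(packed, mode=PackingMode.MIN_SC)
        for r1, r2 in zip(packed.chains["A"], minimized.chains["A"]):
            for name in ("N", "CA", "C", "O"):
                assert np.allclose(r1.atom(name).position,
                                   r2.atom(name).position, atol=1e-9)


class TestSidechainRmsd:
    def test_identical_structures_zero(self, complex_touching):
        spec = MutationSpec(Role.TCR_ALPHA, 3, "A", "Y")
        mut = mutate_and_pack(complex_touching, spec)
        assert sidechain_rmsd(mut, mut, spec) == pytest.approx(0.0, abs=1e-9)

    def test_tyrosine_ring_flip_resolves_to_zero(self, complex_touching):
        from tcrdesign.templates import CHI_ATOMS, dihedral_angle
        spec = MutationSpec(Role.TCR_ALPHA, 3, "A", "Y")
        mut = mutate_and_pack(complex_touching, spec)
        flipped = mut.copy()
        res = flipped.find_residue("A", 3)
        pos = {a.name: a.position for a in res.atoms}
        chi1 = dihedral_angle(*(pos[x] for x in CHI_ATOMS["TYR"][0]))
        chi2 = dihedral_angle(*(pos[x] for x in CHI_ATOMS["TYR"][1]))
        _build_rotamer(res, "TYR", (chi1, chi2 + 180.0), load_parameter_table())
        # without symmetry resolution the flip would read as ~2.4 A; the tiny
        # residual reflects the slight asymmetry of the ideal-ring template
        assert sidechain_rmsd(flipped, mut, spec) == pytest.approx(0.0, abs=0.01)

    def test_uniform_displacement_gives_that_rmsd(self, complex_touching):
        spec = MutationSpec(Role.TCR_ALPHA, 3, "A", "S")
        mut = mutate_and_pack(complex_touching, spec)
        moved = mut.copy()
        res = moved.find_residue("A", 3)
        for a in res.atoms:
            if a.name not in ("N", "CA", "C", "O", "H"):
                a.position = a.position + np.array([0.0, 0.0, 1.0])
        assert sidechain_rmsd(moved, mut, spec) == pytest.approx(1.0, abs=1e-6)
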