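import numpy as np
import pytest

from tcrdesign import (
    MutationSpec,
    Role,
    ScanConfig,
    clash_filter,
    make_synthetic_complex,
    predict_ddg,
    proline_candidates,
    saturation_scan,
    specificity_scan,
)
from tcrdesign.energy import EnergyBreakdown
from tcrdesign.packing import PackingMode, mutate_and_pack
from tcrdesign.scan import ScanRecord, ScanResult, in_region, load_rama_regions
from tcrdesign.structure import StructureError, StructureModel, Role as _Role
from tcrdesign.structure import _build_chain


def _record(vdw_rep, score=0.0, pos=3, mut="W"):
    spec = MutationSpec(Role.TCR_ALPHA, pos, "A", mut)
    bd = EnergyBreakdown(0, vdw_rep, 0, 0, 0, 0)
    return ScanRecord(mutation=spec, ligand="L", mode=PackingMode.NOMIN,
                      score=score, breakdown=bd, contacts=())


class TestSaturationScan:
    def test_nineteen_records_per_interface_residue(self, template_library):
        m = make_synthetic_complex(seed=4, n_receptor=3, n_ligand=2, gap=4.5)
        config = ScanConfig(library=template_library)
        from tcrdesign import interface_residues
        k = len(interface_residues(m, config.defn()))
        result = saturation_scan(m, config)
        assert k > 0
        assert len(result.records) == 19 * k

    def test_ranking_matches_independent_per_mutant_scoring(self, template_library):
        m = make_synthetic_complex(seed=4, n_receptor=2, n_ligand=2, gap=4.5)
        config = ScanConfig(library=template_library)
        result = saturation_scan(m, config)
        for rec in result.records[:10]:
            mutant = mutate_and_pack(m, rec.mutation, lib=template_library)
            assert rec.score == pytest.approx(predict_ddg(m, mutant), abs=1e-9)
        ranked = result.ranked()
        assert all(a.score <= b.score + 1e-12
                   for a, b in zip(ranked, ranked[1:]))

    def test_breakdown_is_weighted_into_score(self, template_library):
        m = make_synthetic_complex(seed=4, n_receptor=2, n_ligand=2, gap=4.5)
        config = ScanConfig(library=template_library)
        for rec in saturation_scan(m, config).records:
            assert rec.score == pytest.approx(
                float(config.weights.as_array() @ rec.breakdown.as_array()),
                abs=1e-9)


class TestSpecificityScan:
    def test_identical_ligands_zero_differential(self, template_library):
        a = make_synthetic_complex(seed=4, n_receptor=2, n_ligand=2, gap=4.5)
        b = a.copy()
        df = specificity_scan(a, b, ScanConfig(library=template_library))
        assert np.allclose(df["differential"], 0.0, atol=1e-9)

    def test_antisymmetric_under_ligand_swap(self, template_library):
        a = make_synthetic_complex(seed=4, n_receptor=2, n_ligand=2, gap=4.2,
                                   ligand_seq="WA")
        b = make_synthetic_complex(seed=4, n_receptor=2, n_ligand=2, gap=4.2,
                                   ligand_seq="GA")
        config = ScanConfig(library=template_library)
        fwd = specificity_scan(a, b, config).set_index(["mutation", "mode"])
        rev = specificity_scan(b, a, config).set_index(["mutation", "mode"])
        for key in fwd.index:
            assert fwd.loc[key, "differential"] == pytest.approx(
                -rev.loc[key, "differential"], abs=1e-9)

    def test_bulky_ligand_disfavors_large_mutations(self, template_library):
        """With a tryptophan packed against the scanned position in ligand A
        but glycine in ligand B, large substitutions clash more with A."""
        a = make_synthetic_complex(seed=4, n_receptor=2, n_ligand=2, gap=3.8,
                                   ligand_seq="WW")
        b = make_synthetic_complex(seed=4, n_receptor=2, n_ligand=2, gap=3.8,
                                   ligand_seq="GG")
        df = specificity_scan(a, b, ScanConfig(library=template_library))
        big = df[df["mutation"].str.endswith("W")]
        assert (big["differential"] > 0).all()

    def test_tcr_mismatch_raises(self, template_library):
        a = make_synthetic_complex(seed=4, n_receptor=2, n_ligand=2,
                                   receptor_seq="AA")
        b = make_synthetic_complex(seed=4, n_receptor=2, n_ligand=2,
                                   receptor_seq="AS")
        with pytest.raises(StructureError, match="TCR"):
            specificity_scan(a, b, ScanConfig(library=template_library))


class TestClashFilter:
    def test_partition_is_disjoint_and_complete(self):
        records = [_record(v, mut=m) for v, m in
                   zip([0, 100, 700, 579, 581, 1000, 20, 3, 590, 55],
                       "WYFMKRHQEN")]
        result = ScanResult(records)
        kept, removed = clash_filter(result)
        assert len(removed.records) == 4
        assert len(kept.records) + len(removed.records) == len(records)
        assert not (set(id(r) for r in kept.records) &
                    set(id(r) for r in removed.records))

    def test_threshold_is_strict(self):
        kept, removed = clash_filter(ScanResult([_record(580.0)]))
        assert len(kept.records) == 1 and removed.records == []

    def test_nothing_removed_below_threshold(self):
        records = [_record(v, mut=m) for v, m in zip([0, 10, 580], "WYF")]
        kept, removed = clash_filter(ScanResult(records))
        assert removed.records == []

    def test_idempotent_on_kept(self):
        records = [_record(v, mut=m) for v, m in zip([0, 700, 100], "WYF")]
        kept, _ = clash_filter(ScanResult(records))
        kept2, removed2 = clash_filter(kept)
        assert kept2.records == kept.records and removed2.records == []


class TestProlineCandidates:
    @staticmethod
    def _bound(phi, psi):
        chain = _build_chain("A", "AAAAA", phi=phi, psi=psi)
        lig = _build_chain("B", "AAA")
        for r in lig:
            for a in r.atoms:
                a.position = a.position + np.array([0.0, 0.0, 6.0])
        return StructureModel(chains={"A": chain, "B": lig},
                              roles={"A": _Role.TCR_ALPHA, "B": _Role.PEPTIDE})

    @staticmethod
    def _scan(score):
        spec = MutationSpec(Role.TCR_ALPHA, 3, "A", "P")
        bd = EnergyBreakdown(0, 0, 0, 0, 0, 0)
        return ScanResult([ScanRecord(mutation=spec, ligand="L",
                                      mode=PackingMode.NOMIN, score=score,
                                      breakdown=bd, contacts=())])

    def test_favorable_geometry_and_score_selected(self):
        bound = self._bound(phi=-60.0, psi=-45.0)
        assert proline_candidates(bound, self._scan(-0.5)) == [("A", 3)]

    def test_unfavorable_phi_excluded(self):
        bound = self._bound(phi=60.0, psi=-45.0)
        assert proline_candidates(bound, self._scan(-0.5)) == []

    def test_unfavorable_score_excluded(self):
        bound = self._bound(phi=-60.0, psi=-45.0)
        assert proline_candidates(bound, self._scan(+0.5)) == []

    def test_terminus_skipped(self):
        bound = self._bound(phi=-60.0, psi=-45.0)
        spec = MutationSpec(Role.TCR_ALPHA, 1, "A", "P")
        bd = EnergyBreakdown(0, 0, 0, 0, 0, 0)
        scan = ScanResult([ScanRecord(mutation=spec, ligand="L",
                                      mode=PackingMode.NOMIN, score=-1.0,
                                      breakdown=bd, contacts=())])
        assert proline_candidates(bound, scan) == []

    def test_region_membership_matches_matplotlib_oracle(self):
        """Shipped polygon membership agrees with an independent
        point-in-polygon implementation on a phi/psi grid."""
        from matplotlib.path import Path as MplPath
        import csv as _csv
        from importlib import resources as _res

        regions = load_rama_regions()
        text = _res.files("tcrdesign.data").joinpath("rama_regions.csv").read_text()
        verts: dict[tuple, list] = {}
        for row in _csv.DictReader(text.splitlines()):
            verts.setdefault((row["region"], row["polygon"]), []).append(
                (float(row["phi"]), float(row["psi"])))
        paths = {}
        for (region, _), pts in verts.items():
            paths.setdefault(region, []).append(MplPath(pts))
        rng = np.random.default_rng(0)
        for _ in range(300):
            phi, psi = rng.uniform(-180, 180, 2)
            for region in regions:
                expected = any(p.contains_point((phi, psi), radius=1e-9)
                               for p in paths[region])
                assert in_region(regions, region, phi, psi) == expected
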