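"""Substitution/AAindex matrices, RSA, residue depth, topology and flags."""

import numpy as np
import pytest
from importlib import resources

from gpcrtherm.aux_features import (
    AAIndexMatrix,
    SubstitutionMatrix,
    TopologyAnnotation,
    aaindex_scores,
    identity_flags,
    parse_aaindex2,
    relative_solvent_accessibility,
    residue_depth,
    sasa_by_residue,
    substitution_scores,
    surface_points,
    topology_flags,
)
from gpcrtherm.errors import ConfigurationError, DataIntegrityError
from gpcrtherm.residues import STANDARD_AA1
from gpcrtherm.structure_io import Atom, Structure
from gpcrtherm.synthetic import BundleSpec, make_helical_bundle

AAS = sorted(STANDARD_AA1)


class TestSubstitutionMatrices:
    def test_blosum62_alanine_diagonal(self):
        m = SubstitutionMatrix.standard("BLOSUM62")
        assert m.score("A", "A") == 4.0

    @pytest.mark.parametrize("name", ["BLOSUM62", "PAM30"])
    def test_symmetry_and_completeness(self, name):
        m = SubstitutionMatrix.standard(name)
        for a in AAS:
            for b in AAS:
                assert m.score(a, b) == m.score(b, a)

    def test_blosum62_diagonal_dominates_rows(self):
        m = SubstitutionMatrix.standard("BLOSUM62")
        for a in AAS:
            assert all(m.score(a, a) >= m.score(a, b) for b in AAS)

    def test_scores_api(self):
        out = substitution_scores("A", "V", [SubstitutionMatrix.standard("BLOSUM62")])
        assert set(out) == {"BLOSUM62"}

    def test_missing_pair_is_integrity_error(self):
        m = SubstitutionMatrix("partial", {("A", "A"): 1.0})
        with pytest.raises(DataIntegrityError):
            m.score("A", "W")


class TestAAIndex:
    @pytest.mark.parametrize("acc", ["BENS940104", "LUTR910108"])
    def test_complete_over_all_400_pairs(self, acc):
        m = AAIndexMatrix.packaged(acc)
        for a in AAS:
            for b in AAS:
                m.score(a, b)  # raises on any gap

    def test_reparse_reproduces_packaged_tables(self):
        text = (
            resources.files("gpcrtherm.data").joinpath("aaindex2_synthetic.txt").read_text()
        )
        reparsed = parse_aaindex2(text)
        for acc in ("BENS940104", "LUTR910108"):
            m = AAIndexMatrix.packaged(acc)
            for a in AAS:
                for b in AAS:
                    assert reparsed[acc][(a, b)] == m.score(a, b)

    def test_genetic_code_diagonal_is_maximal(self):
        m = AAIndexMatrix.packaged("BENS940104")
        for a in AAS:
            assert m.score(a, a) == 3.0  # identical codons share all three bases

    def test_scores_api_and_missing_id(self):
        out = aaindex_scores("P", "A", ["BENS940104", "LUTR910108"])
        assert set(out) == {"BENS940104", "LUTR910108"}
        with pytest.raises(DataIntegrityError):
            aaindex_scores("P", "A", ["NOPE000000"])


def _mini_shrake_rupley(structure, n_points=2000, probe=1.4):
    """Independent SASA oracle: dense Fibonacci sphere sampling per atom."""
    radii = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
    coords = structure.coords()
    r = np.array([radii[a.element] + probe for a in structure.atoms])
    k = np.arange(n_points)
    golden = np.pi * (3 - np.sqrt(5))
    z = 1 - 2 * (k + 0.5) / n_points
    rho = np.sqrt(1 - z * z)
    unit = np.stack([rho * np.cos(golden * k), rho * np.sin(golden * k), z], axis=1)
    out = {}
    for i, a in enumerate(structure.atoms):
        pts = coords[i] + r[i] * unit
        exposed = np.ones(n_points, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            exposed &= np.linalg.norm(pts - coords[j], axis=1) >= r[j]
        area = 4 * np.pi * r[i] ** 2 * exposed.mean()
        key = (a.chain, a.res_seq, a.icode)
        out[key] = out.get(key, 0.0) + area
    return out


class TestRSA:
    def test_single_isolated_residue_exceeds_chain_reference(self):
        # a lone residue exposes surface that the in-chain reference buries
        b = make_helical_bundle(BundleSpec(1, 1, helix_spacing=0.1, sequence="A"))
        rsa = relative_solvent_accessibility(b, b.residues()[0])
        assert rsa > 1.0

    def test_central_residue_of_isolated_tripeptide_near_one(self):
        b = make_helical_bundle(BundleSpec(1, 3, helix_spacing=0.1, sequence="AAA"))
        rsa = relative_solvent_accessibility(b, b.residues()[1])
        assert 0.5 < rsa < 1.2

    def test_core_below_surface(self, bundle):
        cache = sasa_by_residue(bundle)
        residues = bundle.residues()
        core = residues[12]  # mid-helix, facing the bundle
        cap = residues[0]  # helix end, fully exposed
        assert relative_solvent_accessibility(
            bundle, core, cache
        ) < relative_solvent_accessibility(bundle, cap, cache)

    def test_cross_implementation_oracle_two_residues(self):
        b = make_helical_bundle(BundleSpec(1, 2, helix_spacing=0.1, sequence="AL"))
        cache = sasa_by_residue(b)
        oracle = _mini_shrake_rupley(b)
        for key, ref in oracle.items():
            assert cache[key] == pytest.approx(ref, rel=0.05)


def _carbon_cluster():
    atoms = []
    serial = 0
    for x in range(-2, 3):
        for y in range(-2, 3):
            for z in range(-2, 3):
                serial += 1
                atoms.append(
                    Atom(serial, "CA", "C", "GLY", serial, "A", (3.5 * x, 3.5 * y, 3.5 * z))
                )
    return Structure(atoms, "cluster")


class TestResidueDepth:
    def test_core_deeper_than_surface(self):
        s = _carbon_cluster()
        surf = surface_points(s)
        residues = {r.atoms[0].xyz: r for r in s.residues()}
        center = residues[(0.0, 0.0, 0.0)]
        corner = residues[(-7.0, -7.0, -7.0)]
        assert residue_depth(s, center, surf) > residue_depth(s, corner, surf) + 3.0

    def test_depth_nonnegative_everywhere(self, small_bundle):
        surf = surface_points(small_bundle)
        assert all(
            residue_depth(small_bundle, r, surf) >= 0 for r in small_bundle.residues()[:10]
        )

    def test_isolated_residue_probe_scale_constant(self):
        # frozen regression value: lone residue sits ~vdW+probe under its own dots
        b = make_helical_bundle(BundleSpec(1, 1, helix_spacing=0.1, sequence="A"))
        assert residue_depth(b, b.residues()[0]) == pytest.approx(3.03, abs=0.1)


class TestTopology:
    def test_z_slab_rules(self):
        slab = TopologyAnnotation(half_width=15.0)
        mk = lambda z: Structure(
            [Atom(1, "CA", "C", "GLY", 1, "A", (0.0, 0.0, z))], "t"
        ).residues()[0]
        assert topology_flags(slab, mk(0.0)) == (1, 1)
        assert topology_flags(slab, mk(-30.0)) == (0, 0)
        assert topology_flags(slab, mk(30.0)) == (0, 1)
        assert topology_flags(slab, mk(15.0)) == (1, 1)  # boundary inside

    def test_annotation_file_passthrough(self, tmp_path):
        rows = ["chain,res_seq,mem,non_cytosol"]
        expect = {}
        rng = np.random.default_rng(0)
        for i in range(1, 11):
            mem, nc = int(rng.integers(2)), int(rng.integers(2))
            rows.append(f"A,{i},{mem},{nc}")
            expect[i] = (mem, nc)
        path = tmp_path / "topo.csv"
        path.write_text("\n".join(rows) + "\n")
        ann = TopologyAnnotation.from_csv(path)
        for i in range(1, 11):
            res = Structure(
                [Atom(1, "CA", "C", "GLY", i, "A", (0.0, 0.0, 0.0))], "t"
            ).residues()[0]
            assert topology_flags(ann, res) == expect[i]

    def test_missing_annotation_is_configuration_error(self, tmp_path):
        path = tmp_path / "topo.csv"
        path.write_text("chain,res_seq,mem,non_cytosol\nA,1,1,1\n")
        ann = TopologyAnnotation.from_csv(path)
        res = Structure(
            [Atom(1, "CA", "C", "GLY", 99, "A", (0.0, 0.0, 0.0))], "t"
        ).residues()[0]
        with pytest.raises(ConfigurationError):
            topology_flags(ann, res)


class TestIdentityFlags:
    def test_proline_to_alanine(self):
        assert identity_flags("P", "A") == {
            "FromPro": 1, "ToAla": 1, "FromGly": 0, "ToPro": 0
        }

    def test_plain_substitution_all_zero(self):
        assert all(v == 0 for v in identity_flags("A", "V").values())

    def test_exactly_one_wt_sets_frompro(self):
        hits = [aa for aa in AAS if identity_flags(aa, "A")["FromPro"] == 1]
        assert hits == ["P"]
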