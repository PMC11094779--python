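"""Pharmacophore assignment, pair-count signatures, and the change vector."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gpcrtherm.errors import InvalidResidueError
from gpcrtherm.residues import STANDARD_AA1, heavy_atoms, three_letter
from gpcrtherm.signatures import (
    CLASS_ORDER,
    DEFAULT_CUTOFFS,
    PCHANGE_ORDER,
    PharmacophoreClass,
    assign_pharmacophores,
    pair_count_signature,
    pchange,
    residue_pharmacophore_vector,
    signature_feature_names,
)
from gpcrtherm.structure_io import Atom

from conftest import brute_force_pair_counts, random_environment


def _atom(serial, res_name, atom_name, xyz):
    element = "S" if atom_name in ("SG", "SD") else atom_name[0]
    return Atom(serial, atom_name, element, res_name, serial, "A", xyz)


class TestAssignment:
    def test_table_covers_every_canonical_heavy_atom(self, pharmacophore_table):
        for aa in sorted(STANDARD_AA1):
            res = three_letter(aa)
            for atom_name in heavy_atoms(res):
                assert (res, atom_name) in pharmacophore_table

    def test_sulfur_atoms(self, pharmacophore_table):
        assert PharmacophoreClass.SULFUR in pharmacophore_table.lookup("CYS", "SG")
        assert PharmacophoreClass.SULFUR in pharmacophore_table.lookup("MET", "SD")

    def test_charged_groups(self, pharmacophore_table):
        assert PharmacophoreClass.POSITIVE in pharmacophore_table.lookup("ARG", "NH1")
        assert PharmacophoreClass.NEGATIVE in pharmacophore_table.lookup("ASP", "OD1")

    def test_unknown_atom_falls_back_to_neutral_with_warning(self, pharmacophore_table):
        atom = _atom(1, "ALA", "XX1", (0.0, 0.0, 0.0))
        with pytest.warns(UserWarning, match="unknown atom"):
            (classes,) = assign_pharmacophores([atom], pharmacophore_table)
        assert classes == frozenset({PharmacophoreClass.NEUTRAL})

    def test_aromatic_carbons_are_also_hydrophobic(self, pharmacophore_table):
        classes = pharmacophore_table.lookup("PHE", "CZ")
        assert {PharmacophoreClass.AROMATIC, PharmacophoreClass.HYDROPHOBIC} <= classes


class TestPairCounts:
    def test_two_hydrophobic_atoms_cumulative(self):
        atoms = [
            _atom(1, "ALA", "CB", (0.0, 0.0, 0.0)),
            _atom(2, "LEU", "CD1", (3.6, 0.0, 0.0)),
        ]
        classes = [frozenset({PharmacophoreClass.HYDROPHOBIC})] * 2
        counts = pair_count_signature(atoms, classes, cutoffs=(2.5, 4.0))
        assert counts["Hydro:Hydro-2.50"] == 0
        assert counts["Hydro:Hydro-4.00"] == 1

    def test_single_atom_all_zero(self, pharmacophore_table):
        atoms = [_atom(1, "ALA", "CB", (0.0, 0.0, 0.0))]
        counts = pair_count_signature(
            atoms, assign_pharmacophores(atoms, pharmacophore_table)
        )
        assert all(v == 0 for v in counts.values())

    def test_empty_environment_all_zero(self):
        counts = pair_count_signature([], [])
        assert set(counts) == set(signature_feature_names(DEFAULT_CUTOFFS))
        assert all(v == 0 for v in counts.values())

    def test_non_ascending_cutoffs_rejected(self):
        with pytest.raises(ValueError):
            pair_count_signature([], [], cutoffs=(4.0, 2.0))

    def test_matches_brute_force_oracle(self, pharmacophore_table):
        rng = np.random.default_rng(42)
        atoms = random_environment(rng, 20, pharmacophore_table)
        classes = assign_pharmacophores(atoms, pharmacophore_table)
        fast = pair_count_signature(atoms, classes, DEFAULT_CUTOFFS)
        slow = brute_force_pair_counts(atoms, classes, DEFAULT_CUTOFFS)
        assert fast == slow

    def test_multilabel_pair_counts_once_per_class_pair(self):
        # both atoms carry both classes: one atom pair, one count per class pair
        both = frozenset({PharmacophoreClass.AROMATIC, PharmacophoreClass.HYDROPHOBIC})
        atoms = [
            _atom(1, "PHE", "CZ", (0.0, 0.0, 0.0)),
            _atom(2, "PHE", "CE1", (1.4, 0.0, 0.0)),
        ]
        counts = pair_count_signature(atoms, [both, both], cutoffs=(2.0,))
        assert counts["Aro:Aro-2.00"] == 1
        assert counts["Aro:Hydro-2.00"] == 1
        assert counts["Hydro:Hydro-2.00"] == 1

    def test_rigid_motion_invariance(self, pharmacophore_table):
        rng = np.random.default_rng(3)
        atoms = random_environment(rng, 40, pharmacophore_table)
        classes = assign_pharmacophores(atoms, pharmacophore_table)
        rot = Rotation.random(random_state=9).as_matrix()
        shift = rng.uniform(-30, 30, size=3)
        moved = [
            Atom(a.serial, a.name, a.element, a.res_name, a.res_seq, a.chain,
                 tuple(rot @ np.array(a.xyz) + shift))
            for a in atoms
        ]
        assert pair_count_signature(atoms, classes) == pair_count_signature(moved, classes)

    def test_feature_names_canonically_ordered(self):
        for name in signature_feature_names((2.0,)):
            c1, rest = name.split(":")
            c2 = rest.split("-")[0]
            assert c1 <= c2


class TestResidueVectors:
    def test_glycine_is_backbone_only(self, pharmacophore_table):
        gly = residue_pharmacophore_vector("G", pharmacophore_table)
        # N(donor) + CA(hydrophobic) + C(neutral) + O(acceptor)
        expect = {
            PharmacophoreClass.DONOR: 1,
            PharmacophoreClass.HYDROPHOBIC: 1,
            PharmacophoreClass.NEUTRAL: 1,
            PharmacophoreClass.ACCEPTOR: 1,
        }
        for c, i in zip(PCHANGE_ORDER, range(len(PCHANGE_ORDER))):
            assert gly[i] == expect.get(c, 0)

    def test_sulfur_components(self, pharmacophore_table):
        i_sul = PCHANGE_ORDER.index(PharmacophoreClass.SULFUR)
        assert residue_pharmacophore_vector("C", pharmacophore_table)[i_sul] == 1
        assert residue_pharmacophore_vector("S", pharmacophore_table)[i_sul] == 0

    def test_invalid_code_rejected(self):
        with pytest.raises(InvalidResidueError):
            residue_pharmacophore_vector("X")

    @pytest.mark.parametrize("aa", sorted(STANDARD_AA1))
    def test_vector_matches_template_tally(self, aa, pharmacophore_table):
        """Consistency oracle: tally assign_pharmacophores over the canonical
        heavy-atom template of each residue."""
        res = three_letter(aa)
        atoms = [
            _atom(i + 1, res, name, (float(i), 0.0, 0.0))
            for i, name in enumerate(heavy_atoms(res))
        ]
        tally = np.zeros(len(PCHANGE_ORDER), dtype=int)
        for classes in assign_pharmacophores(atoms, pharmacophore_table):
            for c in classes:
                tally[PCHANGE_ORDER.index(c)] += 1
        assert np.array_equal(
            residue_pharmacophore_vector(aa, pharmacophore_table), tally
        )


class TestPChange:
    def test_identity_mutation_is_zero(self, pharmacophore_table):
        for aa in sorted(STANDARD_AA1):
            assert np.array_equal(
                pchange(aa, aa, pharmacophore_table), np.zeros(8, dtype=int)
            )

    def test_antisymmetry_sample(self, pharmacophore_table):
        for wt, mt in [("A", "W"), ("C", "S"), ("P", "G"), ("R", "E")]:
            assert np.array_equal(
                pchange(wt, mt, pharmacophore_table),
                -pchange(mt, wt, pharmacophore_table),
            )

    def test_cys_to_ser_loses_one_sulfur(self, pharmacophore_table):
        i_sul = PCHANGE_ORDER.index(PharmacophoreClass.SULFUR)
        assert pchange("C", "S", pharmacophore_table)[i_sul] == -1

    def test_component_sum_is_multiplicity_difference(self, pharmacophore_table):
        for wt, mt in [("G", "W"), ("A", "R"), ("L", "D")]:
            delta = pchange(wt, mt, pharmacophore_table).sum()
            mult = lambda aa: residue_pharmacophore_vector(aa, pharmacophore_table).sum()
            assert delta == mult(mt) - mult(wt)
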