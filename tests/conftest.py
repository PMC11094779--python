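"""Shared fixtures: handcrafted PDB texts and synthetic structures."""

from __future__ import annotations

import numpy as np
import pytest

from gpcrtherm import BundleSpec, make_helical_bundle
from gpcrtherm.signatures import PharmacophoreTable
from gpcrtherm.structure_io import Atom, Structure


def _pdb_line(serial, name, res_name, chain, res_seq, x, y, z,
              record="ATOM", element=None, altloc=" ", occ=1.0):
    element = element or name[0]
    return (
        f"{record:<6}{serial:>5} {name:^4}{altloc}{res_name:>3} {chain}{res_seq:>4}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00          {element:>2}\n"
    )


@pytest.fixture
def three_residue_pdb(tmp_path):
    """Three glycines, 9 heavy atoms total (N, CA, C each; no O)."""
    lines = []
    serial = 0
    for i, base in enumerate([0.0, 4.0, 8.0]):
        for j, name in enumerate(["N", "CA", "C"]):
            serial += 1
            lines.append(_pdb_line(serial, name, "GLY", "A", i + 1, base + j, 0.0, 0.0))
    lines.append("END\n")
    path = tmp_path / "three_res.pdb"
    path.write_text("".join(lines))
    return path


@pytest.fixture
def mixed_content_pdb(tmp_path):
    """Chain A protein (12 atoms), chain B protein, 2 waters, 1 heme atom."""
    lines = []
    serial = 0
    for i in range(3):  # 3 alanine-like residues x 4 backbone atoms = 12
        for j, name in enumerate(["N", "CA", "C", "O"]):
            serial += 1
            lines.append(_pdb_line(serial, name, "ALA", "A", i + 1, 4.0 * i + j, 0.0, 0.0))
    for j, name in enumerate(["N", "CA"]):
        serial += 1
        lines.append(_pdb_line(serial, name, "GLY", "B", 1, float(j), 5.0, 0.0))
    for k in range(2):
        serial += 1
        lines.append(_pdb_line(serial, "O", "HOH", "A", 100 + k, 20.0 + k, 0.0, 0.0,
                               record="HETATM", element="O"))
    serial += 1
    lines.append(_pdb_line(serial, "FE", "HEM", "A", 200, 25.0, 0.0, 0.0,
                           record="HETATM", element="FE"))
    lines.append("END\n")
    path = tmp_path / "mixed.pdb"
    path.write_text("".join(lines))
    return path


@pytest.fixture(scope="session")
def bundle() -> Structure:
    """Deterministic 7x25 helical bundle used across structural tests."""
    return make_helical_bundle(BundleSpec(n_helices=7, residues_per_helix=25, seed=11))


@pytest.fixture(scope="session")
def small_bundle() -> Structure:
    return make_helical_bundle(
        BundleSpec(n_helices=3, residues_per_helix=10, helix_spacing=9.0, seed=5)
    )


@pytest.fixture(scope="session")
def pharmacophore_table() -> PharmacophoreTable:
    return PharmacophoreTable.default()


def random_environment(rng, n_atoms, table, box=15.0):
    """Random atoms with real (res_name, atom_name) identities inside a box."""
    keys = sorted(table.items())
    picks = rng.integers(0, len(keys), size=n_atoms)
    atoms = []
    for serial, k in enumerate(picks, start=1):
        (res_name, atom_name), _ = keys[k]
        xyz = tuple(rng.uniform(-box / 2, box / 2, size=3))
        element = "S" if atom_name in ("SG", "SD") else atom_name[0]
        atoms.append(
            Atom(serial=serial, name=atom_name, element=element, res_name=res_name,
                 res_seq=serial, chain="A", xyz=xyz)
        )
    return atoms


def brute_force_pair_counts(atoms, classes, cutoffs):
    """Exhaustive O(n^2) oracle for the pair-count signature."""
    from itertools import combinations

    from gpcrtherm.signatures import signature_feature_names

    counts = {name: 0 for name in signature_feature_names(cutoffs)}
    for i, j in combinations(range(len(atoms)), 2):
        d = float(np.linalg.norm(np.array(atoms[i].xyz) - np.array(atoms[j].xyz)))
        pair_keys = {
            tuple(sorted((a.short, b.short)))
            for a in classes[i]
            for b in classes[j]
        }
        for cut in cutoffs:
            if d <= cut:
                for k1, k2 in pair_keys:
                    counts[f"{k1}:{k2}-{cut:.2f}"] += 1
    return counts
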