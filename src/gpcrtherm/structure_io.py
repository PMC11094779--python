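"""PDB ingestion, structure cleaning, and residue-environment extraction.

A receptor structure is reduced to a flat list of heavy atoms.  Cleaning
keeps a single chain of standard amino acids (no waters, ligands, extra
chains, or hydrogens), which is the representation the structural
signatures operate on.  The *environment* of a mutation site is the set of
atoms within a radius ``r`` of the wild-type residue's geometric center.
"""

from __future__ import annotations

import dataclasses
from collections import OrderedDict
from pathlib import Path
from typing import Iterable, Iterator

import gemmi
import numpy as np

from .errors import (
    EmptyStructureError,
    FormatError,
    MissingChainError,
    MissingResidueError,
    WildtypeMismatchError,
)
from .mutations import MutationSpec
from .residues import STANDARD_AA3, one_letter

_HYDROGENS = {"H", "D"}


@dataclasses.dataclass(frozen=True)
class Atom:
    """One heavy atom of a receptor model.

    ``res_seq`` is the author (PDB) residue number, used verbatim; ``icode``
    is the insertion code ('' when absent).
    """

    serial: int
    name: str
    element: str
    res_name: str
    res_seq: int
    chain: str
    xyz: tuple[float, float, float]
    icode: str = ""

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError(f"atom {self.serial} {self.name}: empty element")
        if not all(np.isfinite(self.xyz)):
            raise ValueError(f"atom {self.serial} {self.name}: non-finite coordinates")

    @property
    def position(self) -> np.ndarray:
        return np.asarray(self.xyz, dtype=float)


@dataclasses.dataclass
class Residue:
    """A residue view: identity plus the atoms that belong to it."""

    chain: str
    res_seq: int
    res_name: str
    atoms: list[Atom]
    icode: str = ""

    @property
    def center(self) -> np.ndarray:
        """Unweighted mean of the heavy-atom coordinates."""
        return np.mean([a.position for a in self.atoms], axis=0)


@dataclasses.dataclass
class Structure:
    """An ordered list of atoms with a free-text label."""

    atoms: list[Atom]
    id: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float).reshape(-1, 3)

    def chains(self) -> set[str]:
        return {a.chain for a in self.atoms}

    def residues(self) -> list[Residue]:
        """Residues in atom order, grouped by (chain, res_seq, icode, res_name)."""
        groups: OrderedDict[tuple, Residue] = OrderedDict()
        for a in self.atoms:
            key = (a.chain, a.res_seq, a.icode, a.res_name)
            if key not in groups:
                groups[key] = Residue(a.chain, a.res_seq, a.res_name, [], a.icode)
            groups[key].atoms.append(a)
        return list(groups.values())

    def find_residue(self, chain: str, res_seq: int) -> Residue:
        matches = [r for r in self.residues() if r.chain == chain and r.res_seq == res_seq]
        if not matches:
            raise MissingResidueError(f"residue {chain}/{res_seq} not found in structure {self.id!r}")
        blank = [r for r in matches if r.icode == ""]
        return blank[0] if blank else matches[0]


def _validate_pdb_text(path: Path) -> None:
    # gemmi tolerates short records; reject coordinate lines that are
    # truncated before the xyz fields so corrupt files fail loudly.
    with open(path, "r", errors="replace") as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line.rstrip("\n")
            if rec[:6].strip() in ("ATOM", "HETATM") and len(rec) < 54:
                raise FormatError(f"{path}: truncated coordinate record at line {lineno}")


def load_structure(path: str | Path) -> Structure:
    """Read a PDB file, resolving alternate locations but not filtering.

    All ATOM/HETATM records (waters and ligands included) are retained;
    cleaning is a separate, explicit step.  Alternate locations collapse to
    the highest-occupancy conformer, ties broken by altloc label order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_pdb_text(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"could not parse {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    model = st[0]

    atoms: list[Atom] = []
    for chain in model:
        for res in chain:
            # resolve altlocs per atom name: highest occupancy, then label order
            by_name: OrderedDict[str, gemmi.Atom] = OrderedDict()
            for at in res:
                prev = by_name.get(at.name)
                if prev is None:
                    by_name[at.name] = at
                elif at.occ > prev.occ or (at.occ == prev.occ and (at.altloc or " ") < (prev.altloc or " ")):
                    by_name[at.name] = at
            for at in by_name.values():
                atoms.append(
                    Atom(
                        serial=at.serial,
                        name=at.name,
                        element=at.element.name,
                        res_name=res.name,
                        res_seq=res.seqid.num,
                        chain=chain.name,
                        xyz=(at.pos.x, at.pos.y, at.pos.z),
                        icode=(res.seqid.icode or "").strip(),
                    )
                )
    if not atoms:
        raise EmptyStructureError(f"{path}: no atoms")
    return Structure(atoms=atoms, id=path.stem)


def clean_structure(s: Structure, chain: str) -> Structure:
    """Keep only the standard amino-acid heavy atoms of one chain.

    Removes waters, ligands/hetero residues, every other chain, and
    hydrogens, preserving atom order.  Idempotent.
    """
    if chain not in s.chains():
        raise MissingChainError(f"chain {chain!r} not in structure {s.id!r} (has {sorted(s.chains())})")
    kept = [
        a
        for a in s.atoms
        if a.chain == chain and a.res_name in STANDARD_AA3 and a.element not in _HYDROGENS
    ]
    if not kept:
        raise EmptyStructureError(
            f"no standard amino-acid atoms survive cleaning of chain {chain!r} in {s.id!r}"
        )
    return Structure(atoms=kept, id=s.id)


def residue_environment(s: Structure, m: MutationSpec, r: float) -> list[Atom]:
    """Heavy atoms within ``r`` angstroms of the mutation site's center.

    The wild-type residue's own atoms are part of the environment.  The
    residue named by ``m`` must exist and match ``m.wt_aa``.
    """
    res = s.find_residue(m.chain, m.position)
    found = one_letter(res.res_name) if res.res_name in STANDARD_AA3 else res.res_name
    if found != m.wt_aa:
        raise WildtypeMismatchError(
            f"residue {m.chain}/{m.position}: expected wild type {m.wt_aa}, found {found}"
        )
    center = res.center
    coords = s.coords()
    d = np.linalg.norm(coords - center, axis=1)
    return [a for a, keep in zip(s.atoms, d <= r) if keep]


def write_pdb(s: Structure, path: str | Path) -> None:
    """Write the structure as fixed-column PDB ATOM records."""
    st = gemmi.Structure()
    st.name = s.id or "model"
    model = gemmi.Model("1")
    # gemmi containers copy on add: assemble each level fully before adding
    by_chain: dict[str, list[Residue]] = {}
    for res in s.residues():
        by_chain.setdefault(res.chain, []).append(res)
    for chain_name, residues in by_chain.items():
        chain = gemmi.Chain(chain_name)
        for r in residues:
            res = gemmi.Residue()
            res.name = r.res_name
            res.seqid = gemmi.SeqId(r.res_seq, r.icode or " ")
            for a in r.atoms:
                at = gemmi.Atom()
                at.name = a.name
                at.element = gemmi.Element(a.element)
                at.pos = gemmi.Position(*a.xyz)
                at.occ = 1.0
                res.add_atom(at)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def iter_atoms(residues: Iterable[Residue]) -> Iterator[Atom]:
    for r in residues:
        yield from r.atoms
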