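"""Graph-based structural signatures of a mutation-site environment.

The environment of the wild-type residue is viewed as a contact graph whose
nodes are heavy atoms labelled with pharmacophore classes (hydrophobic,
positive, negative, hydrogen-bond acceptor, hydrogen-bond donor, aromatic,
sulfur, neutral) and whose edges are atom pairs within a distance cutoff.
Scanning the cutoff over a grid yields, for every unordered class pair, a
cumulative count of atom pairs — the signature.  The chemical change the
mutation itself introduces is summarized by the pharmacophore-change
vector: the componentwise difference between the mutant and wild-type
residues' per-class atom tallies (mutant minus wild type), so no mutant
structure is ever built.

Feature names follow the ``<Class1>:<Class2>-<cutoff>`` convention with the
class abbreviations Acc, Aro, Don, Hydro, Neg, Neu, Pos, Sul, the two
classes in lexicographic order, and the cutoff printed with two decimals
(e.g. ``Hydro:Hydro-4.00``).
"""

from __future__ import annotations

import enum
import logging
import warnings
from importlib import resources
from itertools import combinations_with_replacement
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import InvalidResidueError
from .residues import STANDARD_AA1, heavy_atoms, three_letter
from .structure_io import Atom

logger = logging.getLogger(__name__)

#: Default distance-cutoff grid (angstroms) for the signature scan.
DEFAULT_CUTOFFS: tuple[float, ...] = (2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0, 5.5, 6.0)

#: Default radius (angstroms) of the environment sphere about the
#: wild-type residue's geometric center.
DEFAULT_ENVIRONMENT_RADIUS: float = 10.0


class PharmacophoreClass(enum.Enum):
    """The eight atom pharmacophore classes."""

    HYDROPHOBIC = "Hydro"
    POSITIVE = "Pos"
    NEGATIVE = "Neg"
    ACCEPTOR = "Acc"
    DONOR = "Don"
    AROMATIC = "Aro"
    SULFUR = "Sul"
    NEUTRAL = "Neu"

    @property
    def short(self) -> str:
        return self.value


_BY_LONG = {
    "hydrophobic": PharmacophoreClass.HYDROPHOBIC,
    "positive": PharmacophoreClass.POSITIVE,
    "negative": PharmacophoreClass.NEGATIVE,
    "acceptor": PharmacophoreClass.ACCEPTOR,
    "donor": PharmacophoreClass.DONOR,
    "aromatic": PharmacophoreClass.AROMATIC,
    "sulfur": PharmacophoreClass.SULFUR,
    "neutral": PharmacophoreClass.NEUTRAL,
}

#: Classes in the canonical (lexicographic by abbreviation) order.
CLASS_ORDER: tuple[PharmacophoreClass, ...] = tuple(
    sorted(PharmacophoreClass, key=lambda c: c.short)
)

#: Fixed component order of pharmacophore count vectors (enum declaration order).
PCHANGE_ORDER: tuple[PharmacophoreClass, ...] = tuple(PharmacophoreClass)


class PharmacophoreTable:
    """Lookup (res_name, atom_name) -> set of pharmacophore classes."""

    def __init__(self, mapping: Mapping[tuple[str, str], frozenset[PharmacophoreClass]]):
        self._map = dict(mapping)

    @classmethod
    def default(cls) -> "PharmacophoreTable":
        """The packaged class table (versioned CSV)."""
        with resources.files("gpcrtherm.data").joinpath("pharmacophores.csv").open() as fh:
            df = pd.read_csv(fh, comment="#")
        mapping = {}
        for row in df.itertuples(index=False):
            classes = frozenset(_BY_LONG[c] for c in row.classes.split(";"))
            mapping[(row.res_name, row.atom_name)] = classes
        return cls(mapping)

    def lookup(self, res_name: str, atom_name: str) -> frozenset[PharmacophoreClass]:
        """Classes of one atom; unknown atoms degrade to {neutral} with a warning."""
        try:
            return self._map[(res_name, atom_name)]
        except KeyError:
            msg = f"unknown atom ({res_name}, {atom_name}): falling back to neutral"
            logger.warning(msg)
            warnings.warn(msg, stacklevel=2)
            return frozenset({PharmacophoreClass.NEUTRAL})

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._map

    def items(self):
        return self._map.items()


def assign_pharmacophores(
    atoms: Sequence[Atom], table: PharmacophoreTable
) -> list[frozenset[PharmacophoreClass]]:
    """Class sets for each atom, aligned with the input order."""
    return [table.lookup(a.res_name, a.name) for a in atoms]


def feature_name(c1: PharmacophoreClass, c2: PharmacophoreClass, cutoff: float) -> str:
    a, b = sorted((c1.short, c2.short))
    return f"{a}:{b}-{cutoff:.2f}"


def signature_feature_names(cutoffs: Sequence[float] = DEFAULT_CUTOFFS) -> list[str]:
    """All pair-count feature names for a cutoff grid, in canonical order."""
    names = []
    for c1, c2 in combinations_with_replacement(CLASS_ORDER, 2):
        for d in cutoffs:
            names.append(feature_name(c1, c2, d))
    return names


def pchange_feature_names() -> list[str]:
    return [f"PChange:{c.short}" for c in PCHANGE_ORDER]


def pair_count_signature(
    atoms: Sequence[Atom],
    classes: Sequence[frozenset[PharmacophoreClass]],
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
) -> dict[str, int]:
    """Cumulative pharmacophore pair counts over the cutoff grid.

    For each unordered class pair (C1, C2) and cutoff d, counts the
    unordered atom pairs {a, b} at distance <= d where one atom carries C1
    and the other C2.  A pair contributes to every class pair it satisfies,
    but once per class pair even when both atoms carry both classes.
    """
    cutoffs = list(cutoffs)
    if any(d <= 0 for d in cutoffs) or any(
        b <= a for a, b in zip(cutoffs, cutoffs[1:])
    ):
        raise ValueError("cutoffs must be strictly ascending and positive")

    counts = {name: 0 for name in signature_feature_names(cutoffs)}
    n = len(atoms)
    if n < 2:
        return counts

    coords = np.array([a.xyz for a in atoms], dtype=float)
    tree = cKDTree(coords)
    # pairs within the largest cutoff; each counted toward all grid points >= distance
    pairs = tree.query_pairs(r=max(cutoffs), output_type="ndarray")
    if len(pairs) == 0:
        return counts
    d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)

    membership = np.zeros((n, len(CLASS_ORDER)), dtype=bool)
    col = {c: k for k, c in enumerate(CLASS_ORDER)}
    for idx, cset in enumerate(classes):
        for c in cset:
            membership[idx, col[c]] = True
    mi = membership[pairs[:, 0]]
    mj = membership[pairs[:, 1]]
    grid = np.asarray(cutoffs, dtype=float)
    for a, c1 in enumerate(CLASS_ORDER):
        for b in range(a, len(CLASS_ORDER)):
            c2 = CLASS_ORDER[b]
            hit = (mi[:, a] & mj[:, b]) | (mi[:, b] & mj[:, a])
            if not hit.any():
                continue
            d_sel = np.sort(d[hit])
            per_cut = np.searchsorted(d_sel, grid, side="right")
            base = f"{c1.short}:{c2.short}-"
            for cut, cnt in zip(cutoffs, per_cut):
                counts[f"{base}{cut:.2f}"] = int(cnt)
    return counts


def residue_pharmacophore_vector(
    aa: str, table: PharmacophoreTable | None = None
) -> np.ndarray:
    """Per-class heavy-atom membership tally of a residue type's canonical atoms.

    Component c counts (atom, class-c) memberships over the residue's
    backbone plus side-chain heavy atoms; multi-label atoms contribute to
    every class they carry.
    """
    if aa not in STANDARD_AA1:
        raise InvalidResidueError(f"{aa!r} is not a standard one-letter code")
    table = table or PharmacophoreTable.default()
    res_name = three_letter(aa)
    vec = np.zeros(len(PCHANGE_ORDER), dtype=int)
    index = {c: i for i, c in enumerate(PCHANGE_ORDER)}
    for atom_name in heavy_atoms(res_name):
        for c in table.lookup(res_name, atom_name):
            vec[index[c]] += 1
    return vec


def pchange(wt: str, mt: str, table: PharmacophoreTable | None = None) -> np.ndarray:
    """Pharmacophore-change vector: mutant tally minus wild-type tally."""
    table = table or PharmacophoreTable.default()
    return residue_pharmacophore_vector(mt, table) - residue_pharmacophore_vector(wt, table)
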