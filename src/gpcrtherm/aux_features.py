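"""Auxiliary (non-signature) features for a mutation.

Covers substitution-matrix scores (BLOSUM62, PAM30), amino-acid pair
matrices in AAindex2 flat-file format, relative solvent accessibility
(RSA), residue depth, membrane-topology flags, and residue-identity
indicator features (FromPro, ToAla, FromGly, ToPro).

The two packaged pair matrices keyed BENS940104 (genetic-code matrix) and
LUTR910108 (alpha-helix class substitution table) are synthetic
reconstructions derived in-package from the standard genetic code and from
published helix propensities; they preserve the semantics of the published
entries (see ``data/aaindex2_synthetic.txt``) without reproducing their
exact values.

Further feature families (interatomic-contact counts, normal-mode or
potential-energy terms) can be plugged in through ``FEATURE_PROVIDERS``
without touching the featurization pipeline.
"""

from __future__ import annotations

import io
from importlib import resources
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from Bio.PDB.SASA import ShrakeRupley
from Bio.PDB.StructureBuilder import StructureBuilder
from scipy.spatial import cKDTree

from .errors import (
    ConfigurationError,
    DataIntegrityError,
    FeatureComputationError,
    InvalidResidueError,
)
from .residues import STANDARD_AA1, one_letter
from .structure_io import Residue, Structure

PROBE_RADIUS = 1.4  # angstroms, water-sized rolling probe

_VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80}
_VDW_DEFAULT = 1.70

#: Default half-width (angstroms) of the membrane slab along z.
DEFAULT_HALF_WIDTH = 15.0

#: Extension hook: name -> callable(structure, mutation) -> {feature: value}.
#: Registering a provider adds its features to every featurization run.
FEATURE_PROVIDERS: dict[str, Callable] = {}


# ---------------------------------------------------------------------------
# substitution matrices
# ---------------------------------------------------------------------------

class SubstitutionMatrix:
    """A named amino-acid substitution matrix with symmetric lookup."""

    def __init__(self, name: str, scores: Mapping[tuple[str, str], float]):
        self.name = name
        self._scores = dict(scores)

    @classmethod
    def standard(cls, name: str) -> "SubstitutionMatrix":
        """Load a packaged standard matrix (e.g. BLOSUM62, PAM30)."""
        arr = substitution_matrices.load(name)
        scores = {}
        for a in STANDARD_AA1:
            for b in STANDARD_AA1:
                scores[(a, b)] = float(arr[a, b])
        return cls(name, scores)

    def score(self, wt: str, mt: str) -> float:
        try:
            return self._scores[(wt, mt)]
        except KeyError:
            try:
                return self._scores[(mt, wt)]
            except KeyError:
                raise DataIntegrityError(
                    f"matrix {self.name}: no entry for pair ({wt}, {mt})"
                ) from None


def substitution_scores(
    wt: str, mt: str, matrices: Sequence[SubstitutionMatrix]
) -> dict[str, float]:
    """One score per matrix for the ordered pair (wt, mt)."""
    _check_codes(wt, mt)
    return {m.name: m.score(wt, mt) for m in matrices}


# ---------------------------------------------------------------------------
# AAindex2 pair matrices
# ---------------------------------------------------------------------------

def parse_aaindex2(text: str) -> dict[str, dict[tuple[str, str], float]]:
    """Parse the AAindex2 flat-file dialect (H/D/M entries, '//' terminator).

    Lower-triangular matrices are mirrored to full symmetric lookup.
    """
    tables: dict[str, dict[tuple[str, str], float]] = {}
    acc = None
    rows_order = cols_order = None
    values: list[list[float]] = []
    for raw in io.StringIO(text):
        line = raw.rstrip("\n")
        if line.startswith("*") or not line.strip():
            continue
        if line.startswith("H "):
            acc = line[2:].strip()
            values = []
            rows_order = cols_order = None
        elif line.startswith("M "):
            spec = line[2:]
            parts = dict(
                p.strip().split(" = ") for p in spec.split(",") if " = " in p
            )
            rows_order = parts["rows"].strip()
            cols_order = parts["cols"].strip()
        elif line.startswith("//"):
            if acc is None or rows_order is None:
                raise DataIntegrityError("malformed AAindex2 entry (missing H or M line)")
            table: dict[tuple[str, str], float] = {}
            for i, row_vals in enumerate(values):
                for j, v in enumerate(row_vals):
                    a, b = rows_order[i], cols_order[j]
                    table[(a, b)] = v
                    table[(b, a)] = v
            tables[acc] = table
            acc = None
        elif acc is not None and rows_order is not None and line[:1] == " ":
            values.append([float(x) for x in line.split()])
    return tables


class AAIndexMatrix:
    """One AAindex2 pair matrix, keyed by accession."""

    _packaged: dict[str, dict[tuple[str, str], float]] | None = None

    def __init__(self, id: str, scores: Mapping[tuple[str, str], float]):
        self.id = id
        self._scores = dict(scores)

    @classmethod
    def packaged(cls, id: str) -> "AAIndexMatrix":
        if cls._packaged is None:
            text = (
                resources.files("gpcrtherm.data")
                .joinpath("aaindex2_synthetic.txt")
                .read_text()
            )
            cls._packaged = parse_aaindex2(text)
        try:
            return cls(id, cls._packaged[id])
        except KeyError:
            raise DataIntegrityError(f"no packaged AAindex matrix {id!r}") from None

    def score(self, wt: str, mt: str) -> float:
        try:
            return self._scores[(wt, mt)]
        except KeyError:
            raise DataIntegrityError(f"matrix {self.id}: no entry for ({wt}, {mt})") from None


def aaindex_scores(wt: str, mt: str, ids: Sequence[str]) -> dict[str, float]:
    """Scores of the (wt, mt) pair in each requested packaged AAindex matrix."""
    _check_codes(wt, mt)
    return {i: AAIndexMatrix.packaged(i).score(wt, mt) for i in ids}


# ---------------------------------------------------------------------------
# solvent accessibility and depth
# ---------------------------------------------------------------------------

def _max_asa() -> dict[str, float]:
    with resources.files("gpcrtherm.data").joinpath("max_asa.csv").open() as fh:
        df = pd.read_csv(fh, comment="#")
    return dict(zip(df.aa, df.max_asa))


def _to_biopdb(s: Structure):
    """Build a Bio.PDB entity mirroring the cleaned structure."""
    builder = StructureBuilder()
    builder.init_structure(s.id or "s")
    builder.init_model(0)
    builder.init_seg("    ")
    seen_chain = None
    serial = 0
    for res in s.residues():
        if res.chain != seen_chain:
            builder.init_chain(res.chain)
            seen_chain = res.chain
        builder.init_residue(res.res_name, " ", res.res_seq, res.icode or " ")
        for a in res.atoms:
            serial += 1
            builder.init_atom(
                a.name,
                np.asarray(a.xyz, dtype=float),
                0.0,
                1.0,
                " ",
                a.name.center(4),
                serial,
                element=a.element,
            )
    return builder.get_structure()


def sasa_by_residue(s: Structure) -> dict[tuple[str, int, str], float]:
    """Per-residue solvent-accessible surface area (Shrake-Rupley, 1.4 A probe)."""
    entity = _to_biopdb(s)
    try:
        ShrakeRupley(probe_radius=PROBE_RADIUS).compute(entity, level="R")
    except Exception as exc:  # backend failure surfaces as a package error
        raise FeatureComputationError(f"SASA computation failed: {exc}") from exc
    out = {}
    for chain in entity[0]:
        for res in chain:
            _, seq, icode = res.get_id()
            out[(chain.id, seq, icode.strip())] = float(res.sasa)
    return out


def relative_solvent_accessibility(
    s: Structure,
    residue: Residue,
    sasa_cache: Mapping[tuple[str, int, str], float] | None = None,
) -> float:
    """Residue SASA divided by the residue type's maximum reference SASA.

    Values slightly above 1 can occur for highly exposed conformations;
    the reference table is the packaged theoretical-maximum set.
    """
    cache = sasa_cache if sasa_cache is not None else sasa_by_residue(s)
    key = (residue.chain, residue.res_seq, residue.icode)
    try:
        sasa = cache[key]
    except KeyError:
        raise FeatureComputationError(f"no SASA for residue {key}") from None
    return sasa / _max_asa()[one_letter(residue.res_name)]


def surface_points(s: Structure, n_sphere_points: int = 60) -> np.ndarray:
    """Dot representation of the solvent-accessible surface.

    Each atom is expanded to a sphere of radius vdW + probe sampled with a
    Fibonacci lattice; points buried inside any neighboring sphere are
    discarded.  Used as the reference surface for residue depth (an
    MSMS-style molecular surface is not required for a mean-distance
    burial measure).
    """
    coords = s.coords()
    if len(coords) < 4:
        raise FeatureComputationError("too few atoms to define a surface")
    radii = np.array(
        [_VDW_RADII.get(a.element, _VDW_DEFAULT) + PROBE_RADIUS for a in s.atoms]
    )
    k = np.arange(n_sphere_points)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (k + 0.5) / n_sphere_points
    rho = np.sqrt(1.0 - z * z)
    unit = np.stack([rho * np.cos(golden * k), rho * np.sin(golden * k), z], axis=1)

    tree = cKDTree(coords)
    max_r = radii.max()
    dots = []
    for i, (c, r) in enumerate(zip(coords, radii)):
        pts = c + r * unit
        neighbors = [j for j in tree.query_ball_point(c, r + max_r) if j != i]
        if neighbors:
            d = np.linalg.norm(pts[:, None, :] - coords[neighbors][None, :, :], axis=2)
            exposed = (d >= radii[neighbors][None, :] - 1e-9).all(axis=1)
            pts = pts[exposed]
        if len(pts):
            dots.append(pts)
    if not dots:
        raise FeatureComputationError("degenerate geometry: no exposed surface points")
    return np.vstack(dots)


def residue_depth(
    s: Structure, residue: Residue, surface: np.ndarray | None = None
) -> float:
    """Mean distance (angstroms) of the residue's heavy atoms to the surface."""
    surf = surface if surface is not None else surface_points(s)
    tree = cKDTree(surf)
    d, _ = tree.query(np.array([a.position for a in residue.atoms]))
    return float(np.mean(d))


# ---------------------------------------------------------------------------
# topology and identity flags
# ---------------------------------------------------------------------------

class TopologyAnnotation:
    """Per-residue membrane flags, from an annotation file or a z-slab rule.

    In z-slab mode the structure must be membrane-oriented with the
    membrane normal along z and the extracellular side at positive z:
    ``mem = 1`` iff |z_center| <= half_width and ``non_cytosol = 1`` iff
    z_center >= -half_width.
    """

    def __init__(
        self,
        flags: Mapping[tuple[str, int], tuple[int, int]] | None = None,
        half_width: float = DEFAULT_HALF_WIDTH,
    ):
        self._flags = dict(flags) if flags is not None else None
        self.half_width = half_width
        self.provenance = "annotation-file" if flags is not None else "z-slab"

    @classmethod
    def from_csv(cls, path) -> "TopologyAnnotation":
        df = pd.read_csv(path, comment="#")
        required = {"chain", "res_seq", "mem", "non_cytosol"}
        if not required.issubset(df.columns):
            raise ConfigurationError(
                f"topology annotation {path} must have columns {sorted(required)}"
            )
        flags = {
            (str(r.chain), int(r.res_seq)): (int(r.mem), int(r.non_cytosol))
            for r in df.itertuples(index=False)
        }
        return cls(flags=flags)

    def flags_for(self, residue: Residue) -> tuple[int, int]:
        if self._flags is not None:
            try:
                return self._flags[(residue.chain, residue.res_seq)]
            except KeyError:
                raise ConfigurationError(
                    f"no topology annotation for residue {residue.chain}/{residue.res_seq}"
                ) from None
        z = float(residue.center[2])
        mem = int(abs(z) <= self.half_width)
        non_cytosol = int(z >= -self.half_width)
        return mem, non_cytosol


def topology_flags(annotation: TopologyAnnotation, residue: Residue) -> tuple[int, int]:
    """(mem, non_cytosol) flags of the mutated residue."""
    return annotation.flags_for(residue)


def identity_flags(wt: str, mt: str) -> dict[str, int]:
    """Special amino-acid indicators: FromPro, ToAla, FromGly, ToPro."""
    _check_codes(wt, mt)
    return {
        "FromPro": int(wt == "P"),
        "ToAla": int(mt == "A"),
        "FromGly": int(wt == "G"),
        "ToPro": int(mt == "P"),
    }


def _check_codes(*codes: str) -> None:
    for c in codes:
        if c not in STANDARD_AA1:
            raise InvalidResidueError(f"{c!r} is not a standard one-letter code")
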