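"""Synthetic helical bundles and planted-signal mutation tables.

These generators stand in for receptor models and curated mutation data so
that every pipeline stage — structure I/O, signatures, featurization,
selection, training, evaluation — runs end to end with known ground truth.
A bundle is a ring of ideal parametric alpha-helices (1.5 A rise, 3.6
residues per turn) with backbone atoms N/CA/C/O on phase-shifted co-axial
helices and each side chain reduced to a single CB pseudo-atom carrying
the residue's full pharmacophore profile.  Labels are planted as a linear
function of standardized feature columns plus Gaussian noise, giving a
closed-form recovery oracle for the feature-selection stage.

Everything is a pure function of (spec, seed).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .dataset import FeatureMatrix, MutationRecord
from .errors import ConfigurationError, SchemaError
from .residues import STANDARD_AA1, one_letter, three_letter
from .structure_io import Atom, Structure

#: Local cylindrical placement of backbone atoms and the CB pseudo-atom:
#: (radius A, phase offset rad, z offset A) relative to the CA helix.
_ATOM_GEOMETRY = {
    "N": ("N", 1.55, -0.60, -0.70),
    "CA": ("C", 2.30, 0.00, 0.00),
    "C": ("C", 1.70, 0.55, 0.60),
    "O": ("O", 2.04, 0.70, 1.10),
    "CB": ("C", 3.30, 0.25, -0.20),
}

_AA_ALPHABET = sorted(STANDARD_AA1)


@dataclasses.dataclass(frozen=True)
class BundleSpec:
    """Geometry and sequence of a synthetic multi-helix bundle."""

    n_helices: int = 7
    residues_per_helix: int = 25
    helix_spacing: float = 10.0  # ring radius, A
    rise_per_residue: float = 1.5
    residues_per_turn: float = 3.6
    sequence: str | None = None  # None -> random, drawn from seed
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_helices < 1 or self.residues_per_helix < 1:
            raise ConfigurationError("need at least one helix with one residue")
        if self.helix_spacing <= 0:
            raise ConfigurationError("helix_spacing must be positive")

    @property
    def n_residues(self) -> int:
        return self.n_helices * self.residues_per_helix


@dataclasses.dataclass(frozen=True)
class PlantSpec:
    """A planted linear label model over named feature columns."""

    true_features: tuple[str, ...]
    weights: tuple[float, ...]
    noise_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.true_features) != len(self.weights):
            raise ConfigurationError("true_features and weights must align")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")


def make_helical_bundle(spec: BundleSpec) -> Structure:
    """Build the bundle as one chain 'A' with sequential residue numbers.

    Helices sit on a ring of radius ``helix_spacing`` with the bundle axis
    along z (membrane normal), centered at z = 0.  Adjacent helix axes
    closer than ~7 A would interpenetrate and are rejected.
    """
    if spec.n_helices > 1:
        separation = 2 * spec.helix_spacing * np.sin(np.pi / spec.n_helices)
        if separation < 7.0:
            raise ConfigurationError(
                f"helix axes {separation:.1f} A apart would overlap; "
                "increase helix_spacing or reduce n_helices"
            )
    if spec.sequence is not None:
        seq = spec.sequence.upper()
        if len(seq) != spec.n_residues:
            raise ConfigurationError(
                f"sequence length {len(seq)} != {spec.n_residues} residues"
            )
        if not set(seq) <= STANDARD_AA1:
            raise ConfigurationError("sequence contains non-standard codes")
    else:
        rng = np.random.default_rng(spec.seed)
        seq = "".join(rng.choice(_AA_ALPHABET, size=spec.n_residues))

    omega = 2 * np.pi / spec.residues_per_turn
    z_span = (spec.residues_per_helix - 1) * spec.rise_per_residue
    atoms: list[Atom] = []
    serial = 0
    res_seq = 0
    for h in range(spec.n_helices):
        phi = 2 * np.pi * h / spec.n_helices
        cx = spec.helix_spacing * np.cos(phi)
        cy = spec.helix_spacing * np.sin(phi)
        for i in range(spec.residues_per_helix):
            res_seq += 1
            aa = seq[res_seq - 1]
            res_name = three_letter(aa)
            theta = i * omega + phi  # stagger helices' phases by ring position
            z = i * spec.rise_per_residue - z_span / 2
            for name, (element, r, dtheta, dz) in _ATOM_GEOMETRY.items():
                if name == "CB" and aa == "G":
                    continue
                serial += 1
                atoms.append(
                    Atom(
                        serial=serial,
                        name=name,
                        element=element,
                        res_name=res_name,
                        res_seq=res_seq,
                        chain="A",
                        xyz=(
                            cx + r * np.cos(theta + dtheta),
                            cy + r * np.sin(theta + dtheta),
                            z + dz,
                        ),
                    )
                )
    return Structure(atoms=atoms, id=f"bundle-{spec.n_helices}x{spec.residues_per_helix}")


def make_mutation_table(
    structure: Structure,
    n_mutations: int,
    seed: int,
    uniprot_id: str = "SYNTH01",
) -> list[MutationRecord]:
    """Sample unique (position, mutant) pairs uniformly without replacement."""
    residues = structure.residues()
    combos = [
        (res.res_seq, one_letter(res.res_name), mt)
        for res in residues
        for mt in _AA_ALPHABET
        if mt != one_letter(res.res_name)
    ]
    if n_mutations > len(combos):
        raise ConfigurationError(
            f"requested {n_mutations} mutations but only {len(combos)} are possible"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(combos), size=n_mutations, replace=False)
    chain = residues[0].chain
    return [
        MutationRecord(
            uniprot_id=uniprot_id,
            chain=chain,
            position=combos[i][0],
            wt_aa=combos[i][1],
            mt_aa=combos[i][2],
            dTm=None,
            source="synthetic",
        )
        for i in chosen
    ]


def plant_labels(features, plant: PlantSpec) -> np.ndarray:
    """Labels y = sum_i w_i * z(f_i) + Normal(0, sigma^2), seeded.

    Feature columns are standardized internally before weighting, so the
    weights are on a common scale regardless of the features' raw units.
    """
    X = features.X if isinstance(features, FeatureMatrix) else features
    if not isinstance(X, pd.DataFrame):
        raise SchemaError("plant_labels needs a feature DataFrame")
    missing = [f for f in plant.true_features if f not in X.columns]
    if missing:
        raise SchemaError(f"planted features absent from the matrix: {missing}")
    y = np.zeros(len(X), dtype=float)
    for f, w in zip(plant.true_features, plant.weights):
        col = X[f].to_numpy(dtype=float)
        std = col.std()
        if std == 0:
            raise SchemaError(f"planted feature {f!r} is constant; cannot standardize")
        y += w * (col - col.mean()) / std
    rng = np.random.default_rng(plant.seed)
    y += rng.normal(0.0, plant.noise_sigma, size=len(X))
    return y
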