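"""Mutation tables: ingestion, deduplication, splitting, featurization.

A mutation record names a substitution on a receptor (UniProt accession,
chain, position, wild-type and mutant residues) with an optional
experimental melting-temperature change (dTm, degrees C).  Featurization
turns records into a rectangular matrix: graph-based signature counts over
the cutoff grid, the 8 pharmacophore-change components, and the auxiliary
features, in a fixed column order.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from . import aux_features as aux
from . import signatures as sig
from .errors import (
    DataConflictError,
    FeatureComputationError,
    GpcrthermError,
    InsufficientDataError,
    WildtypeMismatchError,
)
from .mutations import MutationSpec
from .residues import one_letter
from .structure_io import Structure, residue_environment

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class MutationRecord:
    """One labeled (or prediction-only) mutation."""

    uniprot_id: str
    chain: str
    position: int
    wt_aa: str
    mt_aa: str
    dTm: float | None = None
    source: str = ""

    @property
    def key(self) -> tuple[str, int, str]:
        """Redundancy key: same receptor, same position, same target residue."""
        return (self.uniprot_id, self.position, self.mt_aa)

    @property
    def spec(self) -> MutationSpec:
        return MutationSpec(
            chain=self.chain, position=self.position, wt_aa=self.wt_aa, mt_aa=self.mt_aa
        )


def read_mutation_table(path) -> list[MutationRecord]:
    """Read the CSV schema (uniprot_id, chain, position, wt_aa, mt_aa, dTm, source)."""
    df = pd.read_csv(path, comment="#")
    records = []
    for row in df.itertuples(index=False):
        dtm = getattr(row, "dTm", None)
        records.append(
            MutationRecord(
                uniprot_id=str(row.uniprot_id),
                chain=str(row.chain),
                position=int(row.position),
                wt_aa=str(row.wt_aa),
                mt_aa=str(row.mt_aa),
                dTm=None if dtm is None or pd.isna(dtm) else float(dtm),
                source=str(getattr(row, "source", "")),
            )
        )
    return records


def write_mutation_table(records: Sequence[MutationRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "uniprot_id": r.uniprot_id,
                "chain": r.chain,
                "position": r.position,
                "wt_aa": r.wt_aa,
                "mt_aa": r.mt_aa,
                "dTm": r.dTm,
                "source": r.source,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def merge_and_deduplicate(tables: Iterable[Sequence[MutationRecord]]) -> list[MutationRecord]:
    """Merge tables, collapsing repeats of (uniprot, position, mutant residue).

    The first-listed source wins; output preserves first-occurrence order.
    Records that share a key but disagree on the wild-type residue are a
    data conflict, not a redundancy.
    """
    seen: dict[tuple, MutationRecord] = {}
    for table in tables:
        for rec in table:
            prev = seen.get(rec.key)
            if prev is None:
                seen[rec.key] = rec
            elif prev.wt_aa != rec.wt_aa:
                raise DataConflictError(
                    f"conflicting wild types at {rec.key}: "
                    f"{prev.wt_aa} (from {prev.source!r}) vs {rec.wt_aa} (from {rec.source!r})"
                )
    return list(seen.values())


def blind_split(
    records: Sequence[MutationRecord], fraction: float, seed: int
) -> tuple[list[MutationRecord], list[MutationRecord]]:
    """Uniform random train/test split; |test| = round(fraction * n).

    Mutations are disjoint between the sides; receptors may be shared.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    n = len(records)
    if n < 2:
        raise InsufficientDataError(f"need at least 2 records to split, got {n}")
    n_test = int(round(fraction * n))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    test_idx = set(order[:n_test].tolist())
    train = [r for i, r in enumerate(records) if i not in test_idx]
    test = [r for i, r in enumerate(records) if i in test_idx]
    return train, test


@dataclasses.dataclass
class FeaturizationConfig:
    """Everything that fixes the feature map and its column order."""

    environment_radius: float = sig.DEFAULT_ENVIRONMENT_RADIUS
    cutoffs: tuple[float, ...] = sig.DEFAULT_CUTOFFS
    substitution_matrix_names: tuple[str, ...] = ("BLOSUM62", "PAM30")
    aaindex_ids: tuple[str, ...] = ("BENS940104", "LUTR910108")
    topology: aux.TopologyAnnotation = dataclasses.field(
        default_factory=aux.TopologyAnnotation
    )
    strict: bool = True
    include_rsa: bool = True
    include_depth: bool = True

    def feature_names(self) -> list[str]:
        names = sig.signature_feature_names(self.cutoffs)
        names += sig.pchange_feature_names()
        names += list(self.substitution_matrix_names)
        names += list(self.aaindex_ids)
        if self.include_rsa:
            names.append("rsa")
        if self.include_depth:
            names.append("residue_depth")
        names += ["mem", "non_cytosol", "FromPro", "ToAla", "FromGly", "ToPro"]
        for provider in aux.FEATURE_PROVIDERS:
            names.append(provider)
        return names


@dataclasses.dataclass
class FeatureMatrix:
    """Featurized records: aligned records, features, and dTm labels."""

    records: list[MutationRecord]
    X: pd.DataFrame
    labels: np.ndarray  # NaN for prediction-only records
    report: list[dict] = dataclasses.field(default_factory=list)

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def __len__(self) -> int:
        return len(self.records)


class _StructureCache:
    """Per-structure lazily computed quantities shared across records."""

    def __init__(self, structure: Structure, config: FeaturizationConfig):
        self.structure = structure
        self.config = config
        self._sasa = None
        self._surface = None
        self._site_counts: dict[tuple, dict[str, int]] = {}
        self._table = sig.PharmacophoreTable.default()

    @property
    def sasa(self):
        if self._sasa is None:
            self._sasa = aux.sasa_by_residue(self.structure)
        return self._sasa

    @property
    def surface(self):
        if self._surface is None:
            self._surface = aux.surface_points(self.structure)
        return self._surface

    def site_signature(self, spec: MutationSpec) -> dict[str, int]:
        key = (spec.chain, spec.position)
        if key not in self._site_counts:
            env = residue_environment(self.structure, spec, self.config.environment_radius)
            classes = sig.assign_pharmacophores(env, self._table)
            self._site_counts[key] = sig.pair_count_signature(
                env, classes, self.config.cutoffs
            )
        return self._site_counts[key]

    @property
    def table(self) -> sig.PharmacophoreTable:
        return self._table


def _featurize_one(
    rec: MutationRecord, cache: _StructureCache, config: FeaturizationConfig
) -> dict[str, float]:
    spec = rec.spec
    # verify the stated wild type before any cached lookup can mask a mismatch
    residue = cache.structure.find_residue(rec.chain, rec.position)
    found = one_letter(residue.res_name)
    if found != rec.wt_aa:
        raise WildtypeMismatchError(
            f"residue {rec.chain}/{rec.position}: expected wild type {rec.wt_aa}, found {found}"
        )
    row: dict[str, float] = {}
    row.update(cache.site_signature(spec))
    pchg = sig.pchange(rec.wt_aa, rec.mt_aa, cache.table)
    for name, v in zip(sig.pchange_feature_names(), pchg):
        row[name] = int(v)
    mats = [aux.SubstitutionMatrix.standard(n) for n in config.substitution_matrix_names]
    row.update(aux.substitution_scores(rec.wt_aa, rec.mt_aa, mats))
    row.update(aux.aaindex_scores(rec.wt_aa, rec.mt_aa, config.aaindex_ids))
    if config.include_rsa:
        row["rsa"] = aux.relative_solvent_accessibility(
            cache.structure, residue, sasa_cache=cache.sasa
        )
    if config.include_depth:
        row["residue_depth"] = aux.residue_depth(
            cache.structure, residue, surface=cache.surface
        )
    mem, non_cyt = aux.topology_flags(config.topology, residue)
    row["mem"] = mem
    row["non_cytosol"] = non_cyt
    row.update(aux.identity_flags(rec.wt_aa, rec.mt_aa))
    for name, provider in aux.FEATURE_PROVIDERS.items():
        row[name] = float(provider(cache.structure, spec))
    return row


def featurize(
    records: Sequence[MutationRecord],
    structures: Mapping[str, Structure],
    config: FeaturizationConfig | None = None,
) -> FeatureMatrix:
    """One feature row per record against its receptor's structure.

    In strict mode (default) any per-record failure aborts the run with an
    aggregated error; in lenient mode failing records are dropped and
    logged in the run report.
    """
    config = config or FeaturizationConfig()
    caches: dict[str, _StructureCache] = {}
    rows, kept, report = [], [], []
    for rec in records:
        key = f"{rec.uniprot_id}:{rec.wt_aa}{rec.position}{rec.mt_aa}"
        try:
            if rec.uniprot_id not in structures:
                raise FeatureComputationError(
                    f"no structure supplied for receptor {rec.uniprot_id}"
                )
            if rec.uniprot_id not in caches:
                caches[rec.uniprot_id] = _StructureCache(
                    structures[rec.uniprot_id], config
                )
            rows.append(_featurize_one(rec, caches[rec.uniprot_id], config))
            kept.append(rec)
            report.append({"record": key, "status": "ok", "message": ""})
        except GpcrthermError as exc:
            report.append({"record": key, "status": "error", "message": str(exc)})
            if config.strict:
                raise FeatureComputationError(f"featurization failed for {key}: {exc}") from exc
            logger.warning("dropping record %s: %s", key, exc)
    names = config.feature_names()
    X = pd.DataFrame(rows, columns=names) if rows else pd.DataFrame(columns=names)
    labels = np.array(
        [np.nan if r.dTm is None else float(r.dTm) for r in kept], dtype=float
    )
    return FeatureMatrix(records=kept, X=X, labels=labels, report=report)


class MutationFeaturizer(TransformerMixin, BaseEstimator):
    """Stateless transformer from mutation records to the feature matrix.

    Composes with scikit-learn pipelines: ``transform`` accepts a sequence
    of MutationRecord (or a DataFrame in the mutation-table schema) and
    returns the feature DataFrame.
    """

    def __init__(
        self,
        structures: Mapping[str, Structure] | None = None,
        config: FeaturizationConfig | None = None,
    ):
        self.structures = structures
        self.config = config

    def fit(self, X, y=None):
        self.feature_names_ = (self.config or FeaturizationConfig()).feature_names()
        return self

    def transform(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            records = [
                MutationRecord(
                    uniprot_id=str(r.uniprot_id),
                    chain=str(r.chain),
                    position=int(r.position),
                    wt_aa=str(r.wt_aa),
                    mt_aa=str(r.mt_aa),
                    dTm=float(r.dTm) if "dTm" in X.columns and not pd.isna(r.dTm) else None,
                )
                for r in X.itertuples(index=False)
            ]
        else:
            records = list(X)
        fm = featurize(records, self.structures or {}, self.config)
        return fm.X

    def get_feature_names_out(self, input_features=None):
        return np.asarray((self.config or FeaturizationConfig()).feature_names())
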