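"""Core in-memory containers shared across the pipeline stages.

Fingerprints are fixed-length binary bit vectors stored as ``numpy`` boolean
arrays.  When compounds are supplied as SMILES the documented default encoding
is a Morgan (circular substructure) fingerprint of radius 2 and 2048 bits; see
:func:`fingerprint_from_smiles`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

APPROVED = "approved"
EXPERIMENTAL = "experimental"
STATUSES = (APPROVED, EXPERIMENTAL)


def as_fingerprint(bits, length: int | None = None) -> np.ndarray:
    """Coerce an iterable of 0/1 values or a set of on-bit indices to a bool array.

    A ``set``/``frozenset`` argument is interpreted as on-bit indices and
    requires ``length``; any other sequence is taken as a dense 0/1 vector.
    """
    if isinstance(bits, (set, frozenset)):
        if length is None:
            raise ValueError("length is required when passing on-bit indices")
        fp = np.zeros(length, dtype=bool)
        fp[list(bits)] = True
        return fp
    fp = np.asarray(bits)
    if fp.dtype != bool:
        fp = fp.astype(bool)
    if fp.ndim != 1:
        raise ValueError("fingerprint must be one-dimensional")
    if length is not None and fp.size != length:
        raise ValueError(f"fingerprint length {fp.size} != expected {length}")
    return fp


def fingerprint_from_smiles(smiles: str, n_bits: int = 2048, radius: int = 2) -> np.ndarray:
    """Morgan circular substructure fingerprint for a SMILES string (needs RDKit)."""
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    return np.array(gen.GetFingerprint(mol), dtype=bool)


@dataclass(frozen=True)
class CompoundRecord:
    """One library member: identifier, approval status and binary fingerprint."""

    compound_id: str
    name: str
    status: str
    fingerprint: np.ndarray

    def __post_init__(self):
        if not self.compound_id:
            raise ValueError("compound_id must be non-empty")
        if self.status not in STATUSES:
            raise ValueError(f"status must be one of {STATUSES}, got {self.status!r}")
        object.__setattr__(self, "fingerprint", as_fingerprint(self.fingerprint))

    @property
    def n_bits_set(self) -> int:
        return int(self.fingerprint.sum())


@dataclass(frozen=True)
class BindingSite:
    """A predicted binding site: confidence score plus predicted-ligand fingerprints."""

    site_id: str
    site_score: float
    ligand_fingerprints: tuple

    def __post_init__(self):
        if not 0.0 <= self.site_score <= 1.0:
            raise ValueError(f"site_score must be in [0,1], got {self.site_score}")
        fps = tuple(as_fingerprint(fp) for fp in self.ligand_fingerprints)
        if not fps:
            raise ValueError("a binding site needs at least one predicted ligand")
        object.__setattr__(self, "ligand_fingerprints", fps)


@dataclass(frozen=True)
class ProteinSiteModel:
    """A protein's predicted binding sites with per-site confidence scores."""

    protein_id: str
    sites: tuple

    def __post_init__(self):
        sites = tuple(self.sites)
        if not sites:
            raise ValueError("a protein needs at least one binding site")
        object.__setattr__(self, "sites", sites)

    def all_ligands(self):
        """Yield (site, ligand_fingerprint) pairs over every site."""
        for site in self.sites:
            for fp in site.ligand_fingerprints:
                yield site, fp


class InteractionMatrix:
    """Dense compounds x proteins matrix of interaction scores in [0, 1].

    Each row is one compound's proteome-wide interaction signature: a vector
    of predicted interaction scores against every protein in the library.
    """

    def __init__(self, compound_ids: Sequence[str], protein_ids: Sequence[str], scores):
        self.compound_ids = list(compound_ids)
        self.protein_ids = list(protein_ids)
        scores = np.asarray(scores, dtype=float)
        if scores.shape != (len(self.compound_ids), len(self.protein_ids)):
            raise ValueError(
                f"scores shape {scores.shape} does not match "
                f"({len(self.compound_ids)}, {len(self.protein_ids)})"
            )
        if len(set(self.compound_ids)) != len(self.compound_ids):
            raise ValueError("duplicate compound_ids")
        if len(set(self.protein_ids)) != len(self.protein_ids):
            raise ValueError("duplicate protein_ids")
        if not np.all(np.isfinite(scores)):
            raise ValueError("scores contain NaN/Inf")
        if scores.size and (scores.min() < 0 or scores.max() > 1):
            raise ValueError("scores must lie in [0, 1]")
        self.scores = scores
        self._row = {c: i for i, c in enumerate(self.compound_ids)}
        self._col = {p: j for j, p in enumerate(self.protein_ids)}

    @property
    def shape(self):
        return self.scores.shape

    def signature(self, compound_id: str) -> np.ndarray:
        try:
            return self.scores[self._row[compound_id]]
        except KeyError:
            raise KeyError(f"unknown compound_id {compound_id!r}") from None

    def column_indices(self, protein_ids: Iterable[str]) -> np.ndarray:
        try:
            return np.array([self._col[p] for p in protein_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown protein_id {exc.args[0]!r}") from None

    def subset_compounds(self, compound_ids: Sequence[str]) -> "InteractionMatrix":
        idx = [self._row[c] for c in compound_ids]
        return InteractionMatrix(list(compound_ids), self.protein_ids, self.scores[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.compound_ids, columns=self.protein_ids)

    def __contains__(self, compound_id: str) -> bool:
        return compound_id in self._row


@dataclass(frozen=True)
class PanelDefinition:
    """A named proteome panel: the subset of matrix columns to compare on.

    Built-in panel semantics mirror the screening design: ``human`` is the
    full proteome, while disease-focused panels (e.g. significantly mutated
    genes in lung adenocarcinoma, or a pathway neighbourhood of a driver
    oncogene) restrict the signature to the columns of interest.
    """

    panel_id: str
    protein_ids: tuple

    def __post_init__(self):
        pids = tuple(self.protein_ids)
        if not pids:
            raise ValueError("a panel must contain at least one protein")
        if len(set(pids)) != len(pids):
            raise ValueError("panel contains duplicate protein ids")
        object.__setattr__(self, "protein_ids", pids)

    @classmethod
    def full(cls, matrix: InteractionMatrix, panel_id: str = "human") -> "PanelDefinition":
        return cls(panel_id, tuple(matrix.protein_ids))

    def validate_against(self, matrix: InteractionMatrix) -> None:
        missing = [p for p in self.protein_ids if p not in matrix._col]
        if missing:
            raise KeyError(f"panel proteins not in matrix: {missing[:5]}")


@dataclass(frozen=True)
class Indication:
    indication_id: str
    name: str
    approved_compound_ids: frozenset

    def __post_init__(self):
        object.__setattr__(
            self, "approved_compound_ids", frozenset(self.approved_compound_ids)
        )

    @property
    def n_drugs(self) -> int:
        return len(self.approved_compound_ids)


class IndicationCatalog:
    """Mapping indication -> set of approved compound ids."""

    def __init__(self, indications: Mapping[str, Indication] | Iterable[Indication]):
        if isinstance(indications, Mapping):
            self.indications = dict(indications)
        else:
            self.indications = {ind.indication_id: ind for ind in indications}

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple], names: Mapping[str, str] | None = None):
        """Build from (indication_id, compound_id) pairs."""
        members: dict = {}
        for ind_id, comp_id in pairs:
            members.setdefault(ind_id, set()).add(comp_id)
        names = names or {}
        return cls(
            {
                ind_id: Indication(ind_id, names.get(ind_id, ind_id), frozenset(comps))
                for ind_id, comps in members.items()
            }
        )

    def with_min_drugs(self, min_drugs: int = 2) -> "IndicationCatalog":
        """Restrict to indications with at least ``min_drugs`` approved drugs."""
        return IndicationCatalog(
            {k: v for k, v in self.indications.items() if v.n_drugs >= min_drugs}
        )

    def restrict_to(self, compound_ids: Iterable[str]) -> "IndicationCatalog":
        keep = set(compound_ids)
        return IndicationCatalog(
            {
                k: Indication(v.indication_id, v.name, v.approved_compound_ids & keep)
                for k, v in self.indications.items()
            }
        )

    def validate_against(self, known_compound_ids: Iterable[str]) -> None:
        known = set(known_compound_ids)
        for ind in self.indications.values():
            missing = ind.approved_compound_ids - known
            if missing:
                raise KeyError(
                    f"indication {ind.indication_id} references unknown compounds: "
                    f"{sorted(missing)[:5]}"
                )

    def all_compound_ids(self) -> set:
        out: set = set()
        for ind in self.indications.values():
            out |= ind.approved_compound_ids
        return out

    def __len__(self):
        return len(self.indications)

    def __iter__(self):
        return iter(self.indications.values())

    def __getitem__(self, key):
        return self.indications[key]
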