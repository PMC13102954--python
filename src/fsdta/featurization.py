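"""Input featurization: molecular graphs, protein encodings, p-scale affinities.

Drugs are represented as heavy-atom graphs with a fixed-width binary/ordinal
node-feature vector (atom symbol, heavy-neighbor count, attached-H count,
implicit valence, aromaticity).  Proteins are integer-encoded amino-acid
sequences padded to a fixed length.  Raw dissociation/inhibition constants
are mapped to the p-scale, ``p = -log10(concentration in M)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ATOM_VOCABULARY",
    "AffinityRecord",
    "DrugGraph",
    "FeaturizationConfig",
    "FeaturizationError",
    "Measurement",
    "ProteinEncoding",
    "SchemaError",
    "TableSchema",
    "encode_protein",
    "load_affinity_table",
    "smiles_to_graph",
    "transform_affinity",
]

#: Fixed atom-symbol vocabulary; any other element maps to the final "other" slot.
ATOM_VOCABULARY: tuple[str, ...] = (
    "C", "N", "O", "S", "F", "Cl", "Br", "I", "P", "B", "Si", "other",
)

#: One-hot cardinality for neighbor count / H count / implicit valence
#: (values 0..10, clipped at the top bin).
_ORDINAL_BINS = 11

#: 0 is the pad token; A..Z map to 1..26 (non-standard letters share the
#: slot of their alphabet position, so the encoding is total over A-Z).
PROTEIN_VOCAB_SIZE = 27
_UNKNOWN_AA = 24  # "X", the conventional unknown residue


class Measurement(str, Enum):
    """Provenance of an affinity value."""

    KD = "Kd"
    KI = "Ki"
    IC50 = "IC50"
    PRETRANSFORMED = "pretransformed"


class Unit(str, Enum):
    NM = "nM"
    UM = "uM"
    M = "M"


_UNIT_TO_MOLAR = {Unit.NM: 1e-9, Unit.UM: 1e-6, Unit.M: 1.0}


class FeaturizationError(ValueError):
    """Raised when a SMILES string or sequence cannot be featurized."""


class SchemaError(ValueError):
    """Raised when an affinity table is missing a required column."""


@dataclass(frozen=True)
class FeaturizationConfig:
    """Controls the node-feature layout and protein encoding.

    ``n_feat`` is identical for every graph produced under one config:
    ``len(ATOM_VOCABULARY) + 3 * 11 + 1``.
    """

    max_len: int = 1000
    input_unit: Unit = Unit.NM

    @property
    def n_feat(self) -> int:
        return len(ATOM_VOCABULARY) + 3 * _ORDINAL_BINS + 1


@dataclass(frozen=True)
class DrugGraph:
    """An attributed molecular graph (heavy atoms only, implicit hydrogens)."""

    node_features: np.ndarray  # [n_atoms, n_feat]
    edges: tuple[tuple[int, int], ...]  # undirected, i < j
    smiles: str = ""

    @property
    def n_atoms(self) -> int:
        return self.node_features.shape[0]

    def directed_edges(self) -> np.ndarray:
        """Both directions of every undirected edge, shape [2*|E|, 2]."""
        if not self.edges:
            return np.zeros((0, 2), dtype=np.int64)
        e = np.asarray(self.edges, dtype=np.int64)
        return np.concatenate([e, e[:, ::-1]], axis=0)

    def validate(self) -> None:
        n = self.n_atoms
        for i, j in self.edges:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"edge ({i},{j}) out of range for {n} atoms")


@dataclass(frozen=True)
class ProteinEncoding:
    """Integer-token encoding of an amino-acid sequence, right-padded with 0."""

    tokens: np.ndarray  # [max_len] int64
    true_length: int
    target_id: str = ""


@dataclass(frozen=True)
class AffinityRecord:
    """One (drug, protein, affinity) observation on the p-scale."""

    drug: DrugGraph
    protein: ProteinEncoding
    affinity: float
    measurement: Measurement = Measurement.PRETRANSFORMED


def _one_hot(index: int, size: int) -> np.ndarray:
    v = np.zeros(size, dtype=np.float64)
    v[min(index, size - 1)] = 1.0
    return v


def atom_features(atom) -> np.ndarray:
    """Five concatenated blocks: symbol, degree, H count, valence, aromatic."""
    symbol = atom.GetSymbol()
    try:
        sym_idx = ATOM_VOCABULARY.index(symbol)
    except ValueError:
        sym_idx = len(ATOM_VOCABULARY) - 1
    return np.concatenate(
        [
            _one_hot(sym_idx, len(ATOM_VOCABULARY)),
            _one_hot(atom.GetDegree(), _ORDINAL_BINS),
            _one_hot(atom.GetTotalNumHs(), _ORDINAL_BINS),
            _one_hot(atom.GetImplicitValence(), _ORDINAL_BINS),
            np.array([1.0 if atom.GetIsAromatic() else 0.0]),
        ]
    )


def smiles_to_graph(smiles: str, config: FeaturizationConfig | None = None) -> DrugGraph:
    """Parse a SMILES string into an attributed heavy-atom graph.

    Raises
    ------
    FeaturizationError
        If the SMILES string is empty or cannot be parsed.
    """
    from rdkit import Chem

    config = config or FeaturizationConfig()
    if not smiles:
        raise FeaturizationError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FeaturizationError(f"unparsable SMILES: {smiles!r}")
    feats = np.stack([atom_features(a) for a in mol.GetAtoms()])
    edges = tuple(
        (min(b.GetBeginAtomIdx(), b.GetEndAtomIdx()), max(b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
        for b in mol.GetBonds()
    )
    assert feats.shape[1] == config.n_feat
    return DrugGraph(node_features=feats, edges=edges, smiles=smiles)


def encode_protein(sequence: str, max_len: int = 1000, target_id: str = "") -> ProteinEncoding:
    """Map a sequence to integer tokens: A..Z -> 1..26, 0 reserved for padding.

    Sequences longer than ``max_len`` are truncated from the right.
    Letters outside A-Z raise; lowercase is accepted and upper-cased.
    """
    if not sequence:
        raise FeaturizationError("empty protein sequence")
    if max_len <= 0:
        raise ValueError("max_len must be positive")
    seq = sequence.upper()[:max_len]
    tokens = np.zeros(max_len, dtype=np.int64)
    for pos, ch in enumerate(seq):
        o = ord(ch) - ord("A")
        if not 0 <= o < 26:
            raise FeaturizationError(f"non-letter residue {ch!r} in sequence")
        tokens[pos] = o + 1
    return ProteinEncoding(tokens=tokens, true_length=len(seq), target_id=target_id)


def transform_affinity(
    value: float,
    measurement: Measurement = Measurement.PRETRANSFORMED,
    input_unit: Unit = Unit.NM,
) -> float:
    """Convert a raw Kd/Ki/IC50 concentration to the p-scale.

    ``p = -log10(value in molar)``; pre-transformed scores (e.g. composite
    kinase-inhibition scores) pass through unchanged.
    """
    measurement = Measurement(measurement)
    if measurement is Measurement.PRETRANSFORMED:
        if not math.isfinite(value):
            raise ValueError("pre-transformed affinity must be finite")
        return float(value)
    if not (value > 0 and math.isfinite(value)):
        raise ValueError(f"raw concentration must be positive and finite, got {value}")
    molar = value * _UNIT_TO_MOLAR[Unit(input_unit)]
    return float(-math.log10(molar))


@dataclass(frozen=True)
class TableSchema:
    """Column map for a delimited affinity table."""

    smiles: str = "smiles"
    protein: str = "sequence"  # sequence text, or an id resolvable via a FASTA
    affinity: str = "affinity"
    measurement: str | None = "measurement"
    unit: Unit = Unit.NM
    default_measurement: Measurement = Measurement.PRETRANSFORMED


def _read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def load_affinity_table(
    path,
    schema: TableSchema | None = None,
    config: FeaturizationConfig | None = None,
    fasta: str | None = None,
    sep: str | None = None,
) -> list[AffinityRecord]:
    """Read a delimited (CSV/TSV) affinity table into featurized records.

    Rows that fail featurization are skipped with a logged count; duplicate
    (drug, protein) rows keep the first occurrence.
    """
    schema = schema or TableSchema()
    config = config or FeaturizationConfig()
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    required = [schema.smiles, schema.protein, schema.affinity]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"affinity table missing column(s): {missing}")

    sequences: Mapping[str, str] = _read_fasta(fasta) if fasta else {}
    graph_cache: dict[str, DrugGraph] = {}
    protein_cache: dict[str, ProteinEncoding] = {}
    seen: set[tuple[str, str]] = set()
    records: list[AffinityRecord] = []
    n_skipped = n_dup = 0

    for row in df.itertuples(index=False):
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        smiles = str(row[schema.smiles])
        prot_key = str(row[schema.protein])
        if (smiles, prot_key) in seen:
            n_dup += 1
            continue
        seen.add((smiles, prot_key))
        try:
            if smiles not in graph_cache:
                graph_cache[smiles] = smiles_to_graph(smiles, config)
            if prot_key not in protein_cache:
                seq = sequences.get(prot_key, prot_key)
                tid = prot_key if prot_key in sequences else f"T{len(protein_cache)}"
                protein_cache[prot_key] = encode_protein(seq, config.max_len, target_id=tid)
            meas = (
                Measurement(str(row[schema.measurement]))
                if schema.measurement and schema.measurement in df.columns
                else schema.default_measurement
            )
            affinity = transform_affinity(float(row[schema.affinity]), meas, schema.unit)
        except (FeaturizationError, ValueError) as exc:
            n_skipped += 1
            logger.warning("skipping row (%s)", exc)
            continue
        records.append(
            AffinityRecord(
                drug=graph_cache[smiles],
                protein=protein_cache[prot_key],
                affinity=affinity,
                measurement=meas,
            )
        )
    if n_skipped:
        logger.info("skipped %d unfeaturizable rows", n_skipped)
    if n_dup:
        logger.info("dropped %d duplicate (drug, protein) rows", n_dup)
    return records


def write_affinity_table(records: Sequence[AffinityRecord], path, sequences: Mapping[str, str], sep: str = ",") -> None:
    """Write records back to the delimited format ``load_affinity_table`` reads.

    ``sequences`` maps target_id to the raw sequence string (graphs carry
    their source SMILES; proteins only carry tokens).
    """
    # stored affinities are already on the p-scale, so they are written as
    # pre-transformed regardless of original provenance (keeps the round trip exact)
    rows = [
        {
            "smiles": r.drug.smiles,
            "sequence": sequences[r.protein.target_id],
            "affinity": r.affinity,
            "measurement": Measurement.PRETRANSFORMED.value,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
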