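"""Molecule parsing, featurization and table I/O.

This module is the chemistry boundary of the package: everything that
touches SMILES, molecular graphs or fingerprints lives here, so the
neural-network modules only ever see NumPy arrays.

Molecules are handled as heavy-atom graphs (hydrogens implicit), which is
the standard convention for graph-based property prediction and matches
the atom counts implied by the SMILES in the packaged fixture.
"""

from __future__ import annotations

import importlib.resources
import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.error")  # parse failures are reported as exceptions

#: Version tag of the atom feature schema; stored in model sidecars so that
#: embeddings are only ever reloaded against the featurization that produced them.
FEATURE_SCHEMA_VERSION = "1"

_ELEMENTS = ("C", "N", "O", "S")  # + "other" slot
_MAX_DEGREE = 4    # degrees 0..3 one-hot, 4+ pooled
_MAX_H = 3         # H counts 0..2 one-hot, 3+ pooled

#: Length of the per-atom feature vector:
#: element one-hot (5) + degree one-hot (5) + aromatic (1) + in-ring (1) + H-count one-hot (4)
ATOM_FEATURE_DIM = len(_ELEMENTS) + 1 + (_MAX_DEGREE + 1) + 2 + (_MAX_H + 1)


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


class TableValidationError(ValueError):
    """Raised when a molecule table contains invalid rows.

    Carries a list of ``(line_number, message)`` pairs in :attr:`row_errors`.
    """

    def __init__(self, row_errors: list[tuple[int, str]]):
        self.row_errors = row_errors
        detail = "; ".join(f"line {ln}: {msg}" for ln, msg in row_errors)
        super().__init__(f"{len(row_errors)} invalid row(s): {detail}")


@dataclass(frozen=True)
class MoleculeRecord:
    """A named chemical structure.

    The SMILES string is kept both exactly as supplied (``smiles_verbatim``)
    and in RDKit canonical form (``smiles_canonical``); two records describe
    the same molecule iff their canonical forms are equal.
    """

    name: str
    smiles_verbatim: str
    smiles_canonical: str

    def to_mol(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.smiles_canonical)


@dataclass(frozen=True)
class MolecularGraph:
    """Heavy-atom graph of a molecule: per-atom features and bond edges."""

    node_features: np.ndarray  # (n_atoms, ATOM_FEATURE_DIM)
    edges: tuple[tuple[int, int], ...]  # one unordered pair per bond
    n_atoms: int


@dataclass(frozen=True)
class FingerprintVector:
    """Folded circular (Morgan / ECFP-style) fingerprint as a 0/1 vector."""

    bits: np.ndarray
    radius: int = 2


@dataclass(frozen=True)
class ODTRecord:
    """A molecule with its odor detection threshold.

    ``odt_ppm`` is the lowest reported detection threshold in parts per
    million and must be strictly positive.
    """

    molecule: MoleculeRecord
    odt_ppm: float

    def __post_init__(self):
        if not self.odt_ppm > 0:
            raise ValueError(f"odt_ppm must be > 0, got {self.odt_ppm}")


@dataclass(frozen=True)
class DescriptorVocabulary:
    """Ordered list of distinct semantic odor descriptors ("fruity", ...)."""

    labels: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("descriptor vocabulary contains duplicate labels")

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def encode(self, labels: set[str] | list[str]) -> np.ndarray:
        """Multi-hot encoding of a descriptor set against this vocabulary."""
        unknown = set(labels) - set(self.labels)
        if unknown:
            raise ValueError(f"labels not in vocabulary: {sorted(unknown)}")
        vec = np.zeros(len(self.labels), dtype=np.int8)
        for lab in labels:
            vec[self.index(lab)] = 1
        return vec


@dataclass(frozen=True)
class DescriptorRecord:
    """A molecule with its multi-hot descriptor labels."""

    molecule: MoleculeRecord
    labels: np.ndarray  # multi-hot, aligned to a DescriptorVocabulary


def parse_smiles(smiles: str, name: str = "") -> MoleculeRecord:
    """Parse a SMILES string into a validated :class:`MoleculeRecord`.

    Raises :class:`SmilesParseError` with RDKit's diagnosis (offending
    token/position where available) if the string is not valid SMILES.
    """
    if not smiles or not smiles.strip():
        raise SmilesParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        problems = []
        try:
            raw = Chem.MolFromSmiles(smiles, sanitize=False)
            if raw is not None:
                problems = [p.Message() for p in Chem.DetectChemistryProblems(raw)]
        except Exception:  # pragma: no cover - diagnosis is best effort
            pass
        detail = "; ".join(problems) if problems else "syntax error (e.g. unclosed ring or branch)"
        raise SmilesParseError(f"invalid SMILES {smiles!r}: {detail}")
    canonical = Chem.MolToSmiles(mol)
    return MoleculeRecord(name=name, smiles_verbatim=smiles, smiles_canonical=canonical)


def _atom_features(atom: Chem.Atom) -> np.ndarray:
    vec = np.zeros(ATOM_FEATURE_DIM, dtype=np.float64)
    sym = atom.GetSymbol()
    vec[_ELEMENTS.index(sym) if sym in _ELEMENTS else len(_ELEMENTS)] = 1.0
    off = len(_ELEMENTS) + 1
    vec[off + min(atom.GetDegree(), _MAX_DEGREE)] = 1.0
    off += _MAX_DEGREE + 1
    vec[off] = float(atom.GetIsAromatic())
    vec[off + 1] = float(atom.IsInRing())
    off += 2
    vec[off + min(atom.GetTotalNumHs(), _MAX_H)] = 1.0
    return vec


def to_molecular_graph(mol: MoleculeRecord | Chem.Mol) -> MolecularGraph:
    """Convert a molecule to its heavy-atom graph representation.

    Node count equals the heavy-atom count and edge count the bond count;
    hydrogens appear only through the attached-H feature.
    """
    rdmol = mol.to_mol() if isinstance(mol, MoleculeRecord) else mol
    feats = np.stack([_atom_features(a) for a in rdmol.GetAtoms()])
    edges = tuple(
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in rdmol.GetBonds()
    )
    return MolecularGraph(node_features=feats, edges=edges, n_atoms=rdmol.GetNumAtoms())


def morgan_fingerprint(
    mol: MoleculeRecord | Chem.Mol, radius: int = 2, n_bits: int = 1024
) -> FingerprintVector:
    """Folded Morgan fingerprint (ECFP4 at the default radius 2 = diameter 4).

    Deterministic and identical for every SMILES spelling of a molecule.
    """
    if n_bits <= 0:
        raise ValueError(f"n_bits must be positive, got {n_bits}")
    if radius < 0:
        raise ValueError(f"radius must be >= 0, got {radius}")
    rdmol = mol.to_mol() if isinstance(mol, MoleculeRecord) else mol
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(rdmol)
    bits = np.zeros(n_bits, dtype=np.int8)
    bits[list(fp.GetOnBits())] = 1
    return FingerprintVector(bits=bits, radius=radius)


def fingerprint_matrix(records: list[MoleculeRecord], radius: int = 2, n_bits: int = 1024) -> np.ndarray:
    """Stack Morgan fingerprints of many molecules into an (n, n_bits) matrix."""
    return np.stack([morgan_fingerprint(r, radius, n_bits).bits.astype(np.float64) for r in records])


# ---------------------------------------------------------------------------
# CSV table I/O
#
# Dialect: UTF-8, comma-separated; descriptor lists are "|"-delimited inside
# one cell so multi-word descriptors stay unambiguous.
# ---------------------------------------------------------------------------

DESCRIPTOR_COLUMNS = ("name", "smiles", "labels")
ODT_COLUMNS = ("name", "smiles", "odt_ppm")
LABEL_DELIMITER = "|"


def read_molecule_table(path, schema: str):
    """Read a molecule CSV table.

    ``schema="descriptor"`` expects columns (name, smiles, labels) and returns
    ``(records, vocabulary)`` where ``records`` are :class:`DescriptorRecord`
    aligned to the returned :class:`DescriptorVocabulary` (labels sorted).

    ``schema="odt"`` expects columns (name, smiles, odt_ppm) and returns a list
    of :class:`ODTRecord`; duplicate molecules (same canonical SMILES) are
    collapsed to the LOWEST threshold, the safest value when several
    measurements are reported.

    Invalid rows are collected and raised together as
    :class:`TableValidationError` with 1-based data line numbers.
    """
    if schema not in ("descriptor", "odt"):
        raise ValueError(f"schema must be 'descriptor' or 'odt', got {schema!r}")
    expected = DESCRIPTOR_COLUMNS if schema == "descriptor" else ODT_COLUMNS
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(expected) - set(df.columns)
    if missing:
        raise TableValidationError([(0, f"missing columns {sorted(missing)}")])
    if df.empty:
        warnings.warn(f"molecule table {path} is empty", stacklevel=2)
        return ([], DescriptorVocabulary(())) if schema == "descriptor" else []

    errors: list[tuple[int, str]] = []
    parsed: list[tuple[int, MoleculeRecord, str]] = []
    for i, row in df.iterrows():
        line = i + 1  # 1-based data row
        try:
            rec = parse_smiles(row["smiles"], name=row["name"])
        except SmilesParseError as exc:
            errors.append((line, str(exc)))
            continue
        parsed.append((line, rec, row))

    if schema == "odt":
        lowest: dict[str, ODTRecord] = {}
        for line, rec, row in parsed:
            try:
                odt = float(row["odt_ppm"])
            except ValueError:
                errors.append((line, f"odt_ppm {row['odt_ppm']!r} is not a number"))
                continue
            if not odt > 0:
                errors.append((line, f"odt_ppm must be > 0, got {odt}"))
                continue
            key = rec.smiles_canonical
            if key not in lowest or odt < lowest[key].odt_ppm:
                lowest[key] = ODTRecord(molecule=rec, odt_ppm=odt)
        if errors:
            raise TableValidationError(errors)
        return list(lowest.values())

    all_labels: set[str] = set()
    rows_labels: list[tuple[MoleculeRecord, set[str]]] = []
    for line, rec, row in parsed:
        labels = {s.strip() for s in row["labels"].split(LABEL_DELIMITER) if s.strip()}
        if not labels:
            errors.append((line, "molecule has no descriptor labels"))
            continue
        all_labels |= labels
        rows_labels.append((rec, labels))
    if errors:
        raise TableValidationError(errors)
    vocab = DescriptorVocabulary(tuple(sorted(all_labels)))
    records = [DescriptorRecord(molecule=rec, labels=vocab.encode(labs)) for rec, labs in rows_labels]
    return records, vocab


def write_molecule_table(path, records, vocabulary: DescriptorVocabulary | None = None) -> None:
    """Write descriptor or ODT records back to CSV (round-trips with the reader)."""
    rows = []
    for rec in records:
        if isinstance(rec, ODTRecord):
            rows.append(
                {"name": rec.molecule.name, "smiles": rec.molecule.smiles_verbatim, "odt_ppm": rec.odt_ppm}
            )
        elif isinstance(rec, DescriptorRecord):
            if vocabulary is None:
                raise ValueError("writing descriptor records requires the vocabulary")
            labs = [vocabulary.labels[j] for j in np.flatnonzero(rec.labels)]
            rows.append(
                {
                    "name": rec.molecule.name,
                    "smiles": rec.molecule.smiles_verbatim,
                    "labels": LABEL_DELIMITER.join(labs),
                }
            )
        else:
            raise TypeError(f"unsupported record type {type(rec).__name__}")
    pd.DataFrame(rows).to_csv(path, index=False)


def read_smi(path) -> list[MoleculeRecord]:
    """Read a .smi file: one SMILES per line, optional whitespace-separated name."""
    records = []
    errors = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            name = parts[1] if len(parts) > 1 else ""
            try:
                records.append(parse_smiles(smiles, name=name))
            except SmilesParseError as exc:
                errors.append((i, str(exc)))
    if errors:
        raise TableValidationError(errors)
    return records


# ---------------------------------------------------------------------------
# Packaged fixture: 22 perfume-relevant molecules with measured detection
# thresholds and the two published model predictions for each.
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FixtureRow:
    molecule: MoleculeRecord
    odt_ppm: float
    benchmark_pred_ppm: float
    transfer_pred_ppm: float
    smiles_corrected: str = ""


def _data_path(filename: str):
    return importlib.resources.files("odortl.data") / filename


def load_table11_fixture() -> list[FixtureRow]:
    """Load the packaged 22-molecule test-set fixture.

    Each row carries the molecule, its measured detection threshold (ppm) and
    the published predictions of the fingerprint benchmark model and of the
    transfer-learning model, transcribed from the source table. SMILES are
    kept as printed even where chemically dubious (several rows draw aromatic
    rings as saturated carbocycles); the two rows printed with a stray space
    inside the SMILES have the space removed. The ``smiles_corrected`` column
    is left empty by default for downstream curation; all published statistics
    use only the numeric columns.
    """
    df = pd.read_csv(_data_path("table11.csv"), keep_default_na=False)
    rows = []
    for _, r in df.iterrows():
        rec = parse_smiles(r["smiles"], name=r["name"])
        rows.append(
            FixtureRow(
                molecule=rec,
                odt_ppm=float(r["odt_ppm"]),
                benchmark_pred_ppm=float(r["benchmark_pred_ppm"]),
                transfer_pred_ppm=float(r["transfer_pred_ppm"]),
                smiles_corrected=str(r["smiles_corrected"]),
            )
        )
    return rows


def load_companion_crossval_mse() -> dict[str, float]:
    """Published test MSEs of the companion cross-validation half (Model A).

    Only one half's per-molecule predictions are published; these three MSEs
    (benchmark, transfer, dummy) complete the two-half averages.
    """
    with open(_data_path("crossval_companion.json"), encoding="utf-8") as fh:
        return json.load(fh)["model_a_mse"]
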