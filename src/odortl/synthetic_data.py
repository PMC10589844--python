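"""Synthetic descriptor and threshold databases with known ground truth.

The real databases behind this problem (a few hundred molecules with
semantic odor descriptors; ~45 perfume compounds with measured detection
thresholds) are not redistributable, and — more importantly for testing —
their structure→label and structure→threshold relationships are unknown.
This module generates stand-in databases from a small fragment grammar of
odorant-like molecules (alkyl chains, esters, aldehydes, ketones, alcohols,
ethers, rings) in which both relationships are constructed and therefore
exactly known:

* descriptor labels are substructure presence (SMARTS match) XOR Bernoulli
  flip noise, so with zero noise a descriptor is a deterministic, learnable
  function of the molecular graph;
* log-thresholds are a linear function of substructure counts plus Gaussian
  noise, ``ln(ODT) = w·c + N(0, σ²)``, so thresholds are positive by
  construction and share their causal substructures with the descriptors —
  the situation in which transferring descriptor embeddings should help.

Default database sizes (273 descriptor molecules, 45 threshold molecules)
mirror the real study so runtimes and variance are representative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .chemio import (
    DescriptorRecord,
    DescriptorVocabulary,
    MoleculeRecord,
    ODTRecord,
    parse_smiles,
)
from .descriptor_gcn import DescriptorDataset

#: Descriptor → SMARTS defining which substructure carries each label.
DEFAULT_LABEL_RULES: dict[str, str] = {
    "fruity": "[CX3](=O)[OX2][#6]",      # ester
    "pungent": "[CX3H1]=O",              # aldehyde
    "minty": "[#6][CX3](=O)[#6]",        # ketone
    "floral": "[OX2H]",                  # hydroxyl
    "woody": "[R]",                      # any ring atom
    "ethereal": "[CX4][OX2][CX4]",       # dialkyl ether
    "aliphatic": "[CX4]",                # sp3 carbon (near-universal base note)
}

#: Per-substructure-count contribution to ln(ODT/ppm). Shared support with
#: the label rules gives the causal descriptor↔threshold coupling the
#: transfer hypothesis assumes.
DEFAULT_ODT_WEIGHTS: dict[str, float] = {
    "fruity": -1.2,
    "pungent": -0.8,
    "minty": -0.5,
    "floral": -0.6,
    "woody": 0.15,
    "ethereal": -0.3,
    "aliphatic": -0.15,
}


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study conditions."""

    n_molecules: int = 273          # descriptor database size
    n_odt_molecules: int = 45       # threshold database size
    label_rules: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_LABEL_RULES))
    label_noise: float = 0.05       # Bernoulli flip probability ε
    odt_weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ODT_WEIGHTS))
    odt_noise_sd: float = 0.1       # σ of ln-scale Gaussian noise
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError(
                f"label_noise must be in [0, 0.5) — ε = 0.5 destroys all signal; "
                f"got {self.label_noise}"
            )
        if self.odt_noise_sd < 0:
            raise ValueError(f"odt_noise_sd must be >= 0, got {self.odt_noise_sd}")
        if not self.label_rules:
            raise ValueError("label_rules must not be empty")

    @property
    def vocabulary(self) -> DescriptorVocabulary:
        return DescriptorVocabulary(tuple(self.label_rules))


# ---------------------------------------------------------------------------
# Fragment grammar
# ---------------------------------------------------------------------------


def _chain(rng: np.random.Generator, lo: int = 1, hi: int = 8,
           branch_p: float = 0.4, alkene_p: float = 0.0) -> str:
    """An alkyl chain with up to two methyl/ethyl branches, optionally one C=C."""
    n = int(rng.integers(lo, hi + 1))
    atoms = ["C"] * n
    if n >= 3:
        for _ in range(2):
            if rng.random() < branch_p:
                pos = int(rng.integers(1, n - 1))
                if atoms[pos] == "C":
                    atoms[pos] = "C(C)" if rng.random() < 0.7 else "C(CC)"
    s = "".join(atoms)
    if n >= 3 and rng.random() < alkene_p:
        # turn the first plain C-C bond into C=C
        i = s.find("CC", 1)
        if i > 0:
            s = s[:i + 1] + "=" + s[i + 1:]
    return s


def _template_alkane(rng):
    return _chain(rng, 3, 9)


def _template_alcohol(rng):
    return _chain(rng, 2, 8, alkene_p=0.25) + "O"


def _template_aldehyde(rng):
    return _chain(rng, 2, 8, alkene_p=0.25) + "C=O"


def _template_ketone(rng):
    return _chain(rng, 1, 5) + "C(=O)" + _chain(rng, 1, 5)


def _template_ester(rng):
    # acyl + O + alkyl, e.g. CCC(=O)OCC (ethyl propanoate)
    return _chain(rng, 1, 5) + "C(=O)O" + _chain(rng, 1, 6)


def _template_ether(rng):
    return _chain(rng, 1, 5) + "O" + _chain(rng, 2, 6)


def _template_aromatic(rng):
    return _chain(rng, 1, 5) + "c1ccccc1"


def _template_aromatic_aldehyde(rng):
    return "O=Cc1ccc(" + _chain(rng, 1, 3) + ")cc1"


def _template_furan(rng):
    return _chain(rng, 1, 4) + "c1ccco1"


def _template_cycloalkane(rng):
    return _chain(rng, 1, 4) + "C1CCCCC1"


def _template_aromatic_ester(rng):
    return _chain(rng, 1, 4) + "C(=O)OCc1ccccc1"


def _template_cyclic_alcohol(rng):
    return "OC1CCCCC1" + _chain(rng, 1, 4)


_TEMPLATES = (
    (_template_ester, 0.25),
    (_template_alcohol, 0.13),
    (_template_aldehyde, 0.11),
    (_template_ketone, 0.11),
    (_template_ether, 0.09),
    (_template_alkane, 0.07),
    (_template_aromatic, 0.07),
    (_template_furan, 0.05),
    (_template_cycloalkane, 0.04),
    (_template_aromatic_aldehyde, 0.03),
    (_template_aromatic_ester, 0.03),
    (_template_cyclic_alcohol, 0.02),
)


def generate_molecules(n: int, seed: int = 0) -> list[MoleculeRecord]:
    """Sample ``n`` distinct valid molecules from the fragment grammar.

    Deterministic for a given seed; distinctness is by canonical SMILES.
    Raises if the grammar cannot supply ``n`` distinct structures.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    templates = [t for t, _ in _TEMPLATES]
    weights = np.array([w for _, w in _TEMPLATES])
    weights = weights / weights.sum()
    seen: set[str] = set()
    records: list[MoleculeRecord] = []
    attempts = 0
    max_attempts = 200 * n
    while len(records) < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"fragment grammar exhausted: produced {len(records)} distinct "
                f"molecules of {n} requested after {attempts} draws"
            )
        tmpl = templates[int(rng.choice(len(templates), p=weights))]
        smiles = tmpl(rng)
        rec = parse_smiles(smiles, name=f"synth-{len(records):04d}")
        if rec.smiles_canonical in seen:
            continue
        seen.add(rec.smiles_canonical)
        records.append(rec)
    return records


def substructure_counts(mols: list[MoleculeRecord], rules: dict[str, str]) -> np.ndarray:
    """Matrix of substructure match counts, shape (n_molecules, n_rules)."""
    patterns = {name: Chem.MolFromSmarts(sm) for name, sm in rules.items()}
    for name, pat in patterns.items():
        if pat is None:
            raise ValueError(f"invalid SMARTS for rule {name!r}: {rules[name]!r}")
    counts = np.zeros((len(mols), len(rules)), dtype=np.float64)
    for i, rec in enumerate(mols):
        rdmol = rec.to_mol()
        for j, pat in enumerate(patterns.values()):
            counts[i, j] = len(rdmol.GetSubstructMatches(pat))
    return counts


def assign_descriptors(mols: list[MoleculeRecord], spec: SyntheticSpec) -> DescriptorDataset:
    """Attach multi-hot descriptor labels to molecules.

    A label is substructure presence XOR a Bernoulli(ε) flip. If the flips
    leave a molecule with no positive label, its noise-free labels are
    restored (every grammar molecule matches at least the near-universal
    base rule), preserving the at-least-one-label invariant of a training
    database.
    """
    vocab = spec.vocabulary
    rng = np.random.default_rng(spec.seed + 10_007)
    presence = (substructure_counts(mols, spec.label_rules) > 0).astype(np.int8)
    flips = (rng.random(presence.shape) < spec.label_noise).astype(np.int8)
    labels = presence ^ flips
    empty = labels.sum(axis=1) == 0
    labels[empty] = presence[empty]
    records = [DescriptorRecord(molecule=m, labels=labels[i]) for i, m in enumerate(mols)]
    return DescriptorDataset(records=records, vocabulary=vocab)


def assign_odt(mols: list[MoleculeRecord], spec: SyntheticSpec) -> list[ODTRecord]:
    """Attach thresholds: ``ln(ODT/ppm) = w · counts + N(0, σ²)``.

    Positive by construction; with σ = 0 the threshold is an exact
    deterministic function of structure.
    """
    rng = np.random.default_rng(spec.seed + 20_011)
    rules = spec.label_rules
    w = np.array([spec.odt_weights.get(name, 0.0) for name in rules])
    counts = substructure_counts(mols, rules)
    log_odt = counts @ w + rng.normal(0.0, spec.odt_noise_sd, size=len(mols))
    return [ODTRecord(molecule=m, odt_ppm=float(np.exp(v))) for m, v in zip(mols, log_odt)]


def make_databases(spec: SyntheticSpec):
    """Generate the full synthetic study: a descriptor database of
    ``spec.n_molecules`` molecules and a threshold database of
    ``spec.n_odt_molecules`` molecules drawn from the same grammar.

    Returns ``(descriptor_dataset, odt_records)``.
    """
    desc_mols = generate_molecules(spec.n_molecules, seed=spec.seed)
    odt_mols = generate_molecules(spec.n_odt_molecules, seed=spec.seed + 1)
    return assign_descriptors(desc_mols, spec), assign_odt(odt_mols, spec)
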