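"""Numerical peptide representations.

Five fixed-convention encodings of a peptide over the canonical
20-letter alphabet (feature order is always alphabetical,
``A C D E F G H I K L M N P Q R S T V W Y``):

* integer tokens — residue i mapped to its 1-based alphabet index,
  right-padded with 0 to ``max_length``;
* one-hot — per-residue 20-dim indicator blocks, concatenated, zero
  blocks as padding (length ``20 · max_length``);
* Morgan fingerprint — each residue represented by the circular
  fingerprint (radius 3, 128 bits by default) of its monomer structure,
  blocks concatenated and zero-padded;
* composition vector — normalised amino-acid fractions, a
  20-dimensional, order-invariant summary;
* dipeptide counts — the 400 ordered adjacent residue pairs, read N→C.

Encoder functions treat the input string position-by-position as given
(position 1 = first character).  Dataset assembly (`encode_records`)
feeds positional encoders the sequence in synthesis order (C→N), so
feature block i always describes synthesis step i and lines up with
stepwise labels; composition and dipeptide features are direction-
independent or defined N→C and use the stored sequence directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .alphabet import AA_INDEX, AA_ORDER, require_canonical
from .curation import PeptideRecord

__all__ = [
    "FREE_MONOMER_SMILES",
    "PROTECTED_MONOMER_SMILES",
    "REPRESENTATIONS",
    "EncoderConfig",
    "EncodedDataset",
    "token_encode",
    "token_decode",
    "onehot_encode",
    "fingerprint_encode",
    "composition_vector",
    "dipeptide_counts",
    "dipeptide_feature_names",
    "encode_records",
]

#: Free (unprotected) amino acids as SMILES, the default monomer table.
FREE_MONOMER_SMILES: dict[str, str] = {
    "A": "CC(N)C(=O)O",
    "C": "NC(CS)C(=O)O",
    "D": "NC(CC(=O)O)C(=O)O",
    "E": "NC(CCC(=O)O)C(=O)O",
    "F": "NC(Cc1ccccc1)C(=O)O",
    "G": "NCC(=O)O",
    "H": "NC(Cc1c[nH]cn1)C(=O)O",
    "I": "CCC(C)C(N)C(=O)O",
    "K": "NCCCCC(N)C(=O)O",
    "L": "CC(C)CC(N)C(=O)O",
    "M": "CSCCC(N)C(=O)O",
    "N": "NC(CC(N)=O)C(=O)O",
    "P": "OC(=O)C1CCCN1",
    "Q": "NC(CCC(N)=O)C(=O)O",
    "R": "NC(CCCNC(=N)N)C(=O)O",
    "S": "NC(CO)C(=O)O",
    "T": "CC(O)C(N)C(=O)O",
    "V": "CC(C)C(N)C(=O)O",
    "W": "NC(Cc1c[nH]c2ccccc12)C(=O)O",
    "Y": "NC(Cc1ccc(O)cc1)C(=O)O",
}

#: Optional table of the Fmoc/side-chain-protected building blocks as
#: actually handled on the synthesizer (t-Bu, Trt, Boc, Pbf protection).
PROTECTED_MONOMER_SMILES: dict[str, str] = {
    "A": "CC(NC(=O)OCC1c2ccccc2-c2ccccc21)C(=O)O",
    "C": "O=C(O)C(CSC(c1ccccc1)(c1ccccc1)c1ccccc1)NC(=O)OCC1c2ccccc2-c2ccccc21",
    "D": "CC(C)(C)OC(=O)CC(NC(=O)OCC1c2ccccc2-c2ccccc21)C(=O)O",
    "E": "CC(C)(C)OC(=O)CCC(NC(=O)OCC1c2ccccc2-c2ccccc21)C(=O)O",
    "F": "O=C(O)C(Cc1ccccc1)NC(=O)OCC1c2ccccc2-c2ccccc21",
    "G": "O=C(O)CNC(=O)OCC1c2ccccc2-c2ccccc21",
    "H": "O=C(O)C(Cc1cn(C(c2ccccc2)(c2ccccc2)c2ccccc2)cn1)NC(=O)OCC1c2ccccc2-c2ccccc21",
    "I": "CCC(C)C(NC(=O)OCC1c2ccccc2-c2ccccc21)C(=O)O",
    "K": "CC(C)(C)OC(=O)NCCCCC(NC(=O)OCC1c2ccccc2-c2ccccc21)C(=O)O",
    "L": "CC(C)CC(NC(=O)OCC1c2ccccc2-c2ccccc21)C(=O)O",
    "M": "CSCCC(NC(=O)OCC1c2ccccc2-c2ccccc21)C(=O)O",
    "N": "O=C(O)C(CC(=O)NC(c1ccccc1)(c1ccccc1)c1ccccc1)NC(=O)OCC1c2ccccc2-c2ccccc21",
    "P": "O=C(O)C1CCCN1C(=O)OCC1c2ccccc2-c2ccccc21",
    "Q": "O=C(O)C(CCC(=O)NC(c1ccccc1)(c1ccccc1)c1ccccc1)NC(=O)OCC1c2ccccc2-c2ccccc21",
    "R": "Cc1c(C)c2c(c(C)c1S(=O)(=O)NC(=N)NCCCC(NC(=O)OCC1c3ccccc3-c3ccccc31)C(=O)O)CC(C)(C)O2",
    "S": "CC(C)(C)OCC(NC(=O)OCC1c2ccccc2-c2ccccc21)C(=O)O",
    "T": "CC(OC(C)(C)C)C(NC(=O)OCC1c2ccccc2-c2ccccc21)C(=O)O",
    "V": "CC(C)C(NC(=O)OCC1c2ccccc2-c2ccccc21)C(=O)O",
    "W": "CC(C)(C)OC(=O)n1cc(CC(NC(=O)OCC2c3ccccc3-c3ccccc32)C(=O)O)c2ccccc21",
    "Y": "CC(C)(C)Oc1ccc(CC(NC(=O)OCC2c3ccccc3-c3ccccc32)C(=O)O)cc1",
}

REPRESENTATIONS = ("token", "onehot", "fingerprint", "composition", "dipeptide")

#: Representations whose feature blocks are positional (block i = step i).
POSITIONAL_REPRESENTATIONS = ("token", "onehot", "fingerprint")


@dataclass
class EncoderConfig:
    aa_order: str = AA_ORDER
    max_length: int = 20
    fingerprint_radius: int = 3
    fingerprint_bits: int = 128
    monomer_structures: dict[str, str] = field(default_factory=lambda: dict(FREE_MONOMER_SMILES))

    def __post_init__(self) -> None:
        if len(self.aa_order) != 20 or len(set(self.aa_order)) != 20:
            raise ValueError("aa_order must contain exactly the 20 canonical letters once each")
        if set(self.aa_order) != set(AA_ORDER):
            raise ValueError("aa_order must be a permutation of the canonical alphabet")
        if self.max_length < 1:
            raise ValueError("max_length must be positive")
        bits = self.fingerprint_bits
        if bits < 1 or (bits & (bits - 1)) != 0:
            raise ValueError("fingerprint_bits must be a power of two")

    def index(self, residue: str) -> int:
        return self.aa_order.index(residue)

    def to_dict(self) -> dict:
        return {
            "aa_order": self.aa_order,
            "max_length": self.max_length,
            "fingerprint_radius": self.fingerprint_radius,
            "fingerprint_bits": self.fingerprint_bits,
            "monomer_structures": dict(self.monomer_structures),
        }


@dataclass
class EncodedDataset:
    """A feature matrix under one named representation, with its labels
    and the exact encoder config that produced it."""

    X: np.ndarray
    y: np.ndarray
    ids: list[str]
    representation: str
    config: EncoderConfig
    feature_names: list[str] = field(default_factory=list)


def _check(sequence: str, config: EncoderConfig, positional: bool) -> str:
    require_canonical(sequence)
    if positional and len(sequence) > config.max_length:
        raise ValueError(f"sequence length {len(sequence)} exceeds max_length {config.max_length}")
    return sequence


def token_encode(sequence: str, config: EncoderConfig | None = None) -> np.ndarray:
    """Integer tokens, residue → 1-based alphabet index, 0-padded."""
    config = config or EncoderConfig()
    _check(sequence, config, positional=True)
    out = np.zeros(config.max_length, dtype=np.int64)
    for i, ch in enumerate(sequence):
        out[i] = config.index(ch) + 1
    return out


def token_decode(tokens: np.ndarray, config: EncoderConfig | None = None) -> str:
    config = config or EncoderConfig()
    out = []
    for v in tokens:
        if v == 0:
            break
        out.append(config.aa_order[int(v) - 1])
    return "".join(out)


def onehot_encode(sequence: str, config: EncoderConfig | None = None) -> np.ndarray:
    """Concatenated per-residue 20-dim indicator blocks, zero-padded."""
    config = config or EncoderConfig()
    _check(sequence, config, positional=True)
    out = np.zeros(20 * config.max_length, dtype=np.float64)
    for i, ch in enumerate(sequence):
        out[20 * i + config.index(ch)] = 1.0
    return out


@lru_cache(maxsize=None)
def _monomer_fingerprint(smiles: str, radius: int, bits: int) -> np.ndarray:
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable monomer structure: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=bits)
    fp = gen.GetFingerprint(mol)
    arr = np.zeros(bits, dtype=np.float64)
    arr[list(fp.GetOnBits())] = 1.0
    return arr


def fingerprint_encode(sequence: str, config: EncoderConfig | None = None) -> np.ndarray:
    """Concatenated per-residue Morgan fingerprints of the monomer
    structures, zero-padded to ``fingerprint_bits · max_length``."""
    config = config or EncoderConfig()
    _check(sequence, config, positional=True)
    bits = config.fingerprint_bits
    out = np.zeros(bits * config.max_length, dtype=np.float64)
    for i, ch in enumerate(sequence):
        smiles = config.monomer_structures.get(ch)
        if smiles is None:
            raise ValueError(f"no monomer structure configured for residue {ch!r}")
        out[bits * i : bits * (i + 1)] = _monomer_fingerprint(smiles, config.fingerprint_radius, bits)
    return out


def composition_vector(sequence: str, config: EncoderConfig | None = None) -> np.ndarray:
    """Normalised amino-acid fractions in ``aa_order`` (sum to 1)."""
    config = config or EncoderConfig()
    require_canonical(sequence)
    out = np.zeros(20, dtype=np.float64)
    for ch in sequence:
        out[config.index(ch)] += 1.0
    return out / len(sequence)


def dipeptide_feature_names(config: EncoderConfig | None = None) -> list[str]:
    config = config or EncoderConfig()
    return [a + b for a in config.aa_order for b in config.aa_order]


def dipeptide_counts(sequence: str, config: EncoderConfig | None = None) -> np.ndarray:
    """Counts of the 400 ordered adjacent residue pairs, read N→C."""
    config = config or EncoderConfig()
    require_canonical(sequence)
    if len(sequence) < 2:
        raise ValueError("dipeptide counts need at least two residues")
    out = np.zeros(400, dtype=np.float64)
    for a, b in zip(sequence, sequence[1:]):
        out[20 * config.index(a) + config.index(b)] += 1.0
    return out


_ENCODERS = {
    "token": token_encode,
    "onehot": onehot_encode,
    "fingerprint": fingerprint_encode,
    "composition": composition_vector,
    "dipeptide": dipeptide_counts,
}


def _feature_names(representation: str, config: EncoderConfig) -> list[str]:
    if representation == "composition":
        return list(config.aa_order)
    if representation == "dipeptide":
        return dipeptide_feature_names(config)
    if representation == "token":
        return [f"step{i + 1}" for i in range(config.max_length)]
    if representation == "onehot":
        return [f"step{i + 1}:{aa}" for i in range(config.max_length) for aa in config.aa_order]
    return [f"step{i + 1}:bit{b}" for i in range(config.max_length) for b in range(config.fingerprint_bits)]


def encode_records(
    records: list[PeptideRecord],
    representation: str,
    config: EncoderConfig | None = None,
    sequences: list[str] | None = None,
) -> EncodedDataset:
    """Encode curated records into a feature matrix plus labels.

    Positional representations (token, one-hot, fingerprint) encode the
    sequence in synthesis order so feature block i describes synthesis
    step i; composition and dipeptide features use the stored N→C
    sequence.  ``sequences`` overrides the encoded strings (used for
    prefix datasets) and must then already be in the intended direction.
    """
    if representation not in _ENCODERS:
        raise ValueError(f"unknown representation {representation!r}; pick from {REPRESENTATIONS}")
    config = config or EncoderConfig()
    encoder = _ENCODERS[representation]
    if sequences is None:
        if representation in POSITIONAL_REPRESENTATIONS:
            sequences = [rec.synthesis_order for rec in records]
        else:
            sequences = [rec.sequence for rec in records]
    X = np.stack([encoder(s, config) for s in sequences])
    y = np.array([bool(rec.sequence_label) for rec in records], dtype=np.int64)
    return EncodedDataset(
        X=X,
        y=y,
        ids=[rec.id for rec in records],
        representation=representation,
        config=config,
        feature_names=_feature_names(representation, config),
    )
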