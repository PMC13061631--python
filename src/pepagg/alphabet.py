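"""The canonical 20-letter amino-acid alphabet and small helpers."""

import numpy as np

#: Alphabetical one-letter codes of the 20 canonical amino acids.  This is
#: the fixed feature order of every 20-dimensional vector in the package.
AA_ORDER: str = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AA_ORDER)}

AA_SET = frozenset(AA_ORDER)


def is_canonical(sequence: str) -> bool:
    """True iff every symbol is one of the 20 canonical one-letter codes."""
    return len(sequence) > 0 and all(ch in AA_SET for ch in sequence)


def require_canonical(sequence: str) -> str:
    if not sequence:
        raise ValueError("empty sequence")
    bad = sorted({ch for ch in sequence if ch not in AA_SET})
    if bad:
        raise ValueError(f"non-canonical residue(s) {bad} in sequence {sequence!r}")
    return sequence


def composition(sequence: str) -> np.ndarray:
    """Normalised 20-dim amino-acid composition of ``sequence`` (sums to 1)."""
    require_canonical(sequence)
    counts = np.zeros(20, dtype=float)
    for ch in sequence:
        counts[AA_INDEX[ch]] += 1.0
    return counts / len(sequence)


def vector_from_mapping(values: dict[str, float], default: float = 0.0) -> np.ndarray:
    """Expand a {one-letter code: value} mapping into a 20-vector in AA_ORDER."""
    bad = sorted(set(values) - AA_SET)
    if bad:
        raise ValueError(f"unknown residue code(s): {bad}")
    out = np.full(20, default, dtype=float)
    for aa, v in values.items():
        out[AA_INDEX[aa]] = v
    return out
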