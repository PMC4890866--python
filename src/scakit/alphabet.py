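"""Canonical amino-acid alphabet and integer/one-hot encodings.

State 0 is the gap; states 1..20 are the amino acids in the fixed order
``ACDEFGHIKLMNPQRSTVWY``.  All numerical modules work on these encodings,
never on raw strings.
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
GAP: str = "-"
N_AA: int = 20
N_STATES: int = 21  # gap + 20 amino acids

#: symbols silently normalized to gap on read (ambiguity codes, stops, etc.)
NON_CANONICAL: frozenset = frozenset("BZXUOJ*.")

_CODE = {GAP: 0}
_CODE.update({aa: i + 1 for i, aa in enumerate(AMINO_ACIDS)})


def encode_row(row: str) -> np.ndarray:
    """Integer codes (0 = gap, 1..20 = amino acids) for one alignment row."""
    try:
        return np.array([_CODE[c] for c in row], dtype=np.int8)
    except KeyError as exc:  # pragma: no cover - MSA validation precludes this
        raise ValueError(f"non-canonical symbol {exc} in row") from exc


def encode_rows(rows) -> np.ndarray:
    """M x L integer code matrix for a list of equal-length rows."""
    return np.vstack([encode_row(r) for r in rows])


def one_hot(codes: np.ndarray, dtype=np.float32) -> np.ndarray:
    """M x (20*L) one-hot of the amino-acid states; gaps are all-zero.

    Column block layout is position-major: entry 20*i + (a-1) is amino acid
    ``a`` at position ``i``.
    """
    m, length = codes.shape
    out = np.zeros((m, N_AA * length), dtype=dtype)
    rows, cols = np.nonzero(codes)
    aa = codes[rows, cols] - 1
    out[rows, cols * N_AA + aa] = 1
    return out


def decode_row(codes: np.ndarray) -> str:
    """Inverse of :func:`encode_row`."""
    lookup = GAP + AMINO_ACIDS
    return "".join(lookup[c] for c in codes)
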