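"""Background amino-acid frequencies.

The packaged table is the composition of the non-redundant protein sequence
database, in the alphabet order of :mod:`scakit.alphabet`.  A gap-adjusted
variant scales the 20 amino-acid frequencies by (1 - gap fraction) and
assigns the remainder to the gap state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import AMINO_ACIDS, N_AA

# Non-redundant-database composition, order ACDEFGHIKLMNPQRSTVWY.
_NR_DATABASE_FREQS = np.array(
    [
        0.073, 0.025, 0.050, 0.061, 0.042, 0.072, 0.023, 0.053, 0.064, 0.089,
        0.023, 0.043, 0.052, 0.040, 0.052, 0.073, 0.056, 0.063, 0.013, 0.033,
    ]
)


@dataclass(frozen=True)
class BackgroundFreqs:
    """Background distribution over amino acids, optionally gap-adjusted.

    Attributes
    ----------
    q : (20,) array, positive, sums to 1.
    gap_fraction : overall gap frequency of the alignment under analysis.
    """

    q: np.ndarray
    gap_fraction: float = 0.0

    def __post_init__(self):
        q = np.asarray(self.q, dtype=float)
        if q.shape != (N_AA,):
            raise ValueError(f"background must have {N_AA} entries")
        if np.any(q <= 0):
            raise ValueError("background frequencies must be positive")
        if abs(q.sum() - 1.0) > 1e-6:
            raise ValueError("background frequencies must sum to 1 (within 1e-6)")
        object.__setattr__(self, "q", q / q.sum())
        if not 0.0 <= self.gap_fraction < 1.0:
            raise ValueError("gap_fraction must be in [0, 1)")

    @property
    def q_adjusted(self) -> np.ndarray:
        """(20,) amino-acid background scaled by the non-gap fraction."""
        return (1.0 - self.gap_fraction) * self.q

    @property
    def q_bar(self) -> np.ndarray:
        """(21,) background over gap + amino acids; sums to 1."""
        return np.concatenate(([self.gap_fraction], self.q_adjusted))

    def as_dict(self) -> dict:
        return {
            "q": dict(zip(AMINO_ACIDS, self.q.tolist())),
            "gap_fraction": float(self.gap_fraction),
        }


def packaged_background(gap_fraction: float = 0.0) -> BackgroundFreqs:
    """The packaged non-redundant-database table."""
    return BackgroundFreqs(q=_NR_DATABASE_FREQS.copy(), gap_fraction=gap_fraction)
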