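"""Alignment preprocessing: gap filtering, sequence weighting, resampling.

The pipeline order is fixed:

1. truncate gapped columns (reference mode or raw gap-fraction cutoff);
2. remove sequences with too many gaps;
3. remove sequences too dissimilar from the reference;
4. compute sequence weights and truncate columns by *weighted* gap
   frequency;
5. recompute the weights on the truncated alignment;
6. optionally down-sample sequences with probability proportional to their
   weights, preserving the effective sequence count.

Fractional identity between two rows counts columns carrying the same
amino acid (gap-gap columns are not matches) over the full alignment
length; see :func:`fractional_identity`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .alphabet import one_hot
from .msa_io import MSA, PositionMap, build_position_map

logger = logging.getLogger(__name__)


class PreprocessError(ValueError):
    pass


@dataclass(frozen=True)
class PreprocessParams:
    """Thresholds for the preprocessing pipeline (defaults as published)."""

    pos_gap_cutoff: float = 0.4
    seq_gap_cutoff: float = 0.2
    min_ref_identity: float = 0.2
    weight_identity_threshold: float = 0.8
    weighted_pos_gap_cutoff: float = 0.2
    regularizer: float = 0.03
    resample: bool = False
    resample_factor: float = 1.5
    seed: int = 0

    def __post_init__(self):
        for name in (
            "pos_gap_cutoff",
            "seq_gap_cutoff",
            "min_ref_identity",
            "weight_identity_threshold",
            "weighted_pos_gap_cutoff",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.regularizer < 1.0:
            raise ValueError("regularizer must be in [0, 1)")
        if self.resample_factor < 1.0:
            raise ValueError("resample_factor must be >= 1")


@dataclass(frozen=True)
class SequenceWeights:
    """Per-sequence weights w_s = 1 / #{r : identity(r, s) > threshold}."""

    w: np.ndarray
    threshold: float

    def __post_init__(self):
        w = np.asarray(self.w, dtype=float)
        if np.any(w <= 0) or np.any(w > 1):
            raise ValueError("weights must lie in (0, 1]")
        object.__setattr__(self, "w", w)

    @property
    def m_eff(self) -> float:
        """Effective number of sequences, the sum of the weights."""
        return float(self.w.sum())


@dataclass(frozen=True)
class ProcessedAlignment:
    msa: MSA
    weights: SequenceWeights
    position_map: Optional[PositionMap]
    params: PreprocessParams
    provenance: tuple = ()

    @property
    def m_eff(self) -> float:
        return self.weights.m_eff


def fractional_identity(r: str, s: str) -> float:
    """Fraction of columns where ``r`` and ``s`` carry the same amino acid.

    Gap-gap columns do not count as matches; the denominator is the full
    alignment length.
    """
    if len(r) != len(s):
        raise ValueError("rows must have equal length")
    matches = sum(1 for a, b in zip(r, s) if a == b and a != "-")
    return matches / len(r)


def identity_matrix(msa: MSA) -> np.ndarray:
    """All-pairs fractional identity, via the one-hot inner product."""
    x = one_hot(msa.codes(), dtype=np.float32)
    sim = (x @ x.T) / np.float32(msa.L)
    return sim.astype(float)


def truncate_positions(
    msa: MSA,
    reference_id: Optional[str] = None,
    gap_cutoff: Optional[float] = None,
) -> tuple:
    """Drop gapped columns; returns (msa, kept column indices).

    Reference mode keeps columns where the reference is ungapped; cutoff
    mode keeps columns whose raw gap fraction is <= ``gap_cutoff``.
    """
    if (reference_id is None) == (gap_cutoff is None):
        raise ValueError("specify exactly one of reference_id / gap_cutoff")
    if reference_id is not None:
        ref_row = msa.rows[msa.index_of(reference_id)]
        kept = [i for i, c in enumerate(ref_row) if c != "-"]
    else:
        codes = msa.codes()
        gap_frac = (codes == 0).mean(axis=0)
        kept = [i for i in range(msa.L) if gap_frac[i] <= gap_cutoff]
    if not kept:
        raise PreprocessError("position truncation removed every column")
    return msa.subset_columns(kept), kept


def filter_sequences(
    msa: MSA,
    seq_gap_cutoff: float,
    reference_id: Optional[str] = None,
    min_ref_identity: Optional[float] = None,
) -> tuple:
    """Drop gappy sequences, then sequences too far from the reference.

    The reference sequence itself is never removed.  Returns
    (msa, removed ids).
    """
    codes = msa.codes()
    gap_frac = (codes == 0).mean(axis=1)
    keep = gap_frac <= seq_gap_cutoff
    if reference_id is not None and min_ref_identity is not None:
        ref_row = msa.rows[msa.index_of(reference_id)]
        ident = np.array([fractional_identity(ref_row, row) for row in msa.rows])
        keep &= ident >= min_ref_identity
        keep[msa.index_of(reference_id)] = True
    kept_idx = np.flatnonzero(keep)
    removed = [msa.ids[i] for i in np.flatnonzero(~keep)]
    if len(kept_idx) < 2:
        raise PreprocessError(
            f"fewer than 2 sequences remain after filtering ({len(kept_idx)})"
        )
    return msa.subset_sequences(kept_idx), removed


def compute_weights(msa: MSA, delta: float = 0.8) -> SequenceWeights:
    """w_s = 1 / #{r : identity(r, s) > delta} (the set includes s itself)."""
    if msa.M == 1:
        return SequenceWeights(w=np.ones(1), threshold=delta)
    sim = identity_matrix(msa)
    # Guard against float32 round-off on the self-identity of ungapped rows.
    np.fill_diagonal(sim, 1.0)
    neighbors = (sim > delta).sum(axis=1)
    return SequenceWeights(w=1.0 / neighbors, threshold=delta)


def weighted_gap_frequency(msa: MSA, weights: SequenceWeights) -> np.ndarray:
    """Per-column gap frequency under sequence weights."""
    codes = msa.codes()
    w = weights.w
    return (w[:, None] * (codes == 0)).sum(axis=0) / w.sum()


def truncate_weighted_gapped_positions(
    msa: MSA, weights: SequenceWeights, gamma_pos: float = 0.2
) -> tuple:
    """Drop columns with weighted gap frequency > gamma_pos.

    Returns (msa, kept column indices).  Callers must recompute weights on
    the truncated alignment afterwards.
    """
    f0 = weighted_gap_frequency(msa, weights)
    kept = [i for i in range(msa.L) if f0[i] <= gamma_pos]
    if not kept:
        raise PreprocessError("weighted gap truncation removed every column")
    return msa.subset_columns(kept), kept


def resample_sequences(
    msa: MSA,
    weights: SequenceWeights,
    factor: float = 1.5,
    seed: int = 0,
    reference_id: Optional[str] = None,
) -> tuple:
    """Down-sample to ~factor * M_eff distinct sequences, weight-biased.

    Sequences are drawn without replacement with probability proportional
    to their weights.  When the target meets or exceeds M the alignment is
    returned unchanged.  The reference sequence, when given, is always part
    of the sample.  Returns (msa, selected indices in original order).
    """
    target = int(round(factor * weights.m_eff))
    if target >= msa.M:
        if factor * weights.m_eff > msa.M:
            logger.warning(
                "resample target %.0f exceeds M=%d; returning full alignment",
                factor * weights.m_eff,
                msa.M,
            )
        return msa, list(range(msa.M))
    rng = np.random.default_rng(seed)
    # sequential conditional draws: each pick is proportional to the weights
    # of the sequences still in the pool
    probs = weights.w.astype(float).copy()
    chosen = set()
    for _ in range(target):
        p = probs / probs.sum()
        pick = int(rng.choice(msa.M, p=p))
        chosen.add(pick)
        probs[pick] = 0.0
    if reference_id is not None:
        ref_idx = msa.index_of(reference_id)
        if ref_idx not in chosen:
            # swap out the lowest-weight pick to keep the sample size fixed
            chosen.discard(min(chosen, key=lambda i: weights.w[i]))
            chosen.add(ref_idx)
    idx = sorted(chosen)
    return msa.subset_sequences(idx), idx


def preprocess(
    msa: MSA,
    params: PreprocessParams = PreprocessParams(),
    reference_id: Optional[str] = None,
    position_labels: Optional[Sequence[str]] = None,
) -> ProcessedAlignment:
    """Run the full preprocessing pipeline; every removal is logged in
    ``provenance`` as (step, removed item count, parameter value)."""
    provenance = []
    pmap = None
    if reference_id is not None:
        pmap = build_position_map(msa, reference_id, position_labels)

    # 1. position truncation
    if reference_id is not None:
        msa1, kept = truncate_positions(msa, reference_id=reference_id)
        step_param = f"reference={reference_id}"
    else:
        msa1, kept = truncate_positions(msa, gap_cutoff=params.pos_gap_cutoff)
        step_param = f"gap_cutoff={params.pos_gap_cutoff}"
    provenance.append(("truncate_positions", msa.L - len(kept), step_param))
    if pmap is not None:
        pmap = pmap.restrict(kept)

    # 2-3. sequence filters
    msa2, removed = filter_sequences(
        msa1,
        params.seq_gap_cutoff,
        reference_id=reference_id,
        min_ref_identity=params.min_ref_identity if reference_id else None,
    )
    provenance.append(("filter_sequences", len(removed), removed))

    # 4. weights + weighted gap truncation
    w4 = compute_weights(msa2, params.weight_identity_threshold)
    msa3, kept2 = truncate_weighted_gapped_positions(
        msa2, w4, params.weighted_pos_gap_cutoff
    )
    provenance.append(
        (
            "truncate_weighted_gapped_positions",
            msa2.L - len(kept2),
            f"gamma_pos={params.weighted_pos_gap_cutoff}",
        )
    )
    if pmap is not None:
        pmap = pmap.restrict(kept2)

    # 5. recompute weights on the truncated alignment
    weights = compute_weights(msa3, params.weight_identity_threshold)

    # 6. optional weighted down-sampling
    if params.resample:
        msa4, idx = resample_sequences(
            msa3,
            weights,
            factor=params.resample_factor,
            seed=params.seed,
            reference_id=reference_id,
        )
        provenance.append(("resample_sequences", msa3.M - msa4.M, params.seed))
        if msa4.M != msa3.M:
            weights = compute_weights(msa4, params.weight_identity_threshold)
        msa3 = msa4

    return ProcessedAlignment(
        msa=msa3,
        weights=weights,
        position_map=pmap,
        params=params,
        provenance=tuple(provenance),
    )
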