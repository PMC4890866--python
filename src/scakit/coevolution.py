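"""Conservation-weighted coevolution statistics.

Frequencies are computed over 21 states (gap = state 0) with sequence
weights and a small regularizer; conservation is the relative entropy of
the observed frequency against a background; raw covariances between
amino-acid indicators are weighted by the gradient of the conservation
measure and compressed position-pair-wise into an L x L matrix by the
Frobenius (default) or spectral norm of each 20 x 20 block.

All logarithms are natural: only in nats does the gradient identity
``phi = dD/df`` hold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .alphabet import N_AA, N_STATES, one_hot
from .background import BackgroundFreqs, packaged_background
from .preprocessing import ProcessedAlignment, SequenceWeights

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FrequencyTables:
    """Weighted, regularized single- and pair-site frequencies.

    ``single`` is L x 21 (state 0 = gap) and sums to 1 per row.
    ``pair_flat`` is the flattened 20L x 20L amino-acid pair frequency
    matrix; block (i, j) holds f_ij^ab for amino acids a, b.
    """

    single: np.ndarray
    single_raw: np.ndarray
    pair_flat: np.ndarray
    regularizer: float

    @property
    def L(self) -> int:
        return self.single.shape[0]

    @property
    def amino(self) -> np.ndarray:
        """L x 20 regularized amino-acid frequencies (gap column dropped)."""
        return self.single[:, 1:]

    def pair_block(self, i: int, j: int) -> np.ndarray:
        """The 20 x 20 pair-frequency block for positions (i, j)."""
        return self.pair_flat[
            i * N_AA : (i + 1) * N_AA, j * N_AA : (j + 1) * N_AA
        ]


@dataclass(frozen=True)
class ConservationProfile:
    """Per-position conservation and its frequency gradient.

    ``d_ia`` and ``phi`` are L x 20 (amino acids only); ``d_i`` is the
    overall positional conservation computed over all 21 states against
    the gap-adjusted background.
    """

    d_ia: np.ndarray
    d_i: np.ndarray
    phi: np.ndarray
    background: BackgroundFreqs


@dataclass(frozen=True)
class CoevolutionResult:
    matrix: np.ndarray  # L x L compressed
    norm_kind: str
    projection: np.ndarray  # L x 20, unit rows (zero rows flagged)
    reduced: np.ndarray  # M x L
    degenerate_columns: tuple
    conservation: ConservationProfile
    freqs: FrequencyTables


def compute_frequencies(
    msa_codes: np.ndarray, weights: np.ndarray, lam: float = 0.03
) -> FrequencyTables:
    """Weighted single/pair frequencies with regularizers lam/21, lam/21^2."""
    if not 0.0 <= lam < 1.0:
        raise ValueError("regularizer must be in [0, 1)")
    m, L = msa_codes.shape
    w = np.asarray(weights, dtype=float)
    m_eff = w.sum()
    if m_eff <= 0:
        raise ValueError("effective sequence count must be positive")
    # single-site over 21 states
    single_raw = np.zeros((L, N_STATES))
    for a in range(N_STATES):
        single_raw[:, a] = (w[:, None] * (msa_codes == a)).sum(axis=0) / m_eff
    single = (1.0 - lam) * single_raw + lam / N_STATES
    # pair frequencies over amino acids via the one-hot inner product
    x = one_hot(msa_codes, dtype=np.float32)
    xw = x * w[:, None].astype(np.float32)
    pair_raw = (xw.T @ x).astype(float) / m_eff
    pair = (1.0 - lam) * pair_raw + lam / (N_STATES**2)
    return FrequencyTables(
        single=single, single_raw=single_raw, pair_flat=pair, regularizer=lam
    )


def relative_entropy(f, q):
    """Binary relative entropy D(f || q) = f ln(f/q) + (1-f) ln((1-f)/(1-q)).

    Both arguments must lie strictly inside (0, 1); vectorized.
    """
    f = np.asarray(f, dtype=float)
    q = np.asarray(q, dtype=float)
    if np.any(f <= 0) or np.any(f >= 1) or np.any(q <= 0) or np.any(q >= 1):
        raise ValueError("relative_entropy requires f, q in the open interval (0, 1)")
    return f * np.log(f / q) + (1.0 - f) * np.log((1.0 - f) / (1.0 - q))


def phi_weights(f, q):
    """Gradient of :func:`relative_entropy` in f: ln[f(1-q) / ((1-f)q)].

    Signed: negative where f < q.
    """
    f = np.asarray(f, dtype=float)
    q = np.asarray(q, dtype=float)
    if np.any(f <= 0) or np.any(f >= 1) or np.any(q <= 0) or np.any(q >= 1):
        raise ValueError("phi_weights requires f, q in the open interval (0, 1)")
    return np.log(f * (1.0 - q) / ((1.0 - f) * q))


def background(
    msa_codes: Optional[np.ndarray] = None,
    weights: Optional[np.ndarray] = None,
    q_table: Optional[np.ndarray] = None,
    mode: str = "packaged",
    lam: float = 0.03,
) -> BackgroundFreqs:
    """Background frequencies with the alignment's weighted gap fraction.

    ``mode='packaged'`` uses the packaged database table (default);
    ``mode='from-alignment'`` pools the weighted amino-acid frequencies of
    the alignment itself (regularized so all entries stay positive).  A
    user table may be supplied instead and must sum to 1 within 1e-6.
    """
    gap_fraction = 0.0
    if msa_codes is not None:
        w = np.ones(msa_codes.shape[0]) if weights is None else np.asarray(weights)
        gap_fraction = float(
            (w[:, None] * (msa_codes == 0)).sum() / (w.sum() * msa_codes.shape[1])
        )
    if q_table is not None:
        return BackgroundFreqs(q=np.asarray(q_table, float), gap_fraction=gap_fraction)
    if mode == "packaged":
        return packaged_background(gap_fraction=gap_fraction)
    if mode == "from-alignment":
        if msa_codes is None:
            raise ValueError("from-alignment mode requires an alignment")
        w = np.ones(msa_codes.shape[0]) if weights is None else np.asarray(weights)
        counts = np.zeros(N_AA)
        for a in range(1, N_STATES):
            counts[a - 1] = (w[:, None] * (msa_codes == a)).sum()
        pooled = counts / counts.sum()
        pooled = (1.0 - lam) * pooled + lam / N_AA
        return BackgroundFreqs(q=pooled, gap_fraction=gap_fraction)
    raise ValueError(f"unknown background mode {mode!r}")


def conservation_profile(
    freqs: FrequencyTables, bg: BackgroundFreqs
) -> ConservationProfile:
    """Relative entropies and phi weights for every position/amino acid.

    Per-amino-acid quantities use the gap-adjusted background; the overall
    positional conservation sums over all 21 states against the full
    gap-inclusive background vector.
    """
    q = bg.q_adjusted  # (20,)
    if np.any(q <= 0) or np.any(q >= 1):
        raise ValueError("gap-adjusted background must be interior; is the "
                         "alignment entirely gaps?")
    f = freqs.amino  # L x 20, interior thanks to the regularizer
    d_ia = relative_entropy(f, q[None, :])
    phi = phi_weights(f, q[None, :])
    q_bar = bg.q_bar
    if q_bar[0] <= 0:
        # gap-free alignment: the gap state carries no mass on either side;
        # restrict the overall conservation sum to the amino acids.
        d_i = (freqs.single[:, 1:] * np.log(freqs.single[:, 1:] / q_bar[None, 1:])).sum(
            axis=1
        )
    else:
        d_i = (freqs.single * np.log(freqs.single / q_bar[None, :])).sum(axis=1)
    return ConservationProfile(d_ia=d_ia, d_i=d_i, phi=phi, background=bg)


def weighted_coevolution_tensor(
    freqs: FrequencyTables,
    conservation: Optional[ConservationProfile] = None,
    phi: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Flattened 20L x 20L weighted covariance phi_i^a phi_j^b (f_ij^ab -
    f_i^a f_j^b).

    Passing ``phi`` overrides the conservation gradient (``phi=1`` recovers
    the plain covariance matrix).
    """
    if phi is None:
        if conservation is None:
            raise ValueError("provide a ConservationProfile or explicit phi")
        phi = conservation.phi
    phi = np.broadcast_to(np.asarray(phi, float), (freqs.L, N_AA))
    f_flat = freqs.amino.reshape(-1)
    phi_flat = phi.reshape(-1)
    cov = freqs.pair_flat - np.outer(f_flat, f_flat)
    return (phi_flat[:, None] * phi_flat[None, :]) * cov


def compress(tensor: np.ndarray, norm_kind: str = "frobenius") -> np.ndarray:
    """Collapse each 20 x 20 position-pair block to a scalar.

    Accepts the flattened 20L x 20L layout or an (L, L, 20, 20) array.
    """
    if tensor.ndim == 2:
        n = tensor.shape[0] // N_AA
        blocks = (
            tensor.reshape(n, N_AA, n, N_AA).transpose(0, 2, 1, 3)
        )
    elif tensor.ndim == 4:
        blocks = tensor
    else:
        raise ValueError("expected a 2-D flattened or 4-D block tensor")
    if norm_kind == "frobenius":
        return np.sqrt((blocks**2).sum(axis=(2, 3)))
    if norm_kind == "spectral":
        L = blocks.shape[0]
        sv = np.linalg.svd(blocks.reshape(L * L, N_AA, N_AA), compute_uv=False)
        return sv[:, 0].reshape(L, L)
    raise ValueError(f"unknown norm_kind {norm_kind!r}")


def projection_and_reduce(
    msa_codes: np.ndarray,
    conservation: ConservationProfile,
    freqs: FrequencyTables,
) -> tuple:
    """Unit projection rows phi*f / ||phi*f|| and the M x L reduced
    alignment x_si = sum_a P_i^a x_sia (gaps give 0).

    Returns (projection, reduced, flagged zero-norm columns).
    """
    pf = conservation.phi * freqs.amino  # L x 20
    norms = np.sqrt((pf**2).sum(axis=1))
    degenerate = tuple(int(i) for i in np.flatnonzero(norms == 0))
    if degenerate:
        logger.warning("zero-norm projection at columns %s", degenerate)
    safe = np.where(norms == 0, 1.0, norms)
    proj = pf / safe[:, None]
    proj[list(degenerate), :] = 0.0
    m, L = msa_codes.shape
    reduced = np.zeros((m, L))
    nongap = msa_codes > 0
    rows, cols = np.nonzero(nongap)
    reduced[rows, cols] = proj[cols, msa_codes[rows, cols] - 1]
    return proj, reduced, degenerate


def sca_matrix(
    processed: ProcessedAlignment,
    bg: Optional[BackgroundFreqs] = None,
    lam: Optional[float] = None,
    norm_kind: str = "frobenius",
) -> CoevolutionResult:
    """End-to-end: frequencies -> conservation -> weighted matrix ->
    compression -> projection/reduced alignment."""
    codes = processed.msa.codes()
    w = processed.weights.w
    if lam is None:
        lam = processed.params.regularizer
    freqs = compute_frequencies(codes, w, lam=lam)
    if bg is None:
        bg = background(codes, w, mode="packaged")
    cons = conservation_profile(freqs, bg)
    tensor = weighted_coevolution_tensor(freqs, cons)
    matrix = compress(tensor, norm_kind=norm_kind)
    proj, reduced, degenerate = projection_and_reduce(codes, cons, freqs)
    return CoevolutionResult(
        matrix=matrix,
        norm_kind=norm_kind,
        projection=proj,
        reduced=reduced,
        degenerate_columns=degenerate,
        conservation=cons,
        freqs=freqs,
    )
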