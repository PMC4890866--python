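"""Spectral decomposition, scrambled-column null, and ICA rotation."""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .background import BackgroundFreqs
from .coevolution import (
    compress,
    compute_frequencies,
    conservation_profile,
    weighted_coevolution_tensor,
)
from .preprocessing import ProcessedAlignment

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpectrumResult:
    """Eigenvalues (descending) and matched eigenvectors of the compressed
    coevolution matrix, plus the randomization null and the significance
    cutoff once computed."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    null_eigenvalues: Optional[np.ndarray] = None
    k_star: Optional[int] = None
    cutoff: Optional[float] = None


@dataclass(frozen=True)
class ICAResult:
    W: np.ndarray  # k x k unmixing matrix
    ics: np.ndarray  # L x k, unit columns, sign-oriented
    iterations: int
    converged: bool
    seed: int


def eigendecompose(matrix: np.ndarray, symmetry_tol: float = 1e-10) -> SpectrumResult:
    """Full spectrum, descending, with a deterministic sign convention
    (largest-magnitude entry of each eigenvector is positive)."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("expected a square matrix")
    if np.abs(matrix - matrix.T).max() > symmetry_tol:
        raise ValueError("matrix is not symmetric within tolerance")
    vals, vecs = np.linalg.eigh(matrix)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    signs = np.sign(vecs[np.abs(vecs).argmax(axis=0), np.arange(vecs.shape[1])])
    signs[signs == 0] = 1.0
    return SpectrumResult(eigenvalues=vals, eigenvectors=vecs * signs[None, :])


def scramble_columns(codes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Permute each column independently across sequences.

    Unweighted per-column symbol counts are exactly preserved.
    """
    out = codes.copy()
    for j in range(codes.shape[1]):
        out[:, j] = codes[rng.permutation(codes.shape[0]), j]
    return out


def null_spectra(
    processed: ProcessedAlignment,
    bg: BackgroundFreqs,
    n_trials: int = 10,
    seed: int = 0,
    lam: Optional[float] = None,
    norm_kind: str = "frobenius",
) -> np.ndarray:
    """Eigenvalue spectra of column-scrambled alignments.

    Sequence weights stay attached to sequences during scrambling, so the
    preserved statistic is the (unweighted) per-column composition.
    Returns an (n_trials, L) array of descending eigenvalues.
    """
    if n_trials < 2:
        raise ValueError("n_trials must be >= 2 to estimate a cutoff spread")
    codes = processed.msa.codes()
    w = processed.weights.w
    if lam is None:
        lam = processed.params.regularizer
    rng = np.random.default_rng(seed)
    spectra = np.empty((n_trials, processed.msa.L))
    for t in range(n_trials):
        scrambled = scramble_columns(codes, rng)
        freqs = compute_frequencies(scrambled, w, lam=lam)
        cons = conservation_profile(freqs, bg)
        matrix = compress(weighted_coevolution_tensor(freqs, cons), norm_kind)
        vals = np.linalg.eigvalsh(matrix)
        spectra[t] = vals[::-1]
    return spectra


def select_k_star(
    spectrum: SpectrumResult, null_eigenvalues: np.ndarray
) -> SpectrumResult:
    """Count eigenvalues above mean + 2 sd of the *second* null eigenvalue.

    The first null eigenvalue is ignored: it reflects the preserved
    single-column statistics, not correlations.  Counting starts from the
    top of the true spectrum and includes the first mode.
    """
    null_eigenvalues = np.asarray(null_eigenvalues, dtype=float)
    if null_eigenvalues.ndim != 2 or null_eigenvalues.shape[0] < 2:
        raise ValueError("need at least 2 null trials")
    lam2 = null_eigenvalues[:, 1]
    cutoff = float(lam2.mean() + 2.0 * lam2.std(ddof=1))
    k_star = int((spectrum.eigenvalues > cutoff).sum())
    if k_star == 0:
        logger.warning("no significant eigenmodes (all below %.4g)", cutoff)
    return replace(
        spectrum,
        null_eigenvalues=null_eigenvalues,
        k_star=k_star,
        cutoff=cutoff,
    )


def _orient_and_order(W: np.ndarray, ics: np.ndarray) -> tuple:
    """Sign-orient ICs (largest-|entry| positive) and order them by the
    eigenvalue rank of their dominant eigenmode, kurtosis as tie-break."""
    from scipy.stats import kurtosis

    k = ics.shape[1]
    norms = np.linalg.norm(ics, axis=0)
    ics = ics / norms[None, :]
    W = W / norms[:, None]  # keep ics == (W @ modes.T).T
    for p in range(k):
        imax = np.abs(ics[:, p]).argmax()
        if ics[imax, p] < 0:
            ics[:, p] *= -1
            W[p, :] *= -1
    dominant = np.abs(W).argmax(axis=1)
    kurt = kurtosis(ics, axis=0)
    order = sorted(range(k), key=lambda p: (dominant[p], -kurt[p]))
    return W[order, :], ics[:, order]


def ica(
    modes: np.ndarray,
    learn_rate: float = 0.1,
    max_iter: int = 100_000,
    tol: float = 1e-7,
    seed: int = 0,
) -> ICAResult:
    """Infomax ICA (logistic/tanh score) on the columns of ``modes``.

    ``modes`` is L x k (the retained eigenvectors).  The update is the
    natural-gradient infomax rule W <- W + lr * (I + g(u) u^T / L) W with
    score g(u) = 1 - 2 sigmoid(u) = -tanh(u/2).  Deterministic (identity
    initialization); ``seed`` is recorded for provenance only.
    """
    modes = np.asarray(modes, dtype=float)
    if modes.ndim != 2:
        raise ValueError("modes must be an L x k matrix")
    L, k = modes.shape
    if k == 1:
        ics = modes / np.linalg.norm(modes)
        if ics[np.abs(ics).argmax()] < 0:
            ics = -ics
        return ICAResult(
            W=np.ones((1, 1)), ics=ics, iterations=0, converged=True, seed=seed
        )
    x = modes.T  # k channels, L samples
    W = np.eye(k)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        u = W @ x
        g = 1.0 - 2.0 / (1.0 + np.exp(-u))
        dW = learn_rate * ((np.eye(k) + (g @ u.T) / L) @ W)
        W = W + dW
        if np.abs(dW).max() < tol:
            converged = True
            break
    if not converged:
        logger.warning("ICA did not converge within %d iterations", max_iter)
    ics = (W @ x).T
    W, ics = _orient_and_order(W, ics)
    return ICAResult(W=W, ics=ics, iterations=it, converged=converged, seed=seed)
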