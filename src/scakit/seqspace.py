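"""Sequence-space projection of positional eigenmodes and ICs.

The reduced alignment x (M x L) maps positional eigenvectors V with
eigenvalues D into sequence coordinates U = x V D^(-1/2); applying the ICA
unmixing matrix W to the retained modes gives the IC-aligned coordinates
U_p = U W^T.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .decomposition import ICAResult, SpectrumResult
from .msa_io import MSA, AnnotationTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SequenceSpace:
    U: np.ndarray  # M x k, per-eigenmode coordinates
    U_p: Optional[np.ndarray]  # M x k, IC-rotated coordinates (None without ICA)
    mode_indices: tuple  # retained eigenmode indices (0-based)


def sequence_projection(
    reduced: np.ndarray,
    spectrum: SpectrumResult,
    ica_result: Optional[ICAResult] = None,
    n_modes: Optional[int] = None,
) -> SequenceSpace:
    """Project sequences onto the retained eigenmodes (and ICs).

    ``n_modes`` defaults to the spectrum's k_star.  Modes with
    non-positive eigenvalues are excluded with a warning (the scaling
    D^(-1/2) is undefined there).
    """
    if n_modes is None:
        if spectrum.k_star is None:
            raise ValueError("spectrum has no k_star; pass n_modes explicitly")
        n_modes = spectrum.k_star
    if n_modes < 1:
        raise ValueError("need at least one retained mode")
    # relative floor: numerically-zero eigenvalues are as unusable as
    # negative ones for the D^(-1/2) scaling
    floor = max(spectrum.eigenvalues.max(), 0.0) * 1e-12
    idx = [i for i in range(n_modes) if spectrum.eigenvalues[i] > floor]
    dropped = [i for i in range(n_modes) if spectrum.eigenvalues[i] <= floor]
    if dropped:
        logger.warning("excluding modes with non-positive eigenvalues: %s", dropped)
    V = spectrum.eigenvectors[:, idx]
    lam = spectrum.eigenvalues[idx]
    U = reduced @ V @ np.diag(1.0 / np.sqrt(lam))
    U_p = None
    if ica_result is not None:
        if ica_result.W.shape[0] != len(idx):
            raise ValueError("ICA rank does not match the retained modes")
        U_p = U @ ica_result.W.T
    return SequenceSpace(U=U, U_p=U_p, mode_indices=tuple(idx))


def rank_biserial(coord: np.ndarray, in_class: np.ndarray) -> float:
    """Rank-biserial separation of one class vs the rest along a coordinate.

    Equals 2*AUC - 1 of the Mann-Whitney statistic; 0 when either group is
    empty or the coordinate carries no class information.
    """
    a = coord[in_class]
    b = coord[~in_class]
    if len(a) == 0 or len(b) == 0:
        return 0.0
    from scipy.stats import mannwhitneyu

    u, _ = mannwhitneyu(a, b, alternative="two-sided")
    return float(2.0 * u / (len(a) * len(b)) - 1.0)


def annotate_modes(
    seqspace: SequenceSpace,
    msa: MSA,
    annotations: AnnotationTable,
    label_key: str,
    n_bins: int = 30,
) -> dict:
    """Per-IC, per-class histograms and separation scores.

    Returns {ic_index: {"bin_edges": ..., "histograms": {class: counts},
    "separation": {class: rank-biserial}}} using the IC coordinates when
    available, else the eigenmode coordinates.
    """
    if label_key not in annotations.keys():
        raise KeyError(f"unknown annotation key {label_key!r}")
    labels = np.array(annotations.column(msa, label_key, default=""))
    coords = seqspace.U_p if seqspace.U_p is not None else seqspace.U
    classes = sorted(c for c in set(labels) if c != "")
    if not classes:
        raise ValueError("annotation join is empty for this alignment")
    out = {}
    for p in range(coords.shape[1]):
        coord = coords[:, p]
        edges = np.histogram_bin_edges(coord, bins=n_bins)
        hists, seps = {}, {}
        for cls in classes:
            mask = labels == cls
            hists[cls] = np.histogram(coord[mask], bins=edges)[0]
            seps[cls] = 0.0 if len(classes) == 1 else rank_biserial(coord, mask)
        out[p] = {"bin_edges": edges, "histograms": hists, "separation": seps}
    return out
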