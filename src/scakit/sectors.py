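"""Sector definition: per-IC position selection, the IC-ordered submatrix,
inter-IC coupling, and grouping of ICs into sectors.

Each sign-oriented IC is fitted with a location-scale t distribution by
maximum likelihood; positions in the upper tail of the fitted CDF (default
above 0.95) define the IC's position set.  Overlaps between ICs are
resolved to the IC with the larger loading.  Grouping links IC pairs whose
normalized between-block coupling exceeds a threshold and takes connected
components; the threshold is a heuristic default with a manual override.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .msa_io import PositionMap

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ICPositionSet:
    ic_index: int
    positions: tuple  # column indices, descending |loading|
    loadings: tuple  # matching loadings
    fit_params: Optional[tuple]  # (df, loc, scale) or None if fallback
    cdf_cutoff: float
    used_fallback: bool = False
    degenerate: bool = False

    def labels(self, pmap: Optional[PositionMap]) -> tuple:
        if pmap is None:
            return tuple(str(p) for p in self.positions)
        return tuple(pmap.label(p) or str(p) for p in self.positions)


@dataclass(frozen=True)
class SectorModel:
    ic_sets: tuple  # disjoint ICPositionSets, one per IC
    submatrix: np.ndarray  # concatenated IC blocks, copied from the matrix
    order: tuple  # column indices in submatrix order
    inter_ic_stats: Optional[np.ndarray] = None
    sector_assignments: Optional[tuple] = None  # partition of IC indices
    mode: str = "auto"

    def sectors_as_positions(self) -> list:
        """Per-sector sorted position lists."""
        out = []
        for group in self.sector_assignments or ():
            positions = []
            for s in self.ic_sets:
                if s.ic_index in group:
                    positions.extend(s.positions)
            out.append(sorted(positions))
        return out


def fit_ic_and_select(
    ic_loadings: np.ndarray, ic_index: int = 0, cdf_cutoff: float = 0.95
) -> ICPositionSet:
    """Fit a t distribution to one IC and keep the upper CDF tail.

    Only the positive tail of the sign-oriented IC is selected.  On fit
    failure (or a degenerate fit) the empirical (cdf_cutoff) quantile is
    used instead, with a warning.
    """
    loadings = np.asarray(ic_loadings, dtype=float)
    if loadings.size < 10:
        raise ValueError("need at least 10 positions to fit an IC")
    if not 0.0 < cdf_cutoff <= 1.0:
        raise ValueError("cdf_cutoff must be in (0, 1]")
    fit_params = None
    used_fallback = False
    degenerate = bool(np.allclose(loadings, loadings[0]))
    threshold = np.inf
    if not degenerate:
        try:
            df, loc, scale = stats.t.fit(loadings)
            if np.isfinite(df) and df < 1.0:
                # maximum likelihood with the df >= 1 bound active
                df, loc, scale = stats.t.fit(loadings, f0=1.0)
            if not (np.isfinite([df, loc, scale]).all() and df >= 1 and scale > 0):
                raise ValueError("degenerate t fit")
            fit_params = (float(df), float(loc), float(scale))
            threshold = (
                np.inf
                if cdf_cutoff >= 1.0
                else stats.t.ppf(cdf_cutoff, df, loc=loc, scale=scale)
            )
        except Exception as exc:
            used_fallback = True
            logger.warning(
                "IC %d: t fit failed (%s); falling back to the empirical "
                "quantile",
                ic_index,
                exc,
            )
    if fit_params is None and not degenerate:
        threshold = (
            np.inf if cdf_cutoff >= 1.0 else float(np.quantile(loadings, cdf_cutoff))
        )
    if degenerate:
        used_fallback = True
        logger.warning("IC %d: all loadings identical; empty selection", ic_index)
    selected = np.flatnonzero(loadings > threshold)
    order = selected[np.argsort(-np.abs(loadings[selected]))]
    return ICPositionSet(
        ic_index=ic_index,
        positions=tuple(int(i) for i in order),
        loadings=tuple(float(loadings[i]) for i in order),
        fit_params=fit_params,
        cdf_cutoff=cdf_cutoff,
        used_fallback=used_fallback,
        degenerate=degenerate,
    )


def resolve_overlaps(sets: Sequence[ICPositionSet], ics: np.ndarray) -> list:
    """Assign each multiply-selected position to the IC with the largest
    |loading| there; ties go to the lower IC index."""
    ics = np.asarray(ics, dtype=float)
    owner = {}
    for s in sets:
        for pos in s.positions:
            if pos not in owner:
                owner[pos] = s.ic_index
            else:
                cur = owner[pos]
                if np.abs(ics[pos, s.ic_index]) > np.abs(ics[pos, cur]):
                    logger.info(
                        "position %d reassigned from IC %d to IC %d", pos, cur,
                        s.ic_index,
                    )
                    owner[pos] = s.ic_index
    out = []
    for s in sets:
        kept = [(p, l) for p, l in zip(s.positions, s.loadings) if owner[p] == s.ic_index]
        out.append(
            ICPositionSet(
                ic_index=s.ic_index,
                positions=tuple(p for p, _ in kept),
                loadings=tuple(l for _, l in kept),
                fit_params=s.fit_params,
                cdf_cutoff=s.cdf_cutoff,
                used_fallback=s.used_fallback,
                degenerate=s.degenerate,
            )
        )
    return out


def build_submatrix(matrix: np.ndarray, sets: Sequence[ICPositionSet]) -> SectorModel:
    """Reorder the coevolution matrix IC-by-IC (within-IC by descending
    loading); entries are copied, never recomputed."""
    order = [p for s in sets for p in s.positions]
    if not order:
        raise ValueError("no positions selected across the ICs")
    if len(order) != len(set(order)):
        raise ValueError("IC position sets must be disjoint; resolve overlaps first")
    idx = np.array(order)
    return SectorModel(
        ic_sets=tuple(sets),
        submatrix=matrix[np.ix_(idx, idx)].copy(),
        order=tuple(order),
    )


def inter_ic_coupling(model: SectorModel) -> np.ndarray:
    """Normalized mean coupling between IC blocks.

    stat(g, h) = mean(off-diagonal block g-h) / sqrt(within(g) * within(h)),
    where within(g) is the mean of block g's off-diagonal entries (its lone
    diagonal entry for singleton ICs, flagged).  The diagonal is 1.
    """
    sets = [s for s in model.ic_sets]
    if len(sets) < 2:
        raise ValueError("need at least 2 ICs for coupling statistics")
    spans = []
    start = 0
    for s in sets:
        spans.append((start, start + len(s.positions)))
        start += len(s.positions)
    sub = model.submatrix
    within = []
    for (a, b), s in zip(spans, sets):
        block = sub[a:b, a:b]
        n = block.shape[0]
        if n == 0:
            within.append(np.nan)
        elif n == 1:
            logger.warning("IC %d is a singleton; using its diagonal entry", s.ic_index)
            within.append(float(block[0, 0]))
        else:
            within.append(float((block.sum() - np.trace(block)) / (n * (n - 1))))
    k = len(sets)
    stat = np.eye(k)
    for g in range(k):
        for h in range(g + 1, k):
            (a0, a1), (b0, b1) = spans[g], spans[h]
            if a1 == a0 or b1 == b0 or not np.isfinite(within[g] * within[h]):
                val = np.nan
            else:
                block = sub[a0:a1, b0:b1]
                denom = np.sqrt(within[g] * within[h])
                val = float(block.mean() / denom) if denom > 0 else np.nan
            stat[g, h] = stat[h, g] = val
    return stat


def group_ics(
    stats_matrix: np.ndarray,
    threshold: float = 0.25,
    manual: Optional[Sequence[Sequence[int]]] = None,
) -> tuple:
    """Partition ICs into sectors.

    Auto mode links IC pairs with coupling > threshold and takes connected
    components (transitive grouping).  ``manual`` applies a user partition
    of the IC indices verbatim.  Returns (partition, mode).
    """
    k = stats_matrix.shape[0]
    if manual is not None:
        flat = [i for grp in manual for i in grp]
        if sorted(flat) != list(range(k)):
            raise ValueError(
                f"manual partition must cover IC indices 0..{k - 1} exactly"
            )
        return tuple(tuple(sorted(g)) for g in manual), "manual"
    parent = list(range(k))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for g in range(k):
        for h in range(g + 1, k):
            if np.isfinite(stats_matrix[g, h]) and stats_matrix[g, h] > threshold:
                parent[find(g)] = find(h)
    groups: dict = {}
    for i in range(k):
        groups.setdefault(find(i), []).append(i)
    partition = tuple(
        tuple(sorted(g)) for g in sorted(groups.values(), key=lambda g: min(g))
    )
    return partition, "auto"


def identify_sectors(
    matrix: np.ndarray,
    ics: np.ndarray,
    cdf_cutoff: float = 0.95,
    group_threshold: float = 0.25,
    manual: Optional[Sequence[Sequence[int]]] = None,
) -> SectorModel:
    """Full sector pipeline: select, resolve, submatrix, couple, group."""
    k = ics.shape[1]
    sets = [fit_ic_and_select(ics[:, p], ic_index=p, cdf_cutoff=cdf_cutoff)
            for p in range(k)]
    sets = resolve_overlaps(sets, ics)
    nonempty = [s for s in sets if s.positions]
    if not nonempty:
        raise ValueError("no IC selected any position at this cutoff")
    model = build_submatrix(matrix, nonempty)
    if len(nonempty) >= 2:
        stats_matrix = inter_ic_coupling(model)
        index_of = {s.ic_index: i for i, s in enumerate(nonempty)}
        part, mode = group_ics(stats_matrix, threshold=group_threshold,
                               manual=[[index_of[i] for i in grp if i in index_of]
                                       for grp in manual] if manual else None)
        assignments = tuple(
            tuple(sorted(nonempty[i].ic_index for i in grp)) for grp in part
        )
    else:
        stats_matrix = None
        assignments = ((nonempty[0].ic_index,),)
        mode = "auto"
    return SectorModel(
        ic_sets=model.ic_sets,
        submatrix=model.submatrix,
        order=model.order,
        inter_ic_stats=stats_matrix,
        sector_assignments=assignments,
        mode=mode,
    )
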