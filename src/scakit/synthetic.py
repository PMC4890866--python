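"""Synthetic alignments with planted conservation, sectors, subfamilies,
and redundancy — the package's offline test bed.

The generative model is a latent-state (Bernoulli) coupling model:
non-sector positions are drawn i.i.d. from a position-specific
distribution (either the background, or a near-invariant mixture that
concentrates on one consensus residue); for each planted sector every
sequence draws a hidden on/off state, and in the "on" state each sector
position shows its preferred residue with probability ``rho``, otherwise a
background draw.  Subfamily swap maps re-map preferred residues on a
subset of sector positions for a fraction of sequences, so one sector's
signal splits across sequence clades.  Redundancy appends mutated
near-copies of each sequence.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np

from .alphabet import AMINO_ACIDS, N_AA
from .background import packaged_background
from .msa_io import MSA


@dataclass(frozen=True)
class SectorSpec:
    """A planted group of co-conserved positions."""

    positions: tuple
    rho: float = 0.9
    preferred: Optional[tuple] = None  # one residue per position; random if None
    on_probability: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [0, 1]")
        if not 0.0 < self.on_probability < 1.0:
            raise ValueError("on_probability must be in (0, 1)")
        if self.preferred is not None and len(self.preferred) != len(self.positions):
            raise ValueError("one preferred residue per sector position")


@dataclass(frozen=True)
class SubfamilySpec:
    """A sequence clade with re-mapped preferred residues."""

    fraction: float
    swaps: dict  # position -> replacement residue (single letter)

    def __post_init__(self):
        if not 0.0 < self.fraction <= 1.0:
            raise ValueError("fraction must be in (0, 1]")
        for pos, res in self.swaps.items():
            if res not in AMINO_ACIDS:
                raise ValueError(f"swap residue {res!r} is not a canonical amino acid")


@dataclass(frozen=True)
class RedundancySpec:
    duplication_factor: int = 1  # total copies per sequence (1 = none)
    mutation_rate: float = 0.0

    def __post_init__(self):
        if self.duplication_factor < 1:
            raise ValueError("duplication_factor must be >= 1")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")


@dataclass(frozen=True)
class PlantedSpec:
    M: int
    L: int
    sectors: tuple = ()
    subfamilies: tuple = ()
    redundancy: RedundancySpec = RedundancySpec()
    invariant_fraction: float = 0.0
    invariant_conservation: float = 0.9
    background: Optional[np.ndarray] = None  # 20-vector; packaged table if None
    seed: int = 0

    def __post_init__(self):
        if self.M < 2 or self.L < 1:
            raise ValueError("need M >= 2 and L >= 1")
        seen = set()
        for sec in self.sectors:
            pos = set(sec.positions)
            if pos & seen:
                raise ValueError("sector position sets must be disjoint")
            if any(p < 0 or p >= self.L for p in pos):
                raise ValueError("sector positions outside [0, L)")
            seen |= pos
        if sum(sf.fraction for sf in self.subfamilies) > 1.0 + 1e-9:
            raise ValueError("subfamily fractions must sum to <= 1")
        if not 0.0 <= self.invariant_fraction <= 1.0:
            raise ValueError("invariant_fraction must be in [0, 1]")
        if not 0.0 < self.invariant_conservation < 1.0:
            raise ValueError("invariant_conservation must be in (0, 1)")


@dataclass(frozen=True)
class SyntheticTruth:
    spec: PlantedSpec
    sector_of_position: tuple  # per position: sector index or -1
    subfamily_of_sequence: tuple  # per emitted sequence: subfamily index or -1
    invariant_positions: tuple
    preferred_residues: dict  # position -> residue letter (sector positions)

    def to_json(self) -> str:
        payload = {
            "M": self.spec.M,
            "L": self.spec.L,
            "seed": self.spec.seed,
            "sectors": [
                {
                    "positions": list(sec.positions),
                    "rho": sec.rho,
                    "on_probability": sec.on_probability,
                }
                for sec in self.spec.sectors
            ],
            "sector_of_position": list(self.sector_of_position),
            "subfamily_of_sequence": list(self.subfamily_of_sequence),
            "invariant_positions": list(self.invariant_positions),
            "preferred_residues": {str(k): v for k, v in self.preferred_residues.items()},
        }
        return json.dumps(payload, indent=2)


def _draw_background(rng, q, size):
    return rng.choice(N_AA, size=size, p=q)


def generate(spec: PlantedSpec) -> tuple:
    """Generate (MSA, SyntheticTruth) from a planted specification."""
    rng = np.random.default_rng(spec.seed)
    q = (
        packaged_background().q
        if spec.background is None
        else np.asarray(spec.background, float)
    )
    q = q / q.sum()
    M, L = spec.M, spec.L

    sector_of_position = np.full(L, -1, dtype=int)
    for si, sec in enumerate(spec.sectors):
        sector_of_position[list(sec.positions)] = si
    free = np.flatnonzero(sector_of_position < 0)
    n_inv = int(round(spec.invariant_fraction * L))
    if n_inv > len(free):
        raise ValueError("not enough non-sector positions for invariant_fraction")
    invariant = rng.choice(free, size=n_inv, replace=False) if n_inv else np.array([], int)

    codes = np.empty((M, L), dtype=np.int64)
    # background / near-invariant positions
    for i in range(L):
        if sector_of_position[i] >= 0:
            continue
        codes[:, i] = _draw_background(rng, q, M)
    consensus = {}
    for i in invariant:
        # consensus residues follow the background distribution, so the
        # conservation spikes of invariant positions stay comparable to
        # one another (rare-residue consensus is correspondingly rare)
        consensus[int(i)] = int(rng.choice(N_AA, p=q))
        keep = rng.random(M) < spec.invariant_conservation
        codes[keep, i] = consensus[int(i)]
        # non-consensus draws stay background

    # planted sectors via latent on/off states
    preferred: dict = {}
    for si, sec in enumerate(spec.sectors):
        pref = (
            [AMINO_ACIDS.index(r) for r in sec.preferred]
            if sec.preferred is not None
            else rng.integers(N_AA, size=len(sec.positions)).tolist()
        )
        for p, r in zip(sec.positions, pref):
            preferred[int(p)] = int(r)
        z = rng.random(M) < sec.on_probability
        for p, r in zip(sec.positions, pref):
            col = _draw_background(rng, q, M)
            show = z & (rng.random(M) < sec.rho)
            col[show] = r
            codes[:, p] = col

    # subfamily swap maps
    subfamily = np.full(M, -1, dtype=int)
    start = 0
    for fi, sf in enumerate(spec.subfamilies):
        n = int(round(sf.fraction * M))
        members = np.arange(start, min(start + n, M))
        start += n
        subfamily[members] = fi
        for pos, res in sf.swaps.items():
            if pos not in preferred:
                raise ValueError(f"swap position {pos} is not a sector position")
            res_code = AMINO_ACIDS.index(res)
            col = codes[members, pos]
            col[col == preferred[pos]] = res_code
            codes[members, pos] = col

    # redundancy: append mutated near-copies
    if spec.redundancy.duplication_factor > 1:
        extra_codes, extra_sub = [], []
        for _ in range(spec.redundancy.duplication_factor - 1):
            copy = codes[:M].copy()
            if spec.redundancy.mutation_rate > 0:
                mutate = rng.random(copy.shape) < spec.redundancy.mutation_rate
                copy[mutate] = _draw_background(rng, q, int(mutate.sum()))
            extra_codes.append(copy)
            extra_sub.append(subfamily[:M].copy())
        codes = np.vstack([codes] + extra_codes)
        subfamily = np.concatenate([subfamily] + extra_sub)

    lookup = np.array(list(AMINO_ACIDS))
    rows = tuple("".join(lookup[codes[s]]) for s in range(codes.shape[0]))
    ids = tuple(f"seq{s:05d}" for s in range(codes.shape[0]))
    descs = tuple(
        f"subfamily={subfamily[s]}" if subfamily[s] >= 0 else ""
        for s in range(codes.shape[0])
    )
    msa = MSA(ids=ids, rows=rows, descriptions=descs)
    truth = SyntheticTruth(
        spec=spec,
        sector_of_position=tuple(int(v) for v in sector_of_position),
        subfamily_of_sequence=tuple(int(v) for v in subfamily),
        invariant_positions=tuple(sorted(int(i) for i in invariant)),
        preferred_residues={k: AMINO_ACIDS[v] for k, v in preferred.items()},
    )
    return msa, truth


def spec_from_json(path) -> PlantedSpec:
    """Load a PlantedSpec from a JSON document (the CLI input schema)."""
    with open(path) as fh:
        doc = json.load(fh)
    sectors = tuple(
        SectorSpec(
            positions=tuple(s["positions"]),
            rho=s.get("rho", 0.9),
            preferred=tuple(s["preferred"]) if "preferred" in s else None,
            on_probability=s.get("on_probability", 0.5),
        )
        for s in doc.get("sectors", [])
    )
    subfamilies = tuple(
        SubfamilySpec(
            fraction=sf["fraction"],
            swaps={int(k): v for k, v in sf.get("swaps", {}).items()},
        )
        for sf in doc.get("subfamilies", [])
    )
    red = doc.get("redundancy", {})
    return PlantedSpec(
        M=doc["M"],
        L=doc["L"],
        sectors=sectors,
        subfamilies=subfamilies,
        redundancy=RedundancySpec(
            duplication_factor=red.get("duplication_factor", 1),
            mutation_rate=red.get("mutation_rate", 0.0),
        ),
        invariant_fraction=doc.get("invariant_fraction", 0.0),
        invariant_conservation=doc.get("invariant_conservation", 0.9),
        seed=doc.get("seed", 0),
    )
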