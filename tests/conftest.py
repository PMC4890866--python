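"""Shared fixtures: toy alignments and cached synthetic pipeline runs."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from scakit.coevolution import background, sca_matrix
from scakit.decomposition import eigendecompose, ica, null_spectra, select_k_star
from scakit.msa_io import MSA
from scakit.preprocessing import PreprocessParams, preprocess
from scakit.sectors import identify_sectors
from scakit.synthetic import PlantedSpec, SectorSpec, SubfamilySpec, generate


@pytest.fixture
def tiny_msa():
    return MSA(
        ids=("s1", "s2", "s3"),
        rows=("ACD-", "ACD-", "AC--"),
    )


@pytest.fixture
def tiny_fasta(tmp_path, tiny_msa):
    path = tmp_path / "tiny.fasta"
    with open(path, "w") as fh:
        for rid, row in zip(tiny_msa.ids, tiny_msa.rows):
            fh.write(f">{rid}\n{row}\n")
    return path


@dataclass
class PipelineRun:
    """One end-to-end run on a synthetic alignment, with its ground truth."""

    truth: object
    processed: object
    coevo: object
    spectrum: object
    ica_result: object
    model: object

    @property
    def recovered_positions(self) -> set:
        return {p for ps in self.model.sectors_as_positions() for p in ps}

    def matched_jaccard(self, planted: list) -> list:
        """Best-match Jaccard for each planted position set."""
        reported = [set(ps) for ps in self.model.sectors_as_positions()]
        return [
            max((len(t & r) / len(t | r) for r in reported), default=0.0)
            for t in (set(t) for t in planted)
        ]


def run_pipeline(spec: PlantedSpec, n_trials: int = 10, seed: int | None = None):
    """Full analysis of one synthetic alignment (no file round-trips)."""
    if seed is None:
        seed = spec.seed
    msa, truth = generate(spec)
    processed = preprocess(msa, PreprocessParams())
    bg = background(processed.msa.codes(), processed.weights.w)
    coevo = sca_matrix(processed, bg=bg)
    spectrum = eigendecompose(coevo.matrix)
    null = null_spectra(processed, bg, n_trials=n_trials, seed=seed)
    spectrum = select_k_star(spectrum, null)
    ica_result = None
    model = None
    if spectrum.k_star and spectrum.k_star > 0:
        ica_result = ica(spectrum.eigenvectors[:, : spectrum.k_star], seed=seed)
        model = identify_sectors(coevo.matrix, ica_result.ics)
    return PipelineRun(
        truth=truth,
        processed=processed,
        coevo=coevo,
        spectrum=spectrum,
        ica_result=ica_result,
        model=model,
    )


def two_sector_spec(seed: int, invariant_fraction: float = 0.0) -> PlantedSpec:
    """The canonical two-planted-sector benchmark alignment."""
    return PlantedSpec(
        M=500,
        L=100,
        sectors=(
            SectorSpec(positions=tuple(range(10)), rho=0.9),
            SectorSpec(positions=tuple(range(10, 20)), rho=0.9),
        ),
        invariant_fraction=invariant_fraction,
        seed=seed,
    )


def hierarchy_spec(seed: int) -> PlantedSpec:
    """One sector split across two subfamilies plus an independent sector."""
    return PlantedSpec(
        M=500,
        L=100,
        sectors=(
            SectorSpec(positions=tuple(range(10)), rho=0.9, preferred=("H",) * 10),
            SectorSpec(positions=tuple(range(10, 20)), rho=0.9, preferred=("E",) * 10),
        ),
        subfamilies=(
            SubfamilySpec(fraction=0.5, swaps={p: "W" for p in range(5)}),
            SubfamilySpec(fraction=0.5, swaps={}),
        ),
        seed=seed,
    )


@pytest.fixture(scope="session")
def planted_runs():
    """20 seeded runs of the clean two-sector benchmark (no decoys)."""
    return [run_pipeline(two_sector_spec(seed)) for seed in range(20)]


@pytest.fixture(scope="session")
def planted_runs_with_decoys():
    """20 seeded runs with 10% near-invariant background positions."""
    return [
        run_pipeline(two_sector_spec(seed, invariant_fraction=0.1))
        for seed in range(20)
    ]


@pytest.fixture(scope="session")
def hierarchy_runs():
    """Three seeded runs of the split-sector hierarchy benchmark."""
    return [run_pipeline(hierarchy_spec(seed)) for seed in range(3)]
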