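"""Benchmark workflows for PFAM protein families.

Runs the standard pipeline on a PFAM full alignment with the default
thresholds and a family-specific reference sequence, reporting the retained
position count, the number of significant eigenmodes, and the number of
positions selected across the ICs.  Alignments are not downloaded here;
callers supply a local Stockholm/FASTA file (e.g. a PFAM release 27.0 full
alignment).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from .coevolution import background, sca_matrix
from .decomposition import eigendecompose, ica, null_spectra, select_k_star
from .msa_io import MSA, read_alignment
from .preprocessing import PreprocessParams, preprocess
from .sectors import identify_sectors

#: family accession -> substring of the reference sequence id in PFAM
#: (human H-Ras, E. coli DHFR, E. coli TEM-1 beta-lactamase)
REFERENCE_PATTERNS = {
    "PF00071": "RASH_HUMAN",
    "PF00186": "DYR_ECOLI",
    "PF13354": "BLAT_ECOLI",
}


@dataclass(frozen=True)
class FamilyResult:
    accession: str
    n_positions: int
    m_sequences: int
    m_eff: float
    k_star: Optional[int] = None
    n_ic_positions: Optional[int] = None


def find_reference(msa: MSA, pattern: str) -> str:
    matches = [rid for rid in msa.ids if pattern in rid]
    if not matches:
        raise ValueError(f"no sequence id matching {pattern!r} in the alignment")
    return matches[0]


def load_family(path, accession: str) -> MSA:
    path = Path(path)
    fmt = "stockholm" if path.suffix in (".sto", ".stockholm", ".an") else "fasta"
    if path.suffix == ".an":
        fmt = "fasta"
    return read_alignment(path, fmt)


def analyze_family(
    path,
    accession: str,
    seed: int = 0,
    n_trials: int = 10,
    cdf_cutoff: float = 0.95,
    full: bool = True,
) -> FamilyResult:
    """Preprocess (and optionally fully analyze) one PFAM family alignment.

    ``full=False`` stops after preprocessing (position counts only).
    """
    pattern = REFERENCE_PATTERNS[accession]
    msa = load_family(path, accession)
    reference_id = find_reference(msa, pattern)
    params = PreprocessParams(resample=True, seed=seed)
    processed = preprocess(msa, params, reference_id=reference_id)
    result = FamilyResult(
        accession=accession,
        n_positions=processed.msa.L,
        m_sequences=processed.msa.M,
        m_eff=processed.m_eff,
    )
    if not full:
        return result
    codes = processed.msa.codes()
    bg = background(codes, processed.weights.w)
    coevo = sca_matrix(processed, bg=bg)
    spectrum = eigendecompose(coevo.matrix)
    null = null_spectra(processed, bg, n_trials=n_trials, seed=seed)
    spectrum = select_k_star(spectrum, null)
    n_ic_positions = None
    if spectrum.k_star and spectrum.k_star > 0:
        res = ica(spectrum.eigenvectors[:, : spectrum.k_star], seed=seed)
        model = identify_sectors(coevo.matrix, res.ics, cdf_cutoff=cdf_cutoff)
        n_ic_positions = len(model.order)
    return FamilyResult(
        accession=accession,
        n_positions=processed.msa.L,
        m_sequences=processed.msa.M,
        m_eff=processed.m_eff,
        k_star=spectrum.k_star,
        n_ic_positions=n_ic_positions,
    )
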