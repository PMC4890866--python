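"""End-to-end orchestration: process -> core -> sectors -> report.

Every stage's outputs are written into one results bundle directory:
processed alignment (FASTA), weights CSV, position map CSV, coevolution
matrix (.npz + TSV), spectrum/null CSVs, ICs, sequence coordinates,
per-IC position sets, sector assignments, and a summary JSON with the
full effective configuration.  Identical seed and inputs give an
identical bundle (timestamps excluded).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .coevolution import background, sca_matrix
from .decomposition import eigendecompose, ica, null_spectra, select_k_star
from .msa_io import (
    AnnotationTable,
    MSA,
    parse_annotations,
    read_alignment,
    write_fasta,
    write_position_map,
)
from .preprocessing import PreprocessParams, preprocess
from .sectors import identify_sectors
from .seqspace import sequence_projection

logger = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "msa",
    "format",
    "reference_id",
    "position_labels",
    "annotations",
    "annotation_id_column",
    "output_dir",
    "seed",
    "preprocess",
    "lam",
    "norm_kind",
    "n_null_trials",
    "cdf_cutoff",
    "group_threshold",
    "manual_sectors",
    "background_mode",
}
_PREPROCESS_KEYS = {f.name for f in dataclasses.fields(PreprocessParams)}


@dataclass(frozen=True)
class RunConfig:
    msa: str
    output_dir: str
    format: str = "fasta"
    reference_id: Optional[str] = None
    position_labels: Optional[tuple] = None
    annotations: Optional[str] = None
    annotation_id_column: str = "id"
    seed: int = 0
    preprocess: PreprocessParams = PreprocessParams()
    lam: float = 0.03
    norm_kind: str = "frobenius"
    n_null_trials: int = 10
    cdf_cutoff: float = 0.95
    group_threshold: float = 0.25
    manual_sectors: Optional[tuple] = None
    background_mode: str = "packaged"

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        unknown = set(doc) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        doc = dict(doc)
        pp = doc.pop("preprocess", {})
        if isinstance(pp, dict):
            bad = set(pp) - _PREPROCESS_KEYS
            if bad:
                raise ValueError(f"unknown preprocess keys: {sorted(bad)}")
            pp = PreprocessParams(**pp)
        return cls(preprocess=pp, **doc)

    def effective(self) -> dict:
        doc = dataclasses.asdict(self)
        doc["version"] = __version__
        return doc


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_all(config: RunConfig) -> dict:
    """Run the full pipeline and write the results bundle.

    Returns the summary dict.  A stage failure raises :class:`StageError`
    after preserving whatever partial outputs were already written.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": config.effective(), "status": "running"}

    def fail(stage, exc):
        summary["status"] = f"failed:{stage}"
        _write_summary(out, summary)
        raise StageError(stage, exc) from exc

    # ---- process ----
    try:
        msa = read_alignment(config.msa, config.format)
        seed_params = dataclasses.replace(config.preprocess, seed=config.seed)
        processed = preprocess(
            msa,
            seed_params,
            reference_id=config.reference_id,
            position_labels=config.position_labels,
        )
        write_fasta(processed.msa, out / "processed.fasta")
        np.savetxt(
            out / "weights.csv",
            np.column_stack(
                [np.arange(processed.msa.M), processed.weights.w]
            ),
            delimiter=",",
            header="sequence_index,weight",
            comments="",
            fmt=["%d", "%.10g"],
        )
        if processed.position_map is not None:
            write_position_map(processed.position_map, out / "position_map.csv")
        with open(out / "provenance.json", "w") as fh:
            json.dump(
                [
                    {"step": s, "removed": r if isinstance(r, int) else len(r),
                     "detail": str(p)[:2000]}
                    for s, r, p in processed.provenance
                ],
                fh,
                indent=2,
            )
        summary["processed"] = {
            "M": processed.msa.M,
            "L": processed.msa.L,
            "m_eff": processed.m_eff,
        }
    except Exception as exc:
        fail("process", exc)

    # ---- core ----
    try:
        codes = processed.msa.codes()
        bg = background(codes, processed.weights.w, mode=config.background_mode,
                        lam=config.lam)
        coevo = sca_matrix(processed, bg=bg, lam=config.lam,
                           norm_kind=config.norm_kind)
        spectrum = eigendecompose(coevo.matrix)
        null = null_spectra(
            processed, bg, n_trials=config.n_null_trials, seed=config.seed,
            lam=config.lam, norm_kind=config.norm_kind,
        )
        spectrum = select_k_star(spectrum, null)
        np.savez_compressed(
            out / "core.npz",
            matrix=coevo.matrix,
            projection=coevo.projection,
            reduced=coevo.reduced,
            eigenvalues=spectrum.eigenvalues,
            eigenvectors=spectrum.eigenvectors,
            null_eigenvalues=spectrum.null_eigenvalues,
        )
        np.savetxt(out / "coevolution_matrix.tsv", coevo.matrix, delimiter="\t")
        np.savetxt(
            out / "spectrum.csv",
            np.column_stack([spectrum.eigenvalues,
                             spectrum.null_eigenvalues.mean(axis=0)]),
            delimiter=",",
            header="eigenvalue,null_mean",
            comments="",
        )
        summary["core"] = {
            "k_star": spectrum.k_star,
            "cutoff": spectrum.cutoff,
            "top_eigenvalues": spectrum.eigenvalues[:10].tolist(),
            "norm_kind": config.norm_kind,
            "ica_algorithm": "infomax-tanh",
        }
    except Exception as exc:
        fail("core", exc)

    if spectrum.k_star == 0:
        summary["status"] = "no significant eigenmodes"
        summary["sectors"] = []
        _write_summary(out, summary)
        logger.warning("no significant eigenmodes; stopping cleanly")
        return summary

    # ---- ICA + sequence space ----
    try:
        ica_result = ica(spectrum.eigenvectors[:, : spectrum.k_star],
                         seed=config.seed)
        seqspace = sequence_projection(coevo.reduced, spectrum, ica_result)
        np.savetxt(
            out / "ics.csv",
            ica_result.ics,
            delimiter=",",
            header=",".join(f"IC{p + 1}" for p in range(ica_result.ics.shape[1])),
            comments="",
        )
        header = ",".join(
            [f"U{p + 1}" for p in range(seqspace.U.shape[1])]
            + [f"ICU{p + 1}" for p in range(seqspace.U_p.shape[1])]
        )
        np.savetxt(
            out / "sequence_coordinates.csv",
            np.column_stack([seqspace.U, seqspace.U_p]),
            delimiter=",",
            header=header,
            comments="",
        )
        summary["ica"] = {"converged": ica_result.converged,
                          "iterations": ica_result.iterations}
    except Exception as exc:
        fail("seqspace", exc)

    # ---- sectors ----
    try:
        model = identify_sectors(
            coevo.matrix,
            ica_result.ics,
            cdf_cutoff=config.cdf_cutoff,
            group_threshold=config.group_threshold,
            manual=config.manual_sectors,
        )
        pmap = processed.position_map
        with open(out / "ic_positions.csv", "w") as fh:
            fh.write("ic,rank,column_index,reference_label,loading\n")
            for s in model.ic_sets:
                labels = s.labels(pmap)
                for rank, (pos, lab, load) in enumerate(
                    zip(s.positions, labels, s.loadings)
                ):
                    fh.write(f"{s.ic_index + 1},{rank + 1},{pos},{lab},{load:.6g}\n")
        np.savetxt(out / "submatrix.tsv", model.submatrix, delimiter="\t")
        with open(out / "sectors.txt", "w") as fh:
            for n, group in enumerate(model.sector_assignments):
                positions = sorted(
                    p for s in model.ic_sets if s.ic_index in group
                    for p in s.positions
                )
                labels = [pmap.label(p) or str(p) for p in positions] if pmap \
                    else [str(p) for p in positions]
                fh.write(f"sector_{n + 1}\tICs={[g + 1 for g in group]}\t"
                         + "+".join(labels) + "\n")
        summary["sectors"] = [
            {
                "sector": n + 1,
                "ics": [g + 1 for g in group],
                "size": sum(len(s.positions) for s in model.ic_sets
                            if s.ic_index in group),
            }
            for n, group in enumerate(model.sector_assignments)
        ]
        summary["n_selected_positions"] = len(model.order)
        summary["grouping_mode"] = model.mode
    except Exception as exc:
        fail("sectors", exc)

    summary["status"] = "ok"
    _write_summary(out, summary)
    return summary


def _write_summary(out: Path, summary: dict) -> None:
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
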