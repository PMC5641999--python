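"""Delimited-text readers and writers for the pipeline artifacts.

All artifacts are plain text: a spectra matrix (first column ppm, one
column per sample), a sample-metadata table, a binned feature table with
a JSON provenance sidecar, and JSON model records.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .chemometrics import OplsModel, ScaledMatrix
from .nmrproc import BinnedMatrix, Spectrum
from .simcohort import CohortDesign, LabeledSpectrumSet

__all__ = [
    "write_spectra_matrix",
    "read_spectra_matrix",
    "write_metadata",
    "read_metadata",
    "write_truth",
    "write_binned_matrix",
    "read_binned_matrix",
    "save_opls_model",
    "load_opls_model",
]


def write_spectra_matrix(path, spectra: list[Spectrum], sample_ids: list[str]):
    """Spectra as CSV: first column ppm, one intensity column per sample."""
    data = {"ppm": spectra[0].ppm}
    for sid, spec in zip(sample_ids, spectra):
        data[sid] = spec.intensity
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.10g")


def read_spectra_matrix(path) -> tuple[list[Spectrum], list[str]]:
    df = pd.read_csv(path)
    ppm = df.iloc[:, 0].to_numpy(dtype=float)
    sample_ids = list(df.columns[1:])
    spectra = [Spectrum(ppm, df[c].to_numpy(dtype=float)) for c in sample_ids]
    return spectra, sample_ids


def write_metadata(path, sample_ids, groups, time_points=None):
    df = pd.DataFrame(
        {
            "sample_id": list(sample_ids),
            "group": list(groups),
            "time_point": list(time_points) if time_points is not None else 0,
        }
    )
    df.to_csv(path, index=False)


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"sample_id", "group"}
    if not required <= set(df.columns):
        raise ValueError(f"metadata must contain columns {sorted(required)}")
    return df


def _design_record(design: CohortDesign) -> dict:
    rec = dataclasses.asdict(design)
    rec["library"] = [
        {"name": t.name, "components": [list(c) for c in t.components]}
        for t in design.library
    ]
    rec["groups"] = [list(g) for g in design.groups]
    rec["shared_factors"] = [
        [list(m), w] for m, w in design.shared_factors
    ]
    return rec


def write_truth(path, cohort: LabeledSpectrumSet):
    """JSON record of the generating design (the ground truth)."""
    Path(path).write_text(json.dumps(_design_record(cohort.truth), indent=2))


def write_binned_matrix(path, matrix: BinnedMatrix, provenance_path=None):
    """Feature table as TSV (rows = samples) plus a JSON sidecar with the
    bin edges, exclusions and alignment shifts."""
    df = pd.DataFrame(
        matrix.values,
        index=list(matrix.sample_ids),
        columns=[f"{c:.4f}" for c in matrix.bin_centers],
    )
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%.12g")
    if provenance_path is not None:
        prov = {
            "bin_edges": matrix.bin_edges.tolist(),
            "excluded_regions": [list(r) for r in matrix.excluded_regions],
            "aligned_regions": [list(r) for r in matrix.aligned_regions],
            "normalized": matrix.normalized,
            "alignment_shifts": {
                f"{lo:g}-{hi:g}": shifts.tolist()
                for (lo, hi), shifts in (matrix.alignment_shifts or {}).items()
            },
        }
        Path(provenance_path).write_text(json.dumps(prov, indent=2))


def read_binned_matrix(path, provenance_path=None) -> BinnedMatrix:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    values = df.to_numpy(dtype=float)
    if provenance_path is not None:
        prov = json.loads(Path(provenance_path).read_text())
        edges = np.asarray(prov["bin_edges"], dtype=float)
        return BinnedMatrix(
            values=values,
            bin_edges=edges,
            sample_ids=tuple(df.index),
            excluded_regions=tuple(tuple(r) for r in prov["excluded_regions"]),
            aligned_regions=tuple(tuple(r) for r in prov["aligned_regions"]),
            normalized=bool(prov["normalized"]),
        )
    centers = df.columns.to_numpy(dtype=float)
    width = float(np.median(np.abs(np.diff(centers)))) or 0.004
    edges = np.column_stack([centers + width / 2, centers - width / 2])
    return BinnedMatrix(values=values, bin_edges=edges, sample_ids=tuple(df.index))


def save_opls_model(path, model: OplsModel):
    rec = {
        "w": model.w.tolist(),
        "p_pred": model.p_pred.tolist(),
        "w_orth": model.w_orth.tolist(),
        "p_orth": model.p_orth.tolist(),
        "t_pred": model.t_pred.tolist(),
        "t_orth": model.t_orth.tolist(),
        "b": model.b,
        "y_encoding": model.y_encoding,
        "scaling": {
            "column_means": model.scaling.column_means.tolist(),
            "column_sds": model.scaling.column_sds.tolist(),
            "mode": model.scaling.mode,
            "kept": model.scaling.kept.tolist(),
        },
    }
    Path(path).write_text(json.dumps(rec))


def load_opls_model(path) -> OplsModel:
    rec = json.loads(Path(path).read_text())
    sc = rec["scaling"]
    scaling = ScaledMatrix(
        values=np.empty((0, len(sc["column_means"]))),
        column_means=np.asarray(sc["column_means"]),
        column_sds=np.asarray(sc["column_sds"]),
        mode=sc["mode"],
        kept=np.asarray(sc["kept"], dtype=bool),
    )
    return OplsModel(
        w=np.asarray(rec["w"]),
        t_pred=np.asarray(rec["t_pred"]),
        p_pred=np.asarray(rec["p_pred"]),
        w_orth=np.asarray(rec["w_orth"]),
        t_orth=np.asarray(rec["t_orth"]),
        p_orth=np.asarray(rec["p_orth"]),
        b=float(rec["b"]),
        scaling=scaling,
        y_encoding=rec["y_encoding"],
    )
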