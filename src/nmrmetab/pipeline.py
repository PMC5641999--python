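"""Config-driven end-to-end runs.

A run simulates (or ingests) a cohort, preprocesses it into the binned
feature matrix, gates outliers once on the pooled cohort by Hotelling's
T2, then for every configured group contrast fits PLS-DA / O-PLS-DA,
validates (sevenfold CV, permutation test, CV-ANOVA, AUC) and writes a
validation grid, per-contrast loading profiles, significant-bin tables,
serialized models and a provenance log.  Fixed seed implies
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chemometrics import (
    backscaled_loadings,
    detect_outliers,
    encode_labels,
    fit_opls_da,
    fit_pca,
    scale_matrix,
    significant_bins,
)
from .io import (
    read_binned_matrix,
    read_metadata,
    read_spectra_matrix,
    write_binned_matrix,
    write_metadata,
    write_spectra_matrix,
    write_truth,
    save_opls_model,
)
from .nmrproc import BinnedMatrix, ProcessingConfig, preprocess_spectra
from .simcohort import CohortDesign, simulate_cohort
from .validation import ValidationReport, validate_contrast

logger = logging.getLogger("nmrmetab")

MIN_GROUP_SIZE = 3

__all__ = ["RunConfig", "run", "report_validation_grid", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    """Everything one end-to-end run needs.

    Exactly one of ``design`` (simulate) or ``spectra_path`` +
    ``metadata_path`` (ingest) must be set.
    """

    contrasts: tuple[tuple[str, str], ...]
    design: CohortDesign | None = None
    spectra_path: str | None = None
    metadata_path: str | None = None
    processing: ProcessingConfig = field(default_factory=ProcessingConfig)
    k: int = 7
    n_perm: int = 200
    alpha: float = 0.05
    pca_components: int = 2
    seed: int = 0

    def __post_init__(self):
        if (self.design is None) == (self.spectra_path is None):
            raise ValueError("set exactly one of design or spectra_path")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


def load_config(path) -> RunConfig:
    """Build a RunConfig from a YAML file (see the README for the schema)."""
    raw = yaml.safe_load(Path(path).read_text())
    design = None
    spectra_path = metadata_path = None
    if "simulate" in raw:
        sim = dict(raw["simulate"])
        groups = tuple((g["label"], int(g["n"])) for g in sim.pop("groups"))
        effects = {
            m: {g: float(f) for g, f in per.items()}
            for m, per in sim.pop("effects", {}).items()
        }
        design = CohortDesign(groups=groups, effects=effects,
                              seed=int(raw.get("seed", 0)), **sim)
    else:
        spectra_path = raw["ingest"]["spectra"]
        metadata_path = raw["ingest"]["metadata"]
    processing = ProcessingConfig(**{
        k: tuple(map(tuple, v)) if k == "align_regions"
        else tuple(v) if isinstance(v, list) else v
        for k, v in raw.get("processing", {}).items()
    })
    val = raw.get("validation", {})
    return RunConfig(
        contrasts=tuple((c[0], c[1]) for c in raw["contrasts"]),
        design=design,
        spectra_path=spectra_path,
        metadata_path=metadata_path,
        processing=processing,
        k=int(val.get("k", 7)),
        n_perm=int(val.get("n_perm", 200)),
        alpha=float(val.get("alpha", 0.05)),
        pca_components=int(raw.get("pca_components", 2)),
        seed=int(raw.get("seed", 0)),
    )


def _acquire(config: RunConfig, outdir: Path):
    if config.design is not None:
        cohort = simulate_cohort(config.design)
        write_spectra_matrix(outdir / "spectra.csv", list(cohort.spectra),
                             list(cohort.sample_ids))
        write_metadata(outdir / "metadata.csv", cohort.sample_ids,
                       cohort.group_labels)
        write_truth(outdir / "truth.json", cohort)
        return list(cohort.spectra), list(cohort.sample_ids), list(cohort.group_labels)
    spectra, sample_ids = read_spectra_matrix(config.spectra_path)
    meta = read_metadata(config.metadata_path).set_index("sample_id")
    groups = [str(meta.loc[sid, "group"]) for sid in sample_ids]
    return spectra, sample_ids, groups


def run(config: RunConfig, output_dir) -> dict:
    """Execute the full pipeline; returns a summary dict of artifacts."""
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(config, outdir)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, outdir: Path) -> dict:
    spectra, sample_ids, groups = _acquire(config, outdir)
    logger.info("cohort: %d samples, groups %s", len(sample_ids),
                sorted(set(groups)))

    matrix = preprocess_spectra(spectra, sample_ids, config.processing)
    write_binned_matrix(outdir / "binned.tsv", matrix,
                        outdir / "binned_provenance.json")

    # one pooled outlier gate before any contrast is fitted
    scaled = scale_matrix(matrix, "unit_variance")
    pca = fit_pca(scaled, config.pca_components)
    outliers = detect_outliers(pca, config.alpha)
    excluded_ids = [sample_ids[i] for i in np.where(outliers)[0]]
    logger.info("Hotelling T2 gate: %d outliers excluded %s",
                len(excluded_ids), excluded_ids)
    matrix = matrix.subset_samples(~outliers)
    groups = [g for g, o in zip(groups, outliers) if not o]

    ss = np.random.SeedSequence(config.seed)
    contrast_seeds = [int(s.generate_state(1)[0] % 2**31)
                      for s in ss.spawn(len(config.contrasts))]

    reports: dict[str, ValidationReport] = {}
    for (pos, ref), cseed in zip(config.contrasts, contrast_seeds):
        name = f"{pos}_vs_{ref}"
        mask = np.array([g in (pos, ref) for g in groups])
        sub_groups = [g for g in groups if g in (pos, ref)]
        n_pos = sub_groups.count(pos)
        n_ref = sub_groups.count(ref)
        if n_pos < MIN_GROUP_SIZE or n_ref < MIN_GROUP_SIZE:
            logger.warning("contrast %s skipped: group sizes %d/%d below %d",
                           name, n_pos, n_ref, MIN_GROUP_SIZE)
            continue
        sub = matrix.subset_samples(mask)
        y, encoding = encode_labels(sub_groups, positive=pos, reference=ref)
        k = min(config.k, n_pos + n_ref)
        report = validate_contrast(sub.values, y, k=k, n_perm=config.n_perm,
                                   seed=cseed, alpha=config.alpha)
        reports[name] = report
        model = fit_opls_da(scale_matrix(sub, "unit_variance"), y, encoding)
        save_opls_model(outdir / f"model_{name}.json", model)
        profile = backscaled_loadings(model, sub)
        profile.to_frame().to_csv(outdir / f"loadings_{name}.tsv", sep="\t",
                                  index=False, float_format="%.6g")
        significant_bins(profile).to_csv(outdir / f"significant_{name}.tsv",
                                         sep="\t", index=False,
                                         float_format="%.6g")
        logger.info("contrast %s: Q2=%.3f AUC=%.3f valid=%s",
                    name, report.q2, report.auc, report.verdict)

    grid = report_validation_grid(reports)
    grid.to_csv(outdir / "validation_grid.tsv", sep="\t", index=False,
                float_format="%.6g")

    provenance = {
        "version": __version__,
        "seed": config.seed,
        "config": _config_record(config),
        "n_samples": len(sample_ids),
        "outliers_excluded": excluded_ids,
        "contrasts_run": list(reports),
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return {
        "output_dir": str(outdir),
        "reports": reports,
        "outliers": excluded_ids,
        "grid": grid,
    }


def _config_record(config: RunConfig) -> dict:
    rec = {
        "contrasts": [list(c) for c in config.contrasts],
        "k": config.k,
        "n_perm": config.n_perm,
        "alpha": config.alpha,
        "pca_components": config.pca_components,
        "processing": dataclasses.asdict(config.processing),
    }
    if config.design is not None:
        rec["simulated"] = True
        rec["groups"] = [list(g) for g in config.design.groups]
    else:
        rec["spectra_path"] = config.spectra_path
        rec["metadata_path"] = config.metadata_path
    return rec


def report_validation_grid(reports: dict[str, ValidationReport]) -> pd.DataFrame:
    """One row per contrast mirroring the standard validation table:
    PLS-DA Q2, O-PLS-DA Q2/R2, permutation pass, CV-ANOVA p, AUC and the
    conjunction verdict."""
    if not reports:
        raise ValueError("no validation reports to tabulate")
    rows = []
    for name, rep in reports.items():
        rows.append(
            {
                "contrast": name,
                "q2_pls_da": rep.q2_pls,
                "q2_opls_da": rep.q2,
                "r2_opls_da": rep.r2,
                "perm_q2_max": rep.perm_q2_max,
                "permutation_pass": rep.perm_pass,
                "cv_anova_F": rep.cv_anova_F,
                "cv_anova_p": rep.cv_anova_p,
                "cv_anova_pass": rep.cv_anova_pass,
                "auc": rep.auc,
                "valid": rep.verdict,
            }
        )
    return pd.DataFrame(rows)
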