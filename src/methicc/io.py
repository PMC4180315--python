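"""Readers and writers for the pipeline's tabular formats.

Beta and detection-p matrices are TSV (optionally gzip-compressed) with probes
as rows and a header of sample IDs; sample sheets and probe annotation are
CSV.  All readers validate on load and raise named errors with coordinates.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "read_beta_matrix",
    "read_detection_p",
    "read_sample_sheet",
    "read_annotation",
    "validate_study",
    "write_study",
]

ISLAND_LEVELS = {"island", "shore", "shelf", "open_sea"}
DESIGN_LEVELS = {"I", "II"}
REQUIRED_SHEET_COLS = ("subject_id", "chip")


class DuplicateIDError(ValueError):
    pass


class DimensionMismatchError(ValueError):
    pass


class UnknownLevelError(ValueError):
    pass


def _read_matrix(path: str | Path, what: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise DuplicateIDError(f"{what}: duplicate probe IDs, e.g. {dups}")
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].unique().tolist()[:5]
        raise DuplicateIDError(f"{what}: duplicate sample IDs, e.g. {dups}")
    vals = df.to_numpy(dtype=float)
    bad = np.argwhere((vals < 0) | (vals > 1))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"{what}: value {vals[i, j]} out of [0, 1] at probe {df.index[i]!r}, sample {df.columns[j]!r}"
        )
    return df


def read_beta_matrix(path: str | Path) -> pd.DataFrame:
    return _read_matrix(path, "beta matrix")


def read_detection_p(path: str | Path) -> pd.DataFrame:
    return _read_matrix(path, "detection-p matrix")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, index_col=0)
    if sheet.index.duplicated().any():
        raise DuplicateIDError("sample sheet: duplicate sample IDs")
    missing = [c for c in REQUIRED_SHEET_COLS if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet lacks required columns {missing}")
    return sheet


def read_annotation(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, index_col=0)
    if ann.index.duplicated().any():
        raise DuplicateIDError("annotation: duplicate probe IDs")
    if "design_type" in ann.columns:
        bad = set(ann["design_type"].dropna().unique()) - DESIGN_LEVELS
        if bad:
            raise UnknownLevelError(f"annotation: unknown design_type levels {sorted(bad)}")
    if "island_relation" in ann.columns:
        bad = set(ann["island_relation"].dropna().unique()) - ISLAND_LEVELS
        if bad:
            raise UnknownLevelError(f"annotation: unknown island_relation levels {sorted(bad)}")
    for flag in ("snp_within_50bp", "cross_reactive"):
        if flag in ann.columns:
            ann[flag] = ann[flag].astype(bool)
    return ann


def validate_study(
    beta: pd.DataFrame,
    detp: pd.DataFrame | None = None,
    sheet: pd.DataFrame | None = None,
    annotation: pd.DataFrame | None = None,
) -> None:
    """Cross-validate a study's tables against the beta matrix."""
    if detp is not None and (not beta.index.equals(detp.index) or not beta.columns.equals(detp.columns)):
        raise DimensionMismatchError("beta and detection-p matrices have different probe/sample indices")
    if sheet is not None:
        unknown = [s for s in sheet.index if s not in set(beta.columns)]
        if unknown:
            raise DimensionMismatchError(f"sample sheet references samples absent from the beta matrix: {unknown[:5]}")
        absent = [s for s in beta.columns if s not in set(sheet.index)]
        if absent:
            raise DimensionMismatchError(f"beta matrix samples missing from the sample sheet: {absent[:5]}")
    if annotation is not None:
        absent = beta.index.difference(annotation.index)
        if len(absent):
            raise DimensionMismatchError(f"probes missing from annotation: {list(absent[:5])}")


def write_study(outdir: str | Path, beta, detp, sheet, annotation, truth=None, config=None) -> dict[str, Path]:
    """Write a study to disk: gzip TSV matrices, CSV sheet/annotation,
    TSV truth table, and the generating config echoed as YAML."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "beta": out / "beta.tsv.gz",
        "detection_p": out / "detection_p.tsv.gz",
        "sample_sheet": out / "sample_sheet.csv",
        "annotation": out / "annotation.csv",
    }
    beta.to_csv(paths["beta"], sep="\t")
    detp.to_csv(paths["detection_p"], sep="\t")
    sheet.to_csv(paths["sample_sheet"])
    annotation.to_csv(paths["annotation"])
    if truth is not None:
        paths["truth_probes"] = out / "truth_probes.tsv"
        truth.probes.to_csv(paths["truth_probes"], sep="\t")
        paths["truth_samples"] = out / "truth_samples.tsv"
        truth.samples.to_csv(paths["truth_samples"], sep="\t")
    if config is not None:
        paths["config"] = out / "sim_config.yaml"
        d = {k: v for k, v in config.__dict__.items() if not k.startswith("_")}
        d["variance_law"] = dict(config.variance_law.__dict__)
        with open(paths["config"], "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(d, default=float)), fh)
    return paths
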