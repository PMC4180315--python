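"""Stratified summaries and the end-to-end pipeline.

Composes qc -> icc -> mixture fitting -> classification -> association ->
summaries, writing every stage's table plus a JSON manifest that records all
thresholds, so a run can be reproduced from the manifest alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import icc as icc_mod
from . import io as io_mod
from . import mixture as mix_mod
from . import qc as qc_mod
from .ewas import EwasConfig, run_ewas, summarize_by_cluster
from .synthetic import SimulationConfig, simulate_methylation_study

__all__ = ["RunConfig", "stratified_icc_summary", "run_pipeline"]

log = logging.getLogger("methicc")

HIST_BINS = np.round(np.arange(0.0, 1.0001, 0.05), 10)  # fixed width 0.05 for comparability
STRATA_FACTORS = ("design_type", "island_relation", "cross_reactive", "snp_within_50bp")


def stratified_icc_summary(
    table: pd.DataFrame,
    annotation: pd.DataFrame,
    thresholds: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8),
) -> pd.DataFrame:
    """Distribution of ICC within annotation strata.

    For each level of each annotation factor (probe design type, CpG-island
    relation, cross-reactive flag, SNP flag): probe count, the fraction of
    probes with ICC above each threshold, and histogram counts on [0, 1] with
    bin width 0.05.  Empty strata are simply absent from the output.
    """
    joined = annotation.join(table[["icc"]], how="inner").dropna(subset=["icc"])
    if joined.empty:
        raise ValueError("no probes shared between ICC table and annotation")
    rows = []
    for factor in STRATA_FACTORS:
        if factor not in joined.columns:
            continue
        for level, grp in joined.groupby(factor, observed=True):
            icc = grp["icc"].to_numpy()
            row: dict = {"factor": factor, "level": str(level), "n": len(icc)}
            for t in thresholds:
                row[f"frac_gt_{t:g}"] = float((icc > t).mean())
            counts, _ = np.histogram(icc, bins=HIST_BINS)
            for lo, c in zip(HIST_BINS[:-1], counts):
                row[f"bin_{lo:.2f}"] = int(c)
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either the four input paths are given, or ``simulate`` is set and the
    study is generated in-memory from ``sim``.
    """

    outdir: str = "methicc_run"
    beta_path: str | None = None
    detp_path: str | None = None
    sheet_path: str | None = None
    annotation_path: str | None = None
    simulate: bool = True
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    detection_alpha: float = 0.01
    min_sample_pass: float = 0.99
    min_probe_pass: float = 0.99
    pi_cutoff: float = 0.01
    ewas_alpha: float = 1e-7
    ewas_mode: str = "lmm"
    run_ewas_stage: bool = True
    classify_model: str = "truncated"
    seed: int = 0

    def validate(self) -> None:
        if not self.simulate:
            for name in ("beta_path", "detp_path", "sheet_path", "annotation_path"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"{name} = {p!r} does not exist")
        self.sim.validate()

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sim_raw = raw.pop("sim", {})
        law_raw = sim_raw.pop("variance_law", {}) if isinstance(sim_raw, dict) else {}
        from .synthetic import VarianceLaw

        sim = SimulationConfig(**sim_raw, variance_law=VarianceLaw(**law_raw))
        return cls(**raw, sim=sim)

    def to_manifest(self) -> dict:
        d = asdict(self)
        return d


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Run the full reliability analysis and write all outputs.

    Outputs under ``config.outdir``: qc_report.json, icc_table.tsv, both
    mixture fits as JSON, classification.tsv, ewas_results.tsv,
    cluster_summary.tsv, stratified_icc.tsv, icc_sd_trend.tsv, icc_hist.tsv
    and manifest.json.  Deterministic for a fixed config.  A stage failure
    aborts with the stage name; outputs already written are kept.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    if config.simulate:
        sim_cfg = config.sim if config.sim.seed == config.seed else None
        if sim_cfg is None:
            d = {k: v for k, v in config.sim.__dict__.items()}
            d["seed"] = config.seed
            sim_cfg = SimulationConfig(**d)
        beta, detp, sheet, annotation, truth = _stage("simulate")(simulate_methylation_study)(sim_cfg)
        results["truth"] = truth
    else:
        beta = io_mod.read_beta_matrix(config.beta_path)
        detp = io_mod.read_detection_p(config.detp_path)
        sheet = io_mod.read_sample_sheet(config.sheet_path)
        annotation = io_mod.read_annotation(config.annotation_path)
        io_mod.validate_study(beta, detp, sheet, annotation)
    log.info("input: %d probes x %d samples", *beta.shape)

    beta_f, qc_report = _stage("qc")(qc_mod.apply_pass_rate_filters)(
        beta, detp, config.min_sample_pass, config.min_probe_pass, config.detection_alpha
    )
    (out / "qc_report.json").write_text(qc_report.to_json())
    (out / "qc_summary.txt").write_text(qc_report.summary() + "\n")
    results["qc_report"] = qc_report
    log.info("qc: %s", qc_report.summary())

    table = _stage("icc")(icc_mod.icc_table)(beta_f, sheet)
    table.to_csv(out / "icc_table.tsv", sep="\t")
    results["icc_table"] = table
    log.info("icc: %d probes, %d unestimable", len(table), int(table.icc.isna().sum()))

    iccs = table["icc"].dropna().to_numpy()
    fit_c = _stage("fit_censored")(mix_mod.fit_censored_mixture)(iccs, seed=config.seed)
    fit_t = _stage("fit_truncated")(mix_mod.fit_truncated_mixture)(iccs, seed=config.seed)
    (out / "fit_censored.json").write_text(fit_c.to_json())
    (out / "fit_truncated.json").write_text(fit_t.to_json())
    winner, ll_diff = mix_mod.compare_models(fit_c, fit_t)
    results.update(fit_censored=fit_c, fit_truncated=fit_t, model_winner=winner.model_kind, loglik_diff=ll_diff)
    log.info("mixture: winner=%s (loglik diff %.1f)", winner.model_kind, ll_diff)

    fit_for_classes = fit_t if config.classify_model == "truncated" else fit_c
    assignment = _stage("classify")(mix_mod.classify_sites)(table, fit_for_classes, config.pi_cutoff)
    assignment.to_csv(out / "classification.tsv", sep="\t")
    results["assignment"] = assignment
    log.info("classify: %s", assignment.attrs["counts"])

    trend = _stage("trend")(icc_mod.icc_sd_trend)(table)
    trend.to_csv(out / "icc_sd_trend.tsv", sep="\t", index=False)
    results["trend"] = trend

    strat = _stage("stratify")(stratified_icc_summary)(table, annotation)
    strat.to_csv(out / "stratified_icc.tsv", sep="\t", index=False)
    results["stratified"] = strat

    hist_counts, _ = np.histogram(iccs, bins=HIST_BINS)
    pd.DataFrame({"bin_left": HIST_BINS[:-1], "count": hist_counts}).to_csv(
        out / "icc_hist.tsv", sep="\t", index=False
    )

    if config.run_ewas_stage:
        ewas_cfg = EwasConfig(mode=config.ewas_mode, alpha=config.ewas_alpha)
        ewas = _stage("ewas")(run_ewas)(beta_f, sheet, annotation, ewas_cfg)
        ewas.to_csv(out / "ewas_results.tsv", sep="\t")
        results["ewas"] = ewas
        common = ewas.index.intersection(assignment.index)
        summary = _stage("cluster_summary")(summarize_by_cluster)(
            ewas.loc[common], assignment.loc[common]
        )
        summary.to_csv(out / "cluster_summary.tsv", sep="\t")
        results["cluster_summary"] = summary
        log.info(
            "ewas: %d significant (%d after SNP mask), fraction in high cluster %.3f",
            ewas.attrs["n_significant"], ewas.attrs["n_significant_unmasked"],
            summary.attrs.get("fraction_high", float("nan")),
        )

    manifest = {
        "config": json.loads(json.dumps(config.to_manifest(), default=str)),
        "mixing_proportion_note": (
            "fitted p is the low-reliability (component-1) proportion; "
            "the high-reliability reading is 1 - p"
        ),
        "n_probes_analyzed": int(len(table)),
        "model_winner": results.get("model_winner"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    results["manifest"] = manifest
    return results
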