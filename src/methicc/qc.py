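"""Detection-p based sample/probe filtering and SNP-proximity masking.

An array entry "passes" detection when its detection p-value is <= the
detection alpha (0.01 by default; the boundary counts as a pass).  Samples
whose pass rate across probes falls below the sample threshold are dropped
first; probe pass rates are then recomputed on the retained samples and
probes below the probe threshold are dropped.  Thresholds are inclusive:
a pass rate exactly at the threshold is retained.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd

__all__ = ["QCReport", "sample_pass_rates", "probe_pass_rates", "apply_pass_rate_filters", "snp_probe_mask"]


@dataclass
class QCReport:
    """Record of a pass-rate filtering run."""

    detection_alpha: float
    min_sample_pass: float
    min_probe_pass: float
    n_samples_before: int
    n_samples_after: int
    n_probes_before: int
    n_probes_after: int
    excluded_samples: dict[str, float] = field(default_factory=dict)
    excluded_probes: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, default=float)

    def summary(self) -> str:
        return (
            f"samples: {self.n_samples_before} -> {self.n_samples_after} "
            f"(excluded {len(self.excluded_samples)} below pass rate {self.min_sample_pass}); "
            f"probes: {self.n_probes_before} -> {self.n_probes_after} "
            f"(excluded {len(self.excluded_probes)} below pass rate {self.min_probe_pass}); "
            f"detection alpha {self.detection_alpha}"
        )


def _check_nonempty(detp: pd.DataFrame) -> None:
    if detp.shape[0] == 0 or detp.shape[1] == 0:
        raise ValueError("detection p-value matrix is empty")


def sample_pass_rates(detp: pd.DataFrame, detection_alpha: float = 0.01) -> pd.Series:
    """Per-sample fraction of probes with detection p <= detection_alpha."""
    _check_nonempty(detp)
    return (detp <= detection_alpha).mean(axis=0)


def probe_pass_rates(detp: pd.DataFrame, detection_alpha: float = 0.01) -> pd.Series:
    """Per-probe fraction of samples with detection p <= detection_alpha."""
    _check_nonempty(detp)
    return (detp <= detection_alpha).mean(axis=1)


def apply_pass_rate_filters(
    beta: pd.DataFrame,
    detp: pd.DataFrame,
    min_sample_pass: float = 0.99,
    min_probe_pass: float = 0.99,
    detection_alpha: float = 0.01,
) -> tuple[pd.DataFrame, QCReport]:
    """Drop low-pass-rate samples, then low-pass-rate probes.

    Returns the filtered beta matrix (a row/column subset of the input, values
    untouched) and a :class:`QCReport`.  Raises if the matrices are not
    aligned or nothing survives sample filtering.
    """
    if not beta.index.equals(detp.index) or not beta.columns.equals(detp.columns):
        raise ValueError("beta and detection-p matrices must share probe and sample indices")
    _check_nonempty(detp)

    srates = sample_pass_rates(detp, detection_alpha)
    keep_samples = srates[srates >= min_sample_pass].index
    excluded_samples = srates[srates < min_sample_pass]
    if len(keep_samples) == 0:
        raise ValueError("no data remaining: every sample fell below the pass-rate threshold")

    detp_s = detp[keep_samples]
    prates = probe_pass_rates(detp_s, detection_alpha)
    keep_probes = prates[prates >= min_probe_pass].index
    excluded_probes = prates[prates < min_probe_pass]

    out = beta.loc[keep_probes, keep_samples]
    report = QCReport(
        detection_alpha=detection_alpha,
        min_sample_pass=min_sample_pass,
        min_probe_pass=min_probe_pass,
        n_samples_before=beta.shape[1],
        n_samples_after=out.shape[1],
        n_probes_before=beta.shape[0],
        n_probes_after=out.shape[0],
        excluded_samples={str(k): float(v) for k, v in excluded_samples.items()},
        excluded_probes={str(k): float(v) for k, v in excluded_probes.items()},
    )
    return out, report


def snp_probe_mask(annotation: pd.DataFrame) -> set[str]:
    """Probe IDs flagged as having a common SNP within 50 bp of the CpG.

    The flag is consumed from the annotation (computed upstream against a
    variant catalogue); these probes are excluded from association summaries.
    """
    if "snp_within_50bp" not in annotation.columns:
        raise ValueError("annotation lacks required column 'snp_within_50bp'")
    flagged = annotation.index[annotation["snp_within_50bp"].astype(bool)]
    return set(map(str, flagged))
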