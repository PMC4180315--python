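"""Per-probe intraclass correlation from technical replicates.

The measurement model for a single CpG probe is the one-way random-effects
ANOVA  y_ij = mu + tau_j + eps_ij,  with tau_j the effect of biological sample
(replicate set) j and eps_ij within-set technical noise.  The reliability of
the probe is the intraclass correlation

    ICC = sigma2_tau / (sigma2_tau + sigma2_eps),

estimated by method-of-moments (the classic ICC(1,1) ANOVA estimator) with
the unbalanced-design coefficient

    k0 = (N - sum(n_j^2)/N) / (J - 1),

sigma2_eps_hat = MSW,  sigma2_tau_hat = (MSB - MSW)/k0, truncated at zero.
Truncation produces the characteristic point mass of probes with ICC exactly
0, where replicate noise swamps any between-subject signal.  The same
estimator with chip (batch) as the grouping factor yields ICC_chip, the
share of measurement variance attributable to chip differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "ReplicateLayout",
    "VarianceComponents",
    "anova_components",
    "icc_from_components",
    "icc_table",
    "icc_chip",
    "icc_sd_trend",
]


@dataclass(frozen=True)
class ReplicateLayout:
    """Replicate-set structure: set id -> member sample ids."""

    sets: dict[str, list[str]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for j, members in self.sets.items():
            if len(members) < 2:
                raise ValueError(f"replicate set {j!r} has fewer than 2 members")
            overlap = seen.intersection(members)
            if overlap:
                raise ValueError(f"samples {sorted(overlap)} appear in more than one set")
            seen.update(members)

    @property
    def n_sets(self) -> int:
        return len(self.sets)

    @property
    def set_sizes(self) -> list[int]:
        return [len(m) for m in self.sets.values()]

    @property
    def n_samples(self) -> int:
        return sum(self.set_sizes)

    @classmethod
    def from_sample_sheet(cls, sheet: pd.DataFrame, subject_col: str = "subject_id") -> "ReplicateLayout":
        counts = sheet[subject_col].value_counts()
        sets = {
            str(subj): sheet.index[sheet[subject_col] == subj].tolist()
            for subj in counts.index[counts >= 2]
        }
        if not sets:
            raise ValueError("sample sheet contains no replicate sets (no subject occurs twice)")
        return cls(sets)


@dataclass(frozen=True)
class VarianceComponents:
    """One-way random-effects components for a single probe.

    ``sigma2_between_raw`` keeps the untruncated method-of-moments value
    (possibly negative) for diagnostics; ``sigma2_between`` is truncated at 0.
    """

    grand_mean: float
    sigma2_between: float
    sigma2_between_raw: float
    sigma2_within: float
    n_sets: int
    n_obs: int


def anova_components(groups: list[np.ndarray] | dict[str, np.ndarray]) -> VarianceComponents:
    """Method-of-moments variance components from grouped measurements.

    ``groups`` maps replicate sets to their measurements (NaN allowed; sets
    reduced below size 2 by missingness are dropped).  Raises if fewer than
    two usable sets remain — a probe in that state is unestimable, never
    silently zero.
    """
    values = list(groups.values()) if isinstance(groups, dict) else list(groups)
    cleaned = []
    for g in values:
        arr = np.asarray(g, dtype=float)
        arr = arr[~np.isnan(arr)]
        if arr.size >= 2:
            cleaned.append(arr)
    if len(cleaned) < 2:
        raise ValueError("need at least 2 replicate sets of size >= 2 after dropping missing values")

    n_j = np.array([g.size for g in cleaned], dtype=float)
    N = n_j.sum()
    J = len(cleaned)
    means = np.array([g.mean() for g in cleaned])
    grand = sum(g.sum() for g in cleaned) / N

    ssw = sum(((g - m) ** 2).sum() for g, m in zip(cleaned, means))
    ssb = float((n_j * (means - grand) ** 2).sum())
    msw = ssw / (N - J)
    msb = ssb / (J - 1)
    k0 = (N - (n_j**2).sum() / N) / (J - 1)
    raw = (msb - msw) / k0
    return VarianceComponents(
        grand_mean=float(grand),
        sigma2_between=max(raw, 0.0),
        sigma2_between_raw=float(raw),
        sigma2_within=float(msw),
        n_sets=J,
        n_obs=int(N),
    )


def icc_from_components(vc: VarianceComponents) -> float:
    """ICC = truncated between-set variance over total; 0/0 defined as 0."""
    total = vc.sigma2_between + vc.sigma2_within
    if total == 0.0:
        return 0.0
    return vc.sigma2_between / total


def _grouped_components_matrix(
    values: np.ndarray, group_codes: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised one-way MoM ANOVA over probes (rows) with NaN handling.

    Returns per-probe (sigma2_between_raw, sigma2_within, grand_mean, J, N).
    Probes with fewer than 2 usable sets get NaN components.
    """
    P = values.shape[0]
    valid = ~np.isnan(values)
    y = np.where(valid, values, 0.0)
    y2 = y * y

    n_groups = group_codes.max() + 1
    # per-probe per-set counts, sums, sums of squares
    cnt = np.zeros((P, n_groups))
    s = np.zeros((P, n_groups))
    s2 = np.zeros((P, n_groups))
    for g in range(n_groups):
        cols = group_codes == g
        cnt[:, g] = valid[:, cols].sum(axis=1)
        s[:, g] = y[:, cols].sum(axis=1)
        s2[:, g] = y2[:, cols].sum(axis=1)

    usable = cnt >= 2
    cnt = np.where(usable, cnt, 0.0)
    s = np.where(usable, s, 0.0)
    s2 = np.where(usable, s2, 0.0)

    J = usable.sum(axis=1).astype(float)
    N = cnt.sum(axis=1)
    ok = J >= 2

    with np.errstate(divide="ignore", invalid="ignore"):
        grand = s.sum(axis=1) / N
        ssw = (s2 - np.where(usable, s**2 / np.where(cnt > 0, cnt, 1.0), 0.0)).sum(axis=1)
        means = np.where(usable, s / np.where(cnt > 0, cnt, 1.0), 0.0)
        ssb = (cnt * (means - grand[:, None]) ** 2).sum(axis=1)
        msw = ssw / (N - J)
        msb = ssb / (J - 1.0)
        k0 = (N - (cnt**2).sum(axis=1) / N) / (J - 1.0)
        raw = (msb - msw) / k0

    raw = np.where(ok, raw, np.nan)
    msw = np.where(ok, msw, np.nan)
    grand = np.where(ok, grand, np.nan)
    return raw, msw, grand, J, N


def _icc_from_arrays(raw: np.ndarray, msw: np.ndarray) -> np.ndarray:
    between = np.maximum(raw, 0.0)
    total = between + msw
    with np.errstate(invalid="ignore", divide="ignore"):
        icc = np.where(total > 0, between / total, 0.0)
    return np.where(np.isnan(raw) | np.isnan(msw), np.nan, icc)


def icc_table(
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    subject_col: str = "subject_id",
    chip_col: str = "chip",
) -> pd.DataFrame:
    """Per-probe ICC table from a beta matrix and its sample sheet.

    The replicate ICC and ICC_chip use replicated samples only; the per-probe
    SD is computed across distinct subjects (first sample of each subject) so
    replicate sets are not double-counted.  Columns: ``icc``,
    ``sigma2_between_raw``, ``sigma2_between``, ``sigma2_within``, ``sd``,
    ``icc_chip``, ``n_sets``.
    """
    missing = [s for s in beta.columns if s not in sheet.index]
    if missing:
        raise ValueError(f"samples missing from sample sheet: {missing[:5]}")
    layout = ReplicateLayout.from_sample_sheet(sheet.loc[beta.columns], subject_col)

    rep_samples = [s for members in layout.sets.values() for s in members]
    rep_samples = [s for s in rep_samples if s in beta.columns]
    sub = beta[rep_samples]
    codes = pd.Categorical(sheet.loc[rep_samples, subject_col]).codes
    raw, msw, _, J, _ = _grouped_components_matrix(sub.to_numpy(dtype=float), codes)
    icc = _icc_from_arrays(raw, msw)

    # SD over one sample per subject
    first = sheet.loc[beta.columns].reset_index().groupby(subject_col, sort=False).head(1)
    first_samples = first.iloc[:, 0].tolist()
    sd = beta[first_samples].std(axis=1, ddof=1)

    chip_icc = icc_chip(beta, sheet, subject_col=subject_col, chip_col=chip_col)

    return pd.DataFrame(
        {
            "icc": icc,
            "sigma2_between_raw": raw,
            "sigma2_between": np.maximum(raw, 0.0),
            "sigma2_within": msw,
            "sd": sd.to_numpy(),
            "icc_chip": chip_icc.to_numpy(),
            "n_sets": J.astype(int),
        },
        index=beta.index,
    )


def icc_chip(
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    subject_col: str = "subject_id",
    chip_col: str = "chip",
    replicates_only: bool = True,
) -> pd.Series:
    """Intraclass correlation with chip as the grouping factor.

    High values flag probes whose measurement variance is dominated by chip
    (batch) differences.  By default computed on replicate samples, the same
    data as the replicate ICC; unestimable probes (fewer than 2 chips with
    >= 2 samples) are NaN.
    """
    if replicates_only:
        layout = ReplicateLayout.from_sample_sheet(sheet.loc[beta.columns], subject_col)
        samples = [s for members in layout.sets.values() for s in members if s in beta.columns]
    else:
        samples = list(beta.columns)
    chips = sheet.loc[samples, chip_col]
    if chips.nunique() < 2:
        raise ValueError("ICC_chip requires samples on at least 2 chips")
    codes = pd.Categorical(chips).codes
    raw, msw, _, _, _ = _grouped_components_matrix(beta[samples].to_numpy(dtype=float), codes)
    return pd.Series(_icc_from_arrays(raw, msw), index=beta.index, name="icc_chip")


def icc_sd_trend(
    table: pd.DataFrame, bandwidth: float = 0.3, n_grid: int = 100
) -> pd.DataFrame:
    """LOWESS trend of ICC against per-probe SD.

    Returns a DataFrame with columns ``sd`` (evaluation grid) and ``icc_fit``.
    Requires at least 50 probes with finite ICC and SD.
    """
    d = table[["sd", "icc"]].dropna()
    if len(d) < 50:
        raise ValueError(f"need >= 50 probes for a stable trend, got {len(d)}")
    x = d["sd"].to_numpy()
    y = d["icc"].to_numpy()
    if np.ptp(x) == 0:
        warnings.warn("all probe SDs identical; trend is degenerate (flat)")
        grid = np.full(n_grid, x[0])
        return pd.DataFrame({"sd": grid, "icc_fit": np.full(n_grid, y.mean())})
    grid = np.linspace(x.min(), x.max(), n_grid)
    fit = lowess(y, x, frac=bandwidth, xvals=grid)
    return pd.DataFrame({"sd": grid, "icc_fit": fit})
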