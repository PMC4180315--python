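"""Synthetic methylation-study generator.

Produces complete synthetic Infinium-style studies — a probe x sample matrix of
beta values, detection p-values, a sample sheet with replicate/chip layout and
covariates, probe annotation, and a ground-truth table — under the one-way
random-effects model the downstream reliability analysis assumes:

    y_ij = mu_probe + tau_j + b_l(ij) + effect * smoker_j + e_ij

where tau_j is a subject (replicate-set) effect, b_l(ij) a chip (batch)
effect, and e_ij residual technical noise.  The per-probe true intraclass
correlation is

    ICC = sigma2_b / (sigma2_b + sigma2_chip + sigma2_e)

since technical replicates of a subject are measured on different chips, so
chip variation acts as within-set noise.

Also provides a direct sampler from the zero-inflated truncated-normal /
normal ICC mixture used to exercise the mixture-fitting code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VarianceLaw",
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_methylation_study",
    "simulate_icc_sample",
]


@dataclass(frozen=True)
class VarianceLaw:
    """Distributional law for per-probe variance components.

    True non-zero ICC values are drawn from a two-mode Beta mixture (modes
    ``icc_low_mode`` and ``icc_high_mode``), mimicking the empirically bimodal
    reliability distribution of methylation arrays.  Total within-set standard
    deviation is log-normal around ``median_sigma_within`` and split between
    chip and residual noise by ``chip_share``.  All component SDs are scaled
    down near the beta boundaries (factor ``2*min(mu, 1-mu)`` floored at
    ``boundary_floor``) so that clamping to [0, 1] stays rare, reflecting the
    compressed variance of near-0/near-1 methylation.
    """

    icc_low_mode: float = 0.10
    icc_high_mode: float = 0.75
    high_weight: float = 0.55
    icc_concentration: float = 12.0
    median_sigma_within: float = 0.015
    sigma_within_log_sd: float = 0.3
    chip_share: float = 0.4
    boundary_floor: float = 0.10

    def validate(self) -> None:
        if not (0.0 < self.icc_low_mode < self.icc_high_mode < 1.0):
            raise ValueError("ICC modes must satisfy 0 < low < high < 1")
        if not 0.0 <= self.high_weight <= 1.0:
            raise ValueError("high_weight must be in [0, 1]")
        if not 0.0 <= self.chip_share <= 1.0:
            raise ValueError("chip_share must be in [0, 1]")
        if self.median_sigma_within < 0:
            raise ValueError("median_sigma_within must be non-negative")


@dataclass(frozen=True)
class SimulationConfig:
    """Design of a synthetic methylation study.

    Defaults emulate a cohort with 130 technical-replicate sets (125
    duplicates plus 5 triplicates, i.e. 265 replicate measurements), replicate
    sets spread across 12-sample chips (6 rows x 2 columns) with all but
    ``n_same_chip_pairs`` pairs on distinct chips, and a binary phenotype
    ("current smoker", prevalence 0.256) carried by ``effect_probes`` probes.
    """

    n_subjects: int = 500
    n_replicate_pairs: int = 125
    n_replicate_triples: int = 5
    n_probes: int = 2000
    samples_per_chip: int = 12
    fraction_zero_icc: float = 0.076
    variance_law: VarianceLaw = field(default_factory=VarianceLaw)
    effect_probes: int = 30
    effect_size: float = 0.05
    effect_on_high_icc: bool = True
    detection_fail_rate: float = 0.002
    n_same_chip_pairs: int = 2
    smoking_prevalence: float = 0.256
    female_fraction: float = 0.634
    age_mean: float = 56.7
    age_sd: float = 5.9
    cross_reactive_rate: float = 0.06
    snp_flag_rate: float = 0.06
    type2_fraction: float = 0.72
    annotation_icc_bias: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_subjects": self.n_subjects,
            "n_replicate_pairs": self.n_replicate_pairs,
            "n_replicate_triples": self.n_replicate_triples,
            "n_probes": self.n_probes,
            "samples_per_chip": self.samples_per_chip,
            "effect_probes": self.effect_probes,
            "n_same_chip_pairs": self.n_same_chip_pairs,
        }
        for name, v in counts.items():
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
        for name in (
            "fraction_zero_icc",
            "detection_fail_rate",
            "smoking_prevalence",
            "female_fraction",
            "cross_reactive_rate",
            "snp_flag_rate",
            "type2_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_replicate_pairs + self.n_replicate_triples > self.n_subjects:
            raise ValueError("replicated subjects cannot exceed n_subjects")
        if self.samples_per_chip < 1:
            raise ValueError("samples_per_chip must be >= 1")
        if self.effect_probes > self.n_probes:
            raise ValueError("effect_probes cannot exceed n_probes")
        self.variance_law.validate()


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated study.

    ``probes`` holds per-probe variance components (sigma2_between = var of
    the subject effect tau_j, sigma2_chip = var of the chip effect b_l(ij),
    sigma2_e = residual), the true ICC, and the phenotype effect.  ``samples``
    repeats the sample sheet's phenotype and covariate columns, one row per
    array sample.
    """

    probes: pd.DataFrame
    samples: pd.DataFrame


def _beta_with_mode(rng: np.random.Generator, mode: float, conc: float, size: int) -> np.ndarray:
    a = 1.0 + conc * mode
    b = 1.0 + conc * (1.0 - mode)
    return rng.beta(a, b, size=size)


def _draw_probe_truth(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    law = cfg.variance_law
    n = cfg.n_probes
    n_zero = int(round(cfg.fraction_zero_icc * n))

    # probe means: tri-modal, mimicking unmethylated / hemi / methylated CpGs
    comp = rng.choice(3, size=n, p=[0.35, 0.30, 0.35])
    mu = np.empty(n)
    mu[comp == 0] = rng.beta(2, 18, size=int((comp == 0).sum()))
    mu[comp == 1] = rng.beta(12, 12, size=int((comp == 1).sum()))
    mu[comp == 2] = rng.beta(18, 2, size=int((comp == 2).sum()))

    icc = np.zeros(n)
    nz = n - n_zero
    hi = rng.random(nz) < law.high_weight
    icc_nz = np.where(
        hi,
        _beta_with_mode(rng, law.icc_high_mode, law.icc_concentration, nz),
        _beta_with_mode(rng, law.icc_low_mode, law.icc_concentration, nz),
    )
    zero_idx = rng.choice(n, size=n_zero, replace=False)
    nz_mask = np.ones(n, dtype=bool)
    nz_mask[zero_idx] = False
    icc[nz_mask] = icc_nz

    if law.median_sigma_within > 0:
        sigma_w = np.exp(rng.normal(math.log(law.median_sigma_within), law.sigma_within_log_sd, n))
    else:  # noise-free limit
        sigma_w = np.zeros(n)
    # boundary scaling keeps draws inside [0,1] without distorting ICC
    scale = np.clip(2.0 * np.minimum(mu, 1.0 - mu), law.boundary_floor, 1.0)
    sigma_w = sigma_w * scale
    s2_w = sigma_w**2
    s2_chip = law.chip_share * s2_w
    s2_e = s2_w - s2_chip
    with np.errstate(divide="ignore"):
        s2_b = np.where((icc > 0) & (s2_w > 0), icc / (1.0 - icc) * s2_w, 0.0)
    icc = np.where(s2_b + s2_w > 0, icc, 0.0)

    effect = np.zeros(n)
    if cfg.effect_probes:
        if cfg.effect_on_high_icc:
            candidates = np.flatnonzero(icc >= 0.5)
            if len(candidates) < cfg.effect_probes:
                candidates = np.argsort(icc)[::-1][: max(cfg.effect_probes, 1)]
        else:
            candidates = np.arange(n)
        chosen = rng.choice(candidates, size=cfg.effect_probes, replace=False)
        effect[chosen] = cfg.effect_size

    probe_ids = [f"cg{i:08d}" for i in range(n)]
    return pd.DataFrame(
        {
            "probe_id": probe_ids,
            "mu": mu,
            "sigma2_between": s2_b,
            "sigma2_chip": s2_chip,
            "sigma2_e": s2_e,
            "icc_true": icc,
            "effect": effect,
        }
    ).set_index("probe_id")


def _build_sample_layout(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Sample sheet skeleton: subject, replicate index, chip, position.

    Samples are laid out in replicate-index blocks so that replicates of a set
    fall on different chips; a configurable number of replicate pairs is then
    deliberately moved onto a shared chip, and any residual same-chip
    collisions at block boundaries are swapped away.
    """
    subjects = [f"S{j:05d}" for j in range(cfg.n_subjects)]
    n_rep = cfg.n_replicate_pairs + cfg.n_replicate_triples
    replicated = list(rng.choice(cfg.n_subjects, size=n_rep, replace=False))
    triples = set(replicated[: cfg.n_replicate_triples])
    doubles = set(replicated[cfg.n_replicate_triples :])

    rows = []
    for block in range(3):
        members = [
            j
            for j in range(cfg.n_subjects)
            if block == 0 or (block == 1 and (j in doubles or j in triples)) or (block == 2 and j in triples)
        ]
        members = list(rng.permutation(members))
        for j in members:
            rows.append((subjects[j], block))

    df = pd.DataFrame(rows, columns=["subject_id", "replicate"])
    df["sample_id"] = [f"{s}_r{r}" for s, r in zip(df.subject_id, df.replicate)]
    spc = cfg.samples_per_chip
    df["chip"] = [f"chip{i // spc:03d}" for i in range(len(df))]
    df["slot"] = [i % spc for i in range(len(df))]

    def _fix_collisions(df: pd.DataFrame) -> pd.DataFrame:
        for _ in range(10):
            dup = df.duplicated(subset=["subject_id", "chip"], keep="first")
            if not dup.any():
                break
            i = int(np.flatnonzero(dup.values)[0])
            # swap chip/slot with a sample two chips away
            j = (i + 2 * spc) % len(df)
            for col in ("chip", "slot"):
                df.iloc[i, df.columns.get_loc(col)], df.iloc[j, df.columns.get_loc(col)] = (
                    df.iloc[j, df.columns.get_loc(col)],
                    df.iloc[i, df.columns.get_loc(col)],
                )
        return df

    df = _fix_collisions(df)

    # deliberately co-locate a few replicate pairs on one chip
    pair_subjects = [subjects[j] for j in sorted(doubles)][: cfg.n_same_chip_pairs]
    for subj in pair_subjects:
        idx = df.index[df.subject_id == subj].tolist()
        if len(idx) < 2:
            continue
        a, b = idx[0], idx[1]
        target_chip = df.at[a, "chip"]
        if df.at[b, "chip"] == target_chip:
            continue
        # swap b with a non-conflicting occupant of a's chip
        occupants = df.index[(df.chip == target_chip) & (df.subject_id != subj)].tolist()
        donor = None
        for o in occupants:
            other_chip = df.at[b, "chip"]
            subj_o = df.at[o, "subject_id"]
            if not ((df.subject_id == subj_o) & (df.chip == other_chip)).any():
                donor = o
                break
        if donor is None:
            continue
        for col in ("chip", "slot"):
            df.at[b, col], df.at[donor, col] = df.at[donor, col], df.at[b, col]

    n_rows = max(1, spc // 2)
    df["chip_row"] = (df.slot % n_rows).astype(int) + 1
    df["chip_col"] = (df.slot // n_rows).astype(int) + 1
    df["position"] = [f"R{r:02d}C{c:02d}" for r, c in zip(df.chip_row, df.chip_col)]
    return df.drop(columns=["slot"]).set_index("sample_id")


def _draw_covariates(cfg: SimulationConfig, layout: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Per-subject phenotype/covariates, copied to every replicate of a subject."""
    subjects = layout.subject_id.unique()
    per_subj = pd.DataFrame(
        {
            "smoker": (rng.random(len(subjects)) < cfg.smoking_prevalence).astype(int),
            "age": rng.normal(cfg.age_mean, cfg.age_sd, len(subjects)),
            "sex_female": (rng.random(len(subjects)) < cfg.female_fraction).astype(int),
            "bmi": rng.normal(28.0, 5.0, len(subjects)),
            "alcohol": (rng.random(len(subjects)) < 0.35).astype(int),
            "pc1": rng.normal(0.0, 1.0, len(subjects)),
            "pc2": rng.normal(0.0, 1.0, len(subjects)),
            "visit": np.where(rng.random(len(subjects)) < 0.152, 3, 2),
        },
        index=pd.Index(subjects, name="subject_id"),
    )
    sheet = layout.join(per_subj, on="subject_id")
    return sheet


def _draw_annotation(cfg: SimulationConfig, truth: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    n = len(truth)
    icc = truth.icc_true.to_numpy()
    # cross-reactive and type-I probes enriched at low reliability
    w = np.exp(-cfg.annotation_icc_bias * icc)
    w = w / w.sum()
    n_cross = int(round(cfg.cross_reactive_rate * n))
    cross = np.zeros(n, dtype=bool)
    cross[rng.choice(n, size=n_cross, replace=False, p=w)] = True

    n_type1 = int(round((1.0 - cfg.type2_fraction) * n))
    w1 = np.exp(-0.5 * cfg.annotation_icc_bias * icc)
    w1 = w1 / w1.sum()
    type1 = np.zeros(n, dtype=bool)
    type1[rng.choice(n, size=n_type1, replace=False, p=w1)] = True

    island = rng.choice(
        ["island", "shore", "shelf", "open_sea"], size=n, p=[0.31, 0.23, 0.10, 0.36]
    )
    return pd.DataFrame(
        {
            "design_type": np.where(type1, "I", "II"),
            "island_relation": island,
            "snp_within_50bp": rng.random(n) < cfg.snp_flag_rate,
            "cross_reactive": cross,
        },
        index=truth.index,
    )


def simulate_methylation_study(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Run the random-effects model forward into a full synthetic study.

    Returns ``(beta, detection_p, sample_sheet, annotation, truth)``.  Beta
    and detection-p are probe x sample DataFrames; replicate samples of a
    subject share the subject effect tau_j and covariates but draw independent
    chip and residual noise.  Output is a pure function of ``config`` (equal
    configs, equal seeds => identical output).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    truth_probes = _draw_probe_truth(config, rng)
    layout = _build_sample_layout(config, rng)
    sheet = _draw_covariates(config, layout, rng)
    annotation = _draw_annotation(config, truth_probes, rng)

    n_probes = config.n_probes
    sample_ids = sheet.index.to_numpy()
    subj_codes = pd.Categorical(sheet.subject_id).codes
    chip_codes = pd.Categorical(sheet.chip).codes
    n_subj = subj_codes.max() + 1
    n_chip = chip_codes.max() + 1

    sd_b = np.sqrt(truth_probes.sigma2_between.to_numpy())[:, None]
    sd_chip = np.sqrt(truth_probes.sigma2_chip.to_numpy())[:, None]
    sd_e = np.sqrt(truth_probes.sigma2_e.to_numpy())[:, None]

    tau = rng.standard_normal((n_probes, n_subj)) * sd_b
    b_chip = rng.standard_normal((n_probes, n_chip)) * sd_chip
    e = rng.standard_normal((n_probes, len(sample_ids))) * sd_e

    y = (
        truth_probes.mu.to_numpy()[:, None]
        + tau[:, subj_codes]
        + b_chip[:, chip_codes]
        + truth_probes.effect.to_numpy()[:, None] * sheet.smoker.to_numpy()[None, :]
        + e
    )
    beta = pd.DataFrame(np.clip(y, 0.0, 1.0), index=truth_probes.index, columns=sample_ids)
    beta.columns.name = "sample_id"

    fail = rng.random(beta.shape) < config.detection_fail_rate
    u = rng.random(beta.shape)
    detp = np.where(fail, 0.01 + 0.99 * u, 0.01 * u)
    detp = pd.DataFrame(detp, index=beta.index, columns=beta.columns)

    truth = SyntheticTruth(probes=truth_probes, samples=sheet.copy())
    return beta, detp, sheet, annotation, truth


def simulate_icc_sample(
    p0: float,
    p: float,
    mu1: float,
    sigma1: float,
    mu2: float,
    sigma2: float,
    n: int,
    seed: int,
) -> np.ndarray:
    """Draw ICC values from the zero-inflated two-component mixture.

    Exactly ``round(n * p0)`` values are 0; the rest come from the truncated
    normal (mu1, sigma1) restricted to (0, 1] with probability ``p`` and from
    the normal (mu2, sigma2) clipped into (0, 1] otherwise.
    """
    for name, v in (("p0", p0), ("p", p)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    if sigma1 <= 0 or sigma2 <= 0:
        raise ValueError("sigma1 and sigma2 must be positive")
    if n < 0:
        raise ValueError("n must be non-negative")

    rng = np.random.default_rng(seed)
    n0 = int(round(n * p0))
    m = n - n0
    from_low = rng.random(m) < p
    n_low = int(from_low.sum())

    a1, b1 = (0.0 - mu1) / sigma1, (1.0 - mu1) / sigma1
    low = stats.truncnorm.rvs(a1, b1, loc=mu1, scale=sigma1, size=n_low, random_state=rng)
    high = np.clip(rng.normal(mu2, sigma2, m - n_low), 1e-12, 1.0)

    out = np.empty(n)
    out[:n0] = 0.0
    nonzero = np.empty(m)
    nonzero[from_low] = low
    nonzero[~from_low] = high
    out[n0:] = nonzero
    rng.shuffle(out)
    return out
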