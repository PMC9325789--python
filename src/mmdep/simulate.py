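"""Synthetic dependency screens, annotation sets and survival cohorts.

Every generator takes an explicit seed and draws from a single
``numpy.random.Generator`` stream, so identical calls are bit-reproducible.
The screens emulate DepMap-style gene-effect matrices: a latent per-gene
effect (negative for essential genes, lineage-restricted for
lineage-essential ones) observed twice — once as a CRISPR score, once as a
linearly coupled shRNA score — with independent measurement noise and
missing entries.  The cohorts emulate newly diagnosed myeloma series:
standard-normal expression, exponential event times under a proportional
hazards model tied to low expression of chosen genes, independent
exponential right-censoring, and age/sex/ISS covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .containers import CohortSurvival, GeneSetCollection, LineMetadata, ScreenMatrix

GENE_CLASSES = ("nonessential", "common_essential", "lineage_essential")


@dataclass
class ScreenTruth:
    """Ground-truth generative parameters for a pair of screens.

    class_means are latent gene effects: 0 for non-essential genes and a
    negative value for essential classes (lineage-essential genes take their
    mean only in lineage-labelled lines, 0 elsewhere).  noise_sd is the
    biological (latent) noise, platform_sd the per-platform measurement
    noise, and slope the shRNA-vs-latent coupling.
    """

    class_means: dict[str, float] = field(
        default_factory=lambda: {
            "nonessential": 0.0,
            "common_essential": -1.5,
            "lineage_essential": -1.5,
        }
    )
    class_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "nonessential": 0.75,
            "common_essential": 0.20,
            "lineage_essential": 0.05,
        }
    )
    noise_sd: float = 0.25
    slope: float = 1.0
    platform_sd: float = 0.25
    # (crispr, shrna) per-entry missing rates; a scalar applies to both.
    # CRISPR gene-effect releases are complete, shRNA screens have gaps.
    missing_rate: float | tuple[float, float] = (0.0, 0.05)
    gene_classes: pd.Series | None = None  # filled by simulate_screens

    @property
    def missing_rates(self) -> tuple[float, float]:
        if isinstance(self.missing_rate, (int, float)):
            return (float(self.missing_rate), float(self.missing_rate))
        return (float(self.missing_rate[0]), float(self.missing_rate[1]))

    def __post_init__(self) -> None:
        for rate in self.missing_rates:
            if not 0.0 <= rate < 1.0:
                raise ValueError("missing rates must lie in [0, 1)")
        for cls in ("common_essential", "lineage_essential"):
            if self.class_means[cls] >= 0:
                raise ValueError(f"class mean for {cls} must be negative")
        if self.noise_sd < 0 or self.platform_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        total = sum(self.class_fractions.values())
        if not np.isclose(total, 1.0):
            raise ValueError("class_fractions must sum to 1")


def simulate_screens(
    n_genes: int,
    n_mm_lines: int,
    n_other_lines: int,
    truth: ScreenTruth | None = None,
    seed: int = 0,
    lineage: str = "multiple_myeloma",
) -> tuple[ScreenMatrix, ScreenMatrix, LineMetadata, ScreenTruth]:
    """Generate coupled CRISPR and shRNA gene-effect matrices.

    Latent effect per gene x line = class mean (restricted to lineage lines
    for lineage-essential genes) + N(0, noise_sd).  CRISPR = latent +
    N(0, platform_sd); shRNA = slope*latent + N(0, platform_sd).  Entries
    are masked missing independently at missing_rate per platform.
    """
    if n_genes < 2 or n_other_lines < 2:
        raise ValueError("need at least 2 genes and 2 background lines")
    if n_mm_lines < 2:
        raise ValueError("n_mm_lines must be >= 2 (percentile undefined)")
    truth = truth if truth is not None else ScreenTruth()
    rng = np.random.default_rng(seed)

    genes = [f"G{i:05d}" for i in range(n_genes)]
    mm_lines = [f"MM_{i:03d}" for i in range(n_mm_lines)]
    other_lines = [f"OTH_{i:03d}" for i in range(n_other_lines)]
    lines = mm_lines + other_lines
    is_mm = np.array([True] * n_mm_lines + [False] * n_other_lines)

    classes = rng.choice(
        GENE_CLASSES,
        size=n_genes,
        p=[truth.class_fractions[c] for c in GENE_CLASSES],
    )
    mean_matrix = np.zeros((n_genes, len(lines)))
    for i, cls in enumerate(classes):
        if cls == "common_essential":
            mean_matrix[i, :] = truth.class_means[cls]
        elif cls == "lineage_essential":
            mean_matrix[i, is_mm] = truth.class_means[cls]

    latent = mean_matrix + rng.normal(0.0, truth.noise_sd, mean_matrix.shape)
    crispr = latent + rng.normal(0.0, truth.platform_sd, latent.shape)
    shrna = truth.slope * latent + rng.normal(0.0, truth.platform_sd, latent.shape)
    rate_c, rate_r = truth.missing_rates
    if rate_c > 0:
        crispr[rng.random(crispr.shape) < rate_c] = np.nan
    if rate_r > 0:
        shrna[rng.random(shrna.shape) < rate_r] = np.nan

    idx = pd.Index(genes, name="gene")
    cols = pd.Index(lines, name="line")
    out_truth = ScreenTruth(
        class_means=dict(truth.class_means),
        class_fractions=dict(truth.class_fractions),
        noise_sd=truth.noise_sd,
        slope=truth.slope,
        platform_sd=truth.platform_sd,
        missing_rate=truth.missing_rate,
        gene_classes=pd.Series(classes, index=idx, name="class"),
    )
    meta = LineMetadata(
        lineage=pd.Series(
            np.where(is_mm, lineage, "other"), index=cols, name="lineage"
        )
    )
    return (
        ScreenMatrix(pd.DataFrame(crispr, index=idx, columns=cols), "crispr"),
        ScreenMatrix(pd.DataFrame(shrna, index=idx, columns=cols), "shrna"),
        meta,
        out_truth,
    )


@dataclass
class CohortTruth:
    """Generative parameters for one survival cohort.

    log_hr maps gene -> log hazard ratio applied to patients in the bottom
    expression quartile of that gene (low vs high contrast); unlisted genes
    are null.  Hazards are exponential: rate = baseline_rate * exp(linear
    predictor).  Censoring is independent exponential with its rate solved
    numerically so the expected censored fraction equals censoring_rate.
    """

    log_hr: dict[str, float] = field(default_factory=dict)
    baseline_rate: float = 0.015  # events per month, median OS ~ 46 months
    censoring_rate: float = 0.3
    beta_age: float = 0.02  # per year above 65
    beta_sex: float = 0.1
    beta_iss: tuple[float, float] = (0.3, 0.6)  # ISS-2, ISS-3 vs ISS-1
    progression_hazard_ratio: float = 1.5  # extra hazard of progression vs death
    iss_missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring_rate must lie in [0, 1)")


def _censoring_scale(event_times: np.ndarray, target: float) -> float:
    """Exponential censoring rate giving an expected censored fraction of
    ``target`` for the realised event times."""
    if target <= 0:
        return 0.0

    def frac(rate: float) -> float:
        return float(np.mean(1.0 - np.exp(-rate * event_times))) - target

    return brentq(frac, 1e-10, 1e4)


def simulate_cohort(
    n_patients: int,
    genes: list[str],
    truth: CohortTruth | None = None,
    seed: int = 0,
    name: str = "synthetic",
) -> CohortSurvival:
    """Generate one cohort with proportional-hazards OS/PFS outcomes.

    Expression is N(0,1) per gene.  A patient in the bottom quartile of a
    gene with a non-zero log_hr coefficient receives that coefficient in the
    linear predictor, so a downstream low-vs-high Cox contrast targets it.
    Progression times carry extra hazard, hence PFS <= OS.
    """
    if n_patients < 20:
        raise ValueError("n_patients must be >= 20")
    truth = truth if truth is not None else CohortTruth()
    unknown = set(truth.log_hr) - set(genes)
    if unknown:
        raise ValueError(f"log_hr given for genes not simulated: {sorted(unknown)}")
    rng = np.random.default_rng(seed)

    patients = [f"{name}_P{i:04d}" for i in range(n_patients)]
    expr = rng.normal(0.0, 1.0, (len(genes), n_patients))
    expression = pd.DataFrame(
        expr, index=pd.Index(genes, name="gene"), columns=patients
    )

    age = rng.normal(65.0, 10.0, n_patients)
    sex = rng.integers(0, 2, n_patients)
    iss = rng.integers(1, 4, n_patients).astype(float)
    if truth.iss_missing_rate > 0:
        iss[rng.random(n_patients) < truth.iss_missing_rate] = np.nan

    lp = truth.beta_age * (age - 65.0) + truth.beta_sex * sex
    iss_filled = np.nan_to_num(iss, nan=1.0)  # missing ISS carries no excess hazard
    lp += np.where(iss_filled == 2, truth.beta_iss[0], 0.0)
    lp += np.where(iss_filled == 3, truth.beta_iss[1], 0.0)
    for gene, beta in truth.log_hr.items():
        values = expression.loc[gene].to_numpy()
        low = values <= np.percentile(values, 25)
        lp += np.where(low, beta, 0.0)

    death_rate = truth.baseline_rate * np.exp(lp)
    death = rng.exponential(1.0 / death_rate)
    prog_rate = death_rate * truth.progression_hazard_ratio
    progression = rng.exponential(1.0 / prog_rate)
    pfs_raw = np.minimum(death, progression)

    if truth.censoring_rate > 0:
        c_rate = _censoring_scale(death, truth.censoring_rate)
        censor = rng.exponential(1.0 / c_rate, n_patients)
    else:
        censor = np.full(n_patients, np.inf)

    clinical = pd.DataFrame(
        {
            "os_time": np.minimum(death, censor),
            "os_event": (death <= censor).astype(int),
            "pfs_time": np.minimum(pfs_raw, censor),
            "pfs_event": (pfs_raw <= censor).astype(int),
            "age": age,
            "sex": sex,
            "iss": iss,
        },
        index=pd.Index(patients, name="patient_id"),
    )
    return CohortSurvival(name=name, expression=expression, clinical=clinical)


def simulate_annotations(
    genes: list[str],
    n_terms: int,
    planted_term_members: set[str],
    seed: int = 0,
    term_size_range: tuple[int, int] = (10, 100),
) -> GeneSetCollection:
    """Random annotation terms plus one planted term with exactly the given
    members (term id "PLANTED")."""
    if not planted_term_members:
        raise ValueError("planted term must have at least one member")
    missing = set(planted_term_members) - set(genes)
    if missing:
        raise ValueError(f"planted members not in gene universe: {sorted(missing)[:5]}")
    rng = np.random.default_rng(seed)
    names = {"PLANTED": "planted term"}
    members: dict[str, frozenset[str]] = {"PLANTED": frozenset(planted_term_members)}
    lo, hi = term_size_range
    hi = min(hi, len(genes))
    for t in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        term = f"RAND{t:04d}"
        names[term] = f"random term {t}"
        members[term] = frozenset(rng.choice(genes, size=size, replace=False))
    return GeneSetCollection(names=names, members=members)
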