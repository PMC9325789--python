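"""Expression-vs-outcome analysis: quartile groups, Kaplan-Meier and
log-rank, covariate-adjusted Cox models, DerSimonian-Laird random-effects
meta-analysis across cohorts, BH FDR control and a Schoenfeld power
approximation.

The hazard-ratio orientation throughout is low expression vs high
(high = reference): HR > 1 means low expression of the gene is adverse.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from scipy.stats import chi2, norm
from statsmodels.stats.multitest import multipletests

from .containers import CohortSurvival

logger = logging.getLogger("mmdep")

Z975 = float(norm.ppf(0.975))


@dataclass
class GroupAssignment:
    """Bottom/top expression-quartile membership per patient."""

    labels: pd.Series  # values in {"low", "high", "excluded"}
    cutoff_low: float  # 25th percentile
    cutoff_high: float  # 75th percentile

    @property
    def low(self) -> pd.Index:
        return self.labels.index[self.labels == "low"]

    @property
    def high(self) -> pd.Index:
        return self.labels.index[self.labels == "high"]


def expression_groups(expr: pd.Series) -> GroupAssignment:
    """Assign patients to bottom-25% (low) and top-25% (high) expression.

    Cutoffs are the linearly interpolated 25th/75th percentiles; boundary
    ties go to the extreme groups so heavily tied data keep group sizes at
    or above the nominal quarter.  The middle half is excluded.
    """
    expr = expr.astype(float)
    n = len(expr)
    if n < 8:
        raise ValueError(f"need >= 8 patients to form quartile groups, got {n}")
    values = expr.to_numpy()
    q25, q75 = np.percentile(values, [25.0, 75.0])
    if q25 >= q75:
        raise ValueError("expression quartiles coincide; groups undefined")
    labels = pd.Series("excluded", index=expr.index, name="group")
    labels[expr <= q25] = "low"
    labels[expr >= q75] = "high"
    n_low, n_high = int((labels == "low").sum()), int((labels == "high").sum())
    logger.info("expression_groups: %d low, %d high of %d", n_low, n_high, n)
    if max(n_low, n_high) >= 0.3 * n:
        logger.warning(
            "tied expression values inflate a quartile group (%d low / %d high of %d)",
            n_low, n_high, n,
        )
    return GroupAssignment(labels=labels, cutoff_low=float(q25), cutoff_high=float(q75))


def km_logrank(
    times: pd.Series, events: pd.Series, groups: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame, float, float]:
    """Kaplan-Meier curves for the low and high groups and the two-sided
    log-rank test (1 df) between them."""
    is_low = groups == "low"
    is_high = groups == "high"
    if not is_low.any() or not is_high.any():
        raise ValueError("both expression groups must be non-empty")

    curves = []
    for mask, label in ((is_low, "low"), (is_high, "high")):
        km = KaplanMeierFitter(label=label)
        km.fit(times[mask], events[mask])
        curves.append(km.survival_function_)
    res = logrank_test(
        times[is_low], times[is_high], events[is_low], events[is_high]
    )
    return curves[0], curves[1], float(res.test_statistic), float(res.p_value)


@dataclass
class CoxResult:
    """Adjusted Cox fit of the low-vs-high contrast for one gene/cohort/endpoint."""

    gene: str
    cohort: str
    endpoint: str
    log_hr: float
    se: float
    hr: float
    ci_low: float
    ci_high: float
    p: float
    logrank_p: float
    n_low: int
    n_high: int
    n_events: int
    n_dropped_iss: int = 0
    flagged: bool = False  # monotone likelihood / non-convergence


def cox_fit(
    times: pd.Series,
    events: pd.Series,
    group_indicator: pd.Series,
    covariates: pd.DataFrame | None = None,
    gene: str = "",
    cohort: str = "",
    endpoint: str = "os",
) -> CoxResult:
    """Proportional-hazards fit of a binary low-expression indicator with
    optional age/sex/ISS adjustment (Efron tie handling).

    ``group_indicator`` is 1 for low expression, 0 for high (reference);
    only patients in either group should be passed.  Patients with missing
    ISS are dropped (complete case) and counted.  Monotone likelihood is
    returned as a flagged result with an infinite-bound CI rather than an
    exception; a singular design is an error.
    """
    ind = group_indicator.astype(float)
    if ind.nunique() < 2:
        raise ValueError("all patients fall in a single expression group")
    df = pd.DataFrame({"time": times, "event": events.astype(int), "low": ind})
    n_dropped_iss = 0
    if covariates is not None:
        cov = covariates.loc[df.index].copy()
        keep = cov["iss"].notna() if "iss" in cov.columns else pd.Series(True, index=cov.index)
        n_dropped_iss = int((~keep).sum())
        if n_dropped_iss:
            logger.info("cox_fit(%s/%s): dropped %d patients with missing ISS", gene, cohort, n_dropped_iss)
        df, cov = df[keep], cov[keep]
        df["age"] = cov["age"].astype(float)
        df["sex"] = cov["sex"].astype(float)
        df["iss2"] = (cov["iss"] == 2).astype(float)
        df["iss3"] = (cov["iss"] == 3).astype(float)
    n_events = int(df["event"].sum())
    if n_events < 10:
        raise ValueError(f"need >= 10 events for a stable Cox fit, got {n_events}")

    predictors = [c for c in df.columns if c not in ("time", "event")]
    x = df[predictors].to_numpy()
    xc = x - x.mean(axis=0)
    if np.linalg.matrix_rank(xc) < len(predictors):
        raise ValueError("singular covariate matrix")

    n_low = int((df["low"] == 1).sum())
    n_high = int((df["low"] == 0).sum())
    _, _, _, logrank_p = km_logrank(
        df["time"], df["event"], df["low"].map({1.0: "low", 0.0: "high"})
    )

    fitter = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(df, duration_col="time", event_col="event")
        log_hr = float(fitter.params_["low"])
        se = float(fitter.standard_errors_["low"])
        flagged = not np.isfinite(se) or se > 50
    except ConvergenceError:
        log_hr, se, flagged = np.nan, np.inf, True
    if flagged:
        hr = float(np.exp(log_hr)) if np.isfinite(log_hr) else np.nan
        ci_low, ci_high, p = 0.0, np.inf, np.nan
    else:
        hr = float(np.exp(log_hr))
        ci_low = float(np.exp(log_hr - Z975 * se))
        ci_high = float(np.exp(log_hr + Z975 * se))
        p = float(2.0 * norm.sf(abs(log_hr / se)))
    return CoxResult(
        gene=gene, cohort=cohort, endpoint=endpoint,
        log_hr=log_hr, se=se, hr=hr, ci_low=ci_low, ci_high=ci_high,
        p=p, logrank_p=logrank_p,
        n_low=n_low, n_high=n_high, n_events=n_events,
        n_dropped_iss=n_dropped_iss, flagged=flagged,
    )


@dataclass
class MetaResult:
    """DerSimonian-Laird random-effects pooling of per-cohort log hazard ratios."""

    pooled_log_hr: float
    pooled_se: float
    pooled_hr: float
    ci_low: float
    ci_high: float
    tau2: float
    q_stat: float
    q_df: int
    p_q: float
    p_meta: float
    k: int
    gene: str = ""
    endpoint: str = ""
    q_bh: float = field(default=np.nan)


def meta_random_effects(
    log_hrs: np.ndarray | list[float], ses: np.ndarray | list[float]
) -> MetaResult:
    """Pool per-cohort log hazard ratios under a random-effects model.

    DerSimonian-Laird moments estimator: with fixed-effect weights
    w_i = 1/se_i^2, Q = sum w_i (y_i - y_FE)^2 and
    tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)); random-effects
    weights are 1/(se_i^2 + tau^2).  Cochran's Q is tested on chi-square
    with k-1 df.  A single cohort passes through with tau^2 = 0 and Q
    undefined.
    """
    y = np.asarray(log_hrs, dtype=float)
    se = np.asarray(ses, dtype=float)
    if y.shape != se.shape or y.ndim != 1 or len(y) == 0:
        raise ValueError("log_hrs and ses must be equal-length 1-D sequences")
    if (se <= 0).any():
        raise ValueError("standard errors must be positive")
    k = len(y)
    if k == 1:
        pooled, pooled_se, tau2 = float(y[0]), float(se[0]), 0.0
        q_stat, q_df, p_q = np.nan, 0, np.nan
    else:
        w = 1.0 / se**2
        y_fe = float(np.sum(w * y) / np.sum(w))
        q_stat = float(np.sum(w * (y - y_fe) ** 2))
        q_df = k - 1
        denom = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (q_stat - q_df) / denom)
        w_star = 1.0 / (se**2 + tau2)
        pooled = float(np.sum(w_star * y) / np.sum(w_star))
        pooled_se = float(np.sum(w_star) ** -0.5)
        p_q = float(chi2.sf(q_stat, q_df))
    p_meta = float(2.0 * norm.sf(abs(pooled / pooled_se)))
    return MetaResult(
        pooled_log_hr=pooled,
        pooled_se=pooled_se,
        pooled_hr=float(np.exp(pooled)),
        ci_low=float(np.exp(pooled - Z975 * pooled_se)),
        ci_high=float(np.exp(pooled + Z975 * pooled_se)),
        tau2=float(tau2),
        q_stat=q_stat,
        q_df=q_df,
        p_q=p_q,
        p_meta=p_meta,
        k=k,
    )


def bh_adjust(
    pvals: np.ndarray | list[float], fdr: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up q-values and rejection flags at ``fdr``."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q, q <= fdr


def power_two_group(
    n_events: int, allocation_p: float, hr: float, alpha: float = 0.05
) -> float:
    """Schoenfeld approximation to the power of a two-group log-rank/Cox
    comparison: Phi(|ln hr| * sqrt(d * p * (1-p)) - z_{1-alpha/2})."""
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    if not 0.0 < allocation_p < 1.0:
        raise ValueError("allocation_p must lie in (0, 1)")
    if hr <= 0:
        raise ValueError("hazard ratio must be positive")
    z = abs(np.log(hr)) * np.sqrt(n_events * allocation_p * (1 - allocation_p))
    return float(norm.cdf(z - norm.ppf(1 - alpha / 2)))


def hr_for_power(
    n_events: int, allocation_p: float, power: float, alpha: float = 0.05
) -> float:
    """Smallest adverse hazard ratio detectable at the given power
    (inverse of the Schoenfeld approximation)."""
    z = norm.ppf(power) + norm.ppf(1 - alpha / 2)
    return float(np.exp(z / np.sqrt(n_events * allocation_p * (1 - allocation_p))))


def run_survival_screen(
    genes: list[str],
    cohorts: list[CohortSurvival],
    endpoints: tuple[str, ...] = ("os", "pfs"),
    fdr: float = 0.05,
    adjust_covariates: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene low-vs-high survival screen across cohorts.

    For each gene and endpoint: quartile groups per cohort, adjusted Cox
    fit, then random-effects pooling over the cohorts where the gene was
    measured.  BH is applied across genes separately within each endpoint.
    Returns (meta table, per-cohort Cox table).
    """
    if not genes:
        raise ValueError("empty gene list")
    for endpoint in endpoints:
        if endpoint not in ("os", "pfs"):
            raise ValueError(f"unknown endpoint {endpoint!r}")
    missing_everywhere = [
        g for g in genes if not any(g in c.expression.index for c in cohorts)
    ]
    if missing_everywhere:
        raise ValueError(
            f"genes absent from every cohort: {missing_everywhere[:5]}"
        )

    cox_rows: list[CoxResult] = []
    meta_rows: list[dict] = []
    for endpoint in endpoints:
        tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
        for gene in genes:
            fits: list[CoxResult] = []
            for cohort in cohorts:
                if gene not in cohort.expression.index:
                    logger.warning("gene %s absent from cohort %s", gene, cohort.name)
                    continue
                grp = expression_groups(cohort.expression.loc[gene])
                keep = grp.labels.isin(["low", "high"])
                clin = cohort.clinical[keep]
                res = cox_fit(
                    clin[tcol],
                    clin[ecol],
                    (grp.labels[keep] == "low").astype(int),
                    covariates=clin[["age", "sex", "iss"]] if adjust_covariates else None,
                    gene=gene,
                    cohort=cohort.name,
                    endpoint=endpoint,
                )
                cox_rows.append(res)
                if not res.flagged:
                    fits.append(res)
            if not fits:
                logger.warning("gene %s: no usable cohort fits for %s", gene, endpoint)
                continue
            meta = meta_random_effects(
                [f.log_hr for f in fits], [f.se for f in fits]
            )
            meta_rows.append(
                {
                    "gene": gene,
                    "endpoint": endpoint,
                    "k_cohorts": meta.k,
                    "pooled_log_hr": meta.pooled_log_hr,
                    "pooled_se": meta.pooled_se,
                    "pooled_hr": meta.pooled_hr,
                    "ci_low": meta.ci_low,
                    "ci_high": meta.ci_high,
                    "tau2": meta.tau2,
                    "q_stat": meta.q_stat,
                    "q_df": meta.q_df,
                    "p_q": meta.p_q,
                    "p_meta": meta.p_meta,
                }
            )

    meta_df = pd.DataFrame(meta_rows)
    if len(meta_df):
        meta_df["q_bh"] = np.nan
        meta_df["reject"] = False
        for endpoint in endpoints:
            mask = meta_df["endpoint"] == endpoint
            if mask.any():
                q, rej = bh_adjust(meta_df.loc[mask, "p_meta"].to_numpy(), fdr)
                meta_df.loc[mask, "q_bh"] = q
                meta_df.loc[mask, "reject"] = rej
    cox_df = pd.DataFrame([vars(r) for r in cox_rows])
    return meta_df, cox_df
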