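"""Efficacy, dispersion, Gaussian essentiality threshold and selectivity.

Efficacy E of a gene is its unified score at the X-th percentile most
sensitive cell line of a group (the k-th smallest score, k = max(1,
floor(n*X/100))).  A Gaussian fitted to the mode of the efficacy
distribution sets the essentiality threshold T = mu + sigma*Phi^{-1}(p)
with a default lower-tail probability of 0.001; genes with efficacy
strictly below T are called essential.  Dispersion D is the spread between
the k-th largest and k-th smallest score; selectivity U is the normalised
residual of D above its ordinary-least-squares trend on E, which separates
selectively essential genes from commonly essential ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import gaussian_kde, norm

from .containers import GaussianFit, UnifiedScores

logger = logging.getLogger("mmdep")


@dataclass
class EssentialityConfig:
    """Percentile and threshold settings for one cell-line group."""

    x: float = 25.0  # percentile of most-sensitive lines (25 target, 1 background)
    tail_p: float = 0.001
    kde_bandwidth_rule: str = "silverman"  # silverman | scott | fixed
    kde_bandwidth: float | None = None  # absolute bandwidth when rule == fixed

    def __post_init__(self) -> None:
        if not 0.0 < self.x < 50.0:
            raise ValueError("percentile x must lie in (0, 50)")
        if not 0.0 < self.tail_p < 0.5:
            raise ValueError("tail_p must lie in (0, 0.5)")
        if self.kde_bandwidth_rule not in ("silverman", "scott", "fixed"):
            raise ValueError("kde_bandwidth_rule must be silverman, scott or fixed")
        if self.kde_bandwidth_rule == "fixed" and not (self.kde_bandwidth or 0) > 0:
            raise ValueError("fixed bandwidth rule requires a positive kde_bandwidth")


def percentile_count(n_lines: int, x: float) -> int:
    """Number of most-sensitive lines at percentile ``x``: max(1, floor(n*x/100)).

    This mapping sends (34 lines, x=25) -> 8 and (449 lines, x=1) -> 4.
    """
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    if not 0.0 < x < 100.0:
        raise ValueError("percentile x must lie in (0, 100)")
    return max(1, int(np.floor(n_lines * x / 100.0)))


def _subset_scores(
    unified: UnifiedScores | pd.DataFrame, lines: list[str]
) -> pd.DataFrame:
    df = unified.scores if isinstance(unified, UnifiedScores) else unified
    if len(lines) < 2:
        raise ValueError("line subset must contain at least 2 lines")
    missing_lines = [l for l in lines if l not in df.columns]
    if missing_lines:
        raise ValueError(f"lines absent from score matrix: {missing_lines[:5]}")
    sub = df[lines]
    incomplete = sub.isna().any(axis=1)
    if incomplete.any():
        logger.warning(
            "dropping %d genes with missing scores in the line subset",
            int(incomplete.sum()),
        )
        sub = sub.loc[~incomplete]
    return sub


def efficacy(
    unified: UnifiedScores | pd.DataFrame, lines: list[str], x: float
) -> pd.Series:
    """Per-gene efficacy: the k-th smallest score across ``lines``."""
    sub = _subset_scores(unified, lines)
    k = percentile_count(len(lines), x)
    vals = np.partition(sub.to_numpy(), k - 1, axis=1)[:, k - 1]
    return pd.Series(vals, index=sub.index, name="efficacy")


def dispersion(
    unified: UnifiedScores | pd.DataFrame, lines: list[str], x: float
) -> pd.Series:
    """Per-gene dispersion: k-th largest minus k-th smallest score."""
    sub = _subset_scores(unified, lines)
    k = percentile_count(len(lines), x)
    arr = np.sort(sub.to_numpy(), axis=1)
    vals = arr[:, -k] - arr[:, k - 1]
    return pd.Series(vals, index=sub.index, name="dispersion")


def fit_gaussian_threshold(
    efficacies: pd.Series | np.ndarray, config: EssentialityConfig | None = None
) -> GaussianFit:
    """Fit a Gaussian to the mode of the efficacy distribution via KDE.

    The KDE (configured bandwidth rule) is evaluated on a 512-point grid
    spanning the data range plus one bandwidth on each side.  mu is the grid
    argmax; sigma comes from a least-squares fit of c*phi((s-mu)/sigma) to
    the KDE between the two half-maximum crossings around the mode — fitting
    only near the mode keeps the left tail of truly essential genes from
    inflating sigma.  The threshold is T = mu + sigma*Phi^{-1}(tail_p).
    """
    config = config if config is not None else EssentialityConfig()
    values = np.asarray(
        efficacies.to_numpy() if isinstance(efficacies, pd.Series) else efficacies,
        dtype=float,
    )
    if len(values) < 100:
        raise ValueError(f"need >= 100 efficacies to fit a threshold, got {len(values)}")
    if not np.isfinite(values).all():
        raise ValueError("efficacies must be finite")

    if config.kde_bandwidth_rule == "fixed":
        bw_method = config.kde_bandwidth / values.std(ddof=1)
    else:
        bw_method = config.kde_bandwidth_rule
    kde = gaussian_kde(values, bw_method=bw_method)
    bandwidth = float(kde.factor * values.std(ddof=1))

    grid = np.linspace(values.min() - bandwidth, values.max() + bandwidth, 512)
    density = kde(grid)
    i_mode = int(np.argmax(density))
    mu = float(grid[i_mode])
    half = density[i_mode] / 2.0

    below_left = np.nonzero(density[:i_mode] < half)[0]
    below_right = np.nonzero(density[i_mode + 1 :] < half)[0]
    if len(below_left) == 0 or len(below_right) == 0:
        raise ValueError(
            "no half-maximum interval brackets the KDE mode; the density may be "
            "multimodal or too flat — consider a different bandwidth"
        )
    lo = below_left[-1] + 1
    hi = i_mode + 1 + below_right[0]
    window, target = grid[lo:hi], density[lo:hi]

    def gauss(s: np.ndarray, c: float, sigma: float) -> np.ndarray:
        return c * np.exp(-0.5 * ((s - mu) / sigma) ** 2)

    fwhm_sigma = (grid[hi - 1] - grid[lo]) / 2.355 if hi - 1 > lo else bandwidth
    (c_hat, sigma_hat), _ = curve_fit(
        gauss, window, target, p0=[density[i_mode], max(fwhm_sigma, 1e-6)]
    )
    sigma_hat = abs(float(sigma_hat))
    threshold = mu + sigma_hat * float(norm.ppf(config.tail_p))
    return GaussianFit(mu=mu, sigma=sigma_hat, threshold=threshold, tail_p=config.tail_p)


def call_essential(efficacies: pd.Series, fit: GaussianFit) -> pd.Series:
    """Essential iff efficacy strictly below the threshold."""
    return (efficacies < fit.threshold).rename("essential")


def lineage_specific(
    essential_mm: set[str], essential_other: set[str]
) -> tuple[set[str], dict[str, int]]:
    """Genes essential only in the target lineage, plus Venn counts."""
    specific = set(essential_mm) - set(essential_other)
    summary = {
        "n_target": len(essential_mm),
        "n_background": len(essential_other),
        "n_shared": len(set(essential_mm) & set(essential_other)),
        "n_specific": len(specific),
    }
    return specific, summary


def selectivity(
    efficacy_values: pd.Series,
    dispersion_values: pd.Series,
    denominator: str = "fit",
) -> pd.DataFrame:
    """Selectivity U from the residual of dispersion above its linear trend
    on efficacy.

    An OLS line D_hat = a + b*E is fitted across genes; the residual is
    R = D - D_hat and U = R / D_hat.  ``denominator="dispersion"`` switches
    to U = R / D.  Genes with a non-positive denominator get NaN selectivity
    and are flagged for exclusion from ranking.
    """
    if denominator not in ("fit", "dispersion"):
        raise ValueError("denominator must be 'fit' or 'dispersion'")
    e = efficacy_values.astype(float)
    d = dispersion_values.reindex(e.index).astype(float)
    ok = np.isfinite(e) & np.isfinite(d)
    if int(ok.sum()) < 10:
        raise ValueError("need >= 10 genes with finite efficacy and dispersion")
    e, d = e[ok], d[ok]
    if np.isclose(e.to_numpy().var(), 0.0):
        raise ValueError("zero variance in efficacy: trend line undefined")

    design = np.column_stack([np.ones(len(e)), e.to_numpy()])
    (a, b), *_ = np.linalg.lstsq(design, d.to_numpy(), rcond=None)
    d_hat = a + b * e
    residual = d - d_hat
    denom = d_hat if denominator == "fit" else d
    u = residual / denom
    u[denom <= 0] = np.nan
    out = pd.DataFrame(
        {
            "efficacy": e,
            "dispersion": d,
            "dispersion_fit": d_hat,
            "residual": residual,
            "selectivity": u,
            "denominator_nonpositive": (denom <= 0),
        }
    )
    out.attrs["intercept"] = float(a)
    out.attrs["slope"] = float(b)
    return out


def essentiality_screen(
    unified: UnifiedScores,
    target_lines: list[str],
    background_lines: list[str],
    target_config: EssentialityConfig | None = None,
    background_config: EssentialityConfig | None = None,
) -> dict:
    """Full essentiality stage: per-group efficacy, thresholds, essential
    calls, lineage-specific set and target-group selectivity table."""
    target_config = target_config or EssentialityConfig(x=25.0)
    background_config = background_config or EssentialityConfig(x=1.0)

    eff_t = efficacy(unified, target_lines, target_config.x)
    eff_b = efficacy(unified, background_lines, background_config.x)
    fit_t = fit_gaussian_threshold(eff_t, target_config)
    fit_b = fit_gaussian_threshold(eff_b, background_config)
    ess_t = call_essential(eff_t, fit_t)
    ess_b = call_essential(eff_b, fit_b)
    specific, venn = lineage_specific(
        set(ess_t.index[ess_t]), set(ess_b.index[ess_b])
    )
    # selectivity is a population-level notion: a selectively essential gene
    # disperses across the full line panel, so E and D are taken over the
    # pooled target + background lines
    all_lines = list(target_lines) + list(background_lines)
    eff_all = efficacy(unified, all_lines, target_config.x)
    disp_all = dispersion(unified, all_lines, target_config.x)
    table = selectivity(eff_all, disp_all)
    table["efficacy_target"] = eff_t.reindex(table.index)
    table["essential"] = ess_t.reindex(table.index)
    return {
        "efficacy_target": eff_t,
        "efficacy_background": eff_b,
        "fit_target": fit_t,
        "fit_background": fit_b,
        "essential_target": ess_t,
        "essential_background": ess_b,
        "lineage_specific": specific,
        "venn": venn,
        "records": table,
    }
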