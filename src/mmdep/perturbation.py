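"""Unification of CRISPR and shRNA gene-effect scores.

The two platforms measure the same latent growth effect with different
noise, so the pipeline (i) imputes each platform's missing entries from the
other via a per-cell-line loess fit, (ii) estimates the data-driven mixing
ratio theta* from the first principal axis of the pooled (S_C, S_R)
scatter, and (iii) forms the unified score S_theta = theta*S_C +
(1-theta)*S_R.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .containers import ScreenMatrix, UnifiedScores

logger = logging.getLogger("mmdep")

MIN_DOUBLY_OBSERVED = 30


def _common_grid(crispr: ScreenMatrix, shrna: ScreenMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    genes = crispr.scores.index.intersection(shrna.scores.index)
    lines = crispr.scores.columns.intersection(shrna.scores.columns)
    if len(genes) == 0 or len(lines) == 0:
        raise ValueError("no common genes or cell lines between platforms")
    n_unmatched = (len(crispr.scores.index) - len(genes)) + (
        len(shrna.scores.index) - len(genes)
    )
    if n_unmatched:
        logger.info("platform intersection: %d unmatched gene rows dropped", n_unmatched)
    return crispr.scores.loc[genes, lines], shrna.scores.loc[genes, lines]


def _loess_predict(
    x_obs: np.ndarray, y_obs: np.ndarray, x_new: np.ndarray, span: float
) -> np.ndarray:
    """Loess fit of y on x at the observed points, evaluated at x_new by
    interpolation; predictions beyond the observed range are clamped to the
    fit at the nearest observed predictor."""
    order = np.argsort(x_obs, kind="stable")
    xs, ys = x_obs[order], y_obs[order]
    delta = 0.01 * (xs[-1] - xs[0]) if len(xs) > 200 else 0.0
    fitted = lowess(ys, xs, frac=span, it=3, delta=delta, is_sorted=True)
    # np.interp clamps outside [xs[0], xs[-1]] — the required edge behaviour
    return np.interp(x_new, fitted[:, 0], fitted[:, 1])


def impute_missing(
    crispr: ScreenMatrix, shrna: ScreenMatrix, span: float = 0.5
) -> tuple[ScreenMatrix, ScreenMatrix]:
    """Impute each platform's missing scores from the other platform.

    For every cell line, a loess curve of observed S_C against observed S_R
    across genes predicts missing S_C from that gene's S_R, and vice versa.
    Entries missing on both platforms stay missing (see
    :func:`flag_double_missing`).  A line with fewer than 30 doubly-observed
    genes is an error.
    """
    c_df, r_df = _common_grid(crispr, shrna)
    c = c_df.to_numpy(copy=True)
    r = r_df.to_numpy(copy=True)
    for j, line in enumerate(c_df.columns):
        c_col, r_col = c[:, j], r[:, j]
        both = ~np.isnan(c_col) & ~np.isnan(r_col)
        if both.sum() < MIN_DOUBLY_OBSERVED:
            raise ValueError(
                f"cell line {line!r} has only {int(both.sum())} genes observed on "
                f"both platforms (need >= {MIN_DOUBLY_OBSERVED})"
            )
        miss_c = np.isnan(c_col) & ~np.isnan(r_col)
        if miss_c.any():
            c_col[miss_c] = _loess_predict(r_col[both], c_col[both], r_col[miss_c], span)
        miss_r = np.isnan(r_col) & ~np.isnan(c_col) & ~miss_c
        if miss_r.any():
            r_col[miss_r] = _loess_predict(c_col[both], r_col[both], c_col[miss_r], span)
    n_double = int((np.isnan(c) & np.isnan(r)).sum())
    if n_double:
        logger.warning("impute_missing: %d entries missing on both platforms remain", n_double)
    out_c = ScreenMatrix(pd.DataFrame(c, index=c_df.index, columns=c_df.columns), "crispr", crispr.entrez)
    out_r = ScreenMatrix(pd.DataFrame(r, index=r_df.index, columns=r_df.columns), "shrna", shrna.entrez)
    return out_c, out_r


def flag_double_missing(
    crispr: ScreenMatrix, shrna: ScreenMatrix
) -> list[tuple[str, str]]:
    """(gene, line) pairs unobserved on both platforms; these cannot be
    imputed and force the gene to be dropped at unification."""
    c_df, r_df = _common_grid(crispr, shrna)
    mask = c_df.isna().to_numpy() & r_df.isna().to_numpy()
    gi, li = np.nonzero(mask)
    return [(c_df.index[i], c_df.columns[j]) for i, j in zip(gi, li)]


def select_theta(crispr: ScreenMatrix, shrna: ScreenMatrix) -> float:
    """Data-driven mixing ratio from the pooled (S_C, S_R) cloud.

    All gene x line score pairs are pooled and mean-centred; the first
    principal axis (v_C, v_R) of the 2x2 covariance, with sign fixed so
    v_C > 0, gives theta* = v_C / (v_C + v_R) — the weight at which the
    unified axis is parallel to the first principal component.
    """
    c_df, r_df = _common_grid(crispr, shrna)
    x = c_df.to_numpy().ravel()
    y = r_df.to_numpy().ravel()
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    if len(x) < 2:
        raise ValueError("need at least 2 score pairs")
    pts = np.column_stack([x - x.mean(), y - y.mean()])
    cov = pts.T @ pts / (len(x) - 1)
    if np.allclose(cov, 0.0):
        raise ValueError("degenerate covariance: all score pairs identical")
    eigvals, eigvecs = np.linalg.eigh(cov)
    v = eigvecs[:, np.argmax(eigvals)]
    if v[0] < 0 or (v[0] == 0 and v[1] < 0):
        v = -v
    return float(v[0] / (v[0] + v[1]))


def unify(
    crispr: ScreenMatrix, shrna: ScreenMatrix, theta: float
) -> UnifiedScores:
    """Weighted average S_theta = theta*S_C + (1-theta)*S_R on the common
    gene x line grid.

    Genes still carrying a missing value on any line (entries unobserved on
    both platforms) are dropped and reported in ``dropped_genes``.
    """
    if not 0.0 <= theta <= 1.0:
        raise ValueError(f"theta must lie in [0, 1], got {theta}")
    c_df, r_df = _common_grid(crispr, shrna)
    unified = theta * c_df + (1.0 - theta) * r_df
    incomplete = unified.isna().any(axis=1)
    dropped = list(unified.index[incomplete])
    if dropped:
        logger.warning("unify: dropped %d genes with unimputable entries", len(dropped))
        unified = unified.loc[~incomplete]
    screen = ScreenMatrix(unified, "unified", dict(crispr.entrez))
    return UnifiedScores(
        screen=screen,
        theta=theta,
        n_genes_common=len(c_df.index),
        dropped_genes=dropped,
    )
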