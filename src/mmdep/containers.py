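"""Core in-memory containers for the dependency-screen pipeline.

All matrices are held as pandas DataFrames oriented gene x (cell line or
patient); downstream code relies on that orientation, so the constructors
validate it once here instead of in every operation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_PLATFORMS = ("crispr", "shrna", "unified")


@dataclass
class ScreenMatrix:
    """Gene x cell-line perturbation scores for one platform.

    ``scores`` is indexed by gene symbol with cell-line identifiers as
    columns; NaN marks a missing measurement.  ``entrez`` optionally maps
    gene symbols to Entrez IDs parsed from "SYMBOL (ENTREZ)" labels; it is
    annotation only and never used as a join key.
    """

    scores: pd.DataFrame
    platform: str
    entrez: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.platform not in VALID_PLATFORMS:
            raise ValueError(
                f"platform must be one of {VALID_PLATFORMS}, got {self.platform!r}"
            )
        if self.scores.index.has_duplicates:
            dups = self.scores.index[self.scores.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols: {dups[:5]}")
        if self.scores.columns.has_duplicates:
            dups = self.scores.columns[self.scores.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate cell-line identifiers: {dups[:5]}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def line_ids(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def n_missing(self) -> int:
        return int(self.scores.isna().to_numpy().sum())


@dataclass
class LineMetadata:
    """Per-cell-line lineage labels used to split target vs background lines."""

    lineage: pd.Series  # index: line id, values: lineage label

    def __post_init__(self) -> None:
        if self.lineage.index.has_duplicates:
            raise ValueError("duplicate line identifiers in metadata")

    def lines_of(self, lineage: str) -> list[str]:
        return list(self.lineage.index[self.lineage == lineage])

    def lines_not_of(self, lineage: str) -> list[str]:
        return list(self.lineage.index[self.lineage != lineage])


@dataclass
class CohortSurvival:
    """One patient cohort: expression matrix plus clinical outcome table.

    ``expression`` is gene x patient; ``clinical`` is indexed by patient id
    with columns os_time, os_event, pfs_time, pfs_event, age, sex, iss.
    ISS may be missing (NaN); other columns may not.
    """

    name: str
    expression: pd.DataFrame
    clinical: pd.DataFrame

    CLINICAL_COLUMNS = ("os_time", "os_event", "pfs_time", "pfs_event", "age", "sex", "iss")

    def __post_init__(self) -> None:
        missing_cols = [c for c in self.CLINICAL_COLUMNS if c not in self.clinical.columns]
        if missing_cols:
            raise ValueError(f"clinical table missing columns: {missing_cols}")
        if list(self.expression.columns) != list(self.clinical.index):
            raise ValueError("expression columns and clinical index must match in order")
        for col in ("os_time", "pfs_time"):
            if (self.clinical[col] < 0).any():
                raise ValueError(f"negative {col}")
        for col in ("os_event", "pfs_event"):
            vals = set(self.clinical[col].unique())
            if not vals <= {0, 1}:
                raise ValueError(f"{col} must be binary 0/1, got {sorted(vals)[:5]}")
        iss = self.clinical["iss"].dropna()
        if not set(iss.unique()) <= {1, 2, 3}:
            raise ValueError("iss must be in {1,2,3} or missing")

    @property
    def patient_ids(self) -> list[str]:
        return list(self.clinical.index)

    @property
    def n_patients(self) -> int:
        return len(self.clinical)


@dataclass
class GeneSetCollection:
    """Annotation terms: term_id -> (name, member genes)."""

    names: dict[str, str]
    members: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for term, genes in self.members.items():
            if not genes:
                raise ValueError(f"term {term!r} has no member genes")
        if set(self.names) != set(self.members):
            raise ValueError("names and members must cover the same term ids")

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def restrict(self, universe: set[str]) -> "GeneSetCollection":
        """Intersect each term with ``universe``, dropping emptied terms."""
        members = {}
        names = {}
        for term, genes in self.members.items():
            inter = genes & universe
            if inter:
                members[term] = frozenset(inter)
                names[term] = self.names[term]
        return GeneSetCollection(names=names, members=members)


@dataclass
class UnifiedScores:
    """Unified perturbation score matrix S_theta = theta*S_C + (1-theta)*S_R."""

    screen: ScreenMatrix
    theta: float
    theta_pca: float | None = None
    n_genes_common: int = 0
    dropped_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError(f"theta must lie in [0, 1], got {self.theta}")

    @property
    def scores(self) -> pd.DataFrame:
        return self.screen.scores


@dataclass
class GaussianFit:
    """Normal curve fitted to an efficacy distribution, with its lower-tail
    essentiality threshold T = mu + sigma * Phi^{-1}(tail_p)."""

    mu: float
    sigma: float
    threshold: float
    tail_p: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        from scipy.stats import norm

        expected = self.mu + self.sigma * norm.ppf(self.tail_p)
        if not np.isclose(self.threshold, expected, rtol=0, atol=1e-9):
            raise ValueError("threshold inconsistent with mu, sigma and tail_p")
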