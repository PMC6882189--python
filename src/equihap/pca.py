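"""Population x haplogroup frequency tables and their principal components.

The phylogeographic PCA operates on a matrix of haplogroup frequencies
(percent) per population.  A packaged fixture ships the published world
survey: 59 populations by the 10 analysable control-region haplogroups
(D, I, EFG, H, L, M, N, OP, Q, R); haplogroups with no diagnostic motif
in the short window never enter the table.

``run_pca`` eigendecomposes either the correlation (default) or the
covariance matrix.  The ``cases`` argument controls the orientation:
with ``cases="haplogroups"`` the haplogroups are the observations and
the populations the variables — the convention under which per-
haplogroup factor scores are defined and which reproduces the published
variance figures for the world table — while ``cases="populations"``
treats the haplogroup columns as variables.  Factor scores use the
regression method (standardized principal-component scores); loading
signs are fixed so each component's largest-magnitude loading is
positive.
"""

from __future__ import annotations

import importlib.resources
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .motifs import UNCLASSIFIED, HaplogroupCall
from .window import SampleRecord

logger = logging.getLogger(__name__)

HAPLOGROUP_ORDER = ("D", "I", "EFG", "H", "L", "M", "N", "OP", "Q", "R")
ROW_SUM_TOLERANCE = 0.5  # absorbs 1-decimal printing of percentages


@dataclass
class FrequencyTable:
    """Populations x haplogroups percentage matrix with sample sizes."""

    populations: list[tuple[str, str, int]]  # (code, region, n)
    haplogroups: tuple[str, ...]
    values: np.ndarray  # percent, shape (n_populations, n_haplogroups)
    unclassified: np.ndarray | None = None  # percent per row, side column

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.populations), len(self.haplogroups)):
            raise ValueError("values shape does not match populations x haplogroups")
        if (self.values < 0).any() or (self.values > 100).any():
            raise ValueError("frequencies must lie in [0, 100]")
        for code, _region, n in self.populations:
            if n < 1:
                raise ValueError(f"population {code} has n < 1")
        sums = self.values.sum(axis=1)
        if self.unclassified is not None:
            sums = sums + np.asarray(self.unclassified, dtype=float)
        off = np.abs(sums - 100.0) > ROW_SUM_TOLERANCE
        if off.any():
            bad = [self.populations[i][0] for i in np.where(off)[0]]
            raise ValueError(f"rows do not sum to 100 +/- {ROW_SUM_TOLERANCE}: {bad}")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       haplogroups: tuple[str, ...] = HAPLOGROUP_ORDER) -> "FrequencyTable":
        pops = [(str(r.code), str(r.region), int(r.n)) for r in df.itertuples(index=False)]
        unclassified = (df["UNCLASSIFIED"].to_numpy(float)
                        if "UNCLASSIFIED" in df.columns else None)
        return cls(pops, tuple(haplogroups), df[list(haplogroups)].to_numpy(float),
                   unclassified)

    @classmethod
    def from_csv(cls, path: str | Path,
                 haplogroups: tuple[str, ...] = HAPLOGROUP_ORDER) -> "FrequencyTable":
        return cls.from_dataframe(pd.read_csv(path), haplogroups)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.haplogroups))
        df.insert(0, "code", [p[0] for p in self.populations])
        df.insert(1, "region", [p[1] for p in self.populations])
        df.insert(2, "n", [p[2] for p in self.populations])
        if self.unclassified is not None:
            df["UNCLASSIFIED"] = self.unclassified
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def load_world_frequency_table() -> FrequencyTable:
    """The packaged 59-population x 10-haplogroup world survey table."""
    ref = importlib.resources.files("equihap") / "data" / "world_haplogroup_frequencies.csv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path)
    df = df.drop(columns=["subregion"])
    return FrequencyTable.from_dataframe(df)


def build_frequency_table(haplogroup_calls: list[HaplogroupCall],
                          sample_records: list[SampleRecord],
                          level: str = "population",
                          haplogroups: tuple[str, ...] | None = None) -> FrequencyTable:
    """Percent haplogroup frequencies per population or region.

    UNCLASSIFIED calls are tracked in a side column and excluded from
    the haplogroup matrix (so matrix rows sum to 100 minus the
    unclassified share, and the table invariant checks the pair).
    """
    if level not in ("population", "region"):
        raise ValueError("level must be 'population' or 'region'")
    by_id = {r.sample_id: r for r in sample_records}
    key_of = (lambda r: r.population) if level == "population" else (lambda r: r.region)

    counts: dict[str, dict[str, int]] = {}
    regions: dict[str, str] = {}
    for call in haplogroup_calls:
        rec = by_id.get(call.sample_id)
        if rec is None:
            raise ValueError(f"call for {call.sample_id} has no sample record")
        key = key_of(rec)
        counts.setdefault(key, {})
        counts[key][call.haplogroup] = counts[key].get(call.haplogroup, 0) + 1
        regions[key] = rec.region

    if haplogroups is None:
        seen = {hg for c in counts.values() for hg in c if hg != UNCLASSIFIED}
        haplogroups = tuple(h for h in HAPLOGROUP_ORDER if h in seen) or tuple(sorted(seen))

    pops, rows, uncls = [], [], []
    for key in sorted(counts):
        n = sum(counts[key].values())
        if n == 0:
            logger.warning("row %s has no samples; excluded", key)
            continue
        pops.append((key, regions[key], n))
        rows.append([100.0 * counts[key].get(hg, 0) / n for hg in haplogroups])
        uncls.append(100.0 * counts[key].get(UNCLASSIFIED, 0) / n)
    return FrequencyTable(pops, tuple(haplogroups), np.array(rows),
                          unclassified=np.array(uncls))


@dataclass
class PCAResult:
    component_variance_percent: np.ndarray
    cumulative_percent: np.ndarray
    scores: np.ndarray        # cases x components (regression-method factor scores)
    loadings: np.ndarray      # variables x components
    standardization: str      # correlation | covariance
    cases: str                # populations | haplogroups
    case_labels: list[str] = field(default_factory=list)
    variable_labels: list[str] = field(default_factory=list)
    dropped_variables: list[str] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "component_variance_percent": [round(float(v), 10) for v in
                                           self.component_variance_percent],
            "cumulative_percent": [round(float(v), 10) for v in self.cumulative_percent],
            "standardization": self.standardization,
            "cases": self.cases,
            "case_labels": self.case_labels,
            "variable_labels": self.variable_labels,
            "dropped_variables": self.dropped_variables,
            "loadings": [[round(float(x), 10) for x in row] for row in self.loadings],
            "scores": [[round(float(x), 10) for x in row] for row in self.scores],
        }


def run_pca(freq_table: FrequencyTable, standardization: str = "correlation",
            cases: str = "populations") -> PCAResult:
    """PCA of a frequency table via eigendecomposition.

    ``standardization="correlation"`` analyses the correlation matrix of
    the variables (constant variables are dropped with a warning);
    ``"covariance"`` analyses the covariance matrix.  Variance
    percentages come from the eigenvalues; scores are regression-method
    factor scores of the cases.
    """
    if standardization not in ("correlation", "covariance"):
        raise ValueError("standardization must be 'correlation' or 'covariance'")
    if cases not in ("populations", "haplogroups"):
        raise ValueError("cases must be 'populations' or 'haplogroups'")

    pop_labels = [p[0] for p in freq_table.populations]
    hg_labels = list(freq_table.haplogroups)
    if cases == "populations":
        matrix = freq_table.values.copy()
        case_labels, variable_labels = pop_labels, hg_labels
    else:
        matrix = freq_table.values.T.copy()
        case_labels, variable_labels = hg_labels, pop_labels

    if matrix.shape[0] < 3:
        raise ValueError("PCA needs at least 3 cases")

    sd = matrix.std(axis=0, ddof=1)
    dropped: list[str] = []
    if standardization == "correlation":
        keep = sd > 0
        if not keep.all():
            dropped = [v for v, k in zip(variable_labels, keep) if not k]
            warnings.warn(f"constant variables dropped: {dropped}")
            matrix = matrix[:, keep]
            variable_labels = [v for v, k in zip(variable_labels, keep) if k]
            sd = sd[keep]
    if matrix.shape[1] < 2:
        raise ValueError("PCA needs at least 2 variables with nonzero variance")

    centred = matrix - matrix.mean(axis=0)
    if standardization == "correlation":
        z = centred / sd
        target = np.corrcoef(matrix, rowvar=False)
    else:
        z = centred
        target = np.cov(matrix, rowvar=False)

    eigvals, eigvecs = np.linalg.eigh(target)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]

    # deterministic sign: largest-magnitude loading entry positive
    for j in range(eigvecs.shape[1]):
        i_max = int(np.argmax(np.abs(eigvecs[:, j])))
        if eigvecs[i_max, j] < 0:
            eigvecs[:, j] *= -1.0

    pct = 100.0 * eigvals / eigvals.sum()
    loadings = eigvecs * np.sqrt(eigvals)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_sqrt = np.where(eigvals > 1e-12, 1.0 / np.sqrt(eigvals), 0.0)
    scores = z @ eigvecs * inv_sqrt

    return PCAResult(
        component_variance_percent=pct,
        cumulative_percent=np.cumsum(pct),
        scores=scores,
        loadings=loadings,
        standardization=standardization,
        cases=cases,
        case_labels=case_labels,
        variable_labels=variable_labels,
        dropped_variables=dropped,
    )


def world_survey_pca(freq_table: FrequencyTable | None = None) -> PCAResult:
    """The published world-survey PCA convention.

    Correlation-matrix PCA with haplogroups as cases and populations as
    variables; this is the orientation under which per-haplogroup
    regression factor scores are defined and which reproduces the
    printed cumulative-variance figures for the world table.
    """
    if freq_table is None:
        freq_table = load_world_frequency_table()
    return run_pca(freq_table, standardization="correlation", cases="haplogroups")


def aggregate_table(freq_table: FrequencyTable,
                    partition: dict[str, str]) -> FrequencyTable:
    """Pool populations into groups (sample-weighted) per a code->group map."""
    missing = [p[0] for p in freq_table.populations if p[0] not in partition]
    if missing:
        raise ValueError(f"partition does not cover populations: {missing}")
    groups: dict[str, list[int]] = {}
    for i, (code, _region, _n) in enumerate(freq_table.populations):
        groups.setdefault(partition[code], []).append(i)
    pops, rows = [], []
    for gname in sorted(groups):
        idx = groups[gname]
        if not idx:
            raise ValueError(f"partition group {gname!r} is empty")
        ns = np.array([freq_table.populations[i][2] for i in idx], dtype=float)
        pooled = (freq_table.values[idx].T @ ns) / ns.sum()
        pops.append((gname, gname, int(ns.sum())))
        rows.append(pooled)
    return FrequencyTable(pops, freq_table.haplogroups, np.array(rows))


def region_subdivision_pca(freq_table: FrequencyTable,
                           partitions: list[dict[str, str]],
                           standardization: str = "correlation",
                           cases: str = "haplogroups") -> list[PCAResult]:
    """One PCA per nested partition level, pooling rows before analysis.

    Each partition maps every population code to a group label; a
    trivial partition (each code its own group) reproduces ``run_pca``
    on the original table.
    """
    results = []
    for partition in partitions:
        results.append(run_pca(aggregate_table(freq_table, partition),
                               standardization=standardization, cases=cases))
    return results
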