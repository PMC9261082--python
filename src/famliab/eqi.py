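"""County-level environmental quality indices (EQIs) by principal components.

Each EQI domain (air, water, land, sociodemographic, built) summarizes many
county-level variables as the first principal component of the
column-standardized county x variable matrix. The sign of PC1 is fixed so
that higher scores mean poorer environmental quality (positive correlation
with the per-county mean of the standardized variables), and scores are
converted to population percentiles with the midrank convention before any
non-linear modelling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

EQI_DOMAINS = ("air", "water", "land", "socio", "built")
EQI_COLUMNS = ["eqi_air", "eqi_water", "eqi_land", "eqi_socio", "eqi_built"]


@dataclass
class PollutantMatrix:
    """County x variable matrix (e.g. 87 air pollutants per county)."""

    county_ids: np.ndarray
    variable_names: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.county_ids = np.asarray(self.county_ids)
        self.variable_names = np.asarray(self.variable_names)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-d matrix")
        n, p = self.values.shape
        if n != len(self.county_ids) or p != len(self.variable_names):
            raise ValueError("values shape inconsistent with labels")
        if n < 3:
            raise ValueError("need at least 3 counties")
        if p < 2:
            raise ValueError("need at least 2 variables")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("pollutant matrix contains missing/non-finite entries")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PollutantMatrix":
        if "county_id" not in df.columns:
            raise ValueError("pollutant table must have a county_id column")
        df = df.set_index("county_id")
        return cls(df.index.to_numpy(), df.columns.to_numpy(), df.to_numpy())

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(self.values, columns=self.variable_names)
        out.insert(0, "county_id", self.county_ids)
        return out


@dataclass
class EqiResult:
    """PC1/PC2 summary of one EQI domain."""

    scores: pd.Series          # per-county PC1 (zero mean)
    loadings: pd.Series        # per-variable PC1 weight (unit norm)
    variance_explained_pc1: float
    scores_pc2: pd.Series


def compute_eqi(m: PollutantMatrix) -> EqiResult:
    """First two principal components of the standardized pollutant matrix.

    Columns are standardized to zero mean / unit variance (correlation-matrix
    PCA), so the index is invariant to the incommensurable units of the raw
    variables. PC1 is oriented to correlate positively with the per-county
    mean of the standardized variables ("higher score = poorer quality").
    """
    X = m.values
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(
            f"constant column (zero variance): {m.variable_names[dead[0]]!r}"
        )
    Z = (X - mu) / sd
    n_comp = min(2, Z.shape[0] - 1, Z.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(Z)
    loadings = pca.components_
    if n_comp < 2:  # degenerate second component
        scores = np.column_stack([scores, np.zeros(len(Z))])
        loadings = np.vstack([loadings, np.zeros(Z.shape[1])])

    rowmean = Z.mean(axis=1)
    for k in range(2):
        c = float(scores[:, k] @ rowmean)
        if c < 0 or (c == 0 and loadings[k][np.argmax(loadings[k] != 0)] < 0):
            scores[:, k] *= -1
            loadings[k] *= -1

    idx = pd.Index(m.county_ids, name="county_id")
    return EqiResult(
        scores=pd.Series(scores[:, 0], index=idx, name="pc1_score"),
        loadings=pd.Series(loadings[0], index=pd.Index(m.variable_names, name="variable"),
                           name="pc1_loading"),
        variance_explained_pc1=float(pca.explained_variance_ratio_[0]),
        scores_pc2=pd.Series(scores[:, 1], index=idx, name="pc2_score"),
    )


def to_percentiles(scores, query) -> np.ndarray | float:
    """Midrank percentile of ``query`` within the reference ``scores``.

    percentile = 100 * (#{scores < q} + 0.5 * #{scores == q}) / n, so ties
    and repeated reference values are handled symmetrically and the result
    is monotone non-decreasing in the query.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty reference score set")
    q = np.asarray(query, dtype=float)
    s = np.sort(scores)
    below = np.searchsorted(s, q, side="left")
    upto = np.searchsorted(s, q, side="right")
    pct = 100.0 * (below + 0.5 * (upto - below)) / scores.size
    return float(pct) if np.isscalar(query) or q.ndim == 0 else pct


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_pollutant_matrix(path) -> PollutantMatrix:
    return PollutantMatrix.from_frame(pd.read_csv(path, dtype={"county_id": str}))


def read_eqi_table(path) -> pd.DataFrame:
    """County EQI table: county_id plus the five domain score columns."""
    df = pd.read_csv(path, dtype={"county_id": str})
    missing = [c for c in ["county_id", *EQI_COLUMNS] if c not in df.columns]
    if missing:
        raise ValueError(f"EQI table missing columns: {missing}")
    if df["county_id"].duplicated().any():
        raise ValueError("EQI table has duplicate county_id rows")
    return df.set_index("county_id")[EQI_COLUMNS]


def write_eqi_table(table: pd.DataFrame, path) -> None:
    table.reset_index().to_csv(path, index=False)


def write_eqi_result(result: EqiResult, out_dir) -> None:
    """Persist one domain's index: scores CSV, loadings CSV, metadata JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frame = result.scores.to_frame()
    frame["pc2_score"] = result.scores_pc2
    frame.to_csv(out / "scores.csv")
    result.loadings.to_frame().to_csv(out / "loadings.csv")
    meta = {
        "variance_explained_pc1": result.variance_explained_pc1,
        "orientation": "pc1 correlates positively with mean standardized variable",
        "n_counties": int(len(result.scores)),
        "n_variables": int(len(result.loadings)),
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=2))
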