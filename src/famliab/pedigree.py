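"""Nuclear-family cohort data model, kinship structure, and cohort I/O.

A cohort is a set of nuclear families (two unrelated parents plus at least
one child aged 16+), each family resident in a single county. Disease
status is a binary indicator derived by thresholding a diagnosis-code
count. The kinship structure is the classical one for nuclear families:
additive-genetic correlation 0.5 between parent and child and between full
siblings, 0 between the two parents.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd

ROLES = ("father", "mother", "child")
SEXES = ("male", "female")
SHARING_LAYERS = ("family", "couple", "sibling", "place")
CASE_RULES = {"at_least_1": 1, "at_least_2": 2}

#: canonical cohort CSV columns, in order
COHORT_COLUMNS = [
    "person_id",
    "family_id",
    "role",
    "sex",
    "age",
    "county_id",
    "dx_code_count",
]


class CohortError(ValueError):
    """Structured cohort validation failure, naming the offending row/family."""


@dataclass(frozen=True)
class Individual:
    person_id: str
    family_id: str
    role: str
    sex: str
    age: int
    county_id: str
    dx_code_count: int
    case: int

    def __post_init__(self):
        if self.role not in ROLES:
            raise CohortError(f"person {self.person_id}: unknown role {self.role!r}")
        if self.sex not in SEXES:
            raise CohortError(f"person {self.person_id}: unknown sex {self.sex!r}")
        if self.age < 16:
            raise CohortError(f"person {self.person_id}: age {self.age} < 16")
        if self.dx_code_count < 0:
            raise CohortError(f"person {self.person_id}: negative dx_code_count")
        if self.case not in (0, 1):
            raise CohortError(f"person {self.person_id}: case must be 0/1")

    @property
    def is_parent(self) -> bool:
        return self.role in ("father", "mother")


@dataclass(frozen=True)
class Family:
    family_id: str
    father: Individual
    mother: Individual
    children: tuple
    county_id: str

    def __post_init__(self):
        if len(self.children) < 1:
            raise CohortError(f"family {self.family_id}: needs at least one child")
        members = [self.father, self.mother, *self.children]
        for m in members:
            if m.family_id != self.family_id:
                raise CohortError(
                    f"family {self.family_id}: member {m.person_id} has family_id {m.family_id}"
                )
            if m.county_id != self.county_id:
                raise CohortError(
                    f"family {self.family_id}: member {m.person_id} lives in county "
                    f"{m.county_id}, family county is {self.county_id}"
                )
        if self.father.role != "father" or self.mother.role != "mother":
            raise CohortError(f"family {self.family_id}: mislabelled parent roles")

    @property
    def members(self) -> list:
        return [self.father, self.mother, *self.children]

    @property
    def size(self) -> int:
        return 2 + len(self.children)


@dataclass
class Cohort:
    """Validated cohort; canonical storage is a tidy per-individual frame."""

    df: pd.DataFrame
    case_rule: str = "at_least_2"

    def __post_init__(self):
        self.df = _validate_frame(self.df, self.case_rule)

    # -- basic accessors -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.df)

    @property
    def n_families(self) -> int:
        return self.df["family_id"].nunique()

    @property
    def n_cases(self) -> int:
        return int(self.df["case"].sum())

    @property
    def county_ids(self) -> set:
        return set(self.df["county_id"].unique())

    @property
    def families(self) -> list:
        """Materialize Family objects (intended for small cohorts / tests)."""
        out = []
        for fid, grp in self.df.groupby("family_id", sort=True):
            inds = {row.person_id: _row_to_individual(row) for row in grp.itertuples()}
            father = next(v for v in inds.values() if v.role == "father")
            mother = next(v for v in inds.values() if v.role == "mother")
            children = tuple(v for v in inds.values() if v.role == "child")
            out.append(Family(str(fid), father, mother, children, father.county_id))
        return out

    def individual(self, person_id: str) -> Individual:
        hit = self.df[self.df["person_id"] == person_id]
        if hit.empty:
            raise CohortError(f"unknown person_id {person_id!r}")
        return _row_to_individual(next(hit.itertuples()))

    # -- fast array views for inference ---------------------------------
    def index_arrays(self) -> dict:
        """Integer-coded arrays used by the samplers and simulators.

        Returns family/county codes, parent/child masks, each family's
        father and mother row positions, and the outcome vector, all
        aligned with ``self.df`` row order.
        """
        df = self.df
        fam_codes, fam_ids = pd.factorize(df["family_id"], sort=True)
        cty_codes, cty_ids = pd.factorize(df["county_id"], sort=True)
        role = df["role"].to_numpy()
        is_father = role == "father"
        is_mother = role == "mother"
        is_child = role == "child"
        n_fam = len(fam_ids)
        father_pos = np.full(n_fam, -1, dtype=np.int64)
        mother_pos = np.full(n_fam, -1, dtype=np.int64)
        rows = np.arange(len(df))
        father_pos[fam_codes[is_father]] = rows[is_father]
        mother_pos[fam_codes[is_mother]] = rows[is_mother]
        return {
            "fam": fam_codes.astype(np.int64),
            "family_ids": np.asarray(fam_ids),
            "county": cty_codes.astype(np.int64),
            "county_ids": np.asarray(cty_ids),
            "is_parent": is_father | is_mother,
            "is_child": is_child,
            "father_pos": father_pos,
            "mother_pos": mother_pos,
            "sex_male": (df["sex"].to_numpy() == "male").astype(float),
            "age": df["age"].to_numpy(dtype=float),
            "case": df["case"].to_numpy(dtype=np.int8),
        }


def _row_to_individual(row) -> Individual:
    return Individual(
        person_id=str(row.person_id),
        family_id=str(row.family_id),
        role=str(row.role),
        sex=str(row.sex),
        age=int(row.age),
        county_id=str(row.county_id),
        dx_code_count=int(row.dx_code_count),
        case=int(row.case),
    )


def _validate_frame(df: pd.DataFrame, case_rule: str) -> pd.DataFrame:
    if case_rule not in CASE_RULES:
        raise CohortError(f"unknown case_rule {case_rule!r}")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortError(f"cohort table missing columns: {missing}")
    df = df.loc[:, COHORT_COLUMNS].copy()
    for col in ("person_id", "family_id", "county_id", "role", "sex"):
        if df[col].isna().any():
            bad = int(df.index[df[col].isna()][0])
            raise CohortError(f"row {bad}: missing value in column {col!r}")
        df[col] = df[col].astype(str)
    for col in ("age", "dx_code_count"):
        if df[col].isna().any():
            bad = int(df.index[df[col].isna()][0])
            raise CohortError(f"row {bad}: missing value in column {col!r}")
        df[col] = df[col].astype(np.int64)

    dup = df["person_id"].duplicated()
    if dup.any():
        raise CohortError(f"duplicate person_id {df.loc[dup.idxmax(), 'person_id']!r}")
    bad_role = ~df["role"].isin(ROLES)
    if bad_role.any():
        raise CohortError(f"row {int(df.index[bad_role][0])}: invalid role")
    bad_sex = ~df["sex"].isin(SEXES)
    if bad_sex.any():
        raise CohortError(f"row {int(df.index[bad_sex][0])}: invalid sex")
    if (df["age"] < 16).any():
        bad = df.loc[df["age"] < 16, "person_id"].iloc[0]
        raise CohortError(f"person {bad!r}: age below 16")
    if (df["dx_code_count"] < 0).any():
        bad = df.loc[df["dx_code_count"] < 0, "person_id"].iloc[0]
        raise CohortError(f"person {bad!r}: negative dx_code_count")

    grp = df.groupby("family_id", sort=False)
    role_counts = grp["role"].value_counts().unstack(fill_value=0)
    for need in ROLES:
        if need not in role_counts:
            role_counts[need] = 0
    bad_fam = role_counts.index[(role_counts["father"] != 1) | (role_counts["mother"] != 1)]
    if len(bad_fam):
        raise CohortError(
            f"family {bad_fam[0]!r}: must have exactly one father and one mother"
        )
    bad_fam = role_counts.index[role_counts["child"] < 1]
    if len(bad_fam):
        raise CohortError(f"family {bad_fam[0]!r}: must have at least one child")
    n_cty = grp["county_id"].nunique()
    bad_fam = n_cty.index[n_cty > 1]
    if len(bad_fam):
        raise CohortError(
            f"family {bad_fam[0]!r}: members in different counties "
            "(county is a family-level attribute)"
        )

    threshold = CASE_RULES[case_rule]
    df["case"] = (df["dx_code_count"] >= threshold).astype(np.int8)
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# kinship / environment sharing
# ---------------------------------------------------------------------------

def genetic_correlation(i: Individual, j: Individual) -> float:
    """Expected additive-genetic correlation between two cohort members.

    1 on the diagonal; 0.5 for parent-child and full-sibling pairs; 0 for
    the two (unrelated) parents and for any cross-family pair.
    """
    if i.person_id == j.person_id:
        return 1.0
    if i.family_id != j.family_id:
        return 0.0
    if i.role == "child" and j.role == "child":
        return 0.5
    if i.is_parent and j.is_parent:
        return 0.0  # spouses assumed unrelated
    return 0.5  # parent-child


def sharing_indicator(i: Individual, j: Individual, layer: str) -> int:
    """1 iff ``i`` and ``j`` share the named environmental layer.

    Layers: ``family`` (whole household), ``couple`` (the two parents),
    ``sibling`` (the children of a family), ``place`` (county of
    residence). On the diagonal the indicator is 1 only if the individual
    carries the layer at all (children carry ``sibling``, parents carry
    ``couple``; everyone carries ``family`` and ``place``).
    """
    if layer not in SHARING_LAYERS:
        raise ValueError(f"unknown sharing layer {layer!r}")
    if layer == "place":
        return int(i.county_id == j.county_id)
    same_family = i.family_id == j.family_id
    if layer == "family":
        return int(same_family)
    if layer == "couple":
        return int(same_family and i.is_parent and j.is_parent)
    return int(same_family and i.role == "child" and j.role == "child")


def relatedness_matrix(family: Family) -> np.ndarray:
    """Expected additive-genetic correlation matrix for one family.

    Rows/columns ordered father, mother, then children.
    """
    members = family.members
    n = len(members)
    K = np.empty((n, n))
    for a in range(n):
        for b in range(n):
            K[a, b] = genetic_correlation(members[a], members[b])
    return K


# ---------------------------------------------------------------------------
# I/O and summaries
# ---------------------------------------------------------------------------

def read_cohort(path, case_rule: Literal["at_least_1", "at_least_2"] = "at_least_2") -> Cohort:
    """Read a cohort CSV and derive case status from the code-count rule."""
    df = pd.read_csv(path, dtype={"person_id": str, "family_id": str, "county_id": str})
    return Cohort(df, case_rule=case_rule)


def write_cohort(cohort: Cohort, path) -> None:
    cohort.df.loc[:, COHORT_COLUMNS].to_csv(path, index=False)


def prevalence(n_total: int, n_case: int) -> float:
    """Percentage of cases; e.g. (1000, 12) -> 1.2."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_case <= n_total:
        raise ValueError("n_case must lie in [0, n_total]")
    return 100.0 * n_case / n_total
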