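"""Synthetic nuclear-family cohorts with the generative structure the
liability models assume.

The generator is the exact counterpart of the fitted model: standardized
latent factors (kinship-correlated genetics, family / couple / sibling /
county environments, individual noise) combine additively — plus
multiplicative gene-environment products — into a liability, which is
thresholded (probit) or Bernoulli-sampled (logit) into a binary diagnosis.
County environmental quality comes from a one-factor pollutant model so the
PCA index stage has a well-defined PC1. This makes every downstream stage
(PCA, MCMC, WAIC, variance partition) testable against known ground truth
without any external data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, special

from .eqi import EQI_COLUMNS, PollutantMatrix
from .models import COMPONENTS
from .pedigree import Cohort
from ._utils import substream

#: components whose latents load only on parents / only on children
PARENT_ONLY = {"c", "hc"}
CHILD_ONLY = {"s", "hs"}


@dataclass
class TruthConfig:
    """Ground-truth generative parameters for a synthetic cohort.

    ``sigma2`` maps variance components to liability variances; with the
    default zero covariate effects, component *fractions* of
    ``sum(sigma2)`` are exactly the h2/f2/... statistics the analysis
    estimates. The intercept is calibrated to ``target_prevalence`` unless
    given explicitly.
    """

    n_families: int = 1000
    n_counties: int = 100
    sigma2: dict = field(default_factory=lambda: {"h": 0.5, "e": 0.5})
    children_lambda: float = 0.8      # children per family = 1 + Poisson, capped
    max_children: int = 4
    beta_sex: float = 0.0
    beta_age: float = 0.0
    beta_eqi: tuple = (0.0, 0.0, 0.0, 0.0, 0.0)
    intercept: float | None = None
    link: str = "probit"
    target_prevalence: float = 0.10
    subthreshold_code_rate: float = 0.005  # single-code (non-case) rate in controls
    seed: int = 0

    def __post_init__(self):
        unknown = set(self.sigma2) - set(COMPONENTS)
        if unknown:
            raise ValueError(f"unknown variance components {sorted(unknown)}")
        if any(v < 0 for v in self.sigma2.values()):
            raise ValueError("variances must be non-negative")
        if self.sigma2.get("e", 0.0) <= 0:
            raise ValueError("the individual component 'e' must be positive")
        if not 0 < self.target_prevalence <= 0.5:
            raise ValueError("target_prevalence must lie in (0, 0.5]")
        if self.link not in ("probit", "logit"):
            raise ValueError(f"unknown link {self.link!r}")
        if self.n_families < 1 or self.n_counties < 1:
            raise ValueError("need at least one family and one county")
        self.beta_eqi = tuple(float(b) for b in self.beta_eqi)
        if len(self.beta_eqi) != 5:
            raise ValueError("beta_eqi must have five entries (one per EQI domain)")
        self.sigma2 = {k: float(v) for k, v in self.sigma2.items()}
        if self.intercept is not None:
            self.intercept = float(self.intercept)

    @property
    def total_variance(self) -> float:
        return float(sum(self.sigma2.values()))

    def sigma(self, comp: str) -> float:
        return float(np.sqrt(self.sigma2.get(comp, 0.0)))

    def fractions(self) -> dict:
        v = self.total_variance
        return {k: self.sigma2.get(k, 0.0) / v for k in COMPONENTS if k in self.sigma2}

    def config_hash(self) -> str:
        payload = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_truth_config(name: str) -> TruthConfig:
    """Shipped ground-truth configurations (``im2_recovery``, ``lm0_recovery``)."""
    text = resources.files("famliab.data").joinpath(f"truth_{name}.yaml").read_text()
    return TruthConfig(**yaml.safe_load(text))


# ---------------------------------------------------------------------------
# counties and EQIs
# ---------------------------------------------------------------------------

def simulate_counties(
    n_counties: int,
    n_pollutants: int,
    seed: int,
    factor_share: float = 0.5,
    cross_domain_corr: float = 0.3,
) -> tuple[PollutantMatrix, pd.DataFrame]:
    """One-factor county pollutant matrix plus five correlated EQI domains.

    Each pollutant is ``sqrt(factor_share)`` times a county-level air factor
    plus independent noise, so any two pollutants correlate at
    ``factor_share`` and PC1 of the correlation matrix explains
    ``(1 + (p-1) * factor_share) / p`` of the variance. The five domain
    scores share a common county factor with pairwise correlation
    ``cross_domain_corr``.
    """
    if n_counties < 3:
        raise ValueError("need at least 3 counties")
    if n_pollutants < 2:
        raise ValueError("need at least 2 pollutants")
    if not 0 <= factor_share <= 1:
        raise ValueError("factor_share must lie in [0, 1]")
    if not 0 <= cross_domain_corr < 1:
        raise ValueError("cross_domain_corr must lie in [0, 1)")
    rng = substream(seed, "counties")
    county_ids = np.array([f"c{k:05d}" for k in range(n_counties)])

    common = rng.standard_normal(n_counties)
    own = rng.standard_normal((n_counties, 5))
    factors = np.sqrt(cross_domain_corr) * common[:, None] + np.sqrt(1 - cross_domain_corr) * own

    lam = np.sqrt(factor_share)
    noise = rng.standard_normal((n_counties, n_pollutants))
    values = lam * factors[:, [0]] + np.sqrt(1 - factor_share) * noise
    names = np.array([f"pollutant_{v:03d}" for v in range(n_pollutants)])
    matrix = PollutantMatrix(county_ids, names, values)

    z = (factors - factors.mean(axis=0)) / factors.std(axis=0, ddof=1)
    table = pd.DataFrame(z, columns=EQI_COLUMNS,
                         index=pd.Index(county_ids, name="county_id"))
    return matrix, table


# ---------------------------------------------------------------------------
# family structure
# ---------------------------------------------------------------------------

def simulate_family_structure(truth: TruthConfig, county_ids=None) -> Cohort:
    """Nuclear-family skeleton: ids, roles, sexes, ages, county assignment.

    Diagnosis columns are zero-filled; :func:`simulate_liability_and_outcome`
    overwrites them.
    """
    rng = substream(truth.seed, "structure")
    if county_ids is None:
        county_ids = np.array([f"c{k:05d}" for k in range(truth.n_counties)])
    county_ids = np.asarray(county_ids)

    n_children = 1 + rng.poisson(truth.children_lambda, truth.n_families)
    n_children = np.minimum(n_children, truth.max_children)
    fam_county = rng.choice(county_ids, size=truth.n_families)

    sizes = 2 + n_children
    n = int(sizes.sum())
    fam_of = np.repeat(np.arange(truth.n_families), sizes)
    first = np.repeat(np.cumsum(sizes) - sizes, sizes)
    rank = np.arange(n) - first  # 0 = father, 1 = mother, 2+ = children
    role = np.where(rank == 0, "father", np.where(rank == 1, "mother", "child"))
    child_sex = np.where(rng.random(n) < 0.5, "male", "female")
    sex = np.where(rank == 0, "male", np.where(rank == 1, "female", child_sex))

    df = pd.DataFrame({
        "person_id": np.char.add("p", np.char.zfill(np.arange(n).astype(str), 8)),
        "family_id": np.char.add("f", np.char.zfill(fam_of.astype(str), 7)),
        "role": role,
        "sex": sex,
        "age": rng.integers(16, 65, size=n),
        "county_id": fam_county[fam_of],
        "dx_code_count": np.zeros(n, dtype=np.int64),
    })
    return Cohort(df)


def simulate_genetic_latents(cohort: Cohort, seed_or_rng) -> np.ndarray:
    """Standardized additive-genetic values with nuclear-family kinship.

    Parents are independent standard normals; each child is the midparent
    value plus independent N(0, 1/2) segregation noise, giving unit child
    variance and correlation 1/2 for parent-child and sibling pairs.
    """
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else substream(seed_or_rng, "genetics"))
    ix = cohort.index_arrays()
    n = cohort.n_individuals
    A = rng.standard_normal(n)
    child = ix["is_child"]
    fam = ix["fam"][child]
    mid = 0.5 * (A[ix["father_pos"][fam]] + A[ix["mother_pos"][fam]])
    A[child] = mid + np.sqrt(0.5) * rng.standard_normal(child.sum())
    return A


def simulate_shared_latents(cohort: Cohort, rng: np.random.Generator) -> dict:
    """Per-family F/C/S, per-county P, per-individual E and G factors."""
    ix = cohort.index_arrays()
    n_fam = len(ix["family_ids"])
    n_cty = len(ix["county_ids"])
    n = cohort.n_individuals
    return {
        "F": rng.standard_normal(n_fam),
        "C": rng.standard_normal(n_fam),
        "S": rng.standard_normal(n_fam),
        "P": rng.standard_normal(n_cty),
        "E": rng.standard_normal(n),
        "G": rng.standard_normal(n),
    }


# ---------------------------------------------------------------------------
# liability and outcome
# ---------------------------------------------------------------------------

def calibrate_intercept(truth: TruthConfig) -> float:
    """Intercept giving the target marginal prevalence at reference covariates.

    probit: ``sqrt(V) * Phi^-1(p)`` with ``V = sum(sigma2)``; logit: 1-d
    root-find on the Gauss-Hermite approximation of the marginal prevalence
    of a logistic outcome with N(b, V) liability mean.
    """
    p = truth.target_prevalence
    if not np.isfinite(p):
        raise ValueError("target prevalence must be finite")
    v = truth.total_variance
    if truth.link == "probit":
        return float(np.sqrt(v) * special.ndtri(p))
    nodes, weights = np.polynomial.hermite_e.hermegauss(61)
    weights = weights / weights.sum()

    def marginal(b):
        return float(weights @ special.expit(b + np.sqrt(v) * nodes)) - p

    return float(optimize.brentq(marginal, -60.0, 60.0))


def simulate_liability_and_outcome(
    cohort: Cohort,
    truth: TruthConfig,
    eqi_table: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Draw latents, build the liability, and threshold it into diagnoses.

    Returns a frame aligned with the cohort (liability, case) and the
    latent draws used (for structural tests). Couple-shared terms load on
    parents only, sibling-shared terms on children only; every product term
    uses independent standardized factors so each contributes exactly its
    ``sigma2`` to the liability variance.
    """
    if rng is None:
        rng = substream(truth.seed, "liability")
    missing = cohort.county_ids - set(eqi_table.index)
    if missing:
        raise ValueError(f"EQI table lacks counties: {sorted(missing)[:5]}")

    ix = cohort.index_arrays()
    A = simulate_genetic_latents(cohort, rng)
    lat = simulate_shared_latents(cohort, rng)
    fam, cty = ix["fam"], ix["county"]
    par = ix["is_parent"].astype(float)
    chi = ix["is_child"].astype(float)
    s = truth.sigma

    age = ix["age"]
    age_sd = age.std() or 1.0
    x_fixed = (truth.beta_sex * ix["sex_male"]
               + truth.beta_age * (age - age.mean()) / age_sd)
    eqi_vals = eqi_table.loc[ix["county_ids"], EQI_COLUMNS].to_numpy()[cty]
    x_fixed = x_fixed + eqi_vals @ np.asarray(truth.beta_eqi)

    intercept = truth.intercept if truth.intercept is not None else calibrate_intercept(truth)
    eta = (
        intercept + x_fixed
        + s("h") * A
        + s("f") * lat["F"][fam]
        + s("c") * lat["C"][fam] * par
        + s("s") * lat["S"][fam] * chi
        + s("p") * lat["P"][cty]
        + s("hf") * A * lat["F"][fam]
        + s("hc") * A * lat["C"][fam] * par
        + s("hs") * A * lat["S"][fam] * chi
        + s("he") * A * lat["G"]
        + s("e") * lat["E"]
    )
    if truth.link == "probit":
        case = (eta > 0).astype(np.int8)
    else:
        case = (rng.random(len(eta)) < special.expit(eta)).astype(np.int8)

    out = pd.DataFrame({"liability": eta, "case": case}, index=cohort.df.index)
    lat["A"] = A
    lat["intercept"] = intercept
    return out, lat


def simulate_cohort(
    truth: TruthConfig,
    eqi_table: pd.DataFrame | None = None,
    n_pollutants: int = 20,
) -> tuple[Cohort, pd.DataFrame, dict]:
    """Full generator: counties, families, latents, outcomes, metadata."""
    if eqi_table is None:
        _, eqi_table = simulate_counties(truth.n_counties, n_pollutants, truth.seed)
    cohort = simulate_family_structure(truth, county_ids=eqi_table.index.to_numpy())
    outcome, _ = simulate_liability_and_outcome(cohort, truth, eqi_table)

    rng = substream(truth.seed, "codes")
    codes = np.where(outcome["case"].to_numpy() == 1, 2, 0)
    sub = (codes == 0) & (rng.random(len(codes)) < truth.subthreshold_code_rate)
    codes[sub] = 1
    df = cohort.df.copy()
    df["dx_code_count"] = codes
    cohort = Cohort(df)

    meta = {
        "config_hash": truth.config_hash(),
        "seed": truth.seed,
        "n_families": cohort.n_families,
        "n_individuals": cohort.n_individuals,
        "n_cases": cohort.n_cases,
        "realized_prevalence_pct": 100.0 * cohort.n_cases / cohort.n_individuals,
        "intercept": truth.intercept if truth.intercept is not None
        else calibrate_intercept(truth),
        "truth_fractions": truth.fractions(),
    }
    return cohort, eqi_table, meta
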