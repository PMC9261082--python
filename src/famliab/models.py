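"""Model specifications for the liability variance-decomposition suite.

Five models form two forward-selection traces over a latent liability

    eta_i = x_i' beta
            + sigma_h A_i + sigma_f F_i + sigma_c C_i [parent]
            + sigma_s S_i [child] + sigma_p P_i
            + sigma_hf A_i F_i + sigma_hc A_i C_i [parent]
            + sigma_hs A_i S_i [child] + sigma_he A_i G_i
            + sigma_e E_i

with standardized latent factors: additive-genetic A (kinship-correlated),
family-shared F, couple-shared C (parents only), sibling-shared S (children
only), place/county P, and individual-specific E and G (G carries the
gene-by-individual-environment product). A binary outcome arises by
thresholding eta at zero (probit) or by a Bernoulli-logistic draw (logit).

Trace a: LM0 (genes + individual env) -> LM1 (all additive layers, linear
EQI fixed effects) -> IM1 (adds the four gene-environment products).
Trace b: LM2 / IM2 repeat LM1 / IM1 with non-linear (penalized B-spline)
EQI fixed effects on the percentile scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml
from scipy import special
from scipy.interpolate import BSpline

from .eqi import EQI_DOMAINS

log = logging.getLogger(__name__)

#: all variance components, in reporting order
COMPONENTS = ("p", "h", "f", "c", "s", "e", "hf", "hc", "hs", "he")
INTERACTIONS = ("hf", "hc", "hs", "he")
#: main-effect component each interaction requires
INTERACTION_PARENTS = {"hf": "f", "hc": "c", "hs": "s", "he": "e"}
MODEL_NAMES = ("LM0", "LM1", "IM1", "LM2", "IM2")


@dataclass(frozen=True)
class ModelSpec:
    name: str
    random_components: frozenset
    eqi_fixed_form: str = "none"       # none | linear | spline
    link: str = "probit"               # probit | logit

    def __post_init__(self):
        comps = frozenset(self.random_components)
        object.__setattr__(self, "random_components", comps)
        unknown = comps - set(COMPONENTS)
        if unknown:
            raise ValueError(f"unknown components {sorted(unknown)}")
        if "e" not in comps:
            raise ValueError("the individual component 'e' must always be active")
        for k in comps & set(INTERACTIONS):
            if "h" not in comps or INTERACTION_PARENTS[k] not in comps:
                raise ValueError(
                    f"interaction {k!r} requires its main effects "
                    f"('h' and {INTERACTION_PARENTS[k]!r})"
                )
        if self.name.startswith("LM") and comps & set(INTERACTIONS):
            raise ValueError("linear models (LM*) carry no interaction components")
        if self.eqi_fixed_form not in ("none", "linear", "spline"):
            raise ValueError(f"unknown eqi_fixed_form {self.eqi_fixed_form!r}")
        if self.link not in ("probit", "logit"):
            raise ValueError(f"unknown link {self.link!r}")

    @property
    def interactions(self) -> frozenset:
        return self.random_components & set(INTERACTIONS)

    def has(self, comp: str) -> bool:
        return comp in self.random_components


def default_model_suite(link: str = "probit") -> list[ModelSpec]:
    """The five models of the forward-selection traces, simplest first."""
    additive = frozenset({"h", "f", "c", "s", "p", "e"})
    full = additive | set(INTERACTIONS)
    return [
        ModelSpec("LM0", frozenset({"h", "e"}), "none", link),
        ModelSpec("LM1", additive, "linear", link),
        ModelSpec("IM1", full, "linear", link),
        ModelSpec("LM2", additive, "spline", link),
        ModelSpec("IM2", full, "spline", link),
    ]


def get_model_spec(name: str, link: str = "probit") -> ModelSpec:
    for spec in default_model_suite(link):
        if spec.name == name:
            return spec
    raise ValueError(f"unknown model {name!r}; expected one of {MODEL_NAMES}")


@dataclass(frozen=True)
class PriorSpec:
    """Priors for the Bayesian fit.

    Half-normal(sigma_scale) on every component scale, normal(beta_mean,
    beta_scale^2) on fixed effects, and a Gaussian second-difference
    (random-walk) penalty on spline ordinates whose smoothing scale itself
    gets a half-normal(smoothing_scale) hyperprior.
    """

    sigma_scale: float = 1.0
    beta_mean: float = 0.0
    beta_scale: float = 5.0
    spline_smoothing_scale: float = 1.0

    def __post_init__(self):
        for v in (self.sigma_scale, self.beta_scale, self.spline_smoothing_scale):
            if not v > 0:
                raise ValueError("all prior scales must be positive")


# ---------------------------------------------------------------------------
# spline basis on the EQI percentile scale
# ---------------------------------------------------------------------------

@dataclass
class SplineBasis:
    """Clamped cubic B-spline basis over percentiles [0, 100].

    ``knots`` are the distinct breakpoints (default 7 equally spaced ones);
    basis rows sum to one (partition of unity), and design matrices are
    returned relative to the 50th-percentile reference so the fitted curve
    is identified as a log-odds/liability *difference* from the median
    environment.
    """

    knots: np.ndarray = field(default_factory=lambda: np.linspace(0.0, 100.0, 7))
    degree: int = 3

    def __post_init__(self):
        self.knots = np.asarray(self.knots, dtype=float)
        if self.knots[0] != 0.0 or self.knots[-1] != 100.0:
            raise ValueError("knots must span [0, 100]")
        t = np.r_[np.repeat(self.knots[0], self.degree),
                  self.knots,
                  np.repeat(self.knots[-1], self.degree)]
        self._t = t
        self.n_basis = len(t) - self.degree - 1

    def design(self, x) -> np.ndarray:
        """Raw basis matrix; rows sum to 1 for x in [0, 100]."""
        x = np.clip(np.asarray(x, dtype=float), 0.0, 100.0)
        # design_matrix is exclusive at the right endpoint; nudge 100 inside
        x = np.minimum(x, 100.0 - 1e-9)
        return BSpline.design_matrix(x, self._t, self.degree).toarray()

    def design_centered(self, x, reference: float = 50.0) -> np.ndarray:
        """Basis relative to the reference percentile (row at ref subtracted)."""
        return self.design(x) - self.design([reference])


# ---------------------------------------------------------------------------
# predictor and pointwise likelihood
# ---------------------------------------------------------------------------

def linear_predictor(ind, eqi_row, beta, latents, sigma, spec: ModelSpec,
                     spline_basis: SplineBasis | None = None,
                     eqi_percentiles=None, age_mean: float = 40.0,
                     age_sd: float = 14.0) -> float:
    """Liability predictor for a single individual (reference implementation).

    ``beta`` maps {"intercept", "sex_male", "age", "eqi"} to coefficients
    (``eqi``: five linear slopes, or a (5, n_basis) ordinate matrix for the
    spline form); ``latents`` maps latent names {"A","F","C","S","P","G"}
    to this individual's factor values; ``sigma`` maps component names to
    scales. Scales supplied for components outside ``spec`` are ignored
    with a warning. The bulk samplers use the vectorized equivalent in
    :mod:`famliab.inference`; this scalar form is the arithmetic contract.
    """
    extra = {k for k, v in sigma.items() if v and k not in spec.random_components and k != "e"}
    if extra:
        log.warning("ignoring scales for components inactive in %s: %s",
                    spec.name, sorted(extra))

    eta = float(beta.get("intercept", 0.0))
    eta += beta.get("sex_male", 0.0) * (1.0 if ind.sex == "male" else 0.0)
    eta += beta.get("age", 0.0) * (ind.age - age_mean) / age_sd
    if spec.eqi_fixed_form == "linear":
        eta += float(np.dot(np.asarray(beta.get("eqi", np.zeros(5))),
                            np.asarray(eqi_row, dtype=float)))
    elif spec.eqi_fixed_form == "spline":
        if spline_basis is None or eqi_percentiles is None:
            raise ValueError("spline form needs a basis and EQI percentiles")
        theta = np.atleast_2d(np.asarray(beta.get("eqi"), dtype=float))  # (5, n_basis)
        B = spline_basis.design_centered(np.asarray(eqi_percentiles, dtype=float))
        eta += float(np.einsum("db,db->", B, theta))

    is_parent = ind.role in ("father", "mother")
    A = latents.get("A", 0.0)
    g = sigma.get
    if spec.has("h"):
        eta += g("h", 0.0) * A
    if spec.has("f"):
        eta += g("f", 0.0) * latents.get("F", 0.0)
    if spec.has("c") and is_parent:
        eta += g("c", 0.0) * latents.get("C", 0.0)
    if spec.has("s") and not is_parent:
        eta += g("s", 0.0) * latents.get("S", 0.0)
    if spec.has("p"):
        eta += g("p", 0.0) * latents.get("P", 0.0)
    if spec.has("hf"):
        eta += g("hf", 0.0) * A * latents.get("F", 0.0)
    if spec.has("hc") and is_parent:
        eta += g("hc", 0.0) * A * latents.get("C", 0.0)
    if spec.has("hs") and not is_parent:
        eta += g("hs", 0.0) * A * latents.get("S", 0.0)
    if spec.has("he"):
        eta += g("he", 0.0) * A * latents.get("G", 0.0)
    eta += g("e", 0.0) * latents.get("E", 0.0)
    return eta


def pointwise_loglik(case, eta, link: str = "probit", scale=1.0):
    """Stable log-likelihood of a binary outcome given its liability mean.

    probit: log Phi(+-eta/scale), where ``scale`` is the residual standard
    deviation of the part of the liability not in ``eta`` (the individual
    E-term, plus the gene-by-individual product when marginalized). logit:
    log Bernoulli-logistic mass. Never returns -inf for finite eta.
    """
    case = np.asarray(case)
    eta = np.asarray(eta, dtype=float)
    sgn = np.where(case == 1, 1.0, -1.0)
    if link == "probit":
        return special.log_ndtr(sgn * eta / np.asarray(scale, dtype=float))
    if link == "logit":
        return -np.logaddexp(0.0, -sgn * eta)
    raise ValueError(f"unknown link {link!r}")


# ---------------------------------------------------------------------------
# suite serialization (shipped as package data)
# ---------------------------------------------------------------------------

def spec_to_dict(spec: ModelSpec) -> dict:
    return {
        "name": spec.name,
        "random_components": sorted(spec.random_components),
        "eqi_fixed_form": spec.eqi_fixed_form,
        "link": spec.link,
    }


def spec_from_dict(d: dict) -> ModelSpec:
    return ModelSpec(d["name"], frozenset(d["random_components"]),
                     d.get("eqi_fixed_form", "none"), d.get("link", "probit"))


def load_model_suite() -> list[ModelSpec]:
    """Load the shipped five-model suite definition."""
    text = resources.files("famliab.data").joinpath("model_suite.yaml").read_text()
    return [spec_from_dict(d) for d in yaml.safe_load(text)["models"]]
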