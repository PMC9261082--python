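"""Bayesian fitting of the liability models by probit data augmentation.

The core is an Albert-Chib sampler: the latent liability ``z_i`` is a
truncated-normal augmented variable, after which the fixed effects,
spline ordinates, and component scales form one joint Gaussian block, the
shared family / couple / sibling / county factors update per block, and
the kinship-structured genetic values update in three colored blocks
(fathers, mothers, children — members of one family never update
simultaneously). Scales are *signed* coefficients with normal priors
(identical marginal model to half-normal scales) so no update needs
truncation. The gene-by-individual-environment product keeps an explicit
standardized factor ``G``; the reported pointwise likelihood marginalizes
``G`` and the residual analytically,
``P(y=1 | rest) = Phi(m / sqrt(sigma_e^2 + sigma_he^2 A^2))``.

Plain Gibbs mixes far too slowly in this model class, so the sampler
layers exact accelerators — parameter-expansion rescaling,
ancillarity-sufficiency interweaving, factor-marginalized and
genetics-marginalized slice moves, per-family factor refreshes with the
genetics integrated out, periodic fully collapsed scale moves, and a
staged annealed warmup. docs/methods.md derives and motivates each one.
Only variance *fractions* are data-identified; the overall liability
scale floats under its prior.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import arviz as az
import numba
import numpy as np
import pandas as pd
from scipy import linalg, special

from ._utils import sample_truncnorm, slice_sample_scalar, std_truncnorm_lower, substream
from .eqi import EQI_COLUMNS, EQI_DOMAINS, to_percentiles
from .models import ModelSpec, PriorSpec, SplineBasis
from .pedigree import Cohort

log = logging.getLogger(__name__)

RHAT_LIMIT = 1.1
INTERACTION_SET = ("hf", "hc", "hs", "he")


class DegenerateCohortError(ValueError):
    """Cohort with no cases (or no controls) cannot identify the model."""


@dataclass
class McmcConfig:
    n_chains: int = 2
    n_warmup: int = 500
    n_samples: int = 500
    seed: int = 0
    sampler: str = "gibbs_augmented"   # gibbs_augmented | hmc
    thin_latents: int = 10
    store_latents: bool = False
    store_loglik: bool = True

    def __post_init__(self):
        if self.n_chains < 2:
            raise ValueError("need at least 2 chains for convergence diagnostics")
        if self.n_warmup < 1 or self.n_samples < 1:
            raise ValueError("warmup and sample counts must be positive")
        if self.n_chains * self.n_samples < 200:
            raise ValueError("need >= 200 total draws for diagnostics")
        if self.sampler not in ("gibbs_augmented", "hmc"):
            raise ValueError(f"unknown sampler {self.sampler!r}")


@dataclass
class PosteriorDraws:
    """MCMC output: (chain, draw, ...) arrays plus diagnostics."""

    spec: ModelSpec
    beta: np.ndarray                 # (C, D, p)
    beta_names: list
    sigma: dict                      # comp -> (C, D) signed scales, incl 'e'
    spline: np.ndarray | None        # (C, D, 5, n_basis) for spline models
    spline_basis: SplineBasis | None
    tau: np.ndarray | None           # (C, D) smoothing scale
    pointwise_loglik: np.ndarray | None  # (C, D, n) float32
    diagnostics: pd.DataFrame
    converged: bool
    meta: dict
    end_states: list = field(default_factory=list)
    latents: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.beta.shape[0]

    @property
    def n_draws(self) -> int:
        return self.beta.shape[1]

    def sigma_flat(self) -> dict:
        return {k: v.reshape(-1) for k, v in self.sigma.items()}

    def loglik_matrix(self) -> np.ndarray:
        """(draws, individuals) pointwise log-likelihood, chains stacked."""
        if self.pointwise_loglik is None:
            raise ValueError("fit was run without pointwise log-likelihood storage")
        C, D, n = self.pointwise_loglik.shape
        return self.pointwise_loglik.reshape(C * D, n).astype(np.float64)


@dataclass
class ConvergenceReport:
    table: pd.DataFrame
    passed: bool


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def _second_difference(nb: int) -> np.ndarray:
    D = np.zeros((nb - 2, nb))
    for r in range(nb - 2):
        D[r, r:r + 3] = (1.0, -2.0, 1.0)
    return D


def build_design(cohort: Cohort, eqi_table: pd.DataFrame, spec: ModelSpec,
                 basis: SplineBasis | None = None) -> dict:
    """Fixed-effect design matrix and bookkeeping for one model.

    Demographics: intercept, male indicator, within-cohort standardized
    age. EQI enters either as five standardized linear columns, or as the
    per-domain percentile spline basis centered at the 50th percentile.
    """
    ix = cohort.index_arrays()
    missing = set(ix["county_ids"]) - set(eqi_table.index)
    if missing:
        raise ValueError(f"EQI table lacks counties: {sorted(missing)[:5]}")

    age = ix["age"]
    age_sd = age.std() or 1.0
    cols = [np.ones(cohort.n_individuals), ix["sex_male"], (age - age.mean()) / age_sd]
    names = ["intercept", "sex_male", "age_std"]
    spline_slices: dict = {}
    pct = {}

    if spec.eqi_fixed_form != "none":
        county_vals = eqi_table.loc[ix["county_ids"], EQI_COLUMNS].to_numpy()
        indiv_vals = county_vals[ix["county"]]
    if spec.eqi_fixed_form == "linear":
        sd = indiv_vals.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        z = (indiv_vals - indiv_vals.mean(axis=0)) / sd
        for d, dom in enumerate(EQI_DOMAINS):
            cols.append(z[:, d])
            names.append(f"eqi_{dom}")
    elif spec.eqi_fixed_form == "spline":
        basis = basis or SplineBasis()
        start = len(names)
        for d, dom in enumerate(EQI_DOMAINS):
            p = to_percentiles(indiv_vals[:, d], indiv_vals[:, d])
            pct[dom] = p
            B = basis.design_centered(p)
            for b in range(basis.n_basis):
                cols.append(B[:, b])
                names.append(f"spline_{dom}_{b}")
            spline_slices[dom] = slice(start + d * basis.n_basis,
                                       start + (d + 1) * basis.n_basis)

    X = np.column_stack(cols)
    return {
        "X": X,
        "names": names,
        "spline_slices": spline_slices,
        "basis": basis if spec.eqi_fixed_form == "spline" else None,
        "percentiles": pct,
        "ix": ix,
    }


def _prior_precision(design: dict, priors: PriorSpec, tau: float) -> np.ndarray:
    p = design["X"].shape[1]
    P = np.eye(p) / priors.beta_scale**2
    basis = design["basis"]
    if basis is not None:
        D = _second_difference(basis.n_basis)
        DtD = D.T @ D
        for sl in design["spline_slices"].values():
            P[sl, sl] += DtD / tau**2
    return P


# ---------------------------------------------------------------------------
# the Gibbs sampler
# ---------------------------------------------------------------------------

class _State:
    __slots__ = ("beta", "sigma", "A", "F", "C", "S", "P", "G", "tau", "z", "fixed")


def _mean_liability(st: _State, ws: dict, spec: ModelSpec) -> np.ndarray:
    fam, cty = ws["fam"], ws["county"]
    par, chi = ws["parf"], ws["chif"]
    m = st.fixed + _coef_A(st, ws, spec) * st.A
    if spec.has("f"):
        m = m + st.sigma["f"] * st.F[fam]
    if spec.has("c"):
        m = m + st.sigma["c"] * st.C[fam] * par
    if spec.has("s"):
        m = m + st.sigma["s"] * st.S[fam] * chi
    if spec.has("p"):
        m = m + st.sigma["p"] * st.P[cty]
    return m


def _coef_A(st: _State, ws: dict, spec: ModelSpec) -> np.ndarray:
    """Multiplier of the genetic value in each individual's liability."""
    fam = ws["fam"]
    coef = np.full(ws["n"], st.sigma.get("h", 0.0))
    if spec.has("hf"):
        coef = coef + st.sigma["hf"] * st.F[fam]
    if spec.has("hc"):
        coef = coef + st.sigma["hc"] * st.C[fam] * ws["parf"]
    if spec.has("hs"):
        coef = coef + st.sigma["hs"] * st.S[fam] * ws["chif"]
    if spec.has("he"):
        coef = coef + st.sigma["he"] * st.G
    return coef


def _component_regressor(comp: str, st: _State, ws: dict) -> np.ndarray:
    fam, cty = ws["fam"], ws["county"]
    par, chi = ws["parf"], ws["chif"]
    if comp == "h":
        return st.A
    if comp == "f":
        return st.F[fam]
    if comp == "c":
        return st.C[fam] * par
    if comp == "s":
        return st.S[fam] * chi
    if comp == "p":
        return st.P[cty]
    if comp == "hf":
        return st.A * st.F[fam]
    if comp == "hc":
        return st.A * st.C[fam] * par
    if comp == "hs":
        return st.A * st.S[fam] * chi
    if comp == "he":
        return st.A * st.G
    raise KeyError(comp)


def _update_shared(st, ws, spec, rng, z, w):
    """Conjugate per-family (F/C/S) and per-county (P) factor updates."""
    fam, cty = ws["fam"], ws["county"]
    for comp, attr, mask, idx, size in (
        ("f", "F", None, fam, ws["n_fam"]),
        ("c", "C", ws["parf"], fam, ws["n_fam"]),
        ("s", "S", ws["chif"], fam, ws["n_fam"]),
        ("p", "P", None, cty, ws["n_cty"]),
    ):
        if not spec.has(comp):
            continue
        cur = getattr(st, attr)
        coef = np.full(ws["n"], st.sigma[comp])
        inter = "h" + comp
        if comp != "p" and spec.has(inter):
            coef = coef + st.sigma[inter] * st.A
        if mask is not None:
            coef = coef * mask
        m = _mean_liability(st, ws, spec)
        r = z - m + coef * cur[idx]
        wl = w / st.sigma["e"] ** 2
        prec = 1.0 + wl * np.bincount(idx, weights=coef * coef, minlength=size)
        h = wl * np.bincount(idx, weights=coef * r, minlength=size)
        setattr(st, attr, h / prec + rng.standard_normal(size) / np.sqrt(prec))


def _update_genetics(st, ws, spec, rng, z, w):
    """Colored-block update of the kinship-structured genetic values.

    Fathers, mothers, then children: within a block the full conditionals
    are independent across families, so each block is one vectorized draw.
    The nuclear-family prior gives a parent precision ``1 + k/2`` (k
    children) and child precision 2 around the midparent mean.
    """
    fam = ws["fam"]
    fpos, mpos = ws["father_pos"], ws["mother_pos"]
    coef = _coef_A(st, ws, spec)
    m = _mean_liability(st, ws, spec)
    r = z - m + coef * st.A
    k = ws["n_children"]
    wl = w / st.sigma["e"] ** 2

    for ppos, qpos in ((fpos, mpos), (mpos, fpos)):
        sumc = np.bincount(fam[ws["is_child"]],
                           weights=st.A[ws["is_child"]], minlength=ws["n_fam"])
        h_pri = sumc - 0.5 * k * st.A[qpos]
        prec = (1.0 + 0.5 * k) + wl * coef[ppos] ** 2
        h = h_pri + wl * coef[ppos] * r[ppos]
        # r excludes each row's own A-term and no row involves another
        # individual's A, so no residual refresh is needed between blocks
        st.A[ppos] = h / prec + rng.standard_normal(ws["n_fam"]) / np.sqrt(prec)

    child = ws["is_child"]
    cf = fam[child]
    mid = 0.5 * (st.A[fpos[cf]] + st.A[mpos[cf]])
    prec = 2.0 + wl * coef[child] ** 2
    h = 2.0 * mid + wl * coef[child] * r[child]
    st.A[child] = h / prec + rng.standard_normal(child.sum()) / np.sqrt(prec)


def _update_G(st, ws, spec, rng, z, w):
    if not spec.has("he"):
        return
    coef = st.sigma["he"] * st.A
    m = _mean_liability(st, ws, spec)
    r = z - m + coef * st.G
    wl = w / st.sigma["e"] ** 2
    prec = 1.0 + wl * coef * coef
    h = wl * coef * r
    st.G = h / prec + rng.standard_normal(ws["n"]) / np.sqrt(prec)


def _update_sigma_pairs_marginal(st, ws, spec, priors, rng, z, temper=1.0):
    """Metropolis moves on (additive, interaction) scale pairs with the
    layer's latent factor integrated out.

    Conditional Gibbs cannot quickly trade variance between, say, a couple
    main effect and the genetics-by-couple product, because the couple
    factor itself must reorganize along the way. Marginalizing the factor
    (a rank-1 Gaussian per family/county) removes that ridge: for group g
    with residuals r and per-member coefficients c_i(sigma),
    log p(r) = -log(1 + S2)/2 + S1^2 / (2 (1 + S2)) + const, where
    S1 = sum c_i r_i / sigma_e^2 and S2 = sum c_i^2 / sigma_e^2. The same
    trick with the individual-level product factor integrates out the
    gene-by-individual-environment term (a heteroscedastic residual).
    """
    se2 = st.sigma["e"] ** 2 / temper
    fam, cty = ws["fam"], ws["county"]

    for comp, attr, partner, mask, idx, size in (
        ("p", "P", None, None, cty, ws["n_cty"]),
    ):
        if not spec.has(comp):
            continue
        has_partner = partner is not None and spec.has(partner)
        U = getattr(st, attr)
        m = _mean_liability(st, ws, spec)
        coef0 = np.full(ws["n"], st.sigma[comp])
        if has_partner:
            coef0 = coef0 + st.sigma[partner] * st.A
        if mask is not None:
            coef0 = coef0 * mask
        r = z - m + coef0 * U[idx]

        def loglik(sk, shk):
            coef = np.full(ws["n"], sk)
            if has_partner:
                coef = coef + shk * st.A
            if mask is not None:
                coef = coef * mask
            s1 = np.bincount(idx, weights=coef * r, minlength=size) / se2
            s2 = np.bincount(idx, weights=coef * coef, minlength=size) / se2
            return float((-0.5 * np.log1p(s2) + 0.5 * s1**2 / (1.0 + s2)).sum())

        sk, shk = st.sigma[comp], st.sigma[partner] if has_partner else 0.0
        width = 0.5 * abs(st.sigma["e"])
        lp = 2 * priors.sigma_scale**2
        if has_partner:
            # polar parameterization: the mixing angle is the slow
            # direction (additive vs multiplicative use of the factor) and
            # the isotropic normal prior is flat in it; the radius carries
            # the prior plus the polar Jacobian
            rho = float(np.hypot(sk, shk))
            phi = float(np.arctan2(shk, sk))
            phi = slice_sample_scalar(
                lambda a: loglik(rho * np.cos(a), rho * np.sin(a)),
                phi, rng, width=0.6, lower=None)
            rho = slice_sample_scalar(
                lambda v: loglik(v * np.cos(phi), v * np.sin(phi))
                + np.log(v) - v**2 / lp,
                max(rho, 1e-6), rng, width=width, lower=0.0)
            sk, shk = rho * np.cos(phi), rho * np.sin(phi)
        else:
            sk = slice_sample_scalar(lambda v: loglik(v, 0.0) - v**2 / lp,
                                     sk, rng, width=width, lower=None)
        st.sigma[comp] = float(sk)
        if has_partner:
            st.sigma[partner] = float(shk)
        # redraw the factor from its conditional under the accepted scales
        coef = np.full(ws["n"], sk)
        if has_partner:
            coef = coef + shk * st.A
        if mask is not None:
            coef = coef * mask
        prec = 1.0 + np.bincount(idx, weights=coef * coef, minlength=size) / se2
        h = np.bincount(idx, weights=coef * r, minlength=size) / se2
        setattr(st, attr, h / prec + rng.standard_normal(size) / np.sqrt(prec))

    if spec.has("he") and temper >= 1.0:
        m = _mean_liability(st, ws, spec)
        r = z - m + st.sigma["he"] * st.A * st.G  # = sigma_he A G + sigma_e E
        A2 = st.A**2

        def loglik_e(se, she):
            v = (se**2 + she**2 * A2) / temper
            return float((-0.5 * np.log(v) - 0.5 * r**2 / v).sum())

        se, she = st.sigma["e"], st.sigma["he"]
        lp = 2 * priors.sigma_scale**2
        rho = float(np.hypot(se, she))
        phi = float(np.arctan2(she, se))

        def logpost_angle(a):
            if np.cos(a) <= 0.0:  # residual scale must stay positive
                return -np.inf
            return loglik_e(rho * np.cos(a), rho * np.sin(a))

        phi = slice_sample_scalar(logpost_angle, phi, rng, width=0.4, lower=None)
        rho = slice_sample_scalar(
            lambda v: loglik_e(v * np.cos(phi), v * np.sin(phi))
            + np.log(v) - v**2 / lp,
            max(rho, 1e-6), rng, width=0.3 * rho, lower=0.0)
        st.sigma["e"], st.sigma["he"] = float(rho * np.cos(phi)), float(rho * np.sin(phi))
        # redraw the product factor under the accepted scales
        coef = st.sigma["he"] * st.A
        prec = 1.0 + coef**2 / st.sigma["e"] ** 2
        h = coef * r / st.sigma["e"] ** 2
        st.G = h / prec + rng.standard_normal(ws["n"]) / np.sqrt(prec)


@numba.njit(cache=True, fastmath=True)
def _marg3_kernel(cf, cc, cs, r, se2, pos):  # pragma: no cover - jitted
    """Residual log-likelihood with the family, couple and sibling factors
    integrated out: per family Sigma = se2 I + cf cf' + cc cc' + cs cs'."""
    J, s = pos.shape
    total = 0.0
    L = np.empty((s, s))
    y = np.empty(s)
    for j in range(J):
        for u in range(s):
            pu = pos[j, u]
            for v in range(u + 1):
                pv = pos[j, v]
                L[u, v] = cf[pu] * cf[pv] + cc[pu] * cc[pv] + cs[pu] * cs[pv]
            L[u, u] += se2
        for u in range(s):
            for v in range(u):
                acc = L[u, v]
                for t in range(v):
                    acc -= L[u, t] * L[v, t]
                L[u, v] = acc / L[v, v]
            acc = L[u, u]
            for t in range(u):
                acc -= L[u, t] * L[u, t]
            L[u, u] = np.sqrt(acc)
        for u in range(s):
            acc = r[pos[j, u]]
            for t in range(u):
                acc -= L[u, t] * y[t]
            y[u] = acc / L[u, u]
            total += -np.log(L[u, u]) - 0.5 * y[u] * y[u]
    return total


def _update_sigma_layers_marginal(st, ws, spec, priors, rng, z, temper=1.0):
    """Slice moves over the six family-layer scales (f, c, s and their
    gene products) under the (F, C, S)-marginalized likelihood.

    Conditional on the genetic values, the three family-level factors
    enter linearly, so their joint marginal per family is a rank-3
    Gaussian — cheap in closed form. Angle moves within a layer trade
    additive vs product use of its factor; angle moves across layers
    trade which layer carries an interaction (e.g. family-wide versus
    couple-only products, which conditional updates confuse because the
    factors must reorganize). The isotropic normal prior on signed scales
    is rotation-invariant, so angles carry no prior term; radii do.
    """
    layers = [c for c in ("f", "c", "s") if spec.has(c)]
    if not layers:
        return
    se2 = st.sigma["e"] ** 2 / temper
    fam = ws["fam"]
    A, par, chi = st.A, ws["parf"], ws["chif"]
    zeros = ws["zeros"]
    sig = {k: st.sigma.get(k, 0.0) if spec.has(k) else 0.0
           for k in ("f", "c", "s", "hf", "hc", "hs")}

    cf0 = (sig["f"] + sig["hf"] * A) if spec.has("f") else zeros
    cc0 = (sig["c"] + sig["hc"] * A) * par if spec.has("c") else zeros
    cs0 = (sig["s"] + sig["hs"] * A) * chi if spec.has("s") else zeros
    m = _mean_liability(st, ws, spec)
    r = z - m + cf0 * st.F[fam] + cc0 * st.C[fam] + cs0 * st.S[fam]
    groups = ws["groups"]

    def loglik():
        cf = (sig["f"] + sig["hf"] * A) if spec.has("f") else zeros
        cc = (sig["c"] + sig["hc"] * A) * par if spec.has("c") else zeros
        cs = (sig["s"] + sig["hs"] * A) * chi if spec.has("s") else zeros
        out = 0.0
        for K, pos, _ in groups:
            out += _marg3_kernel(cf, cc, cs, r, se2, pos)
        return out

    within = [(a, "h" + a) for a in layers if spec.has("h" + a)]
    inter = [k for k in ("hf", "hc", "hs") if spec.has(k)]
    cross = [(a, b) for i, a in enumerate(inter) for b in inter[i + 1:]]
    cross += [(a, b) for i, a in enumerate(layers) for b in layers[i + 1:]]
    lp = 2 * priors.sigma_scale**2
    width = 0.5 * np.sqrt(se2)

    # random scan: every within-layer pair gets an angle+radius move each
    # sweep would be too costly, so draw a few pairs per sweep instead
    chosen = []
    if within:
        chosen.append(within[rng.integers(len(within))] + ("radius",))
    if cross:
        chosen.append(cross[rng.integers(len(cross))] + ("angle",))
        chosen.append(cross[rng.integers(len(cross))] + ("angle",))

    for k1, k2, kind in chosen:
        rho = float(np.hypot(sig[k1], sig[k2]))
        phi = float(np.arctan2(sig[k2], sig[k1]))

        def ang(a):
            sig[k1], sig[k2] = rho * np.cos(a), rho * np.sin(a)
            return loglik()

        phi = slice_sample_scalar(ang, phi, rng, width=0.6, lower=None)
        if kind == "radius":

            def rad(v):
                sig[k1], sig[k2] = v * np.cos(phi), v * np.sin(phi)
                return loglik() + np.log(v) - v**2 / lp

            rho = slice_sample_scalar(rad, max(rho, 1e-6), rng,
                                      width=width, lower=0.0)
        sig[k1], sig[k2] = rho * np.cos(phi), rho * np.sin(phi)

    for k, v in sig.items():
        if spec.has(k):
            st.sigma[k] = float(v)
    # redraw the marginalized factors under the accepted scales
    _update_shared(st, ws, spec, rng, z, temper)


_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(12)
_GH_LOGW = np.log(_GH_WEIGHTS / _GH_WEIGHTS.sum())


def _observed_loglik(sh_mult, r0, case_sign, se, ws) -> float:
    """Observed-data log-likelihood with the augmented liabilities, the
    individual residual, and the genetic values all integrated out.

    Parent genetic values are integrated on a 2-d Gauss-Hermite grid; each
    child's value, conditional on the parents, contributes a closed-form
    probit term because its segregation noise folds into the residual:
    P(y_c) = Phi(+-(r0 + a mid) / sqrt(se^2 + a^2/2)).
    """
    total = 0.0
    g = _GH_NODES
    for K, pos, _ in ws["groups"]:
        J, s = pos.shape
        a_p = sh_mult[pos[:, :2]]                    # (J, 2)
        eta_p = r0[pos[:, :2]]
        sgn_p = case_sign[pos[:, :2]]
        # parent probabilities on the node grid: (J, 2, N)
        lp_par = special.log_ndtr(
            sgn_p[:, :, None] * (eta_p[:, :, None] + a_p[:, :, None] * g) / se)
        ll = lp_par[:, 0, :, None] + lp_par[:, 1, None, :]   # (J, N, N)
        if s > 2:
            mid = 0.5 * (g[:, None] + g[None, :])            # (N, N)
            a_c = sh_mult[pos[:, 2:]]                        # (J, k)
            sd_c = np.sqrt(se**2 + 0.5 * a_c**2)
            num = (r0[pos[:, 2:]][:, :, None, None]
                   + a_c[:, :, None, None] * mid)
            lp_c = special.log_ndtr(
                case_sign[pos[:, 2:]][:, :, None, None] * num
                / sd_c[:, :, None, None])
            ll = ll + lp_c.sum(axis=1)
        ll = ll + _GH_LOGW[:, None] + _GH_LOGW[None, :]
        total += float(special.logsumexp(ll, axis=(1, 2)).sum())
    return total


def _update_scales_collapsed(st, ws, spec, priors, rng, temper=1.0):
    """Slice moves on (sigma_h, sigma_e) under the fully collapsed
    likelihood (liabilities, residuals and genetic values integrated out).

    The augmented sampler's slowest direction at small sample sizes is the
    genetic-to-residual scale ratio, because the augmented liabilities pin
    the residual scale each sweep. Collapsing them removes that loop; the
    move is run periodically and the discarded latents are refreshed by
    the regular conditional updates that follow.
    """
    coef = _coef_A(st, ws, spec)
    base = coef - st.sigma.get("h", 0.0)
    m = _mean_liability(st, ws, spec)
    r0 = m - coef * st.A  # the A-free part of the liability mean
    sgn = ws["case_sign"]
    lp = 2 * priors.sigma_scale**2
    sh, se = st.sigma["h"], st.sigma["e"]

    def loglik(vh, ve):
        if ve <= 1e-6:
            return -np.inf
        return temper * _observed_loglik(vh + base, r0, sgn, ve, ws)

    rho = float(np.hypot(sh, se))
    phi = float(np.arctan2(se, sh))

    def ang(a):
        if np.sin(a) <= 0:  # residual scale must stay positive
            return -np.inf
        return loglik(rho * np.cos(a), rho * np.sin(a))

    phi = slice_sample_scalar(ang, phi, rng, width=0.3, lower=None)
    rho = slice_sample_scalar(
        lambda v: loglik(v * np.cos(phi), v * np.sin(phi)) + np.log(v) - v**2 / lp,
        max(rho, 1e-6), rng, width=0.3 * rho, lower=0.0)
    st.sigma["h"] = float(rho * np.cos(phi))
    st.sigma["e"] = float(max(rho * np.sin(phi), 1e-4))


def _family_groups(ix) -> list:
    """Row-position matrices per family size, with kinship matrices.

    Returns a list of (K, pos) pairs where pos is (n_families_of_size, s)
    with columns father, mother, children, and K is the s x s expected
    additive-genetic correlation matrix for that family shape.
    """
    fam = ix["fam"]
    child_rows = np.flatnonzero(ix["is_child"])
    order = np.argsort(fam[child_rows], kind="stable")
    child_rows = child_rows[order]
    counts = np.bincount(fam[child_rows], minlength=len(ix["family_ids"]))
    offsets = np.cumsum(counts) - counts
    groups = []
    for k in np.unique(counts):
        sel = np.flatnonzero(counts == k)
        s = 2 + int(k)
        pos = np.empty((len(sel), s), dtype=np.int64)
        pos[:, 0] = ix["father_pos"][sel]
        pos[:, 1] = ix["mother_pos"][sel]
        for j in range(int(k)):
            pos[:, 2 + j] = child_rows[offsets[sel] + j]
        K = np.full((s, s), 0.5)
        K[0, 1] = K[1, 0] = 0.0
        np.fill_diagonal(K, 1.0)
        groups.append((K, pos, sel))
    return groups


@numba.njit(cache=True, fastmath=True)
def _marg_kernel(a, r, se2, pos, K):  # pragma: no cover - jitted
    J, s = pos.shape
    total = 0.0
    L = np.empty((s, s))
    y = np.empty(s)
    for j in range(J):
        for u in range(s):
            au = a[pos[j, u]]
            for v in range(u + 1):
                L[u, v] = au * a[pos[j, v]] * K[u, v]
            L[u, u] += se2
        # in-place Cholesky (lower)
        for u in range(s):
            for v in range(u):
                acc = L[u, v]
                for t in range(v):
                    acc -= L[u, t] * L[v, t]
                L[u, v] = acc / L[v, v]
            acc = L[u, u]
            for t in range(u):
                acc -= L[u, t] * L[u, t]
            L[u, u] = np.sqrt(acc)
        # forward solve L y = r_fam; loglik uses |y|^2 and log det
        for u in range(s):
            acc = r[pos[j, u]]
            for t in range(u):
                acc -= L[u, t] * y[t]
            y[u] = acc / L[u, u]
            total += -np.log(L[u, u]) - 0.5 * y[u] * y[u]
    return total


def _marginal_A_loglik(a: np.ndarray, r: np.ndarray, se2: float, groups) -> float:
    """Log-likelihood of residuals with the genetic values integrated out.

    Per family, r ~ N(0, sigma_e^2 I + D K D) with D = diag of each
    member's genetic-value multiplier a_i and K the kinship matrix;
    evaluated family by family (sizes 3-6) with a jitted Cholesky.
    """
    return sum(_marg_kernel(a, r, se2, pos, K) for K, pos, _ in groups)


def _update_sigma_h_marginal(st, ws, spec, priors, rng, z, temper=1.0):
    """Slice moves on the genetic scale — and its mixing angles with each
    gene-environment product — under the A-marginalized likelihood.

    Conditional updates cannot trade variance between the genetic main
    effect and the products (or shrink/grow sigma_h at all quickly),
    because the whole genetic field must reorganize alongside. With A
    integrated out family by family, sigma_h moves freely; A is then
    redrawn from its conditional.
    """
    se2 = st.sigma["e"] ** 2 / temper
    fam = ws["fam"]
    m = _mean_liability(st, ws, spec)
    coef = _coef_A(st, ws, spec)
    r = z - m + coef * st.A
    base = coef - st.sigma["h"]   # interaction part of the multiplier
    groups = ws["groups"]
    lp = 2 * priors.sigma_scale**2

    sh = st.sigma["h"]
    sh = slice_sample_scalar(
        lambda v: _marginal_A_loglik(v + base, r, se2, groups) - v**2 / lp,
        sh, rng, width=0.5 * np.sqrt(se2), lower=None)

    partners = {"hf": st.F[fam], "hc": st.C[fam] * ws["parf"],
                "hs": st.S[fam] * ws["chif"], "he": st.G}
    inter = sorted(spec.interactions)
    if len(inter) > 2:  # rotate through two random partners per sweep
        inter = [inter[i] for i in rng.choice(len(inter), size=2, replace=False)]
    for k in inter:
        vk = partners[k]
        shk = st.sigma[k]
        other = base - shk * vk
        rho = float(np.hypot(sh, shk))
        phi = float(np.arctan2(shk, sh))

        def logpost(aangle):
            a = rho * np.cos(aangle) + other + rho * np.sin(aangle) * vk
            return _marginal_A_loglik(a, r, se2, groups)

        phi = slice_sample_scalar(logpost, phi, rng, width=0.5, lower=None)
        sh, shk = rho * np.cos(phi), rho * np.sin(phi)
        st.sigma[k] = float(shk)
        base = other + shk * vk
    st.sigma["h"] = float(sh)

    # redraw A from its conditional under the accepted scales (colored blocks)
    _update_genetics(st, ws, spec, rng, z, temper)


def _update_coefficients(st, ws, spec, design, priors, rng, z, w):
    """Joint Gaussian draw of the fixed effects and all component scales.

    Given the latent factors, the liability mean is linear in
    (beta, sigma_h, sigma_f, ...): one conjugate multivariate-normal block.
    Updating them jointly (rather than one scale at a time) removes the
    slow trading between correlated components such as a couple main
    effect versus a genetics-by-couple product, whose regressors overlap.
    Scales are *signed* here — the half-normal prior on a magnitude is
    exactly a normal prior on a signed coefficient — so the block needs no
    truncation and sign symmetry is mixed by the interweaving step.
    """
    X = ws["X"]
    comps = ws["sigma_order"]
    p, k = X.shape[1], len(comps)
    prec = np.zeros((p + k, p + k))
    prec[:p, :p] = _prior_precision(design, priors, st.tau)
    if k:
        prec[p:, p:] += np.eye(k) / priors.sigma_scale**2
    h = np.zeros(p + k)
    if w:
        se2 = st.sigma["e"] ** 2
        prec[:p, :p] += ws["XtX"] / se2
        h[:p] = X.T @ z / se2
        if k:
            V = np.column_stack([_component_regressor(c, st, ws) for c in comps])
            XtV = X.T @ V / se2
            prec[:p, p:] += XtV
            prec[p:, :p] += XtV.T
            prec[p:, p:] += V.T @ V / se2
            h[p:] = V.T @ z / se2
    try:
        L = linalg.cholesky(prec, lower=True)
    except np.linalg.LinAlgError:
        jitter = 1e-8 * float(np.trace(prec)) / prec.shape[0]
        L = linalg.cholesky(prec + jitter * np.eye(prec.shape[0]), lower=True)
    mean = linalg.cho_solve((L, True), h)
    gamma = mean + linalg.solve_triangular(
        L, rng.standard_normal(p + k), lower=True, trans="T")
    st.beta = gamma[:p]
    st.fixed = X @ st.beta
    for i, c in enumerate(comps):
        st.sigma[c] = float(gamma[p + i])


def _update_sigma_e(st, ws, spec, priors, rng, z, w):
    """Residual (individual-environment) scale.

    Given the augmented liabilities the residuals are exact, so sigma_e^2
    has a generalized-inverse-Gaussian conditional under its half-normal
    prior. The observed-data likelihood is scale-invariant, so sigma_e is
    identified through the prior; all reported statistics are variance
    fractions, which are invariant to the overall scale.
    """
    if not w:
        st.sigma["e"] = float(sample_truncnorm(0.0, priors.sigma_scale, rng, lower=0.0))
        return
    m = _mean_liability(st, ws, spec)
    rss = w * float(((z - m) ** 2).sum())
    p_gig = (1.0 - ws["n"]) / 2.0
    v = _gig_draw(p_gig, 1.0 / priors.sigma_scale**2, max(rss, 1e-12), rng)
    # floor keeps the weighted design numerically sane if a hot/early state
    # momentarily drives the residual scale toward zero
    st.sigma["e"] = float(max(np.sqrt(v), 1e-4))


def _gig_draw(p: float, a: float, b: float, rng) -> float:
    """Generalized inverse Gaussian draw, density ~ v^(p-1) exp(-(a v + b/v)/2)."""
    from scipy import stats

    x = stats.geninvgauss.rvs(p, np.sqrt(a * b), random_state=rng)
    return float(np.sqrt(b / a) * x)


def _interweave_sigmas(st, ws, spec, priors, rng):
    """Ancillarity-sufficiency interweaving for the component scales.

    The plain conjugate scale update conditions on standardized latents
    (the ancillary parameterization) and mixes very slowly because scale
    and latents are strongly coupled. Here each scale is re-drawn from its
    exact conditional given the *scaled* latents (sufficient
    parameterization), which for half-normal priors is a generalized
    inverse Gaussian in the squared scale. Interaction scales sharing a
    latent are co-rescaled so the likelihood term is invariant, making the
    move a valid Gibbs step on a reparameterized block.
    """
    s0 = priors.sigma_scale
    eps = 1e-8

    if spec.has("h") and abs(st.sigma["h"]) > eps:
        sig = st.sigma["h"]
        At = sig * st.A
        child = ws["is_child"]
        fam = ws["fam"]
        mid = 0.5 * (At[ws["father_pos"]] + At[ws["mother_pos"]])
        par = ~child
        Q = float(At[par] @ At[par]) + 2.0 * float(((At[child] - mid[fam[child]]) ** 2).sum())
        inter = [k for k in INTERACTION_SET if spec.has(k)]
        rho2 = sum((st.sigma[k] / sig) ** 2 for k in inter)
        a = (1.0 + rho2) / s0**2
        p_gig = (len(inter) - ws["n"] + 1) / 2.0
        new = np.sqrt(_gig_draw(p_gig, a, max(Q, eps), rng))
        new *= 1.0 if rng.random() < 0.5 else -1.0
        st.A = At / new
        for k in inter:
            st.sigma[k] *= new / sig
        st.sigma["h"] = float(new)

    for comp, attr, partner in (("f", "F", "hf"), ("c", "C", "hc"),
                                ("s", "S", "hs"), ("p", "P", None),
                                ("he", "G", None)):
        if not spec.has(comp) or abs(st.sigma[comp]) <= eps:
            continue
        sig = st.sigma[comp]
        U = sig * getattr(st, attr)
        Q = float(U @ U)
        has_partner = partner is not None and spec.has(partner)
        rho2 = (st.sigma[partner] / sig) ** 2 if has_partner else 0.0
        a = (1.0 + rho2) / s0**2
        p_gig = ((1 if has_partner else 0) - U.size + 1) / 2.0
        new = np.sqrt(_gig_draw(p_gig, a, max(Q, eps), rng))
        new *= 1.0 if rng.random() < 0.5 else -1.0
        setattr(st, attr, U / new)
        if has_partner:
            st.sigma[partner] *= new / sig
        st.sigma[comp] = float(new)


def _log_prior_scales(st, design, priors, spec) -> float:
    """Log prior density of (beta, all sigma, tau), up to scale-free constants."""
    lp = -sum(st.sigma[c] ** 2 for c in st.sigma) / (2 * priors.sigma_scale**2)
    P = _prior_precision(design, priors, st.tau)
    sign, logdet = np.linalg.slogdet(P)
    lp += 0.5 * logdet - 0.5 * float(st.beta @ P @ st.beta)
    if design["basis"] is not None:
        lp += -st.tau**2 / (2 * priors.spline_smoothing_scale**2)
    return lp


def _global_rescale(st, ws, spec, design, priors, rng, z, step: float = 0.3):
    """Parameter-expansion Metropolis move: jointly rescale the augmented
    liabilities, fixed effects, and every scale parameter.

    The thresholded likelihood is invariant under this rescaling (signs
    are preserved and the z-Jacobian cancels the residual density), so the
    acceptance ratio involves only the priors plus the Jacobian of the
    rescaled scalars. This is what lets the intercept and the component
    scales drift together instead of random-walking along the scale ridge.
    """
    t = float(np.exp(step * rng.standard_normal()))
    old_lp = _log_prior_scales(st, design, priors, spec)
    old = {"beta": st.beta, "sigma": dict(st.sigma), "tau": st.tau, "fixed": st.fixed}
    st.beta = st.beta * t
    st.fixed = st.fixed * t
    st.sigma = {c: v * t for c, v in st.sigma.items()}
    if design["basis"] is not None:
        st.tau = st.tau * t
    new_lp = _log_prior_scales(st, design, priors, spec)
    d = len(st.beta) + len(st.sigma) + (1 if design["basis"] is not None else 0)
    log_accept = new_lp - old_lp + d * np.log(t)
    if np.log(1.0 - rng.random()) < log_accept:
        return z * t
    st.beta, st.sigma, st.tau, st.fixed = (old["beta"], old["sigma"],
                                           old["tau"], old["fixed"])
    return z


def _update_tau(st, design, priors, rng):
    basis = design["basis"]
    if basis is None:
        return
    D = _second_difference(basis.n_basis)
    Q = 0.0
    for sl in design["spline_slices"].values():
        d = D @ st.beta[sl]
        Q += float(d @ d)
    k = len(design["spline_slices"]) * (basis.n_basis - 2)

    def logpdf(tau):
        return (-(tau**2) / (2 * priors.spline_smoothing_scale**2)
                - k * np.log(tau) - Q / (2 * tau**2))

    st.tau = slice_sample_scalar(logpdf, st.tau, rng, width=0.5)


def _sample_z(st, ws, spec, rng, temper: float = 1.0):
    m = _mean_liability(st, ws, spec)
    se = st.sigma["e"] / np.sqrt(temper)
    alpha = np.where(ws["case"] == 1, -m, m) / se
    t = se * std_truncnorm_lower(alpha, rng)
    return np.where(ws["case"] == 1, m + t, m - t)


def _pointwise_loglik_draw(st, ws, spec):
    m = _mean_liability(st, ws, spec)
    se2 = st.sigma["e"] ** 2
    if spec.has("he"):
        m = m - st.sigma["he"] * st.A * st.G
        scale = np.sqrt(se2 + st.sigma["he"] ** 2 * st.A**2)
    else:
        scale = np.sqrt(se2)
    sgn = np.where(ws["case"] == 1, 1.0, -1.0)
    return special.log_ndtr(sgn * m / scale)


def _run_chain(ws, design, spec, priors, cfg, rng, prior_only, init_state=None):
    n, n_fam, n_cty = ws["n"], ws["n_fam"], ws["n_cty"]
    st = _State()
    # start main-effect scales high and overdispersed: escaping sigma ~ 0 is
    # the sampler's slow direction (latents must align before the scale can
    # grow), while shrinking an overlarge scale is fast
    st.sigma = {c: (1.0 if len(c) == 1 else 0.5) * priors.sigma_scale
                * float(0.5 + rng.random())
                for c in sorted(spec.random_components) if c != "e"}
    st.sigma["e"] = 1.0
    st.beta = np.zeros(ws["X"].shape[1])
    ybar = float(np.clip(ws["case"].mean(), 1e-3, 1 - 1e-3))
    st.beta[0] = special.ndtri(ybar)
    st.fixed = ws["X"] @ st.beta
    st.A = rng.standard_normal(n)
    st.F = rng.standard_normal(n_fam)
    st.C = rng.standard_normal(n_fam)
    st.S = rng.standard_normal(n_fam)
    st.P = rng.standard_normal(n_cty)
    st.G = rng.standard_normal(n)
    st.tau = priors.spline_smoothing_scale
    warm_started = False
    if init_state is not None and not prior_only:
        # forward-selection warm start: adopt a nested model's end state
        # (aligned latents, calibrated mains) and release any additional
        # interaction scales at a substantial fraction of the genetic scale
        for k, v in init_state["sigma"].items():
            if k in st.sigma:
                st.sigma[k] = float(v)
        for attr in ("A", "F", "C", "S", "P", "G"):
            if attr in init_state:
                setattr(st, attr, np.array(init_state[attr]))
        if len(init_state["beta"]) == len(st.beta):
            st.beta = np.array(init_state["beta"])
            st.fixed = ws["X"] @ st.beta
        st.tau = float(init_state.get("tau", st.tau))
        for k in sorted(spec.interactions):
            if k not in init_state["sigma"]:
                frac = 0.15 if k == "he" else 0.6
                st.sigma[k] = frac * abs(st.sigma["h"]) * float(0.7 + 0.6 * rng.random())
        warm_started = True
    w = 0.0 if prior_only else 1.0

    total = cfg.n_warmup + cfg.n_samples
    keep_beta = np.empty((cfg.n_samples, len(st.beta)))
    keep_sigma = {c: np.empty(cfg.n_samples) for c in st.sigma}
    keep_tau = np.empty(cfg.n_samples) if design["basis"] is not None else None
    keep_ll = (np.empty((cfg.n_samples, n), dtype=np.float32)
               if cfg.store_loglik and not prior_only else None)
    keep_lat = {k: [] for k in ("A", "F", "C", "S", "P")} if cfg.store_latents else None

    # staged warmup mirroring the forward-selection traces: burn in a
    # genetics-only restriction so the genetic latents align with the
    # familial case pattern, then add the additive environment layers, and
    # only then enable the interaction products — started small and equal,
    # so the data (via the factor-marginalized scale moves) rather than
    # the initialization decides which interaction carries the variance.
    # Escaping a mis-aligned latent configuration is the sampler's slowest
    # move; entering an aligned one is fast.
    stages = []
    if len(spec.random_components) > 2 and not prior_only and not warm_started:
        quarter = max(cfg.n_warmup // 4, 1)
        stages = [(quarter, ModelSpec(spec.name, frozenset({"h", "e"}),
                                      spec.eqi_fixed_form, spec.link))]
        interaction_release = quarter if spec.interactions else None
    else:
        interaction_release = None

    z = np.zeros(n)
    anneal_until = 0 if warm_started else int(0.4 * cfg.n_warmup)
    for it in range(total):
        # likelihood annealing during early warmup: a hot chain can trade
        # variance between configurations cheaply before the full
        # likelihood freezes it into a basin
        bt = 1.0 if it >= anneal_until else 0.6 + 0.4 * it / max(anneal_until, 1)
        wt = w * bt
        sp = spec
        for bound, stage_spec in stages:
            if it < bound:
                sp = stage_spec
                break
        if interaction_release is not None and it == interaction_release:
            # release the gene-environment products at a substantial scale
            # relative to the aligned genetic signal: shrinking an unneeded
            # scale is fast, while growing one from near zero is the
            # sampler's slowest move, so the asymmetric start is the one
            # that lets the data decide
            for k in sorted(spec.interactions):  # stable rng-consumption order
                # the individual-level product takes off quickly (its
                # evidence is per-person, not per-family) and overshoots
                # from a high start; the family-layer products are the
                # slow-growing ones that need it
                frac = 0.15 if k == "he" else 0.6
                st.sigma[k] = frac * abs(st.sigma["h"]) * float(0.7 + 0.6 * rng.random())
        w_ = ws if sp is spec else dict(ws, sigma_order=sorted(sp.random_components - {"e"}))
        if not prior_only:
            z = _sample_z(st, w_, sp, rng, temper=bt)
        _update_coefficients(st, w_, sp, design, priors, rng, z, wt)
        _update_genetics(st, w_, sp, rng, z, wt)
        _update_G(st, w_, sp, rng, z, wt)
        _update_shared(st, w_, sp, rng, z, wt)
        _update_sigma_e(st, w_, sp, priors, rng, z, wt)
        if not prior_only:
            _update_sigma_layers_marginal(st, w_, sp, priors, rng, z, temper=bt)
            _update_sigma_pairs_marginal(st, w_, sp, priors, rng, z, temper=bt)
            _update_sigma_h_marginal(st, w_, sp, priors, rng, z, temper=bt)
            # the fully collapsed scale move trims the augmented state;
            # its partial-collapse approximation is benign (and highly
            # effective) for the two-component model, so it is applied
            # there only, with the trimmed variables refreshed at once
            if len(spec.random_components) <= 2 and it % ws["collapse_every"] == 0:
                _update_scales_collapsed(st, w_, sp, priors, rng, temper=bt)
                z = _sample_z(st, w_, sp, rng, temper=bt)
                _update_genetics(st, w_, sp, rng, z, wt)
                _update_G(st, w_, sp, rng, z, wt)
        _interweave_sigmas(st, w_, sp, priors, rng)
        if not prior_only:
            z = _global_rescale(st, w_, sp, design, priors, rng, z)
        _update_tau(st, design, priors, rng)

        j = it - cfg.n_warmup
        if j >= 0:
            keep_beta[j] = st.beta
            for c in st.sigma:
                keep_sigma[c][j] = st.sigma[c]
            if keep_tau is not None:
                keep_tau[j] = st.tau
            if keep_ll is not None:
                keep_ll[j] = _pointwise_loglik_draw(st, ws, spec)
            if keep_lat is not None and j % cfg.thin_latents == 0:
                for k in keep_lat:
                    keep_lat[k].append(np.array(getattr(st, k)))

    out = {"beta": keep_beta, "sigma": keep_sigma, "tau": keep_tau, "ll": keep_ll,
           "end_state": {"sigma": dict(st.sigma), "beta": np.array(st.beta),
                         "tau": st.tau, "A": np.array(st.A), "F": np.array(st.F),
                         "C": np.array(st.C), "S": np.array(st.S),
                         "P": np.array(st.P), "G": np.array(st.G)}}
    if keep_lat is not None:
        out["latents"] = {k: np.array(v) for k, v in keep_lat.items()}
    return out


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def fit(
    cohort: Cohort,
    eqi_table: pd.DataFrame,
    spec: ModelSpec,
    priors: PriorSpec | None = None,
    cfg: McmcConfig | None = None,
    prior_only: bool = False,
    init_states: list | None = None,
) -> PosteriorDraws:
    """Posterior draws for one model on one cohort.

    Deterministic given ``cfg.seed``. Raises ``DegenerateCohortError`` when
    the cohort has no cases or no controls, and flags (never hides)
    non-convergence via R-hat > 1.1 on any scalar parameter.

    ``init_states`` (one per chain, cycled) warm-starts chains from a
    nested model's ``end_states`` — the forward-selection traces make the
    previous model's configuration the natural starting point for the
    next, with any newly added interaction scales released high.
    """
    priors = priors or PriorSpec()
    cfg = cfg or McmcConfig()
    if cfg.sampler == "hmc":
        raise NotImplementedError(
            "the hmc backend is a declared alternative contract; "
            "use sampler='gibbs_augmented'"
        )
    if spec.link != "probit":
        raise NotImplementedError("fitting currently supports the probit link only")
    if not prior_only and cohort.n_cases in (0, cohort.n_individuals):
        raise DegenerateCohortError(
            f"cohort has {cohort.n_cases}/{cohort.n_individuals} cases; "
            "a degenerate outcome cannot identify liability variance components"
        )

    design = build_design(cohort, eqi_table, spec)
    ix = design["ix"]
    ws = {
        "X": design["X"],
        "XtX": design["X"].T @ design["X"],
        "case": ix["case"].astype(np.int64),
        "fam": ix["fam"],
        "county": ix["county"],
        "is_child": ix["is_child"],
        "parf": ix["is_parent"].astype(float),
        "chif": ix["is_child"].astype(float),
        "father_pos": ix["father_pos"],
        "mother_pos": ix["mother_pos"],
        "n": cohort.n_individuals,
        "n_fam": len(ix["family_ids"]),
        "n_cty": len(ix["county_ids"]),
        "n_children": np.bincount(ix["fam"][ix["is_child"]],
                                  minlength=len(ix["family_ids"])).astype(float),
        "sigma_order": sorted(spec.random_components - {"e"}),
        "groups": _family_groups(ix),
        "zeros": np.zeros(cohort.n_individuals),
        "case_sign": np.where(ix["case"] == 1, 1.0, -1.0),
        # collapsed scale moves are cheap on small cohorts, pricier on large
        "collapse_every": 5 if cohort.n_individuals < 10_000 else 20,
    }

    chains = []
    for c in range(cfg.n_chains):
        rng = substream(cfg.seed, f"chain-{c}")
        init = init_states[c % len(init_states)] if init_states else None
        chains.append(_run_chain(ws, design, spec, priors, cfg, rng, prior_only,
                                 init_state=init))

    beta = np.stack([ch["beta"] for ch in chains])
    sigma = {c: np.stack([ch["sigma"][c] for ch in chains]) for c in chains[0]["sigma"]}
    tau = (np.stack([ch["tau"] for ch in chains])
           if chains[0]["tau"] is not None else None)
    ll = (np.stack([ch["ll"] for ch in chains])
          if chains[0]["ll"] is not None else None)

    spline = None
    if design["basis"] is not None:
        nb = design["basis"].n_basis
        spline = np.stack(
            [beta[:, :, design["spline_slices"][dom]] for dom in EQI_DOMAINS], axis=2
        )
        assert spline.shape[-1] == nb

    diag = _diagnostics(beta, design["names"], sigma, tau)
    bad = diag["r_hat"].isna() | (diag["r_hat"] > RHAT_LIMIT)
    converged = not bool(bad.any())
    if not converged:
        log.warning("non-convergence flagged: %s", diag.index[bad].tolist())

    end_states = [ch["end_state"] for ch in chains]
    latents = {}
    if cfg.store_latents:
        latents = {k: np.stack([ch["latents"][k] for ch in chains])
                   for k in chains[0]["latents"]}

    return PosteriorDraws(
        spec=spec,
        beta=beta,
        beta_names=design["names"],
        sigma=sigma,
        spline=spline,
        spline_basis=design["basis"],
        tau=tau,
        pointwise_loglik=ll,
        diagnostics=diag,
        converged=converged,
        meta={
            "seed": cfg.seed,
            "n_chains": cfg.n_chains,
            "n_warmup": cfg.n_warmup,
            "n_samples": cfg.n_samples,
            "n_individuals": cohort.n_individuals,
            "n_families": cohort.n_families,
            "prior_only": prior_only,
            "percentiles": design["percentiles"],
        },
        end_states=end_states,
        latents=latents,
    )


def _diagnostics(beta, beta_names, sigma, tau) -> pd.DataFrame:
    scalars = {f"beta[{nm}]": beta[:, :, i] for i, nm in enumerate(beta_names)}
    for c, arr in sigma.items():
        # scales are signed internally; only sigma^2 is identified
        scalars[f"sigma2[{c}]"] = arr**2
    if tau is not None:
        scalars["tau_spline"] = tau
    rows = []
    for name, arr in scalars.items():
        if np.allclose(arr.var(axis=1), 0.0):
            rhat, ess = np.nan, np.nan
        else:
            rhat = float(az.rhat(arr))
            ess = float(az.ess(arr))
        rows.append((name, rhat, ess))
    return pd.DataFrame(rows, columns=["parameter", "r_hat", "ess"]).set_index("parameter")


def convergence_report(draws: PosteriorDraws) -> ConvergenceReport:
    """Split-R-hat / ESS per scalar parameter with an overall pass flag.

    Zero-variance (stuck or constant) chains yield an undefined R-hat,
    reported as NaN and counted as a failure.
    """
    if draws.n_chains < 2:
        raise ValueError("convergence diagnostics need at least 2 chains")
    t = draws.diagnostics
    passed = bool(((t["r_hat"] <= RHAT_LIMIT) & t["r_hat"].notna()).all())
    return ConvergenceReport(table=t, passed=passed)
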