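"""Model comparison and posterior summaries: WAIC, variance partition,
non-linear environmental effect curves, and a tetrachoric-correlation
helper for liability-scale checks.

WAIC here is the *conditional* flavour standard for hierarchical MCMC
output: the pointwise likelihood conditions on the sampled shared latents,
with the individual-level residual (and the gene-by-individual product)
integrated out analytically. Every report that includes a WAIC records
this choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .eqi import EQI_DOMAINS
from .inference import PosteriorDraws
from .models import COMPONENTS, ModelSpec, default_model_suite

LOGIT_RESIDUAL_VARIANCE = np.pi**2 / 3.0


@dataclass
class WaicResult:
    waic: float
    lppd: float
    p_waic: float
    pointwise_lppd: np.ndarray
    pointwise_p: np.ndarray
    n_individuals: int
    likelihood: str = "conditional"

    def __post_init__(self):
        assert np.isclose(self.waic, -2.0 * (self.lppd - self.p_waic))


def waic(pointwise_loglik: np.ndarray) -> WaicResult:
    """Widely-applicable information criterion from a (draws x individuals)
    pointwise log-likelihood matrix.

    lppd_i = log mean_d exp(ll_di) (computed with a stable log-sum-exp);
    p_waic_i = unbiased sample variance over draws of ll_di;
    WAIC = -2 (sum_i lppd_i - sum_i p_waic_i). Lower is better.
    """
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim != 2:
        raise ValueError("pointwise log-likelihood must be draws x individuals")
    S, n = ll.shape
    if S < 2:
        raise ValueError("need at least 2 draws (pointwise variance undefined)")
    if n < 1:
        raise ValueError("need at least 1 individual")
    if not np.all(np.isfinite(ll)):
        raise ValueError("pointwise log-likelihood contains non-finite entries")
    lppd_i = special.logsumexp(ll, axis=0) - np.log(S)
    p_i = ll.var(axis=0, ddof=1)
    lppd = float(lppd_i.sum())
    p_waic = float(p_i.sum())
    return WaicResult(
        waic=-2.0 * (lppd - p_waic),
        lppd=lppd,
        p_waic=p_waic,
        pointwise_lppd=lppd_i,
        pointwise_p=p_i,
        n_individuals=n,
    )


def waic_of(draws: PosteriorDraws) -> WaicResult:
    return waic(draws.loglik_matrix())


def rank_models(results: dict, component_counts: dict | None = None) -> list:
    """Model names ordered best (smallest WAIC) first.

    All results must cover the identical individual set. Exact ties go to
    the model with fewer active variance components, then lexicographic
    name. ``component_counts`` defaults to the shipped five-model suite.
    """
    if len(results) < 2:
        raise ValueError("need at least two models to rank")
    sizes = {name: r.n_individuals for name, r in results.items()}
    if len(set(sizes.values())) != 1:
        raise ValueError(f"models evaluated on different individual sets: {sizes}")
    if component_counts is None:
        component_counts = {s.name: len(s.random_components) for s in default_model_suite()}
    return sorted(results,
                  key=lambda nm: (results[nm].waic, component_counts.get(nm, 0), nm))


# ---------------------------------------------------------------------------
# variance partition
# ---------------------------------------------------------------------------

def variance_partition(sigma_draws: dict, spec: ModelSpec,
                       interval: float = 0.95) -> pd.DataFrame:
    """Posterior summary of the variance-fraction statistics.

    Per draw, fraction_k = sigma_k^2 / V with V the sum of active
    sigma_k^2 (probit) or that sum plus pi^2/3 (logit; the implicit
    logistic residual is folded into e2 so the statistics stay comparable
    across links). Rows appear only for active components — an absent
    component is absent, not zero.
    """
    active = [c for c in COMPONENTS if c in spec.random_components]
    missing = [c for c in active if c not in sigma_draws]
    if missing:
        raise ValueError(f"draws lack active components {missing}")
    sq = {c: np.asarray(sigma_draws[c], dtype=float).reshape(-1) ** 2 for c in active}
    V = np.sum([sq[c] for c in active], axis=0)
    if spec.link == "logit":
        V = V + LOGIT_RESIDUAL_VARIANCE
        sq["e"] = sq["e"] + LOGIT_RESIDUAL_VARIANCE
    lo_q, hi_q = (1 - interval) / 2, 1 - (1 - interval) / 2
    rows = []
    for c in active:
        frac = sq[c] / V
        rows.append((f"{c}2", float(frac.mean()),
                     float(np.quantile(frac, lo_q)), float(np.quantile(frac, hi_q))))
    return pd.DataFrame(rows, columns=["statistic", "mean", "lo", "hi"]).set_index("statistic")


def partition_of(draws: PosteriorDraws, interval: float = 0.95) -> pd.DataFrame:
    return variance_partition(draws.sigma_flat(), draws.spec, interval)


# ---------------------------------------------------------------------------
# non-linear environmental effect curves
# ---------------------------------------------------------------------------

PROBIT_TO_LOGODDS = np.pi / np.sqrt(3.0)


@dataclass
class EffectCurve:
    domain: str
    grid: np.ndarray
    mean: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    segments: list  # (start_percentile, end_percentile, significant)


def effect_curve(draws: PosteriorDraws, domain: str,
                 grid_step: float = 2.5, interval: float = 0.95) -> EffectCurve:
    """Posterior effect of one EQI domain across its percentile range.

    The curve is the fitted spline evaluated on percentiles 2.5-97.5,
    expressed as the log-odds difference from the 50th-percentile
    reference (probit-scale effects are mapped to log-odds by the
    logistic/normal scale factor pi/sqrt(3)). A grid point is *significant*
    when the equal-tailed credible interval excludes zero; contiguous
    same-flag runs are merged into segments.
    """
    if draws.spline is None or draws.spline_basis is None:
        raise ValueError(f"model {draws.spec.name!r} has no spline EQI effects")
    if domain not in EQI_DOMAINS:
        raise ValueError(f"unknown EQI domain {domain!r}")
    d = EQI_DOMAINS.index(domain)
    grid = np.arange(2.5, 97.5 + 1e-9, grid_step)
    B = draws.spline_basis.design_centered(grid)              # (g, nb)
    theta = draws.spline[:, :, d, :].reshape(-1, draws.spline.shape[-1])
    curves = theta @ B.T                                      # (draws, g)
    if draws.spec.link == "probit":
        curves = curves * PROBIT_TO_LOGODDS
    lo_q, hi_q = (1 - interval) / 2, 1 - (1 - interval) / 2
    lo = np.quantile(curves, lo_q, axis=0)
    hi = np.quantile(curves, hi_q, axis=0)
    mean = curves.mean(axis=0)
    flags = (lo > 0) | (hi < 0)

    segments = []
    start = 0
    for g in range(1, len(grid) + 1):
        if g == len(grid) or flags[g] != flags[start]:
            segments.append((float(grid[start]), float(grid[g - 1]), bool(flags[start])))
            start = g
    return EffectCurve(domain, grid, mean, lo, hi, segments)


def effect_curve_frame(curve: EffectCurve) -> pd.DataFrame:
    flags = np.zeros(len(curve.grid), dtype=bool)
    for s, e, sig in curve.segments:
        flags |= (curve.grid >= s) & (curve.grid <= e) & sig
    return pd.DataFrame({
        "percentile": curve.grid,
        "log_odds_mean": curve.mean,
        "log_odds_lo": curve.lo,
        "log_odds_hi": curve.hi,
        "significant": flags,
    })


# ---------------------------------------------------------------------------
# tetrachoric correlation (liability-scale concordance checks)
# ---------------------------------------------------------------------------

def tetrachoric_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Correlation of underlying bivariate-normal liabilities from paired
    binary outcomes (maximum likelihood with thresholds fixed at the
    observed margins)."""
    x = np.asarray(x).astype(int)
    y = np.asarray(y).astype(int)
    if x.shape != y.shape:
        raise ValueError("paired arrays must have equal length")
    n = x.size
    p11 = np.mean((x == 1) & (y == 1))
    px, py = x.mean(), y.mean()
    if not (0 < px < 1 and 0 < py < 1):
        raise ValueError("degenerate margins: both traits need cases and controls")
    hx, hy = special.ndtri(1 - px), special.ndtri(1 - py)

    def upper_tail(rho):
        dist = stats.multivariate_normal(mean=[0, 0], cov=[[1, rho], [rho, 1]])
        return dist.cdf([-hx, -hy])  # P(Z1 > hx, Z2 > hy) by symmetry

    def obj(rho):
        return upper_tail(rho) - p11

    return float(optimize.brentq(obj, -0.999, 0.999, xtol=1e-6))
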