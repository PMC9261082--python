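"""Shared numerical helpers: seeded substreams and stable truncated-normal draws."""

from __future__ import annotations

import zlib

import numpy as np
from scipy import special


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible child stream of a single top-level seed.

    Streams are derived as ``SeedSequence([seed, crc32(name)])`` so every
    stage (simulation, each MCMC chain, ...) gets an independent generator
    while the whole run is reproducible from one integer.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def std_truncnorm_lower(alpha: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw standard normals truncated to ``(alpha, inf)``, elementwise.

    Uses inverse-CDF sampling in log space (``ndtri_exp``) which stays
    accurate even for truncation points far in the upper tail, where the
    plain ``ndtri(ndtr(...))`` route underflows.
    """
    alpha = np.asarray(alpha, dtype=float)
    u = 1.0 - rng.random(alpha.shape)  # in (0, 1]
    # survival mass above alpha, in log space; u slides within it
    log_tail = special.log_ndtr(-alpha)
    return -special.ndtri_exp(log_tail + np.log(u))


def sample_truncnorm(mean, sd, rng: np.random.Generator, lower=None, upper=None):
    """One-sided truncated normal draws with broadcasting.

    Exactly one of ``lower`` / ``upper`` must be given.
    """
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if (lower is None) == (upper is None):
        raise ValueError("exactly one of lower/upper must be set")
    if lower is not None:
        alpha = (np.asarray(lower, dtype=float) - mean) / sd
        alpha, mean, sd = np.broadcast_arrays(alpha, mean, sd)
        return mean + sd * std_truncnorm_lower(alpha, rng)
    alpha = (mean - np.asarray(upper, dtype=float)) / sd
    alpha, mean, sd = np.broadcast_arrays(alpha, mean, sd)
    return mean - sd * std_truncnorm_lower(alpha, rng)


def slice_sample_scalar(
    logpdf,
    x0: float,
    rng: np.random.Generator,
    width: float = 1.0,
    max_steps: int = 50,
    lower: float | None = 0.0,
) -> float:
    """Univariate slice sampler with stepping-out; ``lower=None`` means
    unbounded below."""
    logy = logpdf(x0) + np.log(1.0 - rng.random())
    left = x0 - width * rng.random()
    right = left + width
    steps = max_steps
    while (lower is None or left > lower) and logpdf(left) > logy and steps > 0:
        left -= width
        steps -= 1
    if lower is not None:
        left = max(left, lower + 1e-12)
    steps = max_steps
    while logpdf(right) > logy and steps > 0:
        right += width
        steps -= 1
    while True:
        x1 = left + (right - left) * rng.random()
        if logpdf(x1) > logy:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1
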