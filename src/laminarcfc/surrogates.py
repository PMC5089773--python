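"""Surrogate-data significance testing.

The null hypothesis of "no coupling" is materialized by circularly shifting
the source series by a random offset (drawn uniformly over the middle 80% of
the series length, so that small shifts cannot leak true coupling) and
recomputing the statistic.  Marginal distributions and autocorrelation are
preserved while temporal alignment is destroyed.  From the surrogate
distribution a z-score and two-sided Gaussian p-value are computed; |Z| >
1.96 is significant at alpha = 0.05, and a Benjamini-Hochberg false
discovery rate correction is applied across all simultaneously tested
entries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SurrogateConfig",
    "SignificanceResult",
    "surrogate_offsets",
    "surrogate_null",
    "z_and_p",
    "fdr_mask",
    "significance_from_draws",
    "attach_significance",
]


@dataclass(frozen=True)
class SurrogateConfig:
    """n_surrogates: null-sample count; lag_range: offset bounds as fractions
    of the series length; seed: base RNG seed (each tested pair derives an
    independent stream from it)."""

    n_surrogates: int = 1000
    lag_range: tuple[float, float] = (0.1, 0.9)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_surrogates < 2:
            raise ValueError("n_surrogates must be >= 2")
        lo, hi = self.lag_range
        if not (0 <= lo < hi <= 1):
            raise ValueError("lag_range must satisfy 0 <= lo < hi <= 1")


@dataclass
class SignificanceResult:
    """z-scores, two-sided Gaussian p-values, post-FDR mask and the surrogate
    moments they were computed from."""

    z: np.ndarray
    p: np.ndarray
    mask: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray


def surrogate_offsets(
    T: int, config: SurrogateConfig = SurrogateConfig(), pair_index: int = 0
) -> np.ndarray:
    """The circular offsets one ``surrogate_null`` call would apply.

    Exposed so that vectorized estimators can evaluate the identical null
    (same seeding, same offsets) without the per-surrogate loop.
    """
    lo = max(int(config.lag_range[0] * T), 1)
    hi = max(int(config.lag_range[1] * T), lo + 1)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, pair_index]))
    return rng.integers(lo, hi, size=config.n_surrogates)


def surrogate_null(
    estimator,
    source: np.ndarray,
    target: np.ndarray,
    config: SurrogateConfig = SurrogateConfig(),
    pair_index: int = 0,
) -> np.ndarray:
    """Null distribution of ``estimator(shifted_source, target)``.

    Each surrogate applies an independent circular offset to the source
    series.  ``pair_index`` decorrelates the RNG streams of simultaneously
    tested pairs while keeping the whole procedure reproducible under
    ``config.seed``.
    """
    source = np.asarray(source)
    target = np.asarray(target)
    if np.all(source == source.flat[0]) or np.all(target == target.flat[0]):
        raise ValueError("degenerate (constant) series cannot be tested")
    offsets = surrogate_offsets(source.shape[0], config, pair_index)
    draws = np.array([estimator(np.roll(source, int(s)), target) for s in offsets])
    if draws.std() == 0:
        import logging

        logging.getLogger(__name__).warning(
            "offset-invariant statistic: all %d surrogates identical", len(draws)
        )
    return draws


def z_and_p(stat: float, surrogates: np.ndarray) -> tuple[float, float]:
    """z = (stat - mu) / sigma against the surrogate moments, and the
    two-sided standard-normal p-value."""
    surrogates = np.asarray(surrogates, dtype=float)
    mu = surrogates.mean()
    sigma = surrogates.std(ddof=1)
    if sigma == 0:
        raise ZeroDivisionError("surrogate distribution has zero variance")
    z = (stat - mu) / sigma
    return float(z), float(2.0 * sstats.norm.sf(abs(z)))


def fdr_mask(pvalues: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask over all entries."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value array")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject = multipletests(p.ravel(), alpha=alpha, method="fdr_bh")[0]
    return reject.reshape(p.shape)


def significance_from_draws(
    values: np.ndarray, draws: np.ndarray, alpha: float = 0.05
) -> SignificanceResult:
    """Vectorized z/p/mask computation for a matrix of statistics.

    ``draws`` is an object array (same shape as ``values``) of surrogate
    vectors.  The mask requires both |z| above the two-sided Gaussian
    threshold and survival of the BH-FDR correction across all entries.
    Offset-invariant entries (zero surrogate spread) are marked
    non-significant unless the observed value departs from the degenerate
    null, in which case z is +/-inf.
    """
    values = np.asarray(values, dtype=float)
    z = np.zeros_like(values)
    p = np.ones_like(values)
    mu = np.zeros_like(values)
    sigma = np.zeros_like(values)
    for idx in np.ndindex(values.shape):
        s = np.asarray(draws[idx], dtype=float)
        mu[idx] = s.mean()
        sigma[idx] = s.std(ddof=1)
        if sigma[idx] == 0:
            if values[idx] != mu[idx]:
                z[idx] = np.inf if values[idx] > mu[idx] else -np.inf
                p[idx] = 0.0
            continue
        z[idx], p[idx] = z_and_p(values[idx], s)
    crit = sstats.norm.ppf(1 - alpha / 2)
    mask = fdr_mask(p, alpha=alpha) & (np.abs(z) > crit)
    return SignificanceResult(z=z, p=p, mask=mask, mu=mu, sigma=sigma)


def attach_significance(result, draws: np.ndarray, alpha: float = 0.05) -> None:
    """Fill a CFCResult's zscores/pvalues/mask fields in place."""
    sig = significance_from_draws(result.values, draws, alpha=alpha)
    result.zscores = sig.z
    result.pvalues = sig.p
    result.mask = sig.mask
    result.meta["surrogate_mu"] = sig.mu.tolist()
    result.meta["surrogate_sigma"] = sig.sigma.tolist()
    result.meta["alpha"] = alpha
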