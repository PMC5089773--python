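"""Indirect-coupling decomposition and cascade regression models.

For a feed-forward chain y1 -> y2 -> y3 the indirect transfer entropy from
y1 to y3 decomposes exactly (for plug-in estimates sharing one
discretization) as

    cTE(y1 ~> y3) = cTE(y1 -> y2) + cTE(y2 -> y3) + I~

where I~ is a combination of joint mutual-information terms.  The residual
I~ is what a pure "cascade of direct couplings" picture ignores; the cascade
regression models approximate the indirect phase-to-amplitude coupling
PAC_theta1->gamma3 by sums of direct cross-frequency (PAC, APC, AAC, PPC)
and same-frequency couplings through the relay population 2.

Also here: the Fourier-series nonlinear correlation coefficient used to
relate coupling strength to model parameters, r_nl = |corr(Y, Yhat)| with
Yhat(X) = a0 + sum_k a_k sin(b_k X + c_k).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cfc import (
    DiscretizationScheme,
    _discretize_feature,
    conditional_transfer_entropy,
    entropy_bits,
    mutual_information,
)
from .signals import AnalyticDecomposition
from .surrogates import SurrogateConfig, significance_from_draws, surrogate_null

__all__ = [
    "DecompositionResult",
    "CascadeModel",
    "FourierFit",
    "decompose_indirect",
    "cascade_terms",
    "compute_cascade_predictors",
    "fit_cascade",
    "fourier_nonlinear_correlation",
    "TABLE_MODELS",
]


@dataclass
class DecompositionResult:
    """Terms of the indirect-coupling identity, all in bits.

    ``indirect = direct12 + direct23 + residual`` holds exactly for plug-in
    estimates computed on the shared discretized samples.
    """

    indirect: float
    direct12: float
    direct23: float
    residual: float

    @property
    def identity_gap(self) -> float:
        return self.indirect - (self.direct12 + self.direct23 + self.residual)


def _as_codes(y, feature: str, scheme: DiscretizationScheme) -> np.ndarray:
    y = np.asarray(y)
    if np.issubdtype(y.dtype, np.integer):
        return y.astype(np.int64)
    return _discretize_feature(np.asarray(y, dtype=float), feature, scheme.n_bins)


def decompose_indirect(
    y1,
    y2,
    y3,
    n_lags: int = 10,
    scheme: DiscretizationScheme = DiscretizationScheme(),
    features: tuple[str, str, str] = ("phase", "amplitude", "amplitude"),
) -> DecompositionResult:
    """Exact decomposition of the indirect coupling y1 ~> y3 through y2.

    Inputs may be continuous series (discretized per ``features``: 'phase'
    uses circular bins, anything else quantile bins) or already-discrete
    integer series.  All four quantities are evaluated on the same sample
    rows, so the identity is algebraically exact.
    """
    c1, c2, c3 = (
        _as_codes(y, f, scheme) for y, f in zip((y1, y2, y3), features)
    )
    if not (c1.shape == c2.shape == c3.shape):
        raise ValueError("series must have equal length")
    T = c1.shape[0]
    if n_lags >= T:
        raise ValueError("n_lags must be smaller than the series length")
    L = T - n_lags
    y1_, y2_, y3_ = c1[:L], c2[:L], c3[:L]

    ind = d12 = d23 = 0.0
    resid_sum = 0.0
    for delta in range(1, n_lags + 1):
        y2d = c2[delta:delta + L]
        y3d = c3[delta:delta + L]
        # chain-rule cMIs of the three connections
        ind += mutual_information(y1_, [y2_, y3_, y3d]) - mutual_information(y1_, [y2_, y3_])
        d12 += mutual_information(y1_, [y2_, y2d, y3_]) - mutual_information(y1_, [y2_, y3_])
        d23 += mutual_information(y2_, [y1_, y3_, y3d]) - mutual_information(y2_, [y1_, y3_])
        resid_sum += (
            mutual_information(y1_, [y2_, y3_, y3d])
            - mutual_information(y1_, [y2_, y2d, y3_])
            - mutual_information(y2_, [y1_, y3_, y3d])
        )
    residual = mutual_information(y2_, [y1_, y3_]) + resid_sum / n_lags
    return DecompositionResult(
        indirect=ind / n_lags,
        direct12=d12 / n_lags,
        direct23=d23 / n_lags,
        residual=residual,
    )


# ---------------------------------------------------------------------------
# Cascade regression models.  Population 1 oscillates in theta, population 3
# in gamma; the relay population 2 oscillates in delta (case I) or beta
# (case II), written X below.  Terms are (type, src_band, src_pop, tgt_band,
# tgt_pop) with pops numbered 1..3; same-band terms are SFC variables
# labelled like their cross-band counterparts.
# ---------------------------------------------------------------------------

_MODEL_TERMS = {
    1: [("PPC", "theta", 1, "theta", 2), ("PAC", "theta", 2, "gamma", 3)],
    2: [("PAC", "theta", 1, "theta", 2), ("AAC", "theta", 2, "gamma", 3)],
    3: [("PPC", "theta", 1, "X", 2), ("PAC", "X", 2, "gamma", 3)],
    4: [("PAC", "theta", 1, "X", 2), ("AAC", "X", 2, "gamma", 3)],
    5: [("PPC", "theta", 1, "theta", 2), ("PPC", "theta", 2, "theta", 3),
        ("PAC", "theta", 3, "gamma", 3)],
    6: [("PPC", "theta", 1, "X", 2), ("PPC", "X", 2, "theta", 3),
        ("PAC", "theta", 3, "gamma", 3)],
    7: [("PPC", "theta", 1, "X", 2), ("PPC", "X", 2, "X", 3),
        ("PAC", "X", 3, "gamma", 3)],
    8: [("PAC", "theta", 1, "theta", 2), ("APC", "theta", 2, "theta", 3),
        ("PAC", "theta", 3, "gamma", 3)],
    9: [("PAC", "theta", 1, "X", 2), ("APC", "X", 2, "theta", 3),
        ("PAC", "theta", 3, "gamma", 3)],
    10: [("PAC", "theta", 1, "X", 2), ("APC", "X", 2, "X", 3),
         ("PAC", "X", 3, "gamma", 3)],
}

_CASE_MID_BAND = {"I": "delta", "II": "beta"}

#: response variable: indirect PAC from theta phase in 1 to gamma amplitude in 3
RESPONSE_TERM = ("PAC", "theta", 1, "gamma", 3)

#: feature carried by each end of a term type
_TERM_FEATURES = {
    "PAC": ("phase", "amplitude"),
    "APC": ("amplitude", "phase"),
    "AAC": ("amplitude", "amplitude"),
    "PPC": ("phase", "phase"),
    "PFC": ("phase", "frequency"),
}


@dataclass(frozen=True)
class CascadeModel:
    """One Table-style cascade model: indirect PAC regressed on direct terms."""

    id: int
    case: str
    predictors: tuple
    response: tuple = RESPONSE_TERM


def _resolve(term, case: str):
    mid = _CASE_MID_BAND[case]
    ctype, sb, sp, tb, tp = term
    return ctype, (mid if sb == "X" else sb), sp, (mid if tb == "X" else tb), tp


def term_name(term, case: str) -> str:
    ctype, sb, sp, tb, tp = _resolve(term, case)
    return f"{ctype}_{sb}{sp}{tb}{tp}"


def cascade_terms(case: str) -> list[tuple]:
    """The 16 unique predictor terms for a case, resolved to concrete bands."""
    if case not in _CASE_MID_BAND:
        raise ValueError("case must be 'I' or 'II'")
    seen: dict[str, tuple] = {}
    for terms in _MODEL_TERMS.values():
        for t in terms:
            seen.setdefault(term_name(t, case), _resolve(t, case))
    return list(seen.values())


def TABLE_MODELS(case: str) -> list[CascadeModel]:
    """The ten cascade models for one case."""
    return [
        CascadeModel(id=i, case=case, predictors=tuple(_resolve(t, case) for t in terms))
        for i, terms in _MODEL_TERMS.items()
    ]


def _term_value(
    decomp: AnalyticDecomposition,
    term,
    n_lags: int,
    scheme: DiscretizationScheme,
    surrogate_config: SurrogateConfig | None,
    pair_index: int,
):
    """One term's cTE (and surrogate draws) from a 3-population decomposition."""
    ctype, sb, sp, tb, tp = term
    sf, tf = _TERM_FEATURES[ctype]
    src = _discretize_feature(decomp.get(sb, sp - 1, sf), sf, scheme.n_bins)
    tgt = _discretize_feature(decomp.get(tb, tp - 1, tf), tf, scheme.n_bins)
    cond = [tgt]
    val = conditional_transfer_entropy(src, tgt, cond, n_lags)
    draws = None
    if surrogate_config is not None:
        draws = surrogate_null(
            lambda s, t: conditional_transfer_entropy(s, t, [t], n_lags),
            src,
            tgt,
            config=surrogate_config,
            pair_index=pair_index,
        )
    return max(val, 0.0), draws


def compute_cascade_predictors(
    decomp: AnalyticDecomposition,
    case: str,
    n_lags: int = 10,
    scheme: DiscretizationScheme = DiscretizationScheme(),
    surrogate_config: SurrogateConfig | None = None,
    alpha: float = 0.05,
) -> dict[str, float]:
    """The response plus all 16 predictors for one simulated sweep point.

    With a surrogate config, values are surrogate-masked (non-significant
    terms set to 0 after the FDR correction across all terms).
    """
    terms = [RESPONSE_TERM] + cascade_terms(case)
    names = [term_name(t, case) for t in [RESPONSE_TERM]] + [
        f"{t[0]}_{t[1]}{t[2]}{t[3]}{t[4]}" for t in cascade_terms(case)
    ]
    values = np.zeros(len(terms))
    draws = np.zeros(len(terms), dtype=object)
    resolved = [_resolve(RESPONSE_TERM, case)] + cascade_terms(case)
    for i, t in enumerate(resolved):
        values[i], d = _term_value(decomp, t, n_lags, scheme, surrogate_config, i)
        draws[i] = d
    if surrogate_config is not None:
        sig = significance_from_draws(values, draws, alpha=alpha)
        values = values * sig.mask
    return dict(zip(names, values))


def fit_cascade(response: np.ndarray, predictors: np.ndarray) -> float:
    """Coefficient of determination of an OLS fit with intercept.

    ``predictors`` is (n_points, n_terms).  Rank-deficient designs are fitted
    through the pseudo-inverse (lstsq) and flagged via a logged warning.
    """
    import logging

    y = np.asarray(response, dtype=float)
    X = np.column_stack([np.ones_like(y), np.asarray(predictors, dtype=float)])
    if y.size < 3:
        raise ValueError("need at least 3 points per regression")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        logging.getLogger(__name__).warning("rank-deficient design; pseudo-inverse fit")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sst = np.sum((y - y.mean()) ** 2)
    if sst == 0:
        return 1.0
    return float(max(0.0, min(1.0, 1.0 - np.sum(resid**2) / sst)))


@dataclass
class FourierFit:
    """Fitted Fourier regression Yhat(X) = a0 + sum_k a_k sin(b_k X + c_k)."""

    a0: float
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    r_nl: float
    sse: float
    p_value: float | None = None
    meta: dict = field(default_factory=dict)

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.a0 + np.sum(
            self.a[:, None] * np.sin(self.b[:, None] * X[None, :] + self.c[:, None]),
            axis=0,
        )


def _fit_fourier_once(X, Y, K, rng, b_init=None):
    from scipy.optimize import least_squares

    span = max(np.ptp(X), 1e-12)
    if b_init is None:
        b0 = rng.uniform(0.1, 2 * np.pi * K / span, size=K)
    else:
        b0 = b_init
    theta0 = np.concatenate(
        [[Y.mean()], rng.normal(0, max(Y.std(), 1e-6), K) / np.sqrt(K),
         b0, rng.uniform(-np.pi, np.pi, K)]
    )

    def resid(theta):
        a0, a, b, c = theta[0], theta[1:K + 1], theta[K + 1:2 * K + 1], theta[2 * K + 1:]
        return a0 + np.sum(
            a[:, None] * np.sin(b[:, None] * X[None, :] + c[:, None]), axis=0
        ) - Y

    sol = least_squares(resid, theta0, max_nfev=2000)
    return sol.x, float(np.sum(sol.fun**2))


def fourier_nonlinear_correlation(
    X: np.ndarray,
    Y: np.ndarray,
    K: int = 10,
    n_restarts: int = 20,
    seed: int = 0,
    n_shuffle: int | None = None,
) -> FourierFit:
    """Nonlinear correlation between a parameter vector X and responses Y.

    Fits the K-term Fourier series by nonlinear least squares with
    ``n_restarts`` seeded random restarts (plus one start with linearly
    spaced frequencies), keeps the best SSE, and reports
    r_nl = |corr(Y, Yhat)|.  With ``n_shuffle`` set, a permutation p-value is
    attached by refitting on shuffled responses.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.ndim != 1:
        raise ValueError("X and Y must be equal-length vectors")
    if Y.size <= 3 * K + 1:
        raise ValueError("need more than 3K + 1 points to fit K Fourier terms")
    if Y.std() == 0:
        raise ValueError("constant response")
    rng = np.random.default_rng(seed)

    def best_fit(y, restarts):
        span = max(np.ptp(X), 1e-12)
        best = None
        starts = [np.linspace(1, K, K) * np.pi / span] + [None] * restarts
        for b_init in starts:
            theta, sse = _fit_fourier_once(X, y, K, rng, b_init)
            if best is None or sse < best[1]:
                best = (theta, sse)
        return best

    theta, sse = best_fit(Y, n_restarts)
    a0, a, b, c = theta[0], theta[1:K + 1], theta[K + 1:2 * K + 1], theta[2 * K + 1:]
    fit = FourierFit(a0=float(a0), a=a, b=b, c=c, r_nl=0.0, sse=sse)
    yhat = fit.predict(X)
    fit.r_nl = float(abs(np.corrcoef(Y, yhat)[0, 1])) if yhat.std() > 0 else 0.0

    if n_shuffle:
        null = np.empty(n_shuffle)
        for i in range(n_shuffle):
            ys = rng.permutation(Y)
            th, _ = best_fit(ys, max(2, n_restarts // 4))
            f = FourierFit(th[0], th[1:K + 1], th[K + 1:2 * K + 1], th[2 * K + 1:], 0.0, 0.0)
            yh = f.predict(X)
            null[i] = abs(np.corrcoef(ys, yh)[0, 1]) if yh.std() > 0 else 0.0
        fit.p_value = float((1 + np.sum(null >= fit.r_nl)) / (1 + n_shuffle))
        fit.meta["shuffle_null_mean"] = float(null.mean())
    return fit
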