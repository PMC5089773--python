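"""Cross-frequency and same-frequency coupling estimators.

All couplings are expressed as information quantities between discretized
instantaneous phase / amplitude / frequency series:

* ``modulation_index`` -- |sum_t a(t) exp(i phi(t))|, the amplitude-weighted
  phase vector magnitude (a pairwise, non-directional PAC measure);
* ``esc`` -- Pearson correlation of cos(phase) with amplitude;
* ``conditional_mutual_information`` -- plug-in cMI on discrete series via
  the chain rule I(x; y | M) = I(x; y, M) - I(x; M);
* ``conditional_transfer_entropy`` -- cMI between the source now and the
  target shifted delta steps into the future, averaged over delta = 1..N
  lags, optionally conditioned on other series; direction-sensitive.

``estimate_cfc`` evaluates one coupling type (PAC, APC, AAC, PPC, PFC or
same-band SFC) for every ordered population pair of an analytic
decomposition and returns the matrix of cTE values in bits.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .signals import AnalyticDecomposition

__all__ = [
    "CouplingSpec",
    "DiscretizationScheme",
    "CFCResult",
    "COUPLING_FEATURES",
    "modulation_index",
    "esc",
    "discretize",
    "entropy_bits",
    "mutual_information",
    "conditional_mutual_information",
    "conditional_mutual_information_knn",
    "conditional_mutual_information_gaussian",
    "conditional_transfer_entropy",
    "conditional_transfer_entropy_gaussian",
    "conditional_transfer_entropy_gaussian_sweep",
    "modulation_index_sweep",
    "esc_sweep",
    "gaussian_copula_transform",
    "copula_columns",
    "conditioning_keys",
    "estimate_cfc",
]

logger = logging.getLogger(__name__)

#: feature pair (source, target) implied by each coupling type
COUPLING_FEATURES = {
    "PAC": ("phase", "amplitude"),
    "APC": ("amplitude", "phase"),
    "AAC": ("amplitude", "amplitude"),
    "PPC": ("phase", "phase"),
    "PFC": ("phase", "frequency"),
    "SFC-amp": ("amplitude", "amplitude"),
    "SFC-phase": ("phase", "phase"),
}

#: coupling types that require source band strictly below target band
_CROSS_BAND = {"PAC": True, "APC": False, "AAC": None, "PPC": None, "PFC": None}


@dataclass(frozen=True)
class CouplingSpec:
    """One coupling family: type, source/target (band, feature) and lag count.

    The lag unit is one sample of the decomposition, so the temporal horizon
    is ``n_lags / fs`` seconds.
    """

    type: str
    source_band: str
    target_band: str
    n_lags: int = 100

    def __post_init__(self) -> None:
        if self.type not in COUPLING_FEATURES:
            raise ValueError(f"unknown coupling type {self.type!r}")
        if self.n_lags < 1:
            raise ValueError("n_lags must be >= 1")
        if self.type.startswith("SFC") and self.source_band != self.target_band:
            raise ValueError("SFC couplings require the same band at both ends")

    @property
    def source_feature(self) -> str:
        return COUPLING_FEATURES[self.type][0]

    @property
    def target_feature(self) -> str:
        return COUPLING_FEATURES[self.type][1]

    @property
    def label(self) -> str:
        return f"{self.type}_{self.source_band}-{self.target_band}"


@dataclass(frozen=True)
class DiscretizationScheme:
    """How continuous series are turned into symbols.

    Phases are binned uniformly on [-pi, pi) (circular); amplitudes and
    frequencies by equiprobable quantile bins.  ``conditioning_bins`` (when
    set) coarsens conditioning variables to limit the joint alphabet.
    """

    n_bins: int = 8
    conditioning_bins: int | None = None

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")

    @property
    def cond_bins(self) -> int:
        return self.conditioning_bins or self.n_bins


def discretize(x: np.ndarray, n_bins: int, circular: bool) -> np.ndarray:
    """Integer codes in [0, n_bins): uniform circular bins for phases,
    quantile (equiprobable) bins otherwise."""
    x = np.asarray(x, dtype=float)
    if circular:
        codes = np.floor((x + np.pi) / (2 * np.pi) * n_bins).astype(np.int64)
        return np.clip(codes, 0, n_bins - 1)
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, x, side="right").astype(np.int64)


def _discretize_feature(x: np.ndarray, feature: str, n_bins: int) -> np.ndarray:
    return discretize(x, n_bins, circular=(feature == "phase"))


def _joint_codes(codes: list[np.ndarray]) -> np.ndarray:
    """Collapse several integer code series into one, re-compacting when the
    running alphabet would overflow int64."""
    out = codes[0].astype(np.int64)
    card = int(out.max()) + 1
    for c in codes[1:]:
        nb = int(c.max()) + 1
        if card > 2**62 // max(nb, 1):
            _, out = np.unique(out, return_inverse=True)
            card = int(out.max()) + 1
        out = out * nb + c
        card *= nb
    return out


def entropy_bits(codes: list[np.ndarray]) -> float:
    """Plug-in joint Shannon entropy (bits) of one or more discrete series."""
    joint = _joint_codes(codes)
    _, counts = np.unique(joint, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def mutual_information(x: np.ndarray, ys: list[np.ndarray]) -> float:
    """I(x; ys) = H(x) + H(ys) - H(x, ys) in bits (ys jointly)."""
    return entropy_bits([x]) + entropy_bits(ys) - entropy_bits([x] + ys)


def conditional_mutual_information(
    x: np.ndarray,
    y: np.ndarray,
    conditioning: list[np.ndarray] | None = None,
) -> float:
    """Plug-in cMI I(x; y | M) via the chain rule I(x; y, M) - I(x; M).

    Inputs are aligned discrete (integer) series; an empty conditioning set
    degrades to plain mutual information.  The plug-in estimate is
    non-negative up to floating-point roundoff.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    M = [np.asarray(c) for c in (conditioning or [])]
    if any(c.shape != x.shape for c in M):
        raise ValueError("conditioning series must match x in length")
    if not M:
        return mutual_information(x, [y])
    n_cells = np.prod([float(np.max(s)) + 1 for s in [x, y] + M])
    if n_cells > x.size:
        logger.debug(
            "cMI alphabet (%g cells) exceeds sample count (%d): undersampled",
            n_cells, x.size,
        )
    return mutual_information(x, [y] + M) - mutual_information(x, M)


def conditional_mutual_information_knn(
    x: np.ndarray,
    y: np.ndarray,
    conditioning: list[np.ndarray] | None = None,
    k: int = 4,
) -> float:
    """k-nearest-neighbour cMI estimator (bits) for continuous series.

    Frenzel-Pompe / Vejmelka-Palus form of the KSG estimator with the
    Chebyshev metric:

        I(X; Y | Z) = psi(k) - < psi(n_xz + 1) + psi(n_yz + 1) - psi(n_z + 1) >

    Useful when the conditioning set is too high-dimensional for histograms.
    """
    from scipy.spatial import cKDTree
    from scipy.special import digamma

    x = np.asarray(x, dtype=float).reshape(-1, 1)
    y = np.asarray(y, dtype=float).reshape(-1, 1)
    Z = (
        np.column_stack([np.asarray(c, dtype=float) for c in conditioning])
        if conditioning
        else np.empty((x.shape[0], 0))
    )
    xz = np.hstack([x, Z])
    yz = np.hstack([y, Z])
    xyz = np.hstack([x, y, Z])
    tree = cKDTree(xyz)
    # distance to the k-th neighbour in the full joint space
    d, _ = tree.query(xyz, k=k + 1, p=np.inf)
    eps = d[:, -1]

    def counts(pts):
        t = cKDTree(pts)
        return np.array(
            [len(t.query_ball_point(p, r=e - 1e-12, p=np.inf)) - 1
             for p, e in zip(pts, eps)]
        )

    n_xz = counts(xz)
    n_yz = counts(yz)
    if Z.shape[1]:
        n_z = counts(Z)
        val = digamma(k) - np.mean(
            digamma(n_xz + 1) + digamma(n_yz + 1) - digamma(n_z + 1)
        )
    else:
        n = x.shape[0]
        val = digamma(k) + digamma(n) - np.mean(
            digamma(n_xz + 1) + digamma(n_yz + 1)
        )
    return float(val / np.log(2))


def gaussian_copula_transform(x: np.ndarray) -> np.ndarray:
    """Normal scores: rank-transform to (0, 1) and map through the standard
    normal quantile function.  Invariant to any strictly monotone transform
    of the input, and to circular shifts up to reordering."""
    from scipy.stats import norm, rankdata

    x = np.asarray(x, dtype=float)
    return norm.ppf(rankdata(x) / (x.size + 1))


def copula_columns(x: np.ndarray, feature: str) -> np.ndarray:
    """Copula-normalized column block for one series.

    Phases are circular, so they enter as the pair (cos, sin) -- each
    copula-transformed -- which avoids the artificial discontinuity at
    +/- pi; amplitudes and frequencies are single columns.
    """
    x = np.asarray(x, dtype=float)
    if feature == "phase":
        return np.column_stack(
            [gaussian_copula_transform(np.cos(x)), gaussian_copula_transform(np.sin(x))]
        )
    return gaussian_copula_transform(x)[:, None]


def _gauss_logdet(X: np.ndarray) -> float:
    if X.shape[1] == 0:
        return 0.0
    c = np.atleast_2d(np.cov(X, rowvar=False))
    sign, ld = np.linalg.slogdet(c)
    if sign <= 0:
        raise np.linalg.LinAlgError("singular covariance in copula cMI")
    return float(ld)


def conditional_mutual_information_gaussian(
    x_cols: np.ndarray,
    y_cols: np.ndarray,
    cond_cols: np.ndarray | None = None,
) -> float:
    """Gaussian-copula cMI (bits) between column blocks (time x features).

    After the copula transform every margin is exactly standard normal, so
    the mutual information of the copula is computed in closed form from
    covariance log-determinants:

        I(X; Y | Z) = [ld(X,Z) + ld(Y,Z) - ld(Z) - ld(X,Y,Z)] / (2 ln 2)

    This captures all monotone dependence and has no histogram binning bias,
    which matters when surrogate and observed estimates must be compared on
    an equal footing.
    """
    X = np.asarray(x_cols, dtype=float)
    Y = np.asarray(y_cols, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if Y.ndim == 1:
        Y = Y[:, None]
    Z = (
        np.asarray(cond_cols, dtype=float)
        if cond_cols is not None and np.size(cond_cols)
        else np.empty((X.shape[0], 0))
    )
    xz = np.hstack([X, Z])
    yz = np.hstack([Y, Z])
    xyz = np.hstack([X, Y, Z])
    val = 0.5 * (
        _gauss_logdet(xz) + _gauss_logdet(yz) - _gauss_logdet(Z) - _gauss_logdet(xyz)
    ) / np.log(2)
    return float(val)


def conditional_transfer_entropy_gaussian(
    source: np.ndarray,
    target: np.ndarray,
    conditioning: list[tuple[np.ndarray, str]] | None = None,
    n_lags: int = 100,
    source_feature: str = "phase",
    target_feature: str = "amplitude",
    lag_step: int = 1,
) -> float:
    """Gaussian-copula cTE(source -> target) in bits on continuous series.

    Same lag structure as ``conditional_transfer_entropy`` (average of
    I(source_t; target_{t+delta} | M) over delta = lag_step, 2*lag_step, ...
    <= n_lags, all sharing the rows t = 0..T-n_lags-1).  ``conditioning`` is
    a list of (series, feature) pairs; phase features enter as circular
    cos/sin blocks.

    The source's copula scores are computed on the *full* series and then
    truncated, so the statistic commutes exactly with circular shifts of the
    source (rank transforms are permutation-equivariant); this is what makes
    the vectorized surrogate sweep below bit-identical to shifting the raw
    series.
    """
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if source.shape != target.shape:
        raise ValueError("source and target must have equal length")
    T = source.shape[0]
    if n_lags >= T:
        raise ValueError("n_lags must be smaller than the series length")
    if lag_step < 1 or lag_step > n_lags:
        raise ValueError("lag_step must lie in [1, n_lags]")
    L = T - n_lags
    src = copula_columns(source, source_feature)[:L]
    tgt_cols = copula_columns(target, target_feature)
    M = [copula_columns(np.asarray(c, dtype=float), f)[:L] for c, f in (conditioning or [])]
    Z = np.hstack(M) if M else np.empty((L, 0))
    vals = [
        conditional_mutual_information_gaussian(src, tgt_cols[d:d + L], Z)
        for d in range(lag_step, n_lags + 1, lag_step)
    ]
    return float(np.mean(vals))


def conditional_transfer_entropy_gaussian_sweep(
    source: np.ndarray,
    target: np.ndarray,
    offsets: np.ndarray,
    conditioning: list[tuple[np.ndarray, str]] | None = None,
    n_lags: int = 100,
    source_feature: str = "phase",
    target_feature: str = "amplitude",
    lag_step: int = 1,
) -> np.ndarray:
    """Gaussian-copula cTE for many circular shifts of the source at once.

    Returns one value per entry of ``offsets``; entry ``o`` equals
    ``conditional_transfer_entropy_gaussian(np.roll(source, o), target, ...)``
    up to floating-point roundoff (offset 0 is the observed statistic).

    The rank transform commutes with circular shifts, so the shifted source's
    copula scores are circular shifts of the observed scores; every
    sample cross-moment between the shifted source block and the fixed
    (target, conditioning) blocks is then a circular cross-correlation,
    evaluated for all offsets simultaneously via the FFT.  This turns the
    O(n_surrogates * T) surrogate loop into O(T log T) plus tiny per-offset
    log-determinants, which is what makes surrogate-calibrated conditional
    inference affordable at long durations.
    """
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if source.shape != target.shape:
        raise ValueError("source and target must have equal length")
    T = source.shape[0]
    if n_lags >= T:
        raise ValueError("n_lags must be smaller than the series length")
    if lag_step < 1 or lag_step > n_lags:
        raise ValueError("lag_step must lie in [1, n_lags]")
    offsets = np.asarray(offsets, dtype=int) % T
    L = T - n_lags
    lags = range(lag_step, n_lags + 1, lag_step)

    S = copula_columns(source, source_feature)  # (T, ds)
    Yf = copula_columns(target, target_feature)  # (T, dt)
    M = [copula_columns(np.asarray(c, dtype=float), f)[:L] for c, f in (conditioning or [])]
    Z = np.hstack(M) if M else np.empty((L, 0))
    ds, dt, dz = S.shape[1], Yf.shape[1], Z.shape[1]

    fft, ifft = np.fft.rfft, np.fft.irfft
    window = np.zeros(T)
    window[:L] = 1.0
    f_window = fft(window)
    f_S = fft(S, axis=0)  # (freq, ds)

    def corr_with_src(y_pad: np.ndarray) -> np.ndarray:
        """(x ⋆ S_i)[o] = sum_t x[t] S_i[(t - o) % T] for all offsets o."""
        return ifft(fft(y_pad)[:, None] * np.conj(f_S), n=T, axis=0)

    # per-offset source moments over the analysis window
    src_sums = corr_with_src(window)  # (T, ds): sum of S_i over the window
    prod_sums = np.empty((T, ds, ds))
    for i in range(ds):
        for j in range(i, ds):
            s = ifft(f_window * np.conj(fft(S[:, i] * S[:, j])), n=T)
            prod_sums[:, i, j] = prod_sums[:, j, i] = s

    # fixed block (conditioning) cross-moments, shared across lags
    z_pads = np.zeros((dz, T))
    z_pads[:, :L] = Z.T
    src_z_sums = np.stack([corr_with_src(zp) for zp in z_pads], axis=2) if dz else (
        np.empty((T, ds, 0))
    )
    z_means = Z.mean(axis=0) if dz else np.empty(0)

    ln2x2 = 2.0 * np.log(2.0)
    values = np.zeros(offsets.shape[0])
    for delta in lags:
        Yd = Yf[delta:delta + L]  # (L, dt)
        fixed = np.hstack([Yd, Z])  # (L, dt + dz)
        fixed_means = fixed.mean(axis=0)
        cov_fixed = np.atleast_2d(np.cov(fixed, rowvar=False))
        y_pads = np.zeros((dt, T))
        y_pads[:, :L] = Yd.T
        src_y_sums = np.stack([corr_with_src(yp) for yp in y_pads], axis=2)

        # offset-independent pieces
        ld_yz = _logdet_psd(cov_fixed)
        ld_z = _logdet_psd(cov_fixed[dt:, dt:]) if dz else 0.0

        for n, o in enumerate(offsets):
            m_src = src_sums[o] / L
            d = ds + dt + dz
            cov = np.empty((d, d))
            cov[ds:, ds:] = cov_fixed
            cov[:ds, :ds] = (prod_sums[o] - L * np.outer(m_src, m_src)) / (L - 1)
            cross = np.concatenate([src_y_sums[o], src_z_sums[o]], axis=1)
            cov[:ds, ds:] = (cross - L * np.outer(m_src, fixed_means)) / (L - 1)
            cov[ds:, :ds] = cov[:ds, ds:].T
            xz = np.concatenate([np.arange(ds), ds + dt + np.arange(dz)])
            ld_xz = _logdet_psd(cov[np.ix_(xz, xz)])
            ld_xyz = _logdet_psd(cov)
            values[n] += (ld_xz + ld_yz - ld_z - ld_xyz) / ln2x2
    return values / len(list(lags))


def modulation_index_sweep(
    phase: np.ndarray, amplitude: np.ndarray, offsets: np.ndarray
) -> np.ndarray:
    """Midx for many circular shifts of the phase series at once.

    Entry ``o`` equals ``modulation_index(np.roll(phase, o), amplitude)``:
    the amplitude-weighted phase-vector sum over shifts is a circular
    cross-correlation, evaluated for all offsets via one FFT.
    """
    phase = np.asarray(phase, dtype=float)
    amplitude = np.asarray(amplitude, dtype=float)
    if phase.shape != amplitude.shape:
        raise ValueError("phase and amplitude must have equal length")
    offsets = np.asarray(offsets, dtype=int) % phase.shape[0]
    # sum_t a[t] e^{i phi[(t - o) % T]} = IFFT(FFT(a) * conj(FFT(e^{i phi})))*
    f = np.fft.ifft(np.fft.fft(amplitude) * np.conj(np.fft.fft(np.exp(-1j * phase))))
    return np.abs(f[offsets])


def esc_sweep(
    phase: np.ndarray, amplitude: np.ndarray, offsets: np.ndarray
) -> np.ndarray:
    """ESC for many circular shifts of the phase series at once.

    Entry ``o`` equals ``esc(np.roll(phase, o), amplitude)``; the mean and
    variance of cos(phase) are shift-invariant, so only the cross term needs
    the FFT.
    """
    phase = np.asarray(phase, dtype=float)
    amplitude = np.asarray(amplitude, dtype=float)
    if phase.shape != amplitude.shape:
        raise ValueError("phase and amplitude must have equal length")
    T = phase.shape[0]
    offsets = np.asarray(offsets, dtype=int) % T
    c = np.cos(phase)
    if c.std() == 0 or amplitude.std() == 0:
        raise ValueError("zero-variance input")
    cross = np.fft.irfft(
        np.fft.rfft(amplitude) * np.conj(np.fft.rfft(c)), n=T
    )
    cov = cross / T - c.mean() * amplitude.mean()
    return cov[offsets] / (c.std() * amplitude.std())


def _logdet_psd(c: np.ndarray) -> float:
    if c.size == 0:
        return 0.0
    sign, ld = np.linalg.slogdet(np.atleast_2d(c))
    if sign <= 0:
        raise np.linalg.LinAlgError("singular covariance in copula cMI")
    return float(ld)


def conditional_transfer_entropy(
    source: np.ndarray,
    target: np.ndarray,
    conditioning: list[np.ndarray] | None = None,
    n_lags: int = 100,
) -> float:
    """cTE(source -> target) in bits on discrete series.

    The average over delta = 1..n_lags of I(source_t; target_{t+delta} | M),
    where M is the caller-supplied conditioning set (typically including the
    target's own present series).  All terms share the sample rows
    t = 0..T-n_lags-1 so estimates at different lags are comparable.
    """
    source = np.asarray(source)
    target = np.asarray(target)
    if source.shape != target.shape:
        raise ValueError("source and target must have equal length")
    T = source.shape[0]
    if n_lags >= T:
        raise ValueError("n_lags must be smaller than the series length")
    L = T - n_lags
    M = [np.asarray(c)[:L] for c in (conditioning or [])]
    src = source[:L]
    total = 0.0
    for delta in range(1, n_lags + 1):
        total += conditional_mutual_information(src, target[delta:delta + L], M)
    return total / n_lags


def modulation_index(
    phase: np.ndarray, amplitude: np.ndarray, normalized: bool = False
) -> float:
    """Midx = |sum_t a(t) exp(i phi(t))|; the normalized variant divides by T."""
    phase = np.asarray(phase, dtype=float)
    amplitude = np.asarray(amplitude, dtype=float)
    if phase.shape != amplitude.shape:
        raise ValueError("phase and amplitude must have equal length")
    m = np.abs(np.sum(amplitude * np.exp(1j * phase)))
    return float(m / phase.size) if normalized else float(m)


def esc(phase: np.ndarray, amplitude: np.ndarray) -> float:
    """Envelope-to-signal correlation: corr(cos(phase), amplitude) in [-1, 1]."""
    phase = np.asarray(phase, dtype=float)
    amplitude = np.asarray(amplitude, dtype=float)
    if phase.shape != amplitude.shape:
        raise ValueError("phase and amplitude must have equal length")
    c = np.cos(phase)
    if c.std() == 0 or amplitude.std() == 0:
        raise ValueError("zero-variance input")
    return float(np.corrcoef(c, amplitude)[0, 1])


@dataclass
class CFCResult:
    """Directed coupling matrix for one (type, band pair) combination.

    ``values[k, l]`` is the coupling from source population k to target
    population l in bits; z-scores, p-values and the FDR mask are attached by
    the surrogate-significance step.  Negative plug-in estimates are clipped
    to zero; ``n_clipped`` counts them.
    """

    values: np.ndarray
    coupling: CouplingSpec
    names: list[str]
    zscores: np.ndarray | None = None
    pvalues: np.ndarray | None = None
    mask: np.ndarray | None = None
    n_clipped: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def masked_values(self) -> np.ndarray:
        if self.mask is None:
            return self.values
        return self.values * self.mask

    def to_csv(self, directory: str | Path) -> Path:
        """Write ``{type}_{srcband}-{tgtband}.csv`` plus a JSON sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        base = directory / f"{self.coupling.label}.csv"
        pd.DataFrame(self.values, index=self.names, columns=self.names).to_csv(base)
        sidecar = {
            "coupling": {
                "type": self.coupling.type,
                "source_band": self.coupling.source_band,
                "target_band": self.coupling.target_band,
                "n_lags": self.coupling.n_lags,
            },
            "n_clipped": self.n_clipped,
            "meta": self.meta,
        }
        for name in ("zscores", "pvalues", "mask"):
            arr = getattr(self, name)
            if arr is not None:
                sidecar[name] = np.asarray(arr, dtype=float).tolist()
        base.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
        return base


def _band_low(decomp: AnalyticDecomposition, band: str) -> float:
    return decomp.bands[decomp.band_index(band)].low


def conditioning_keys(
    spec: CouplingSpec,
    source_pop: int,
    target_pop: int,
    policy,
    n_pops: int,
    available: list[tuple] | None = None,
) -> list[tuple]:
    """(band, population, feature) keys of the conditioning set M for one pair.

    Policies: 'none'; 'target_past' (the target's own present series,
    default); 'exclude_source' (target past plus the source-band source
    feature and target-band target feature of every other population); 'all'
    (every available series except the source and the target themselves --
    warned, histogram estimates are undersampled at this dimension); or an
    explicit list of (band, population, feature) tuples, always prefixed by
    the target's own series.
    """
    tgt_key = (spec.target_band, target_pop, spec.target_feature)
    if policy == "none":
        return []
    if policy == "target_past":
        return [tgt_key]
    if policy == "exclude_source":
        cond = [tgt_key]
        for j in range(n_pops):
            if j in (source_pop, target_pop):
                continue
            cond.append((spec.source_band, j, spec.source_feature))
            cond.append((spec.target_band, j, spec.target_feature))
        return cond
    if policy == "all":
        logger.warning(
            "conditioning on all series: histogram estimates will be "
            "undersampled at this dimension"
        )
        cond = [tgt_key]
        src_key = (spec.source_band, source_pop, spec.source_feature)
        for key in available or []:
            if key in (src_key, tgt_key):
                continue
            cond.append(key)
        return cond
    # explicit list of (band, population, feature)
    return [tgt_key] + [tuple(item) for item in policy]


def build_conditioning(
    decomp_codes: dict,
    spec: CouplingSpec,
    source_pop: int,
    target_pop: int,
    target_codes: np.ndarray,
    policy,
    n_pops: int,
) -> list[np.ndarray]:
    """Discrete conditioning series for one pair (see ``conditioning_keys``)."""
    keys = conditioning_keys(
        spec, source_pop, target_pop, policy, n_pops,
        available=list(decomp_codes),
    )
    tgt_key = (spec.target_band, target_pop, spec.target_feature)
    return [
        target_codes if key == tgt_key else decomp_codes[key] for key in keys
    ]


def estimate_cfc(
    decomp: AnalyticDecomposition,
    spec: CouplingSpec,
    scheme: DiscretizationScheme = DiscretizationScheme(),
    conditioning_policy="target_past",
    surrogate_config=None,
    alpha: float = 0.05,
    estimator: str = "histogram",
    lag_step: int = 1,
) -> CFCResult:
    """Directed coupling matrix over all population pairs.

    ``estimator`` selects the cTE backend: 'histogram' (plug-in on
    discretized series) or 'gaussian' (Gaussian-copula closed form on the
    continuous series; unbiased in the sense that circular-shift surrogates
    share its rank transform, so observed and null estimates are directly
    comparable).  ``lag_step`` thins the lag average (gaussian backend only).

    When ``surrogate_config`` is given, circular-shift surrogates of the
    source series are used to attach z-scores, Gaussian p-values and a
    Benjamini-Hochberg FDR mask across the full matrix.
    """
    if estimator not in ("histogram", "gaussian"):
        raise ValueError(f"unknown estimator {estimator!r}")
    if spec.source_band not in decomp.band_names or spec.target_band not in decomp.band_names:
        raise ValueError("decomposition does not cover the requested bands")
    cross = _CROSS_BAND.get(spec.type)
    if cross is True and not _band_low(decomp, spec.source_band) < _band_low(decomp, spec.target_band):
        raise ValueError("PAC requires the source band below the target band")
    if cross is False and not _band_low(decomp, spec.source_band) > _band_low(decomp, spec.target_band):
        raise ValueError("APC requires the source band above the target band")

    n_pops = len(decomp.names)
    # collect every series this estimate may touch
    needed_feats = {spec.source_feature, spec.target_feature}
    raw: dict = {}
    for band in {spec.source_band, spec.target_band}:
        for j in range(n_pops):
            for feat in needed_feats:
                raw[(band, j, feat)] = decomp.get(band, j, feat)
    if estimator == "histogram":
        codes = {
            key: _discretize_feature(series, key[2], scheme.n_bins)
            for key, series in raw.items()
        }
    else:
        codes = raw

    values = np.zeros((n_pops, n_pops))
    n_clipped = 0
    surrogate_draws = np.zeros((n_pops, n_pops), dtype=object) if surrogate_config else None
    logger.info(
        "estimating %s over %d^2 pairs (backend=%s, bins=%d, lags=%d, policy=%s)",
        spec.label, n_pops, estimator, scheme.n_bins, spec.n_lags, conditioning_policy,
    )
    for k in range(n_pops):
        src = codes[(spec.source_band, k, spec.source_feature)]
        for l in range(n_pops):
            tgt = codes[(spec.target_band, l, spec.target_feature)]
            keys = conditioning_keys(
                spec, k, l, conditioning_policy, n_pops, available=list(codes)
            )
            cond_series = [codes[key] for key in keys]
            if estimator == "histogram":
                def est(s, t, M=cond_series, n=spec.n_lags):
                    return conditional_transfer_entropy(s, t, M, n)

                val = est(src, tgt)
                if surrogate_config is not None:
                    from .surrogates import surrogate_null

                    surrogate_draws[k, l] = surrogate_null(
                        est, src, tgt,
                        config=surrogate_config,
                        pair_index=k * n_pops + l,
                    )
            else:
                cond_pairs = [
                    (series, key[2]) for series, key in zip(cond_series, keys)
                ]
                if surrogate_config is not None:
                    from .surrogates import surrogate_offsets

                    offsets = np.concatenate([
                        [0],
                        surrogate_offsets(
                            src.shape[0], surrogate_config,
                            pair_index=k * n_pops + l,
                        ),
                    ])
                    vals = conditional_transfer_entropy_gaussian_sweep(
                        src, tgt, offsets, cond_pairs, spec.n_lags,
                        source_feature=spec.source_feature,
                        target_feature=spec.target_feature,
                        lag_step=lag_step,
                    )
                    val = float(vals[0])
                    surrogate_draws[k, l] = vals[1:]
                else:
                    val = conditional_transfer_entropy_gaussian(
                        src, tgt, cond_pairs, spec.n_lags,
                        source_feature=spec.source_feature,
                        target_feature=spec.target_feature,
                        lag_step=lag_step,
                    )
            if val < 0:
                n_clipped += 1
                val = 0.0
            values[k, l] = val

    result = CFCResult(
        values=values,
        coupling=spec,
        names=list(decomp.names),
        n_clipped=n_clipped,
        meta={
            "estimator": estimator,
            "n_bins": scheme.n_bins,
            "policy": str(conditioning_policy),
            "fs": decomp.fs,
            "lag_step": lag_step,
        },
    )
    if n_clipped:
        logger.info("%s: clipped %d negative plug-in estimates to 0", spec.label, n_clipped)
    if surrogate_config is not None:
        from .surrogates import attach_significance

        attach_significance(result, surrogate_draws, alpha=alpha)
    return result
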