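"""Fixed-step integration of the stochastic column model.

The model is a random differential equation: external inputs are
p_m(t) = p_mean + p_sigma * xi_k / sqrt(dt), with xi_k a standard-normal
draw held constant within each integration step -- band-limited white noise
of spectral density p_sigma^2 rather than an Ito diffusion, so trajectories
have a dt-independent noise response.  The default scheme is local linearization (LL): at
each step the drift is linearized at the current state and the resulting
affine system is propagated exactly through a matrix exponential, which makes
the scheme exact on linear systems and improves stability on the stiff,
oscillatory column dynamics.  A conventional Euler scheme sharing the same
noise stream is provided as an independent cross-check.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .model import ColumnModel, ModelState

try:  # optional compiled fast path; the pure-numpy loop is the reference
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is part of the standard stack
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def deco(f):
            return f

        return deco

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "SimulationDiverged",
    "simulate",
    "step_local_linearization",
]

logger = logging.getLogger(__name__)


class SimulationDiverged(RuntimeError):
    """Raised when a trajectory exceeds the configured amplitude bound."""


@dataclass(frozen=True)
class SimulationConfig:
    """Integration settings.

    dt: step (s); duration: total simulated time (s); burn_in: initial span
    discarded to remove transients (s); method: 'local_linearization' or
    'euler_maruyama'; divergence_bound: abort when any |x| exceeds it (mV).
    """

    dt: float = 1e-4
    duration: float = 12.0
    burn_in: float = 2.0
    seed: int = 0
    method: str = "local_linearization"
    divergence_bound: float = 1e6

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if not (0 <= self.burn_in < self.duration):
            raise ValueError("burn_in must lie in [0, duration)")
        if self.method not in ("local_linearization", "euler_maruyama"):
            raise ValueError(f"unknown method {self.method!r}")


@dataclass
class SimulationResult:
    """Post-burn-in trajectory: t (s) and x (time x population, mV)."""

    t: np.ndarray
    x: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.x)):
            raise ValueError("trajectory contains non-finite values")

    # -- round-trip I/O --------------------------------------------------------
    def to_csv(self, path: str | Path, names: list[str] | None = None) -> None:
        names = names or [f"x{i}" for i in range(self.x.shape[1])]
        frame = pd.DataFrame(self.x, columns=names)
        frame.insert(0, "t", self.t)
        frame.to_csv(path, index=False, float_format="%.17g")

    @staticmethod
    def from_csv(path: str | Path) -> "SimulationResult":
        frame = pd.read_csv(path)
        return SimulationResult(
            t=frame["t"].to_numpy(),
            x=frame.drop(columns="t").to_numpy(),
            meta={"names": [c for c in frame.columns if c != "t"]},
        )

    def to_hdf5(self, path: str | Path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("t", data=self.t)
            f.create_dataset("x", data=self.x)
            for key, val in self.meta.items():
                try:
                    f.attrs[key] = val
                except TypeError:
                    f.attrs[key] = json.dumps(val)

    @staticmethod
    def from_hdf5(path: str | Path) -> "SimulationResult":
        import h5py

        with h5py.File(path, "r") as f:
            return SimulationResult(
                t=f["t"][:], x=f["x"][:], meta=dict(f.attrs)
            )


def _model_hash(model: ColumnModel) -> str:
    payload = json.dumps(model.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _drift_factory(model: ColumnModel):
    """Vectorized drift and Jacobian closures for the 2n-dimensional system."""
    n = model.n
    g = model.vector("g")
    G = model.vector("G")
    b = model.vector("b")
    e0 = np.array([p.sigmoid.e0 for p in model.populations])
    v0 = np.array([p.sigmoid.v0 for p in model.populations])
    r = np.array([p.sigmoid.r for p in model.populations])
    gamma_T = model.gamma.T.copy()
    g2 = g**2
    two_gb = 2.0 * g * b
    Gg = G * g
    linear = model.linear

    def rates(x):
        if linear:
            return x
        return e0 / (1.0 + np.exp(np.clip(r * (v0 - x), -700.0, 700.0)))

    def rates_deriv(x):
        if linear:
            return np.ones_like(x)
        s = rates(x)
        return r * s * (e0 - s) / e0

    def drift(z, p):
        x, y = z[:n], z[n:]
        dy = -two_gb * y - g2 * x + Gg * (p + gamma_T @ rates(x))
        return np.concatenate([y, dy])

    def jacobian(z):
        x = z[:n]
        J = np.zeros((2 * n, 2 * n))
        J[:n, n:] = np.eye(n)
        J[n:, :n] = Gg[:, None] * gamma_T * rates_deriv(x)[None, :]
        J[n:, :n] -= np.diag(g2)
        J[n:, n:] = -np.diag(two_gb)
        return J

    return drift, jacobian


def step_local_linearization(
    state: ModelState,
    model: ColumnModel,
    dt: float,
    noise_draw: np.ndarray | None = None,
) -> ModelState:
    """Advance one step with the local linearization scheme.

    ``noise_draw`` is the standard-normal vector multiplying p_sigma for this
    step (zeros when omitted).  Falls back to an Euler step with a warning if
    the matrix exponential of the linearization cannot be evaluated.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    drift, jacobian = _drift_factory(model)
    p = model.vector("p_mean")
    if noise_draw is not None:
        p = p + model.vector("p_sigma") * np.asarray(noise_draw, dtype=float)
    z = np.concatenate([state.x, state.y])
    z1 = _ll_advance(z, p, dt, drift, jacobian)
    n = model.n
    return ModelState(x=z1[:n], y=z1[n:])


def _ll_advance(z, p, dt, drift, jacobian):
    f0 = drift(z, p)
    J = jacobian(z)
    d = z.size
    aug = np.zeros((d + 1, d + 1))
    aug[:d, :d] = J
    aug[:d, d] = f0
    try:
        E = expm(aug * dt)
        if not np.all(np.isfinite(E)):
            raise FloatingPointError("non-finite matrix exponential")
    except (FloatingPointError, ValueError) as err:  # pragma: no cover - rare
        logger.warning("local linearization step failed (%s); Euler fallback", err)
        return z + dt * f0
    return z + E[:d, d]


# Pade-13 coefficients for the scaling-and-squaring matrix exponential
_PADE13 = np.array([
    64764752532480000.0, 32382376266240000.0, 7771770303897600.0,
    1187353796428800.0, 129060195264000.0, 10559470521600.0, 670442572800.0,
    33522128640.0, 1323241920.0, 40840800.0, 960960.0, 16380.0, 182.0, 1.0,
])
_PADE13_THETA = 5.371920351148152


@_njit(cache=True)
def _expm_pade13(A):
    """expm(A) by scaling-and-squaring with a degree-13 Pade approximant."""
    A = np.ascontiguousarray(A)
    d = A.shape[0]
    nrm = 0.0
    for j in range(d):
        col = 0.0
        for i in range(d):
            col += abs(A[i, j])
        if col > nrm:
            nrm = col
    s = 0
    if nrm > _PADE13_THETA:
        s = int(np.ceil(np.log2(nrm / _PADE13_THETA)))
    As = A / (2.0 ** s)
    I = np.eye(d)
    A2 = As @ As
    A4 = A2 @ A2
    A6 = A4 @ A2
    b = _PADE13
    U = As @ (
        A6 @ (b[13] * A6 + b[11] * A4 + b[9] * A2)
        + b[7] * A6 + b[5] * A4 + b[3] * A2 + b[1] * I
    )
    V = (
        A6 @ (b[12] * A6 + b[10] * A4 + b[8] * A2)
        + b[6] * A6 + b[4] * A4 + b[2] * A2 + b[0] * I
    )
    R = np.linalg.solve(V - U, V + U)
    for _ in range(s):
        R = R @ R
    return R


@_njit(cache=True)
def _simulate_loop(
    z, p_mean, p_sigma, noisy_idx, noise, gammaT, Gg, g2, two_gb,
    e0, v0, r, linear, use_ll, dt, n_steps, n_burn, bound, out,
):
    """Fixed-step integration loop (LL or Euler).  Returns the step index of
    divergence, or -1 on success.  Mathematically identical to the pure-numpy
    reference loop below (same drift, same LL augmented-exponential step,
    same noise stream)."""
    n = p_mean.size
    d = 2 * n
    M = np.zeros((d + 1, d + 1))
    s_vec = np.empty(n)
    sd_vec = np.empty(n)
    p = np.empty(n)
    f0 = np.empty(d)
    for k in range(n_steps):
        for i in range(n):
            p[i] = p_mean[i]
        for j in range(noisy_idx.size):
            i = noisy_idx[j]
            p[i] += p_sigma[i] * noise[k, j]
        # rate function and its derivative at the current state
        for i in range(n):
            if linear:
                s_vec[i] = z[i]
                sd_vec[i] = 1.0
            else:
                e = r[i] * (v0[i] - z[i])
                if e > 700.0:
                    e = 700.0
                elif e < -700.0:
                    e = -700.0
                si = e0[i] / (1.0 + np.exp(e))
                s_vec[i] = si
                sd_vec[i] = r[i] * si * (e0[i] - si) / e0[i]
        gs = gammaT @ s_vec
        for i in range(n):
            f0[i] = z[n + i]
            f0[n + i] = (
                -two_gb[i] * z[n + i] - g2[i] * z[i] + Gg[i] * (p[i] + gs[i])
            )
        if use_ll:
            # augmented system [J f0; 0 0]: z <- z + expm(M)[0:d, d]
            for i in range(n):
                M[i, n + i] = dt
                M[n + i, n + i] = -two_gb[i] * dt
                for j in range(n):
                    M[n + i, j] = Gg[i] * gammaT[i, j] * sd_vec[j] * dt
                M[n + i, i] -= g2[i] * dt
            for i in range(d):
                M[i, d] = f0[i] * dt
            E = _expm_pade13(M)
            for i in range(d):
                z[i] += E[i, d]
        else:
            for i in range(d):
                z[i] += dt * f0[i]
        for i in range(n):
            if abs(z[i]) > bound:
                return k
        if k >= n_burn:
            for i in range(n):
                out[k - n_burn, i] = z[i]
    return -1


def simulate(model: ColumnModel, config: SimulationConfig) -> SimulationResult:
    """Integrate the column model and return the post-burn-in PSP trajectory.

    Deterministic given (model, config.seed).  The same noise stream is used
    by both integration methods, so they can be compared pathwise.
    """
    n = model.n
    dt = config.dt
    n_steps = int(round(config.duration / dt))
    n_burn = int(round(config.burn_in / dt))
    rng = np.random.default_rng(config.seed)

    drift, jacobian = _drift_factory(model)
    p_mean = model.vector("p_mean")
    p_sigma = model.vector("p_sigma") / np.sqrt(dt)  # white-noise scaling
    noisy = p_sigma > 0
    # one standard-normal row per step for the noisy populations; drawing the
    # block at once equals drawing per step from the same generator
    noise = rng.standard_normal((n_steps, int(noisy.sum())))

    z = np.concatenate([model.fixed_point_uncoupled(), np.zeros(n)])
    out = np.empty((n_steps - n_burn, n))
    use_ll = config.method == "local_linearization"

    if _HAVE_NUMBA:
        diverged = _simulate_loop(
            z, p_mean, p_sigma, np.flatnonzero(noisy), noise,
            model.gamma.T.copy(), model.vector("G") * model.vector("g"),
            model.vector("g") ** 2,
            2.0 * model.vector("g") * model.vector("b"),
            np.array([p.sigmoid.e0 for p in model.populations]),
            np.array([p.sigmoid.v0 for p in model.populations]),
            np.array([p.sigmoid.r for p in model.populations]),
            model.linear, use_ll, dt, n_steps, n_burn,
            float(config.divergence_bound), out,
        )
        if diverged >= 0:
            raise SimulationDiverged(
                f"|x| exceeded {config.divergence_bound} mV at "
                f"t={diverged * dt:.4f} s"
            )
    else:
        for k in range(n_steps):
            p = p_mean
            if noisy.any():
                p = p_mean.copy()
                p[noisy] += p_sigma[noisy] * noise[k]
            if use_ll:
                z = _ll_advance(z, p, dt, drift, jacobian)
            else:
                z = z + dt * drift(z, p)
            if np.max(np.abs(z[:n])) > config.divergence_bound:
                raise SimulationDiverged(
                    f"|x| exceeded {config.divergence_bound} mV at t={k * dt:.4f} s"
                )
            if k >= n_burn:
                out[k - n_burn] = z[:n]

    if not np.all(np.isfinite(out)):
        raise SimulationDiverged("trajectory contains non-finite values")
    t = config.burn_in + dt * np.arange(out.shape[0])
    meta = {
        "dt": dt,
        "duration": config.duration,
        "burn_in": config.burn_in,
        "seed": config.seed,
        "method": config.method,
        "model_hash": _model_hash(model),
        "names": model.names,
    }
    return SimulationResult(t=t, x=out, meta=meta)
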