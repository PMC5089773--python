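"""Laminar cortical-column neural mass model.

The column comprises 14 neuronal populations distributed over four layers
(L2/3, L4, L5, L6) and four cell classes: regular-spiking (RS) and
intrinsically-bursting (IB) excitatory cells, and low-threshold-spiking (LTS)
and fast-spiking (FS) inhibitory cells.  Each population m is a damped
second-order system driven through a sigmoidal rate function:

    dx_m/dt = y_m
    dy_m/dt = -2 g_m b_m y_m - g_m^2 x_m + G_m g_m (p_m + sum_n Gamma[n, m] S(x_n))

where x_m is the population's average postsynaptic potential (mV), g_m the
reciprocal synaptic time constant (1/s), b_m a dimensionless damping factor
(b_m < 1 lets an isolated population oscillate at g_m*sqrt(1-b_m^2)/(2*pi)
Hz), G_m the synaptic gain (mV) and Gamma a signed effective connectivity
matrix indexed [source, target].  p_m is an external firing-rate input.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SigmoidParams",
    "PopulationSpec",
    "ColumnModel",
    "ModelState",
    "sigmoid",
    "sigmoid_derivative",
    "impulse_response",
    "rhs",
    "natural_frequency",
    "default_column_model",
    "three_population_chain",
    "load_model",
    "POPULATION_ORDER",
]

#: Canonical population order (layer 2/3 is labelled L2).
POPULATION_ORDER = (
    "L2RS", "L2IB", "L2LTS", "L2FS",
    "L4RS", "L4LTS", "L4FS",
    "L5RS", "L5IB", "L5LTS", "L5FS",
    "L6RS", "L6LTS", "L6FS",
)

_EXCITATORY_CLASSES = frozenset({"RS", "IB"})
_INHIBITORY_CLASSES = frozenset({"LTS", "FS"})
_LAYERS = ("L2/3", "L4", "L5", "L6")


@dataclass(frozen=True)
class SigmoidParams:
    """Parameters of the PSP-to-rate sigmoid S(x) = e0 / (1 + exp(r (v0 - x))).

    e0 : maximal firing rate (1/s); v0 : PSP at half-maximal rate (mV);
    r : steepness (1/mV).
    """

    e0: float = 2.5
    v0: float = 6.0
    r: float = 0.56

    def __post_init__(self) -> None:
        if not (self.e0 > 0):
            raise ValueError("e0 must be positive")
        if not (self.r > 0):
            raise ValueError("r must be positive")


def sigmoid(x, params: SigmoidParams = SigmoidParams()):
    """Average firing rate (1/s) as a function of the PSP x (mV).

    Saturates at ``params.e0`` for large x and vanishes for very negative x;
    equals e0/2 at x = v0.
    """
    z = params.r * (params.v0 - np.asarray(x, dtype=float))
    # guard against overflow for strongly hyperpolarized inputs
    return params.e0 / (1.0 + np.exp(np.clip(z, -700.0, 700.0)))


def sigmoid_derivative(x, params: SigmoidParams = SigmoidParams()):
    """dS/dx, used by the local-linearization integrator."""
    s = sigmoid(x, params)
    return params.r * s * (params.e0 - s) / params.e0


def impulse_response(t, G: float, g: float):
    """Synaptic impulse response h(t) = G g t exp(-g t) for t >= 0 (mV/s scale).

    Peaks at t = 1/g with value G/e and integrates to G/g.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("impulse_response is defined for t >= 0")
    return G * g * t * np.exp(-g * t)


@dataclass(frozen=True)
class PopulationSpec:
    """Physiological parameters of one neuronal population."""

    name: str
    layer: str
    cell_class: str
    G: float  # synaptic gain, mV
    g: float  # reciprocal time constant, 1/s
    b: float  # damping, dimensionless
    p_mean: float = 0.0  # external input mean, 1/s
    p_sigma: float = 0.0  # external input noise SD, 1/s
    sigmoid: SigmoidParams = field(default_factory=SigmoidParams)

    def __post_init__(self) -> None:
        if self.layer not in _LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}")
        if self.cell_class not in _EXCITATORY_CLASSES | _INHIBITORY_CLASSES:
            raise ValueError(f"unknown cell class {self.cell_class!r}")
        if not (self.G > 0 and self.g > 0):
            raise ValueError("G and g must be positive")
        if self.b < 0:
            raise ValueError("damping b must be non-negative")
        if self.p_sigma < 0:
            raise ValueError("p_sigma must be non-negative")

    @property
    def excitatory(self) -> bool:
        return self.cell_class in _EXCITATORY_CLASSES


def natural_frequency(pop: PopulationSpec) -> float | None:
    """Ringing frequency (Hz) of the isolated, linearized population.

    ``g*sqrt(1-b^2)/(2*pi)`` for underdamped populations (b < 1); ``None``
    for critically damped or overdamped populations, which relax to a fixed
    point without oscillating.
    """
    if pop.b >= 1.0:
        return None
    return pop.g * math.sqrt(1.0 - pop.b**2) / (2.0 * math.pi)


@dataclass
class ModelState:
    """PSPs x (mV) and their time derivatives y (mV/s)."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-d arrays of equal length")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("state contains non-finite entries")


@dataclass
class ColumnModel:
    """Ordered populations plus the signed effective connectivity Gamma.

    ``gamma[n, m]`` is the weight of the connection from source population n
    to target population m.  Inhibitory sources must have non-positive
    outgoing weights and excitatory sources non-negative ones.  Setting
    ``linear=True`` replaces the sigmoid by the identity S(x) = x, which
    makes the whole system linear (used as a control: a linear system cannot
    create cross-frequency coupling).
    """

    populations: list[PopulationSpec]
    gamma: np.ndarray
    linear: bool = False

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        n = len(self.populations)
        if self.gamma.shape != (n, n):
            raise ValueError(
                f"gamma must be {n}x{n}, got {self.gamma.shape}"
            )
        for i, pop in enumerate(self.populations):
            row = self.gamma[i]
            if pop.excitatory and np.any(row < 0):
                raise ValueError(
                    f"excitatory source {pop.name} has negative outgoing weight"
                )
            if not pop.excitatory and np.any(row > 0):
                raise ValueError(
                    f"inhibitory source {pop.name} has positive outgoing weight"
                )

    # -- convenience accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.populations)

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.populations]

    @property
    def layers(self) -> list[str]:
        return [p.layer for p in self.populations]

    def vector(self, attr: str) -> np.ndarray:
        return np.array([getattr(p, attr) for p in self.populations], dtype=float)

    def firing_rate(self, x: np.ndarray) -> np.ndarray:
        """S(x) per population (identity when the model is linearized)."""
        x = np.asarray(x, dtype=float)
        if self.linear:
            return x.copy()
        return np.array(
            [sigmoid(xi, p.sigmoid) for xi, p in zip(x, self.populations)]
        )

    def firing_rate_derivative(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.linear:
            return np.ones_like(x)
        return np.array(
            [sigmoid_derivative(xi, p.sigmoid) for xi, p in zip(x, self.populations)]
        )

    def fixed_point_uncoupled(self) -> np.ndarray:
        """x* = G p_mean / g of the noise-free system with Gamma = 0."""
        return self.vector("G") * self.vector("p_mean") / self.vector("g")

    def drift_jacobian(self, x: np.ndarray) -> np.ndarray:
        """Jacobian of the deterministic drift at PSP vector x (2n x 2n)."""
        n = self.n
        g = self.vector("g")
        G = self.vector("G")
        b = self.vector("b")
        J = np.zeros((2 * n, 2 * n))
        J[:n, n:] = np.eye(n)
        # d(dy)/dx: -g^2 I + diag(G g) @ Gamma^T @ diag(S'(x))
        J[n:, :n] = (G * g)[:, None] * self.gamma.T * self.firing_rate_derivative(x)[None, :]
        J[n:, :n] -= np.diag(g**2)
        J[n:, n:] = -np.diag(2.0 * g * b)
        return J

    # -- serialization ---------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "populations": [
                {
                    "name": p.name,
                    "layer": p.layer,
                    "cell_class": p.cell_class,
                    "G": p.G,
                    "g": p.g,
                    "b": p.b,
                    "p_mean": p.p_mean,
                    "p_sigma": p.p_sigma,
                    "sigmoid": {"e0": p.sigmoid.e0, "v0": p.sigmoid.v0, "r": p.sigmoid.r},
                }
                for p in self.populations
            ],
            "gamma": self.gamma.tolist(),
            "linear": self.linear,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    def gamma_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.gamma, index=self.names, columns=self.names)

    def save_gamma_csv(self, path: str | Path) -> None:
        self.gamma_frame().to_csv(path)

    @classmethod
    def from_dict(cls, d: dict) -> "ColumnModel":
        pops = [
            PopulationSpec(
                name=p["name"],
                layer=p["layer"],
                cell_class=p["cell_class"],
                G=p["G"],
                g=p["g"],
                b=p["b"],
                p_mean=p.get("p_mean", 0.0),
                p_sigma=p.get("p_sigma", 0.0),
                sigmoid=SigmoidParams(**p.get("sigmoid", {})),
            )
            for p in d["populations"]
        ]
        return cls(pops, np.asarray(d["gamma"], dtype=float), linear=d.get("linear", False))

    def with_gamma_csv(self, path: str | Path) -> "ColumnModel":
        """Return a copy whose Gamma is read from a labelled CSV matrix."""
        frame = pd.read_csv(path, index_col=0)
        frame = frame.loc[self.names, self.names]
        return replace(self, gamma=frame.to_numpy(dtype=float))


def load_model(path: str | Path) -> ColumnModel:
    """Load a model definition from a JSON (or YAML) file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in {".yaml", ".yml"}:
        import yaml

        d = yaml.safe_load(text)
    else:
        d = json.loads(text)
    return ColumnModel.from_dict(d)


def rhs(state: ModelState, model: ColumnModel, p: np.ndarray) -> ModelState:
    """Time derivative of the model state given instantaneous inputs p (1/s)."""
    p = np.asarray(p, dtype=float)
    if p.shape != state.x.shape or state.x.shape[0] != model.n:
        raise ValueError("dimension mismatch between state, model and input")
    g = model.vector("g")
    G = model.vector("G")
    b = model.vector("b")
    drive = model.firing_rate(state.x) @ model.gamma  # sum_n Gamma[n, m] S(x_n)
    dy = -2.0 * g * b * state.y - g**2 * state.x + G * g * (p + drive)
    return ModelState(x=state.y.copy(), y=dy)


# ---------------------------------------------------------------------------
# Shipped default models: canonical defaults chosen so each population class
# rings in its physiological band.  Natural frequencies follow canonical
# uncoupled spectral peaks for the laminar cell classes, gains and sigmoid
# constants follow standard Jansen-Rit values, and Gamma is a laminar motif
# with the conventional sign structure (including the L4FS->L4FS
# self-connection).
# ---------------------------------------------------------------------------

#: Canonical uncoupled spectral peaks (Hz) used to place each population's
#: natural frequency.
NATURAL_FREQUENCIES = {
    "L2RS": 8.25, "L2IB": 10.48, "L2LTS": 5.40, "L2FS": 55.87,
    "L4RS": 8.25, "L4LTS": 5.40, "L4FS": 46.35,
    "L5RS": 7.30, "L5IB": 9.52, "L5LTS": 5.40, "L5FS": 46.35,
    "L6RS": 6.98, "L6LTS": 5.40, "L6FS": 44.76,
}

_DEFAULT_B = 0.1
_GAIN_E = 3.25  # mV, excitatory synaptic gain
_GAIN_I = 22.0  # mV, inhibitory synaptic gain


def _g_for_frequency(f_hz: float, b: float = _DEFAULT_B) -> float:
    return 2.0 * math.pi * f_hz / math.sqrt(1.0 - b * b)


def _layer_of(name: str) -> str:
    return {"L2": "L2/3", "L4": "L4", "L5": "L5", "L6": "L6"}[name[:2]]


def _class_of(name: str) -> str:
    return name[2:]


def default_column_model(
    p_mean_l4: float = 200.0,
    p_sigma_l4: float = 2.0,
    b: float = _DEFAULT_B,
) -> ColumnModel:
    """Canonical 14-population column with literature-standard defaults.

    External input enters only the layer-4 RS and FS populations (mean
    ``p_mean_l4`` 1/s, noise SD ``p_sigma_l4`` 1/s).
    """
    pops = []
    for name in POPULATION_ORDER:
        cls = _class_of(name)
        drive = name in ("L4RS", "L4FS")
        pops.append(
            PopulationSpec(
                name=name,
                layer=_layer_of(name),
                cell_class=cls,
                G=_GAIN_E if cls in _EXCITATORY_CLASSES else _GAIN_I,
                g=_g_for_frequency(NATURAL_FREQUENCIES[name], b),
                b=b,
                p_mean=p_mean_l4 if drive else 0.0,
                p_sigma=p_sigma_l4 if drive else 0.0,
            )
        )
    gamma = _default_gamma()
    return ColumnModel(pops, gamma)


def _default_gamma() -> np.ndarray:
    """Invented laminar connectivity motif (rows = source, cols = target).

    Within each layer: E->E, E->I excitation and I->E, I->I inhibition;
    across layers a canonical feedforward loop L4 -> L2/3 -> L5 -> L6 with an
    L6 -> L4 feedback, carried by RS/IB cells.  Inhibitory weights are
    negative; the only self-connection is L4FS->L4FS.
    """
    idx = {name: i for i, name in enumerate(POPULATION_ORDER)}
    G = np.zeros((14, 14))

    def put(src: str, dst: str, w: float) -> None:
        G[idx[src], idx[dst]] = w

    layers = {
        "L2": ["L2RS", "L2IB", "L2LTS", "L2FS"],
        "L4": ["L4RS", "L4LTS", "L4FS"],
        "L5": ["L5RS", "L5IB", "L5LTS", "L5FS"],
        "L6": ["L6RS", "L6LTS", "L6FS"],
    }
    for names in layers.values():
        exc = [n for n in names if _class_of(n) in _EXCITATORY_CLASSES]
        for e in exc:
            for other in names:
                if other == e:
                    continue
                if _class_of(other) in _EXCITATORY_CLASSES:
                    put(e, other, 50.0)
                else:
                    put(e, other, 80.0)
        for i_name in names:
            if _class_of(i_name) in _EXCITATORY_CLASSES:
                continue
            for other in names:
                if other == i_name:
                    continue
                if _class_of(other) in _EXCITATORY_CLASSES:
                    put(i_name, other, -25.0 if _class_of(i_name) == "FS" else -15.0)
                else:
                    put(i_name, other, -8.0)

    # interlaminar excitatory pathway
    put("L4RS", "L2RS", 90.0)
    put("L4RS", "L2IB", 60.0)
    put("L4RS", "L2FS", 50.0)
    put("L2RS", "L5RS", 90.0)
    put("L2IB", "L5IB", 60.0)
    put("L2RS", "L5FS", 40.0)
    put("L5RS", "L6RS", 80.0)
    put("L5IB", "L6FS", 40.0)
    put("L6RS", "L4RS", 50.0)
    put("L6RS", "L4LTS", 30.0)
    # translaminar inhibition and the anatomical L4FS self-connection
    put("L5LTS", "L2RS", -10.0)
    put("L6LTS", "L4RS", -10.0)
    put("L4FS", "L4FS", -15.0)
    return G


def three_population_chain(
    coupling: float = 700.0,
    p_sigma: float | tuple[float, float, float] = 2.0,
    f_hz: tuple[float, float, float] = (50.0, 4.4, 57.8),
    b: float = 0.1,
    self_coupling: float = 260.0,
    operating_point: float = 3.6,
    p_mean: float | None = None,
    gamma: np.ndarray | None = None,
    linear: bool = False,
) -> ColumnModel:
    """Three excitatory populations with the control architecture 2->1, 2->3.

    Population 2 oscillates in the theta band (4.4 Hz) and drives populations
    1 and 3 whose natural frequencies sit in the gamma band (50 and 57.8 Hz);
    populations 1 and 3 are not connected, so any apparent coupling between
    them is spurious (common drive).

    The driven populations carry an excitatory self-connection: a purely
    linear target cannot exhibit phase-amplitude coupling (a slow additive
    input superposes with, but cannot modulate, the gamma response), whereas
    a sigmoid acting on the population's own mixed slow+fast state turns the
    slow input into gain modulation of the self-loop.  To make that work the
    populations are parameterized around an operating point x* (mV) where
    the sigmoid curvature is large:

    * g is solved per population so the *effective* damped frequency at x*,
      sqrt(g^2 - G g c S'(x*) - (g b)^2) / 2 pi with c the self-connection
      weight, equals the nominal f_hz;
    * each population's mean drive is solved so the coupled fixed point sits
      exactly at x*: p = x* g / G - sum_n Gamma[n, m] S(x*).

    Passing an explicit ``p_mean`` overrides the solved drive (all
    populations); ``self_coupling=0`` recovers plain linear targets.
    ``p_sigma`` may be a scalar (shared) or one value per population --
    driving the targets harder than the source decorrelates the relayed
    theta phases, which is what lets conditional measures separate genuine
    relays from common drive.

    An explicit 3x3 ``gamma`` replaces the 2->1, 2->3 architecture entirely
    (``coupling``/``self_coupling`` are then ignored); g and the mean drives
    are still solved per population from its diagonal and column sums, so
    e.g. a feed-forward cascade 1 -> 2 -> 3 keeps the nominal frequencies.

    ``linear=True`` builds the S(x) = x control: the same architecture with
    the identity rate function; g and the mean drives are then solved with
    S(x*) = x*, S'(x*) = 1 so the nominal frequencies are preserved.
    """
    from scipy.optimize import brentq

    sigmas = (
        tuple(float(s) for s in p_sigma)
        if isinstance(p_sigma, (tuple, list, np.ndarray))
        else (float(p_sigma),) * 3
    )
    if len(sigmas) != 3:
        raise ValueError("p_sigma must be a scalar or one value per population")

    sig = SigmoidParams()
    if linear:
        s_star, sp_star = float(operating_point), 1.0
    else:
        s_star = float(sigmoid(np.asarray(operating_point, dtype=float), sig))
        sp_star = float(
            sigmoid_derivative(np.asarray(operating_point, dtype=float), sig)
        )

    if gamma is None:
        gamma = np.zeros((3, 3))
        gamma[1, 0] = coupling  # 2 -> 1
        gamma[1, 2] = coupling  # 2 -> 3
        gamma[0, 0] = self_coupling
        gamma[2, 2] = self_coupling
    else:
        gamma = np.asarray(gamma, dtype=float)
        if gamma.shape != (3, 3):
            raise ValueError("gamma override must be 3x3")

    pops = []
    for i, f in enumerate(f_hz):
        c = gamma[i, i]

        def freq_gap(g, c=c, f=f):
            return g * g - _GAIN_E * g * c * sp_star - (g * b) ** 2 - (2 * math.pi * f) ** 2

        g = brentq(freq_gap, 1.0, 1e6)
        pm = p_mean if p_mean is not None else (
            operating_point * g / _GAIN_E - gamma[:, i].sum() * s_star
        )
        pops.append(
            PopulationSpec(
                name=f"P{i + 1}",
                layer="L4",
                cell_class="RS",
                G=_GAIN_E,
                g=g,
                b=b,
                p_mean=pm,
                p_sigma=sigmas[i],
            )
        )
    return ColumnModel(pops, gamma, linear=linear)
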