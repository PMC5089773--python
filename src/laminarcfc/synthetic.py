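"""Synthetic test signals with known ground-truth coupling.

Four fixture kinds are provided:

* ``am_coupled`` -- a slow channel plus a fast carrier whose amplitude is
  modulated by the slow channel's phase: planted, directional
  phase-amplitude coupling with a known modulation depth;
* ``chain3`` -- a simulation of the three-population control architecture
  (population 2 drives 1 and 3; 1 and 3 are unconnected);
* ``markov_discrete`` -- discrete samples drawn from (or enumerated exactly
  proportional to) a stored joint probability table, enabling exact
  information-theoretic oracles;
* ``null_noise`` -- independent white-noise channels (no coupling at all).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .integrate import SimulationConfig, simulate
from .model import three_population_chain

__all__ = [
    "Fixture",
    "am_coupled",
    "chain3",
    "markov_discrete",
    "null_noise",
    "generate_fixture",
    "XOR_TABLE",
]

#: joint pmf of (X, Y, Z) with Z = X xor Y, X and Y iid Bernoulli(1/2):
#: I(X;Y) = 0 but I(X;Y|Z) = 1 bit.
XOR_TABLE = np.zeros((2, 2, 2))
for _x in (0, 1):
    for _y in (0, 1):
        XOR_TABLE[_x, _y, _x ^ _y] = 0.25


@dataclass
class Fixture:
    """Generated data plus its ground-truth coupling structure."""

    kind: str
    data: np.ndarray  # time x channel (or samples x variable for discrete)
    fs: float | None
    truth: dict = field(default_factory=dict)

    def save(self, directory: str | Path, stem: str | None = None) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        stem = stem or self.kind
        path = directory / f"{stem}.csv"
        pd.DataFrame(self.data).to_csv(path, index=False)
        meta = {"kind": self.kind, "fs": self.fs, "truth": self.truth}
        (directory / f"{stem}.truth.json").write_text(json.dumps(meta, indent=1))
        return path


def am_coupled(
    duration: float = 10.0,
    fs: float = 1000.0,
    f_slow: float = 6.0,
    f_fast: float = 60.0,
    m: float = 0.8,
    noise: float = 0.2,
    phase_jitter: float = 0.05,
    seed: int = 0,
) -> Fixture:
    """Two channels: slow oscillation, and a fast carrier amplitude-modulated
    by the slow channel's phase, x(t) = (1 + m cos(phi_slow)) cos(phi_fast) + noise.

    ``phase_jitter`` adds a small random walk to both phases so the signals
    are not perfectly periodic (as in any physiological rhythm).
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    jit_s = phase_jitter * np.cumsum(rng.standard_normal(n)) / np.sqrt(fs)
    jit_f = phase_jitter * np.cumsum(rng.standard_normal(n)) / np.sqrt(fs)
    phi_slow = 2 * np.pi * f_slow * t + jit_s
    phi_fast = 2 * np.pi * f_fast * t + jit_f
    slow = np.cos(phi_slow) + noise * rng.standard_normal(n)
    fast = (1 + m * np.cos(phi_slow)) * np.cos(phi_fast) + noise * rng.standard_normal(n)
    return Fixture(
        kind="am_coupled",
        data=np.column_stack([slow, fast]),
        fs=fs,
        truth={
            "modulation_depth": m,
            "f_slow": f_slow,
            "f_fast": f_fast,
            "coupled_pairs": [[0, 1]],
            "direction": "slow_phase -> fast_amplitude",
        },
    )


def chain3(
    duration: float = 8.0,
    coupling: float = 150.0,
    p_sigma: float = 2.0,
    seed: int = 0,
    dt: float = 1e-4,
    burn_in: float = 1.0,
) -> Fixture:
    """Simulated three-population control chain (2 -> 1, 2 -> 3)."""
    model = three_population_chain(coupling=coupling, p_sigma=p_sigma)
    result = simulate(
        model, SimulationConfig(dt=dt, duration=duration, burn_in=burn_in, seed=seed)
    )
    return Fixture(
        kind="chain3",
        data=result.x,
        fs=1.0 / dt,
        truth={"edges": [[1, 0], [1, 2]], "absent": [[0, 2], [2, 0]]},
    )


def markov_discrete(
    table: np.ndarray | None = None,
    n: int = 4096,
    seed: int = 0,
    exact: bool = False,
) -> Fixture:
    """Samples from a joint probability table over discrete variables.

    With ``exact=True`` the sample counts are exactly proportional to the
    table (requires n divisible by 1/min-probability granularity), so
    plug-in estimators reproduce table-based information quantities exactly.
    """
    table = XOR_TABLE if table is None else np.asarray(table, dtype=float)
    p = table.ravel()
    p = p / p.sum()
    n_vars = table.ndim
    if exact:
        counts = p * n
        rounded = np.round(counts).astype(int)
        if not np.allclose(counts, rounded):
            raise ValueError("n does not yield integer counts for this table")
        flat = np.repeat(np.arange(p.size), rounded)
    else:
        rng = np.random.default_rng(seed)
        flat = rng.choice(p.size, size=n, p=p)
    idx = np.column_stack(np.unravel_index(flat, table.shape))
    return Fixture(
        kind="markov_discrete",
        data=idx,
        fs=None,
        truth={"table": table.tolist(), "n_vars": n_vars, "exact": exact},
    )


def null_noise(
    n_channels: int = 2, duration: float = 10.0, fs: float = 1000.0, seed: int = 0
) -> Fixture:
    """Independent white-noise channels: every coupling ground truth is null."""
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    return Fixture(
        kind="null_noise",
        data=rng.standard_normal((n, n_channels)),
        fs=fs,
        truth={"coupled_pairs": []},
    )


_KINDS = {
    "am_coupled": am_coupled,
    "chain3": chain3,
    "markov_discrete": markov_discrete,
    "null_noise": null_noise,
}


def generate_fixture(kind: str, params: dict | None = None, seed: int = 0) -> Fixture:
    """Dispatch by fixture kind; unknown kinds are rejected."""
    if kind not in _KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {sorted(_KINDS)}")
    return _KINDS[kind](**{**(params or {}), "seed": seed})
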