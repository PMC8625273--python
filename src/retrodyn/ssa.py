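"""Single-cell stochastic simulation (Gillespie direct method).

Trajectories record the copy-number state at every integer generation (the
state after the last reaction event at or before that time), which is the
resolution at which all population statistics operate.  A trajectory is
fully determined by (parameters, initial state, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from .params import ModelParameters
from .reactions import CopyNumberState

ENGINES = ("exact", "tau-leap")


@dataclass(frozen=True)
class Trajectory:
    """Per-generation copy numbers of one simulated cell."""

    counts: np.ndarray  # int64, shape (generations+1, dim)
    params: ModelParameters
    seed: int
    n_events: int
    engine: str = "exact"

    @property
    def generations(self) -> np.ndarray:
        return np.arange(self.counts.shape[0])

    @property
    def species_names(self) -> tuple[str, ...]:
        return ("L", "S", "R_L", "S2")[: self.counts.shape[1]]

    def species(self, name: str) -> np.ndarray:
        return self.counts[:, self.species_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=list(self.species_names))
        df.insert(0, "generation", self.generations)
        return df


def _init_array(init, has_s2: bool) -> np.ndarray:
    if isinstance(init, CopyNumberState):
        arr = init.as_array(has_s2)
    else:
        arr = np.asarray(init, dtype=np.int64)
    expected = 4 if has_s2 else 3
    if arr.shape != (expected,):
        raise ValueError(f"initial state has shape {arr.shape}, expected ({expected},)")
    if np.any(arr < 0):
        raise ValueError("initial copy numbers must be non-negative")
    full = np.zeros(4, dtype=np.int64)
    full[: arr.size] = arr
    return full


def simulate_cell(
    params: ModelParameters,
    init,
    generations: int,
    seed: int,
    *,
    engine: str = "exact",
    tau: float = 0.01,
    literal_counts: bool = False,
) -> Trajectory:
    """Simulate one cell for ``generations`` cell generations.

    ``init`` is a :class:`CopyNumberState` or a sequence ``(L, S, R_L[, S2])``.
    ``engine`` selects the exact direct method (default) or approximate
    Poisson tau-leaping with leap size ``tau``.  Identical arguments produce
    bit-identical trajectories.
    """
    if generations < 1:
        raise ValueError("generations must be >= 1")
    if engine not in ENGINES:
        raise ValueError(f"unknown engine {engine!r}; expected one of {ENGINES}")
    seed = int(seed)
    if not 0 <= seed < 2**32:
        raise ValueError("seed must fit in 32 bits")
    state0 = _init_array(init, params.has_second_predator)
    vec, use_mm, has_s2 = _kernels.pack_params(params)
    out = np.empty((generations + 1, 4), dtype=np.int64)
    if engine == "exact":
        n_events = _kernels.ssa_direct(
            state0, generations, seed, vec, use_mm, has_s2, int(literal_counts), out
        )
    else:
        if tau <= 0:
            raise ValueError("tau must be positive")
        n_events = _kernels.ssa_tau_leap(
            state0, generations, seed, vec, use_mm, has_s2, int(literal_counts),
            float(tau), out,
        )
    dim = 4 if has_s2 else 3
    return Trajectory(
        counts=out[:, :dim].copy(),
        params=params,
        seed=seed,
        n_events=int(n_events),
        engine=engine,
    )
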