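"""Reaction channels and propensity functions of the stochastic model.

The stochastic model is a continuous-time Markov jump process on integer
copy numbers.  Six channels drive the standard variants (eight with a
second predator):

====================  ============================  =================
channel               propensity                    state change
====================  ============================  =================
production            V * v_R(L/V)                  R_L + 1
insertion_L           b_L * R_L                     R_L - 1, L + 1
insertion_S           (b_S/V) * R_L * S             R_L - 1, S + 1
degradation_R         d_R * R_L                     R_L - 1
silencing_L           d_L * L                       L - 1
silencing_S           d_S * S                       S - 1
insertion_S2          (b_S2/V) * R_L * S2           R_L - 1, S2 + 1
silencing_S2          d_S * S2                      S2 - 1
====================  ============================  =================

The production propensity is the volume-scaled rate law evaluated at the
L *concentration*, ``V * v_R(L/V)``; for the saturating law this is
``V * v_max * (L/V) / (k_r + L/V)``, which reproduces the mean-field
model's rates at matching concentrations (so the reference ``k_r = 149``
yields the same dynamics as the basic model at its stationary state).  A
``literal_counts`` flag applies the saturating law to raw counts instead
(``v_max * L / (k_r + L)``), for comparison only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParameters, effective_rate_constants


@dataclass(frozen=True)
class CopyNumberState:
    """Integer copy numbers of one cell at time ``t`` (generations)."""

    L: int
    S: int
    R_L: int
    S2: int | None = None
    t: float = 0.0

    def __post_init__(self) -> None:
        for name in ("L", "S", "R_L"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
        if self.S2 is not None and (int(self.S2) != self.S2 or self.S2 < 0):
            raise ValueError(f"S2 must be a non-negative integer, got {self.S2}")

    def as_array(self, has_second_predator: bool = False) -> np.ndarray:
        if has_second_predator:
            return np.array([self.L, self.S, self.R_L, self.S2 or 0], dtype=np.int64)
        return np.array([self.L, self.S, self.R_L], dtype=np.int64)


#: Channel state-change vectors over (L, S, R_L, S2).
CHANNELS = (
    ("production", (0, 0, 1, 0)),
    ("insertion_L", (1, 0, -1, 0)),
    ("insertion_S", (0, 1, -1, 0)),
    ("degradation_R", (0, 0, -1, 0)),
    ("silencing_L", (-1, 0, 0, 0)),
    ("silencing_S", (0, -1, 0, 0)),
    ("insertion_S2", (0, 0, -1, 1)),
    ("silencing_S2", (0, 0, 0, -1)),
)


def reaction_channels(params: ModelParameters):
    """Names and state-change vectors of the active channels, in order."""
    n = 8 if params.has_second_predator else 6
    dim = 4 if params.has_second_predator else 3
    return [(name, delta[:dim]) for name, delta in CHANNELS[:n]]


def propensities(
    params: ModelParameters,
    state,
    *,
    literal_counts: bool = False,
) -> list[tuple[str, float, tuple[int, ...]]]:
    """Per-channel event rates and state changes at an integer state.

    Returns ``[(name, rate, delta), ...]`` in channel order.  Every rate is
    non-negative, and vanishes whenever a consumed species is zero.
    """
    if isinstance(state, CopyNumberState):
        arr = state.as_array(params.has_second_predator)
    else:
        arr = np.asarray(state)
        if not np.issubdtype(arr.dtype, np.integer):
            if np.any(arr != np.floor(arr)):
                raise ValueError(f"copy numbers must be integers, got {arr}")
            arr = arr.astype(np.int64)
        if np.any(arr < 0):
            raise ValueError(f"copy numbers must be non-negative, got {arr}")
    expected = 4 if params.has_second_predator else 3
    if arr.shape != (expected,):
        raise ValueError(f"state has shape {arr.shape}, expected ({expected},)")

    r = effective_rate_constants(params)
    V = params.V
    L, S, R = int(arr[0]), int(arr[1]), int(arr[2])
    S2 = int(arr[3]) if params.has_second_predator else 0

    if r.uses_mm and literal_counts:
        production = r.v_max_eff * L / (r.k_r + L) if L > 0 else 0.0
    else:
        production = V * r.v_R(L / V)
    rates = [
        production,
        r.b_L_eff * R,
        (r.b_S_eff / V) * R * S,
        params.d_R * R,
        params.d_L * L,
        params.d_S * S,
    ]
    if params.has_second_predator:
        rates += [(r.b_S2_eff / V) * R * S2, params.d_S * S2]
    return [
        (name, float(rate), delta)
        for (name, delta), rate in zip(reaction_channels(params), rates)
    ]
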