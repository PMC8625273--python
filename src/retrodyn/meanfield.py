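"""Mean-field (deterministic) retrotransposon dynamics.

The expected concentrations ``Lbar, Sbar, Rbar`` (copies per volume ``V``)
obey

    dL/dt = b_L * R - d_L * L
    dS/dt = b_S * S * R - d_S * S
    dR/dt = v_R(L) - b_L * R - b_S * S * R - d_R * R

with the production law ``v_R`` and effective constants resolved by the
model variant.  The two-predator variant adds ``dS2/dt = b_S2 * S2 * R -
d_S * S2`` and the matching drain on ``R``.  The reduced model drops the
``S`` equation and sets ``S = 0``; it describes cells whose non-autonomous
elements have gone extinct.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .params import ModelParameters, EffectiveRates, effective_rate_constants

SPECIES = ("L", "S", "R_L")
SPECIES_2P = ("L", "S", "R_L", "S2")
SPECIES_REDUCED = ("L", "R_L")


def state_dimension(params: ModelParameters, reduced: bool = False) -> int:
    if reduced:
        return 2
    return 4 if params.has_second_predator else 3


def species_names(params: ModelParameters, reduced: bool = False):
    if reduced:
        return SPECIES_REDUCED
    return SPECIES_2P if params.has_second_predator else SPECIES


def deterministic_rhs(
    params: ModelParameters,
    state: np.ndarray,
    *,
    reduced: bool = False,
    rates: EffectiveRates | None = None,
) -> np.ndarray:
    """Time derivatives of the mean concentrations.

    ``state`` is ``(L, S, R_L)`` (``(L, S, R_L, S2)`` for two_predator, or
    ``(L, R_L)`` when ``reduced``), in concentration units.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (state_dimension(params, reduced),):
        raise ValueError(
            f"state has shape {state.shape}, expected "
            f"({state_dimension(params, reduced)},)"
        )
    if np.any(state < 0):
        raise ValueError(f"negative concentration in state {state}")
    r = rates if rates is not None else effective_rate_constants(params)
    if reduced:
        L, R = state
        return np.array(
            [
                r.b_L_eff * R - params.d_L * L,
                r.v_R(L) - r.b_L_eff * R - params.d_R * R,
            ]
        )
    if params.has_second_predator:
        L, S, R, S2 = state
        return np.array(
            [
                r.b_L_eff * R - params.d_L * L,
                r.b_S_eff * S * R - params.d_S * S,
                r.v_R(L)
                - r.b_L_eff * R
                - r.b_S_eff * S * R
                - r.b_S2_eff * S2 * R
                - params.d_R * R,
                r.b_S2_eff * S2 * R - params.d_S * S2,
            ]
        )
    L, S, R = state
    return np.array(
        [
            r.b_L_eff * R - params.d_L * L,
            r.b_S_eff * S * R - params.d_S * S,
            r.v_R(L) - r.b_L_eff * R - r.b_S_eff * S * R - params.d_R * R,
        ]
    )


def jacobian(
    params: ModelParameters,
    state: np.ndarray,
    *,
    reduced: bool = False,
    rates: EffectiveRates | None = None,
) -> np.ndarray:
    """Analytic Jacobian of the mean-field right-hand side at ``state``."""
    state = np.asarray(state, dtype=float)
    r = rates if rates is not None else effective_rate_constants(params)
    if reduced:
        L, R = state
        return np.array(
            [
                [-params.d_L, r.b_L_eff],
                [r.v_R_prime(L), -(r.b_L_eff + params.d_R)],
            ]
        )
    if params.has_second_predator:
        L, S, R, S2 = state
        return np.array(
            [
                [-params.d_L, 0.0, r.b_L_eff, 0.0],
                [0.0, r.b_S_eff * R - params.d_S, r.b_S_eff * S, 0.0],
                [
                    r.v_R_prime(L),
                    -r.b_S_eff * R,
                    -(r.b_L_eff + r.b_S_eff * S + r.b_S2_eff * S2 + params.d_R),
                    -r.b_S2_eff * R,
                ],
                [0.0, 0.0, r.b_S2_eff * S2, r.b_S2_eff * R - params.d_S],
            ]
        )
    L, S, R = state
    return np.array(
        [
            [-params.d_L, 0.0, r.b_L_eff],
            [0.0, r.b_S_eff * R - params.d_S, r.b_S_eff * S],
            [
                r.v_R_prime(L),
                -r.b_S_eff * R,
                -(r.b_L_eff + r.b_S_eff * S + params.d_R),
            ],
        ]
    )


@dataclass(frozen=True)
class MeanFieldSolution:
    """Mean-field trajectory sampled at every integer generation."""

    t: np.ndarray
    states: np.ndarray  # shape (len(t), dim), concentration units
    params: ModelParameters
    reduced: bool

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def to_frame(self):
        import pandas as pd

        names = species_names(self.params, self.reduced)
        df = pd.DataFrame(self.states, columns=list(names))
        df.insert(0, "generation", self.t)
        return df


def integrate_mean_field(
    params: ModelParameters,
    init: np.ndarray,
    t_end: float,
    *,
    reduced: bool = False,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> MeanFieldSolution:
    """Integrate the mean-field equations from ``init`` to ``t_end``.

    Sampling is at every integer generation (plus ``t_end`` if fractional).
    The positive orthant is invariant under the dynamics; the solution is
    asserted non-negative (to solver tolerance) rather than clipped.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    init = np.asarray(init, dtype=float)
    if np.any(init < 0):
        raise ValueError("initial state must be non-negative")
    rates = effective_rate_constants(params)

    def rhs(_t, y):
        # Guard tiny negative excursions within solver tolerance.
        return deterministic_rhs(
            params, np.maximum(y, 0.0), reduced=reduced, rates=rates
        )

    def jac(_t, y):
        return jacobian(params, np.maximum(y, 0.0), reduced=reduced, rates=rates)

    t_eval = np.arange(0.0, np.floor(t_end) + 1.0)
    if t_eval[-1] < t_end:
        t_eval = np.append(t_eval, t_end)
    sol = solve_ivp(
        rhs,
        (0.0, float(t_end)),
        init,
        method="LSODA",
        jac=jac,
        rtol=rtol,
        atol=atol,
        t_eval=t_eval,
    )
    if not sol.success:
        raise RuntimeError(f"mean-field integration failed: {sol.message}")
    states = sol.y.T
    if np.any(states < -1e3 * atol):
        raise RuntimeError(
            "mean-field solution left the positive orthant; "
            f"min component {states.min():.3e}"
        )
    states = np.maximum(states, 0.0)
    return MeanFieldSolution(t=sol.t, states=states, params=params, reduced=reduced)
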