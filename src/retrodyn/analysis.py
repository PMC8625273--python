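"""Stationary states, linear stability and bifurcation scans.

The mean-field model has up to three stationary branches:

``trivial``
    All concentrations zero; both element types have stopped replicating.
``alu_free``
    ``S = 0`` with ``L > 0``: the autonomous element persists alone.  A
    finite branch exists only under the saturating (ribosome-limited)
    production law; with linear production the S-free subsystem has no
    non-zero stationary state.
``coexistence``
    Both elements positive; the predator-prey regime.  The machinery
    concentration is pinned at ``R = d_S / b_S`` by the predator's balance.

Each branch is seeded from its closed form, refined with a Newton root
finder on the full right-hand side, and equipped with the eigenvalues of
the analytic Jacobian.  Scans over the ribosome-competition parameter
``k_r`` or the energy level ``e`` locate bifurcations (branch components
crossing zero, leading eigenvalues crossing the imaginary axis) by
bracketing and bisection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, root

from .params import ModelParameters, effective_rate_constants
from .meanfield import (
    deterministic_rhs,
    jacobian,
    species_names,
    state_dimension,
)

#: Residual tolerance for a state to count as stationary (max-norm of RHS).
STATIONARY_TOL = 1e-10
#: Eigenvalue real parts below -STABILITY_TOL mean stable; within
#: +/-STABILITY_TOL the point is flagged marginal (exactly at bifurcations).
STABILITY_TOL = 1e-9
#: Bisection tolerance for bifurcation parameter values.
BIFURCATION_TOL = 1e-6


@dataclass(frozen=True)
class StationaryPoint:
    """One stationary solution with its linear-stability data."""

    state: np.ndarray
    branch: str
    eigenvalues: np.ndarray
    stable: bool
    marginal: bool
    params: ModelParameters
    reduced: bool = False

    @property
    def period(self) -> float | None:
        """Linearized quasi-cycle period 2*pi/|Im lambda| of the leading
        complex pair, or None if all eigenvalues are real."""
        return predicted_period(self.eigenvalues)

    def component(self, name: str) -> float:
        names = species_names(self.params, self.reduced)
        return float(self.state[names.index(name)])


def predicted_period(eigenvalues: np.ndarray) -> float | None:
    complex_eigs = eigenvalues[np.abs(eigenvalues.imag) > 1e-12]
    if complex_eigs.size == 0:
        return None
    lead = complex_eigs[np.argmax(complex_eigs.real)]
    return float(2.0 * np.pi / abs(lead.imag))


def _classify(eigenvalues: np.ndarray) -> tuple[bool, bool]:
    re = eigenvalues.real
    marginal = bool(np.any(np.abs(re) <= STABILITY_TOL))
    stable = bool(np.all(re < -STABILITY_TOL))
    return stable, marginal


def linear_stability(
    params: ModelParameters, state: np.ndarray, *, reduced: bool = False
) -> tuple[np.ndarray, bool, float | None]:
    """Eigenvalues, stability flag and predicted oscillation period.

    ``state`` must be stationary to :data:`STATIONARY_TOL`.
    """
    state = np.asarray(state, dtype=float)
    residual = np.abs(deterministic_rhs(params, state, reduced=reduced)).max()
    if residual > 100 * STATIONARY_TOL:
        raise ValueError(f"state is not stationary (|RHS| = {residual:.2e})")
    eigs = np.linalg.eigvals(jacobian(params, state, reduced=reduced))
    stable, _ = _classify(eigs)
    return eigs, stable, predicted_period(eigs)


# ---------------------------------------------------------------------------
# Closed-form branch seeds
# ---------------------------------------------------------------------------


def _coexistence_seed(params: ModelParameters) -> np.ndarray | None:
    """Closed-form coexistence state; components may be negative beyond the
    bifurcation (callers check the sign)."""
    r = effective_rate_constants(params)
    R = params.d_S / r.b_S_eff
    L = r.b_L_eff * R / params.d_L
    S = (r.v_R(L) / R - r.b_L_eff - params.d_R) / r.b_S_eff
    return np.array([L, S, R])


def _alu_free_seed(params: ModelParameters) -> np.ndarray | None:
    """Closed-form S-free state (L, R); None when no finite branch exists."""
    r = effective_rate_constants(params)
    c = (r.b_L_eff + params.d_R) * params.d_L / r.b_L_eff
    if not r.uses_mm:
        return None  # linear production: v_R(L) = c*L only degenerately
    L = r.v_max_eff / c - r.k_r
    R = params.d_L * L / r.b_L_eff
    return np.array([L, R])


def coexistence_S(params: ModelParameters) -> float:
    """Coexistence-branch Alu concentration (negative beyond the bifurcation)."""
    return float(_coexistence_seed(params)[1])


def alu_free_L(params: ModelParameters) -> float | None:
    """S-free-branch L concentration, or None when no finite branch exists."""
    seed = _alu_free_seed(params)
    return None if seed is None else float(seed[0])


def _refine(params: ModelParameters, seed: np.ndarray, reduced: bool) -> np.ndarray:
    rates = effective_rate_constants(params)

    def fun(y):
        return deterministic_rhs(
            params, np.maximum(y, 0.0), reduced=reduced, rates=rates
        )

    sol = root(fun, seed, method="hybr", tol=1e-13)
    refined = np.maximum(sol.x, 0.0)
    if np.abs(fun(refined)).max() > STATIONARY_TOL:
        # fall back to the closed-form seed if the refiner wandered off
        refined = np.maximum(seed, 0.0)
    return refined


def _make_point(
    params: ModelParameters, state: np.ndarray, branch: str, reduced: bool
) -> StationaryPoint | None:
    residual = np.abs(deterministic_rhs(params, state, reduced=reduced)).max()
    if residual > STATIONARY_TOL:
        return None
    eigs = np.linalg.eigvals(jacobian(params, state, reduced=reduced))
    stable, marginal = _classify(eigs)
    return StationaryPoint(
        state=state,
        branch=branch,
        eigenvalues=eigs,
        stable=stable,
        marginal=marginal,
        params=params,
        reduced=reduced,
    )


def find_stationary_points(
    params: ModelParameters, *, reduced: bool = False
) -> list[StationaryPoint]:
    """All stationary solutions with real, non-negative components.

    Branches are enumerated from closed-form seeds (exhaustive for this
    rate structure) and refined by a root finder; each returned point has
    ``|RHS|_inf < 1e-10``.  For the two-predator variant, single-predator
    coexistence states are reported for each predator; no state with both
    predators positive exists unless their insertion constants coincide.
    """
    dim = state_dimension(params, reduced)
    points: list[StationaryPoint] = []

    trivial = _make_point(params, np.zeros(dim), "trivial", reduced)
    if trivial is not None:
        points.append(trivial)

    if reduced:
        seed = _alu_free_seed(params)
        if seed is not None and np.all(seed >= 0) and seed[0] > 0:
            state = _refine(params, seed, reduced=True)
            pt = _make_point(params, state, "alu_free", reduced=True)
            if pt is not None:
                points.append(pt)
        return points

    if params.has_second_predator:
        r = effective_rate_constants(params)
        # coexistence with the first predator only (S2 = 0)
        L, S, R = _coexistence_seed(params)
        if S >= 0:
            state = _refine(params, np.array([L, S, R, 0.0]), reduced=False)
            pt = _make_point(params, state, "coexistence_S", reduced=False)
            if pt is not None:
                points.append(pt)
        # coexistence with the second predator only (S = 0)
        R2 = params.d_S / r.b_S2_eff
        L2 = r.b_L_eff * R2 / params.d_L
        S2 = (r.v_R(L2) / R2 - r.b_L_eff - params.d_R) / r.b_S2_eff
        if S2 >= 0:
            state = _refine(params, np.array([L2, 0.0, R2, S2]), reduced=False)
            pt = _make_point(params, state, "coexistence_S2", reduced=False)
            if pt is not None:
                points.append(pt)
        return points

    seed = _alu_free_seed(params)
    if seed is not None and seed[0] > 0:
        L, R = seed
        state = _refine(params, np.array([L, 0.0, R]), reduced=False)
        pt = _make_point(params, state, "alu_free", reduced=False)
        if pt is not None:
            points.append(pt)

    coex = _coexistence_seed(params)
    if coex is not None and np.all(coex >= 0):
        state = _refine(params, coex, reduced=False)
        pt = _make_point(params, state, "coexistence", reduced=False)
        if pt is not None:
            points.append(pt)

    return points


# ---------------------------------------------------------------------------
# Parameter scans
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Bifurcation:
    parameter: str
    value: float
    branch: str
    kind: str  # "branch_zero" or "stability_change"


@dataclass
class BifurcationScan:
    """Stationary branches and detected bifurcations over a parameter grid."""

    parameter: str
    grid: np.ndarray
    points: list[list[StationaryPoint]]
    bifurcations: list[Bifurcation] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (parameter value, branch)."""
        rows = []
        for value, pts in zip(self.grid, self.points):
            for pt in pts:
                names = species_names(pt.params, pt.reduced)
                row = {self.parameter: value, "branch": pt.branch}
                V = pt.params.V
                for name, comp in zip(names, pt.state):
                    row[name] = comp
                    row[f"{name}_copies"] = comp * V
                row["max_re_lambda"] = float(pt.eigenvalues.real.max())
                row["stable"] = pt.stable
                row["marginal"] = pt.marginal
                rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        return {
            "parameter": self.parameter,
            "grid_min": float(self.grid[0]),
            "grid_max": float(self.grid[-1]),
            "bifurcations": [
                {
                    "parameter": b.parameter,
                    "value": b.value,
                    "branch": b.branch,
                    "kind": b.kind,
                }
                for b in self.bifurcations
            ],
        }


def _with_value(params: ModelParameters, parameter: str, value: float):
    return params.with_updates(**{parameter: float(value)})


def _branch_indicators(params: ModelParameters, parameter: str, reduced: bool):
    """Smooth branch-existence indicators f(p) whose zeros are bifurcations."""

    def coex(p: float) -> float:
        return coexistence_S(_with_value(params, parameter, p))

    def alufree(p: float) -> float | None:
        return alu_free_L(_with_value(params, parameter, p))

    indicators = {}
    if not params.has_second_predator:
        if reduced:
            if alu_free_L(params) is not None:
                indicators["alu_free"] = alufree
        else:
            indicators["coexistence"] = coex
            if alu_free_L(params) is not None:
                indicators["alu_free"] = alufree
    return indicators


def _max_re(params: ModelParameters, branch: str, reduced: bool) -> float | None:
    for pt in find_stationary_points(params, reduced=reduced):
        if pt.branch == branch:
            return float(pt.eigenvalues.real.max())
    return None


def scan_parameter(
    params: ModelParameters,
    parameter: str,
    grid: Sequence[float],
    *,
    reduced: bool = False,
) -> BifurcationScan:
    """Track all stationary branches over a grid of ``k_r`` or ``e`` values.

    Bifurcations are detected as sign changes of (i) a branch component's
    closed-form continuation across zero and (ii) the leading eigenvalue's
    real part along a branch, bracketed between grid points and refined by
    bisection to :data:`BIFURCATION_TOL`.
    """
    if parameter not in ("k_r", "e"):
        raise ValueError(f"unsupported scan parameter {parameter!r}")
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be one-dimensional and strictly increasing")

    points = [
        find_stationary_points(_with_value(params, parameter, p), reduced=reduced)
        for p in grid
    ]

    bifurcations: list[Bifurcation] = []
    # (i) branch components crossing zero
    for branch, fun in _branch_indicators(params, parameter, reduced).items():
        values = [fun(p) for p in grid]
        for a, b, fa, fb in zip(grid[:-1], grid[1:], values[:-1], values[1:]):
            if fa is None or fb is None:
                continue
            if fa == 0.0:
                bifurcations.append(Bifurcation(parameter, float(a), branch, "branch_zero"))
            elif fa * fb < 0:
                z = brentq(fun, a, b, xtol=BIFURCATION_TOL / 10)
                bifurcations.append(Bifurcation(parameter, float(z), branch, "branch_zero"))
    # (ii) leading eigenvalue of each branch crossing zero
    branches = {pt.branch for pts in points for pt in pts}
    for branch in branches:
        def g(p: float, _branch=branch) -> float | None:
            return _max_re(_with_value(params, parameter, p), _branch, reduced)

        values = [g(p) for p in grid]
        for a, b, fa, fb in zip(grid[:-1], grid[1:], values[:-1], values[1:]):
            if fa is None or fb is None:
                continue
            if fa * fb < 0:
                z = brentq(lambda p: g(p), a, b, xtol=BIFURCATION_TOL / 10)
                bifurcations.append(
                    Bifurcation(parameter, float(z), branch, "stability_change")
                )

    bifurcations.sort(key=lambda b: (b.value, b.branch, b.kind))
    return BifurcationScan(
        parameter=parameter, grid=grid, points=points, bifurcations=bifurcations
    )


# ---------------------------------------------------------------------------
# Two-parameter stability map (mixed model)
# ---------------------------------------------------------------------------


def stability_map(
    params: ModelParameters,
    k_r_grid: Sequence[float],
    e_grid: Sequence[float],
) -> dict:
    """Existence/stability of the coexistence and trivial solutions over a
    (k_r, e) grid of the mixed model.

    Returns arrays of shape ``(len(e_grid), len(k_r_grid))``:
    ``coexistence_exists``, ``coexistence_stable``, ``trivial_stable``.
    """
    if params.variant != "mixed":
        raise ValueError("stability_map requires the mixed variant")
    k_r_grid = np.asarray(k_r_grid, dtype=float)
    e_grid = np.asarray(e_grid, dtype=float)
    for g in (k_r_grid, e_grid):
        if np.any(np.diff(g) <= 0):
            raise ValueError("grids must be strictly increasing")
    shape = (e_grid.size, k_r_grid.size)
    coex_exists = np.zeros(shape, dtype=bool)
    coex_stable = np.zeros(shape, dtype=bool)
    trivial_stable = np.zeros(shape, dtype=bool)
    for i, e in enumerate(e_grid):
        for j, kr in enumerate(k_r_grid):
            p = params.with_updates(e=float(e), k_r=float(kr))
            for pt in find_stationary_points(p):
                if pt.branch == "coexistence":
                    coex_exists[i, j] = True
                    coex_stable[i, j] = pt.stable
                elif pt.branch == "trivial":
                    trivial_stable[i, j] = pt.stable
    return {
        "k_r": k_r_grid,
        "e": e_grid,
        "coexistence_exists": coex_exists,
        "coexistence_stable": coex_stable,
        "trivial_stable": trivial_stable,
    }


def critical_k_r(params: ModelParameters, bracket: tuple[float, float] = (1.0, 400.0)) -> float | None:
    """k_r at which the coexistence branch vanishes (S crosses zero), for
    ribosome or mixed parameters; None if no sign change in the bracket."""
    lo, hi = bracket
    f = lambda p: coexistence_S(params.with_updates(k_r=float(p)))
    if f(lo) * f(hi) > 0:
        return None
    return float(brentq(f, lo, hi, xtol=BIFURCATION_TOL / 10))
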