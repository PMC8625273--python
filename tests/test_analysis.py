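"""Stationary branches, eigenvalues, bifurcation scans and stability maps."""

import numpy as np
import pytest
import sympy

import retrodyn as rd
from retrodyn.analysis import STATIONARY_TOL


def branch(points, name):
    matches = [p for p in points if p.branch == name]
    return matches[0] if matches else None


def test_every_reported_point_is_stationary(ribosome_params):
    for kr in (120.0, 176.0, 199.0, 205.0):
        p = ribosome_params.with_updates(k_r=kr)
        for pt in rd.find_stationary_points(p):
            res = np.abs(rd.deterministic_rhs(p, pt.state)).max()
            assert res < STATIONARY_TOL


def test_three_branch_structure_below_first_bifurcation(ribosome_params):
    p = ribosome_params.with_updates(k_r=176.0)
    pts = rd.find_stationary_points(p)
    assert {pt.branch for pt in pts} == {"trivial", "alu_free", "coexistence"}
    coex = branch(pts, "coexistence")
    # S = 600/(k_r+1) - 3 from the machinery balance with R=0.5, L=1
    assert coex.state[1] == pytest.approx(600.0 / 177.0 - 3.0, abs=1e-10)
    assert coex.stable
    alu_free = branch(pts, "alu_free")
    assert not alu_free.stable
    # the destabilizing direction is the predator invasion rate b_S*R - d_S
    R = alu_free.state[2]
    assert np.any(np.isclose(alu_free.eigenvalues.real, 1.0 * R - 0.5))


def test_branches_merge_at_first_bifurcation(ribosome_params):
    pts = rd.find_stationary_points(ribosome_params.with_updates(k_r=199.0))
    coex = branch(pts, "coexistence")
    assert coex is not None
    assert coex.state[1] == pytest.approx(0.0, abs=1e-9)


def test_reduced_model_branches():
    p = rd.default_parameters("ribosome").with_updates(k_r=150.0)
    pts = rd.find_stationary_points(p, reduced=True)
    nonzero = branch(pts, "alu_free")
    assert nonzero.state[0] == pytest.approx(50.0, abs=1e-10)
    assert nonzero.stable  # stable once the predator is gone
    # at and beyond the second bifurcation only the trivial solution is left
    pts200 = rd.find_stationary_points(
        p.with_updates(k_r=200.0), reduced=True
    )
    assert [pt.branch for pt in pts200] == ["trivial"]


def test_basic_characteristic_polynomial_and_period(basic_params):
    """Independent symbolic expansion of det(J - lambda I) at (1, 1, 0.5)
    gives lambda^3 + 4.5 lambda^2 + 0.5 lambda + 0.25, whose complex pair
    sets a quasi-cycle period that rounds to 27 generations."""
    J = rd.jacobian(basic_params, np.array([1.0, 1.0, 0.5]))
    lam = sympy.symbols("lam")
    charpoly = sympy.expand(
        (sympy.Matrix(J) - lam * sympy.eye(3)).det() * -1
    )
    coeffs = sympy.Poly(charpoly, lam).all_coeffs()
    assert [float(c) for c in coeffs] == pytest.approx([1.0, 4.5, 0.5, 0.25])
    eigs, stable, period = rd.linear_stability(
        basic_params, np.array([1.0, 1.0, 0.5])
    )
    assert stable
    assert round(period) == 27


def test_linear_stability_rejects_non_stationary_state(basic_params):
    with pytest.raises(ValueError, match="stationary"):
        rd.linear_stability(basic_params, np.array([2.0, 2.0, 2.0]))


def test_kr_scan_finds_both_bifurcations(ribosome_params):
    scan = rd.scan_parameter(ribosome_params, "k_r", np.linspace(100, 210, 23))
    zeros = {
        b.branch: b.value for b in scan.bifurcations if b.kind == "branch_zero"
    }
    assert zeros["coexistence"] == pytest.approx(199.0, abs=1e-3)
    assert zeros["alu_free"] == pytest.approx(200.0, abs=1e-3)
    # coexistence S decreases monotonically along the stable branch
    df = scan.to_frame()
    S = df[df.branch == "coexistence"].sort_values("k_r")["S"].to_numpy()
    assert np.all(np.diff(S) < 0)


def test_energy_scan_bifurcation_matches_quadratic_root():
    """With k_tr=0.2 and k_int=3.2 the coexistence existence condition
    reduces to e^2 - 7e - 1.28 > 0; the scan recovers its positive root."""
    p = rd.default_parameters("energy", e=10.0)
    scan = rd.scan_parameter(p, "e", np.linspace(5.0, 12.0, 15))
    zeros = [b for b in scan.bifurcations if b.kind == "branch_zero"]
    assert len(zeros) == 1
    analytic = (7.0 + np.sqrt(7.0**2 + 4 * 1.28)) / 2.0
    assert zeros[0].value == pytest.approx(analytic, abs=1e-6)


def test_single_point_scan_equals_find_stationary_points(ribosome_params):
    p = ribosome_params.with_updates(k_r=176.0)
    scan = rd.scan_parameter(ribosome_params, "k_r", [176.0])
    direct = rd.find_stationary_points(p)
    assert len(scan.points[0]) == len(direct)
    for a, b in zip(scan.points[0], direct):
        assert a.branch == b.branch
        assert np.allclose(a.state, b.state)
        assert a.stable == b.stable


def test_stability_flags_invariant_to_grid_refinement(ribosome_params):
    coarse = rd.scan_parameter(ribosome_params, "k_r", np.linspace(150, 198, 4))
    fine = rd.scan_parameter(ribosome_params, "k_r", np.linspace(150, 198, 13))
    for value, pts in zip(coarse.grid, coarse.points):
        j = np.flatnonzero(np.isclose(fine.grid, value))[0]
        assert {(p.branch, p.stable) for p in pts} == {
            (p.branch, p.stable) for p in fine.points[j]
        }


def test_trajectories_from_random_initial_states_converge(basic_params):
    rng = np.random.default_rng(7)
    target = np.array([1.0, 1.0, 0.5])
    for _ in range(20):
        init = rng.uniform(0.05, 3.0, size=3)
        sol = rd.integrate_mean_field(basic_params, init, 600)
        assert np.allclose(sol.final_state, target, atol=1e-5)


def test_stability_map_limits_and_monotone_boundary():
    pm = rd.default_parameters("mixed", e=10.0)
    # huge e reproduces the ribosome-variant threshold near k_r = 199
    m = rd.stability_map(pm, [150.0, 195.0, 198.0, 201.0, 205.0], [1e6])
    assert list(m["coexistence_exists"][0]) == [True, True, True, False, False]
    assert m["coexistence_stable"][0][:3].all()
    # the critical k_r decreases monotonically as e decreases
    crits = [
        rd.critical_k_r(pm.with_updates(e=e)) for e in (1e6, 50.0, 20.0, 10.0, 8.0)
    ]
    assert all(c is not None for c in crits)
    assert np.all(np.diff(crits) < 0)
    assert crits[0] == pytest.approx(199.0, abs=0.1)


def test_two_predator_has_no_two_predator_stationary_state():
    """With unequal insertion constants each predator demands a different
    machinery level (R = d_S/b), so the model admits no stationary state
    with both predators positive (competitive exclusion)."""
    p = rd.default_parameters("two_predator")
    pts = rd.find_stationary_points(p)
    for pt in pts:
        assert not (pt.state[1] > 1e-12 and pt.state[3] > 1e-12)
    assert {pt.branch for pt in pts} >= {"coexistence_S", "coexistence_S2"}
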