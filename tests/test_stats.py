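"""Survival curves, pooled summaries and oscillation metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import retrodyn as rd
from retrodyn.stats import estimate_period_autocorrelation, sliding_frame_amplitude

from conftest import make_toy_ensemble


def empirical_survival(ext_gens, generations, buffer):
    """Brute-force oracle: fraction of at-risk cells still alive, among
    cells alive at the end of the buffer."""
    ext = np.array([np.inf if e is None else e for e in ext_gens])
    at_risk0 = (ext > buffer).sum()
    return np.array(
        [(ext > g).sum() / at_risk0 if at_risk0 else 1.0 for g in generations]
    )


def test_survival_constant_one_without_extinctions():
    ens = make_toy_ensemble([None] * 8)
    curve = rd.kaplan_meier(ens, "Alu")
    assert np.all(curve.survival == 1.0)
    assert np.all(rd.kaplan_meier(ens, "L1").survival == 1.0)


def test_single_extinction_gives_single_step():
    ens = make_toy_ensemble([105] + [None] * 9, n_generations=120, buffer=100)
    curve = rd.kaplan_meier(ens, "Alu")
    assert curve.at(104) == 1.0
    assert curve.at(105) == pytest.approx(0.9)
    assert curve.at(120) == pytest.approx(0.9)


def test_km_equals_empirical_survival_on_toy_ensemble():
    """Without censoring the product-limit estimate reduces to the simple
    surviving fraction at every generation."""
    ext = [102, 102, 104, None, None]
    ens = make_toy_ensemble(ext, n_generations=110, buffer=100)
    curve = rd.kaplan_meier(ens, "Alu")
    oracle = empirical_survival(ext, curve.generations, buffer=100)
    assert np.allclose(curve.survival, oracle)


@settings(max_examples=50, deadline=None)
@given(
    ext=st.lists(
        st.one_of(st.none(), st.integers(1, 30)), min_size=1, max_size=25
    )
)
def test_km_matches_brute_force_counting(ext):
    ens = make_toy_ensemble(ext, n_generations=30, buffer=0)
    curve = rd.kaplan_meier(ens, "Alu")
    oracle = empirical_survival(ext, curve.generations, buffer=0)
    assert np.allclose(curve.survival, oracle)
    assert np.all(np.diff(curve.survival) <= 1e-12)
    assert np.all((0.0 <= curve.survival) & (curve.survival <= 1.0))


def test_km_agrees_with_lifelines():
    """Cross-check the product-limit arithmetic against lifelines on a toy
    ensemble with end-of-study censoring."""
    from lifelines import KaplanMeierFitter

    ext = [3, 3, 7, 12, None, None, 20, None]
    T = 25
    ens = make_toy_ensemble(ext, n_generations=T, buffer=0)
    curve = rd.kaplan_meier(ens, "Alu")
    durations = [T if e is None else e for e in ext]
    observed = [e is not None for e in ext]
    kmf = KaplanMeierFitter().fit(durations, observed)
    for g in range(T + 1):
        assert curve.at(g) == pytest.approx(
            float(kmf.survival_function_at_times(g).iloc[0])
        )


def test_empty_ensemble_rejected(small_basic_ensemble):
    ens = small_basic_ensemble
    empty = rd.PopulationEnsemble(
        counts=ens.counts[:0],
        params=ens.params,
        buffer=ens.buffer,
        master_seed=None,
        cell_seeds=None,
        cell_ids=np.array([], dtype=int),
        n_requested=0,
        n_excluded=0,
    )
    with pytest.raises(ValueError):
        rd.kaplan_meier(empty, "Alu")


def test_time_average_of_constant_series():
    ens = make_toy_ensemble([None] * 4, n_generations=20)
    ens.counts[:, :, 0] = 500
    avg = rd.time_averaged_distribution(ens, (5, 15), "L")
    assert np.allclose(avg, 500.0)


def test_cells_extinct_during_window_are_excluded():
    ens = make_toy_ensemble([None] * 3, n_generations=20)
    # cell 0 enters the fully-extinct pool mid-window
    ens.counts[0, 10:, :] = 0
    avg = rd.time_averaged_distribution(ens, (5, 15), "L")
    assert set(avg.index) == {1, 2}
    with pytest.warns(UserWarning):
        ens2 = make_toy_ensemble([None], n_generations=20)
        ens2.counts[0, 2:, :] = 0
        out = rd.time_averaged_distribution(ens2, (5, 15), "L")
    assert out.empty


def test_pool_summary_closed_forms():
    ens = make_toy_ensemble([None] * 2, n_generations=11)
    # constant L -> CV 0; alternating 0/2 (mean 1, sd 1) -> CV 1
    ens.counts[0, :, 0] = 7
    ens.counts[1, :, 0] = np.tile([0, 2], 6)[:12]
    ens.counts[:, :, 2] = 1  # machinery present: L never extinct
    df = rd.summarize_pools(ens, (0, 11))
    row_L = df[(df.pool == 1) & (df.species == "L")].iloc[0]
    assert row_L["n_cells"] == 2
    assert row_L["mean"] == pytest.approx((7 + 1) / 2)
    assert row_L["cv"] == pytest.approx((0.0 + 1.0) / 2)
    # empty pools report NaN
    row3 = df[(df.pool == 3) & (df.species == "L")].iloc[0]
    assert np.isnan(row3["mean"]) and row3["n_cells"] == 0


def test_pool_mean_near_stationary_prediction(small_basic_ensemble):
    """In the basic model nearly all cells keep both elements; the pool-1
    time means sit within a few SEM of the deterministic V*(1, 1)."""
    ens = small_basic_ensemble
    df = rd.summarize_pools(ens, (101, 300))
    for species in ("L", "S"):
        row = df[(df.pool == 1) & (df.species == species)].iloc[0]
        assert row["n_cells"] > 50
        assert abs(row["mean"] - 500.0) < 30.0


def test_amplitude_shift_invariance_and_cv_scale_invariance():
    rng = np.random.default_rng(0)
    x = rng.normal(50.0, 5.0, size=300)
    amp = sliding_frame_amplitude(x, 100, 10)
    assert sliding_frame_amplitude(x + 123.4, 100, 10) == pytest.approx(amp)
    assert amp >= 0
    cv = x.std() / x.mean()
    y = 7.5 * x
    assert y.std() / y.mean() == pytest.approx(cv)


def test_amplitude_requires_full_frame():
    with pytest.raises(ValueError):
        sliding_frame_amplitude(np.ones(50), 100, 10)


def test_period_of_noisy_sinusoid_recovered():
    rng = np.random.default_rng(1)
    t = np.arange(600)
    rows = np.stack(
        [np.sin(2 * np.pi * t / 27.0) + 0.1 * rng.normal(size=t.size) for _ in range(5)]
    )
    period = estimate_period_autocorrelation(rows)
    assert period == pytest.approx(27, abs=1)


def test_constant_series_has_no_period_and_zero_amplitude():
    ens = make_toy_ensemble([None] * 3, n_generations=200)
    ens.counts[:, :, 0] = 400
    out = rd.oscillation_metrics(ens, 1, species="L", frame=100, step=10, window=(0, 200))
    assert out.amplitude == 0.0
    assert out.period is None
    assert out.cv == 0.0
    assert estimate_period_autocorrelation(np.ones((2, 50))) is None


def test_oscillation_period_near_linearized_prediction(small_basic_ensemble):
    """Basic-model quasi-cycles: the autocorrelation period of pool-1 cells
    matches the eigenvalue prediction of about 27 generations within 20%."""
    out = rd.oscillation_metrics(
        small_basic_ensemble, 1, species="S", frame=100, step=10, window=(101, 300)
    )
    assert out.period_linearized == pytest.approx(27.0, abs=0.1)
    assert out.period is not None
    assert abs(out.period - 27.0) <= 0.2 * 27.0
    assert out.amplitude > 0
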