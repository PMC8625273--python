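"""Population summaries: survival, distributions, noise and oscillations.

All statistics operate on the per-generation counts of a
:class:`~retrodyn.population.PopulationEnsemble`, restricted to the
post-buffer analysis window.  The survival of each element type is a
product-limit (Kaplan-Meier) estimate over generations

    F(i) = prod_{j <= i} (1 - d_j / n_{j-1}),

where ``d_j`` counts cells whose element went extinct between generations
j-1 and j and ``n_{j-1}`` counts cells still carrying it at j-1.  There is
no censoring (every retained cell is observed to the end of the run), so F
coincides with the empirical survival fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .analysis import find_stationary_points
from .population import (
    NEVER,
    POOL_ALL_EXTINCT,
    POOL_ALU_EXTINCT,
    POOL_BOTH_ACTIVE,
    PopulationEnsemble,
)

_SPECIES_COLUMN = {"L1": 0, "L": 0, "Alu": 1, "S": 1, "R_L": 2, "S2": 3}
_SPECIES_EXTINCTION = {"L1": "L1", "L": "L1", "Alu": "Alu", "S": "Alu", "S2": "S2"}


@dataclass(frozen=True)
class SurvivalCurve:
    """Generation-indexed product-limit survival of one element type."""

    generations: np.ndarray
    survival: np.ndarray
    deaths: np.ndarray
    at_risk: np.ndarray
    species: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generation": self.generations,
                "survival": self.survival,
                "deaths": self.deaths,
                "at_risk": self.at_risk,
            }
        )

    def to_json_dict(self) -> dict:
        return {
            "species": self.species,
            "generation": self.generations.tolist(),
            "F": self.survival.tolist(),
            "d": self.deaths.tolist(),
            "n": self.at_risk.tolist(),
        }

    def at(self, generation: int) -> float:
        idx = np.searchsorted(self.generations, generation, side="right") - 1
        if idx < 0:
            return 1.0
        return float(self.survival[idx])


def kaplan_meier(ensemble: PopulationEnsemble, species: str) -> SurvivalCurve:
    """Product-limit survival of ``species`` ("L1" or "Alu") over the
    analysis window.

    The at-risk set at the end of the buffer consists of retained cells in
    which the species is still active; F is 1 there by construction and
    decreases by the factor (1 - d_i/n_{i-1}) at each later generation.
    """
    if ensemble.n_cells == 0:
        raise ValueError("ensemble has no retained cells")
    ext = ensemble.extinction_generations(_SPECIES_EXTINCTION[species])
    start = ensemble.buffer
    T = ensemble.n_generations
    gens = np.arange(start, T + 1)
    deaths = np.zeros(gens.size, dtype=np.int64)
    at_risk = np.zeros(gens.size, dtype=np.int64)
    F = np.ones(gens.size)
    # cells extinct during the buffer never enter the risk set
    for k, i in enumerate(gens):
        at_risk[k] = int((ext > i - 1).sum()) if i > start else int((ext > start).sum())
        if i == start:
            continue
        deaths[k] = int((ext == i).sum())
        factor = 1.0 - deaths[k] / at_risk[k] if at_risk[k] > 0 else 1.0
        F[k] = F[k - 1] * factor
    return SurvivalCurve(
        generations=gens, survival=F, deaths=deaths, at_risk=at_risk, species=species
    )


def _window_slice(ensemble: PopulationEnsemble, window) -> tuple[int, int]:
    if window is None:
        return ensemble.analysis_start, ensemble.n_generations
    start, stop = int(window[0]), int(window[1])
    if not 0 <= start < stop <= ensemble.n_generations:
        raise ValueError(
            f"window {window} outside recorded range (0, {ensemble.n_generations})"
        )
    return start, stop


def time_averaged_distribution(
    ensemble: PopulationEnsemble,
    window=None,
    species: str = "L",
) -> pd.Series:
    """Per-cell time averages of ``species`` over ``window = (start, stop)``.

    Only cells in which the species never went extinct up to the end of the
    window are included (the element must be active throughout).  Returns
    raw averages indexed by cell id; histogram binning is the caller's
    concern.
    """
    start, stop = _window_slice(ensemble, window)
    col = _SPECIES_COLUMN[species]
    ext = ensemble.extinction_generations(_SPECIES_EXTINCTION[species])
    keep = ext > stop
    if not keep.any():
        warnings.warn("no cells with the species active over the window", stacklevel=2)
        return pd.Series(dtype=float, name=species)
    values = ensemble.counts[keep, start : stop + 1, col].mean(axis=1)
    return pd.Series(values, index=ensemble.cell_ids[keep], name=species)


def summarize_pools(
    ensemble: PopulationEnsemble,
    window=None,
    *,
    whole_window: bool = False,
) -> pd.DataFrame:
    """Per-pool mean copy numbers and coefficients of variation of L and S.

    Per cell, the time mean and CV (standard deviation over mean) are
    computed over the generations of the window attributed to each pool the
    cell visits (cells switching pools contribute to each pool only the
    generations spent there); with ``whole_window=True`` the cell is instead
    attributed entirely to its pool at the window's end.  Per pool, the
    per-cell statistics are averaged.  Empty statistics are NaN.
    """
    start, stop = _window_slice(ensemble, window)
    if stop - start < 1:
        raise ValueError("window must span at least 2 generations")
    pools = ensemble.pool_labels[:, start : stop + 1]
    data = ensemble.counts[:, start : stop + 1, :]
    rows = []
    for pool in (POOL_BOTH_ACTIVE, POOL_ALU_EXTINCT, POOL_ALL_EXTINCT):
        for species, col in (("L", 0), ("S", 1)):
            means, cvs = [], []
            for c in range(ensemble.n_cells):
                if whole_window:
                    if pools[c, -1] != pool:
                        continue
                    series = data[c, :, col].astype(float)
                else:
                    mask = pools[c] == pool
                    if mask.sum() < 2:
                        continue
                    series = data[c, mask, col].astype(float)
                m = series.mean()
                means.append(m)
                cvs.append(series.std(ddof=0) / m if m > 0 else np.nan)
            rows.append(
                {
                    "pool": pool,
                    "species": species,
                    "n_cells": len(means),
                    "mean": float(np.mean(means)) if means else np.nan,
                    "cv": (
                        float(np.nanmean(cvs))
                        if cvs and not np.all(np.isnan(cvs))
                        else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Oscillation metrics
# ---------------------------------------------------------------------------


def sliding_frame_amplitude(
    series: np.ndarray, frame: int, step: int
) -> float:
    """Mean over sliding frames of (max - min) within the frame.

    ``series`` is 1-D; frames of length ``frame`` start every ``step``
    samples.  Adding a constant to the series leaves the result unchanged.
    """
    n = series.size
    if n < frame:
        raise ValueError(f"series of length {n} shorter than frame {frame}")
    starts = range(0, n - frame + 1, step)
    amps = [series[s : s + frame].max() - series[s : s + frame].min() for s in starts]
    return float(np.mean(amps))


def estimate_period_autocorrelation(series_matrix: np.ndarray) -> float | None:
    """Dominant oscillation period from the ensemble-averaged autocorrelation.

    Each row is mean-subtracted, its autocorrelation computed, rows averaged,
    and the period read off as the lag of the highest local maximum after the
    first zero crossing.  Returns None when no crossing or maximum exists
    (e.g. constant input).
    """
    x = np.asarray(series_matrix, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    n = x.shape[1]
    acfs = []
    for row in x:
        row = row - row.mean()
        var = np.dot(row, row)
        if var == 0:
            continue
        acf = np.correlate(row, row, mode="full")[n - 1 :] / var
        acfs.append(acf)
    if not acfs:
        return None
    acf = np.mean(acfs, axis=0)
    below = np.flatnonzero(acf < 0)
    if below.size == 0:
        return None
    crossing = below[0]
    tail = acf[crossing:]
    if tail.size < 3:
        return None
    # highest interior local maximum after the crossing
    interior = tail[1:-1]
    local_max = (interior >= tail[:-2]) & (interior >= tail[2:])
    candidates = np.flatnonzero(local_max) + 1
    if candidates.size == 0:
        return None
    best = candidates[np.argmax(tail[candidates])]
    return float(crossing + best)


@dataclass(frozen=True)
class OscillationSummary:
    """Amplitude, noise and period of the quasi-cycles in one cell pool."""

    pool: int
    species: str
    amplitude: float
    frame: int
    step: int
    period: float | None
    period_method: str
    period_linearized: float | None
    cv: float
    n_cells: int

    def to_json_dict(self) -> dict:
        return {
            "pool": self.pool,
            "species": self.species,
            "amplitude": self.amplitude,
            "frame": self.frame,
            "step": self.step,
            "period": self.period,
            "period_method": self.period_method,
            "period_linearized": self.period_linearized,
            "cv": self.cv,
            "n_cells": self.n_cells,
        }


def _linearized_period(ensemble: PopulationEnsemble) -> float | None:
    try:
        points = [
            p for p in find_stationary_points(ensemble.params) if p.stable
        ]
    except Exception:
        return None
    if not points:
        return None
    return points[0].period


def _longest_run(mask: np.ndarray) -> tuple[int, int]:
    """(start, length) of the longest run of True in a 1-D boolean mask."""
    best_start, best_len, run_start = 0, 0, None
    for i, flag in enumerate(mask):
        if flag and run_start is None:
            run_start = i
        elif not flag and run_start is not None:
            if i - run_start > best_len:
                best_start, best_len = run_start, i - run_start
            run_start = None
    if run_start is not None and mask.size - run_start > best_len:
        best_start, best_len = run_start, mask.size - run_start
    return best_start, best_len


def oscillation_metrics(
    ensemble: PopulationEnsemble,
    pool: int,
    *,
    species: str = "L",
    frame: int = 100,
    step: int = 10,
    window=None,
) -> OscillationSummary:
    """Quasi-cycle amplitude and period of ``species`` in one cell pool.

    Cells contribute their longest contiguous stretch of ``pool``
    membership within the window, provided it spans at least one frame
    (cells drift between pools as elements go extinct, so requiring
    whole-window membership would discard all data near the bifurcation).
    The amplitude is the max-minus-min within sliding frames (default 100
    generations, moved in 10-generation increments), averaged over frames
    and cells.  The period is estimated from the ensemble-averaged
    autocorrelation of the segments, with the linearized eigenvalue
    prediction reported alongside.
    """
    start, stop = _window_slice(ensemble, window)
    if stop - start + 1 < frame:
        raise ValueError(
            f"window of {stop - start + 1} generations shorter than frame {frame}"
        )
    col = _SPECIES_COLUMN[species]
    pools = ensemble.pool_labels[:, start : stop + 1]
    segments = []
    for c in range(ensemble.n_cells):
        seg_start, seg_len = _longest_run(pools[c] == pool)
        if seg_len >= frame:
            segments.append(
                ensemble.counts[
                    c, start + seg_start : start + seg_start + seg_len, col
                ].astype(float)
            )
    n_cells = len(segments)
    if n_cells == 0:
        return OscillationSummary(
            pool=pool,
            species=species,
            amplitude=np.nan,
            frame=frame,
            step=step,
            period=None,
            period_method="ensemble_autocorrelation",
            period_linearized=_linearized_period(ensemble),
            cv=np.nan,
            n_cells=0,
        )
    amplitude = float(
        np.mean([sliding_frame_amplitude(seg, frame, step) for seg in segments])
    )
    cvs = []
    for seg in segments:
        m = seg.mean()
        if m > 0:
            cvs.append(seg.std(ddof=0) / m)
    cv = float(np.mean(cvs)) if cvs else np.nan
    # average per-segment autocorrelations up to the shortest segment
    min_len = min(seg.size for seg in segments)
    period = estimate_period_autocorrelation(
        np.stack([seg[:min_len] - seg[:min_len].mean() for seg in segments])
    )
    return OscillationSummary(
        pool=pool,
        species=species,
        amplitude=amplitude,
        frame=frame,
        step=step,
        period=period,
        period_method="ensemble_autocorrelation",
        period_linearized=_linearized_period(ensemble),
        cv=cv,
        n_cells=n_cells,
    )
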