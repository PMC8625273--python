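"""Cell-population simulation protocol and extinction bookkeeping.

A population run simulates ``n_cells`` independent cells from a common
initial state, discards an initial buffer period (default 100 generations)
to wash out initial-condition effects, and excludes cells that lost all
active transposons during the buffer.  The first analysis generation is
``buffer + 1``.

Extinction definitions (per generation):

* Alu (``S``) is extinct at the first generation with ``S = 0``; the state
  is absorbing because the insertion reaction needs at least one S copy.
* L1 is extinct at the first generation with ``L = 0`` **and** ``R_L = 0``:
  with machinery still present, the insertion reaction can regenerate L, so
  only the joint zero is absorbing.

Retained cells carry a per-generation pool label: pool 1 (both element
types active, predator-prey regime), pool 2 (L1 active, Alu extinct) and
pool 3 (L1 extinct — replication has stopped for good).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import ModelParameters
from .ssa import Trajectory, simulate_cell

#: Sentinel for "never extinct in the recorded window".
NEVER = np.iinfo(np.int64).max

POOL_BOTH_ACTIVE = 1
POOL_ALU_EXTINCT = 2
POOL_ALL_EXTINCT = 3


def _first_true(mask: np.ndarray) -> np.ndarray:
    """Per-row index of the first True, NEVER where none (mask is 2-D)."""
    any_true = mask.any(axis=1)
    idx = mask.argmax(axis=1).astype(np.int64)
    idx[~any_true] = NEVER
    return idx


def extinction_generation(counts: np.ndarray, species: str) -> np.ndarray:
    """First extinction generation per cell for ``species`` in {"L1","Alu","S2"}.

    ``counts`` has shape (n_cells, generations+1, dim).  Returns NEVER where
    the species survives the whole window.
    """
    if species == "Alu":
        return _first_true(counts[:, :, 1] == 0)
    if species == "L1":
        return _first_true((counts[:, :, 0] == 0) & (counts[:, :, 2] == 0))
    if species == "S2":
        if counts.shape[2] < 4:
            raise ValueError("ensemble has no second predator")
        return _first_true(counts[:, :, 3] == 0)
    raise ValueError(f"unknown species {species!r}; expected 'L1', 'Alu' or 'S2'")


def classify_extinction(traj: Trajectory, species: str) -> int | None:
    """First generation at which ``species`` is extinct in ``traj``, or None.

    L1 counts as extinct only when both ``L`` and ``R_L`` are zero (the
    absorbing set); Alu when ``S`` is zero.
    """
    gen = extinction_generation(traj.counts[None, :, :], species)[0]
    return None if gen == NEVER else int(gen)


@dataclass
class PopulationEnsemble:
    """Retained trajectories of a population run, with pool labels."""

    counts: np.ndarray  # int64, (n_retained, generations+1, dim)
    params: ModelParameters
    buffer: int
    master_seed: int | None
    cell_seeds: np.ndarray | None  # per retained cell, None if unknown
    cell_ids: np.ndarray  # original indices before exclusion
    n_requested: int
    n_excluded: int
    engine: str = "exact"
    _pools: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_generations(self) -> int:
        return self.counts.shape[1] - 1

    @property
    def analysis_start(self) -> int:
        """The first post-buffer generation (the 101st for the reference
        100-generation buffer)."""
        return self.buffer + 1

    @property
    def species_names(self) -> tuple[str, ...]:
        return ("L", "S", "R_L", "S2")[: self.counts.shape[2]]

    def extinction_generations(self, species: str) -> np.ndarray:
        return extinction_generation(self.counts, species)

    @property
    def pool_labels(self) -> np.ndarray:
        """int8 array (n_retained, generations+1): pool of each cell at each
        generation (1 both active, 2 Alu extinct, 3 L1 extinct)."""
        if self._pools is None:
            l1 = self.extinction_generations("L1")
            alu = self.extinction_generations("Alu")
            gens = np.arange(self.counts.shape[1], dtype=np.int64)
            pools = np.full(self.counts.shape[:2], POOL_BOTH_ACTIVE, dtype=np.int8)
            pools[gens[None, :] >= alu[:, None]] = POOL_ALU_EXTINCT
            pools[gens[None, :] >= l1[:, None]] = POOL_ALL_EXTINCT
            self._pools = pools
        return self._pools

    def pool_sizes(self) -> pd.DataFrame:
        """Per-generation cell counts of the three pools."""
        pools = self.pool_labels
        data = {
            "generation": np.arange(self.counts.shape[1]),
            "pool1": (pools == POOL_BOTH_ACTIVE).sum(axis=0),
            "pool2": (pools == POOL_ALU_EXTINCT).sum(axis=0),
            "pool3": (pools == POOL_ALL_EXTINCT).sum(axis=0),
        }
        return pd.DataFrame(data)

    def to_frame(self) -> pd.DataFrame:
        """Long format: cell_id, generation, counts, pool."""
        n, T1, dim = self.counts.shape
        pools = self.pool_labels
        df = pd.DataFrame(
            self.counts.reshape(n * T1, dim), columns=list(self.species_names)
        )
        df.insert(0, "generation", np.tile(np.arange(T1), n))
        df.insert(0, "cell_id", np.repeat(self.cell_ids, T1))
        df["pool"] = pools.reshape(n * T1)
        return df

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        params: ModelParameters,
        buffer: int,
        *,
        master_seed: int | None = None,
        engine: str = "exact",
    ) -> "PopulationEnsemble":
        """Rebuild an ensemble from the long-format table (for re-analysis)."""
        names = [c for c in ("L", "S", "R_L", "S2") if c in df.columns]
        df = df.sort_values(["cell_id", "generation"])
        cell_ids = df["cell_id"].unique()
        T1 = df["generation"].nunique()
        counts = (
            df[names].to_numpy(dtype=np.int64).reshape(len(cell_ids), T1, len(names))
        )
        return cls(
            counts=counts,
            params=params,
            buffer=buffer,
            master_seed=master_seed,
            cell_seeds=None,
            cell_ids=np.asarray(cell_ids),
            n_requested=len(cell_ids),
            n_excluded=0,
            engine=engine,
        )


def spawn_cell_seeds(master_seed: int, n_cells: int) -> np.ndarray:
    """Deterministic 32-bit per-cell seeds derived from the master seed."""
    ss = np.random.SeedSequence(master_seed)
    return np.array(
        [child.generate_state(1)[0] for child in ss.spawn(n_cells)], dtype=np.uint32
    )


def simulate_population(
    params: ModelParameters,
    n_cells: int,
    total_generations: int,
    buffer: int,
    init,
    master_seed: int,
    *,
    engine: str = "exact",
    tau: float = 0.01,
    literal_counts: bool = False,
    literal_exclusion: bool = False,
    progress: bool = False,
) -> PopulationEnsemble:
    """Simulate ``n_cells`` independent cells and apply the exclusion rule.

    The reference protocol uses 3000 cells, a 100-generation buffer and the
    initial state (L, S, R_L) = (250, 250, 100).  Cells that lost all
    active transposons by the end of the buffer (Alu extinct and L1 in its
    absorbing set) are excluded; ``literal_exclusion`` instead applies the
    literal rule L = 0 and S = 0 regardless of remaining machinery.
    """
    if buffer >= total_generations:
        raise ValueError("buffer must be smaller than total_generations")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    seeds = spawn_cell_seeds(master_seed, n_cells)
    trajectories = []
    iterator = range(n_cells)
    if progress:
        from tqdm import tqdm  # pragma: no cover - cosmetic

        iterator = tqdm(iterator, desc="cells")
    for i in iterator:
        trajectories.append(
            simulate_cell(
                params,
                init,
                total_generations,
                int(seeds[i]),
                engine=engine,
                tau=tau,
                literal_counts=literal_counts,
            )
        )
    counts = np.stack([t.counts for t in trajectories])

    end = counts[:, buffer, :]
    if literal_exclusion:
        dead = (end[:, 0] == 0) & (end[:, 1] == 0)
    else:
        l1_dead = (end[:, 0] == 0) & (end[:, 2] == 0)
        s_dead = end[:, 1] == 0
        if params.has_second_predator:
            s_dead &= end[:, 3] == 0
        dead = l1_dead & s_dead
    keep = ~dead
    if not keep.any():
        raise RuntimeError(
            "every cell lost all active transposons during the buffer period; "
            "weaken the competition or shorten the buffer"
        )
    n_excluded = int(dead.sum())
    if n_excluded:
        warnings.warn(
            f"excluded {n_excluded}/{n_cells} cells extinct within the buffer",
            stacklevel=2,
        )
    return PopulationEnsemble(
        counts=counts[keep],
        params=params,
        buffer=buffer,
        master_seed=int(master_seed),
        cell_seeds=seeds[keep],
        cell_ids=np.flatnonzero(keep),
        n_requested=n_cells,
        n_excluded=n_excluded,
        engine=engine,
    )
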