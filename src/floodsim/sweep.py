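"""Replicated factorial sweep over migration fraction, mating penalty and
mating structure.

Each grid cell runs ``n_replicates`` independent seeded replicates and
records the proportion in which both resident alleles (W1 and W2) were lost
by the final generation — the collapse probability. Replicate seeds are
derived from the base seed and the cell's *parameter values* (not grid
indices) through :class:`numpy.random.SeedSequence`, so enlarging or
reordering the grid never perturbs existing cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import run_replicate
from .params import ModelParams

__all__ = [
    "SweepGrid",
    "CellResult",
    "replicate_seed",
    "run_cell",
    "run_sweep",
    "cells_to_dataframe",
    "cells_from_dataframe",
    "heatmap_matrix",
]

logger = logging.getLogger(__name__)

#: Default migration-fraction grid: 0.05 to 0.40 in steps of 0.025.
DEFAULT_M_VALUES = tuple(np.round(np.arange(0.05, 0.4001, 0.025), 4))
DEFAULT_PENALTY_VALUES = (0.0, 0.25, 0.5, 0.75)
DEFAULT_PATERNITY_VALUES = (1, 2, 3)


@dataclass(frozen=True)
class SweepGrid:
    """Factorial design: m x mating_penalty x multiple_paternity_factor."""

    m_values: tuple[float, ...] = DEFAULT_M_VALUES
    penalty_values: tuple[float, ...] = DEFAULT_PENALTY_VALUES
    paternity_values: tuple[int, ...] = DEFAULT_PATERNITY_VALUES
    n_replicates: int = 50
    base_params: ModelParams = field(default_factory=ModelParams)
    base_seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "m_values", tuple(float(v) for v in self.m_values))
        object.__setattr__(
            self, "penalty_values", tuple(float(v) for v in self.penalty_values)
        )
        object.__setattr__(
            self, "paternity_values", tuple(int(v) for v in self.paternity_values)
        )
        ms = self.m_values
        if not ms:
            raise ValueError("m_values must be non-empty")
        if any(not (0 <= v < 1) for v in ms):
            raise ValueError(f"m_values must lie in [0, 1), got {ms}")
        if any(b <= a for a, b in zip(ms, ms[1:])):
            raise ValueError("m_values must be strictly increasing")
        if not self.penalty_values or not self.paternity_values:
            raise ValueError("penalty_values and paternity_values must be non-empty")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @property
    def n_cells(self) -> int:
        return len(self.m_values) * len(self.penalty_values) * len(self.paternity_values)

    def cells(self) -> list[tuple[float, float, int]]:
        """Grid cells in deterministic iteration order."""
        return [
            (m, penalty, paternity)
            for paternity in self.paternity_values
            for penalty in self.penalty_values
            for m in self.m_values
        ]


@dataclass(frozen=True)
class CellResult:
    """Replicate tally for one (m, penalty, paternity) cell.

    ``collapse_probability`` is exactly ``n_collapsed / n_reps``;
    ``n_extinct`` counts replicates whose final population was empty, so
    collapse-by-replacement and collapse-by-extinction stay separable.
    """

    m: float
    penalty: float
    paternity: int
    n_reps: int
    n_collapsed: int
    collapse_generations: tuple[int, ...]
    n_extinct: int

    @property
    def collapse_probability(self) -> float:
        return self.n_collapsed / self.n_reps


def replicate_seed(
    base_seed: int, m: float, penalty: float, paternity: int, replicate: int
) -> int:
    """Stable per-replicate seed from the cell's parameter values.

    The entropy fed to ``SeedSequence`` quantizes m and penalty at 1e-6, so
    the seed depends only on the cell's coordinates and the base seed —
    adding grid points or re-slicing the grid never changes existing cells.
    """
    entropy = (
        int(base_seed) & 0x7FFFFFFF,
        int(round(m * 1_000_000)),
        int(round(penalty * 1_000_000)),
        int(paternity),
        int(replicate),
    )
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31))


def run_cell(
    grid: SweepGrid, m: float, penalty: float, paternity: int
) -> CellResult:
    """Run all replicates of one cell and tally collapse outcomes."""
    n_collapsed = 0
    n_extinct = 0
    collapse_generations: list[int] = []
    for rep in range(grid.n_replicates):
        params = grid.base_params.replace(
            m=m,
            mating_penalty=penalty,
            multiple_paternity_factor=paternity,
            seed=replicate_seed(grid.base_seed, m, penalty, paternity, rep),
        )
        result = run_replicate(params)
        if result.collapsed:
            n_collapsed += 1
            collapse_generations.append(result.collapse_generation)
        if result.extinct:
            n_extinct += 1
    cell = CellResult(
        m=m,
        penalty=penalty,
        paternity=paternity,
        n_reps=grid.n_replicates,
        n_collapsed=n_collapsed,
        collapse_generations=tuple(collapse_generations),
        n_extinct=n_extinct,
    )
    logger.info(
        "cell m=%.3f penalty=%.2f paternity=%d: collapse %d/%d",
        m, penalty, paternity, n_collapsed, grid.n_replicates,
    )
    return cell


def _run_cell_star(args: tuple[SweepGrid, float, float, int]) -> CellResult:
    return run_cell(*args)


def run_sweep(
    grid: SweepGrid, n_jobs: int = 1, progress: bool = False
) -> list[CellResult]:
    """Evaluate every grid cell; order and values are independent of n_jobs.

    Cells are mutually independent (per-cell seeds are value-derived), so
    concurrent evaluation reproduces the serial result exactly.
    """
    cells = grid.cells()
    if not cells:
        raise ValueError("sweep grid is empty")
    iterator: list[tuple[SweepGrid, float, float, int]] = [
        (grid, m, p, t) for (m, p, t) in cells
    ]
    if n_jobs > 1:
        from concurrent.futures import ProcessPoolExecutor

        with ProcessPoolExecutor(max_workers=n_jobs) as pool:
            results = list(pool.map(_run_cell_star, iterator))
    else:
        results = []
        todo = iterator
        if progress:
            try:
                from tqdm import tqdm

                todo = tqdm(iterator, desc="sweep", unit="cell")
            except ImportError:
                pass
        for args in todo:
            results.append(_run_cell_star(args))
    return results


def cells_to_dataframe(results: list[CellResult]) -> pd.DataFrame:
    """Tidy frame, one row per cell (the ``cells.csv`` schema)."""
    return pd.DataFrame(
        {
            "m": [c.m for c in results],
            "penalty": [c.penalty for c in results],
            "paternity": [c.paternity for c in results],
            "n_reps": [c.n_reps for c in results],
            "n_collapsed": [c.n_collapsed for c in results],
            "collapse_probability": [c.collapse_probability for c in results],
            "n_extinct": [c.n_extinct for c in results],
        }
    )


def cells_from_dataframe(frame: pd.DataFrame) -> list[CellResult]:
    """Inverse of :func:`cells_to_dataframe` (collapse generations are not
    serialized; they round-trip as empty)."""
    results = []
    for row in frame.itertuples(index=False):
        results.append(
            CellResult(
                m=float(row.m),
                penalty=float(row.penalty),
                paternity=int(row.paternity),
                n_reps=int(row.n_reps),
                n_collapsed=int(row.n_collapsed),
                collapse_generations=(),
                n_extinct=int(row.n_extinct),
            )
        )
    return results


def heatmap_matrix(results: list[CellResult], paternity: int) -> pd.DataFrame:
    """Dense collapse-probability matrix (rows: penalty, columns: m).

    Requires a complete rectangular (m x penalty) slice at the given
    paternity value; missing cells raise with their coordinates listed.
    """
    slice_ = [c for c in results if c.paternity == paternity]
    if not slice_:
        raise ValueError(f"no cells at paternity={paternity}")
    m_values = sorted({c.m for c in slice_})
    penalties = sorted({c.penalty for c in slice_})
    lookup = {(c.penalty, c.m): c.collapse_probability for c in slice_}
    missing = [
        (p, m) for p in penalties for m in m_values if (p, m) not in lookup
    ]
    if missing:
        raise ValueError(
            f"incomplete grid slice at paternity={paternity}; "
            f"missing (penalty, m) cells: {missing}"
        )
    data = [[lookup[(p, m)] for m in m_values] for p in penalties]
    frame = pd.DataFrame(data, index=penalties, columns=m_values)
    frame.index.name = "penalty"
    frame.columns.name = "m"
    return frame
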