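"""Synthetic input generators: random tables, noisy dose-response data,
parameter-jittered libraries.

Everything is driven by a seeded :class:`numpy.random.Generator`, so any
fixture is bit-reproducible from ``(seed, config)``.  The dose-response
generator mimics flow-cytometry counting: at each concentration the number
of positive cells is binomial with the Hill response as success
probability, matching the percent-positive metric of the transfer-function
measurements (default 10,000 cells per sample).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .library import CellModel, HillParams, LibrarySpec, hill_response
from .truthtable import TruthTable


@dataclass(frozen=True)
class FixtureConfig:
    seed: int = 0
    n: int = 3
    on_density: float = 0.5
    n_cells: int = 10_000
    concentration_grid: tuple[float, ...] = tuple(
        float(x) for x in np.logspace(-1, 3, 12)
    )

    def __post_init__(self):
        if not 0 <= self.on_density <= 1:
            raise ValueError("on_density must be in [0, 1]")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.n < 1:
            raise ValueError("n must be >= 1")


def random_truth_table(config: FixtureConfig) -> TruthTable:
    """Each minterm independently on with probability ``on_density``."""
    rng = np.random.default_rng(config.seed)
    draws = rng.random(1 << config.n) < config.on_density
    names = tuple(f"x{k}" for k in range(config.n))
    on = frozenset(int(m) for m in np.flatnonzero(draws))
    return TruthTable(names, ("f",), {"f": on})


def random_truth_table_named(
    config: FixtureConfig, input_names: tuple[str, ...]
) -> TruthTable:
    """As :func:`random_truth_table` but over given input labels."""
    if len(input_names) != config.n:
        raise ValueError("input name count must match config.n")
    tt = random_truth_table(config)
    return TruthTable(input_names, ("f",), {"f": tt.on_set("f")})


def synthetic_transfer_data(
    params: HillParams, config: FixtureConfig
) -> pd.DataFrame:
    """Binomially noisy percent-positive measurements on a dose grid."""
    rng = np.random.default_rng(config.seed)
    xs = np.asarray(config.concentration_grid, dtype=float)
    p = np.clip(hill_response(params, xs) / 100.0, 0.0, 1.0)
    positives = rng.binomial(config.n_cells, p)
    return pd.DataFrame(
        {
            "concentration": xs,
            "percent_positive": 100.0 * positives / config.n_cells,
            "n_cells": config.n_cells,
        }
    )


def _jitter_params(p: HillParams, jitter: float, rng: np.random.Generator) -> HillParams:
    K = p.K * float(np.exp(rng.normal(0.0, jitter)))
    n = p.n * float(np.exp(rng.normal(0.0, jitter)))
    y_low = float(np.clip(p.y_low + rng.normal(0.0, jitter * max(p.y_low, 1.0)), 0.0, 99.0))
    y_high = float(np.clip(p.y_high + rng.normal(0.0, jitter * p.y_high), y_low + 0.5, 100.0))
    return HillParams(y_low, y_high, K, n, p.mode)


def perturbed_library(lib: LibrarySpec, jitter: float, seed: int) -> LibrarySpec:
    """Multiplicative log-normal jitter on K and n, additive on the floors
    and ceilings (clamped so the library invariants still hold)."""
    if jitter < 0:
        raise ValueError("jitter must be non-negative")
    if jitter == 0:
        return lib
    rng = np.random.default_rng(seed)

    def perturb(cell: CellModel) -> CellModel:
        return replace(cell, params=_jitter_params(cell.params, jitter, rng))

    il_pairs = {
        label: {logic: perturb(cell) for logic, cell in pair.items()}
        for label, pair in lib.il_pairs.items()
    }
    ol_cells = {name: perturb(cell) for name, cell in lib.ol_cells.items()}
    buf = perturb(lib.buf_cell) if lib.buf_cell is not None else None
    return replace(lib, il_pairs=il_pairs, ol_cells=ol_cells, buf_cell=buf)
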