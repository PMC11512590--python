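"""Convergence diagnostics: per-minimum free energies along the simulation.

Reference minima and basins are detected once on the surface reconstructed
from the *full* hill set and held fixed; for every checkpoint (a prefix of
the hill list, spaced by hill count) the prefix surface is rebuilt and the
population-weighted free energy of each fixed basin is re-evaluated.  Stable
profiles indicate (but do not prove) convergence of the free energy
estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fes import DEFAULT_KT, FreeEnergySurface, fes_exact, fes_fast, marginalize, normalize
from .hills_io import Hills, slice_hills
from .minima import BasinAssignment, MinimaSet, basin_populations, find_minima_precise, minima_free_energies

__all__ = ["ConvergenceProfile", "profile", "marginal_evolution", "heights_series", "cv_series"]


@dataclass
class ConvergenceProfile:
    """Per-minimum free energy as a function of simulation progress.

    ``g_by_minimum[k, m]`` is the free energy of reference minimum *m* from
    the first ``checkpoints[k]`` hills, shifted so each row's global minimum
    is 0.  Columns follow ``minima_ref`` order.
    """

    checkpoints: np.ndarray  # hill counts, monotone
    times: np.ndarray  # deposition time of the last hill in each prefix
    g_by_minimum: np.ndarray  # (n_checkpoints, n_minima)
    minima_ref: MinimaSet
    assignment_ref: BasinAssignment

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.g_by_minimum, columns=self.minima_ref.labels)
        df.insert(0, "n_hills", self.checkpoints)
        df.insert(1, "time", self.times)
        return df[["n_hills", "time"] + sorted(self.minima_ref.labels, key=lambda s: (len(s), s))]


def _grid_and_builder(hills: Hills, resolution, fast: bool, scale_biasfactor: bool):
    """Resolve the grid once from the full hill set so all prefixes share it."""
    from .fes import _resolve_grid  # same resolution/range logic as the builders

    res, lo, hi = _resolve_grid(hills, resolution, None, None)
    builder = fes_fast if fast else fes_exact

    def build(h: Hills) -> FreeEnergySurface:
        return builder(h, resolution=res, range_lo=lo, range_hi=hi, scale_biasfactor=scale_biasfactor)

    return build


def profile(
    hills: Hills,
    n_checkpoints: int = 10,
    kT: float = DEFAULT_KT,
    fast: bool = True,
    resolution=None,
    scale_biasfactor: bool = False,
) -> ConvergenceProfile:
    """Track the minima free energies across ``n_checkpoints`` hill-count prefixes.

    Checkpoint *k* uses the first ``ceil(n·k/n_checkpoints)`` hills; the last
    checkpoint is the full simulation.
    """
    if n_checkpoints < 1:
        raise ValueError("n_checkpoints must be at least 1")
    build = _grid_and_builder(hills, resolution, fast, scale_biasfactor)
    full = normalize(build(hills))
    _, assignment = find_minima_precise(full)
    minima_ref = minima_free_energies(full, assignment, kT)
    assignment = BasinAssignment(assignment.owner, assignment.boundary_mask, minima_ref)

    n = hills.n_hills
    counts = sorted({max(1, math.ceil(n * k / n_checkpoints)) for k in range(1, n_checkpoints + 1)})
    rows = []
    times = []
    for c in counts:
        prefix = slice_hills(hills, 0, c)
        surf = build(prefix)
        _, lse = basin_populations(surf, assignment, kT)
        g = -kT * (lse - lse.max())
        rows.append(g)
        times.append(hills.times[c - 1])
    return ConvergenceProfile(
        checkpoints=np.asarray(counts),
        times=np.asarray(times),
        g_by_minimum=np.asarray(rows),
        minima_ref=minima_ref,
        assignment_ref=assignment,
    )


def marginal_evolution(
    hills: Hills,
    keep,
    stages: int = 4,
    kT: float = DEFAULT_KT,
    fast: bool = True,
    resolution=None,
    scale_biasfactor: bool = False,
) -> list[FreeEnergySurface]:
    """Lower-dimensional marginal FES for successive prefix stages.

    Stage *k* (1-based) marginalizes the surface built from the first
    ``ceil(n·k/stages)`` hills down to the ``keep`` dimensions; each marginal
    is normalized.  Useful to see a 1D profile settle as the run proceeds.
    """
    if stages < 1:
        raise ValueError("stages must be at least 1")
    build = _grid_and_builder(hills, resolution, fast, scale_biasfactor)
    n = hills.n_hills
    counts = sorted({max(1, math.ceil(n * k / stages)) for k in range(1, stages + 1)})
    return [marginalize(build(slice_hills(hills, 0, c)), keep, kT) for c in counts]


def heights_series(hills: Hills):
    """Deposition time / hill height pairs, untransformed (for plotting)."""
    return hills.times.copy(), hills.heights.copy()


def cv_series(hills: Hills):
    """Deposition time / CV center pairs, untransformed (for plotting)."""
    return hills.times.copy(), hills.centers.copy()
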