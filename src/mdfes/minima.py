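"""Detection of free-energy minima, basin assignment and state free energies.

A grid node is a local minimum when it is strictly lower than every node in
its full Moore neighborhood (3^d − 1 neighbors, with wrap-around on periodic
CVs; missing neighbors at non-periodic edges count as +∞).  Basins are carved
by steepest descent: every node hops to the lowest node of its closed
neighborhood (ties broken by the smallest row-major index) until a fixed
point is reached.  Boundaries are the nodes with a face neighbor owned by a
different minimum.

The free energy of a metastable state sums Boltzmann probabilities over its
whole basin, ``g_m = −kT ln Σ_{i∈basin m} exp(−F_i/kT)`` (log-sum-exp,
shifted so the most populated state sits at 0), so a wide shallow basin can
outrank a narrow deep one.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .fes import DEFAULT_KT, FreeEnergySurface, normalize

__all__ = [
    "DEFAULT_DIVISIONS",
    "Minimum",
    "MinimaSet",
    "BasinAssignment",
    "find_minima_precise",
    "find_minima_grid",
    "minima_free_energies",
    "basin_populations",
    "label_and_sort",
]

#: default number of coarse-search cells per CV dimension
DEFAULT_DIVISIONS = 8


@dataclass
class Minimum:
    """One local free-energy minimum (a metastable state)."""

    label: str
    grid_index: tuple[int, ...]
    cv_coords: np.ndarray
    depth: float  # FES value at the minimum node on the normalized surface
    g_population: float = float("nan")  # population-weighted free energy


@dataclass
class MinimaSet:
    """An ordered collection of minima.

    The list order is the stable creation order (row-major over the grid);
    labels encode the energetic ranking, see :func:`label_and_sort`.
    """

    minima: list[Minimum] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.minima)

    def __iter__(self):
        return iter(self.minima)

    def __getitem__(self, i) -> Minimum:
        return self.minima[i]

    @property
    def labels(self) -> list[str]:
        return [m.label for m in self.minima]

    def by_label(self, label: str) -> Minimum:
        for m in self.minima:
            if m.label == label:
                return m
        raise KeyError(f"no minimum labelled {label!r}")

    def sorted_by_label(self) -> "MinimaSet":
        return MinimaSet(sorted(self.minima, key=lambda m: (len(m.label), m.label)))

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "label": m.label,
                **{f"cv{j + 1}": c for j, c in enumerate(m.cv_coords)},
                "depth": m.depth,
                "g_population": m.g_population,
            }
            for m in self.sorted_by_label()
        ]
        return pd.DataFrame(rows)


@dataclass
class BasinAssignment:
    """Watershed-by-descent partition of the FES grid.

    ``owner`` holds, for every node, the flat (row-major) index of the grid
    node of its owning minimum — an identifier that is stable under any
    re-ordering of the minima list.  ``boundary_mask`` marks nodes with a
    face neighbor owned by a different minimum.
    """

    owner: np.ndarray
    boundary_mask: np.ndarray
    minima: MinimaSet


def _spreadsheet_label(i: int) -> str:
    """0 → A, 25 → Z, 26 → AA, ..."""
    label = ""
    i += 1
    while i > 0:
        i, r = divmod(i - 1, 26)
        label = chr(ord("A") + r) + label
    return label


def _neighbor_tables(shape, periodic, offsets):
    """Per-offset neighbor flat indices (−1 where missing at an edge)."""
    grids = np.meshgrid(*[np.arange(r) for r in shape], indexing="ij")
    tables = []
    for off in offsets:
        idx = []
        invalid = np.zeros(shape, dtype=bool)
        for j, (g, o) in enumerate(zip(grids, off)):
            gj = g + o
            if periodic[j]:
                gj = np.mod(gj, shape[j])
            else:
                bad = (gj < 0) | (gj >= shape[j])
                invalid |= bad
                gj = np.clip(gj, 0, shape[j] - 1)
            idx.append(gj)
        flat = np.ravel_multi_index(idx, shape)
        flat[invalid] = -1
        tables.append(flat.ravel())
    return np.stack(tables)  # (k, N)


def _moore_offsets(d: int):
    return [off for off in itertools.product((-1, 0, 1), repeat=d) if any(off)]


def _face_offsets(d: int):
    out = []
    for j in range(d):
        for s in (-1, 1):
            off = [0] * d
            off[j] = s
            out.append(tuple(off))
    return out


def _strict_minima_mask(values: np.ndarray, nbr: np.ndarray) -> np.ndarray:
    flat = values.ravel()
    nbr_vals = np.where(nbr >= 0, flat[np.clip(nbr, 0, None)], np.inf)
    return flat < nbr_vals.min(axis=0)


def find_minima_precise(fes: FreeEnergySurface):
    """Locate all strict local minima and partition the grid into their basins.

    Returns ``(MinimaSet, BasinAssignment)``.  Raises on a surface with no
    strict minima (e.g. a constant grid).
    """
    work = normalize(fes)
    values = work.values
    shape = values.shape
    periodic = work.periodic
    flat = values.ravel()
    N = flat.size

    nbr = _neighbor_tables(shape, periodic, _moore_offsets(work.ndim))
    strict = _strict_minima_mask(values, nbr)
    if not strict.any():
        raise ValueError("no strict minima on this surface")

    # steepest descent: hop to the lex-min (value, flat index) of the closed
    # neighborhood; minima are the fixed points
    self_idx = np.arange(N)
    cand_idx = np.vstack([self_idx[None, :], np.where(nbr >= 0, nbr, self_idx[None, :])])
    cand_vals = flat[cand_idx]
    min_vals = cand_vals.min(axis=0)
    nxt = np.where(cand_vals == min_vals[None, :], cand_idx, N).min(axis=0)

    while True:
        nxt2 = nxt[nxt]
        if np.array_equal(nxt2, nxt):
            break
        nxt = nxt2

    minima_nodes = np.flatnonzero(strict)
    # degenerate plateau terminals (exactly tied neighbors): fold each into the
    # nearest strict minimum (Euclidean in index space, smallest index on ties)
    terminals = np.unique(nxt)
    stray = [t for t in terminals if not strict[t]]
    if stray:
        min_coords = np.array(np.unravel_index(minima_nodes, shape)).T
        for t in stray:
            tc = np.array(np.unravel_index(t, shape))
            d2 = ((min_coords - tc) ** 2).sum(axis=1)
            nxt[nxt == t] = minima_nodes[np.argmin(d2)]

    owner = nxt.reshape(shape)

    face = _neighbor_tables(shape, periodic, _face_offsets(work.ndim))
    owner_flat = owner.ravel()
    nbr_owner = np.where(face >= 0, owner_flat[np.clip(face, 0, None)], owner_flat[None, :])
    boundary = (nbr_owner != owner_flat[None, :]).any(axis=0).reshape(shape)

    minima = _make_minima_set(work, minima_nodes)
    return minima, BasinAssignment(owner=owner, boundary_mask=boundary, minima=minima)


def _make_minima_set(work: FreeEnergySurface, nodes: np.ndarray) -> MinimaSet:
    """Build a MinimaSet from flat node indices, provisionally labelled by depth."""
    shape = work.values.shape
    flat = work.values.ravel()
    entries = []
    for node in nodes:
        gi = tuple(int(i) for i in np.unravel_index(node, shape))
        entries.append(
            Minimum(
                label="",
                grid_index=gi,
                cv_coords=work.node_coords(gi),
                depth=float(flat[node]),
            )
        )
    order = np.lexsort((nodes, flat[nodes]))
    for rank, i in enumerate(order):
        entries[i].label = _spreadsheet_label(rank)
    return MinimaSet(entries)


def find_minima_grid(fes: FreeEnergySurface, divisions=None) -> MinimaSet:
    """Coarse-grid minima search.

    The CV range is divided into ``divisions`` cells per dimension (default
    8, i.e. 8, 8 × 8 or 8 × 8 × 8 cells); the lowest node of each cell is
    kept iff it is a strict local minimum of the full-resolution grid, so at
    most ``Π divisions`` minima are returned.
    """
    work = normalize(fes)
    d = work.ndim
    shape = work.values.shape
    div = np.atleast_1d(np.asarray(divisions if divisions is not None else DEFAULT_DIVISIONS, dtype=int))
    if div.size == 1:
        div = np.repeat(div, d)
    if div.size != d or np.any(div < 1):
        raise ValueError("divisions must be >= 1 per dimension")
    if np.any(np.asarray(shape) < div):
        raise ValueError("FES resolution must be at least the number of divisions")

    nbr = _neighbor_tables(shape, work.periodic, _moore_offsets(d))
    strict = _strict_minima_mask(work.values, nbr).reshape(shape)

    edges = [np.floor(np.arange(div[j] + 1) * shape[j] / div[j]).astype(int) for j in range(d)]
    found: list[int] = []
    for cell in itertools.product(*[range(div[j]) for j in range(d)]):
        sl = tuple(slice(edges[j][cell[j]], edges[j][cell[j] + 1]) for j in range(d))
        block = work.values[sl]
        local = np.unravel_index(np.argmin(block), block.shape)
        gi = tuple(edges[j][cell[j]] + local[j] for j in range(d))
        if strict[gi]:
            found.append(int(np.ravel_multi_index(gi, shape)))
    nodes = np.unique(np.asarray(found, dtype=int))
    return _make_minima_set(work, nodes)


def basin_populations(fes: FreeEnergySurface, assignment: BasinAssignment, kT: float = DEFAULT_KT):
    """Boltzmann probability mass of each basin (sums to 1 over minima).

    Returns ``(populations, log_weights)`` aligned with ``assignment.minima``
    order; ``log_weights[m] = ln Σ_{i∈basin m} exp(−F_i/kT)`` (unnormalized).
    """
    if kT <= 0:
        raise ValueError("kT must be positive")
    work = normalize(fes)
    logw = -work.values.ravel() / kT
    owner = assignment.owner.ravel()
    lse = np.empty(len(assignment.minima))
    for i, m in enumerate(assignment.minima):
        node = int(np.ravel_multi_index(m.grid_index, work.values.shape))
        mask = owner == node
        if not mask.any():
            raise ValueError(f"minimum {m.label!r} owns no grid nodes")
        lse[i] = logsumexp(logw[mask])
    total = logsumexp(lse)
    return np.exp(lse - total), lse


def minima_free_energies(
    fes: FreeEnergySurface, assignment: BasinAssignment, kT: float = DEFAULT_KT
) -> MinimaSet:
    """Population-weighted free energies of the minima.

    ``g_m = −kT ln P_m`` with ``P_m`` the summed Boltzmann probability of
    basin *m*, shifted so the most populated state has ``g = 0``.  Returns a
    new MinimaSet (same order as ``assignment.minima``) relabelled in
    ascending ``g``.
    """
    _, lse = basin_populations(fes, assignment, kT)
    g = -kT * (lse - lse.max())
    out = MinimaSet(
        [replace(m, g_population=float(gi)) for m, gi in zip(assignment.minima, g)]
    )
    return label_and_sort(out)


def label_and_sort(minima: MinimaSet) -> MinimaSet:
    """Assign letters A, B, C, … (then AA, AB, …) in ascending ``g_population``.

    Ties are broken by ascending row-major grid index.  The list order is
    preserved (stable creation order); only labels change.
    """
    g = [m.g_population for m in minima]
    if any(np.isnan(gi) for gi in g):
        raise ValueError("g_population must be computed before labelling")
    # grid_index tuple comparison == row-major node order for a common shape
    order = sorted(range(len(minima.minima)), key=lambda i: (g[i], minima[i].grid_index))
    relabelled = [replace(m) for m in minima]
    for rank, i in enumerate(order):
        relabelled[i].label = _spreadsheet_label(rank)
    return MinimaSet(relabelled)
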