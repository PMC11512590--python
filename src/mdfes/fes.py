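"""Free-energy-surface reconstruction from Gaussian hills.

The accumulated metadynamics bias is ``V(s) = Σ_k h_k exp(−Σ_j Δ_jk²/(2σ_jk²))``
with minimum-image displacements on periodic CVs; the free energy estimate is
its negative, ``F(s) = −V(s)``.  Two summation paths are provided:

* :func:`fes_exact` evaluates every Gaussian on the full grid (separable
  per-dimension factors, accumulated through BLAS) — the quantitative path;
* :func:`fes_fast` stamps one precomputed, truncated kernel at the grid node
  nearest each hill center — the fast visualization path, valid when all
  hills of a CV share a single width.

Both paths accumulate hills in a canonical sorted order so that the result is
bit-identical under any permutation of the input hills.

For well-tempered runs Plumed already writes rescaled heights, so by default
heights are summed exactly as stored; ``scale_biasfactor=True`` applies the
γ/(γ−1) factor for files that carry raw deposited heights instead.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import logsumexp

from .hills_io import CVMeta, Hills

__all__ = [
    "DEFAULT_KT",
    "GAS_CONSTANT_KJ",
    "KCAL_PER_KJ",
    "FreeEnergySurface",
    "fes_exact",
    "fes_fast",
    "normalize",
    "fes_add",
    "fes_sub",
    "fes_scale",
    "marginalize",
]

#: gas constant in kJ/mol/K
GAS_CONSTANT_KJ = 0.0083144621
#: thermal energy at 300 K in kJ/mol
DEFAULT_KT = 2.494339
#: kJ → kcal conversion factor
KCAL_PER_KJ = 0.239006

#: fast-path kernel is truncated where the Gaussian exponent exceeds this
KERNEL_CUTOFF_EXPONENT = 6.25


@dataclass
class FreeEnergySurface:
    """Free energy tabulated on a regular grid over the CV ranges.

    For a periodic CV the nodes cover ``[lo, hi)`` (the wrap point appears
    once); for a non-periodic CV both endpoints are nodes.
    """

    values: np.ndarray
    cv_meta: tuple[CVMeta, ...]
    grid_lo: np.ndarray
    grid_hi: np.ndarray
    unit: str = "kJ/mol"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.grid_lo = np.atleast_1d(np.asarray(self.grid_lo, dtype=float))
        self.grid_hi = np.atleast_1d(np.asarray(self.grid_hi, dtype=float))
        d = self.values.ndim
        if len(self.cv_meta) != d or self.grid_lo.size != d or self.grid_hi.size != d:
            raise ValueError("cv_meta / grid bounds inconsistent with values dimensionality")
        if any(r < 2 for r in self.values.shape):
            raise ValueError("grid resolution must be at least 2 per dimension")
        if np.any(self.grid_lo >= self.grid_hi):
            raise ValueError("grid_lo must be strictly below grid_hi")

    # -- geometry -----------------------------------------------------------
    @property
    def ndim(self) -> int:
        return self.values.ndim

    @property
    def resolution(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def periodic(self) -> tuple[bool, ...]:
        return tuple(m.periodic for m in self.cv_meta)

    def spacing(self, dim: int) -> float:
        r = self.values.shape[dim]
        span = self.grid_hi[dim] - self.grid_lo[dim]
        return span / r if self.cv_meta[dim].periodic else span / (r - 1)

    def axis(self, dim: int) -> np.ndarray:
        """Node coordinates along one dimension."""
        return self.grid_lo[dim] + self.spacing(dim) * np.arange(self.values.shape[dim])

    def node_coords(self, index) -> np.ndarray:
        """CV coordinates of a (multi-)index grid node."""
        idx = np.atleast_1d(np.asarray(index))
        return np.array([self.axis(j)[idx[j]] for j in range(self.ndim)])

    def copy(self) -> "FreeEnergySurface":
        return replace(self, values=self.values.copy())

    # -- arithmetic sugar ---------------------------------------------------
    def __add__(self, other):
        return fes_add(self, other)

    def __sub__(self, other):
        return fes_sub(self, other)

    def __mul__(self, c):
        return fes_scale(self, float(c))

    __rmul__ = __mul__


# ---------------------------------------------------------------------------
# grid resolution / range handling
# ---------------------------------------------------------------------------

def _default_resolution(d: int) -> int:
    return 256 if d <= 2 else 64


def _as_dim_array(value, d: int, name: str, dtype=float) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(value, dtype=dtype))
    if arr.size == 1:
        arr = np.repeat(arr, d)
    if arr.size != d:
        raise ValueError(f"{name} must have one entry per dimension (d={d})")
    return arr


def _resolve_grid(hills: Hills, resolution, range_lo, range_hi):
    """Grid bounds: periodic bounds for periodic CVs, hill extent ± 3 mean widths otherwise."""
    d = hills.ndim
    res = _as_dim_array(
        resolution if resolution is not None else _default_resolution(d), d, "resolution", int
    )
    if np.any(res < 2):
        raise ValueError("resolution must be at least 2 per dimension")
    lo = np.empty(d)
    hi = np.empty(d)
    for j, meta in enumerate(hills.cv_meta):
        if meta.periodic:
            lo[j], hi[j] = meta.period_lo, meta.period_hi
        else:
            pad = 3.0 * hills.widths[:, j].mean()
            lo[j] = hills.centers[:, j].min() - pad
            hi[j] = hills.centers[:, j].max() + pad
            if hi[j] <= lo[j]:  # degenerate (all centers equal, tiny widths)
                lo[j] -= 1.0
                hi[j] += 1.0
    if range_lo is not None:
        lo = _as_dim_array(range_lo, d, "range_lo")
    if range_hi is not None:
        hi = _as_dim_array(range_hi, d, "range_hi")
    if np.any(lo >= hi):
        raise ValueError("range_lo must be strictly below range_hi")
    return res, lo, hi


def _axis_nodes(lo, hi, r, periodic):
    step = (hi - lo) / r if periodic else (hi - lo) / (r - 1)
    return lo + step * np.arange(r), step


def _canonical_order(hills: Hills) -> np.ndarray:
    """Permutation-invariant accumulation order (time-major lexicographic)."""
    keys = [hills.heights]
    keys += [hills.widths[:, j] for j in range(hills.ndim - 1, -1, -1)]
    keys += [hills.centers[:, j] for j in range(hills.ndim - 1, -1, -1)]
    keys.append(hills.times)  # primary key
    return np.lexsort(tuple(keys))


def _effective_heights(hills: Hills, scale_biasfactor: bool) -> np.ndarray:
    h = hills.heights
    if scale_biasfactor and hills.biasfactors is not None:
        gamma = hills.biasfactors
        if np.any(gamma <= 1):
            raise ValueError("bias factors must exceed 1 to apply γ/(γ−1) scaling")
        h = h * gamma / (gamma - 1.0)
    return h


def _delta(nodes: np.ndarray, center: float, meta: CVMeta) -> np.ndarray:
    """Displacement node − center, minimum-image on periodic CVs."""
    delta = nodes - center
    if meta.periodic:
        per = meta.period
        delta -= per * np.round(delta / per)
    return delta


# ---------------------------------------------------------------------------
# exact summation
# ---------------------------------------------------------------------------

def fes_exact(
    hills: Hills,
    resolution=None,
    range_lo=None,
    range_hi=None,
    scale_biasfactor: bool = False,
    _chunk: int = 512,
) -> FreeEnergySurface:
    """Reconstruct the FES by explicit evaluation of every Gaussian hill.

    Each hill's Gaussian is separable across dimensions, so the per-dimension
    factors are evaluated once per hill and combined by an outer product; no
    truncation is applied.
    """
    d = hills.ndim
    res, lo, hi = _resolve_grid(hills, resolution, range_lo, range_hi)
    axes = [_axis_nodes(lo[j], hi[j], res[j], hills.cv_meta[j].periodic)[0] for j in range(d)]

    order = _canonical_order(hills)
    centers = hills.centers[order]
    widths = hills.widths[order]
    heights = _effective_heights(hills, scale_biasfactor)[order]
    n = hills.n_hills

    V = np.zeros(tuple(res), dtype=float)
    for start in range(0, n, _chunk):
        sl = slice(start, min(start + _chunk, n))
        m = sl.stop - sl.start
        factors = []
        for j in range(d):
            delta = axes[j][None, :] - centers[sl, j][:, None]
            if hills.cv_meta[j].periodic:
                per = hills.cv_meta[j].period
                delta -= per * np.round(delta / per)
            factors.append(np.exp(-(delta**2) / (2.0 * widths[sl, j][:, None] ** 2)))
        if d == 1:
            V += heights[sl] @ factors[0]
        elif d == 2:
            V += (heights[sl][:, None] * factors[0]).T @ factors[1]
        else:
            V += np.einsum("m,mi,mj,mk->ijk", heights[sl], *factors, optimize=True)
    return FreeEnergySurface(values=-V, cv_meta=hills.cv_meta, grid_lo=lo, grid_hi=hi)


# ---------------------------------------------------------------------------
# fast summation with a precomputed kernel
# ---------------------------------------------------------------------------

def _build_kernel(widths, steps, res, periodic):
    """Truncated Gaussian kernel sampled on the grid spacing.

    Returns (kernel, per-dim target-offset arrays).  Along a periodic
    dimension whose kernel would exceed the grid, the kernel is pre-folded by
    wrapping so that target offsets stay unique.
    """
    d = len(widths)
    offsets = []
    for j in range(d):
        m = int(np.floor(np.sqrt(2.0 * KERNEL_CUTOFF_EXPONENT) * widths[j] / steps[j]))
        offsets.append(np.arange(-m, m + 1))
    exponent = np.zeros(tuple(len(o) for o in offsets))
    for j, off in enumerate(offsets):
        e1 = (off * steps[j]) ** 2 / (2.0 * widths[j] ** 2)
        exponent += e1.reshape((-1,) + (1,) * (d - 1 - j))
    kernel = np.where(exponent <= KERNEL_CUTOFF_EXPONENT, np.exp(-exponent), 0.0)

    for j in range(d):
        if periodic[j] and offsets[j].size > res[j]:
            folded_off = np.arange(res[j])
            shape = list(kernel.shape)
            shape[j] = res[j]
            folded = np.zeros(shape)
            idx = np.mod(offsets[j], res[j])
            for src, dst in enumerate(idx):
                sl_src = [slice(None)] * d
                sl_dst = [slice(None)] * d
                sl_src[j] = src
                sl_dst[j] = dst
                folded[tuple(sl_dst)] += kernel[tuple(sl_src)]
            kernel = folded
            offsets[j] = folded_off
    return kernel, offsets


def fes_fast(
    hills: Hills,
    resolution=None,
    range_lo=None,
    range_hi=None,
    scale_biasfactor: bool = False,
) -> FreeEnergySurface:
    """Reconstruct the FES by stamping one precomputed Gaussian kernel per hill.

    Requires all hills of each CV to share one width (relative tolerance
    1e−6); otherwise a :class:`ValueError` directs the caller to
    :func:`fes_exact`.  Each hill is placed at the grid node nearest its
    center, with wrap-around on periodic CVs; the kernel is truncated where
    the Gaussian exponent exceeds ``KERNEL_CUTOFF_EXPONENT``.
    """
    d = hills.ndim
    for j in range(d):
        w = hills.widths[:, j]
        if (w.max() - w.min()) > 1e-6 * w.mean():
            raise ValueError(
                f"hill widths of CV {hills.cv_names[j]!r} are not constant "
                "(relative spread > 1e-6); use fes_exact for variable widths"
            )
    res, lo, hi = _resolve_grid(hills, resolution, range_lo, range_hi)
    periodic = [m.periodic for m in hills.cv_meta]
    steps = [
        _axis_nodes(lo[j], hi[j], res[j], periodic[j])[1] for j in range(d)
    ]
    widths = hills.widths.mean(axis=0)
    kernel, offsets = _build_kernel(widths, steps, res, periodic)

    order = _canonical_order(hills)
    centers = hills.centers[order]
    heights = _effective_heights(hills, scale_biasfactor)[order]

    V = np.zeros(tuple(res), dtype=float)
    full_kidx = [np.arange(o.size) for o in offsets]
    for h, c in zip(heights, centers):
        target = []
        kidx = []
        skip = False
        for j in range(d):
            node = int(np.round((c[j] - lo[j]) / steps[j]))
            if periodic[j]:
                target.append(np.mod(node + offsets[j], res[j]))
                kidx.append(full_kidx[j])
            else:
                node = min(max(node, 0), res[j] - 1)
                idx = node + offsets[j]
                valid = np.flatnonzero((idx >= 0) & (idx < res[j]))
                if valid.size == 0:
                    skip = True
                    break
                target.append(idx[valid])
                kidx.append(valid)
        if skip:
            continue
        V[np.ix_(*target)] += h * kernel[np.ix_(*kidx)]
    return FreeEnergySurface(values=-V, cv_meta=hills.cv_meta, grid_lo=lo, grid_hi=hi)


# ---------------------------------------------------------------------------
# FES algebra
# ---------------------------------------------------------------------------

def normalize(fes: FreeEnergySurface) -> FreeEnergySurface:
    """Shift the surface so that its global minimum is exactly zero."""
    return replace(fes, values=fes.values - fes.values.min())


def _check_compatible(a: FreeEnergySurface, b: FreeEnergySurface) -> None:
    mismatched = []
    if a.cv_meta != b.cv_meta:
        mismatched.append("cv_meta")
    if a.values.shape != b.values.shape:
        mismatched.append("resolution")
    elif not (np.allclose(a.grid_lo, b.grid_lo) and np.allclose(a.grid_hi, b.grid_hi)):
        mismatched.append("grid range")
    if a.unit != b.unit:
        mismatched.append("unit")
    if mismatched:
        raise ValueError(f"incompatible surfaces; differing: {', '.join(mismatched)}")


def fes_add(a: FreeEnergySurface, b: FreeEnergySurface) -> FreeEnergySurface:
    """Element-wise sum of two surfaces on identical grids."""
    _check_compatible(a, b)
    return replace(a, values=a.values + b.values)


def fes_sub(a: FreeEnergySurface, b: FreeEnergySurface) -> FreeEnergySurface:
    """Element-wise difference of two surfaces on identical grids."""
    _check_compatible(a, b)
    return replace(a, values=a.values - b.values)


def fes_scale(a: FreeEnergySurface, c: float, unit: str | None = None) -> FreeEnergySurface:
    """Multiply a surface by a scalar, optionally relabelling the energy unit.

    E.g. ``fes_scale(f, KCAL_PER_KJ, unit="kcal/mol")`` converts kJ/mol values
    to the kcal/mol scale; the unit tag changes only when the caller sets it.
    """
    out = replace(a, values=a.values * c)
    if unit is not None:
        out.unit = unit
    return out


def marginalize(fes: FreeEnergySurface, keep, kT: float = DEFAULT_KT) -> FreeEnergySurface:
    """Boltzmann-marginalize out the CVs not listed in ``keep``.

    ``F'(s_keep) = −kT ln Σ_removed exp(−F/kT)``, computed with log-sum-exp
    stabilization, then normalized so the minimum is zero.  ``keep`` must be a
    non-empty proper subset of the dimensions; result dimensions follow the
    original dimension order.
    """
    if kT <= 0:
        raise ValueError("kT must be positive")
    keep = sorted(int(k) for k in np.atleast_1d(keep))
    d = fes.ndim
    if not keep or len(keep) >= d or any(k < 0 or k >= d for k in keep) or len(set(keep)) != len(keep):
        raise ValueError("keep must be a non-empty proper subset of dimensions")
    removed = tuple(j for j in range(d) if j not in keep)
    marg = -kT * logsumexp(-fes.values / kT, axis=removed)
    out = FreeEnergySurface(
        values=marg,
        cv_meta=tuple(fes.cv_meta[k] for k in keep),
        grid_lo=fes.grid_lo[keep],
        grid_hi=fes.grid_hi[keep],
        unit=fes.unit,
    )
    return normalize(out)
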