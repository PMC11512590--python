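"""Standard errors of free-energy differences via autocorrelation analysis.

Hill deposition points are CV samples of the biased ensemble; mapping each
to its basin gives per-minimum indicator (occupancy) series.  The integrated
autocorrelation time of such a series converts the sample count into an
effective number of independent samples, from which the standard error of
the basin occupancy — and, by first-order propagation, of the free-energy
difference — follows.

The occupancy series are *unweighted* biased-ensemble indicators: no
reweighting by the bias potential is applied.  For a converged well-tempered
run the biased ensemble is Boltzmann at effective thermal energy γ·kT, so
free-energy differences on the physical scale follow from evaluating
:func:`dg_error` with ``kT_eff = γ·kT``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .fes import DEFAULT_KT, FreeEnergySurface
from .hills_io import Hills
from .minima import BasinAssignment

__all__ = ["SeriesStats", "DeltaGEstimate", "occupancy_series", "autocorr_stats", "dg_error"]


@dataclass(frozen=True)
class SeriesStats:
    """Summary statistics of one (occupancy) time series."""

    n: int
    mean: float
    act: float  # integrated autocorrelation time, in samples (>= 0.5 when estimable)
    n_eff: float  # effective number of independent samples
    se: float  # standard error of the mean
    zero_variance: bool = False


class DeltaGEstimate(NamedTuple):
    dg: float
    se: float


def occupancy_series(hills: Hills, assignment: BasinAssignment, fes: FreeEnergySurface):
    """Per-minimum binary occupancy series of the hill deposition points.

    Each hill center is snapped to its nearest grid node of ``fes`` and
    assigned to that node's basin; row *m* of the returned ``(n_minima,
    n_hills)`` array is 1 where the sample falls in basin *m*.  Centers
    outside a non-periodic grid range are clamped to the edge node (noted in
    the returned warnings list).

    Returns ``(series, warnings)``.
    """
    d = fes.ndim
    shape = fes.values.shape
    warnings: list[str] = []
    idx = []
    for j in range(d):
        t = np.round((hills.centers[:, j] - fes.grid_lo[j]) / fes.spacing(j)).astype(int)
        if fes.cv_meta[j].periodic:
            t = np.mod(t, shape[j])
        else:
            out = (t < 0) | (t >= shape[j])
            if out.any():
                warnings.append(
                    f"{int(out.sum())} hill centers outside the grid range of CV "
                    f"{fes.cv_meta[j].name!r}; clamped to the edge node"
                )
            t = np.clip(t, 0, shape[j] - 1)
        idx.append(t)
    nodes = np.ravel_multi_index(idx, shape)
    owner = assignment.owner.ravel()[nodes]

    series = np.zeros((len(assignment.minima), hills.n_hills))
    for m, minimum in enumerate(assignment.minima):
        node = int(np.ravel_multi_index(minimum.grid_index, shape))
        series[m] = owner == node
    return series, warnings


def _autocovariance(x: np.ndarray) -> np.ndarray:
    """Biased (1/n) autocovariance via FFT."""
    n = x.size
    xc = x - x.mean()
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conjugate(f), nfft)[:n]
    return acov / n


def autocorr_stats(series, maxlag: int | None = None) -> SeriesStats:
    """Integrated autocorrelation time and correlation-adjusted standard error.

    Uses the initial-positive-sequence truncation: successive pairs of
    autocorrelations ``ρ(2j−1)+ρ(2j)`` are summed while positive, giving
    ``act = 1/2 + Σ ρ(k)``; then ``n_eff = n/(2·act)`` and
    ``se = sd/√n_eff``.  A zero-variance series is flagged with ``se = 0``.
    """
    x = np.asarray(series, dtype=float).ravel()
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 samples")
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        return SeriesStats(n=n, mean=float(x.mean()), act=math.nan, n_eff=math.nan, se=0.0, zero_variance=True)

    acov = _autocovariance(x)
    rho = acov / acov[0]
    L = n - 1 if maxlag is None else min(maxlag, n - 1)
    total = 0.0
    k = 1
    while k + 1 <= L:
        pair = rho[k] + rho[k + 1]
        if pair <= 0.0:
            break
        total += pair
        k += 2
    act = 0.5 + total
    n_eff = n / (2.0 * act)
    return SeriesStats(n=n, mean=float(x.mean()), act=float(act), n_eff=float(n_eff), se=float(sd / math.sqrt(n_eff)))


def dg_error(stats_a: SeriesStats, stats_b: SeriesStats, kT: float = DEFAULT_KT) -> DeltaGEstimate:
    """Free-energy difference between two states from their occupancies.

    ``ΔG = −kT ln(p_a/p_b)`` with first-order error propagation
    ``SE = kT·√((se_a/p_a)² + (se_b/p_b)²)``.  Occupancy means must lie
    strictly inside (0, 1); a basin that was never (or always) visited makes
    the difference not estimable.
    """
    if kT <= 0:
        raise ValueError("kT must be positive")
    for s in (stats_a, stats_b):
        if not (0.0 < s.mean < 1.0):
            raise ValueError(
                f"occupancy mean {s.mean} outside (0, 1): free-energy difference not estimable"
            )
    dg = -kT * math.log(stats_a.mean / stats_b.mean)
    se = kT * math.hypot(stats_a.se / stats_a.mean, stats_b.se / stats_b.mean)
    return DeltaGEstimate(dg=dg, se=se)
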