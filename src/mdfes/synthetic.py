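"""Ground-truth metadynamics fixtures on analytic potentials.

Overdamped (position-only) Langevin dynamics is integrated with the
Euler–Maruyama scheme on an analytic potential plus the accumulating
metadynamics bias:

    s_{t+1} = s_t − dt·∇[U(s_t) + V_bias(s_t)] + √(2·kT·dt)·ξ_t

where ``dt`` is the friction-scaled timestep (mobility × timestep, units
CV²·mol/kJ per step) and ξ is unit Gaussian noise.  Every ``stride`` steps a
hill is deposited — height ``w`` for standard metadynamics, or
``w·exp(−V_bias(s)/((γ−1)kT))`` for well-tempered runs with bias factor γ.
The heights recorded in the emitted HILLS file are the actually deposited
(already tempered) heights, so ``−Σ hills`` reconstructs the bias potential
itself; see the fes module for the γ/(γ−1) rescaling switch.

This is a deliberately minimal stand-in for a molecular dynamics engine: it
exercises every analysis path with a known free energy surface (the analytic
potential itself) but has trivial kinetics and a one-to-one CV↔coordinate
mapping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable

import numpy as np

from .fes import DEFAULT_KT, FreeEnergySurface, normalize
from .hills_io import CVMeta, Hills

__all__ = ["Potential", "POTENTIALS", "SimSpec", "default_spec", "simulate", "analytic_fes"]


@dataclass(frozen=True)
class Potential:
    """An analytic potential with its CV metadata and simulation domain."""

    name: str
    ndim: int
    cv_meta: tuple[CVMeta, ...]
    domain_lo: tuple[float, ...]
    domain_hi: tuple[float, ...]
    energy: Callable[[np.ndarray], np.ndarray]
    gradient: Callable[[np.ndarray], np.ndarray]


def _dw_energy(x):
    x = np.asarray(x, dtype=float)
    return 10.0 * (x[..., 0] ** 2 - 1.0) ** 2 + 1.25 * x[..., 0]


def _dw_gradient(x):
    x = np.asarray(x, dtype=float)
    return np.stack([40.0 * x[..., 0] * (x[..., 0] ** 2 - 1.0) + 1.25], axis=-1)


def _fw_energy(x):
    x = np.asarray(x, dtype=float)
    return (
        5.0 * (x[..., 0] ** 2 - 1.0) ** 2
        + 5.0 * (x[..., 1] ** 2 - 1.0) ** 2
        + 0.8 * x[..., 0]
        + 0.4 * x[..., 1]
    )


def _fw_gradient(x):
    x = np.asarray(x, dtype=float)
    return np.stack(
        [
            20.0 * x[..., 0] * (x[..., 0] ** 2 - 1.0) + 0.8,
            20.0 * x[..., 1] * (x[..., 1] ** 2 - 1.0) + 0.4,
        ],
        axis=-1,
    )


def _cos_energy(x):
    x = np.asarray(x, dtype=float)
    return DEFAULT_KT * (1.0 - np.cos(x[..., 0]))


def _cos_gradient(x):
    x = np.asarray(x, dtype=float)
    return np.stack([DEFAULT_KT * np.sin(x[..., 0])], axis=-1)


POTENTIALS: dict[str, Potential] = {
    "double_well_1d": Potential(
        name="double_well_1d",
        ndim=1,
        cv_meta=(CVMeta("x"),),
        domain_lo=(-2.5,),
        domain_hi=(2.5,),
        energy=_dw_energy,
        gradient=_dw_gradient,
    ),
    "four_well_2d": Potential(
        name="four_well_2d",
        ndim=2,
        cv_meta=(CVMeta("x"), CVMeta("y")),
        domain_lo=(-2.5, -2.5),
        domain_hi=(2.5, 2.5),
        energy=_fw_energy,
        gradient=_fw_gradient,
    ),
    "periodic_cosine_1d": Potential(
        name="periodic_cosine_1d",
        ndim=1,
        cv_meta=(CVMeta("phi", periodic=True, period_lo=-math.pi, period_hi=math.pi),),
        domain_lo=(-math.pi,),
        domain_hi=(math.pi,),
        energy=_cos_energy,
        gradient=_cos_gradient,
    ),
}

# study defaults per potential: (dt, n_steps, stride, height, width, biasfactor, x0)
_DEFAULTS = {
    "double_well_1d": (2e-3, 50_000, 150, 0.15, (0.12,), 10.0, (-1.0,)),
    "four_well_2d": (5e-4, 50_000, 5, 0.8, (0.2, 0.2), 10.0, (-1.0, -1.0)),
    "periodic_cosine_1d": (2e-3, 100_000, 100, 0.5, (0.3,), None, (0.0,)),
}


@dataclass
class SimSpec:
    """Parameters of one synthetic metadynamics run.

    ``height`` may be zero (unbiased Brownian dynamics); every other numeric
    parameter must be positive, and ``biasfactor`` (when set) must exceed 1.
    """

    potential: str
    kT: float = DEFAULT_KT
    dt: float = 2e-4
    n_steps: int = 50_000
    stride: int = 50
    height: float = 1.0
    width: tuple[float, ...] = (0.15,)
    biasfactor: float | None = None
    seed: int = 1
    x0: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.potential not in POTENTIALS:
            raise ValueError(f"unknown potential {self.potential!r}")
        pot = POTENTIALS[self.potential]
        self.width = tuple(float(w) for w in np.atleast_1d(self.width))
        if len(self.width) == 1 and pot.ndim > 1:
            self.width = self.width * pot.ndim
        if len(self.width) != pot.ndim:
            raise ValueError("width must have one entry per CV")
        if self.kT <= 0 or self.dt <= 0 or self.n_steps <= 0 or self.stride <= 0:
            raise ValueError("kT, dt, n_steps and stride must be positive")
        if self.height < 0 or any(w <= 0 for w in self.width):
            raise ValueError("height must be >= 0 and widths > 0")
        if self.biasfactor is not None and self.biasfactor <= 1:
            raise ValueError("biasfactor must exceed 1")
        if self.x0 is not None and len(self.x0) != pot.ndim:
            raise ValueError("x0 must have one entry per CV")


def default_spec(potential: str, **overrides) -> SimSpec:
    """The study conditions for a named potential, with optional overrides."""
    dt, n_steps, stride, height, width, gamma, x0 = _DEFAULTS[potential]
    spec = SimSpec(
        potential=potential,
        dt=dt,
        n_steps=n_steps,
        stride=stride,
        height=height,
        width=width,
        biasfactor=gamma,
        x0=x0,
    )
    return replace(spec, **overrides) if overrides else spec


# bias grid resolution used during simulation (per dimension)
_BIAS_RES = {1: 2048, 2: 256}


class _BiasGrid:
    """Running metadynamics bias tabulated on a fine grid.

    Hills are stamped at the node nearest the deposition point (same
    truncated-kernel scheme as the fast FES path); the force is the exact
    gradient of the multilinear interpolant of the tabulated bias.
    """

    def __init__(self, pot: Potential, width, margin: float = 0.6):
        d = pot.ndim
        self.periodic = tuple(m.periodic for m in pot.cv_meta)
        self.lo = np.array(
            [pot.domain_lo[j] - (0.0 if self.periodic[j] else margin) for j in range(d)]
        )
        self.hi = np.array(
            [pot.domain_hi[j] + (0.0 if self.periodic[j] else margin) for j in range(d)]
        )
        res = _BIAS_RES[d]
        self.res = np.full(d, res, dtype=int)
        self.step = np.array(
            [
                (self.hi[j] - self.lo[j]) / (self.res[j] if self.periodic[j] else self.res[j] - 1)
                for j in range(d)
            ]
        )
        self.V = np.zeros(tuple(self.res))
        self.d = d
        # truncated kernel on the bias grid spacing
        self._koffsets = []
        for j in range(d):
            m = int(np.floor(3.6 * width[j] / self.step[j]))
            self._koffsets.append(np.arange(-m, m + 1))
        exponent = np.zeros(tuple(o.size for o in self._koffsets))
        for j, off in enumerate(self._koffsets):
            e1 = (off * self.step[j]) ** 2 / (2.0 * width[j] ** 2)
            exponent += e1.reshape((-1,) + (1,) * (d - 1 - j))
        self._kernel = np.exp(-exponent)

    def deposit(self, x: np.ndarray, h: float) -> None:
        target, kidx = [], []
        for j in range(self.d):
            node = int(np.round((x[j] - self.lo[j]) / self.step[j]))
            off = self._koffsets[j]
            if self.periodic[j]:
                target.append(np.mod(node + off, self.res[j]))
                kidx.append(np.arange(off.size))
            else:
                idx = node + off
                valid = np.flatnonzero((idx >= 0) & (idx < self.res[j]))
                target.append(idx[valid])
                kidx.append(valid)
        self.V[np.ix_(*target)] += h * self._kernel[np.ix_(*kidx)]

    def _cell(self, x):
        idx, frac = [], []
        for j in range(self.d):
            t = (x[j] - self.lo[j]) / self.step[j]
            i = int(np.floor(t))
            if self.periodic[j]:
                i %= self.res[j]
                frac.append(t - np.floor(t))
            else:
                i = min(max(i, 0), self.res[j] - 2)
                frac.append(min(max(t - i, 0.0), 1.0))
            idx.append(i)
        return idx, frac

    def value(self, x: np.ndarray) -> float:
        idx, frac = self._cell(x)
        if self.d == 1:
            i, f = idx[0], frac[0]
            i1 = (i + 1) % self.res[0] if self.periodic[0] else i + 1
            return (1 - f) * self.V[i] + f * self.V[i1]
        (i, k), (fx, fy) = idx, frac
        i1 = (i + 1) % self.res[0] if self.periodic[0] else i + 1
        k1 = (k + 1) % self.res[1] if self.periodic[1] else k + 1
        return (
            self.V[i, k] * (1 - fx) * (1 - fy)
            + self.V[i1, k] * fx * (1 - fy)
            + self.V[i, k1] * (1 - fx) * fy
            + self.V[i1, k1] * fx * fy
        )

    def gradient(self, x: np.ndarray) -> np.ndarray:
        idx, frac = self._cell(x)
        if self.d == 1:
            i = idx[0]
            i1 = (i + 1) % self.res[0] if self.periodic[0] else i + 1
            return np.array([(self.V[i1] - self.V[i]) / self.step[0]])
        (i, k), (fx, fy) = idx, frac
        i1 = (i + 1) % self.res[0] if self.periodic[0] else i + 1
        k1 = (k + 1) % self.res[1] if self.periodic[1] else k + 1
        v00, v10, v01, v11 = self.V[i, k], self.V[i1, k], self.V[i, k1], self.V[i1, k1]
        gx = ((v10 - v00) * (1 - fy) + (v11 - v01) * fy) / self.step[0]
        gy = ((v01 - v00) * (1 - fx) + (v11 - v10) * fx) / self.step[1]
        return np.array([gx, gy])


def simulate(spec: SimSpec):
    """Run one synthetic metadynamics trajectory.

    Returns ``(hills, trajectory)`` where ``trajectory`` has shape
    ``(n_steps + 1, d)``.  Fully deterministic for a fixed seed.  Aborts with
    a diagnostic if the walker leaves ten times the simulation range.
    """
    pot = POTENTIALS[spec.potential]
    d = pot.ndim
    rng = np.random.default_rng(spec.seed)
    noise = rng.standard_normal((spec.n_steps, d)) * math.sqrt(2.0 * spec.kT * spec.dt)

    bias = _BiasGrid(pot, spec.width)
    lo = np.asarray(pot.domain_lo)
    hi = np.asarray(pot.domain_hi)
    span = hi - lo
    center = 0.5 * (lo + hi)
    periodic = np.asarray(bias.periodic)

    x = np.array(spec.x0 if spec.x0 is not None else center, dtype=float)
    traj = np.empty((spec.n_steps + 1, d))
    traj[0] = x

    times, centers, heights = [], [], []
    for t in range(spec.n_steps):
        force = -(pot.gradient(x) + bias.gradient(x))
        x = x + spec.dt * force + noise[t]
        if periodic.any():
            x = np.where(periodic, lo + np.mod(x - lo, span), x)
        if np.any(np.abs(x - center) > 10.0 * span):
            raise RuntimeError(
                f"trajectory diverged at step {t + 1}: position {x} left 10x the "
                f"simulation range of potential {spec.potential!r}; reduce dt"
            )
        traj[t + 1] = x
        if (t + 1) % spec.stride == 0:
            if spec.biasfactor is None:
                h = spec.height
            else:
                h = spec.height * math.exp(
                    -bias.value(x) / ((spec.biasfactor - 1.0) * spec.kT)
                )
            if h > 0.0:
                bias.deposit(x, h)
            times.append(float(t + 1))
            centers.append(x.copy())
            heights.append(h)

    hills = Hills(
        times=np.array(times),
        centers=np.array(centers),
        widths=np.tile(np.asarray(spec.width), (len(times), 1)),
        heights=np.array(heights),
        biasfactors=None
        if spec.biasfactor is None
        else np.full(len(times), float(spec.biasfactor)),
        cv_meta=pot.cv_meta,
    )
    return hills, traj


def analytic_fes(spec: SimSpec | str, resolution=256, range_lo=None, range_hi=None) -> FreeEnergySurface:
    """Tabulate the analytic potential on a grid as a normalized reference FES."""
    name = spec.potential if isinstance(spec, SimSpec) else spec
    pot = POTENTIALS[name]
    d = pot.ndim
    res = np.atleast_1d(np.asarray(resolution, dtype=int))
    if res.size == 1:
        res = np.repeat(res, d)
    lo = np.asarray(range_lo if range_lo is not None else pot.domain_lo, dtype=float)
    hi = np.asarray(range_hi if range_hi is not None else pot.domain_hi, dtype=float)
    axes = []
    for j in range(d):
        step = (hi[j] - lo[j]) / (res[j] if pot.cv_meta[j].periodic else res[j] - 1)
        axes.append(lo[j] + step * np.arange(res[j]))
    mesh = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    values = pot.energy(mesh)
    return normalize(
        FreeEnergySurface(values=values, cv_meta=pot.cv_meta, grid_lo=lo, grid_hi=hi)
    )
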