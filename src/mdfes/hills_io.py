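"""Reading, writing and slicing of Plumed-dialect HILLS files.

A HILLS file is whitespace-separated text.  The first non-blank line must be a
``#! FIELDS`` header naming the columns; optional ``#! SET min_<cv>`` /
``#! SET max_<cv>`` lines declare the periodic range of a collective variable
(CV).  A CV column is recognised by the presence of a matching ``sigma_<cv>``
width column; every hill row then carries deposition time, CV centers, per-CV
Gaussian widths, the hill height and, for well-tempered runs, the bias factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CVMeta",
    "Hills",
    "HillsFormatError",
    "read_hills",
    "write_hills",
    "slice_hills",
]

#: significant digits used when writing numbers (survives read/write round trips)
_FMT = "{: .8e}"


class HillsFormatError(ValueError):
    """Raised when a HILLS (or derived text) file violates the dialect."""


@dataclass(frozen=True)
class CVMeta:
    """Metadata for one collective variable.

    ``period_lo``/``period_hi`` are meaningful only when ``periodic`` is True.
    """

    name: str
    periodic: bool = False
    period_lo: float | None = None
    period_hi: float | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("CV name must be non-empty")
        if self.periodic:
            if self.period_lo is None or self.period_hi is None:
                raise ValueError(f"periodic CV {self.name!r} needs period_lo/period_hi")
            if not self.period_hi > self.period_lo:
                raise ValueError(f"periodic CV {self.name!r}: period_hi must exceed period_lo")

    @property
    def period(self) -> float:
        if not self.periodic:
            raise ValueError(f"CV {self.name!r} is not periodic")
        return self.period_hi - self.period_lo


@dataclass
class Hills:
    """A set of deposited Gaussian hills plus CV metadata.

    Arrays are aligned on the hill index: ``times`` (ps), ``centers`` and
    ``widths`` of shape ``(n, d)`` in CV units (widths are the Gaussian
    sigmas), ``heights`` in energy units (kJ/mol by convention) and, when the
    run was well-tempered, per-hill ``biasfactors``.  Centers of periodic CVs
    are canonically wrapped into ``[period_lo, period_hi)`` on construction.
    """

    times: np.ndarray
    centers: np.ndarray
    widths: np.ndarray
    heights: np.ndarray
    biasfactors: np.ndarray | None = None
    cv_meta: tuple[CVMeta, ...] = ()
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if self.centers.shape[0] != self.times.size and self.centers.shape[1] == self.times.size:
            self.centers = self.centers.T
        self.widths = np.atleast_2d(np.asarray(self.widths, dtype=float))
        if self.widths.shape[0] != self.times.size and self.widths.shape[1] == self.times.size:
            self.widths = self.widths.T
        self.heights = np.asarray(self.heights, dtype=float)
        if self.biasfactors is not None:
            self.biasfactors = np.asarray(self.biasfactors, dtype=float)

        n = self.times.size
        if n == 0:
            raise ValueError("a Hills set must contain at least one hill")
        d = self.centers.shape[1]
        if d not in (1, 2, 3):
            raise ValueError(f"dimensionality d={d} unsupported (must be 1, 2 or 3)")
        if self.centers.shape != (n, d) or self.widths.shape != (n, d):
            raise ValueError("times, centers and widths have inconsistent shapes")
        if self.heights.shape != (n,):
            raise ValueError("heights must have one value per hill")
        if self.biasfactors is not None and self.biasfactors.shape != (n,):
            raise ValueError("biasfactors must have one value per hill")
        if not np.all(self.widths > 0):
            raise ValueError("all hill widths must be strictly positive")
        if not self.cv_meta:
            self.cv_meta = tuple(CVMeta(f"cv{j + 1}") for j in range(d))
        if len(self.cv_meta) != d:
            raise ValueError("cv_meta length must match dimensionality")
        names = [m.name for m in self.cv_meta]
        if len(set(names)) != len(names):
            raise ValueError("CV names must be unique")
        # canonical wrap of periodic centers into [lo, hi)
        for j, meta in enumerate(self.cv_meta):
            if meta.periodic:
                lo, per = meta.period_lo, meta.period
                self.centers[:, j] = lo + np.mod(self.centers[:, j] - lo, per)

    @property
    def n_hills(self) -> int:
        return self.times.size

    @property
    def ndim(self) -> int:
        return self.centers.shape[1]

    @property
    def cv_names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.cv_meta)


def _parse_set_value(token: str) -> float:
    """Parse a SET header value; 'pi' tokens map to ±π at double precision."""
    t = token.strip().replace("−", "-")  # unicode minus
    if t == "pi":
        return math.pi
    if t == "-pi":
        return -math.pi
    try:
        return float(t)
    except ValueError as exc:
        raise HillsFormatError(f"cannot parse SET value {token!r}") from exc


def read_hills(path) -> Hills:
    """Read a Plumed-dialect HILLS file.

    CV columns are those with a matching ``sigma_<name>`` column; any other
    column that is not ``time``, ``height`` or ``biasf`` is ignored with a
    warning.  Repeated ``#!`` header blocks (simulation restarts) are skipped
    and the data rows concatenated; rows whose time does not increase are kept
    and flagged in ``Hills.warnings``.
    """
    with open(path) as fh:
        lines = fh.readlines()

    fields: list[str] | None = None
    set_lo: dict[str, float] = {}
    set_hi: dict[str, float] = {}
    rows: list[list[float]] = []
    warnings: list[str] = []
    seen_header = False

    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#!"):
            tokens = line[2:].split()
            if not tokens:
                continue
            if tokens[0] == "FIELDS":
                if fields is None:
                    fields = tokens[1:]
                # restart-duplicated headers are skipped
                continue
            if tokens[0] == "SET" and len(tokens) >= 3 and not seen_header:
                key, val = tokens[1], tokens[2]
                if key.startswith("min_"):
                    set_lo[key[4:]] = _parse_set_value(val)
                elif key.startswith("max_"):
                    set_hi[key[4:]] = _parse_set_value(val)
            continue
        if line.startswith("#"):
            continue
        if fields is None:
            raise HillsFormatError(f"{path}: first non-blank line must be a '#! FIELDS' header")
        seen_header = True
        parts = line.split()
        if len(parts) != len(fields):
            raise HillsFormatError(
                f"{path}:{lineno}: row has {len(parts)} columns, header declares {len(fields)}"
            )
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise HillsFormatError(f"{path}:{lineno}: non-numeric value in data row") from exc

    if fields is None:
        raise HillsFormatError(f"{path}: missing '#! FIELDS' header")
    if not rows:
        raise HillsFormatError(f"{path}: no data rows")

    col = {name: i for i, name in enumerate(fields)}
    if "time" not in col:
        raise HillsFormatError(f"{path}: no 'time' column in FIELDS")
    if "height" not in col:
        raise HillsFormatError(f"{path}: no 'height' column in FIELDS")

    cv_names = [f for f in fields if f"sigma_{f}" in col]
    if not cv_names:
        raise HillsFormatError(f"{path}: no CV columns (need matching sigma_<cv> columns)")
    recognised = {"time", "height", "biasf"} | set(cv_names) | {f"sigma_{c}" for c in cv_names}
    for f in fields:
        if f not in recognised:
            warnings.append(f"ignoring unrecognised column {f!r}")

    data = np.asarray(rows, dtype=float)
    times = data[:, col["time"]]
    bad = np.flatnonzero(np.diff(times) <= 0)
    for i in bad:
        warnings.append(f"non-increasing time at data row {i + 2} (restart overlap?)")

    meta = []
    for name in cv_names:
        periodic = name in set_lo and name in set_hi
        meta.append(
            CVMeta(
                name,
                periodic=periodic,
                period_lo=set_lo[name] if periodic else None,
                period_hi=set_hi[name] if periodic else None,
            )
        )

    return Hills(
        times=times,
        centers=data[:, [col[c] for c in cv_names]],
        widths=data[:, [col[f"sigma_{c}"] for c in cv_names]],
        heights=data[:, col["height"]],
        biasfactors=data[:, col["biasf"]] if "biasf" in col else None,
        cv_meta=tuple(meta),
        warnings=warnings,
    )


def write_hills(hills: Hills, path) -> None:
    """Write ``hills`` as a Plumed-dialect HILLS file (9 significant digits)."""
    names = hills.cv_names
    cols = ["time", *names, *(f"sigma_{c}" for c in names), "height"]
    if hills.biasfactors is not None:
        cols.append("biasf")
    out = ["#! FIELDS " + " ".join(cols)]
    for meta in hills.cv_meta:
        if meta.periodic:
            out.append(f"#! SET min_{meta.name} {_FMT.format(meta.period_lo).strip()}")
            out.append(f"#! SET max_{meta.name} {_FMT.format(meta.period_hi).strip()}")
    body = np.column_stack(
        [hills.times, hills.centers, hills.widths, hills.heights]
        + ([hills.biasfactors] if hills.biasfactors is not None else [])
    )
    for row in body:
        out.append(" ".join(_FMT.format(v) for v in row))
    with open(path, "w") as fh:
        fh.write("\n".join(out) + "\n")


def slice_hills(hills: Hills, first: int, last: int) -> Hills:
    """Contiguous subset of hills over the half-open, 0-based range [first, last)."""
    if not (0 <= first < last <= hills.n_hills):
        raise IndexError(
            f"slice [{first}, {last}) out of range for {hills.n_hills} hills"
        )
    return Hills(
        times=hills.times[first:last].copy(),
        centers=hills.centers[first:last].copy(),
        widths=hills.widths[first:last].copy(),
        heights=hills.heights[first:last].copy(),
        biasfactors=None if hills.biasfactors is None else hills.biasfactors[first:last].copy(),
        cv_meta=hills.cv_meta,
        warnings=list(hills.warnings),
    )
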