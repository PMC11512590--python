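"""FES plots (1D line / 2D filled contour) and plain-text grid round trips.

Minima letters are drawn directly on the surface; on 2D maps the letter
color flips between black and white according to the relative luminance of
the underlying fill color (Rec. 709 coefficients, threshold 0.5, ties going
to black) so labels stay readable on any colormap.  Basin boundaries are
overlaid as dotted node markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fes import FreeEnergySurface
from .minima import BasinAssignment, MinimaSet

__all__ = ["PlotStyle", "GridFormatError", "letter_color", "plot_fes", "export_grid", "import_grid"]

_FMT = "{: .8e}"


class GridFormatError(ValueError):
    """Raised for malformed text-grid files."""


@dataclass
class PlotStyle:
    """Customisable plot appearance."""

    colormap: str = "viridis"
    levels: list[float] | None = None  # explicit contour isovalues; None = every 10 energy units
    label_color: str = "auto"  # "auto" | fixed matplotlib color
    xlabel: str | None = None  # None = CV name from the HILLS header
    ylabel: str | None = None
    dpi: int = 150
    figsize: tuple[float, float] = (6.0, 5.0)

    def __post_init__(self) -> None:
        if self.levels is not None:
            lv = list(self.levels)
            if any(b <= a for a, b in zip(lv, lv[1:])):
                raise ValueError("explicit contour levels must be strictly increasing")


def letter_color(rgb) -> str:
    """Label color for a given background color: white on dark, black on light."""
    r, g, b = rgb[:3]
    luminance = 0.2126 * r + 0.7152 * g + 0.0722 * b
    return "white" if luminance < 0.5 else "black"


def _auto_levels(values: np.ndarray, spacing: float = 10.0) -> np.ndarray:
    vmin, vmax = float(values.min()), float(values.max())
    levels = np.arange(np.floor(vmin / spacing) * spacing, vmax, spacing)
    levels = levels[(levels > vmin) & (levels < vmax)]
    if levels.size == 0:
        levels = np.linspace(vmin, vmax, 6)[1:-1]
    return levels


def plot_fes(
    fes: FreeEnergySurface,
    minima: MinimaSet | None = None,
    assignment: BasinAssignment | None = None,
    style: PlotStyle | None = None,
    path=None,
):
    """Render a 1D or 2D free energy surface; returns the matplotlib Figure.

    When ``path`` is given the figure is also saved (PNG/SVG/PDF by
    extension) and closed.  Inputs are never mutated.
    """
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib import colors

    style = style or PlotStyle()
    d = fes.ndim
    if d not in (1, 2):
        raise ValueError("plot_fes supports 1D and 2D surfaces only")

    fig, ax = plt.subplots(figsize=style.figsize)
    xlab = style.xlabel if style.xlabel is not None else fes.cv_meta[0].name

    if d == 1:
        x = fes.axis(0)
        ax.plot(x, fes.values, lw=1.5)
        ax.set_xlabel(xlab)
        ax.set_ylabel(f"free energy ({fes.unit})")
        if minima is not None:
            span = fes.values.max() - fes.values.min()
            for m in minima:
                ax.annotate(
                    m.label,
                    (m.cv_coords[0], m.depth + 0.03 * span),
                    ha="center",
                    color="black" if style.label_color == "auto" else style.label_color,
                )
    else:
        x, y = fes.axis(0), fes.axis(1)
        norm = colors.Normalize(vmin=float(fes.values.min()), vmax=float(fes.values.max()))
        mesh = ax.pcolormesh(x, y, fes.values.T, cmap=style.colormap, norm=norm, shading="nearest")
        levels = np.asarray(style.levels) if style.levels is not None else _auto_levels(fes.values)
        if levels.size:
            ax.contour(x, y, fes.values.T, levels=levels, colors="black", linewidths=0.6)
        fig.colorbar(mesh, ax=ax, label=f"free energy ({fes.unit})")
        if assignment is not None:
            by, bx = None, None
            bidx = np.argwhere(assignment.boundary_mask)
            if bidx.size:
                bx = x[bidx[:, 0]]
                by = y[bidx[:, 1]]
                ax.plot(bx, by, ls="none", marker=".", ms=1.0, color="white", alpha=0.7)
        if minima is not None:
            cmap = matplotlib.colormaps[style.colormap]
            for m in minima:
                if style.label_color == "auto":
                    rgba = cmap(norm(fes.values[m.grid_index]))
                    color = letter_color(rgba)
                else:
                    color = style.label_color
                ax.text(
                    m.cv_coords[0], m.cv_coords[1], m.label,
                    ha="center", va="center", color=color, fontweight="bold",
                )
        ax.set_xlabel(xlab)
        ax.set_ylabel(style.ylabel if style.ylabel is not None else fes.cv_meta[1].name)

    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=style.dpi)
        plt.close(fig)
    return fig


# ---------------------------------------------------------------------------
# plain-text grid round trip
# ---------------------------------------------------------------------------

def export_grid(fes: FreeEnergySurface, path) -> None:
    """Write a FES as plain text: commented header plus one node per row.

    Rows are in deterministic row-major order (last dimension fastest), each
    carrying the node coordinates followed by the free energy, at 9
    significant digits.
    """
    lines = ["# mdfes free energy surface grid v1", f"# unit: {fes.unit}"]
    for j, meta in enumerate(fes.cv_meta):
        lines.append(
            "# cv: {} {} {} {} {}".format(
                meta.name,
                "periodic" if meta.periodic else "nonperiodic",
                _FMT.format(fes.grid_lo[j]).strip(),
                _FMT.format(fes.grid_hi[j]).strip(),
                fes.values.shape[j],
            )
        )
    lines.append("# columns: " + " ".join(m.name for m in fes.cv_meta) + " free_energy")
    axes = [fes.axis(j) for j in range(fes.ndim)]
    for idx in np.ndindex(fes.values.shape):
        coords = " ".join(_FMT.format(axes[j][idx[j]]) for j in range(fes.ndim))
        lines.append(f"{coords} {_FMT.format(fes.values[idx])}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def import_grid(path) -> FreeEnergySurface:
    """Read a text grid written by :func:`export_grid`."""
    from .hills_io import CVMeta

    meta: list[CVMeta] = []
    lo, hi, res = [], [], []
    values = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("cv:"):
                    parts = body[3:].split()
                    if len(parts) != 5 or parts[1] not in ("periodic", "nonperiodic"):
                        raise GridFormatError(f"{path}:{lineno}: malformed cv header line")
                    periodic = parts[1] == "periodic"
                    try:
                        a, b, r = float(parts[2]), float(parts[3]), int(parts[4])
                    except ValueError as exc:
                        raise GridFormatError(f"{path}:{lineno}: malformed cv header line") from exc
                    meta.append(
                        CVMeta(parts[0], periodic=periodic,
                               period_lo=a if periodic else None,
                               period_hi=b if periodic else None)
                    )
                    lo.append(a)
                    hi.append(b)
                    res.append(r)
                continue
            try:
                values.append(float(line.split()[-1]))
            except ValueError as exc:
                raise GridFormatError(f"{path}:{lineno}: malformed data row") from exc
    if not meta:
        raise GridFormatError(f"{path}: no '# cv:' header lines")
    expected = int(np.prod(res))
    if len(values) != expected:
        raise GridFormatError(
            f"{path}: {len(values)} data rows, header implies {expected}"
        )
    return FreeEnergySurface(
        values=np.asarray(values).reshape(tuple(res)),
        cv_meta=tuple(meta),
        grid_lo=np.asarray(lo),
        grid_hi=np.asarray(hi),
    )
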