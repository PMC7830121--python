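"""The `.var` container file and the three plot products.

`.var` dialect: tab-delimited ASCII, one fixed header line, numeric fields
with 5 decimal places, ASCII hyphen-minus for negatives. One row is appended
per processed input volume, IDs consecutive from 1 in file order.

Plots: a per-file variogram plot (empirical dots, fitted model curves,
(a, c) square markers), the Component MS-LDP (per-direction ln a vs ln c)
and the MS-LDP proper (ln-mean a vs ln-mean c). Red/green/blue encode the
x/y/z directions throughout. LDP axes default to the cohort-derived
convention a in [0, 3], c in [-12, -4] on the ln scale; out-of-span points
are drawn anyway with a logged warning.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")  # headless batch tool; must precede pyplot import
import matplotlib.pyplot as plt
import numpy as np

from .variography import EmpiricalVariogram
from .variomodel import ExpModelFit, LDPRecord, exponential_model

logger = logging.getLogger(__name__)

__all__ = [
    "VAR_HEADER",
    "VarTable",
    "append_var_record",
    "read_var_file",
    "plot_variograms",
    "plot_component_ldp",
    "plot_ldp",
]

VAR_HEADER = (
    "ID", "ln(avg(a[xyz]))", "ln(avg(C[xyz]))",
    "ln(aX)", "ln(CX)", "ln(aY)", "ln(CY)", "ln(az)", "ln(CZ)", "File",
)

DIRECTION_COLORS = {"x": "red", "y": "green", "z": "blue"}

#: ln-scale plot spans derived from cohort analyses: range a 0..3, sill c -12..-4.
LDP_A_SPAN = (0.0, 3.0)
LDP_C_SPAN = (-12.0, -4.0)

DEFAULT_DPI = 100


@dataclass
class VarTable:
    """Ordered collection of LDP records as stored in a `.var` file."""

    records: list[LDPRecord] = field(default_factory=list)
    header: tuple[str, ...] = VAR_HEADER

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def _format_row(record: LDPRecord) -> str:
    nums = (
        record.ln_mean_a, record.ln_mean_c,
        record.ln_aX, record.ln_cX,
        record.ln_aY, record.ln_cY,
        record.ln_aZ, record.ln_cZ,
    )
    cells = [str(record.id)] + [f"{v:.5f}" for v in nums] + [record.filename]
    return "\t".join(cells)


def append_var_record(path: str | os.PathLike, record: LDPRecord) -> None:
    """Append one tab-delimited row; write the header first on a fresh file."""
    path = os.fspath(path)
    fresh = not os.path.exists(path) or os.path.getsize(path) == 0
    with open(path, "a", encoding="ascii", newline="\n") as fh:
        if fresh:
            fh.write("\t".join(VAR_HEADER) + "\n")
        fh.write(_format_row(record) + "\n")


def read_var_file(path: str | os.PathLike) -> VarTable:
    """Parse a `.var` container file, reporting malformed rows by line number."""
    path = os.fspath(path)
    with open(path, "r", encoding="ascii") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln.strip() != ""]
    if not lines:
        raise ValueError(f"{path}: missing header (file is empty)")
    header = tuple(lines[0].split("\t"))
    if header != VAR_HEADER:
        raise ValueError(
            f"{path}: missing or malformed header; expected {list(VAR_HEADER)}, "
            f"got {list(header)}"
        )
    records = []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(VAR_HEADER):
            raise ValueError(
                f"{path}: line {lineno}: expected {len(VAR_HEADER)} columns, got {len(cells)}"
            )
        try:
            rec = LDPRecord(
                id=int(cells[0]),
                ln_mean_a=float(cells[1]), ln_mean_c=float(cells[2]),
                ln_aX=float(cells[3]), ln_cX=float(cells[4]),
                ln_aY=float(cells[5]), ln_cY=float(cells[6]),
                ln_aZ=float(cells[7]), ln_cZ=float(cells[8]),
                filename=cells[9],
            )
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: unparseable value ({exc})") from exc
        records.append(rec)
    return VarTable(records=records)


def _figure(width_px: int, height_px: int):
    return plt.figure(
        figsize=(width_px / DEFAULT_DPI, height_px / DEFAULT_DPI), dpi=DEFAULT_DPI
    )


def plot_variograms(
    emps: tuple[EmpiricalVariogram, ...],
    fits: tuple[ExpModelFit, ...],
    out_path: str | os.PathLike,
    width_px: int = 1200,
    height_px: int = 900,
    title: str = "",
) -> str:
    """Per-file variogram plot: empirical dots, model curves, (a, c) squares.

    Distance (mm) on the abscissa, gamma on the ordinate; one color per
    direction. An annotation box lists the fitted a, c per direction.
    """
    fig = _figure(width_px, height_px)
    ax = fig.add_subplot(111)
    notes = []
    h_max = max(float(e.distances_mm[-1]) for e in emps)
    for emp, fit in zip(emps, fits):
        color = DIRECTION_COLORS[emp.direction]
        ax.plot(emp.distances_mm, emp.gamma, "o", color=color, ms=5,
                label=f"empirical {emp.direction}")
        if fit.converged:
            grid = np.linspace(0.0, h_max, 200)
            ax.plot(grid, exponential_model(grid, fit.a, fit.c), "-", color=color, lw=1.5)
            ax.plot([fit.a], [fit.c], "s", color=color, ms=9, mfc="none", mew=2)
            notes.append(f"{emp.direction}: a = {fit.a:.3f} mm, c = {fit.c:.3g}")
        else:
            notes.append(f"{emp.direction}: fit not converged")
    ax.set_xlabel("Distance [mm]")
    ax.set_ylabel(r"$\gamma$")
    if title:
        ax.set_title(title)
    ax.legend(loc="lower right", fontsize=9)
    ax.text(
        0.02, 0.98, "\n".join(notes), transform=ax.transAxes, va="top", ha="left",
        fontsize=9, bbox=dict(boxstyle="round", fc="white", ec="grey", alpha=0.8),
    )
    return _save(fig, out_path, width_px, height_px)


def _check_span(name: str, a_val: float, c_val: float, label) -> None:
    if not (LDP_A_SPAN[0] <= a_val <= LDP_A_SPAN[1] and LDP_C_SPAN[0] <= c_val <= LDP_C_SPAN[1]):
        logger.warning(
            "%s: point %s at (ln a=%.3f, ln c=%.3f) lies outside the standard "
            "plot span a %s, c %s; drawn anyway", name, label, a_val, c_val,
            LDP_A_SPAN, LDP_C_SPAN,
        )


def plot_component_ldp(
    table: VarTable,
    out_path: str | os.PathLike,
    width_px: int = 1200,
    height_px: int = 900,
    symbol_size: float = 9.0,
    text_size: float = 9.0,
) -> str:
    """Component MS-LDP: per-direction (ln a, ln c) squares, labelled by ID."""
    if len(table) == 0:
        raise ValueError("cannot plot an empty table")
    fig = _figure(width_px, height_px)
    ax = _ldp_axes(fig, "Component MS-LDP")
    for rec in table:
        for direction, ln_a, ln_c in rec.component_lns:
            _check_span("Component MS-LDP", ln_a, ln_c, rec.id)
            ax.plot([ln_a], [ln_c], "s", color=DIRECTION_COLORS[direction], ms=symbol_size)
            ax.annotate(str(rec.id), (ln_a, ln_c), textcoords="offset points",
                        xytext=(5, 5), fontsize=text_size)
    handles = [
        plt.Line2D([], [], marker="s", ls="", color=c, label=d)
        for d, c in DIRECTION_COLORS.items()
    ]
    ax.legend(handles=handles, loc="upper left", fontsize=text_size)
    return _save(fig, out_path, width_px, height_px)


def plot_ldp(
    table: VarTable,
    out_path: str | os.PathLike,
    width_px: int = 1200,
    height_px: int = 900,
    symbol_size: float = 9.0,
    text_size: float = 9.0,
) -> str:
    """MS-LDP: one labelled point per record at (ln mean a, ln mean c)."""
    if len(table) == 0:
        raise ValueError("cannot plot an empty table")
    fig = _figure(width_px, height_px)
    ax = _ldp_axes(fig, "MS-LDP")
    for rec in table:
        _check_span("MS-LDP", rec.ln_mean_a, rec.ln_mean_c, rec.id)
        ax.plot([rec.ln_mean_a], [rec.ln_mean_c], "o", color="black", ms=symbol_size)
        ax.annotate(str(rec.id), (rec.ln_mean_a, rec.ln_mean_c),
                    textcoords="offset points", xytext=(5, 5), fontsize=text_size)
    return _save(fig, out_path, width_px, height_px)


def _ldp_axes(fig, title: str):
    ax = fig.add_subplot(111)
    ax.set_xlim(*LDP_A_SPAN)
    ax.set_ylim(*LDP_C_SPAN)
    ax.set_xlabel("ln(a)  [spatial continuity]")
    ax.set_ylabel("ln(c)  [lesion-load proxy]")
    ax.set_title(title)
    ax.grid(True, alpha=0.3)
    return ax


def _save(fig, out_path, width_px: int, height_px: int) -> str:
    out_path = os.fspath(out_path)
    # pad with exact pixel geometry: bbox_inches would change the canvas size
    fig.savefig(out_path, dpi=DEFAULT_DPI, format="png")
    plt.close(fig)
    return out_path
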