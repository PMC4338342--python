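"""Gridded diurnal concentration fields and space-time lookups.

A :class:`ConcentrationField` holds one average diurnal cycle of a pollutant
(24 hourly layers on a regular grid, μg/m³).  Exposure assessment queries it
with planar coordinates and a minute-of-day; the answer is piecewise constant
in both space (grid cell) and time (hour of day) — no interpolation, matching
a cell-intersection assignment of receptors to locations.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GridSpec",
    "ConcentrationField",
    "OutOfDomainError",
    "diurnal_average",
    "cell_index",
    "lookup",
    "read_field",
    "write_field",
]


class OutOfDomainError(ValueError):
    """A queried point lies outside the concentration grid."""


@dataclass(frozen=True)
class GridSpec:
    """Regular planar grid: ``x0, y0`` is the southwest corner in meters.

    Cells are half-open squares of side ``cell_size_m``; cell (i, j) covers
    ``[x0 + i*Δ, x0 + (i+1)*Δ) × [y0 + j*Δ, y0 + (j+1)*Δ)``.
    """

    x0: float
    y0: float
    cell_size_m: float
    nx: int
    ny: int

    def __post_init__(self) -> None:
        if self.cell_size_m <= 0:
            raise ValueError("cell_size_m must be positive")
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid must have at least one cell per axis")

    @property
    def bbox(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the covered domain."""
        return (
            self.x0,
            self.y0,
            self.x0 + self.nx * self.cell_size_m,
            self.y0 + self.ny * self.cell_size_m,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """1-D arrays of cell-center x and y coordinates."""
        d = self.cell_size_m
        cx = self.x0 + (np.arange(self.nx) + 0.5) * d
        cy = self.y0 + (np.arange(self.ny) + 0.5) * d
        return cx, cy


class ConcentrationField:
    """24 hourly concentration layers (μg/m³) on a :class:`GridSpec`.

    ``layers`` has shape (24, ny, nx), indexed ``layers[hour, j, i]`` with
    i the column (x) and j the row (y) index.
    """

    def __init__(self, grid: GridSpec, layers: np.ndarray):
        layers = np.asarray(layers, dtype=float)
        if layers.shape != (24, grid.ny, grid.nx):
            raise ValueError(
                f"layers must have shape (24, {grid.ny}, {grid.nx}), "
                f"got {layers.shape}"
            )
        if np.any(layers < 0) or not np.all(np.isfinite(layers)):
            raise ValueError("concentrations must be finite and non-negative")
        self.grid = grid
        self.layers = layers

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ConcentrationField):
            return NotImplemented
        return self.grid == other.grid and np.array_equal(self.layers, other.layers)


def diurnal_average(hourly_stack: np.ndarray, grid: GridSpec) -> ConcentrationField:
    """Collapse a multi-day hourly stack to one average diurnal cycle.

    ``hourly_stack`` has shape (24*D, ny, nx) for D whole days, hour 0 of day 1
    first.  Layer h of the result is the mean over days of the hour-h slices.
    A single-day stack is returned unchanged (up to dtype).
    """
    stack = np.asarray(hourly_stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] % 24 != 0 or stack.shape[0] == 0:
        raise ValueError(
            f"stack length must be a positive multiple of 24, got shape {stack.shape}"
        )
    days = stack.shape[0] // 24
    cycle = stack.reshape(days, 24, stack.shape[1], stack.shape[2]).mean(axis=0)
    return ConcentrationField(grid, cycle)


def cell_index(grid: GridSpec, x: float, y: float) -> tuple[int, int]:
    """Map a point to (i, j) cell indices; half-open cells.

    A point exactly on an interior cell boundary belongs to the higher-index
    cell.  Points outside the grid raise :class:`OutOfDomainError`.
    """
    i = math.floor((x - grid.x0) / grid.cell_size_m)
    j = math.floor((y - grid.y0) / grid.cell_size_m)
    if not (0 <= i < grid.nx and 0 <= j < grid.ny):
        raise OutOfDomainError(
            f"point ({x}, {y}) outside grid domain {grid.bbox}"
        )
    return i, j


def lookup(
    field: ConcentrationField, x: float, y: float, minute: float, clamp: bool = False
) -> float:
    """Concentration (μg/m³) at a point and minute-of-day.

    Piecewise constant: the value of the containing cell in the layer for
    ``floor(minute / 60)``.  With ``clamp=True`` an out-of-domain point is
    snapped to the nearest edge cell instead of raising (off by default).
    """
    if not 0 <= minute < 1440:
        raise ValueError(f"minute must be in [0, 1440), got {minute}")
    try:
        i, j = cell_index(field.grid, x, y)
    except OutOfDomainError:
        if not clamp:
            raise
        g = field.grid
        i = min(max(math.floor((x - g.x0) / g.cell_size_m), 0), g.nx - 1)
        j = min(max(math.floor((y - g.y0) / g.cell_size_m), 0), g.ny - 1)
    return float(field.layers[int(minute // 60), j, i])


# ---------------------------------------------------------------------------
# File format: one JSON document with the grid header and 24 nested layers.
# ---------------------------------------------------------------------------

def write_field(field: ConcentrationField, path) -> None:
    """Write a field as JSON: grid header + 24 row-major layers."""
    doc = {
        "x0": field.grid.x0,
        "y0": field.grid.y0,
        "cell_size_m": field.grid.cell_size_m,
        "nx": field.grid.nx,
        "ny": field.grid.ny,
        "units": "ug/m3",
        "layers": field.layers.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, sort_keys=True)
        fh.write("\n")


def read_field(path) -> ConcentrationField:
    """Read a field written by :func:`write_field`; validates shape and sign."""
    with open(path) as fh:
        doc = json.load(fh)
    grid = GridSpec(
        x0=float(doc["x0"]),
        y0=float(doc["y0"]),
        cell_size_m=float(doc["cell_size_m"]),
        nx=int(doc["nx"]),
        ny=int(doc["ny"]),
    )
    return ConcentrationField(grid, np.asarray(doc["layers"], dtype=float))
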