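"""Kernel-smoothed intensity surfaces and multi-channel composite images.

Each phenotype's point pattern is converted to an intensity surface
(points per um^2) on a regular grid with an isotropic Gaussian kernel,
truncated at 4 sigma.  Near the window border part of a point's kernel
mass would fall outside the observation window; with edge correction
enabled each point's (truncated, discretized) kernel is renormalized to
unit in-window mass — a Diggle-style per-point correction under which
``sum(values) * cell_area`` equals the point count exactly.

Grid convention: row index corresponds to y (row 0 at the bottom edge),
column index to x, values sampled at cell centers.  The per-phenotype
surfaces of one image are stacked into an ``l x m x c`` composite, the
pseudocolor representation fed to patch extraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import CellTable, Window


@dataclass(frozen=True)
class GridSpec:
    """Regular grid over an observation window (square cells).

    ``n_rows`` (l) counts cells along y, ``n_cols`` (m) along x;
    ``cell_size_um`` is the side of one square cell; ``origin`` is the
    window's lower-left corner in microns.
    """

    n_rows: int = 70
    n_cols: int = 50
    cell_size_um: float = 20.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.cell_size_um <= 0:
            raise ValueError("cell_size_um must be positive")

    @classmethod
    def for_window(cls, window: Window, n_rows: int = 70, n_cols: int = 50) -> "GridSpec":
        """Aspect-preserving grid over ``window``.

        The cell size is chosen so the grid covers the window; the window
        aspect ratio must match the grid's to within one cell.
        """
        cell_x = window.width_um / n_cols
        cell_y = window.height_um / n_rows
        cell = max(cell_x, cell_y)
        if abs(cell_x - cell_y) > cell:
            raise ValueError(
                "grid aspect does not match window aspect within one cell; "
                "choose n_rows/n_cols proportional to the window"
            )
        return cls(n_rows=n_rows, n_cols=n_cols, cell_size_um=cell)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def cell_area_um2(self) -> float:
        return self.cell_size_um**2

    def covers(self, window: Window) -> bool:
        x0, y0 = self.origin
        return (
            x0 <= 0.0
            and y0 <= 0.0
            and x0 + self.n_cols * self.cell_size_um >= window.width_um - 1e-9
            and y0 + self.n_rows * self.cell_size_um >= window.height_um - 1e-9
        )


@dataclass
class PhenotypeSurface:
    """One phenotype's intensity surface (points per um^2) on a grid."""

    values: np.ndarray
    phenotype: str
    grid: GridSpec
    bandwidth_um: float
    edge_corrected: bool

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("surface shape does not match grid")
        if not np.isfinite(self.values).all():
            raise ValueError("surface contains non-finite values")
        if (self.values < 0).any():
            raise ValueError("surface contains negative intensities")

    @property
    def total_mass(self) -> float:
        """Integral of the surface (expected to equal the point count)."""
        return float(self.values.sum() * self.grid.cell_area_um2)


@dataclass
class CompositeImage:
    """l x m x c stack of per-phenotype intensity surfaces for one image."""

    stack: np.ndarray
    channel_order: tuple[str, ...]
    grid: GridSpec
    image_id: str
    subject_id: str
    class_label: int

    def __post_init__(self) -> None:
        self.stack = np.asarray(self.stack, dtype=float)
        if self.stack.ndim != 3 or self.stack.shape[2] != len(self.channel_order):
            raise ValueError("stack shape does not match channel order")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.stack.shape

    def channel(self, phenotype: str) -> np.ndarray:
        return self.stack[:, :, self.channel_order.index(phenotype)]


def estimate_intensity(
    table: CellTable,
    phenotype: str,
    grid: GridSpec,
    bandwidth_um: float | None = None,
    edge_correction: bool = True,
) -> PhenotypeSurface:
    """Isotropic Gaussian kernel intensity estimate on ``grid``.

    ``bandwidth_um`` is the Gaussian sigma (default ``1.5 * cell_size``).
    The kernel is truncated at 4 sigma.  With ``edge_correction`` each
    point's discrete kernel is renormalized to unit in-window mass, so the
    surface integrates exactly to the number of points.
    """
    if bandwidth_um is None:
        bandwidth_um = 1.5 * grid.cell_size_um
    if bandwidth_um <= 0:
        raise ValueError("bandwidth_um must be positive")
    if not grid.covers(table.window):
        raise ValueError("grid does not cover the observation window")
    pts = table.positions(phenotype)  # raises on undeclared phenotype
    l, m = grid.shape
    values = np.zeros((l, m), dtype=float)
    if len(pts) == 0:
        return PhenotypeSurface(values, phenotype, grid, bandwidth_um, edge_correction)

    cell = grid.cell_size_um
    x0, y0 = grid.origin
    sigma = bandwidth_um
    reach = int(np.ceil(4.0 * sigma / cell))
    offs = np.arange(-reach, reach + 1)
    # Base cell of each point and exact offsets to nearby cell centers.
    px = pts[:, 0] - x0
    py = pts[:, 1] - y0
    c0 = np.clip((px // cell).astype(int), 0, m - 1)
    r0 = np.clip((py // cell).astype(int), 0, l - 1)
    rows = r0[:, None] + offs[None, :]  # (n, S)
    cols = c0[:, None] + offs[None, :]
    cy = (rows + 0.5) * cell  # cell-center coordinates
    cx = (cols + 0.5) * cell
    dy2 = (cy - py[:, None]) ** 2
    dx2 = (cx - px[:, None]) ** 2
    # Separable kernel: outer product of the row and column factors.
    ky = np.exp(-dy2 / (2.0 * sigma**2))
    kx = np.exp(-dx2 / (2.0 * sigma**2))
    radius2 = (4.0 * sigma) ** 2
    d2 = dy2[:, :, None] + dx2[:, None, :]  # (n, S, S)
    kern = ky[:, :, None] * kx[:, None, :]
    kern[d2 > radius2] = 0.0  # circular truncation at 4 sigma
    in_rows = (rows >= 0) & (rows < l)
    in_cols = (cols >= 0) & (cols < m)
    valid = in_rows[:, :, None] & in_cols[:, None, :]
    kern[~valid] = 0.0
    if edge_correction:
        mass = kern.sum(axis=(1, 2)) * grid.cell_area_um2
        # A point whose entire truncated kernel lies outside the grid can
        # not occur because the grid covers the window.
        kern /= mass[:, None, None]
    else:
        kern /= 2.0 * np.pi * sigma**2
    flat = np.clip(rows[:, :, None], 0, l - 1) * m + np.clip(cols[:, None, :], 0, m - 1)
    np.add.at(values, np.unravel_index(flat.ravel(), (l, m)), kern.ravel())
    return PhenotypeSurface(values, phenotype, grid, bandwidth_um, edge_correction)


def build_composite(
    surfaces: list[PhenotypeSurface],
    order: tuple[str, ...] | list[str],
    image_id: str = "",
    subject_id: str = "",
    class_label: int = 1,
    normalize_channels: bool = False,
) -> CompositeImage:
    """Stack per-phenotype surfaces into a composite in channel ``order``.

    ``normalize_channels`` optionally rescales each channel to unit maximum
    (off by default; raw intensities are the standard representation).
    """
    order = tuple(order)
    by_phen = {}
    for s in surfaces:
        if s.phenotype in by_phen:
            raise ValueError(f"duplicate surface for phenotype {s.phenotype!r}")
        by_phen[s.phenotype] = s
    if set(order) != set(by_phen):
        raise ValueError(
            f"channel order {order!r} does not match surfaces {sorted(by_phen)!r}"
        )
    grid = surfaces[0].grid
    for s in surfaces:
        if s.grid != grid:
            raise ValueError("surfaces are on mismatched grids")
    stack = np.stack([by_phen[p].values for p in order], axis=-1)
    if normalize_channels:
        peak = stack.max(axis=(0, 1), keepdims=True)
        peak[peak == 0] = 1.0
        stack = stack / peak
    return CompositeImage(stack, order, grid, image_id, subject_id, class_label)


def composite_from_table(
    table: CellTable,
    grid: GridSpec | None = None,
    bandwidth_um: float | None = None,
    edge_correction: bool = True,
    normalize_channels: bool = False,
) -> CompositeImage:
    """Full per-image pipeline: one surface per declared phenotype, stacked."""
    if grid is None:
        grid = GridSpec.for_window(table.window)
    surfaces = [
        estimate_intensity(table, p, grid, bandwidth_um, edge_correction)
        for p in table.phenotypes
    ]
    return build_composite(
        surfaces,
        table.phenotypes,
        image_id=table.image_id,
        subject_id=table.subject_id,
        class_label=table.class_label,
        normalize_channels=normalize_channels,
    )
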