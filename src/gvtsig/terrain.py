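"""GeneTerrain rendering: network layout plus Gaussian-peak rasterization.

The terrain base is the scored interaction subnetwork laid out in 2-D by a
force-directed algorithm whose edge attraction is proportional to
interaction confidence.  Each gene then contributes a Gaussian bump whose
height is its score (final score by default, log2 ratio selectable), and
the bumps are summed on a regular grid:

    surface(p) = sum_g  z_g * exp(-||p - p_g||^2 / (2 sigma^2))

Negative heights are allowed and render as depressions.  Tests and
downstream consumers work on the numeric matrix; a raster image is an
optional side product.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np

from .errors import ConfigError, UsageError
from .network import SubNetwork

__all__ = ["LayoutCoords", "TerrainSurface", "layout_network",
           "render_terrain", "save_terrain_png"]

#: Layout margin: coordinates are rescaled into [MARGIN, 1 - MARGIN]^2 so
#: that peaks stay clear of the raster border.
MARGIN = 0.05


@dataclass
class LayoutCoords:
    """Deterministic 2-D node positions in the unit square."""

    coords: dict[str, tuple[float, float]]
    layout_seed: int

    def __getitem__(self, gene: str) -> tuple[float, float]:
        return self.coords[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self.coords

    def __len__(self) -> int:
        return len(self.coords)


@dataclass
class TerrainSurface:
    """Rasterized terrain: ``grid[iy, ix]`` over the unit square.

    Row index runs along y, column index along x; cell centers sit at
    ``(i + 0.5) / grid_size``.
    """

    grid: np.ndarray
    sigma: float
    heights_of: dict[str, float]

    def __post_init__(self) -> None:
        if self.grid.ndim != 2 or self.grid.shape[0] != self.grid.shape[1]:
            raise ValueError("grid must be square")
        if self.grid.shape[0] < 16:
            raise ValueError("grid must be at least 16 x 16")
        if not np.isfinite(self.grid).all():
            raise ValueError("grid contains non-finite values")

    @property
    def grid_size(self) -> int:
        return self.grid.shape[0]


def layout_network(sub: SubNetwork | nx.Graph, seed: int) -> LayoutCoords:
    """Force-directed layout of the subnetwork, rescaled to the unit square.

    Edge attraction is proportional to confidence, so high-confidence
    clusters (the terrain's mountain ranges) contract together.  The layout
    is deterministic for a fixed seed and graph.  A single node sits at the
    center.
    """
    graph = sub.graph if isinstance(sub, SubNetwork) else sub
    if graph.number_of_nodes() == 0:
        raise UsageError("cannot lay out an empty network")
    pos = nx.spring_layout(graph, seed=seed, weight="confidence")
    xs = np.array([p[0] for p in pos.values()])
    ys = np.array([p[1] for p in pos.values()])
    lo, hi = MARGIN, 1.0 - MARGIN

    def rescale(v: np.ndarray) -> np.ndarray:
        span = v.max() - v.min()
        if span == 0:
            return np.full_like(v, 0.5)
        return lo + (v - v.min()) * (hi - lo) / span

    xs, ys = rescale(xs), rescale(ys)
    coords = {g: (float(x), float(y)) for g, x, y in zip(pos, xs, ys)}
    return LayoutCoords(coords=coords, layout_seed=seed)


def render_terrain(coords: LayoutCoords | Mapping[str, tuple[float, float]],
                   heights: Mapping[str, float], grid_size: int = 256,
                   sigma: float = 0.05) -> TerrainSurface:
    """Sum per-gene Gaussian kernels on a ``grid_size`` x ``grid_size`` raster.

    Every gene in ``heights`` must have coordinates.  ``sigma`` is the
    kernel width in unit coordinates; the default 0.05 resolves a few dozen
    genes into distinct peaks at 256 x 256.
    """
    if sigma <= 0:
        raise ConfigError(f"sigma must be > 0, got {sigma}")
    if grid_size < 16:
        raise ConfigError(f"grid_size must be >= 16, got {grid_size}")
    lookup = coords.coords if isinstance(coords, LayoutCoords) else coords
    missing = [g for g in heights if g not in lookup]
    if missing:
        raise UsageError(f"genes without layout coordinates: {missing[:5]}")

    centers = (np.arange(grid_size) + 0.5) / grid_size
    gx = centers[np.newaxis, :]   # x varies along columns
    gy = centers[:, np.newaxis]   # y varies along rows
    grid = np.zeros((grid_size, grid_size))
    inv = 1.0 / (2.0 * sigma * sigma)
    for gene in sorted(heights):  # fixed order: input order never matters
        z = heights[gene]
        if z == 0:
            continue
        x0, y0 = lookup[gene]
        grid += z * np.exp(-((gx - x0) ** 2 + (gy - y0) ** 2) * inv)
    return TerrainSurface(grid=grid, sigma=sigma, heights_of=dict(heights))


def save_terrain_png(surface: TerrainSurface, path: str | Path,
                     coords: LayoutCoords | None = None,
                     label_top: int = 15) -> None:
    """Render the terrain matrix as a heat-map image (optional side output)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    vmax = np.abs(surface.grid).max() or 1.0
    ax.imshow(surface.grid, origin="lower", extent=(0, 1, 0, 1),
              cmap="terrain", vmin=-vmax, vmax=vmax)
    if coords is not None:
        top = sorted(surface.heights_of, key=lambda g: -abs(surface.heights_of[g]))
        for gene in top[:label_top]:
            x, y = coords[gene]
            ax.annotate(gene, (x, y), fontsize=6, ha="center")
    ax.set_xticks(())
    ax.set_yticks(())
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
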