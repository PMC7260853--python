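"""Color-coded 2D density maps and 1D axis projections.

Pooled normalized positions are turned into a Gaussian-kernel density
evaluated on a regular grid over the unit square and renormalized to
integrate to one there (mass leaking past the frame border is folded
back by the renormalization).  Marginal projections give the 1D
dorsoventral / mediolateral profiles.  Densities are data; the
red-high / blue-low colormap is applied only at plot time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .geometry import PooledSample

__all__ = [
    "DensityMap",
    "MarginalDensity",
    "density_map",
    "marginal_projection",
    "density_difference",
    "write_density_tsv",
    "render_png",
    "DEFAULT_GRID_SIZE",
    "BANDWIDTH_FLOOR",
]

DEFAULT_GRID_SIZE = 64
#: minimum bandwidth in normalized units, so single points and
#: zero-variance samples still produce a finite map
BANDWIDTH_FLOOR = 0.02


@dataclass
class DensityMap:
    """2D density on a regular grid over [0,1]×[0,1].

    ``values[iy, ix]`` is the density at ``(x_centers[ix], y_centers[iy])``;
    sum(values) × cell_area == 1.
    """

    x_centers: np.ndarray
    y_centers: np.ndarray
    values: np.ndarray
    bandwidth: tuple[float, float]
    n_points: int
    marker: str = ""
    genotype: str = ""

    @property
    def cell_area(self) -> float:
        return float(
            (self.x_centers[1] - self.x_centers[0])
            * (self.y_centers[1] - self.y_centers[0])
        )

    def integral(self) -> float:
        return float(self.values.sum() * self.cell_area)


@dataclass
class MarginalDensity:
    """1D density of one projected axis; integrates to 1."""

    axis: str
    centers: np.ndarray
    values: np.ndarray
    bandwidth: float
    n_points: int

    def integral(self) -> float:
        step = float(self.centers[1] - self.centers[0])
        return float(self.values.sum() * step)


def _scott_bandwidth(x: np.ndarray) -> float:
    """Scott's rule per axis with a floor for degenerate samples."""
    n = len(x)
    sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
    bw = sd * n ** (-1.0 / 6.0)
    return max(bw, BANDWIDTH_FLOOR)


def _grid_centers(grid_size: int) -> np.ndarray:
    return (np.arange(grid_size) + 0.5) / grid_size


def density_map(
    sample: PooledSample | np.ndarray,
    grid_size: int = DEFAULT_GRID_SIZE,
    bandwidth: tuple[float, float] | float | None = None,
) -> DensityMap:
    """Gaussian-kernel density of a pooled sample on the unit square.

    ``bandwidth`` may be a scalar, an (x, y) pair, or ``None`` for
    Scott's rule per axis (floored at :data:`BANDWIDTH_FLOOR`).
    Deterministic; raises on an empty sample.
    """
    marker = genotype = ""
    if isinstance(sample, PooledSample):
        pts = sample.points
        marker, genotype = sample.marker, sample.genotype
    else:
        pts = np.asarray(sample, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"sample must have shape (n, 2), got {pts.shape}")
    if len(pts) == 0:
        raise ValueError("cannot build a density map from an empty sample")
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    if bandwidth is None:
        bw = (_scott_bandwidth(pts[:, 0]), _scott_bandwidth(pts[:, 1]))
    elif np.isscalar(bandwidth):
        bw = (float(bandwidth), float(bandwidth))
    else:
        bw = (float(bandwidth[0]), float(bandwidth[1]))
    if bw[0] <= 0 or bw[1] <= 0:
        raise ValueError(f"bandwidth must be positive, got {bw}")
    xc = _grid_centers(grid_size)
    yc = _grid_centers(grid_size)
    # separable kernel: values = Gy @ Gx.T, shape (grid, grid) as [iy, ix]
    gx = np.exp(-0.5 * ((xc[:, None] - pts[None, :, 0]) / bw[0]) ** 2)
    gy = np.exp(-0.5 * ((yc[:, None] - pts[None, :, 1]) / bw[1]) ** 2)
    values = gy @ gx.T
    area = (xc[1] - xc[0]) * (yc[1] - yc[0])
    total = values.sum() * area
    if total <= 0:
        raise ValueError("density mass on the grid is zero; bandwidth too small?")
    values /= total
    return DensityMap(
        x_centers=xc,
        y_centers=yc,
        values=values,
        bandwidth=bw,
        n_points=len(pts),
        marker=marker,
        genotype=genotype,
    )


def marginal_projection(
    sample: PooledSample | np.ndarray,
    axis: str,
    grid_size: int = DEFAULT_GRID_SIZE,
    bandwidth: float | None = None,
) -> MarginalDensity:
    """1D density of the chosen projected axis (``"ML_x"`` or ``"DV_y"``)."""
    if isinstance(sample, PooledSample):
        pts = sample.points
    else:
        pts = np.asarray(sample, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"sample must have shape (n, 2), got {pts.shape}")
    if len(pts) == 0:
        raise ValueError("cannot project an empty sample")
    if axis not in ("ML_x", "DV_y"):
        raise ValueError(f"axis must be 'ML_x' or 'DV_y', got {axis!r}")
    x = pts[:, 0] if axis == "ML_x" else pts[:, 1]
    bw = _scott_bandwidth(x) if bandwidth is None else float(bandwidth)
    if bw <= 0:
        raise ValueError(f"bandwidth must be positive, got {bw}")
    centers = _grid_centers(grid_size)
    values = np.exp(-0.5 * ((centers[:, None] - x[None, :]) / bw) ** 2).sum(axis=1)
    step = centers[1] - centers[0]
    total = values.sum() * step
    if total <= 0:
        raise ValueError("density mass on the grid is zero; bandwidth too small?")
    values /= total
    return MarginalDensity(
        axis=axis, centers=centers, values=values, bandwidth=bw, n_points=len(x)
    )


def density_difference(map_control: DensityMap, map_mutant: DensityMap) -> DensityMap:
    """Pointwise mutant − control difference; sums to zero.

    Both maps must share the same grid; interpret only within one
    marker (cross-marker density scales are not comparable).
    """
    if map_control.values.shape != map_mutant.values.shape or not (
        np.array_equal(map_control.x_centers, map_mutant.x_centers)
        and np.array_equal(map_control.y_centers, map_mutant.y_centers)
    ):
        raise ValueError("density maps must share an identical grid")
    return DensityMap(
        x_centers=map_control.x_centers,
        y_centers=map_control.y_centers,
        values=map_mutant.values - map_control.values,
        bandwidth=map_control.bandwidth,
        n_points=map_control.n_points + map_mutant.n_points,
        marker=map_control.marker,
        genotype=f"{map_mutant.genotype}-{map_control.genotype}",
    )


def write_density_tsv(dmap: DensityMap, path) -> Path:
    """Write the density matrix as TSV plus a JSON metadata sidecar."""
    path = Path(path)
    np.savetxt(path, dmap.values, delimiter="\t", fmt="%.10g")
    meta = {
        "marker": dmap.marker,
        "genotype": dmap.genotype,
        "grid_size": [len(dmap.y_centers), len(dmap.x_centers)],
        "bandwidth": list(dmap.bandwidth),
        "n_points": dmap.n_points,
        "layout": "rows are y (ventral->dorsal), columns are x (medial->lateral)",
    }
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return path


def render_png(dmap: DensityMap, path, cmap: str = "jet") -> Path:
    """Optional PNG rendering (red = highest, blue = lowest density)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(
        dmap.values,
        origin="lower",
        extent=(0, 1, 0, 1),
        cmap=cmap,
        aspect="auto",
    )
    ax.set_xlabel("mediolateral (normalized)")
    ax.set_ylabel("dorsoventral (normalized)")
    title = " ".join(v for v in (dmap.marker, dmap.genotype) if v)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
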