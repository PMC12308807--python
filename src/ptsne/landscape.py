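"""Free-energy landscapes over a 2-D embedding by Boltzmann inversion.

Given embedded samples whose stationary distribution reflects a Boltzmann
ensemble at temperature T, the free energy over the embedding plane is
estimated as ``F = -k_B T ln(rho / rho_max)`` from a 2-D histogram density,
so the global minimum sits at zero and bins never visited stay masked
rather than being assigned an arbitrary (infinite) value.  Optional
per-sample weights provide the hook for reweighted (biased) ensembles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["KB_KJ_PER_MOL_K", "LandscapeGrid", "histogram2d", "free_energy",
           "barrier_1d", "path_through_points", "profile_along_path",
           "render_landscape", "write_landscape"]

# Boltzmann constant in kJ/(mol K)
KB_KJ_PER_MOL_K = 0.0083144626


@dataclass
class LandscapeGrid:
    """A free-energy surface on a rectangular grid.

    F is in kJ/mol, shifted so the minimum over populated bins is zero;
    ``mask`` is True on empty bins, whose F values are NaN.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    F: np.ndarray
    mask: np.ndarray
    temperature: float

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])


def histogram2d(Z, bins: int = 64, weights=None, pad: float = 0.05):
    """Bin a 2-D embedding into a density grid.

    The grid spans the data's bounding box padded by ``pad`` on each side.
    Returns ``(counts, x_edges, y_edges)`` with counts indexed [ix, iy];
    total mass equals the sample count (or the weight sum).
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2 or Z.shape[1] != 2:
        raise ValueError(f"Z must be (n, 2) for a 2-D landscape, got {Z.shape}")
    if np.isscalar(bins):
        bins = (int(bins), int(bins))
    if min(bins) < 2:
        raise ValueError("need at least 2 bins per axis")
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if (weights < 0).any():
            raise ValueError("weights must be nonnegative")
    lo = Z.min(axis=0)
    hi = Z.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    lo = lo - pad * span
    hi = hi + pad * span
    counts, xe, ye = np.histogram2d(
        Z[:, 0], Z[:, 1], bins=bins,
        range=[(lo[0], hi[0]), (lo[1], hi[1])], weights=weights,
    )
    return counts, xe, ye


def free_energy(counts, x_edges=None, y_edges=None,
                temperature: float = 300.0) -> LandscapeGrid:
    """Boltzmann-invert a density grid into free energies (kJ/mol).

    ``F = -k_B T ln(rho / rho_max)``: the densest bin defines F = 0, empty
    bins are masked.  Uniformly rescaling the density leaves F unchanged.
    """
    counts = np.asarray(counts, dtype=float)
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature} K")
    if counts.ndim != 2:
        raise ValueError("density grid must be 2-D")
    mask = counts <= 0.0
    if mask.all():
        raise ValueError("all bins are empty")
    rho_max = counts.max()
    F = np.full(counts.shape, np.nan)
    F[~mask] = -KB_KJ_PER_MOL_K * temperature * np.log(counts[~mask] / rho_max)
    if x_edges is None:
        x_edges = np.arange(counts.shape[0] + 1, dtype=float)
    if y_edges is None:
        y_edges = np.arange(counts.shape[1] + 1, dtype=float)
    return LandscapeGrid(np.asarray(x_edges, float), np.asarray(y_edges, float),
                         F, mask, float(temperature))


def barrier_1d(grid: LandscapeGrid, path) -> float:
    """Barrier height along a bin path: max F on the path minus F at its start.

    ``path`` is a sequence of (ix, iy) bin indices connecting two minima;
    crossing a masked (never-visited) bin is an error, since no free energy
    is defined there.
    """
    path = list(path)
    if len(path) < 2:
        raise ValueError("path must contain at least 2 bins")
    values = []
    for step, (ix, iy) in enumerate(path):
        if grid.mask[ix, iy]:
            raise ValueError(f"path crosses empty bin ({ix}, {iy}) at step {step}")
        values.append(grid.F[ix, iy])
    values = np.asarray(values)
    return float(values.max() - values[0])


def path_through_points(grid: LandscapeGrid, points) -> list[tuple[int, int]]:
    """Bin-index path traced by a polyline of embedding-space points.

    Maps every point to its (ix, iy) bin (points outside the grid are
    clamped to the border bin) and drops consecutive duplicates.  Sample
    the polyline finely enough that consecutive points fall in adjacent
    bins.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"points must be (k, 2), got {pts.shape}")
    ix = np.clip(np.searchsorted(grid.x_edges, pts[:, 0], side="right") - 1,
                 0, len(grid.x_edges) - 2)
    iy = np.clip(np.searchsorted(grid.y_edges, pts[:, 1], side="right") - 1,
                 0, len(grid.y_edges) - 2)
    path: list[tuple[int, int]] = []
    for b in zip(ix.tolist(), iy.tolist()):
        if not path or b != path[-1]:
            path.append(b)
    return path


def profile_along_path(Z, points, temperature: float = 300.0,
                       bins: int = 72, max_dist: float | None = None,
                       weights=None):
    """Free-energy profile along a 1-D path through the embedding plane.

    Quantifying a barrier between two basins of a 2-D landscape from single
    grid bins is fragile when the data concentrate on a thin manifold: a
    bin clipped by a short segment of the manifold collects few samples for
    purely geometric reasons and its inverted free energy spikes.  The
    standard remedy is a profile along a path coordinate: every sample is
    assigned the arc-length position of its nearest path vertex, the
    positions are histogrammed in 1-D, and the density is Boltzmann
    inverted.

    Parameters
    ----------
    Z : (n, 2) array
        Embedded samples.
    points : (k, 2) array
        Polyline tracing the path; sample it finely (vertex spacing well
        below the expected data spread).
    temperature : float
        In kelvin.
    bins : int
        Number of equal arc-length bins along the path.
    max_dist : float, optional
        Ignore samples farther than this from every path vertex (a tube
        radius); ``None`` keeps all samples.
    weights : array, optional
        Per-sample nonnegative weights.

    Returns
    -------
    s_centers : (bins,) array
        Arc-length bin centers.
    F : (bins,) array
        Free energy in kJ/mol, min-shifted to zero; NaN on empty bins.
    """
    Z = np.asarray(Z, dtype=float)
    pts = np.asarray(points, dtype=float)
    if Z.ndim != 2 or Z.shape[1] != 2:
        raise ValueError(f"Z must be (n, 2), got {Z.shape}")
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError(f"points must be (k>=2, 2), got {pts.shape}")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s_vertex = np.concatenate([[0.0], np.cumsum(seg)])
    # nearest path vertex per sample, chunked to bound memory
    n = Z.shape[0]
    nearest = np.empty(n, dtype=np.intp)
    dist = np.empty(n)
    step = max(1, int(4e6 // max(1, pts.shape[0])))
    for lo in range(0, n, step):
        d2 = ((Z[lo:lo + step, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
        nearest[lo:lo + step] = d2.argmin(axis=1)
        dist[lo:lo + step] = np.sqrt(d2.min(axis=1))
    keep = np.ones(n, dtype=bool) if max_dist is None else dist <= max_dist
    s = s_vertex[nearest[keep]]
    w = None if weights is None else np.asarray(weights, float)[keep]
    counts, edges = np.histogram(s, bins=bins, range=(0.0, s_vertex[-1]),
                                 weights=w)
    if (counts > 0).sum() == 0:
        raise ValueError("no samples near the path")
    F = np.full(bins, np.nan)
    pos = counts > 0
    F[pos] = -KB_KJ_PER_MOL_K * temperature * np.log(counts[pos] / counts[pos].max())
    return 0.5 * (edges[:-1] + edges[1:]), F


def render_landscape(grid: LandscapeGrid, path=None, ax=None):
    """Render the landscape as a masked pseudocolor map (requires matplotlib).

    Returns the matplotlib axes; saves to ``path`` when given.
    """
    import matplotlib
    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    F = np.ma.masked_where(grid.mask, grid.F)
    mesh = ax.pcolormesh(grid.x_edges, grid.y_edges, F.T, shading="flat")
    ax.figure.colorbar(mesh, ax=ax, label="F (kJ/mol)")
    ax.set_xlabel("z1")
    ax.set_ylabel("z2")
    if path is not None:
        ax.figure.savefig(path, dpi=150)
        plt.close(ax.figure)
    return ax


def write_landscape(path, grid: LandscapeGrid) -> None:
    """Write the grid as TSV: x-center, y-center, F (kJ/mol), mask flag."""
    xc, yc = grid.x_centers, grid.y_centers
    with open(path, "w") as fh:
        fh.write(f"# free-energy landscape, T = {grid.temperature} K\n")
        fh.write("# x_center\ty_center\tF_kJ_per_mol\tempty\n")
        for i, x in enumerate(xc):
            for j, y in enumerate(yc):
                f = grid.F[i, j]
                fh.write(
                    f"{x:.10g}\t{y:.10g}\t"
                    f"{'nan' if grid.mask[i, j] else format(f, '.10g')}\t"
                    f"{int(grid.mask[i, j])}\n"
                )
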