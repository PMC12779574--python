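"""Grid-discretised trait probability densities (TPDs).

Each species is represented by a diagonal Gaussian kernel centred on its
3-D trait-space position; the kernel width plays the role of intraspecific
variation (IV) and is shared across all species in a study landscape.  The
landscape's trait space is discretised into a fixed grid (50 cells per
dimension, 125,000 cells by default), every species' density is evaluated at
cell centres, trimmed to its highest-density region, and renormalised to a
proper probability mass function.  Assemblage TPDs are abundance-weighted
mixtures of member species TPDs on the same grid, which keeps functional
diversity values comparable across land uses within a landscape.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

DEFAULT_CELLS_PER_DIM = 50
DEFAULT_TRIM_ALPHA = 0.99
_KERNEL_EXTENT_SD = 3.0  # grid bounds cover means +/- this many kernel SDs


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned 3-D grid shared by all TPDs within a landscape."""

    n_cells_per_dim: int
    bounds: tuple[tuple[float, float], tuple[float, float], tuple[float, float]]

    def __post_init__(self):
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ValueError("grid bounds must be strictly ordered")

    @property
    def n_cells(self) -> int:
        return self.n_cells_per_dim ** 3

    @property
    def edges(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            np.linspace(lo, hi, self.n_cells_per_dim + 1) for lo, hi in self.bounds
        )

    @property
    def centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(0.5 * (e[:-1] + e[1:]) for e in self.edges)

    @property
    def cell_edge_lengths(self) -> np.ndarray:
        return np.array([(hi - lo) / self.n_cells_per_dim for lo, hi in self.bounds])

    @property
    def cell_volume(self) -> float:
        return float(np.prod(self.cell_edge_lengths))

    def ravel(self, ix: np.ndarray, iy: np.ndarray, iz: np.ndarray) -> np.ndarray:
        """Row-major linear cell index (x slowest, z fastest)."""
        n = self.n_cells_per_dim
        return (ix * n + iy) * n + iz

    def contains(self, point: np.ndarray) -> bool:
        return all(lo <= p <= hi for p, (lo, hi) in zip(point, self.bounds))


@dataclass
class SpeciesTPD:
    """Sparse probability mass for one species over a :class:`GridSpec`."""

    species_id: str
    cell_idx: np.ndarray  # sorted linear indices
    probs: np.ndarray

    def __post_init__(self):
        if len(self.cell_idx) == 0:
            raise ValueError(f"{self.species_id}: empty TPD support")
        if (self.probs < 0).any() or abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError(f"{self.species_id}: probabilities must be >=0 and sum to 1")

    @property
    def support_size(self) -> int:
        return len(self.cell_idx)


@dataclass
class AssemblageTPD:
    """Abundance-weighted mixture of member species TPDs."""

    assemblage_id: str
    cell_idx: np.ndarray
    probs: np.ndarray
    member_ids: list[str]
    weights: np.ndarray
    member_tpds: Mapping[str, SpeciesTPD] = field(repr=False, default_factory=dict)
    _member_pos: dict[str, np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    @property
    def support_size(self) -> int:
        return len(self.cell_idx)

    def member_positions(self, species_id: str) -> np.ndarray:
        """Indices of the member's support cells within ``cell_idx`` (cached)."""
        if self._member_pos is None:
            object.__setattr__(self, "_member_pos", {})
        if species_id not in self._member_pos:
            t = self.member_tpds[species_id]
            self._member_pos[species_id] = np.searchsorted(self.cell_idx, t.cell_idx)
        return self._member_pos[species_id]


def normal_reference_bandwidth(coords: np.ndarray) -> np.ndarray:
    """Diagonal normal-reference (Silverman-type) bandwidth per dimension.

    ``sigma_hat * (4 / ((d + 2) n)) ** (1 / (d + 4))`` with d = number of
    dimensions, n = number of species and sigma_hat the per-dimension sample
    standard deviation of species means.
    """
    coords = np.asarray(coords, dtype=float)
    n, d = coords.shape
    if n < 2:
        raise ValueError("need at least 2 points")
    sd = coords.std(axis=0, ddof=1)
    return sd * (4.0 / ((d + 2) * n)) ** (1.0 / (d + 4))


def estimate_iv_kernel(
    coords: Mapping[str, np.ndarray] | np.ndarray,
    assemblage_members: Sequence[Sequence[str]],
    species_ids: Sequence[str] | None = None,
) -> np.ndarray:
    """Landscape-common intraspecific-variation kernel (3 standard deviations).

    For every assemblage a diagonal bandwidth is estimated from the spread of
    its co-occurring species means via the normal-reference rule; the kernel
    *dimensions* are the variance-scale diagonal entries (squared SD-scale
    bandwidths, matching plug-in estimators that return a variance matrix),
    and the common kernel is the square root of their dimension-wise mean —
    i.e. the root-mean-square of the per-assemblage bandwidths.
    """
    if species_ids is not None:
        coords = {s: np.asarray(coords)[i] for i, s in enumerate(species_ids)}
    bandwidths = []
    for members in assemblage_members:
        members = list(members)
        if len(members) < 4:
            raise ValueError("each assemblage needs >=4 species with coordinates")
        pts = np.stack([coords[s] for s in members])
        bandwidths.append(normal_reference_bandwidth(pts) ** 2)
    mean_bw = np.mean(bandwidths, axis=0)
    if (mean_bw <= 0).any():
        raise ValueError("degenerate axis: zero variance in every assemblage")
    return np.sqrt(mean_bw)


def build_grid(
    coords: np.ndarray,
    kernel: np.ndarray,
    n_cells_per_dim: int = DEFAULT_CELLS_PER_DIM,
    padding: float = 0.02,
) -> GridSpec:
    """Grid covering all species means extended by the kernel, plus padding.

    Bounds per dimension are ``[min - pad * range, max + pad * range]`` where
    min/max are taken over species means extended by ``_KERNEL_EXTENT_SD``
    kernel standard deviations, so at least 99% of every species' kernel mass
    falls inside the grid at the default settings.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    kernel = np.asarray(kernel, dtype=float)
    if (kernel <= 0).any():
        raise ValueError("kernel must be strictly positive")
    lo = coords.min(axis=0) - _KERNEL_EXTENT_SD * kernel
    hi = coords.max(axis=0) + _KERNEL_EXTENT_SD * kernel
    rng = hi - lo
    lo = lo - padding * rng
    hi = hi + padding * rng
    return GridSpec(
        n_cells_per_dim=n_cells_per_dim,
        bounds=tuple((float(a), float(b)) for a, b in zip(lo, hi)),
    )


def species_tpd(
    species_id: str,
    mean: np.ndarray,
    kernel: np.ndarray,
    grid: GridSpec,
    trim_alpha: float = DEFAULT_TRIM_ALPHA,
    _window_sd: float = 5.0,
) -> SpeciesTPD:
    """Diagonal-Gaussian TPD on the grid, trimmed to its highest-density region.

    Each cell receives the exact Gaussian mass over its extent (product of
    per-dimension CDF differences — equivalent to cell-centre density times
    cell volume once the kernel spans several cells, but exact in the
    narrow-kernel limit); after normalising over the grid, cells outside the
    smallest set holding ``trim_alpha`` of the mass are zeroed and the
    remainder renormalised.  Evaluation is windowed to ``_window_sd`` kernel
    SDs around the mean (the mass beyond is numerically negligible).
    """
    from scipy.special import ndtr

    mean = np.asarray(mean, dtype=float)
    kernel = np.asarray(kernel, dtype=float)
    if (kernel <= 0).any():
        raise ValueError("kernel must be strictly positive")
    if not grid.contains(mean):
        raise ValueError(f"{species_id}: mean outside grid bounds; rebuild the grid")

    centers = grid.centers
    edges = grid.edges
    axes_dens, axes_idx = [], []
    for d in range(3):
        c = centers[d]
        lo, hi = mean[d] - _window_sd * kernel[d], mean[d] + _window_sd * kernel[d]
        sel = np.nonzero((c >= lo) & (c <= hi))[0]
        if len(sel) == 0:  # kernel far narrower than a cell: take the nearest centre
            sel = np.array([int(np.argmin(np.abs(c - mean[d])))])
        e = edges[d]
        cdf_hi = ndtr((e[sel + 1] - mean[d]) / kernel[d])
        cdf_lo = ndtr((e[sel] - mean[d]) / kernel[d])
        mass = cdf_hi - cdf_lo
        if mass.sum() <= 0:  # extreme underflow: all mass to the nearest cell
            mass = np.zeros(len(sel))
            mass[int(np.argmin(np.abs(c[sel] - mean[d])))] = 1.0
        axes_dens.append(mass)
        axes_idx.append(sel)

    dens = (
        axes_dens[0][:, None, None]
        * axes_dens[1][None, :, None]
        * axes_dens[2][None, None, :]
    ).ravel()
    ix, iy, iz = np.meshgrid(*axes_idx, indexing="ij")
    lin = grid.ravel(ix.ravel(), iy.ravel(), iz.ravel())

    total = dens.sum()
    if total <= 0:
        raise ValueError(f"{species_id}: zero density on grid")
    probs = dens / total

    # highest-density-region trim: keep the smallest cell set holding trim_alpha
    order = np.argsort(probs)[::-1]
    csum = np.cumsum(probs[order])
    k = int(np.searchsorted(csum, trim_alpha) + 1)
    keep = order[:k]
    lin, probs = lin[keep], probs[keep]
    probs = probs / probs.sum()
    srt = np.argsort(lin)
    return SpeciesTPD(species_id=species_id, cell_idx=lin[srt], probs=probs[srt])


def assemblage_tpd(
    assemblage_id: str,
    members: Sequence[tuple[SpeciesTPD, float]],
) -> AssemblageTPD:
    """Mix member species TPDs with weights proportional to abundance."""
    if not members:
        raise ValueError("empty member list")
    abund = np.array([a for _, a in members], dtype=float)
    if (abund < 0).any():
        raise ValueError("abundances must be non-negative")
    if abund.sum() <= 0:
        raise ValueError("all abundances are zero")
    w = abund / abund.sum()

    all_idx = np.concatenate([t.cell_idx for t, _ in members])
    uniq, inv = np.unique(all_idx, return_inverse=True)
    probs = np.zeros(len(uniq))
    offset = 0
    for (t, _), wi in zip(members, w):
        k = len(t.cell_idx)
        np.add.at(probs, inv[offset : offset + k], wi * t.probs)
        offset += k
    return AssemblageTPD(
        assemblage_id=assemblage_id,
        cell_idx=uniq,
        probs=probs,
        member_ids=[t.species_id for t, _ in members],
        weights=w,
        member_tpds={t.species_id: t for t, _ in members},
    )


def build_landscape_tpds(
    coords: Mapping[str, np.ndarray],
    assemblage_members: Sequence[Sequence[str]],
    n_cells_per_dim: int = DEFAULT_CELLS_PER_DIM,
    trim_alpha: float = DEFAULT_TRIM_ALPHA,
    padding: float = 0.02,
) -> tuple[GridSpec, dict[str, SpeciesTPD], np.ndarray]:
    """Convenience: common kernel, shared grid and one TPD per landscape species."""
    kernel = estimate_iv_kernel(coords, assemblage_members)
    pts = np.stack(list(coords.values()))
    grid = build_grid(pts, kernel, n_cells_per_dim=n_cells_per_dim, padding=padding)
    tpds = {
        sid: species_tpd(sid, xyz, kernel, grid, trim_alpha=trim_alpha)
        for sid, xyz in coords.items()
    }
    return grid, tpds, kernel


__all__ = [
    "DEFAULT_CELLS_PER_DIM", "DEFAULT_TRIM_ALPHA",
    "GridSpec", "SpeciesTPD", "AssemblageTPD",
    "normal_reference_bandwidth", "estimate_iv_kernel", "build_grid",
    "species_tpd", "assemblage_tpd", "build_landscape_tpds",
]
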