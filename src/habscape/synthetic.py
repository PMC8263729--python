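"""Synthetic landscapes, covariates and basin partitions.

The generators emulate the statistical structure the downstream analysis
assumes, without any external data:

* **Land use** — a categorical grid whose class proportions match a requested
  mix.  Urban (construction) cells are seeded as a fixed number of compact,
  mutually disjoint clusters; the remaining cells are assigned to the
  non-urban classes by slicing the rank order of a smoothed Gaussian noise
  field into quantile bands, which yields spatially clustered classes with
  exact (up to rounding) proportions.
* **Urban growth** — a one-shot stochastic conversion of non-urban cells to
  construction, with conversion probability increasing in the urban fraction
  of the 3x3 neighbourhood (compact growth) and the converted count fixed at
  ``round(growth_rate * n_non_urban)``.
* **Covariates** — nighttime-light and population-density surfaces built from
  a smoothed built-up indicator plus Gaussian noise, so both correlate
  positively with built-up density by construction.
* **Basins** — a seeded discrete Voronoi tessellation, with basins below a
  minimum area merged (smallest first) into the neighbour sharing the longest
  border, emulating a watershed partition with a minimum-area rule.

Every generator is a pure function of its integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .landuse import CLASS_CODES, CONSTRUCTION_CODES, is_construction, resolve_code
from .raster import Raster

__all__ = [
    "LandscapeConfig",
    "CovariateConfig",
    "generate_landscape",
    "grow_urban",
    "generate_covariates",
    "generate_basins",
]


@dataclass
class LandscapeConfig:
    """Geometry, class mix and urban seeding of a synthetic land-use grid."""

    grid_height: int = 256
    grid_width: int = 256
    cell_size: float = 30.0  # metres
    class_mix: dict = field(
        default_factory=lambda: {
            "cropland": 0.30,
            "forestland": 0.25,
            "bush_forest": 0.05,
            "high_cover_grassland": 0.10,
            "water": 0.10,
            "city_town": 0.10,
            "rural_settlements": 0.05,
            "unused_land": 0.03,
            "land_reclamation": 0.02,
        }
    )
    n_urban_seeds: int = 5
    epochs: int = 4
    growth_rate: float = 0.05  # fraction of non-urban cells converted per epoch
    compactness: float = 4.0
    smoothing_sigma: float = 4.0  # cells; spatial autocorrelation of the class field
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_height <= 0 or self.grid_width <= 0 or self.n_urban_seeds <= 0:
            raise ValueError("grid dimensions and n_urban_seeds must be positive")
        if not 0.0 <= self.growth_rate <= 1.0:
            raise ValueError("growth_rate must lie in [0, 1]")
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_mix proportions must sum to 1, got {total}")
        # resolve (and validate) class references up front
        self.class_mix = {resolve_code(k): float(v) for k, v in self.class_mix.items()}


@dataclass
class CovariateConfig:
    """Intensity levels and noise of the synthetic NTL / POP covariates.

    ``noise_sd`` is expressed as a fraction of each covariate's
    urban-background contrast, so one knob controls both layers.
    """

    ntl_urban_mean: float = 60.0
    ntl_background_mean: float = 2.0
    pop_urban_mean: float = 1500.0
    pop_background_mean: float = 30.0
    noise_sd: float = 0.05
    smoothing_sigma: float = 3.0  # cells
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ntl_urban_mean <= self.ntl_background_mean:
            raise ValueError("ntl_urban_mean must exceed ntl_background_mean")
        if self.pop_urban_mean <= self.pop_background_mean:
            raise ValueError("pop_urban_mean must exceed pop_background_mean")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _largest_remainder_counts(mix: dict[int, float], n_cells: int) -> dict[int, int]:
    """Integer cell counts per class matching the mix exactly up to rounding."""
    codes = sorted(mix)
    raw = np.array([mix[c] * n_cells for c in codes])
    base = np.floor(raw).astype(int)
    short = n_cells - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:short]] += 1
    return dict(zip(codes, base))


def _grow_disjoint_clusters(
    shape: tuple[int, int], quotas: list[int], rng: np.random.Generator
) -> np.ndarray:
    """Grow ``len(quotas)`` disjoint 4-connected clusters to the given sizes.

    Each cluster claims cells from its own frontier only; cells 8-adjacent to
    a different cluster are off limits, guaranteeing the clusters stay
    separate connected components.  Returns a boolean urban mask.
    """
    H, W = shape
    owner = np.full(shape, -1, dtype=int)  # -1 free, else cluster index
    n_clusters = len(quotas)

    # spread seeds with rejection sampling on a minimum separation
    min_sep = max(3.0, 0.5 * np.sqrt(H * W / max(n_clusters, 1)))
    seeds: list[tuple[int, int]] = []
    for _ in range(10_000):
        if len(seeds) == n_clusters:
            break
        r, c = int(rng.integers(H)), int(rng.integers(W))
        if all((r - sr) ** 2 + (c - sc) ** 2 >= min_sep**2 for sr, sc in seeds):
            seeds.append((r, c))
    while len(seeds) < n_clusters:  # fallback: any free cell
        r, c = int(rng.integers(H)), int(rng.integers(W))
        if (r, c) not in seeds:
            seeds.append((r, c))

    frontiers: list[list[tuple[int, int]]] = [[] for _ in range(n_clusters)]
    sizes = [0] * n_clusters

    def claim(idx: int, r: int, c: int) -> None:
        owner[r, c] = idx
        sizes[idx] += 1
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < H and 0 <= cc < W and owner[rr, cc] == -1:
                frontiers[idx].append((rr, cc))

    for idx, (r, c) in enumerate(seeds):
        if owner[r, c] == -1:
            claim(idx, r, c)

    def other_adjacent(idx: int, r: int, c: int) -> bool:
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                rr, cc = r + dr, c + dc
                if 0 <= rr < H and 0 <= cc < W:
                    o = owner[rr, cc]
                    if o != -1 and o != idx:
                        return True
        return False

    active = [i for i in range(n_clusters) if sizes[i] < quotas[i]]
    while active:
        still = []
        for idx in active:
            grown = False
            frontier = frontiers[idx]
            while frontier and sizes[idx] < quotas[idx]:
                pick = int(rng.integers(len(frontier)))
                r, c = frontier.pop(pick)
                if owner[r, c] != -1 or other_adjacent(idx, r, c):
                    continue
                claim(idx, r, c)
                grown = True
                break
            if sizes[idx] < quotas[idx] and grown:
                still.append(idx)
        active = still
    mask = owner >= 0
    deficit = sum(quotas) - int(mask.sum())
    if deficit > 0:
        # a cluster got boxed in; top up with the free cells nearest to the
        # existing urban area so overall proportions stay exact
        dist = ndimage.distance_transform_edt(~mask)
        free = np.flatnonzero(~mask.ravel())
        nearest = free[np.argsort(dist.ravel()[free], kind="stable")[:deficit]]
        mask.ravel()[nearest] = True
    return mask


def generate_landscape(config: LandscapeConfig) -> Raster:
    """Generate one categorical land-use grid per the config.

    Urban cells form ``n_urban_seeds`` disjoint connected clusters; class
    proportions match ``class_mix`` up to integer rounding.
    """
    rng = np.random.default_rng(config.seed)
    shape = (config.grid_height, config.grid_width)
    n_cells = shape[0] * shape[1]
    counts = _largest_remainder_counts(config.class_mix, n_cells)

    urban_codes = [c for c in counts if c in CONSTRUCTION_CODES]
    urban_total = sum(counts[c] for c in urban_codes)

    codes_grid = np.zeros(shape, dtype=np.int16)
    urban_mask = np.zeros(shape, dtype=bool)
    if urban_total > 0:
        n_seeds = min(config.n_urban_seeds, urban_total)
        quotas = [urban_total // n_seeds] * n_seeds
        for i in range(urban_total - sum(quotas)):
            quotas[i] += 1
        urban_mask = _grow_disjoint_clusters(shape, quotas, rng)
        # partition the urban area among the construction codes by rank of
        # distance from each cluster's core (city/town inner, settlements outer)
        urb_idx = np.flatnonzero(urban_mask.ravel())
        dist_in = ndimage.distance_transform_edt(urban_mask)
        order = np.argsort(-dist_in.ravel()[urb_idx], kind="stable")
        flat = codes_grid.ravel()
        start = 0
        for code in sorted(urban_codes):
            k = counts[code]
            flat[urb_idx[order[start : start + k]]] = code
            start += k

    # non-urban classes: quantile bands of a smoothed noise field
    noise = rng.standard_normal(shape)
    fieldv = ndimage.gaussian_filter(noise, sigma=config.smoothing_sigma, mode="reflect")
    free_idx = np.flatnonzero(~urban_mask.ravel())
    order = np.argsort(fieldv.ravel()[free_idx], kind="stable")
    flat = codes_grid.ravel()
    start = 0
    for code in sorted(c for c in counts if c not in CONSTRUCTION_CODES):
        k = counts[code]
        flat[free_idx[order[start : start + k]]] = code
        start += k
    return Raster(data=codes_grid, cell_size=config.cell_size)


def grow_urban(
    lulc: Raster,
    growth_rate: float,
    compactness: float = 4.0,
    seed: int = 0,
    convert_to: int | str = "city_town",
) -> Raster:
    """Convert ``round(growth_rate * n_non_urban)`` cells to construction.

    Conversion probability is proportional to
    ``exp(compactness * f)`` where f is the urban fraction of the cell's 3x3
    neighbourhood, so growth accretes onto existing urban area when
    ``compactness > 0``.  Existing construction cells are never altered.
    """
    if not 0.0 <= growth_rate <= 1.0:
        raise ValueError("growth_rate must lie in [0, 1]")
    codes = lulc.data.astype(np.int16)
    urban = is_construction(codes)
    if not urban.any():
        raise ValueError("input grid has no construction cells to grow from")
    non_urban = ~urban
    n_convert = int(round(growth_rate * non_urban.sum()))
    out = codes.copy()
    if n_convert > 0:
        rng = np.random.default_rng(seed)
        kernel = np.ones((3, 3))
        frac = ndimage.convolve(urban.astype(float), kernel, mode="constant") / (
            ndimage.convolve(np.ones_like(urban, dtype=float), kernel, mode="constant")
        )
        logw = compactness * frac
        # Gumbel top-k == weighted sampling without replacement
        keys = logw + rng.gumbel(size=codes.shape)
        keys[urban] = -np.inf
        flat = np.argpartition(-keys.ravel(), n_convert - 1)[:n_convert]
        out.ravel()[flat] = resolve_code(convert_to)
    return lulc.with_data(out)


def generate_covariates(
    lulc: Raster, config: CovariateConfig
) -> tuple[Raster, Raster]:
    """Nighttime-light and population rasters tied to built-up density.

    Each covariate is ``background + (urban - background) * s`` where s is the
    Gaussian-smoothed construction indicator, plus zero-mean noise with
    standard deviation ``noise_sd * (urban - background)``; values are clipped
    at zero.
    """
    rng = np.random.default_rng(config.seed)
    built = is_construction(lulc.data).astype(float)
    smooth = ndimage.gaussian_filter(built, sigma=config.smoothing_sigma, mode="reflect")

    def layer(bg: float, urb: float) -> np.ndarray:
        contrast = urb - bg
        vals = bg + contrast * smooth
        if config.noise_sd > 0:
            vals = vals + rng.normal(0.0, config.noise_sd * contrast, size=vals.shape)
        return np.clip(vals, 0.0, None)

    ntl = lulc.with_data(layer(config.ntl_background_mean, config.ntl_urban_mean))
    pop = lulc.with_data(layer(config.pop_background_mean, config.pop_urban_mean))
    return ntl, pop


def _border_lengths(labels: np.ndarray, target: int) -> dict[int, int]:
    """Shared-border cell-pair counts between basin ``target`` and neighbours."""
    counts: dict[int, int] = {}
    mask = labels == target
    for axis in (0, 1):
        a = np.take(labels, np.arange(labels.shape[axis] - 1), axis=axis)
        b = np.take(labels, np.arange(1, labels.shape[axis]), axis=axis)
        am = np.take(mask, np.arange(mask.shape[axis] - 1), axis=axis)
        bm = np.take(mask, np.arange(1, mask.shape[axis]), axis=axis)
        for nb in np.unique(b[am & (b != target)]):
            counts[int(nb)] = counts.get(int(nb), 0) + int(((b == nb) & am).sum())
        for nb in np.unique(a[bm & (a != target)]):
            counts[int(nb)] = counts.get(int(nb), 0) + int(((a == nb) & bm).sum())
    return counts


def _fix_connectivity(labels: np.ndarray) -> np.ndarray:
    """Reattach any disconnected fragments to an adjacent basin."""
    for lab in np.unique(labels):
        comp, n = ndimage.label(labels == lab)
        if n <= 1:
            continue
        sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        for frag in range(1, n + 1):
            if frag == keep:
                continue
            frag_mask = comp == frag
            dil = ndimage.binary_dilation(frag_mask)
            nbrs = labels[dil & ~frag_mask]
            nbrs = nbrs[nbrs != lab]
            if nbrs.size:
                vals, cnts = np.unique(nbrs, return_counts=True)
                labels[frag_mask] = int(vals[np.argmax(cnts)])
    return labels


def generate_basins(
    grid_shape: tuple[int, int],
    n_basins: int,
    min_area_km2: float,
    cell_size: float,
    seed: int = 0,
) -> Raster:
    """Contiguous basin tessellation with a minimum-area merge rule.

    Seeds a discrete Voronoi partition with ``n_basins`` generators, then
    merges basins smaller than ``min_area_km2`` (smallest first) into the
    neighbour sharing the longest border.  Labels are contiguous integers
    from 1, each basin 4-connected.
    """
    H, W = grid_shape
    if n_basins < 1:
        raise ValueError("n_basins must be at least 1")
    if n_basins > H * W:
        raise ValueError("n_basins exceeds the number of grid cells")
    rng = np.random.default_rng(seed)
    flat = rng.choice(H * W, size=n_basins, replace=False)
    seeds = np.column_stack(np.unravel_index(flat, (H, W)))
    rows, cols = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    tree = cKDTree(seeds)
    _, labels = tree.query(np.column_stack([rows.ravel(), cols.ravel()]))
    labels = labels.reshape(H, W).astype(np.int32)
    labels = _fix_connectivity(labels)

    cell_area = (cell_size / 1000.0) ** 2
    min_cells = int(np.ceil(min_area_km2 / cell_area))
    total_cells = H * W
    while True:
        counts = np.bincount(labels.ravel())
        present = np.flatnonzero(counts > 0)
        if present.size <= 1:
            break
        sizes = {int(l): int(counts[int(l)]) for l in present}
        small = [int(l) for l in present if sizes[int(l)] < min(min_cells, total_cells)]
        if not small:
            break
        target = min(small, key=lambda l: sizes[l])
        borders = _border_lengths(labels, target)
        if not borders:
            break
        into = max(borders, key=lambda nb: (borders[nb], -nb))
        labels[labels == target] = into

    labels = _fix_connectivity(labels)
    # relabel to contiguous 1..K in row-major first-occurrence order
    flatlab = labels.ravel()
    _, first = np.unique(flatlab, return_index=True)
    order = flatlab[np.sort(first)]
    remap = {int(old): i + 1 for i, old in enumerate(order)}
    relabeled = np.vectorize(remap.__getitem__)(labels).astype(np.int32)
    return Raster(data=relabeled, cell_size=cell_size)
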