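"""Habitat degradation and quality model.

The model scores every grid cell in two steps.

**Degradation.**  Each threat source class r radiates influence up to a
maximum distance ``d_rmax``; the influence of a source cell y on a cell x
decays with the Euclidean centre-to-centre distance ``d_xy`` either linearly,

    i(d) = 1 - d / d_rmax,

or exponentially with the conventional constant 2.99,

    i(d) = exp(-2.99 d / d_rmax),

and is exactly zero beyond ``d_rmax``.  The decayed presence of threat r
around x is aggregated into a *density* in [0, 1] by normalizing the decayed
sum over actual source cells by the decayed sum over every in-bounds cell of
the kernel: density 1 means every cell within reach of x is a source, 0 means
none is.  Densities are combined across threats with normalized weights and
scaled by the habitat's sensitivity S to each threat and by an optional
accessibility factor beta:

    D(x) = sum_r [w_r / sum w] * density_r(x) * beta(x) * S_{j(x), r}

with j(x) the land class of x.  Under this normalization D is guaranteed to
lie in [0, 1].

**Quality.**  Degradation converts to quality through the half-saturation
form

    Q(x) = H_j * [1 - D^2 / (D^2 + k^2)]

so Q equals the intrinsic suitability H when D = 0 and falls to H/2 when
D = k.  The half-saturation constant k defaults to 0.5.

Quality surfaces are graded into five classes on the thresholds
[0, .2) -> I, [.2, .4) -> II, [.4, .6) -> III, [.6, .8) -> IV, [.8, 1] -> V.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .landuse import CODE_NAMES
from .params import SensitivityTable, ThreatSpec
from .raster import Raster

__all__ = [
    "decay_factor",
    "threat_kernel",
    "threat_presence",
    "threat_density",
    "compute_degradation",
    "compute_quality",
    "grade_quality",
    "DegradationSurface",
    "QualitySurface",
    "GRADE_EDGES",
    "DEFAULT_HALF_SATURATION",
]

DEFAULT_HALF_SATURATION = 0.5

#: Upper-open grade bin edges; Q = 0.2 falls in grade II, Q = 1.0 in grade V.
GRADE_EDGES = np.array([0.2, 0.4, 0.6, 0.8])
GRADE_LABELS = ("I", "II", "III", "IV", "V")


@dataclass
class DegradationSurface:
    """Per-cell habitat degradation D in [0, 1] plus the parameters used."""

    raster: Raster
    threats: list[ThreatSpec]
    normalized: bool = True
    beta_applied: bool = False


@dataclass
class QualitySurface:
    """Per-cell habitat quality Q in [0, 1], its grade map, and k."""

    raster: Raster
    half_saturation: float
    grade: Raster | None = None

    @property
    def data(self) -> np.ndarray:
        return self.raster.data


def decay_factor(d, d_rmax: float, decay: str):
    """Distance-decay i(d) of a threat at distance ``d`` km, reach ``d_rmax`` km.

    Returns a value in [0, 1]; exactly 0 for d > d_rmax; monotone
    non-increasing in d.  ``d`` may be a scalar or array.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    if d_rmax <= 0:
        raise ValueError("d_rmax must be positive")
    if decay == "linear":
        out = 1.0 - d / d_rmax
    elif decay == "exponential":
        out = np.exp(-2.99 * d / d_rmax)
    else:
        raise ValueError(f"unknown decay {decay!r}")
    out = np.where(d > d_rmax, 0.0, out)
    out = np.clip(out, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def threat_kernel(spec: ThreatSpec, cell_size: float, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Decay kernel for one threat on a grid with cells of ``cell_size`` metres.

    The kernel covers every integer offset whose centre distance is within
    ``d_rmax``; entries hold the decay factor at that distance.  When the grid
    ``shape`` is given the kernel radius is clipped to the largest offset that
    can matter on that grid.
    """
    d_rmax_m = spec.d_rmax_km * 1000.0
    radius = int(np.floor(d_rmax_m / cell_size))
    if shape is not None:
        radius = min(radius, max(shape) - 1)
    offsets = np.arange(-radius, radius + 1)
    dy, dx = np.meshgrid(offsets, offsets, indexing="ij")
    dist_km = np.hypot(dy, dx) * cell_size / 1000.0
    kernel = decay_factor(dist_km, spec.d_rmax_km, spec.decay)
    return np.asarray(kernel)


def threat_presence(lulc: Raster, spec: ThreatSpec) -> np.ndarray:
    """Binary source map: 1 where the cell's land class belongs to the threat."""
    codes = np.unique(lulc.data[lulc.valid_mask])
    unknown = [int(c) for c in codes if int(c) not in CODE_NAMES]
    if unknown:
        warnings.warn(
            f"land-use grid contains unknown codes {unknown}; treated as non-threat",
            stacklevel=2,
        )
    return np.isin(lulc.data, spec.source_codes).astype(float)


def threat_density(
    presence: np.ndarray,
    spec: ThreatSpec,
    cell_size: float,
    normalize: bool = True,
) -> np.ndarray:
    """Decayed, kernel-normalized threat exposure in [0, 1] at every cell.

    With ``normalize`` (default) the decayed sum over source cells is divided
    by the decayed sum over all in-bounds cells of the kernel, so an
    all-source map scores 1 everywhere (edges included — the normalizer uses
    no padding) and a source-free map scores 0.  ``normalize=False`` returns
    the raw decayed sum.
    """
    presence = np.asarray(presence, dtype=float)
    kernel = threat_kernel(spec, cell_size, shape=presence.shape)
    num = fftconvolve(presence, kernel, mode="same")
    if not normalize:
        return num
    den = fftconvolve(np.ones_like(presence), kernel, mode="same")
    return np.clip(num / den, 0.0, 1.0)


def compute_degradation(
    lulc: Raster,
    threats: list[ThreatSpec],
    sens: SensitivityTable,
    accessibility: Raster | None = None,
    normalize: bool = True,
) -> DegradationSurface:
    """Aggregate weighted, sensitivity-scaled threat densities into D per cell.

    ``accessibility`` is an optional per-cell factor beta in [0, 1] scaling
    the exposure (1 everywhere when omitted).
    """
    total_w = sum(t.weight for t in threats)
    if total_w <= 0:
        raise ValueError("threat weights must not all be zero")

    codes = lulc.data.astype(int)
    max_code = int(codes.max(initial=0))
    D = np.zeros(lulc.shape, dtype=float)
    for spec in threats:
        presence = threat_presence(lulc, spec)
        density = threat_density(presence, spec, lulc.cell_size, normalize=normalize)
        s_lut = sens.sensitivity_lookup(spec.name, max_code=max_code)
        D += (spec.weight / total_w) * density * s_lut[codes]
    if accessibility is not None:
        lulc.require_same_geometry(accessibility)
        D *= accessibility.data
    if normalize:
        D = np.clip(D, 0.0, 1.0)
    out = lulc.with_data(D.astype(float))
    return DegradationSurface(
        raster=out, threats=list(threats), normalized=normalize,
        beta_applied=accessibility is not None,
    )


def compute_quality(
    degradation: DegradationSurface | Raster,
    sens: SensitivityTable,
    lulc: Raster,
    k: float = DEFAULT_HALF_SATURATION,
    with_grade: bool = True,
) -> QualitySurface:
    """Half-saturation quality Q = H * [1 - D^2/(D^2 + k^2)] per cell."""
    if k <= 0:
        raise ValueError("half-saturation constant k must be positive")
    D = degradation.raster.data if isinstance(degradation, DegradationSurface) else degradation.data
    codes = lulc.data.astype(int)
    h_lut = sens.suitability_lookup(max_code=int(codes.max(initial=0)))
    H = h_lut[codes]
    Q = H * (1.0 - D**2 / (D**2 + k**2))
    qr = lulc.with_data(Q.astype(float))
    surface = QualitySurface(raster=qr, half_saturation=k)
    if with_grade:
        surface.grade = grade_quality(surface)
    return surface


def grade_quality(quality: QualitySurface | Raster) -> Raster:
    """Map Q to grades 1–5 (I–V) on the 0.2-wide quality bands."""
    qr = quality.raster if isinstance(quality, QualitySurface) else quality
    Q = qr.data
    finite = np.isfinite(Q)
    if np.any((Q[finite] < 0) | (Q[finite] > 1)):
        raise ValueError("quality values must lie in [0, 1]")
    grades = np.digitize(Q, GRADE_EDGES, right=False) + 1
    grades = grades.astype(np.uint8)
    grades[~finite] = 0
    return qr.with_data(grades, nodata=0)
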