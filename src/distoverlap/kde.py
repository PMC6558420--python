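"""Kernel density estimation and the plug-in overlapping index.

The overlapping index eta(A, B) of two densities is the area under their
pointwise minimum,

    eta(A, B) = integral of min(f_A(x), f_B(x)) dx,

which equals 1 for identical distributions and 0 for distributions with
disjoint supports.  When only samples are available, the densities are
replaced by kernel density estimates evaluated on a shared, equally spaced
grid, and the integral is computed with the trapezoidal rule.  This module
implements that plug-in estimator together with its supporting pieces:
bandwidth selection, the shared evaluation grid, density estimation,
intersection points of two density curves, and the pairwise overlap matrix
for more than two groups.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DegenerateSpreadError",
    "GridMismatchError",
    "Sample",
    "KernelSpec",
    "Grid",
    "DensityEstimate",
    "PairOverlap",
    "OverlapMatrix",
    "silverman_bandwidth",
    "scott_bandwidth",
    "bandwidth_for",
    "build_common_grid",
    "estimate_density",
    "overlap_hat",
    "intersection_points",
    "pairwise_overlap",
]

#: Default number of equally spaced grid points for the integral computations.
DEFAULT_NBINS = 1024

#: Grid extension beyond the pooled data range, in units of the largest
#: per-sample bandwidth (mirrors the tail cut-off of classic density routines).
GRID_CUT = 3.0


class DegenerateSpreadError(ValueError):
    """Raised when a sample has zero spread (all values identical)."""


class GridMismatchError(ValueError):
    """Raised when two density estimates do not share the same grid."""


@dataclass(frozen=True)
class Sample:
    """A labelled vector of univariate observations for one group.

    Parameters
    ----------
    label : str
        Non-empty group identifier.
    values : numpy.ndarray
        Finite float observations; at least 3 are required so that a
        bandwidth can be estimated.
    """

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("sample label must be non-empty")
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1:
            raise ValueError(f"sample {self.label!r}: values must be 1-D")
        if vals.size < 3:
            raise ValueError(
                f"sample {self.label!r}: need at least 3 observations, got {vals.size}"
            )
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"sample {self.label!r}: non-finite values present")
        object.__setattr__(self, "values", vals)

    @property
    def n(self) -> int:
        return int(self.values.size)


_KERNELS = ("gaussian", "epanechnikov", "biweight")
_BANDWIDTH_RULES = ("silverman_nrd0", "scott")


@dataclass(frozen=True)
class KernelSpec:
    """Kernel shape and bandwidth rule for density estimation.

    ``bandwidth`` is either the name of a data-driven rule
    (``"silverman_nrd0"`` — the default normal reference rule — or
    ``"scott"``) or a fixed positive number used verbatim for every sample.
    """

    kernel: str = "gaussian"
    bandwidth: str | float = "silverman_nrd0"

    def __post_init__(self) -> None:
        if self.kernel not in _KERNELS:
            raise ValueError(f"unknown kernel {self.kernel!r}; choose from {_KERNELS}")
        if isinstance(self.bandwidth, str):
            if self.bandwidth not in _BANDWIDTH_RULES:
                raise ValueError(
                    f"unknown bandwidth rule {self.bandwidth!r}; "
                    f"choose from {_BANDWIDTH_RULES} or a positive number"
                )
        else:
            if not (float(self.bandwidth) > 0):
                raise ValueError("fixed bandwidth must be > 0")


@dataclass(frozen=True)
class Grid:
    """Equally spaced evaluation grid shared by a set of density estimates."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 1 or pts.size < 2:
            raise ValueError("grid needs at least 2 points")
        steps = np.diff(pts)
        if np.any(steps <= 0):
            raise ValueError("grid points must be strictly increasing")
        span = pts[-1] - pts[0]
        if np.max(np.abs(steps - steps[0])) > 1e-12 * max(span, 1.0):
            raise ValueError("grid points must be equally spaced")
        object.__setattr__(self, "points", pts)

    @property
    def nbins(self) -> int:
        return int(self.points.size)

    @property
    def lower(self) -> float:
        return float(self.points[0])

    @property
    def upper(self) -> float:
        return float(self.points[-1])

    @property
    def spacing(self) -> float:
        return float((self.upper - self.lower) / (self.nbins - 1))


@dataclass(frozen=True)
class DensityEstimate:
    """A kernel density estimate evaluated on a grid, with unit trapezoidal mass."""

    grid: Grid
    ordinates: np.ndarray
    source_label: str
    bandwidth_used: float

    def __post_init__(self) -> None:
        ords = np.asarray(self.ordinates, dtype=float)
        if ords.shape != self.grid.points.shape:
            raise ValueError("ordinates must align with the grid")
        if not np.all(np.isfinite(ords)) or np.any(ords < 0):
            raise ValueError("density ordinates must be finite and non-negative")
        if self.bandwidth_used <= 0:
            raise ValueError("bandwidth must be > 0")
        object.__setattr__(self, "ordinates", ords)


@dataclass(frozen=True)
class PairOverlap:
    """Overlap estimate for one pair of groups."""

    label_a: str
    label_b: str
    eta: float
    xpoints: np.ndarray
    grid: Grid
    bandwidth_a: float = float("nan")
    bandwidth_b: float = float("nan")


@dataclass(frozen=True)
class OverlapMatrix:
    """Symmetric pairwise overlap matrix over K groups (unit diagonal)."""

    labels: tuple[str, ...]
    values: np.ndarray
    pairs: tuple[PairOverlap, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        if vals.shape != (k, k):
            raise ValueError("matrix shape must be K x K")
        object.__setattr__(self, "values", vals)

    def pair(self, label_a: str, label_b: str) -> float:
        i, j = self.labels.index(label_a), self.labels.index(label_b)
        return float(self.values[i, j])


# --------------------------------------------------------------------------
# bandwidths

def _iqr(values: np.ndarray) -> float:
    # linearly interpolated quartiles (numpy default; R quantile type 7)
    q1, q3 = np.percentile(values, [25.0, 75.0])
    return float(q3 - q1)


def _spread(sample: Sample) -> float:
    """Robust spread min(sd, IQR/1.34) with one-sided fallback."""
    sd = float(np.std(sample.values, ddof=1))
    iqr_term = _iqr(sample.values) / 1.34
    if sd > 0 and iqr_term > 0:
        return min(sd, iqr_term)
    if sd > 0 or iqr_term > 0:
        return max(sd, iqr_term)
    raise DegenerateSpreadError(
        f"sample {sample.label!r}: all values identical, bandwidth undefined"
    )


def silverman_bandwidth(sample: Sample) -> float:
    """Silverman's normal reference rule, 0.9 * min(sd, IQR/1.34) * n^(-1/5)."""
    return 0.9 * _spread(sample) * sample.n ** (-0.2)


def scott_bandwidth(sample: Sample) -> float:
    """Scott's variant of the normal reference rule (factor 1.06)."""
    return 1.06 * _spread(sample) * sample.n ** (-0.2)


def bandwidth_for(sample: Sample, spec: KernelSpec) -> float:
    """Resolve the bandwidth a :class:`KernelSpec` prescribes for a sample."""
    if isinstance(spec.bandwidth, str):
        if spec.bandwidth == "silverman_nrd0":
            return silverman_bandwidth(sample)
        return scott_bandwidth(sample)
    return float(spec.bandwidth)


# --------------------------------------------------------------------------
# kernels

def _kernel_values(u: np.ndarray, kernel: str) -> np.ndarray:
    if kernel == "gaussian":
        return np.exp(-0.5 * u * u) / math.sqrt(2.0 * math.pi)
    if kernel == "epanechnikov":
        out = 0.75 * (1.0 - u * u)
        return np.where(np.abs(u) < 1.0, out, 0.0)
    # biweight
    t = 1.0 - u * u
    out = (15.0 / 16.0) * t * t
    return np.where(np.abs(u) < 1.0, out, 0.0)


# --------------------------------------------------------------------------
# grid and densities

def build_common_grid(
    samples: list[Sample],
    kernel_spec: KernelSpec | None = None,
    nbins: int = DEFAULT_NBINS,
    cut: float = GRID_CUT,
) -> Grid:
    """Build one equally spaced grid covering all samples.

    The grid spans the pooled data range extended by ``cut`` times the
    largest per-sample bandwidth on each side, so that kernel tails are
    captured for every group.
    """
    kernel_spec = kernel_spec or KernelSpec()
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to build a common grid")
    if nbins < 16:
        raise ValueError(f"nbins={nbins} is too coarse for integration (minimum 16)")
    bwmax = max(bandwidth_for(s, kernel_spec) for s in samples)
    lo = min(float(np.min(s.values)) for s in samples) - cut * bwmax
    hi = max(float(np.max(s.values)) for s in samples) + cut * bwmax
    return Grid(np.linspace(lo, hi, nbins))


# support radius beyond which each kernel is (numerically) zero, in bandwidth
# units; the Gaussian tail past 8.7 sd is below double-precision resolution
_KERNEL_SUPPORT = {"gaussian": 8.7, "epanechnikov": 1.0, "biweight": 1.0}


def _kde_on_grid(
    values: np.ndarray, grid_points: np.ndarray, bandwidth: float, kernel: str
) -> np.ndarray:
    """Direct (non-binned) KDE evaluation of n^-1 sum_i K((z - x_i)/beta)/beta.

    Small problems are evaluated as one broadcast; large ones restrict each
    grid point to the observations inside the kernel's numerical support,
    which is exact to double precision.
    """
    n, m = values.size, grid_points.size
    if n * m <= 2_000_000:
        u = (grid_points[None, :] - values[:, None]) / bandwidth
        out = _kernel_values(u, kernel).sum(axis=0)
    else:
        xs = np.sort(values)
        radius = _KERNEL_SUPPORT[kernel] * bandwidth
        lo = np.searchsorted(xs, grid_points - radius, side="left")
        hi = np.searchsorted(xs, grid_points + radius, side="right")
        out = np.zeros_like(grid_points)
        for j in range(m):
            if hi[j] > lo[j]:
                u = (grid_points[j] - xs[lo[j] : hi[j]]) / bandwidth
                out[j] = _kernel_values(u, kernel).sum()
    return out / (n * bandwidth)


def estimate_density(
    sample: Sample, grid: Grid, kernel_spec: KernelSpec | None = None
) -> DensityEstimate:
    """Kernel density estimate of one sample on a grid.

    Ordinates are (1/n) * sum_i K((z - x_i)/beta)/beta at each grid point z,
    then rescaled so the trapezoidal integral over the grid is exactly 1
    (the grid truncates the kernel tails, so a small mass renormalization is
    required for eta(A, A) = 1 to hold).
    """
    kernel_spec = kernel_spec or KernelSpec()
    bw = bandwidth_for(sample, kernel_spec)
    if bw <= 0:
        raise ValueError("bandwidth must be > 0")
    raw = _kde_on_grid(sample.values, grid.points, bw, kernel_spec.kernel)
    mass = float(np.trapezoid(raw, grid.points))
    if not np.isfinite(mass) or mass <= 0:
        raise ValueError(
            f"sample {sample.label!r}: no density mass on the grid "
            f"[{grid.lower}, {grid.upper}]"
        )
    return DensityEstimate(
        grid=grid,
        ordinates=raw / mass,
        source_label=sample.label,
        bandwidth_used=bw,
    )


def _require_shared_grid(dens_a: DensityEstimate, dens_b: DensityEstimate) -> None:
    if dens_a.grid.points is dens_b.grid.points:
        return
    if not np.array_equal(dens_a.grid.points, dens_b.grid.points):
        raise GridMismatchError(
            "density estimates are on different grids; rebuild them on a common "
            "grid instead of re-interpolating"
        )


# --------------------------------------------------------------------------
# overlap

def overlap_hat(dens_a: DensityEstimate, dens_b: DensityEstimate) -> PairOverlap:
    """Plug-in overlap: trapezoidal integral of min(f_A, f_B) on the shared grid."""
    _require_shared_grid(dens_a, dens_b)
    z = dens_a.grid.points
    eta = float(np.trapezoid(np.minimum(dens_a.ordinates, dens_b.ordinates), z))
    eta = min(1.0, max(0.0, eta))
    return PairOverlap(
        label_a=dens_a.source_label,
        label_b=dens_b.source_label,
        eta=eta,
        xpoints=intersection_points(dens_a, dens_b),
        grid=dens_a.grid,
        bandwidth_a=dens_a.bandwidth_used,
        bandwidth_b=dens_b.bandwidth_used,
    )


def intersection_points(
    dens_a: DensityEstimate, dens_b: DensityEstimate
) -> np.ndarray:
    """Abscissas where the two density curves cross.

    Only strict sign changes of d(z) = f_A(z) - f_B(z) count as crossings:
    a plain sign change between adjacent grid points yields the linearly
    interpolated root, while a run of exact zeros flanked by opposite signs
    collapses to the midpoint of the run.  Tangencies (zero runs flanked by
    equal signs) and identical densities yield no points.
    """
    _require_shared_grid(dens_a, dens_b)
    z = dens_a.grid.points
    d = dens_a.ordinates - dens_b.ordinates
    sign = np.sign(d)

    nz = np.flatnonzero(sign)
    if nz.size < 2:
        return np.array([])

    # consecutive non-zero points with opposite signs, possibly separated by
    # a run of exact zeros
    change = np.flatnonzero(sign[nz[1:]] != sign[nz[:-1]])
    if change.size == 0:
        return np.array([])
    i0, i1 = nz[change], nz[change + 1]
    d0, d1 = d[i0], d[i1]
    interp_root = z[i0] + (z[i1] - z[i0]) * d0 / (d0 - d1)
    zero_run_mid = 0.5 * (z[np.minimum(i0 + 1, z.size - 1)] + z[np.maximum(i1 - 1, 0)])
    roots = np.where(i1 == i0 + 1, interp_root, zero_run_mid)
    return np.sort(roots)


def pairwise_overlap(
    samples: list[Sample],
    kernel_spec: KernelSpec | None = None,
    nbins: int = DEFAULT_NBINS,
) -> OverlapMatrix:
    """Overlap of every unordered pair among K >= 2 groups.

    All densities are estimated on one grid common to the K samples, then
    the K(K-1)/2 pair overlaps are assembled into a symmetric matrix with
    unit diagonal.
    """
    kernel_spec = kernel_spec or KernelSpec()
    labels = [s.label for s in samples]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate sample labels: {labels}")
    grid = build_common_grid(samples, kernel_spec, nbins=nbins)
    densities = [estimate_density(s, grid, kernel_spec) for s in samples]

    k = len(samples)
    values = np.eye(k)
    pairs: list[PairOverlap] = []
    for i, j in itertools.combinations(range(k), 2):
        p = overlap_hat(densities[i], densities[j])
        values[i, j] = values[j, i] = p.eta
        pairs.append(p)
    return OverlapMatrix(labels=tuple(labels), values=values, pairs=tuple(pairs))
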