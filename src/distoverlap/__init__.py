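"""distoverlap: distribution-free overlap between empirical distributions.

The central quantity is the overlapping index eta, the area under the
pointwise minimum of two probability densities (1 = identical, 0 =
disjoint).  The package estimates eta from raw samples via kernel density
estimation on a shared grid (``overlap`` / ``pairwise_overlap``), provides
the exact Normal closed forms that anchor it to Cohen's d
(``closed_form``), classical two-sample statistics (``effect_stats``),
bootstrap intervals (``resampling``), synthetic scenario generators
(``synthetic``), and a small CLI (``overlap`` command).
"""

__version__ = "0.1.0"

from .kde import (
    DegenerateSpreadError,
    DensityEstimate,
    Grid,
    GridMismatchError,
    KernelSpec,
    OverlapMatrix,
    PairOverlap,
    Sample,
    build_common_grid,
    estimate_density,
    intersection_points,
    overlap_hat,
    pairwise_overlap,
    silverman_bandwidth,
)
from .closed_form import (
    NormalParams,
    normal_overlap_equal_sd,
    normal_overlap_general,
    numeric_overlap_oracle,
    overlap_from_cohens_d,
)
from .effect_stats import (
    ErrorComponents,
    TwoSampleSummary,
    classification_error_components,
    cohens_d_pooled,
    complement_delta,
    pooled_sd,
    pooled_t,
    welch_t,
)
from .resampling import BootstrapResult, bootstrap_eta


def overlap(
    sample_a: Sample,
    sample_b: Sample,
    kernel_spec: KernelSpec | None = None,
    nbins: int = 1024,
) -> PairOverlap:
    """Estimate the overlap of two samples end to end.

    Convenience wrapper: builds the common grid, estimates both densities,
    and integrates the pointwise minimum.
    """
    kernel_spec = kernel_spec or KernelSpec()
    grid = build_common_grid([sample_a, sample_b], kernel_spec, nbins=nbins)
    return overlap_hat(
        estimate_density(sample_a, grid, kernel_spec),
        estimate_density(sample_b, grid, kernel_spec),
    )


__all__ = [
    "__version__",
    "overlap",
    "DegenerateSpreadError",
    "DensityEstimate",
    "Grid",
    "GridMismatchError",
    "KernelSpec",
    "OverlapMatrix",
    "PairOverlap",
    "Sample",
    "build_common_grid",
    "estimate_density",
    "intersection_points",
    "overlap_hat",
    "pairwise_overlap",
    "silverman_bandwidth",
    "NormalParams",
    "normal_overlap_equal_sd",
    "normal_overlap_general",
    "numeric_overlap_oracle",
    "overlap_from_cohens_d",
    "ErrorComponents",
    "TwoSampleSummary",
    "classification_error_components",
    "cohens_d_pooled",
    "complement_delta",
    "pooled_sd",
    "pooled_t",
    "welch_t",
    "BootstrapResult",
    "bootstrap_eta",
]
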