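"""Intensity preprocessing: histogram matching and linear normalization.

A DRR is computed from the planning CT while the kV radiograph comes off
the flat-panel imager with its own acquisition technique (mAs/kVp), so
their grey-level distributions are related by an unknown monotone map.
Quantile-landmark histogram matching estimates that map and applies it to
the kV image before any similarity metric is evaluated; without it the
metric landscapes are dominated by the intensity mismatch rather than the
anatomy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import ConfigError, ProjectionImage

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class HistogramMatchConfig:
    """Configuration of the quantile-landmark histogram matcher.

    ``n_levels`` sets the histogram resolution used to estimate quantiles
    (and hence the bin width within which matched landmarks agree);
    ``n_quantiles`` is the number of matched landmarks; when
    ``exclude_below_mean`` is set, pixels at or below the image mean (the
    dark background surrounding the patient) are excluded from landmark
    estimation, though the fitted map is still applied to them.
    """

    n_levels: int = 1024
    n_quantiles: int = 7
    exclude_below_mean: bool = True

    def __post_init__(self) -> None:
        if self.n_levels < 8:
            raise ConfigError(f"n_levels must be >= 8, got {self.n_levels}")
        if not 1 <= self.n_quantiles <= self.n_levels:
            raise ConfigError(
                f"n_quantiles must be in [1, n_levels], got {self.n_quantiles}"
            )


def _foreground(values: np.ndarray, exclude_below_mean: bool) -> np.ndarray:
    if not exclude_below_mean:
        return values
    sel = values[values > values.mean()]
    return sel if sel.size else values


def _histogram_quantiles(values: np.ndarray, levels: np.ndarray, n_bins: int) -> np.ndarray:
    """Quantile landmarks estimated from an n_bins histogram CDF."""
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        return np.full(levels.shape, lo)
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    cdf = np.concatenate([[0.0], np.cumsum(counts)]) / values.size
    return np.interp(levels, cdf, edges)


def histogram_match(
    source: ProjectionImage,
    reference: ProjectionImage,
    config: HistogramMatchConfig | None = None,
) -> ProjectionImage:
    """Monotonically remap ``source`` intensities onto ``reference``'s.

    Quantile landmarks of the (foreground) source are mapped piecewise-
    linearly onto the corresponding reference landmarks; intensities
    beyond the outermost landmarks are extrapolated with the end-segment
    slopes.  The remap is monotone non-decreasing by construction, so the
    ordering of source intensities is preserved.

    A source that is constant after foreground exclusion is returned
    unchanged with a logged warning.
    """
    cfg = config or HistogramMatchConfig()
    src = source.pixels.ravel()
    ref = reference.pixels.ravel()
    src_fg = _foreground(src, cfg.exclude_below_mean)
    ref_fg = _foreground(ref, cfg.exclude_below_mean)

    if np.unique(src_fg).size < 2:
        log.warning("histogram_match: source constant after exclusion; returning unchanged")
        return source.with_pixels(source.pixels.copy())

    levels = (
        np.linspace(0.0, 1.0, cfg.n_quantiles)
        if cfg.n_quantiles > 1
        else np.array([0.5])
    )
    src_lm = _histogram_quantiles(src_fg, levels, cfg.n_levels)
    ref_lm = _histogram_quantiles(ref_fg, levels, cfg.n_levels)
    if cfg.exclude_below_mean:
        # anchor the low end at the full-image minima so the excluded
        # background maps into the reference's background range instead of
        # being extrapolated off-scale
        src_lm = np.concatenate([[src.min()], src_lm])
        ref_lm = np.concatenate([[ref.min()], ref_lm])
    # enforce monotone knots; collapse duplicate source landmarks
    ref_lm = np.maximum.accumulate(ref_lm)
    src_lm, idx = np.unique(src_lm, return_index=True)
    ref_lm = ref_lm[idx]

    if src_lm.size == 1:
        mapped = src - src_lm[0] + ref_lm[0]
    else:
        mapped = np.interp(src, src_lm, ref_lm)
        # linear extrapolation beyond the end landmarks
        lo_slope = (ref_lm[1] - ref_lm[0]) / (src_lm[1] - src_lm[0])
        hi_slope = (ref_lm[-1] - ref_lm[-2]) / (src_lm[-1] - src_lm[-2])
        below = src < src_lm[0]
        above = src > src_lm[-1]
        mapped[below] = ref_lm[0] + (src[below] - src_lm[0]) * lo_slope
        mapped[above] = ref_lm[-1] + (src[above] - src_lm[-1]) * hi_slope

    return source.with_pixels(mapped.reshape(source.shape))


def normalize(image: ProjectionImage) -> ProjectionImage:
    """Linearly rescale intensities to [0, 1]; constant images map to 0.5."""
    lo = float(image.pixels.min())
    hi = float(image.pixels.max())
    if hi <= lo:
        log.warning("normalize: constant image; mapping to 0.5 everywhere")
        return image.with_pixels(np.full(image.shape, 0.5))
    return image.with_pixels((image.pixels - lo) / (hi - lo))
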