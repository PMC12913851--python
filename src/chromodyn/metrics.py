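"""DNA-density, intensity and coefficient-of-variation metrics.

Chromatin compaction is read out from the DNA counterstain:

* the *normalized DNA image* divides each background-subtracted DNA frame
  by its maximum over the nucleus mask, mapping intensities to [0, 1];
* *DNA density* is the mean of that normalized image over the damage foci
  (restricted to the nucleus) — high values mean the damage sits in
  compact, heterochromatic regions;
* the *coefficient of variation* CV = σ/μ of the counterstain in the
  damage-area mask reports staining heterogeneity: compact chromatin is
  heterogeneous (high CV), relaxed chromatin homogeneous (low CV).

Traces can be normalized to the first post-bleach time point or to their
peak for cross-cell comparison.
"""

from __future__ import annotations

import numpy as np

from .errors import NormalizationError

__all__ = [
    "normalized_dna_image",
    "dna_density",
    "roi_stats",
    "normalize_trace",
]


def normalized_dna_image(
    dna_frame: np.ndarray, nucleus_mask: np.ndarray
) -> np.ma.MaskedArray:
    """DNA frame divided by its in-nucleus maximum; masked outside.

    The maximum is taken strictly over the nucleus mask, so bright pixels
    outside the nucleus (debris, neighboring cells) cannot skew the
    normalization.  Raises :class:`NormalizationError` if the in-mask
    maximum is not positive.
    """
    frame = np.asarray(dna_frame, dtype=float)
    mask = np.asarray(nucleus_mask, dtype=bool)
    if not mask.any():
        raise NormalizationError("empty nucleus mask")
    i_max = frame[mask].max()
    if i_max <= 0:
        raise NormalizationError(f"in-nucleus maximum must be > 0, got {i_max}")
    return np.ma.MaskedArray(frame / i_max, mask=~mask)


def dna_density(
    dna_frame: np.ndarray,
    nucleus_mask: np.ndarray,
    foci_mask: np.ndarray,
) -> float:
    """Mean normalized DNA intensity at the damage foci, in [0, 1].

    The averaging region is nucleus ∩ foci; an empty region yields NaN
    (flagged missing) so time-series code continues.
    """
    region = np.asarray(nucleus_mask, dtype=bool) & np.asarray(foci_mask, dtype=bool)
    if not region.any():
        return float("nan")
    norm = normalized_dna_image(dna_frame, nucleus_mask)
    return float(norm.data[region].mean())


def roi_stats(frame: np.ndarray, mask: np.ndarray) -> tuple[float, float, float]:
    """Mean, population standard deviation and CV = σ/μ inside a mask.

    CV is NaN when the mean is zero (undefined ratio).  Requires at least
    two mask pixels for a meaningful σ.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 2:
        raise ValueError("mask must contain at least 2 pixels")
    vals = np.asarray(frame, dtype=float)[mask]
    mu = float(vals.mean())
    sigma = float(vals.std())  # population (n) definition
    cv = sigma / mu if mu != 0 else float("nan")
    return mu, sigma, cv


def normalize_trace(
    series: np.ndarray,
    time_s: np.ndarray,
    mode: str = "first_post",
) -> np.ndarray:
    """Normalize a metric trace for cross-cell comparison.

    ``first_post`` divides by the value at the first post-bleach stamp
    (t > 0); ``peak`` divides by the series maximum.  NaNs propagate but
    are ignored when locating the peak.  The reference must be positive.
    """
    y = np.asarray(series, dtype=float)
    t = np.asarray(time_s, dtype=float)
    if mode == "first_post":
        post = np.nonzero(t > 0)[0]
        if len(post) == 0:
            raise NormalizationError("no post-bleach time points")
        ref = y[post[0]]
    elif mode == "peak":
        if not np.isfinite(y).any():
            raise NormalizationError("all-NaN trace")
        ref = np.nanmax(y)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if not np.isfinite(ref) or ref <= 0:
        raise NormalizationError(f"normalization reference must be > 0, got {ref}")
    return y / ref
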