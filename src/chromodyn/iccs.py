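"""Mask-restricted image cross-correlation spectroscopy (ICCS).

Colocalization of two image channels is quantified from the amplitudes of
their spatial correlation functions rather than pixel-wise coefficients.
For fluctuation images ``δx = x − ⟨x⟩_mask`` (zero outside the mask) the
correlation surface is

    G(ξ, η) = ⟨δa δb⟩(ξ, η) / (⟨a⟩_mask ⟨b⟩_mask),

where the pair average at lag (ξ, η) divides the pair sum by the number of
in-mask pixel pairs at that lag — obtained from the autocorrelation of the
mask itself, so arbitrarily shaped analysis regions (e.g. the irradiated
part of one nucleus) are handled exactly.

The cross-correlation fraction of channel 1 is

    f1 = G_cc(0, 0) / G_ac,2(0),

the ratio of the cross-correlation amplitude at zero lag (measured
directly: detector shot noise is uncorrelated between channels) to the
channel-2 autocorrelation amplitude extrapolated to zero lag by a radial
Gaussian fit that excludes the r = 0 bin (which carries the shot-noise
spike).  f1 = 1 means every channel-1 fluctuation is mirrored in channel 2,
0 means no co-fluctuation, and −1 maximal anti-correlation; f2 swaps the
roles of the channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.signal import fftconvolve

from .errors import InsufficientRegionError, NormalizationError
from .stack import TimelapseStack

__all__ = [
    "CorrelationSurface",
    "CorrelationFit",
    "ColocFractions",
    "masked_correlation",
    "fit_amplitude",
    "coloc_fractions",
    "timelapse_iccs",
]

MIN_MASK_PIXELS = 100


@dataclass
class CorrelationSurface:
    """2D spatial correlation over lag offsets, centered at zero lag."""

    values: np.ndarray  # (2L+1, 2L+1) correlation values
    lags_px: np.ndarray  # (2L+1,) lag axis, −L..L
    n_pairs: np.ndarray  # per-lag count of contributing in-mask pixel pairs

    @property
    def max_lag(self) -> int:
        return int(self.lags_px[-1])

    @property
    def zero_lag(self) -> float:
        c = self.max_lag
        return float(self.values[c, c])

    def central_mean(self, half: int = 1) -> float:
        """Mean over the (2*half+1)^2 central lags (optional smoothing of
        the zero-lag estimate)."""
        c = self.max_lag
        return float(self.values[c - half : c + half + 1, c - half : c + half + 1].mean())


@dataclass
class CorrelationFit:
    """Radial Gaussian fit g(r) = g0·exp(−r²/w²) + offset."""

    g0: float
    width_px: float
    offset: float
    success: bool
    residual_rms: float


@dataclass
class ColocFractions:
    """Cross-correlation fractions and the amplitudes they derive from."""

    f1: float
    f2: float
    gcc0: float
    gac1_0: float
    gac2_0: float
    valid: bool = True


def masked_correlation(
    img_a: np.ndarray,
    img_b: np.ndarray,
    mask: np.ndarray,
    max_lag: int = 32,
) -> CorrelationSurface:
    """Spatial correlation of two images restricted to a binary mask.

    Pair sums are computed by FFT correlation of the zero-padded
    fluctuation images and normalized per lag by the number of in-mask
    pixel pairs (the autocorrelation of the mask).  Lags with no pairs are
    NaN.  Requires at least ``MIN_MASK_PIXELS`` mask pixels and strictly
    positive in-mask means.
    """
    a = np.asarray(img_a, dtype=float)
    b = np.asarray(img_b, dtype=float)
    m = np.asarray(mask, dtype=bool)
    if a.shape != b.shape or a.shape != m.shape:
        raise ValueError("images and mask must share one shape")
    n_mask = int(m.sum())
    if n_mask < MIN_MASK_PIXELS:
        raise InsufficientRegionError(
            f"mask has {n_mask} px, need >= {MIN_MASK_PIXELS}"
        )
    mean_a = a[m].mean()
    mean_b = b[m].mean()
    if mean_a <= 0 or mean_b <= 0:
        raise NormalizationError("in-mask channel means must be > 0")

    da = np.where(m, a - mean_a, 0.0)
    db = np.where(m, b - mean_b, 0.0)
    mf = m.astype(float)

    # full 2D cross-correlation: sum_x da(x) db(x + lag)
    pair_sum = fftconvolve(db, da[::-1, ::-1], mode="full")
    pair_count = np.rint(fftconvolve(mf, mf[::-1, ::-1], mode="full"))

    cy, cx = a.shape[0] - 1, a.shape[1] - 1  # zero-lag position in 'full'
    L = min(max_lag, a.shape[0] - 1, a.shape[1] - 1)
    sl = (slice(cy - L, cy + L + 1), slice(cx - L, cx + L + 1))
    counts = pair_count[sl]
    with np.errstate(invalid="ignore", divide="ignore"):
        g = pair_sum[sl] / counts / (mean_a * mean_b)
    g[counts <= 0] = np.nan
    return CorrelationSurface(
        values=g,
        lags_px=np.arange(-L, L + 1),
        n_pairs=counts,
    )


def _radial_profile(surface: CorrelationSurface) -> tuple[np.ndarray, np.ndarray]:
    """Flatten the surface into (radius, value) pairs within the max lag.

    Exact radii are kept (no integer binning), so an isotropic model fits
    the profile without discretization bias; points at equal radius enter
    once each, which weights the fit by the natural lag multiplicity.
    """
    L = surface.max_lag
    yy, xx = np.meshgrid(surface.lags_px, surface.lags_px, indexing="ij")
    r = np.hypot(yy, xx)
    vals = surface.values
    good = np.isfinite(vals) & (r <= L)
    order = np.argsort(r[good], kind="stable")
    return r[good][order], vals[good][order]


def fit_amplitude(
    surface: CorrelationSurface,
    exclude_zero_lag: bool = True,
) -> CorrelationFit:
    """Zero-lag amplitude by radial Gaussian fit.

    The surface is radially averaged and g(r) = g0·exp(−r²/w²) + offset is
    fit by least squares.  With ``exclude_zero_lag`` the r = 0 bin is
    omitted, so g0 is the amplitude extrapolated to zero lag with the
    shot-noise spike removed.  Negative amplitudes are permitted.
    Non-convergence returns ``success=False`` rather than raising.
    """
    r, g = _radial_profile(surface)
    if exclude_zero_lag:
        keep = r > 0
        r, g = r[keep], g[keep]
    if len(r) < 4 or not np.all(np.isfinite(g)):
        return CorrelationFit(np.nan, np.nan, np.nan, False, np.nan)

    def model(r, g0, w, offset):
        return g0 * np.exp(-(r**2) / w**2) + offset

    g0_init = g[0]
    w_init = max(2.0, float(r[-1]) / 4.0)
    try:
        popt, _ = optimize.curve_fit(
            model,
            r,
            g,
            p0=[g0_init, w_init, 0.0],
            bounds=([-np.inf, 1e-3, -np.inf], [np.inf, 10.0 * r[-1], np.inf]),
            maxfev=10000,
        )
    except (RuntimeError, ValueError):
        return CorrelationFit(np.nan, np.nan, np.nan, False, np.nan)
    resid = g - model(r, *popt)
    return CorrelationFit(
        g0=float(popt[0]),
        width_px=float(abs(popt[1])),
        offset=float(popt[2]),
        success=True,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def coloc_fractions(
    ch1: np.ndarray,
    ch2: np.ndarray,
    mask: np.ndarray,
    max_lag: int = 32,
    smooth_central: bool = False,
) -> ColocFractions:
    """Cross-correlation fractions f1 and f2 of two channels in a mask.

    f1 divides the measured zero-lag cross-correlation amplitude by the
    fitted (zero-lag-extrapolated) channel-2 autocorrelation amplitude; f2
    uses the channel-1 amplitude.  Results are clipped to [−1, 1].  A
    non-positive or failed autocorrelation fit flags the result invalid
    (NaN fractions) instead of raising.
    """
    gcc = masked_correlation(ch1, ch2, mask, max_lag=max_lag)
    gac1 = fit_amplitude(masked_correlation(ch1, ch1, mask, max_lag=max_lag))
    gac2 = fit_amplitude(masked_correlation(ch2, ch2, mask, max_lag=max_lag))
    gcc0 = gcc.central_mean(1) if smooth_central else gcc.zero_lag

    if not (gac1.success and gac2.success) or gac1.g0 <= 0 or gac2.g0 <= 0:
        return ColocFractions(np.nan, np.nan, gcc0, gac1.g0, gac2.g0, valid=False)
    f1 = float(np.clip(gcc0 / gac2.g0, -1.0, 1.0))
    f2 = float(np.clip(gcc0 / gac1.g0, -1.0, 1.0))
    return ColocFractions(f1=f1, f2=f2, gcc0=gcc0, gac1_0=gac1.g0, gac2_0=gac2.g0)


def _largest_label_mask(label_frame: np.ndarray) -> np.ndarray:
    """Binary mask of the largest labeled object (one irradiated nucleus
    per ROI by design); empty frame gives an empty mask."""
    labels, counts = np.unique(label_frame[label_frame > 0], return_counts=True)
    if len(labels) == 0:
        return np.zeros(label_frame.shape, dtype=bool)
    return label_frame == labels[np.argmax(counts)]


def timelapse_iccs(
    stack: TimelapseStack,
    damage_area_masks: np.ndarray,
    max_lag: int = 32,
    min_mask_px: int = MIN_MASK_PIXELS,
) -> pd.DataFrame:
    """Per-frame f1/f2 of (damage, dna) within the damage-area mask.

    Only post-bleach frames are analyzed.  Frames whose mask is too small
    or whose fits fail carry NaN — never zeros, since zero is a meaningful
    colocalization value.  Returns a DataFrame with columns
    ``time_s, f1, f2, valid``.
    """
    ch_damage = stack.channel("damage")
    ch_dna = stack.channel("dna")
    rows = []
    for i in np.nonzero(stack.post_bleach)[0]:
        mask = _largest_label_mask(damage_area_masks[i])
        t = stack.time_s[i]
        if mask.sum() < min_mask_px:
            rows.append({"time_s": t, "f1": np.nan, "f2": np.nan, "valid": False})
            continue
        try:
            res = coloc_fractions(ch_damage[i], ch_dna[i], mask, max_lag=max_lag)
        except (InsufficientRegionError, NormalizationError):
            res = ColocFractions(np.nan, np.nan, np.nan, np.nan, np.nan, valid=False)
        rows.append({"time_s": t, "f1": res.f1, "f2": res.f2, "valid": res.valid})
    return pd.DataFrame(rows, columns=["time_s", "f1", "f2", "valid"])
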