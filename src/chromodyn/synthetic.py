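"""Ground-truthed synthetic two-channel nuclear time-lapse generator.

Emulates a laser micro-irradiation experiment on a counterstained nucleus:

* **Channel 2 (DNA counterstain, e.g. Hoechst)** — a nucleus with
  heterochromatin texture (bright Gaussian blobs over a dimmer euchromatin
  background).  After the bleach, chromatin inside the irradiated ROI
  relaxes: the ROI mean intensity decays exponentially with time constant
  ``t_off_intensity`` (multiplicative factor on the whole ROI) and the ROI
  coefficient of variation decays with ``t_off_cv`` (fluctuations shrink
  toward the ROI mean).  Both decays share the amplitude
  ``relax_amplitude``; setting it to 0 models a PARP-inhibited cell in
  which relaxation is suppressed.

* **Channel 1 (damage marker, e.g. PARP1-RFP)** — a uniform nucleoplasmic
  background plus damage foci.  Focus centers are placed inside the ROI,
  preferentially in high-density (heterochromatic) pixels with probability
  ``damage_bias``.  The focus amplitude follows a one-phase association
  ``recruit_amplitude * (1 - exp(-t / t_on))`` and decays exponentially
  after ``decay_start_s``.

Pixel values are Poisson draws around the expected photon rates, matching
hybrid detectors operated in photon-counting mode.  All randomness flows
from an explicit integer seed; identical seeds give bit-identical stacks.

The acquisition schedule mirrors a confocal bleach protocol: pre-bleach
frames at one interval, a bleach exposure that produces no analyzed frames
(dead time), then post-bleach frames at a second interval, with t = 0 at
the start of the bleach.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import GeometryError, InvalidScheduleError, ParameterError
from .stack import RoiRect, TimelapseStack

__all__ = [
    "AcquisitionSchedule",
    "NucleusTruth",
    "KineticsTruth",
    "SyntheticStack",
    "make_schedule",
    "blob_texture",
    "synth_nucleus",
    "edge_roi",
    "internal_roi",
    "synth_timelapse",
    "control_kinetics",
    "parp_inhibited_kinetics",
]


@dataclass(frozen=True)
class AcquisitionSchedule:
    """Time-lapse/bleach protocol.

    Defaults follow a standard confocal micro-irradiation series:
    5 pre-bleach frames at 1.3 s, 2 bleach iterations of 1.3 s (2.6 s dead
    time, no frames), 50 post-bleach frames at 3 s.
    """

    n_pre: int = 5
    dt_pre: float = 1.3
    n_bleach: int = 2
    dt_bleach: float = 1.3
    n_post: int = 50
    dt_post: float = 3.0

    def __post_init__(self) -> None:
        if min(self.n_pre, self.n_bleach, self.n_post) < 0:
            raise InvalidScheduleError("frame counts must be >= 0")
        if min(self.dt_pre, self.dt_bleach, self.dt_post) <= 0:
            raise InvalidScheduleError("frame intervals must be > 0")

    @property
    def bleach_end_s(self) -> float:
        return self.n_bleach * self.dt_bleach


def make_schedule(schedule: AcquisitionSchedule) -> np.ndarray:
    """Per-frame time stamps in seconds, t = 0 at bleach onset.

    Pre-bleach frames end at ``-dt_pre`` (the last image before
    irradiation); the first post-bleach frame is acquired when the bleach
    exposure ends, at ``n_bleach * dt_bleach``.  Under the defaults the
    first post stamp is 2.6 s and the last is 149.6 s.  Bleach iterations
    are dead time only — they emit no frames.
    """
    s = schedule
    pre = -s.dt_pre * np.arange(s.n_pre, 0, -1)
    post = s.bleach_end_s + s.dt_post * np.arange(s.n_post)
    return np.concatenate([pre, post])


@dataclass
class NucleusTruth:
    """Ground-truth nucleus geometry and chromatin density.

    ``chromatin_density_map`` is the expected counterstain photon rate per
    pixel (arbitrary units, zero outside the nucleus);
    ``heterochromatin_mask`` marks in-nucleus pixels above a density
    quantile.
    """

    nucleus_mask: np.ndarray
    chromatin_density_map: np.ndarray
    heterochromatin_mask: np.ndarray
    pixel_size_um: float = 0.072


@dataclass(frozen=True)
class KineticsTruth:
    """Ground-truth kinetic parameters of a simulated cell.

    Times are in seconds.  ``relax_amplitude`` is the fractional drop of
    both the ROI counterstain mean and its CV at t -> infinity (0 = no
    relaxation, the PARP-inhibited phenotype).  ``recruit_amplitude`` is
    the peak focus amplitude relative to the nucleoplasmic background.
    ``decay_start_s`` is when the damage-channel focus amplitude stops
    growing and starts decaying with constant ``t_off_foci``.
    """

    t_on: float = 5.8
    t_off_intensity: float = 26.5
    t_off_cv: float = 35.4
    relax_amplitude: float = 0.4
    recruit_amplitude: float = 3.0
    decay_start_s: float = 53.6
    t_off_foci: float = 40.0

    def __post_init__(self) -> None:
        for name in ("t_on", "t_off_intensity", "t_off_cv", "t_off_foci"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if not 0.0 <= self.relax_amplitude <= 1.0:
            raise ParameterError("relax_amplitude must be in [0, 1]")
        if self.recruit_amplitude < 0:
            raise ParameterError("recruit_amplitude must be >= 0")


def control_kinetics() -> KineticsTruth:
    """Untreated-cell preset: fast recruitment, full chromatin relaxation."""
    return KineticsTruth()


def parp_inhibited_kinetics() -> KineticsTruth:
    """PARP-inhibited preset: slow recruitment, sustained foci, no relaxation."""
    return KineticsTruth(
        t_on=18.2,
        relax_amplitude=0.0,
        decay_start_s=1e9,  # trapped marker: no decay within the acquisition
    )


@dataclass
class SyntheticStack:
    """A simulated stack bundled with its generating ground truth."""

    stack: TimelapseStack
    nucleus: NucleusTruth
    kinetics: KineticsTruth
    roi: RoiRect
    foci_yx: np.ndarray  # (n_foci, 2) row/col centers
    damage_bias: float
    mean_counts: float
    seed: int


def blob_texture(
    shape: tuple[int, int],
    n_blobs: int,
    blob_sigma_px: float,
    contrast: float,
    seed: int,
    base: float = 1.0,
    centers_yx: np.ndarray | None = None,
) -> np.ndarray:
    """Constant background plus isotropic Gaussian blobs.

    Each blob peaks at ``(contrast - 1) * base`` above the background, so
    ``contrast`` is the peak-to-background ratio of an isolated blob.
    Centers are uniform over the frame unless given explicitly.
    """
    if blob_sigma_px <= 0:
        raise ParameterError("blob_sigma_px must be > 0")
    if contrast < 1:
        raise ParameterError("contrast must be >= 1")
    rng = np.random.default_rng(seed)
    if centers_yx is None:
        centers_yx = np.column_stack(
            [rng.integers(0, shape[0], n_blobs), rng.integers(0, shape[1], n_blobs)]
        )
    impulses = np.zeros(shape, dtype=float)
    for y, x in np.asarray(centers_yx):
        impulses[int(y), int(x)] += 1.0
    # gaussian_filter of a unit impulse peaks at 1/(2*pi*sigma^2)
    blobs = gaussian_filter(impulses, blob_sigma_px, mode="constant")
    blobs *= 2.0 * np.pi * blob_sigma_px**2
    return base * (1.0 + (contrast - 1.0) * blobs)


def synth_nucleus(
    shape: tuple[int, int] = (512, 512),
    n_blobs: int = 120,
    blob_sigma_px: float = 4.0,
    contrast: float = 3.0,
    seed: int = 0,
    pixel_size_um: float = 0.072,
    het_quantile: float = 0.75,
    axis_fraction: tuple[float, float] = (0.40, 0.44),
) -> NucleusTruth:
    """Generate an elliptical nucleus with heterochromatin blob texture.

    The density map is a constant euchromatin rate inside the nucleus plus
    Gaussian blobs of the stated sigma whose peaks are ``contrast`` times
    the euchromatin level; the heterochromatin mask is the set of
    in-nucleus pixels strictly above the ``het_quantile`` quantile of the
    in-nucleus density.
    """
    if shape[0] < 64 or shape[1] < 64:
        raise ParameterError("frame must be at least 64x64")
    if blob_sigma_px <= 0:
        raise ParameterError("blob_sigma_px must be > 0")
    if contrast < 1:
        raise ParameterError("contrast must be >= 1")

    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    ry, rx = axis_fraction[0] * rows, axis_fraction[1] * cols
    nucleus = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0

    rng = np.random.default_rng(seed)
    in_y, in_x = np.nonzero(nucleus)
    picks = rng.integers(0, len(in_y), n_blobs)
    centers = np.column_stack([in_y[picks], in_x[picks]])
    density = blob_texture(
        shape, n_blobs, blob_sigma_px, contrast, seed, centers_yx=centers
    )
    density[~nucleus] = 0.0

    inside = density[nucleus]
    thr = np.quantile(inside, het_quantile)
    het = nucleus & (density > thr)
    return NucleusTruth(
        nucleus_mask=nucleus,
        chromatin_density_map=density,
        heterochromatin_mask=het,
        pixel_size_um=pixel_size_um,
    )


def edge_roi(
    nucleus: NucleusTruth,
    width_um: float = 18.0,
    height_um: float = 4.0,
) -> RoiRect:
    """Rectangular irradiation ROI straddling the top edge of the nucleus.

    The default 18 x 4 um geometry targets the nuclear periphery; a
    6 x 4 um box gives the internal-ROI variant (pass ``width_um=6`` and
    move it with :func:`dataclasses.replace` if needed).
    """
    px = nucleus.pixel_size_um
    w = max(4, int(np.floor(width_um / px + 0.5)))
    h = max(4, int(np.floor(height_um / px + 0.5)))
    rows_any = np.nonzero(nucleus.nucleus_mask.any(axis=1))[0]
    cols_any = np.nonzero(nucleus.nucleus_mask.any(axis=0))[0]
    if len(rows_any) == 0:
        raise GeometryError("empty nucleus mask")
    top = rows_any[0]
    cx = int(cols_any.mean())
    frame_h, frame_w = nucleus.nucleus_mask.shape
    w = min(w, frame_w)
    h = min(h, frame_h)
    # straddle the edge: half the ROI height above the top nuclear row
    y0 = int(np.clip(top - h // 2, 0, frame_h - h))
    x0 = int(np.clip(cx - w // 2, 0, frame_w - w))
    return RoiRect(x0=x0, y0=y0, width=w, height=h)


def internal_roi(
    nucleus: NucleusTruth,
    width_um: float = 6.0,
    height_um: float = 4.0,
) -> RoiRect:
    """Smaller irradiation ROI fully inside the nucleus (6 x 4 um preset),
    centered on the nuclear centroid's upper half."""
    px = nucleus.pixel_size_um
    w = max(4, int(np.floor(width_um / px + 0.5)))
    h = max(4, int(np.floor(height_um / px + 0.5)))
    ys, xs = np.nonzero(nucleus.nucleus_mask)
    if len(ys) == 0:
        raise GeometryError("empty nucleus mask")
    frame_h, frame_w = nucleus.nucleus_mask.shape
    w = min(w, frame_w)
    h = min(h, frame_h)
    cy, cx = int(ys.mean()), int(xs.mean())
    x0 = int(np.clip(cx - w // 2, 0, frame_w - w))
    # prefer the upper half of the nucleus, but fall back toward the
    # centroid until the rectangle is fully internal
    for shift in range(int((ys.max() - ys.min()) * 0.25), -1, -4):
        y0 = int(np.clip(cy - shift - h // 2, 0, frame_h - h))
        rect = RoiRect(x0=x0, y0=y0, width=w, height=h)
        if np.all(nucleus.nucleus_mask[rect.slices()]):
            return rect
    raise GeometryError(
        f"no fully internal {w}x{h} px placement found; nucleus too small"
    )


def _focus_amplitude(t: np.ndarray, k: KineticsTruth) -> np.ndarray:
    """Damage-focus amplitude profile: association then post-peak decay."""
    t = np.asarray(t, dtype=float)
    rise = k.recruit_amplitude * (1.0 - np.exp(-np.clip(t, 0, None) / k.t_on))
    peak = k.recruit_amplitude * (1.0 - np.exp(-k.decay_start_s / k.t_on))
    fall = peak * np.exp(-np.clip(t - k.decay_start_s, 0.0, None) / k.t_off_foci)
    amp = np.where(t <= k.decay_start_s, rise, fall)
    amp[t < 0] = 0.0
    return amp


def _place_foci(
    nucleus: NucleusTruth,
    roi: RoiRect,
    n_foci: int,
    damage_bias: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Pick focus centers in roi∩nucleus, biased toward heterochromatin.

    Each focus independently lands on a density-weighted heterochromatin
    pixel with probability ``damage_bias``, otherwise uniformly in
    roi∩nucleus.  Both candidate draws are made for every focus so the
    heterochromatin fraction is non-decreasing in ``damage_bias`` for a
    fixed seed (common random numbers).
    """
    roi_mask = roi.mask(nucleus.nucleus_mask.shape)
    region = roi_mask & nucleus.nucleus_mask
    if not region.any():
        raise GeometryError("ROI does not intersect the nucleus")
    het_region = region & nucleus.heterochromatin_mask
    if not het_region.any():
        het_region = region  # degenerate texture: no preference possible

    uy, ux = np.nonzero(region)
    hy, hx = np.nonzero(het_region)
    weights = nucleus.chromatin_density_map[hy, hx]
    weights = weights / weights.sum() if weights.sum() > 0 else None

    u = rng.random(n_foci)
    uniform_idx = rng.integers(0, len(uy), n_foci)
    het_idx = rng.choice(len(hy), size=n_foci, p=weights)
    centers = np.empty((n_foci, 2), dtype=int)
    for i in range(n_foci):
        if u[i] < damage_bias:
            centers[i] = hy[het_idx[i]], hx[het_idx[i]]
        else:
            centers[i] = uy[uniform_idx[i]], ux[uniform_idx[i]]
    return centers


def expected_rates(
    nucleus: NucleusTruth,
    kinetics: KineticsTruth,
    roi: RoiRect,
    time_s: np.ndarray,
    foci_yx: np.ndarray,
    mean_counts: float = 20.0,
    focus_sigma_px: float = 2.0,
    bleach_fraction: float = 0.0,
) -> np.ndarray:
    """Noiseless expected photon rates, shape (T, 2, Y, X).

    Channel 0 is the damage marker, channel 1 the DNA counterstain.  This
    is the generative model used by :func:`synth_timelapse` before Poisson
    sampling; it doubles as the oracle for kinetics-recovery tests.
    """
    shape = nucleus.nucleus_mask.shape
    density = nucleus.chromatin_density_map
    in_mean = density[nucleus.nucleus_mask].mean()
    density = density * (mean_counts / in_mean)  # counterstain rate, mean = mean_counts

    roi_mask = roi.mask(shape)
    region = roi_mask & nucleus.nucleus_mask
    mu_roi = density[region].mean()

    # unit-peak focus profile
    impulses = np.zeros(shape, dtype=float)
    for y, x in np.asarray(foci_yx):
        impulses[int(y), int(x)] += 1.0
    foci_profile = gaussian_filter(impulses, focus_sigma_px, mode="constant")
    foci_profile *= 2.0 * np.pi * focus_sigma_px**2

    amp = _focus_amplitude(time_s, kinetics)
    k = kinetics
    rates = np.empty((len(time_s), 2, *shape), dtype=float)
    for i, t in enumerate(np.asarray(time_s, dtype=float)):
        ch1 = mean_counts * nucleus.nucleus_mask.astype(float)
        ch1 = ch1 + mean_counts * amp[i] * foci_profile * nucleus.nucleus_mask
        ch2 = density.copy()
        if t > 0:
            m = 1.0 - k.relax_amplitude * (1.0 - np.exp(-t / k.t_off_intensity))
            c = 1.0 - k.relax_amplitude * (1.0 - np.exp(-t / k.t_off_cv))
            relaxed = (mu_roi + (density - mu_roi) * c) * m
            ch2 = np.where(region, relaxed, ch2)
            if bleach_fraction > 0:
                ch2 = ch2 * (1.0 - bleach_fraction)
        rates[i, 0] = ch1
        rates[i, 1] = ch2
    return rates


def synth_timelapse(
    nucleus: NucleusTruth,
    kinetics: KineticsTruth,
    roi: RoiRect,
    schedule: AcquisitionSchedule = AcquisitionSchedule(),
    damage_bias: float = 0.9,
    mean_counts: float = 20.0,
    seed: int = 0,
    n_foci: int = 12,
    focus_sigma_px: float = 2.0,
    bleach_fraction: float = 0.0,
    poisson: bool = True,
) -> SyntheticStack:
    """Simulate a two-channel micro-irradiation time-lapse.

    Parameters
    ----------
    damage_bias : float
        Probability that each damage focus is seeded in a heterochromatin
        pixel (density-weighted) rather than uniformly in roi∩nucleus.
    mean_counts : float
        Mean photon counts per in-nucleus pixel, both channels' baseline.
    poisson : bool
        When False the stack holds the noiseless expected rates (floats),
        for use as a fitting oracle.

    Returns
    -------
    SyntheticStack
        The stack (channel 0 = damage, channel 1 = dna) plus the full
        ground truth: nucleus, kinetics, ROI, focus centers and seed.
    """
    time_s = make_schedule(schedule)
    rng = np.random.default_rng(seed)
    foci_yx = _place_foci(nucleus, roi, n_foci, damage_bias, rng)
    rates = expected_rates(
        nucleus,
        kinetics,
        roi,
        time_s,
        foci_yx,
        mean_counts=mean_counts,
        focus_sigma_px=focus_sigma_px,
        bleach_fraction=bleach_fraction,
    )
    data = rng.poisson(rates).astype(np.uint16) if poisson else rates
    stack = TimelapseStack(
        data=data,
        time_s=time_s,
        pixel_size_um=nucleus.pixel_size_um,
        channel_roles={"damage": 0, "dna": 1},
    )
    return SyntheticStack(
        stack=stack,
        nucleus=nucleus,
        kinetics=kinetics,
        roi=roi,
        foci_yx=foci_yx,
        damage_bias=damage_bias,
        mean_counts=mean_counts,
        seed=seed,
    )
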