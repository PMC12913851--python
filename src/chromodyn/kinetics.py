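"""One-phase exponential kinetics fits for recruitment and relaxation.

Recruitment of a damage marker to the irradiated region is summarized by
the association time constant T_on from

    y(t) = y0 + (plateau − y0) · (1 − exp(−(t − t_first)/τ)),

fit over a short window after the bleach (default: first post-bleach frame
to 60 s, before redistribution sets in).  Relaxation and release are
summarized by the decay constant T_off from

    y(t) = plateau + (y_start − plateau) · exp(−(t − t_start)/τ),

started either at the detected trace peak (damage-channel traces, which
rise before they fall) or at the first post-bleach frame (counterstain
intensity and CV traces, which decay from the start).

Fits use bounded trust-region least squares (via lmfit) with
τ ∈ (0.1, 1000] s and quantile-based initialization; non-convergence is
reported through ``success=False``, never an exception.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lmfit import Model

__all__ = ["KineticsFit", "fit_association", "fit_decay"]

TAU_MIN_S = 0.1
TAU_MAX_S = 1000.0


@dataclass
class KineticsFit:
    """Result of a one-phase association or decay fit."""

    tau_s: float
    y0: float
    plateau: float
    r_squared: float
    success: bool
    window_s: tuple[float, float]

    def __bool__(self) -> bool:  # truthiness = usable fit
        return self.success


def _r_squared(y: np.ndarray, resid: np.ndarray) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 1.0
    return 1.0 - float(np.sum(resid**2)) / ss_tot


def _failed(window: tuple[float, float]) -> KineticsFit:
    return KineticsFit(np.nan, np.nan, np.nan, np.nan, False, window)


def _select_window(
    time_s: np.ndarray, y: np.ndarray, lo: float, hi: float
) -> tuple[np.ndarray, np.ndarray]:
    keep = (time_s >= lo) & (time_s <= hi) & np.isfinite(y)
    return time_s[keep], y[keep]


def fit_association(
    time_s: np.ndarray,
    y: np.ndarray,
    window_s: tuple[float, float] = (0.0, 60.0),
) -> KineticsFit:
    """Fit a one-phase association and report τ as T_on.

    ``window_s`` bounds the fitted interval; the lower bound defaults to 0
    so the window effectively starts at the first post-bleach frame.  At
    least 4 finite points are required.  τ at its bounds (within 1%) is
    treated as non-convergence.
    """
    t = np.asarray(time_s, dtype=float)
    yv = np.asarray(y, dtype=float)
    if len(t) != len(yv):
        raise ValueError("time and y must have equal length")
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("time must be strictly increasing")
    tw, yw = _select_window(t, yv, *window_s)
    window = (float(window_s[0]), float(window_s[1]))
    if len(tw) < 4:
        return _failed(window)
    t_first = tw[0]

    def assoc(t, y0, plateau, tau):
        return y0 + (plateau - y0) * (1.0 - np.exp(-(t - t_first) / tau))

    model = Model(assoc)
    params = model.make_params(
        y0=yw[0],
        plateau=yw[-1],
        tau=max((window[1] - window[0]) / 5.0, 2 * TAU_MIN_S),
    )
    params["tau"].set(min=TAU_MIN_S, max=TAU_MAX_S)
    try:
        res = model.fit(yw, params, t=tw)
    except Exception:
        return _failed(window)
    tau = float(res.params["tau"].value)
    at_bounds = tau <= TAU_MIN_S * 1.01 or tau >= TAU_MAX_S * 0.99
    return KineticsFit(
        tau_s=tau,
        y0=float(res.params["y0"].value),
        plateau=float(res.params["plateau"].value),
        r_squared=_r_squared(yw, res.residual),
        success=bool(res.success) and not at_bounds,
        window_s=(float(tw[0]), float(tw[-1])),
    )


def _peak_index(y: np.ndarray) -> int:
    """Index of the trace maximum after 3-point moving-average smoothing
    (suppresses single-frame noise peaks)."""
    if len(y) < 3:
        return int(np.nanargmax(y))
    kernel = np.ones(3) / 3.0
    padded = np.concatenate([y[:1], y, y[-1:]])
    smooth = np.convolve(padded, kernel, mode="valid")
    return int(np.nanargmax(smooth))


def fit_decay(
    time_s: np.ndarray,
    y: np.ndarray,
    start_mode: str = "at_first_post",
) -> KineticsFit:
    """Fit a one-phase decay and report τ as T_off.

    ``start_mode='at_peak'`` starts at the smoothed trace maximum (for
    damage-channel traces that rise before decaying);
    ``'at_first_post'`` starts at the first t > 0 point (for counterstain
    intensity/CV traces).  A trace that never decreases after the start
    yields ``success=False``.
    """
    t = np.asarray(time_s, dtype=float)
    yv = np.asarray(y, dtype=float)
    if len(t) != len(yv):
        raise ValueError("time and y must have equal length")
    post = np.nonzero(t > 0)[0]
    if len(post) == 0:
        return _failed((np.nan, np.nan))
    if start_mode == "at_peak":
        start = post[0] + _peak_index(yv[post])
    elif start_mode == "at_first_post":
        start = post[0]
    else:
        raise ValueError(f"unknown start_mode {start_mode!r}")
    tw, yw = t[start:], yv[start:]
    finite = np.isfinite(yw)
    tw, yw = tw[finite], yw[finite]
    window = (float(tw[0]), float(tw[-1])) if len(tw) else (np.nan, np.nan)
    if len(tw) < 4:
        return _failed(window)
    if yw[-1] >= yw[0]:  # no net decay to fit
        return _failed(window)
    t_start = tw[0]

    def decay(t, y0, plateau, tau):
        return plateau + (y0 - plateau) * np.exp(-(t - t_start) / tau)

    model = Model(decay)
    params = model.make_params(
        y0=yw[0],
        plateau=yw[-1],
        tau=max((tw[-1] - tw[0]) / 5.0, 2 * TAU_MIN_S),
    )
    params["tau"].set(min=TAU_MIN_S, max=TAU_MAX_S)
    try:
        res = model.fit(yw, params, t=tw)
    except Exception:
        return _failed(window)
    tau = float(res.params["tau"].value)
    at_bounds = tau <= TAU_MIN_S * 1.01 or tau >= TAU_MAX_S * 0.99
    return KineticsFit(
        tau_s=tau,
        y0=float(res.params["y0"].value),
        plateau=float(res.params["plateau"].value),
        r_squared=_r_squared(yw, res.residual),
        success=bool(res.success) and not at_bounds,
        window_s=window,
    )
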