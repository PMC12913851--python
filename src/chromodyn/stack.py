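"""In-memory containers for time-lapse stacks, masks and ROIs, plus TIFF I/O.

A :class:`TimelapseStack` holds a ``(frames, channels, rows, cols)`` array of
photon counts together with per-frame time stamps (seconds, t = 0 at the
onset of micro-irradiation) and the physical pixel size.  Channel roles map
semantic names (``damage`` for the recruitment marker, ``dna`` for the
counterstain) onto channel indices, so the analysis code never hard-codes
channel order.

Stacks round-trip through multi-page TIFF (axes ``TCYX``) with a JSON
sidecar carrying time stamps, pixel size and channel roles; label and binary
masks are written as 16-bit multi-page TIFF.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .errors import GeometryError, ConfigError

__all__ = [
    "TimelapseStack",
    "RoiRect",
    "read_stack",
    "write_stack",
    "read_masks",
    "write_masks",
]


@dataclass(frozen=True)
class RoiRect:
    """Rectangular ROI in pixel coordinates: 0-based, half-open.

    ``x0``/``y0`` are column/row of the top-left corner; the rectangle covers
    columns ``[x0, x0 + width)`` and rows ``[y0, y0 + height)``.
    """

    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise GeometryError(f"ROI must have positive area, got {self}")
        if self.x0 < 0 or self.y0 < 0:
            raise GeometryError(f"ROI origin must be non-negative, got {self}")

    @classmethod
    def from_um(
        cls,
        x0_um: float,
        y0_um: float,
        width_um: float,
        height_um: float,
        pixel_size_um: float,
    ) -> "RoiRect":
        """Convert a physical ROI (µm) to pixels with round-half-up."""

        def px(v: float) -> int:
            return int(np.floor(v / pixel_size_um + 0.5))

        return cls(px(x0_um), px(y0_um), px(width_um), px(height_um))

    def slices(self) -> tuple[slice, slice]:
        """Return ``(row_slice, col_slice)`` for numpy indexing."""
        return (
            slice(self.y0, self.y0 + self.height),
            slice(self.x0, self.x0 + self.width),
        )

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Binary mask of the ROI on a frame of the given shape.

        Raises :class:`GeometryError` if the ROI does not fit in the frame.
        """
        rows, cols = shape
        if self.y0 + self.height > rows or self.x0 + self.width > cols:
            raise GeometryError(
                f"ROI {self} exceeds frame bounds {rows}x{cols}"
            )
        m = np.zeros(shape, dtype=bool)
        m[self.slices()] = True
        return m


@dataclass
class TimelapseStack:
    """Two-channel (or single-channel) photon-count time-lapse.

    Parameters
    ----------
    data : ndarray, shape (T, C, Y, X)
        Non-negative pixel values. Integer counts for raw stacks; float for
        background-subtracted intensity images.
    time_s : ndarray, shape (T,)
        Per-frame time stamps in seconds, strictly increasing; t = 0 is the
        start of micro-irradiation, so pre-bleach frames carry negative
        stamps.
    pixel_size_um : float
        Physical pixel size in micrometers.
    channel_roles : dict
        Maps ``"damage"`` and/or ``"dna"`` to channel indices.
    """

    data: np.ndarray
    time_s: np.ndarray
    pixel_size_um: float
    channel_roles: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.time_s = np.asarray(self.time_s, dtype=float)
        if self.data.ndim != 4:
            raise ConfigError(
                f"stack data must be (frames, channels, rows, cols), got shape {self.data.shape}"
            )
        if len(self.time_s) != self.data.shape[0]:
            raise ConfigError(
                f"{len(self.time_s)} time stamps for {self.data.shape[0]} frames"
            )
        if len(self.time_s) > 1 and not np.all(np.diff(self.time_s) > 0):
            raise ConfigError("time stamps must be strictly increasing")
        for role, idx in self.channel_roles.items():
            if not 0 <= idx < self.data.shape[1]:
                raise ConfigError(f"channel role {role!r} -> {idx} out of range")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    def channel(self, role: str) -> np.ndarray:
        """All frames of the channel playing ``role`` — shape (T, Y, X)."""
        if role not in self.channel_roles:
            raise ConfigError(f"no channel assigned to role {role!r}")
        return self.data[:, self.channel_roles[role]]

    @property
    def post_bleach(self) -> np.ndarray:
        """Boolean selector of post-bleach frames (t > 0)."""
        return self.time_s > 0


def write_stack(path: str | Path, stack: TimelapseStack) -> None:
    """Write a stack as multi-page TIFF (axes TCYX) plus a JSON sidecar."""
    path = Path(path)
    data = stack.data
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.uint16)
    else:
        data = data.astype(np.float32)
    tifffile.imwrite(path, data, metadata={"axes": "TCYX"})
    sidecar = {
        "time_s": stack.time_s.tolist(),
        "pixel_size_um": stack.pixel_size_um,
        "channel_roles": stack.channel_roles,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_stack(path: str | Path) -> TimelapseStack:
    """Read a stack written by :func:`write_stack`."""
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 3:  # single channel without explicit C axis
        data = data[:, None]
    meta = json.loads(path.with_suffix(".json").read_text())
    return TimelapseStack(
        data=data,
        time_s=np.asarray(meta["time_s"], dtype=float),
        pixel_size_um=float(meta["pixel_size_um"]),
        channel_roles={k: int(v) for k, v in meta["channel_roles"].items()},
    )


def write_masks(path: str | Path, masks: np.ndarray) -> None:
    """Write a (T, Y, X) label or binary mask sequence as 16-bit TIFF."""
    tifffile.imwrite(Path(path), np.asarray(masks).astype(np.uint16))


def read_masks(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(Path(path))
    if arr.ndim == 2:
        arr = arr[None]
    return arr.astype(np.int32)
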