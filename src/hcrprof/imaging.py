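"""Image stacks, maximum projections and medial→lateral intensity line profiles.

The measurement unit of the whole pipeline is a :class:`LineProfile`: per-channel
pixel intensities sampled at unit steps along a user-defined segment running from
the medial (``position 0``) to the lateral endpoint, optionally averaged over a
perpendicular line width.  Profiles are min–max normalized per channel so that
replicate embryos imaged at different gains become comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "ImageStack",
    "Projection",
    "LineSpec",
    "LineProfile",
    "NormalizedProfile",
    "DegenerateProfileError",
    "max_project",
    "extract_profile",
    "normalize_profile",
]


class DegenerateProfileError(ValueError):
    """Raised when a profile channel is constant and min–max normalization is undefined."""


@dataclass
class ImageStack:
    """Multi-channel, multi-z grayscale stack.

    Parameters
    ----------
    pixels
        Array of shape ``(n_channels, n_z, n_rows, n_cols)`` with nonnegative
        intensities.
    channel_labels
        One unique label per channel (e.g. ``("klf17", "pax3")``).
    pixel_size
        Physical size of one pixel in µm, if known.
    stack_id
        Identifier used in profile provenance and file names.
    """

    pixels: np.ndarray
    channel_labels: tuple[str, ...]
    pixel_size: float | None = None
    stack_id: str = "stack"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.pixels.ndim != 4:
            raise ValueError(
                f"pixels must have shape (channel, z, row, col); got ndim={self.pixels.ndim}"
            )
        if self.pixels.size == 0:
            raise ValueError("pixels: empty stack")
        if len(self.channel_labels) != self.pixels.shape[0]:
            raise ValueError(
                f"channel_labels: {len(self.channel_labels)} labels for "
                f"{self.pixels.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel_labels: labels must be unique")
        if np.any(self.pixels < 0):
            raise ValueError("pixels: intensities must be nonnegative")

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_z(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) of one slice."""
        return self.pixels.shape[2], self.pixels.shape[3]


@dataclass
class Projection:
    """Per-channel 2-D maximum intensity projection of an :class:`ImageStack`."""

    pixels: np.ndarray  # (channel, row, col)
    channel_labels: tuple[str, ...]
    provenance: str = "stack"
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.pixels.ndim != 3:
            raise ValueError("projection pixels must have shape (channel, row, col)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[1], self.pixels.shape[2]


@dataclass(frozen=True)
class LineSpec:
    """A measurement segment in pixel coordinates, (row, col), 0-based.

    ``medial_end`` declares which clicked endpoint sits toward the embryo
    midline; the extracted profile always runs medial→lateral regardless of
    click order.
    """

    start: tuple[float, float]
    end: tuple[float, float]
    linewidth: int = 1
    label: str = "line"
    medial_end: str = "start"

    def __post_init__(self) -> None:
        if tuple(self.start) == tuple(self.end):
            raise ValueError("start: line endpoints must differ")
        if self.linewidth < 1:
            raise ValueError("linewidth: must be >= 1")
        if self.medial_end not in ("start", "end"):
            raise ValueError("medial_end: must be 'start' or 'end'")

    def oriented(self) -> tuple[tuple[float, float], tuple[float, float]]:
        """(medial, lateral) endpoint pair."""
        if self.medial_end == "start":
            return tuple(self.start), tuple(self.end)
        return tuple(self.end), tuple(self.start)


@dataclass
class LineProfile:
    """Raw per-channel intensities at unit-spaced positions from the medial endpoint."""

    positions: np.ndarray  # (n,) ints 0,1,2,...
    values: np.ndarray  # (channel, n)
    channel_labels: tuple[str, ...]
    source: tuple[str, str] = ("stack", "line")

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.channel_labels = tuple(self.channel_labels)
        if self.values.shape != (len(self.channel_labels), len(self.positions)):
            raise ValueError("values must have shape (n_channels, n_positions)")
        d = np.diff(self.positions)
        if len(d) and not np.all(d == 1):
            raise ValueError("positions must be strictly increasing with unit spacing")

    def channel(self, label: str) -> np.ndarray:
        return self.values[self.channel_labels.index(label)]


@dataclass
class NormalizedProfile:
    """Profile rescaled per channel to [0, 1]; ``norm_params`` records (min, max) used."""

    positions: np.ndarray
    values: np.ndarray  # (channel, n), each channel spanning [0, 1]
    channel_labels: tuple[str, ...]
    norm_params: tuple[tuple[float, float], ...] | None = None
    source: tuple[str, str] = ("stack", "line")

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.channel_labels = tuple(self.channel_labels)
        if self.values.shape != (len(self.channel_labels), len(self.positions)):
            raise ValueError("values must have shape (n_channels, n_positions)")

    def channel(self, label: str) -> np.ndarray:
        return self.values[self.channel_labels.index(label)]


def max_project(stack: ImageStack) -> Projection:
    """Maximum intensity projection over z, per channel.

    With a single z-slice the projection is an identical copy of that slice.
    """
    return Projection(
        pixels=stack.pixels.max(axis=1),
        channel_labels=stack.channel_labels,
        provenance=stack.stack_id,
        pixel_size=stack.pixel_size,
    )


def _check_inside(point: tuple[float, float], shape: tuple[int, int], name: str) -> None:
    r, c = point
    if not (0 <= r <= shape[0] - 1 and 0 <= c <= shape[1] - 1):
        raise ValueError(f"{name} endpoint {point} lies outside the {shape} image")


def extract_profile(projection: Projection, line: LineSpec) -> LineProfile:
    """Sample all channels along ``line`` at unit steps with bilinear interpolation.

    Positions run 0, 1, …, round(L) from the medial endpoint, where L is the
    Euclidean length of the segment.  Each sample is the mean of ``linewidth``
    bilinear interpolations taken perpendicular to the line, centred on it.
    All channels are sampled at identical coordinates.
    """
    _check_inside(tuple(line.start), projection.shape, "start")
    _check_inside(tuple(line.end), projection.shape, "end")

    (r0, c0), (r1, c1) = line.oriented()
    length = float(np.hypot(r1 - r0, c1 - c0))
    if length == 0.0:
        raise ValueError("zero-length line")
    n = int(round(length))
    positions = np.arange(n + 1)

    ur, uc = (r1 - r0) / length, (c1 - c0) / length  # along-line unit vector
    pr, pc = -uc, ur  # perpendicular unit vector
    offsets = np.arange(line.linewidth) - (line.linewidth - 1) / 2.0

    rows = r0 + positions[:, None] * ur + offsets[None, :] * pr
    cols = c0 + positions[:, None] * uc + offsets[None, :] * pc

    coords = np.vstack([rows.ravel(), cols.ravel()])
    values = np.empty((projection.pixels.shape[0], n + 1))
    for ci, img in enumerate(projection.pixels):
        samples = map_coordinates(img, coords, order=1, mode="nearest")
        values[ci] = samples.reshape(rows.shape).mean(axis=1)

    return LineProfile(
        positions=positions,
        values=values,
        channel_labels=projection.channel_labels,
        source=(projection.provenance, line.label),
    )


def normalize_profile(profile: LineProfile) -> NormalizedProfile:
    """Min–max normalize each channel over this profile's samples.

    value = (I − min) / (max − min), per channel, so every channel spans [0, 1].
    A constant channel has no defined normalization and raises
    :class:`DegenerateProfileError` naming the channel.
    """
    out = np.empty_like(profile.values)
    params = []
    for ci, label in enumerate(profile.channel_labels):
        v = profile.values[ci]
        lo, hi = float(v.min()), float(v.max())
        if hi <= lo:
            raise DegenerateProfileError(
                f"channel {label!r} is constant along the line; normalization undefined"
            )
        out[ci] = (v - lo) / (hi - lo)
        params.append((lo, hi))
    return NormalizedProfile(
        positions=profile.positions.copy(),
        values=out,
        channel_labels=profile.channel_labels,
        norm_params=tuple(params),
        source=profile.source,
    )
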