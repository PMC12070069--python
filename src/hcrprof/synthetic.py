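"""Seeded synthetic confocal-style scenes of stripe-shaped expression domains.

Each scene emulates a maximum-projection image of an embryo region in which
gene-expression domains form bands perpendicular to the medial–lateral axis.
A channel's noiseless intensity at a pixel depends only on the signed distance
``d`` of the pixel along that axis:

    I(d) = background + sum_k amplitude_k * exp(-(d - c_k)^2 / (2 * w_k^2))

so the ground truth of every rendered image is an analytic mixture of
Gaussians.  Per replicate, a rigid jitter shift (embryo-to-embryo placement
variation) is applied to all band centers of all channels, independent
Gaussian read noise (truncated at zero) is added per z-slice, and the
medial→lateral measurement line through the scene is recorded so downstream
profile extraction can be checked against the analytic curve.

Two named presets ship with the package:

``stage13``
    Query channel (*klf17*) broadly overlapping a unimodal reference stripe
    (*pax3*) — the early-neurula geometry.
``stage17``
    Query channel split into two bands flanking, and strictly outside the
    FWHM of, a non-overlapping reference stripe (*snai2*) — the late-neurula
    geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

from .imaging import ImageStack, LineSpec

__all__ = [
    "StripeSpec",
    "SceneConfig",
    "ChannelTruth",
    "GroundTruth",
    "generate_scene",
    "expected_field",
    "axis_line",
    "stage13_scene",
    "stage17_scene",
    "PRESETS",
]


class StripeSpec(BaseModel):
    """Ground-truth description of one channel's banded expression domain.

    One entry in ``band_centers`` gives a unimodal stripe; two entries give a
    bimodal (flanking) pattern.  Centers are positions in pixels along the
    medial–lateral axis; widths are Gaussian sigmas in pixels; amplitudes and
    background are in arbitrary intensity units.
    """

    channel_label: str
    band_centers: list[float] = Field(min_length=1)
    band_widths: list[float] = Field(min_length=1)
    amplitudes: list[float] = Field(min_length=1)
    background: float = Field(default=0.0, ge=0.0)

    @field_validator("band_widths")
    @classmethod
    def _widths_positive(cls, v: list[float]) -> list[float]:
        if any(w <= 0 for w in v):
            raise ValueError("band_widths: all widths must be > 0")
        return v

    @field_validator("amplitudes")
    @classmethod
    def _amps_nonnegative(cls, v: list[float]) -> list[float]:
        if any(a < 0 for a in v):
            raise ValueError("amplitudes: all amplitudes must be >= 0")
        return v

    @model_validator(mode="after")
    def _lengths_match(self) -> "StripeSpec":
        if not (len(self.band_centers) == len(self.band_widths) == len(self.amplitudes)):
            raise ValueError(
                "band_centers, band_widths and amplitudes must have equal length"
            )
        return self


class SceneConfig(BaseModel):
    """Full description of a replicated synthetic scene."""

    image_height: int = Field(ge=64)
    image_width: int = Field(ge=64)
    n_z: int = Field(default=3, ge=1)
    channels: list[StripeSpec] = Field(min_length=1)
    stripe_axis_angle: float = 0.0  # degrees; 0 = medial-lateral axis along columns
    noise_sd: float = Field(default=0.0, ge=0.0)
    replicate_jitter_sd: float = Field(default=0.0, ge=0.0)
    n_replicates: int = Field(default=5, ge=1)
    seed: int = 0

    @model_validator(mode="after")
    def _labels_unique(self) -> "SceneConfig":
        labels = [c.channel_label for c in self.channels]
        if len(set(labels)) != len(labels):
            raise ValueError("channels: channel_label values must be unique")
        return self

    @property
    def channel_labels(self) -> tuple[str, ...]:
        return tuple(c.channel_label for c in self.channels)


@dataclass(frozen=True)
class ChannelTruth:
    """Realized (jittered) band parameters of one channel in one replicate.

    ``profile_centers`` restates the band centers in the coordinate of the
    replicate's measurement line (distance in pixels from the medial endpoint),
    which is what profile-level estimates should be compared against.
    """

    replicate: int
    channel_label: str
    band_centers: tuple[float, ...]
    band_widths: tuple[float, ...]
    amplitudes: tuple[float, ...]
    background: float
    profile_centers: tuple[float, ...]


@dataclass(frozen=True)
class GroundTruth:
    """One :class:`ChannelTruth` per (replicate, channel), plus per-replicate lines."""

    records: tuple[ChannelTruth, ...]
    lines: tuple[LineSpec, ...]
    jitters: tuple[float, ...]

    def for_replicate(self, replicate: int, channel_label: str) -> ChannelTruth:
        for rec in self.records:
            if rec.replicate == replicate and rec.channel_label == channel_label:
                return rec
        raise KeyError(f"no ground truth for replicate={replicate}, channel={channel_label!r}")


def _axis_distance(config: SceneConfig) -> np.ndarray:
    """Signed axis distance d(row, col) for every pixel; d = col at angle 0."""
    theta = math.radians(config.stripe_axis_angle)
    rows = np.arange(config.image_height)[:, None]
    cols = np.arange(config.image_width)[None, :]
    return cols * math.cos(theta) + rows * math.sin(theta)


def expected_field(config: SceneConfig, channel: StripeSpec, jitter: float = 0.0) -> np.ndarray:
    """Noiseless expected image of one channel under a rigid center shift."""
    d = _axis_distance(config)
    out = np.full(d.shape, float(channel.background))
    for c, w, a in zip(channel.band_centers, channel.band_widths, channel.amplitudes):
        out += a * np.exp(-((d - (c + jitter)) ** 2) / (2.0 * w**2))
    return out


def axis_line(config: SceneConfig, label: str = "ml_axis") -> LineSpec:
    """Measurement segment along the medial–lateral axis through the image center.

    The segment is the longest stretch of the axis direction through the image
    center that stays inside the pixel grid; its start is the medial (lower
    axis-distance) endpoint.
    """
    theta = math.radians(config.stripe_axis_angle)
    ur, uc = math.sin(theta), math.cos(theta)  # (row, col) direction of increasing d
    h, w = config.image_height, config.image_width
    cr, cc = (h - 1) / 2.0, (w - 1) / 2.0

    t_lo, t_hi = -math.inf, math.inf
    for u, lo, hi, c in ((ur, 0.0, h - 1.0, cr), (uc, 0.0, w - 1.0, cc)):
        if abs(u) < 1e-12:
            continue
        a, b = (lo - c) / u, (hi - c) / u
        t_lo, t_hi = max(t_lo, min(a, b)), min(t_hi, max(a, b))
    start = (cr + t_lo * ur, cc + t_lo * uc)
    end = (cr + t_hi * ur, cc + t_hi * uc)
    return LineSpec(start=start, end=end, linewidth=1, label=label, medial_end="start")


def generate_scene(config: SceneConfig) -> tuple[list[ImageStack], GroundTruth]:
    """Render ``n_replicates`` seeded stacks plus their analytic ground truth.

    Identical configs (including seed) produce bit-identical pixel arrays.
    Changing the seed changes only the noise and jitter realizations, never
    the expected (noiseless) intensities.
    """
    rng = np.random.default_rng(config.seed)
    line = axis_line(config)
    (r0, c0), _ = line.oriented()
    theta = math.radians(config.stripe_axis_angle)
    d_start = c0 * math.cos(theta) + r0 * math.sin(theta)

    stacks: list[ImageStack] = []
    records: list[ChannelTruth] = []
    jitters: list[float] = []
    shape = (config.image_height, config.image_width)
    for rep in range(config.n_replicates):
        jitter = float(rng.normal(0.0, config.replicate_jitter_sd))
        jitters.append(jitter)
        pixels = np.empty((len(config.channels), config.n_z) + shape)
        for ci, chan in enumerate(config.channels):
            field = expected_field(config, chan, jitter)
            for z in range(config.n_z):
                noise = rng.normal(0.0, config.noise_sd, shape)
                pixels[ci, z] = np.clip(field + noise, 0.0, None)
            centers = tuple(c + jitter for c in chan.band_centers)
            records.append(
                ChannelTruth(
                    replicate=rep,
                    channel_label=chan.channel_label,
                    band_centers=centers,
                    band_widths=tuple(chan.band_widths),
                    amplitudes=tuple(chan.amplitudes),
                    background=chan.background,
                    profile_centers=tuple(c - d_start for c in centers),
                )
            )
        stacks.append(
            ImageStack(
                pixels=pixels,
                channel_labels=config.channel_labels,
                stack_id=f"rep{rep:02d}",
            )
        )
    lines = tuple(
        LineSpec(start=line.start, end=line.end, linewidth=1, label=line.label, medial_end="start")
        for _ in range(config.n_replicates)
    )
    return stacks, GroundTruth(records=tuple(records), lines=lines, jitters=tuple(jitters))


# --- shipped presets -------------------------------------------------------
#
# Geometry mirrors the early- vs late-neurula arrangement of the query channel
# relative to the reference stripe: broadly overlapping at stage 13, split into
# two bands strictly outside the reference FWHM at stage 17.  Five replicates,
# 3 px placement jitter and noise sd 0.02 (amplitudes O(1)) emulate a small
# cohort of high-SNR confocal projections.


def stage13_scene(seed: int = 0, n_replicates: int = 5) -> SceneConfig:
    """Early-neurula preset: unimodal query overlapping the reference stripe."""
    return SceneConfig(
        image_height=96,
        image_width=200,
        n_z=3,
        channels=[
            StripeSpec(
                channel_label="pax3",
                band_centers=[100.0],
                band_widths=[14.0],
                amplitudes=[1.0],
                background=0.05,
            ),
            StripeSpec(
                channel_label="klf17",
                band_centers=[98.0],
                band_widths=[16.0],
                amplitudes=[0.9],
                background=0.05,
            ),
        ],
        noise_sd=0.02,
        replicate_jitter_sd=3.0,
        n_replicates=n_replicates,
        seed=seed,
    )


def stage17_scene(seed: int = 0, n_replicates: int = 5) -> SceneConfig:
    """Late-neurula preset: bimodal query flanking a non-overlapping reference stripe."""
    return SceneConfig(
        image_height=96,
        image_width=200,
        n_z=3,
        channels=[
            StripeSpec(
                channel_label="snai2",
                band_centers=[100.0],
                band_widths=[8.0],
                amplitudes=[1.0],
                background=0.05,
            ),
            StripeSpec(
                channel_label="klf17",
                band_centers=[70.0, 132.0],
                band_widths=[7.0, 7.0],
                amplitudes=[0.9, 0.8],
                background=0.05,
            ),
        ],
        noise_sd=0.02,
        replicate_jitter_sd=3.0,
        n_replicates=n_replicates,
        seed=seed,
    )


PRESETS = {"stage13": stage13_scene, "stage17": stage17_scene}
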