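"""Peak-centred registration and averaging of replicate line profiles.

Replicate profiles from different embryos cannot be averaged directly: the
measured segment starts at an arbitrary point on each embryo, so the domain
peaks land at arbitrary positions.  The pipeline therefore

1. fits a peaked curve (Gaussian peak plus baseline by default) to the
   reference channel of each image,
2. shifts all of that image's profiles so the fitted reference peak sits at
   position 0, and
3. restricts every shifted profile to the intersection of their position
   grids before computing the per-channel mean ± s.e.m. curve.

In the default integer-grid mode the fitted center is rounded to the nearest
pixel before shifting, so profile positions stay on a shared integer lattice
and the grid intersection is exact set intersection.  A sub-pixel mode shifts
by the exact center and linearly resamples onto the integer lattice instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import reduce
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .imaging import NormalizedProfile

__all__ = [
    "PeakFit",
    "AlignedProfileSet",
    "AverageProfile",
    "PEAK_MODELS",
    "fit_peak",
    "align_profiles",
    "average_profiles",
]


def _gaussian_peak(x: np.ndarray, baseline: float, amplitude: float, center: float, width: float) -> np.ndarray:
    return baseline + amplitude * np.exp(-((x - center) ** 2) / (2.0 * width**2))


def _lorentzian_peak(x: np.ndarray, baseline: float, amplitude: float, center: float, width: float) -> np.ndarray:
    return baseline + amplitude / (1.0 + ((x - center) / width) ** 2)


#: Peaked model functions available for reference-channel fitting.  All share
#: the signature f(x, baseline, amplitude, center, width).
PEAK_MODELS = {"gaussian": _gaussian_peak, "lorentzian": _lorentzian_peak}


@dataclass(frozen=True)
class PeakFit:
    """Least-squares fit of a peaked curve to one reference profile."""

    amplitude: float
    center: float
    width: float
    baseline: float
    rss: float
    converged: bool
    model: str = "gaussian"

    def to_dict(self) -> dict:
        return {
            "amplitude": self.amplitude,
            "center": self.center,
            "width": self.width,
            "baseline": self.baseline,
            "rss": self.rss,
            "converged": self.converged,
            "model": self.model,
        }


@dataclass
class AlignedProfileSet:
    """Replicate profiles shifted onto a common peak-centred grid.

    Invariants: for every profile, ``original positions - shift = stored
    positions`` (exact in integer-grid mode), and ``common_grid`` is the set
    intersection of all shifted position sets.
    """

    reference_channel: str
    profiles: tuple[NormalizedProfile, ...]
    shifts: tuple[float, ...]
    common_grid: np.ndarray
    fits: dict[str, PeakFit]


@dataclass
class AverageProfile:
    """Per-channel mean and s.e.m. versus centred position — the plotted output."""

    grid: np.ndarray
    means: np.ndarray  # (channel, grid)
    sems: np.ndarray  # (channel, grid)
    n: int
    channel_labels: tuple[str, ...]

    def channel_mean(self, label: str) -> np.ndarray:
        return self.means[self.channel_labels.index(label)]

    def channel_sem(self, label: str) -> np.ndarray:
        return self.sems[self.channel_labels.index(label)]


def fit_peak(positions: np.ndarray, values: np.ndarray, model: str = "gaussian") -> PeakFit:
    """Fit ``baseline + amplitude * peak((x - center)/width)`` by bounded least squares.

    Initialization is deterministic: baseline = min value, amplitude =
    max − min, center = position of the (first) maximum, width = a quarter of
    the sampled range.  The center is constrained inside the sampled range.
    If the optimizer fails, the argmax initialization is returned with
    ``converged=False``.
    """
    x = np.asarray(positions, dtype=float)
    v = np.asarray(values, dtype=float)
    if x.size < 5:
        raise ValueError(f"need at least 5 samples to fit a peak; got {x.size}")
    if model not in PEAK_MODELS:
        raise ValueError(f"unknown peak model {model!r}; options: {sorted(PEAK_MODELS)}")
    fn = PEAK_MODELS[model]

    span = float(x.max() - x.min())
    b0 = float(v.min())
    a0 = float(v.max() - v.min())
    c0 = float(x[int(np.argmax(v))])  # first maximum -> smallest position on ties
    w0 = span / 4.0
    p0 = (b0, max(a0, 1e-6), c0, max(w0, 1e-3))
    lower = (b0 - 1.0, 1e-9, float(x.min()), 1e-6)
    upper = (float(v.max()) + 1.0, 2.0 * max(a0, 1e-6) + 1.0, float(x.max()), 4.0 * span)

    try:
        popt, _ = curve_fit(fn, x, v, p0=p0, bounds=(lower, upper), maxfev=10_000)
        b, a, c, w = (float(p) for p in popt)
        rss = float(np.sum((fn(x, b, a, c, w) - v) ** 2))
        return PeakFit(amplitude=a, center=c, width=w, baseline=b, rss=rss, converged=True, model=model)
    except RuntimeError:
        rss = float(np.sum((fn(x, *p0) - v) ** 2))
        return PeakFit(
            amplitude=a0, center=c0, width=w0, baseline=b0, rss=rss, converged=False, model=model
        )


def _positions_intersection(position_sets: Sequence[np.ndarray]) -> np.ndarray:
    return reduce(np.intersect1d, position_sets)


def _values_at(profile: NormalizedProfile, grid: np.ndarray) -> np.ndarray:
    """(channel, grid) values of a profile at the given subset of its positions."""
    idx = np.searchsorted(profile.positions, grid)
    if np.any(idx >= len(profile.positions)) or np.any(profile.positions[idx] != grid):
        raise ValueError("grid contains positions absent from the profile")
    return profile.values[:, idx]


def align_profiles(
    profiles: Sequence[NormalizedProfile],
    reference_channel: str,
    grouping: Mapping[int, str] | None = None,
    model: str = "gaussian",
    subpixel: bool = False,
) -> AlignedProfileSet:
    """Centre every image's profiles on that image's fitted reference peak.

    Profiles are grouped by source image (``grouping`` maps profile index to
    image id; by default the stack id recorded in each profile's provenance).
    Per image, the reference-channel values of its profiles are averaged
    position-wise on their shared positions, a peak is fitted to the average,
    and the fitted center (rounded to the nearest pixel in integer-grid mode)
    is subtracted from the positions of all of that image's profiles.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles to align")
    for p in profiles:
        if reference_channel not in p.channel_labels:
            raise ValueError(
                f"profile {p.source} has no reference channel {reference_channel!r}"
            )
    if grouping is None:
        grouping = {i: p.source[0] for i, p in enumerate(profiles)}

    groups: dict[str, list[int]] = {}
    for i in range(len(profiles)):
        groups.setdefault(grouping[i], []).append(i)

    fits: dict[str, PeakFit] = {}
    shifted: list[NormalizedProfile | None] = [None] * len(profiles)
    shifts: list[float] = [0.0] * len(profiles)
    for image_id, idxs in groups.items():
        members = [profiles[i] for i in idxs]
        common = _positions_intersection([p.positions for p in members])
        if common.size == 0:
            raise ValueError(f"image {image_id!r}: member profiles share no positions")
        ref_avg = np.mean(
            [_values_at(p, common)[p.channel_labels.index(reference_channel)] for p in members],
            axis=0,
        )
        fit = fit_peak(common, ref_avg, model=model)
        fits[image_id] = fit
        shift = fit.center if subpixel else float(round(fit.center))
        for i in idxs:
            p = profiles[i]
            new_pos = p.positions - shift
            if subpixel:
                grid = np.arange(math.ceil(new_pos.min()), math.floor(new_pos.max()) + 1)
                vals = np.vstack([np.interp(grid, new_pos, ch) for ch in p.values])
                new_pos = grid
            else:
                new_pos = new_pos.astype(p.positions.dtype)
                vals = p.values.copy()
            shifts[i] = shift
            shifted[i] = NormalizedProfile(
                positions=new_pos,
                values=vals,
                channel_labels=p.channel_labels,
                norm_params=p.norm_params,
                source=p.source,
            )

    common_grid = _positions_intersection([p.positions for p in shifted])
    return AlignedProfileSet(
        reference_channel=reference_channel,
        profiles=tuple(shifted),
        shifts=tuple(shifts),
        common_grid=common_grid,
        fits=fits,
    )


def average_profiles(aligned: AlignedProfileSet) -> AverageProfile:
    """Per-channel mean and s.e.m. over all aligned profiles on the common grid.

    s.e.m. is the sample standard deviation (ddof=1) divided by sqrt(n).  All
    profiles cover the common grid by construction, so n is constant across
    the grid.
    """
    if len(aligned.profiles) < 2:
        raise ValueError("need at least 2 profiles to average")
    grid = aligned.common_grid
    if grid.size == 0:
        raise ValueError(
            "common grid is empty; use longer or better-targeted measurement lines"
        )
    labels = aligned.profiles[0].channel_labels
    stacked = np.empty((len(aligned.profiles), len(labels), grid.size))
    for pi, p in enumerate(aligned.profiles):
        vals = _values_at(p, grid)
        order = [p.channel_labels.index(lab) for lab in labels]
        stacked[pi] = vals[order]
    means = stacked.mean(axis=0)
    sems = stacked.std(axis=0, ddof=1) / math.sqrt(stacked.shape[0])
    return AverageProfile(
        grid=grid, means=means, sems=sems, n=stacked.shape[0], channel_labels=labels
    )
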