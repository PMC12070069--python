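"""Spatial-relationship metrics between a query and a reference expression domain.

Given an :class:`~hcrprof.alignment.AverageProfile` whose reference channel is
peak-centred at 0, the module measures how the query channel's signal mass is
arranged relative to the reference domain:

* the reference domain is operationalized as the FWHM interval of the
  reference mean profile around 0 (scale-free, standard);
* query domains are the prominent local maxima of the query mean profile;
* the overlap coefficient is the fraction of baseline-subtracted query signal
  mass that falls inside the reference FWHM.

The categorical call (``overlapping`` / ``partial`` / ``flanking``) is this
package's explicit operationalization of the qualitative transition between a
query channel that covers the reference stripe and one that splits into two
bands surrounding it; the thresholds are plain configuration, never hidden.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .alignment import AverageProfile

__all__ = [
    "DomainRelation",
    "reference_fwhm",
    "find_query_modes",
    "classify_relation",
]

DEFAULT_T_HI = 0.5
DEFAULT_T_LO = 0.2
DEFAULT_MIN_PROMINENCE = 0.1


@dataclass(frozen=True)
class DomainRelation:
    """Metrics and categorical call for one (reference, query) channel pair."""

    reference_channel: str
    query_channel: str
    reference_fwhm: tuple[float, float]
    query_modes: tuple[float, ...]
    peak_offsets: tuple[float, ...]  # signed query-mode positions relative to the reference peak
    overlap_coefficient: float
    call: str  # 'overlapping' | 'partial' | 'flanking'
    thresholds_used: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "reference_channel": self.reference_channel,
            "query_channel": self.query_channel,
            "reference_fwhm": list(self.reference_fwhm),
            "query_modes": list(self.query_modes),
            "peak_offsets": list(self.peak_offsets),
            "overlap_coefficient": self.overlap_coefficient,
            "call": self.call,
            "thresholds_used": list(self.thresholds_used),
            "note": "categorical call is a geometric operationalization on averaged profiles",
        }


def reference_fwhm(avg: AverageProfile, reference_channel: str) -> tuple[float, float]:
    """Full-width-at-half-maximum interval of the reference mean profile around 0.

    The interval is the maximal contiguous run containing position 0 where the
    baseline-subtracted mean is at least half its maximum (baseline = minimum
    of the mean on the grid); endpoints are located by linear interpolation
    between grid points.
    """
    m = avg.channel_mean(reference_channel)
    grid = np.asarray(avg.grid, dtype=float)
    baseline = float(m.min())
    peak = float(m.max())
    if peak <= baseline:
        raise ValueError(
            f"reference channel {reference_channel!r}: maximum not above baseline"
        )
    half = baseline + (peak - baseline) / 2.0

    i0 = int(np.argmin(np.abs(grid)))
    if m[i0] < half:
        raise ValueError(
            "reference mean at position 0 is below half maximum; "
            "alignment contract (peak centred at 0) not satisfied"
        )

    lo_idx = i0
    while lo_idx > 0 and m[lo_idx - 1] >= half:
        lo_idx -= 1
    hi_idx = i0
    while hi_idx < len(m) - 1 and m[hi_idx + 1] >= half:
        hi_idx += 1

    if lo_idx == 0:
        lo = float(grid[0])
    else:
        f = (half - m[lo_idx - 1]) / (m[lo_idx] - m[lo_idx - 1])
        lo = float(grid[lo_idx - 1] + f * (grid[lo_idx] - grid[lo_idx - 1]))
    if hi_idx == len(m) - 1:
        hi = float(grid[-1])
    else:
        f = (half - m[hi_idx + 1]) / (m[hi_idx] - m[hi_idx + 1])
        hi = float(grid[hi_idx + 1] - f * (grid[hi_idx + 1] - grid[hi_idx]))
    return lo, hi


def find_query_modes(
    avg: AverageProfile, query_channel: str, min_prominence: float = DEFAULT_MIN_PROMINENCE
) -> np.ndarray:
    """Positions of prominent local maxima of the query mean, medial→lateral.

    Prominence is standard topographic prominence (scipy); an empty result is
    a valid outcome for flat profiles.
    """
    m = avg.channel_mean(query_channel)
    idx, _ = find_peaks(m, prominence=min_prominence)
    return np.asarray(avg.grid, dtype=float)[idx]


def classify_relation(
    avg: AverageProfile,
    reference_channel: str,
    query_channel: str,
    t_hi: float = DEFAULT_T_HI,
    t_lo: float = DEFAULT_T_LO,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
) -> DomainRelation:
    """Quantify and classify the query channel's arrangement around the reference domain.

    overlap_coefficient = (baseline-subtracted query mass inside the reference
    FWHM) / (total baseline-subtracted query mass), with the mass floored at 0.
    The call is ``overlapping`` when the coefficient is at least ``t_hi``;
    ``flanking`` when it is at most ``t_lo`` AND query modes sit on both sides
    of 0 outside the reference FWHM; otherwise ``partial``.
    """
    if not (0.0 < t_lo < t_hi < 1.0):
        raise ValueError(f"thresholds must satisfy 0 < t_lo < t_hi < 1; got ({t_hi}, {t_lo})")
    lo, hi = reference_fwhm(avg, reference_channel)
    modes = find_query_modes(avg, query_channel, min_prominence)

    q = avg.channel_mean(query_channel)
    grid = np.asarray(avg.grid, dtype=float)
    mass = np.clip(q - q.min(), 0.0, None)
    total = float(mass.sum())
    if total > 0.0:
        inside = (grid >= lo) & (grid <= hi)
        overlap = float(mass[inside].sum() / total)
    else:
        overlap = 0.0

    flank_geometry = bool(np.any(modes < lo) and np.any(modes > hi))
    if overlap >= t_hi:
        call = "overlapping"
    elif overlap <= t_lo and flank_geometry:
        call = "flanking"
    else:
        call = "partial"

    return DomainRelation(
        reference_channel=reference_channel,
        query_channel=query_channel,
        reference_fwhm=(lo, hi),
        query_modes=tuple(float(x) for x in modes),
        peak_offsets=tuple(float(x) for x in modes),
        overlap_coefficient=overlap,
        call=call,
        thresholds_used=(t_hi, t_lo),
    )
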