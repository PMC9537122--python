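"""The 13 temporal pulse markers and their per-segment averaging.

All markers are computed on the 2D-normalized beat, so they are
dimensionless fractions of the beat duration (rising time and widths) or of
the unit square (total area):

* rising time — onset-to-peak duration;
* total area — trapezoid-rule area under the normalized pulse;
* width at f — pulse width at a horizontal level equal to fraction
  f ∈ {10, 20, 25, 30, 40, 50, 60, 70, 75, 80, 90}% of the onset-to-peak
  amplitude, measured from the first upward crossing before the peak to the
  last downward crossing after it (linear interpolation between samples).

The first-rise / last-fall convention makes level sets nested, so widths
are non-increasing in f for every beat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import Beat

WIDTH_FRACTIONS = (0.10, 0.20, 0.25, 0.30, 0.40, 0.50, 0.60, 0.70, 0.75, 0.80, 0.90)

MARKER_NAMES: tuple[str, ...] = (
    "rising_time", "total_area",
    *(f"width_{int(round(100 * f))}" for f in WIDTH_FRACTIONS),
)


def rising_time(beat: Beat) -> float:
    """Onset-to-peak duration as a fraction of the beat duration."""
    lm = beat.landmarks
    return (lm.peak_index - lm.onset_index) / (lm.end_index - lm.onset_index)


def total_area(beat: Beat) -> float:
    """Trapezoid-rule area of the normalized pulse over the unit interval."""
    y = beat.normalized
    return float(np.trapezoid(y, dx=1.0 / (len(y) - 1)))


def width_at(beat: Beat, f: float) -> float | None:
    """Pulse width at level ``f`` of the normalized amplitude.

    Returns None when the level is never crossed on the rising side
    (pathological shapes; a normalized beat starts at exactly 0, so genuine
    beats always cross); such beats are dropped wholesale by the segment
    averaging so per-segment marker vectors stay jointly consistent.  A
    beat whose tail stays above the level counts its width to the beat end.
    """
    if not (0.0 < f < 1.0):
        raise ValueError("level fraction must be in (0, 1)")
    y = beat.normalized
    n = len(y)
    peak = int(np.argmax(y))
    dt = 1.0 / (n - 1)

    t_up = None
    for i in range(peak):
        if y[i] < f <= y[i + 1]:
            t_up = (i + (f - y[i]) / (y[i + 1] - y[i])) * dt
            break
        if y[i] == f:
            t_up = i * dt
            break

    # a tail that ends at or above the level belongs to the level set up to
    # the beat end; only otherwise is the last genuine down-crossing taken
    # (this precedence keeps level sets nested even for oscillating tails)
    t_down = None
    if y[-1] >= f:
        t_down = 1.0
    else:
        for i in range(n - 2, peak - 1, -1):
            if y[i + 1] < f <= y[i]:
                t_down = (i + (y[i] - f) / (y[i] - y[i + 1])) * dt
                break
            if y[i + 1] == f:
                t_down = (i + 1) * dt
                break

    if t_up is None or t_down is None:
        return None
    return t_down - t_up


def beat_markers(beat: Beat) -> dict[str, float] | None:
    """All 13 markers for one beat; None if any width is undefined."""
    out = {"rising_time": rising_time(beat), "total_area": total_area(beat)}
    for f in WIDTH_FRACTIONS:
        w = width_at(beat, f)
        if w is None:
            return None
        out[f"width_{int(round(100 * f))}"] = w
    return out


@dataclass
class SegmentFeatures:
    """Per-segment marker means with provenance."""

    values: dict[str, float]
    n_beats: int
    subject_id: str
    label: str
    start_time: float


def extract_segment_features(segment, beats: list[Beat],
                             min_beats: int = 3) -> SegmentFeatures | None:
    """Average each marker over the segment's usable beats.

    A beat with any undefined marker is excluded from all means; segments
    with fewer than ``min_beats`` usable beats are rejected (None).
    """
    rows = [m for m in (beat_markers(b) for b in beats) if m is not None]
    if len(rows) < min_beats:
        return None
    means = {name: float(np.mean([r[name] for r in rows])) for name in MARKER_NAMES}
    return SegmentFeatures(values=means, n_beats=len(rows),
                           subject_id=segment.subject_id, label=segment.label,
                           start_time=segment.start_time)
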