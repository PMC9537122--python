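"""Per-segment preprocessing: smoothing, baseline removal, beat delineation,
and 2D normalization of individual pulses.

The delineation strategy is slope-based: extrema are located where the sign
of the first difference changes, candidate systolic peaks are filtered by a
prominence rule (to reject dicrotic maxima) and a refractory period, and
each beat onset is the global minimum between consecutive accepted peaks.
Every beat is then rescaled to the unit square — onset amplitude 0, peak
amplitude 1, and a fixed number of samples along the time axis — which is
what makes the downstream markers invariant to sensor gain and to the
100 Hz / 125 Hz acquisition-rate difference between source databases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import savgol_filter

#: number of samples in a normalized beat; >= native per-beat sample count
#: at both 100 and 125 Hz for heart rates up to ~75 bpm
DEFAULT_BEAT_LENGTH = 100


@dataclass(frozen=True)
class Landmarks:
    """Sample indices of one beat within its parent segment."""

    onset_index: int
    peak_index: int
    end_index: int  # next onset

    def __post_init__(self) -> None:
        if not (self.onset_index < self.peak_index < self.end_index):
            raise ValueError("landmarks must satisfy onset < peak < end")


@dataclass(frozen=True)
class Beat:
    """One 2D-normalized pulse."""

    normalized: np.ndarray  # length L, values in [0, 1]
    landmarks: Landmarks
    period_s: float
    source_fs: float


def savgol_smooth(samples: np.ndarray, order: int = 4, frame: int = 21) -> np.ndarray:
    """Savitzky-Golay smoothing (local least-squares polynomial fit).

    A 4th-order, 21-sample filter is the default; it attenuates broadband
    noise while preserving the sharp systolic upstroke better than a moving
    average.  Edges are handled by polynomial fits on truncated windows.
    """
    samples = np.asarray(samples, dtype=float)
    if frame <= order:
        raise ValueError("frame length must exceed polynomial order")
    if frame % 2 == 0:
        raise ValueError("frame length must be odd")
    if frame > len(samples):
        raise ValueError("frame length exceeds segment length")
    return savgol_filter(samples, window_length=frame, polyorder=order,
                         mode="interp")


def find_extrema(signal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Slope sign-change extrema.

    Index ``i`` is a maximum iff the first difference changes sign from
    positive to negative there (negative to positive for minima); a plateau
    is attributed to its first sample.  Monotone signals have no extrema.
    """
    signal = np.asarray(signal, dtype=float)
    if len(signal) < 3:
        raise ValueError("need at least 3 samples")
    d = np.diff(signal)
    maxima: list[int] = []
    minima: list[int] = []
    last_sign = 0
    cand = 0
    for i, di in enumerate(d):
        s = 1 if di > 0 else (-1 if di < 0 else 0)
        if s == 0:
            continue
        if last_sign > 0 and s < 0:
            maxima.append(cand)
        elif last_sign < 0 and s > 0:
            minima.append(cand)
        last_sign = s
        cand = i + 1
    return np.asarray(maxima, dtype=int), np.asarray(minima, dtype=int)


def remove_baseline(samples: np.ndarray, fs: float) -> np.ndarray:
    """Subtract respiration-driven baseline wander.

    A cubic spline is anchored at detected beat-onset values and subtracted,
    which flattens the slow drift while leaving pulse shape untouched (the
    anchor points are the morphological zeros of the pulse train).  With
    fewer than 4 anchors the interpolant degenerates to linear; with fewer
    than 2 the segment mean is subtracted instead.
    """
    samples = np.asarray(samples, dtype=float)
    onsets = _provisional_onsets(samples, fs)
    if len(onsets) < 2:
        return samples - samples.mean()
    x = np.arange(len(samples), dtype=float)
    vals = samples[onsets]
    if len(onsets) >= 4:
        spline = CubicSpline(onsets.astype(float), vals, bc_type="natural")
        baseline = spline(x)
    else:
        baseline = np.interp(x, onsets.astype(float), vals)
    return samples - baseline


def _provisional_onsets(samples: np.ndarray, fs: float) -> np.ndarray:
    """Coarse onset guesses used only to anchor the baseline spline."""
    peaks = _select_peaks(samples, fs)
    if len(peaks) < 2:
        return np.asarray([], dtype=int)
    onsets = [int(peaks[i] + np.argmin(samples[peaks[i]:peaks[i + 1]]))
              for i in range(len(peaks) - 1)]
    return np.asarray(onsets, dtype=int)


def _select_peaks(samples: np.ndarray, fs: float,
                  prominence_frac: float = 0.30,
                  refractory_s: float = 0.30) -> np.ndarray:
    """Systolic-peak candidates: slope maxima passing prominence + refractory.

    The prominence of a maximum is its height above the larger of the two
    flanking minima; maxima below ``prominence_frac`` of the upper-quartile
    prominence (dicrotic bumps, noise wiggles) are rejected.  The upper
    quartile, not the median, is the reference: dicrotic maxima can be as
    numerous as systolic ones, which would drag a median reference down
    between the two populations.  Of any two survivors closer than the
    refractory period the higher one wins; the refractory scales with the
    beat period estimated from the segment's autocorrelation (floored at
    ``refractory_s``), since a pronounced dicrotic wave can be nearly as
    prominent as the systolic peak and only its sub-period spacing gives
    it away.
    """
    maxima, _ = find_extrema(samples)
    if len(maxima) == 0:
        return maxima
    # flanking minimum on each side of each maximum
    bounds = np.concatenate(([0], maxima, [len(samples) - 1]))
    prominences = np.empty(len(maxima))
    for k, m in enumerate(maxima):
        left = samples[bounds[k]:m + 1].min()
        right = samples[m:bounds[k + 2] + 1].min()
        prominences[k] = samples[m] - max(left, right)
    positive = prominences[prominences > 0]
    ref = float(np.percentile(positive, 75)) if len(positive) else 0.0
    keep = maxima[prominences >= prominence_frac * ref] if ref > 0 else maxima
    if len(keep) == 0:
        return keep
    # refractory: greedy scan, keep the higher of two close peaks
    period = _estimate_period(samples, fs)
    spacing = refractory_s if period is None else max(refractory_s,
                                                      0.55 * period)
    refractory = int(round(spacing * fs))
    out = [int(keep[0])]
    for m in keep[1:]:
        if m - out[-1] < refractory:
            if samples[m] > samples[out[-1]]:
                out[-1] = int(m)
        else:
            out.append(int(m))
    return np.asarray(out, dtype=int)


def _estimate_period(samples: np.ndarray, fs: float,
                     lo_s: float = 0.33, hi_s: float = 2.0) -> float | None:
    """Dominant beat period from the autocorrelation peak, in seconds.

    Searches lags corresponding to 30-180 bpm; returns None when the
    autocorrelation has no positive peak there (aperiodic signal).
    """
    x = samples - samples.mean()
    n = len(x)
    lo = max(int(lo_s * fs), 1)
    hi = min(int(hi_s * fs), n - 2)
    if hi <= lo:
        return None
    ac = np.correlate(x, x, mode="full")[n - 1:]
    seg = ac[lo:hi + 1]
    i = int(np.argmax(seg))
    if seg[i] <= 0:
        return None
    return (lo + i) / fs


def _onset_between(samples: np.ndarray, left_peak: int, right_peak: int,
                   refine_on: np.ndarray | None = None) -> int:
    """Onset between two peaks: foot of the upstroke.

    The onset is the valley bottom.  When ``refine_on`` (the unsmoothed,
    detrended signal) is given, the argmin found on the smoothed signal is
    refined within a +-5-sample window on it: smoothing displaces the
    diastolic corner by a few samples, the raw valley does not.
    """
    seg = samples[left_peak:right_peak]
    i = int(np.argmin(seg))
    if refine_on is not None:
        lo = max(left_peak + i - 5, 0)
        hi = min(left_peak + i + 6, len(refine_on))
        return int(lo + np.argmin(refine_on[lo:hi]))
    return int(left_peak + i)


def delineate_beats(samples: np.ndarray, fs: float,
                    refine_on: np.ndarray | None = None) -> list[Landmarks]:
    """Delineate complete beats (onset -> peak -> next onset) in a segment.

    ``samples`` should already be baseline-removed; ``refine_on`` may give
    the unsmoothed detrended signal for sub-smoothing onset refinement.
    Partial beats at the segment edges are kept only when the boundary
    minimum genuinely reaches onset level (within 10% of the median pulse
    amplitude of the interior onsets), i.e. when the record happens to
    start or end at an onset.
    """
    samples = np.asarray(samples, dtype=float)
    peaks = _select_peaks(samples, fs)
    if len(peaks) < 2:
        return []
    interior = np.asarray(
        [_onset_between(samples, peaks[i], peaks[i + 1], refine_on)
         for i in range(len(peaks) - 1)], dtype=int)
    onset_level = np.median(samples[interior])
    amp = np.median(samples[peaks]) - onset_level
    if amp <= 0:
        return []
    onsets = list(interior)
    lead = int(np.argmin(samples[:peaks[0] + 1]))
    if lead < interior[0] and samples[lead] <= onset_level + 0.10 * amp:
        onsets.insert(0, lead)
    trail = int(peaks[-1] + np.argmin(samples[peaks[-1]:]))
    if (interior[-1] < trail < len(samples) - 1
            and samples[trail] <= onset_level + 0.10 * amp):
        onsets.append(trail)

    beats: list[Landmarks] = []
    for a, b in zip(onsets[:-1], onsets[1:]):
        inside = peaks[(peaks > a) & (peaks < b)]
        if len(inside) == 0:
            continue
        peak = int(inside[np.argmax(samples[inside])])
        beats.append(Landmarks(onset_index=int(a), peak_index=peak,
                               end_index=int(b)))
    return beats


def normalize_beat(samples: np.ndarray, landmarks: Landmarks, fs: float,
                   L: int = DEFAULT_BEAT_LENGTH) -> Beat:
    """2D-normalize one beat: amplitude to [0, 1], time axis to L samples.

    Amplitude is rescaled so the onset value maps to 0 and the peak value to
    1 (values outside the onset->peak range clip to [0, 1]); the time axis
    is linearly resampled over onset -> end.  This removes inter-subject
    gain differences and the sampling-rate difference between databases.
    """
    samples = np.asarray(samples, dtype=float)
    a, p, b = landmarks.onset_index, landmarks.peak_index, landmarks.end_index
    if b >= len(samples):
        raise ValueError("landmarks outside segment")
    v_on, v_pk = samples[a], samples[p]
    if v_pk <= v_on:
        raise ValueError("degenerate beat: peak amplitude not above onset")
    grid = np.linspace(a, b, L)
    y = np.interp(grid, np.arange(a, b + 1), samples[a:b + 1])
    y = (y - v_on) / (v_pk - v_on)
    np.clip(y, 0.0, 1.0, out=y)
    y /= y.max()  # resampling grid can narrowly miss the peak sample
    return Beat(normalized=y, landmarks=landmarks,
                period_s=(b - a) / fs, source_fs=fs)


def preprocess_segment(samples: np.ndarray, fs: float, order: int = 4,
                       frame: int = 21,
                       L: int = DEFAULT_BEAT_LENGTH) -> list[Beat]:
    """Full per-segment chain: smooth, de-trend, delineate, normalize."""
    samples = np.asarray(samples, dtype=float)
    sm = savgol_smooth(samples, order=order, frame=frame)
    flat = remove_baseline(sm, fs)
    flat_raw = samples - (sm - flat)  # same baseline, no smoothing
    beats = []
    for lm in delineate_beats(flat, fs, refine_on=flat_raw):
        try:
            beats.append(normalize_beat(flat, lm, fs, L=L))
        except ValueError:
            continue  # degenerate beat: drop, keep the rest of the segment
    return beats
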