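"""Synthetic two-class PPG cohort generator.

Each cardiac pulse is modeled as the sum of two Gaussian components on a
zero baseline: a systolic wave and a smaller, later dicrotic wave.  The two
classes of the default cohort (anesthesia vs non-anesthesia) differ in the
timing of the systolic peak (rising time) and in the component widths, but
are matched in area under the normalized pulse — the same contrast pattern
a two-sample t-test shows on the real markers, where every width and the
rising time separate the groups while the total area does not.

Records are assembled beat by beat with per-beat period jitter, then
contaminated with respiratory baseline wander, powerline interference,
white sensor noise, and occasional motion-artefact bursts, so the
delineation and quality-screening stages downstream have realistic work to
do.  Everything is driven by a single integer seed and is bit-for-bit
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

ANESTHESIA = "anesthesia"
NON_ANESTHESIA = "non_anesthesia"
LABELS = (NON_ANESTHESIA, ANESTHESIA)


@dataclass(frozen=True)
class PulseShapeParams:
    """Closed-form description of one pulse morphology.

    Centers and sigmas are fractions of the beat period; the dicrotic wave
    amplitude is relative to the systolic one and must stay below 1 so the
    systolic peak is the global maximum.
    """

    systolic_center: float
    systolic_sigma: float
    dicrotic_center: float
    dicrotic_sigma: float
    dicrotic_rel_amp: float
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.systolic_center < self.dicrotic_center < 1.0):
            raise ValueError("require 0 < systolic_center < dicrotic_center < 1")
        if self.systolic_sigma <= 0 or self.dicrotic_sigma <= 0:
            raise ValueError("component sigmas must be positive")
        if not (0.0 <= self.dicrotic_rel_amp < 1.0):
            raise ValueError("dicrotic_rel_amp must be in [0, 1)")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")


@dataclass(frozen=True)
class NoiseParams:
    """Additive contamination: respiration, mains, sensor noise, motion."""

    baseline_amp: float = 0.15
    baseline_freq: float = 0.25  # respiratory band, Hz
    powerline_amp: float = 0.02
    powerline_freq: float = 50.0
    white_sd: float = 0.01
    motion_burst_rate: float = 0.5  # events per minute
    motion_burst_amp: float = 0.6

    def __post_init__(self) -> None:
        for name in ("baseline_amp", "powerline_amp", "white_sd",
                     "motion_burst_rate", "motion_burst_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.baseline_freq <= 0 or self.powerline_freq <= 0:
            raise ValueError("noise frequencies must be positive")


# Default morphologies.  The non-anesthesia pulse has an early, narrow
# systolic wave with a pronounced dicrotic wave; anesthesia subjects sit on
# a depth continuum between two endpoint shapes: an early-but-wide pulse
# (vasodilation dominating) and a late-but-narrow one (delayed systolic
# upstroke dominating).  sigma_s + rel_amp * sigma_d, which controls the
# area of the normalized pulse, is matched across classes and along the
# continuum so total area carries no class signal.
DEFAULT_CLASS0_SHAPE = PulseShapeParams(
    systolic_center=0.27, systolic_sigma=0.078,
    dicrotic_center=0.64, dicrotic_sigma=0.115,
    dicrotic_rel_amp=0.41,
)
DEFAULT_CLASS1_SHAPE = PulseShapeParams(
    systolic_center=0.33, systolic_sigma=0.122,
    dicrotic_center=0.72, dicrotic_sigma=0.120,
    dicrotic_rel_amp=0.09,
)
DEFAULT_CLASS1_SHAPE_B = PulseShapeParams(
    systolic_center=0.46, systolic_sigma=0.094,
    dicrotic_center=0.80, dicrotic_sigma=0.105,
    dicrotic_rel_amp=0.37,
)


@dataclass(frozen=True)
class CohortConfig:
    """Study-design knobs for one synthetic cohort.

    The default emulates the source databases' design: 32 subjects per
    class, one class sampled at 100 Hz and the other at 125 Hz (a deliberate
    acquisition confound that 2D normalization must absorb), heart rate
    around 75 bpm (0.8-s cardiac cycle).
    """

    n_subjects_per_class: int = 32
    record_seconds: float = 60.0
    fs_class0: float = 125.0
    fs_class1: float = 100.0
    heart_rate_mean: float = 75.0
    heart_rate_sd: float = 4.0
    class0_shape: PulseShapeParams = DEFAULT_CLASS0_SHAPE
    class1_shape: PulseShapeParams = DEFAULT_CLASS1_SHAPE
    class1_shape_b: Optional[PulseShapeParams] = DEFAULT_CLASS1_SHAPE_B
    subject_jitter_rel_sd: float = 0.035
    #: sd of the common log-factor applied to class-0 pulse timing and
    #: widths jointly (between-subject vascular-tone covariation)
    class0_covariation_sd: float = 0.15
    beat_jitter_rel_sd: float = 0.02
    noise: NoiseParams = field(default_factory=NoiseParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects_per_class < 1:
            raise ValueError("need at least one subject per class")
        if self.record_seconds < 5:
            raise ValueError("record_seconds must be >= 5 (one analysis window)")
        if self.fs_class0 <= 0 or self.fs_class1 <= 0:
            raise ValueError("sampling rates must be positive")
        if self.heart_rate_mean <= 0 or self.heart_rate_sd < 0:
            raise ValueError("invalid heart-rate distribution")


@dataclass
class RawRecord:
    """One subject's continuous PPG trace."""

    samples: np.ndarray
    fs: float
    subject_id: str
    label: str
    source: str = "synthetic"
    #: optional ground truth / bookkeeping (synthetic records carry true
    #: landmark times; readers record non-finite sample counts here)
    annotations: dict = field(default_factory=dict)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


def _gauss(x: np.ndarray | float, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - center) / sigma) ** 2)


def _raw_pulse(phase, shape: PulseShapeParams):
    return (_gauss(phase, shape.systolic_center, shape.systolic_sigma)
            + shape.dicrotic_rel_amp
            * _gauss(phase, shape.dicrotic_center, shape.dicrotic_sigma))


def generate_beat(shape: PulseShapeParams, period_s: float, fs: float) -> np.ndarray:
    """Sample one beat of ``period_s`` seconds at ``fs`` Hz.

    The chord through the pulse's endpoint values is subtracted so the beat
    starts and ends exactly at zero; the first sample is therefore the beat
    onset (a minimum of the concatenated waveform) and consecutive beats
    join continuously.
    """
    if period_s <= 0 or fs <= 0:
        raise ValueError("period_s and fs must be positive")
    n = int(round(period_s * fs))
    if n < 10:
        raise ValueError("beat must span at least 10 samples (period_s * fs >= 10)")
    phase = np.arange(n) / n
    raw = _raw_pulse(phase, shape)
    v0 = float(_raw_pulse(0.0, shape))
    v1 = float(_raw_pulse(1.0, shape))
    y = raw - (v0 + (v1 - v0) * phase)
    return shape.amplitude * y


def _jitter_shape(shape: PulseShapeParams, rel_sd: float,
                  rng: np.random.Generator) -> PulseShapeParams:
    """Per-subject morphology variation: multiplicative lognormal jitter."""
    if rel_sd <= 0:
        return shape

    def j(v, lo=None, hi=None):
        out = v * float(np.exp(rng.normal(0.0, rel_sd)))
        if lo is not None:
            out = max(out, lo)
        if hi is not None:
            out = min(out, hi)
        return out

    sc = j(shape.systolic_center, 0.05, 0.60)
    dc = j(shape.dicrotic_center, sc + 0.05, 0.95)
    return PulseShapeParams(
        systolic_center=sc,
        systolic_sigma=j(shape.systolic_sigma, 1e-3),
        dicrotic_center=dc,
        dicrotic_sigma=j(shape.dicrotic_sigma, 1e-3),
        dicrotic_rel_amp=min(j(shape.dicrotic_rel_amp, 0.0), 0.95),
        amplitude=j(shape.amplitude, 1e-6),
    )


def _subject_rng(config: CohortConfig, class_idx: int,
                 subject_index: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=config.seed,
                                spawn_key=(class_idx, subject_index))
    return np.random.default_rng(ss)


def _subject_shape(config: CohortConfig, class_idx: int,
                   rng: np.random.Generator) -> PulseShapeParams:
    if class_idx == 0:
        base = config.class0_shape
        if config.class0_covariation_sd > 0:
            # vascular tone couples pulse timing and width between subjects:
            # one common log-factor stretches the whole temporal layout of
            # the pulse (systolic timing and width, dicrotic timing and
            # width), clamped so the dicrotic wave stays distinct from the
            # systolic one and still anchors a nonzero diastolic decay at
            # the beat boundary
            g = float(np.exp(rng.normal(0.0, config.class0_covariation_sd)))
            sc = min(base.systolic_center * g, 0.60)
            dc = min(max(base.dicrotic_center * g, sc + 0.22, 0.58), 0.88)
            # keep the dicrotic wide enough that the diastolic decay is
            # still sloped at the beat boundary (no ambiguous flat foot)
            sd = max(base.dicrotic_sigma * g, (1.0 - dc) / 3.2)
            base = PulseShapeParams(
                systolic_center=sc,
                systolic_sigma=base.systolic_sigma * g,
                dicrotic_center=dc,
                dicrotic_sigma=sd,
                dicrotic_rel_amp=base.dicrotic_rel_amp,
                amplitude=base.amplitude,
            )
    else:
        A, B = config.class1_shape, config.class1_shape_b
        if B is None:
            base = A
        else:
            # anesthetic-depth continuum: subjects sit on an arc from the
            # early-but-wide pulse (A) to the late-but-narrow one (B); the
            # systolic width follows a convex trade-off against timing, and
            # the dicrotic load is rebalanced so the area under the
            # normalized pulse stays constant along the arc
            u = float(rng.random())
            target_area = A.systolic_sigma + A.dicrotic_rel_amp * A.dicrotic_sigma
            ss = (B.systolic_sigma
                  + (A.systolic_sigma - B.systolic_sigma) * (1 - u) ** 2)
            sc = A.systolic_center + (B.systolic_center - A.systolic_center) * u
            dc = A.dicrotic_center + (B.dicrotic_center - A.dicrotic_center) * u
            sd = A.dicrotic_sigma + (B.dicrotic_sigma - A.dicrotic_sigma) * u
            rel = float(np.clip((target_area - ss) / sd, 0.02, 0.9))
            base = PulseShapeParams(
                systolic_center=sc, systolic_sigma=ss,
                dicrotic_center=max(dc, sc + 0.05), dicrotic_sigma=sd,
                dicrotic_rel_amp=rel, amplitude=A.amplitude)
    return _jitter_shape(base, config.subject_jitter_rel_sd, rng)


def generate_record(config: CohortConfig, subject_index: int,
                    class_label: str) -> RawRecord:
    """Generate one subject's labeled record with noise and ground truth."""
    if class_label not in LABELS:
        raise ValueError(f"unknown class label {class_label!r}")
    class_idx = LABELS.index(class_label)
    fs = config.fs_class1 if class_idx == 1 else config.fs_class0
    rng = _subject_rng(config, class_idx, subject_index)

    shape = _subject_shape(config, class_idx, rng)
    hr = rng.normal(config.heart_rate_mean, config.heart_rate_sd)
    hr = float(np.clip(hr, 30.0, 180.0))
    mean_period = 60.0 / hr

    n_total = int(round(config.record_seconds * fs))
    pieces: list[np.ndarray] = []
    onset_times: list[float] = []
    peak_times: list[float] = []
    t_cursor = 0.0
    n_done = 0
    while n_done < n_total:
        period = rng.normal(mean_period, config.beat_jitter_rel_sd * mean_period)
        period = float(np.clip(period, 0.7 * mean_period, 1.3 * mean_period))
        beat = generate_beat(shape, period, fs)
        onset_times.append(t_cursor)
        peak_times.append(t_cursor + float(np.argmax(beat)) / fs)
        pieces.append(beat)
        t_cursor += len(beat) / fs
        n_done += len(beat)
    clean = np.concatenate(pieces)[:n_total]

    # annotate onsets as the waveform's actual local minima around each
    # beat joint (the chord tilt can displace the minimum from the joint
    # by a few samples when the dicrotic wave is strong and late)
    half = max(int(round(0.12 * mean_period * fs)), 2)
    refined = []
    for b, t0 in zip(np.cumsum([0] + [len(p) for p in pieces[:-1]]), onset_times):
        i0 = max(int(b) - half, 0)
        i1 = min(int(b) + half + 1, n_total)
        if i0 >= i1:
            continue
        refined.append((i0 + int(np.argmin(clean[i0:i1]))) / fs)
    onset_times = refined

    t = np.arange(n_total) / fs
    noise = config.noise
    sig = clean.copy()
    if noise.baseline_amp > 0:
        sig = sig + noise.baseline_amp * np.sin(
            2 * np.pi * noise.baseline_freq * t + rng.uniform(0, 2 * np.pi))
    if noise.powerline_amp > 0:
        sig = sig + noise.powerline_amp * np.sin(
            2 * np.pi * noise.powerline_freq * t + rng.uniform(0, 2 * np.pi))
    if noise.white_sd > 0:
        sig = sig + rng.normal(0.0, noise.white_sd, n_total)
    if noise.motion_burst_rate > 0 and noise.motion_burst_amp > 0:
        n_bursts = rng.poisson(noise.motion_burst_rate *
                               config.record_seconds / 60.0)
        half = int(round(0.25 * fs))  # 0.5-s triangular ramp
        for _ in range(n_bursts):
            center = int(rng.integers(half, max(half + 1, n_total - half)))
            amp = noise.motion_burst_amp * rng.uniform(0.5, 1.5) * rng.choice([-1, 1])
            ramp = amp * (1.0 - np.abs(np.arange(-half, half + 1)) / half)
            lo, hi = center - half, center + half + 1
            sig[max(lo, 0):min(hi, n_total)] += ramp[max(lo, 0) - lo:
                                                     len(ramp) - (hi - min(hi, n_total))]

    prefix = "a" if class_idx == 1 else "n"
    return RawRecord(
        samples=sig,
        fs=fs,
        subject_id=f"{prefix}{subject_index:03d}",
        label=class_label,
        source="synthetic",
        annotations={
            "onset_times": np.asarray(onset_times),
            "peak_times": np.asarray(peak_times),
            "shape": shape,
            "heart_rate_bpm": hr,
        },
    )


def generate_cohort(config: CohortConfig) -> list[RawRecord]:
    """Generate the full two-class cohort (class 0 first, then class 1)."""
    records = [
        generate_record(config, i, label)
        for label in LABELS
        for i in range(config.n_subjects_per_class)
    ]
    ids = [r.subject_id for r in records]
    if len(set(ids)) != len(ids):  # defensive: subject ids key the CV grouping
        raise RuntimeError("duplicate subject ids in generated cohort")
    return records


def noiseless(config: CohortConfig) -> CohortConfig:
    """Copy of ``config`` with every noise source silenced."""
    quiet = NoiseParams(baseline_amp=0.0, powerline_amp=0.0, white_sd=0.0,
                        motion_burst_rate=0.0, motion_burst_amp=0.0)
    return replace(config, noise=quiet)
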