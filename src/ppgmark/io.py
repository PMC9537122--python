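"""Record ingestion, 5-s segmentation, and automatic quality screening.

Two on-disk dialects are supported: plain CSV with a named pleth column
(100-Hz-style exports) and WFDB record pairs (.hea header + format-16 .dat,
the layout of the 125-Hz waveform database).  The WFDB support here is a
deliberately small reader/writer for single-signal format-16 records — the
subset the synthetic cohort writer emits — not a general WFDB library.

Quality screening replaces a manual review with four deterministic rules:
flatline, clipping, broadband noise (excess slope sign changes), and too
few delineated beats.  Thresholds live in :class:`QualityRules`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import RawRecord

WINDOW_S = 5.0  # analysis window length


@dataclass(frozen=True)
class QualityRules:
    flatline_var_frac: float = 1e-6       # of squared signal range
    clipping_frac: float = 0.05           # samples allowed near rails
    clipping_margin_frac: float = 0.001   # "near" = within this of min/max
    max_sign_changes_per_beat: float = 12.0
    expected_beat_rate_hz: float = 2.0    # generous ceiling, ~120 bpm
    min_beats: int = 3


@dataclass
class Segment:
    samples: np.ndarray
    fs: float
    subject_id: str
    label: str
    start_time: float
    quality_ok: bool = True
    quality_reason: str = "ok"

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


def read_record(path: str | os.PathLike, format: str, *, subject_id: str,
                label: str, pleth_column: str = "pleth",
                fs: float | None = None) -> RawRecord:
    """Read one labeled record from disk (no resampling is performed)."""
    path = Path(path)
    if format == "csv":
        if fs is None:
            raise ValueError("fs must be given for CSV records")
        try:
            df = pd.read_csv(path, float_precision="round_trip")
        except pd.errors.EmptyDataError as e:
            raise ValueError(f"empty CSV record: {path}") from e
        if pleth_column not in df.columns:
            raise ValueError(
                f"column {pleth_column!r} not found in {path} "
                f"(columns: {list(df.columns)})")
        samples = df[pleth_column].to_numpy(dtype=float)
    elif format == "wfdb":
        samples, header_fs = _read_wfdb(path)
        fs = header_fs if fs is None else fs
    else:
        raise ValueError(f"unknown format {format!r}")
    if len(samples) == 0:
        raise ValueError(f"record {path} contains no samples")
    n_nonfinite = int(np.sum(~np.isfinite(samples)))
    return RawRecord(samples=samples, fs=float(fs), subject_id=subject_id,
                     label=label, source=format,
                     annotations={"n_nonfinite": n_nonfinite, "path": str(path)})


def segment_record(record: RawRecord, window_s: float = WINDOW_S) -> list[Segment]:
    """Cut a record into consecutive non-overlapping windows.

    The trailing remainder shorter than ``window_s`` is dropped; a record
    shorter than one window yields an empty list.
    """
    n_win = int(round(window_s * record.fs))
    n_segments = len(record.samples) // n_win
    return [
        Segment(samples=record.samples[i * n_win:(i + 1) * n_win].copy(),
                fs=record.fs, subject_id=record.subject_id,
                label=record.label, start_time=i * n_win / record.fs)
        for i in range(n_segments)
    ]


def screen_quality(segment: Segment,
                   rules: QualityRules = QualityRules()) -> Segment:
    """Return the segment with its quality flag set.

    Rules fire in a fixed order (flatline, clipping, out_of_band) and the
    first firing rule is recorded; the too_few_beats rule is applied later
    by the pipeline once delineation has run.
    """
    x = segment.samples
    rng_ = float(np.max(x) - np.min(x))
    reason = "ok"
    if rng_ <= 0 or float(np.var(x)) < rules.flatline_var_frac * rng_ ** 2:
        reason = "flatline"
    else:
        # saturation shows as a long contiguous dwell at a rail; the total
        # near-rail fraction would also trip on the flat diastolic foot of a
        # clean pulse train, so the longest single run is the statistic
        margin = rules.clipping_margin_frac * rng_
        near_rail = (x <= np.min(x) + margin) | (x >= np.max(x) - margin)
        if _longest_run(near_rail) > rules.clipping_frac * len(x):
            reason = "clipping"
        else:
            # count slope reversals after denoising: mains ripple and mild
            # sensor noise are removed by the smoothing stage anyway, so only
            # broadband noise that survives it should condemn a segment
            from .preprocess import savgol_smooth
            xs = savgol_smooth(x) if len(x) >= 21 else x
            d = np.diff(xs)
            s = np.sign(d)
            s = s[s != 0]
            n_changes = int(np.sum(s[1:] != s[:-1]))
            expected_beats = segment.duration_s * rules.expected_beat_rate_hz
            if n_changes > rules.max_sign_changes_per_beat * expected_beats:
                reason = "out_of_band"
    return replace(segment, quality_ok=(reason == "ok"), quality_reason=reason)


def _longest_run(mask: np.ndarray) -> int:
    best = cur = 0
    for v in mask:
        cur = cur + 1 if v else 0
        best = max(best, cur)
    return best


def flag_too_few_beats(segment: Segment, n_beats: int,
                       rules: QualityRules = QualityRules()) -> Segment:
    if segment.quality_ok and n_beats < rules.min_beats:
        return replace(segment, quality_ok=False, quality_reason="too_few_beats")
    return segment


# ---------------------------------------------------------------------------
# writers (round-trip surface for the synthetic cohort)

def write_record_csv(record: RawRecord, directory: str | os.PathLike) -> Path:
    """Write one record as ``<subject_id>.csv`` with time_s, pleth columns."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{record.subject_id}.csv"
    t = np.arange(len(record.samples)) / record.fs
    pd.DataFrame({"time_s": t, "pleth": record.samples}).to_csv(
        path, index=False, float_format="%.17g")
    return path


def write_cohort_csv(records: list[RawRecord],
                     directory: str | os.PathLike) -> pd.DataFrame:
    """Write all records plus a ``manifest.csv`` of ids, labels and rates."""
    directory = Path(directory)
    paths = [write_record_csv(r, directory) for r in records]
    manifest = pd.DataFrame({
        "subject_id": [r.subject_id for r in records],
        "label": [r.label for r in records],
        "fs": [r.fs for r in records],
        "path": [str(p) for p in paths],
    })
    manifest.to_csv(directory / "manifest.csv", index=False)
    return manifest


# ---------------------------------------------------------------------------
# minimal WFDB (single signal, format 16)

_ADC_MAX = 32000


def write_record_wfdb(record: RawRecord, directory: str | os.PathLike) -> Path:
    """Write ``<subject_id>.hea`` + ``.dat`` (format 16, little-endian)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = record.subject_id
    x = np.asarray(record.samples, dtype=float)
    scale = float(np.max(np.abs(x))) or 1.0
    gain = _ADC_MAX / scale
    adc = np.round(x * gain).astype("<i2")
    (directory / f"{name}.dat").write_bytes(adc.tobytes())
    header = (f"{name} 1 {record.fs:g} {len(x)}\n"
              f"{name}.dat 16 {gain:.6f}(0)/adu 16 0 {int(adc[0])} 0 0 pleth\n")
    hea = directory / f"{name}.hea"
    hea.write_text(header)
    return hea


def _read_wfdb(path: Path) -> tuple[np.ndarray, float]:
    """Read a single-signal format-16 WFDB record given its .hea path."""
    if path.suffix != ".hea":
        path = path.with_suffix(".hea")
    if not path.exists():
        raise ValueError(f"missing WFDB header: {path}")
    lines = [ln for ln in path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    if len(lines) < 2:
        raise ValueError(f"malformed WFDB header: {path}")
    rec_fields = lines[0].split()
    if len(rec_fields) < 3:
        raise ValueError(f"malformed WFDB record line: {lines[0]!r}")
    fs = float(rec_fields[2])
    sig = lines[1].split()
    dat_name, fmt = sig[0], sig[1]
    if fmt != "16":
        raise ValueError(f"unsupported WFDB format {fmt!r} (only 16)")
    gain_field = sig[2] if len(sig) > 2 else "200"
    gain_str = gain_field.split("(")[0]
    baseline = 0
    if "(" in gain_field:
        baseline = int(gain_field.split("(")[1].split(")")[0])
    gain = float(gain_str.split("/")[0]) or 200.0
    raw = np.frombuffer((path.parent / dat_name).read_bytes(), dtype="<i2")
    return (raw.astype(float) - baseline) / gain, fs
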