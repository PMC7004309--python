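"""Beat-level preprocessing of transcranial Doppler velocity recordings.

A 30-second per-depth cerebral blood flow velocity (CBFV) recording is reduced
to a single *normalized average beat*:

1. :func:`detect_beats` segments the recording at the foot of each systolic
   upstroke (derivative-threshold foot detection with a 0.3 s refractory
   period).
2. :func:`reject_outliers` discards artifact beats by iterated interquartile
   range (Tukey) fences on beat length and on maximum normalized
   cross-correlation against the ensemble mean.
3. :func:`average_beats` aligns the accepted beats at their onsets, pads each
   with its final value to the length of the longest beat, and averages the
   resulting rectangular ensemble.
4. :func:`standardize` resamples to 125 Hz if needed, smooths with a unit-sum
   90 ms Hanning window, rescales velocity to [0, 1], and cubic-spline
   resamples time to exactly 100 samples.

Recordings contribute to an analysis only if they retain at least
``min_beats`` (default 15) accepted beats, and subjects only if they have a
bilateral pair of qualifying recordings at insonation depths of 45-60 mm
(:func:`filter_exams`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import find_peaks, resample_poly

from .exceptions import ConfigurationError, DegenerateWaveformError

__all__ = [
    "Provenance",
    "RawRecording",
    "Beat",
    "AverageBeat",
    "NormalizedBeat",
    "detect_beats",
    "reject_outliers",
    "average_beats",
    "standardize",
    "filter_exams",
    "process_recording",
    "process_cohort",
    "TARGET_FS",
    "N_SAMPLES",
]

log = logging.getLogger(__name__)

#: Common sampling rate all waveforms are brought to before smoothing (Hz).
TARGET_FS = 125.0
#: Number of samples of a time-normalized beat.
N_SAMPLES = 100
#: Sampling rates accepted from the acquisition hardware (Hz).
VALID_FS = (125.0, 400.0)
#: Duration of the Hanning smoothing window (seconds).
SMOOTH_DURATION_S = 0.090
#: Minimum plausible beat length (seconds); shorter segments are discarded.
MIN_BEAT_S = 0.3

GROUPS = ("LVO", "IHC", "OHC")
HEMISPHERES = ("left", "right")


@dataclass(frozen=True)
class Provenance:
    """Acquisition metadata carried through the pipeline with each waveform."""

    subject_id: str
    group: str
    hemisphere: str
    depth_mm: float
    n_beats_used: int | None = None

    def as_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "group": self.group,
            "hemisphere": self.hemisphere,
            "depth_mm": self.depth_mm,
            "n_beats_used": self.n_beats_used,
        }


@dataclass
class RawRecording:
    """One contiguous per-depth CBFV time series with acquisition metadata.

    Parameters
    ----------
    samples : ndarray
        Velocity in cm/s.
    fs : float
        Sampling rate, 125 or 400 Hz.
    subject_id, group, hemisphere, depth_mm :
        Acquisition metadata; ``group`` is one of LVO / IHC / OHC.
    ground_truth : dict, optional
        Generator bookkeeping (beat onsets, artifact flags, flow type).  Never
        consumed by the analysis path; carried for validation only.
    """

    samples: np.ndarray
    fs: float
    subject_id: str = "anon"
    group: str = "OHC"
    hemisphere: str = "left"
    depth_mm: float = 52.0
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ConfigurationError("recording samples must be 1-D")
        if not np.all(np.isfinite(self.samples)):
            raise ConfigurationError("recording contains non-finite samples")
        if self.fs not in VALID_FS:
            raise ConfigurationError(
                f"sampling rate must be one of {VALID_FS}, got {self.fs}"
            )

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    @property
    def provenance(self) -> Provenance:
        return Provenance(self.subject_id, self.group, self.hemisphere, self.depth_mm)


@dataclass
class Beat:
    """One beat, from a systolic-upstroke onset to the next onset."""

    samples: np.ndarray
    onset_index: int

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class AverageBeat:
    """Ensemble average over accepted beats of one recording (native rate)."""

    samples: np.ndarray
    fs: float
    n_beats_used: int
    provenance: Provenance | None = None


@dataclass
class NormalizedBeat:
    """Average beat rescaled to [0, 1] velocity and exactly 100 time samples."""

    samples: np.ndarray
    provenance: Provenance | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.shape != (N_SAMPLES,):
            raise ValueError(f"normalized beat must have {N_SAMPLES} samples")


# ---------------------------------------------------------------------------
# beat segmentation


def detect_beats(rec: RawRecording, refractory_s: float = 0.3) -> list[Beat]:
    """Segment a recording into beats at the foot of each systolic upstroke.

    Candidate upstrokes are maxima of the first difference of a lightly
    smoothed copy of the signal, at least ``refractory_s`` apart and exceeding
    0.3x the 99th percentile of positive differences (robust to isolated
    amplitude-spike artifacts).  Each onset is the local minimum immediately
    preceding the upstroke.  Beats run from one onset to the next; the tail
    after the last onset is kept as a final beat when at least 0.3 s long.

    Returns an empty list (recording unusable) when no pulsatility is found.
    """
    x = rec.samples
    if len(x) < 2 * rec.fs:
        raise ConfigurationError("recording shorter than 2 s")
    if np.ptp(x) == 0.0:
        log.info("recording %s: constant signal, no beats", rec.subject_id)
        return []

    # light smoothing for detection only (~40 ms)
    win = max(3, int(round(0.04 * rec.fs)) | 1)
    w = np.hanning(win)
    w /= w.sum()
    xs = np.convolve(np.pad(x, win // 2, mode="reflect"), w, mode="valid")

    d = np.diff(xs)
    pos = d[d > 0]
    if pos.size == 0:
        return []
    height = 0.3 * np.percentile(pos, 99)
    if height <= 0:
        return []
    upstrokes, _ = find_peaks(
        d, height=height, distance=max(1, int(round(0.1 * rec.fs)))
    )
    if upstrokes.size == 0:
        return []

    # a systolic foot sits near the diastolic level; rises off troughs between
    # systolic peaks start much higher and are discarded (robust percentiles
    # keep the level estimate stable under amplitude-spike artifacts)
    p5, p95 = np.percentile(xs, [5, 95])
    foot_level = p5 + 0.35 * (p95 - p5)

    max_back = int(round(0.25 * rec.fs))
    refractory = int(round(refractory_s * rec.fs))
    onsets: list[int] = []
    for i in upstrokes:
        j = int(i)
        lo = max(0, j - max_back)
        while j > lo and xs[j - 1] <= xs[j]:
            j -= 1
        if xs[j] > foot_level:
            continue
        if onsets and j - onsets[-1] < refractory:
            # two candidate feet within one refractory period: keep the lower
            if xs[j] < xs[onsets[-1]]:
                onsets[-1] = j
            continue
        if not onsets or j > onsets[-1]:
            onsets.append(j)
    if not onsets:
        return []

    min_len = int(round(MIN_BEAT_S * rec.fs))
    bounds = onsets + ([len(x)] if len(x) - onsets[-1] >= min_len else [])
    beats = [
        Beat(samples=x[a:b].copy(), onset_index=a)
        for a, b in zip(bounds[:-1], bounds[1:])
        if b - a >= min_len
    ]
    return beats


# ---------------------------------------------------------------------------
# outlier rejection


def _max_norm_xcorr(a: np.ndarray, b: np.ndarray) -> float:
    """Maximum over lags of the normalized cross-correlation of two series.

    Both series are end-padded to a common length, z-scored, and correlated;
    the result lies in [-1, 1] (0 when either series is constant).
    """
    n = max(len(a), len(b))
    pa = np.concatenate([a, np.full(n - len(a), a[-1])])
    pb = np.concatenate([b, np.full(n - len(b), b[-1])])
    sa, sb = pa.std(), pb.std()
    if sa == 0 or sb == 0:
        return 0.0
    za = (pa - pa.mean()) / sa
    zb = (pb - pb.mean()) / sb
    return float(np.max(np.correlate(za, zb, mode="full")) / n)


def _tukey_fence(
    values: np.ndarray, mult: float, min_halfwidth: float = 1e-9
) -> tuple[float, float]:
    """Tukey fences with a floor on the fence half-width.

    The floor encodes the comparator's resolution: when the ensemble is
    nearly homogeneous the IQR collapses and unfloored fences would reject
    beats that differ only by measurement jitter, cascading on iteration.
    """
    q1, q3 = np.percentile(values, [25, 75])
    half = max(mult * (q3 - q1), min_halfwidth)
    return q1 - half, q3 + half


def reject_outliers(
    beats: Sequence[Beat],
    iqr_mult: float = 1.5,
    floor: int = 3,
    max_iter: int = 50,
) -> tuple[list[Beat], list[Beat]]:
    """Iterated-IQR beat rejection on length and cross-correlation.

    At each pass the ensemble mean of the surviving beats (onset-aligned,
    end-padded) is formed; beats whose length or maximum normalized
    cross-correlation against that mean falls outside the Tukey fences
    ``[Q1 - iqr_mult*IQR, Q3 + iqr_mult*IQR]`` are removed.  Iterates to a
    fixed point, never shrinking the ensemble below ``floor`` beats.

    Returns ``(accepted, rejected)``.  Fewer than 3 input beats are all
    rejected (too few to form fences).
    """
    beats = list(beats)
    if len(beats) < 3:
        return [], beats

    accepted = beats
    rejected: list[Beat] = []
    for _ in range(max_iter):
        lengths = np.array([len(b) for b in accepted], dtype=float)
        n = int(lengths.max())
        padded = np.stack(
            [
                np.concatenate([b.samples, np.full(n - len(b), b.samples[-1])])
                for b in accepted
            ]
        )
        ens_mean = padded.mean(axis=0)
        corrs = np.array([_max_norm_xcorr(b.samples, ens_mean) for b in accepted])

        # resolution floors: ~2% of the median beat length; 0.01 correlation
        lo_l, hi_l = _tukey_fence(
            lengths, iqr_mult, min_halfwidth=max(2.0, 0.02 * np.median(lengths))
        )
        lo_c, hi_c = _tukey_fence(corrs, iqr_mult, min_halfwidth=0.01)
        keep = (
            (lengths >= lo_l)
            & (lengths <= hi_l)
            & (corrs >= lo_c)
            & (corrs <= hi_c)
        )
        if keep.all():
            break
        if keep.sum() < floor:
            break
        rejected.extend(b for b, k in zip(accepted, keep) if not k)
        accepted = [b for b, k in zip(accepted, keep) if k]
    return accepted, rejected


# ---------------------------------------------------------------------------
# ensemble averaging


def average_beats(
    accepted: Sequence[Beat],
    fs: float = TARGET_FS,
    provenance: Provenance | None = None,
) -> AverageBeat:
    """Average onset-aligned beats end-padded to the longest beat's length.

    Each beat is padded with its own final value; the element-wise mean over
    the rectangular ensemble is returned.  The result has the length of the
    longest accepted beat.
    """
    if len(accepted) == 0:
        raise ValueError("cannot average an empty beat ensemble")
    n = max(len(b) for b in accepted)
    padded = np.stack(
        [
            np.concatenate([b.samples, np.full(n - len(b), b.samples[-1])])
            for b in accepted
        ]
    )
    return AverageBeat(
        samples=padded.mean(axis=0),
        fs=fs,
        n_beats_used=len(accepted),
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# normalization


def _smooth_hanning(x: np.ndarray, fs: float, duration_s: float) -> np.ndarray:
    """Convolve with a unit-sum Hanning window of ``duration_s`` seconds.

    The window length is rounded to the nearest odd sample count so alignment
    is preserved; edges are handled by reflection.
    """
    n = int(round(duration_s * fs))
    if n % 2 == 0:
        n -= 1
    n = max(n, 3)
    w = np.hanning(n)
    w /= w.sum()
    xp = np.pad(x, n // 2, mode="reflect")
    return np.convolve(xp, w, mode="valid")


def standardize(
    avg: AverageBeat | np.ndarray,
    native_fs: float | None = None,
    n_samples: int = N_SAMPLES,
) -> NormalizedBeat:
    """Normalize an average beat to [0, 1] velocity and 100 time samples.

    Order of operations: (1) polyphase resample 400 -> 125 Hz if the native
    rate is 400 Hz; (2) smooth with a unit-sum 90 ms Hanning window; (3)
    subtract the minimum and divide by the resulting maximum; (4) cubic-spline
    resample to exactly ``n_samples`` spanning the beat duration.  A final
    min-max rescale guards against spline overshoot so the output attains 0
    and 1 exactly.
    """
    if isinstance(avg, AverageBeat):
        x = np.asarray(avg.samples, dtype=float)
        fs = native_fs if native_fs is not None else avg.fs
        prov = avg.provenance
        if prov is not None:
            prov = replace(prov, n_beats_used=avg.n_beats_used)
    else:
        x = np.asarray(avg, dtype=float)
        fs = native_fs if native_fs is not None else TARGET_FS
        prov = None

    if fs not in VALID_FS:
        raise ConfigurationError(f"native_fs must be one of {VALID_FS}")
    if np.ptp(x) == 0.0:
        raise DegenerateWaveformError("constant waveform cannot be normalized")

    if fs == 400.0:
        # 125/400 = 5/16 exactly
        x = resample_poly(x, 5, 16)

    x = _smooth_hanning(x, TARGET_FS, SMOOTH_DURATION_S)

    x = x - x.min()
    peak = x.max()
    if peak == 0.0:
        raise DegenerateWaveformError("waveform collapsed to a constant")
    x = x / peak

    spline = CubicSpline(np.arange(len(x)), x)
    y = spline(np.linspace(0.0, len(x) - 1.0, n_samples))
    y = y - y.min()
    y = y / y.max()
    return NormalizedBeat(samples=y, provenance=prov)


# ---------------------------------------------------------------------------
# exam-level orchestration


def process_recording(
    rec: RawRecording,
    min_beats: int = 15,
    iqr_mult: float = 1.5,
) -> tuple[NormalizedBeat | None, str]:
    """Run one recording through segmentation, rejection, averaging and
    normalization.

    Returns ``(normalized_beat, "ok")`` or ``(None, reason)`` when the
    recording is unusable (no beats, fewer than ``min_beats`` accepted beats,
    or a degenerate average waveform).
    """
    beats = detect_beats(rec)
    if not beats:
        return None, "no beats detected"
    accepted, _ = reject_outliers(beats, iqr_mult=iqr_mult)
    if len(accepted) < min_beats:
        log.info(
            "recording %s %s %.0fmm: %d accepted beats < %d, excluded",
            rec.subject_id, rec.hemisphere, rec.depth_mm, len(accepted), min_beats,
        )
        return None, f"only {len(accepted)} accepted beats"
    avg = average_beats(accepted, fs=rec.fs, provenance=rec.provenance)
    try:
        norm = standardize(avg, native_fs=rec.fs)
    except DegenerateWaveformError as exc:
        return None, str(exc)
    return norm, "ok"


def filter_exams(
    normalized: Sequence[NormalizedBeat],
    min_beats: int = 15,
    depth_range: tuple[float, float] = (45.0, 60.0),
) -> list[NormalizedBeat]:
    """Apply the bilateral-exam inclusion rule.

    A waveform qualifies when its insonation depth lies within
    ``depth_range`` and it was averaged from at least ``min_beats`` beats
    (when that count is recorded).  Subjects are retained only if they have at
    least one qualifying recording in *each* hemisphere; all qualifying
    waveforms of retained subjects are returned in input order.
    """
    def qualifies(b: NormalizedBeat) -> bool:
        p = b.provenance
        if p is None:
            return False
        if not (depth_range[0] <= p.depth_mm <= depth_range[1]):
            return False
        if p.n_beats_used is not None and p.n_beats_used < min_beats:
            return False
        return True

    hemis: dict[str, set[str]] = {}
    for b in normalized:
        if qualifies(b):
            hemis.setdefault(b.provenance.subject_id, set()).add(
                b.provenance.hemisphere
            )
    bilateral = {s for s, h in hemis.items() if {"left", "right"} <= h}
    dropped = set(hemis) - bilateral
    if dropped:
        log.info("excluding %d subjects without bilateral pairs", len(dropped))
    return [
        b for b in normalized if qualifies(b) and b.provenance.subject_id in bilateral
    ]


def process_cohort(
    recordings: Sequence[RawRecording],
    min_beats: int = 15,
    iqr_mult: float = 1.5,
    apply_exam_filter: bool = True,
) -> list[NormalizedBeat]:
    """Process a list of recordings and apply the exam inclusion filter."""
    out: list[NormalizedBeat] = []
    for rec in recordings:
        norm, reason = process_recording(rec, min_beats=min_beats, iqr_mult=iqr_mult)
        if norm is not None:
            out.append(norm)
        else:
            log.debug("recording excluded: %s", reason)
    if apply_exam_filter:
        out = filter_exams(out, min_beats=min_beats)
    return out
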