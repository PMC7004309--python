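"""Morphological features of normalized beat waveforms.

Three scalar features summarize each normalized beat ``x(t_0..t_99)``:

* ``onset`` — the sample index at which the velocity maximum is attained
  (earliest index on ties), marking the temporal onset of maximal velocity.
* ``canopy`` — the number of samples in the systolic "canopy", the set
  ``{i : x(t_i) > x(t_0) + 0.25 (x(t_sys) - x(t_dias))}`` where ``t_sys`` and
  ``t_dias`` are the argmax and argmin of the waveform.
* ``peaks`` — a weighted count of peaks/troughs: every canopy sample where
  the successive-sample difference changes sign (a *true* peak or trough)
  counts 1; every maximal run of canopy samples whose difference magnitude is
  positive but below a critical threshold (default 0.01) and which contains
  no true peak contributes a *pseudo* peak of weight
  ``1 - |x(t_k) - x(t_k-1)| / threshold`` evaluated at the run's smallest
  difference magnitude.

All features are invariant to velocity scale and heart rate by construction,
since the inputs are velocity- and time-normalized.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateWaveformError
from .pipeline import NormalizedBeat

__all__ = [
    "FeatureMatrix",
    "FEATURE_NAMES",
    "PSEUDO_PEAK_THRESHOLD",
    "onset",
    "canopy",
    "canopy_mask",
    "true_peaks",
    "pseudo_peaks",
    "peaks",
    "build_feature_matrix",
]

FEATURE_NAMES = ("onset", "canopy", "peaks")

#: Critical successive-difference threshold below which a sample may count as
#: a pseudo-peak (dimensionless, on the [0, 1] velocity scale).
PSEUDO_PEAK_THRESHOLD = 0.01


def _as_array(w) -> np.ndarray:
    x = w.samples if isinstance(w, NormalizedBeat) else np.asarray(w, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("waveform must be a 1-D array of >= 3 samples")
    return x


def onset(w) -> int:
    """Sample index of the velocity maximum (earliest index on ties)."""
    return int(np.argmax(_as_array(w)))


def canopy_mask(w) -> np.ndarray:
    """Boolean mask of the canopy samples.

    The threshold is the first sample's value plus one quarter of the
    diastolic-systolic range.
    """
    x = _as_array(w)
    if np.ptp(x) == 0.0:
        raise DegenerateWaveformError("constant waveform has no canopy")
    return x > x[0] + 0.25 * (x.max() - x.min())


def canopy(w) -> int:
    """Number of samples in the canopy."""
    return int(canopy_mask(w).sum())


def true_peaks(w) -> list[int]:
    """Canopy sample indices where the successive difference changes sign.

    With the forward difference ``d_k = x(t_k) - x(t_k-1)``, index ``k`` is a
    true peak/trough when ``d_k`` is non-zero and the next non-zero
    difference has the opposite sign (so the first sample of a plateau marks
    the plateau's extremum).  Only canopy samples are eligible.
    """
    x = _as_array(w)
    d = np.diff(x)  # d[k-1] == x[k] - x[k-1]
    cm = canopy_mask(x)
    n = len(x)
    out: list[int] = []
    for k in range(1, n - 1):
        dk = d[k - 1]
        if dk == 0.0 or not cm[k]:
            continue
        m = k
        while m < n - 1 and d[m] == 0.0:
            m += 1
        if m < n - 1 and dk * d[m] < 0.0:
            out.append(k)
    return out


def pseudo_peaks(
    w, threshold: float = PSEUDO_PEAK_THRESHOLD
) -> list[tuple[int, float]]:
    """Pseudo-peaks: canopy samples where the derivative is small but non-zero.

    Candidates are canopy indices ``k`` with ``0 < |d_k| < threshold``.  Each
    maximal run of consecutive candidates that contains no true-peak index
    yields one pseudo-peak at the run's sample of smallest difference
    magnitude (earliest on ties), with weight ``1 - |d_k| / threshold``.
    Returns ``(index, weight)`` pairs; weights lie in (0, 1).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    x = _as_array(w)
    d = np.diff(x)
    cm = canopy_mask(x)
    tp = set(true_peaks(x))

    candidates = [
        k for k in range(1, len(x)) if cm[k] and 0.0 < abs(d[k - 1]) < threshold
    ]
    runs: list[list[int]] = []
    for k in candidates:
        if runs and k == runs[-1][-1] + 1:
            runs[-1].append(k)
        else:
            runs.append([k])

    out: list[tuple[int, float]] = []
    for run in runs:
        if any(k in tp for k in run):
            continue  # the structure is already counted as a true peak
        mags = np.array([abs(d[k - 1]) for k in run])
        j = int(np.argmin(mags))
        out.append((run[j], 1.0 - mags[j] / threshold))
    return out


def peaks(w, threshold: float = PSEUDO_PEAK_THRESHOLD) -> float:
    """Weighted peak count: ``card(TP) + sum of pseudo-peak weights``."""
    return float(len(true_peaks(w)) + sum(wt for _, wt in pseudo_peaks(w, threshold)))


@dataclass
class FeatureMatrix:
    """N x 3 morphological feature matrix with per-row provenance.

    ``values`` columns are (onset, canopy, peaks) in row order of the input
    waveforms; ``provenance`` is an aligned DataFrame with subject_id, group,
    hemisphere and depth_mm columns (empty when unavailable).
    """

    values: np.ndarray
    provenance: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 3:
            raise ValueError("feature matrix must be N x 3")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        df = self.provenance.reset_index(drop=True).copy()
        for j, name in enumerate(FEATURE_NAMES):
            df[name] = self.values[:, j]
        return df


def build_feature_matrix(
    beats: Sequence[NormalizedBeat | np.ndarray],
    threshold: float = PSEUDO_PEAK_THRESHOLD,
) -> FeatureMatrix:
    """Compute (onset, canopy, peaks) for each beat, preserving row order."""
    if len(beats) == 0:
        raise ValueError("cannot build a feature matrix from zero waveforms")
    rows = np.array(
        [[onset(b), canopy(b), peaks(b, threshold)] for b in beats], dtype=float
    )
    prov_rows = []
    for b in beats:
        p = b.provenance if isinstance(b, NormalizedBeat) else None
        prov_rows.append(
            p.as_dict()
            if p is not None
            else {
                "subject_id": None, "group": None, "hemisphere": None,
                "depth_mm": np.nan, "n_beats_used": None,
            }
        )
    return FeatureMatrix(values=rows, provenance=pd.DataFrame(prov_rows))
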