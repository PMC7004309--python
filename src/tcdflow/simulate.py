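"""Synthetic transcranial Doppler beat-train generator.

Real CBFV beat waveforms consist of an initial systolic upstroke followed by
up to three peaks (P1, P2, P3) and a diastolic runoff.  The generator models a
beat as a sum of skewed Gaussian bumps (one per peak) plus a broad diastolic
runoff hump, all defined on the dimensionless beat phase [0, 1), so that beat
shape scales exactly with beat duration.  Four morphological archetypes are
provided, mirroring the flow types an unsupervised analysis of stroke-center
data distinguishes:

* type I   - normal: early velocity maximum, wide canopy, strong P1/P2/P3;
* type II  - late-onset: maximum at the mid-systolic peak, otherwise normal;
* type III - narrow-spike: early sharp systolic spike, suppressed later
  structure, low diastolic flow;
* type IV  - blunted: slow flow acceleration, single broad late maximum.

Component widths are kept above ~0.065 beat-phase units so that beat shape is
robust to the pipeline's fixed 90 ms smoothing window across physiological
heart rates (50-100 bpm); narrower features would make the normalized shape
heart-rate dependent.

Ground truth (beat onsets, artifact flags, flow-type labels) is carried in
``RawRecording.ground_truth`` and is never consumed by the analysis path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError
from .pipeline import GROUPS, HEMISPHERES, RawRecording

__all__ = [
    "FlowTypeSpec",
    "SimConfig",
    "FLOW_TYPES",
    "generate_beat",
    "generate_recording",
    "generate_feature_cloud",
    "simulate_cohort",
]

#: Default systolic velocity amplitude (cm/s) of generated beats.
DEFAULT_SYSTOLIC_CM_S = 80.0

VALID_FS = (125.0, 400.0)
BEAT_DURATION_RANGE = (0.4, 2.0)


@dataclass(frozen=True)
class FlowTypeSpec:
    """Parametric morphology of one flow type.

    Each peak component is a skewed Gaussian bump with separate left/right
    widths (fast upstroke, slower decay); ``runoff`` is a broad hump modelling
    the diastolic velocity decay.  All positions and widths are fractions of
    the beat duration.

    Parameters
    ----------
    type_id : str
        "I", "II", "III" or "IV".
    peak_positions, peak_amplitudes : tuple of float
        Fractional beat-phase locations (strictly increasing, within [0, 1])
        and relative heights of the P1/P2/P3 components.
    peak_widths : tuple of (float, float)
        Left/right Gaussian widths of each component.
    onset_delay : float
        Fraction of the beat at which the velocity maximum occurs; equals the
        position of the largest-amplitude component.
    canopy_width : float
        Nominal fraction of the beat spent above quarter-range (descriptive).
    diastolic_level : float
        Foot velocity as a fraction of the systolic amplitude.
    runoff : (center, amplitude, width)
        Diastolic runoff hump parameters.
    """

    type_id: str
    peak_positions: tuple[float, ...]
    peak_amplitudes: tuple[float, ...]
    peak_widths: tuple[tuple[float, float], ...]
    onset_delay: float
    canopy_width: float
    diastolic_level: float
    runoff: tuple[float, float, float]

    def __post_init__(self) -> None:
        p = np.asarray(self.peak_positions, dtype=float)
        if len(p) != len(self.peak_amplitudes) or len(p) != len(self.peak_widths):
            raise ConfigurationError("peak parameter tuples must share a length")
        if np.any(p < 0) or np.any(p > 1):
            raise ConfigurationError("peak positions must lie in [0, 1]")
        if np.any(np.diff(p) <= 0):
            raise ConfigurationError("peak positions must be strictly increasing")
        if any(a <= 0 for a in self.peak_amplitudes):
            raise ConfigurationError("peak amplitudes must be positive")
        dominant = self.peak_positions[int(np.argmax(self.peak_amplitudes))]
        if abs(dominant - self.onset_delay) > 0.02:
            raise ConfigurationError(
                "onset_delay must match the dominant peak position"
            )

    def jittered(self, rng: np.random.Generator, strength: float = 1.0
                 ) -> "FlowTypeSpec":
        """Perturbed copy emulating inter-subject morphological variability.

        At ``strength`` 1, peak positions move by sd 0.01 beat-phase units and
        amplitudes/widths/runoff scale by ~5-10% lognormal factors.  The
        dominant peak keeps its identity, so the flow type is preserved.
        """
        if strength == 0:
            return self
        npk = len(self.peak_positions)
        pos = np.asarray(self.peak_positions) + rng.normal(0, 0.01 * strength, npk)
        amps = np.asarray(self.peak_amplitudes) * np.exp(
            rng.normal(0, 0.05 * strength, npk)
        )
        widths = tuple(
            (sl * f, sr * f)
            for (sl, sr), f in zip(
                self.peak_widths, np.exp(rng.normal(0, 0.05 * strength, npk))
            )
        )
        c0, a0, s0 = self.runoff
        runoff = (
            float(np.clip(c0 + rng.normal(0, 0.01 * strength), 0.0, 1.0)),
            a0 * float(np.exp(rng.normal(0, 0.10 * strength))),
            s0 * float(np.exp(rng.normal(0, 0.05 * strength))),
        )
        dias = float(
            np.clip(self.diastolic_level * np.exp(rng.normal(0, 0.10 * strength)),
                    0.0, 0.6)
        )
        return FlowTypeSpec(
            type_id=self.type_id,
            peak_positions=tuple(pos),
            peak_amplitudes=tuple(amps),
            peak_widths=widths,
            onset_delay=float(pos[int(np.argmax(amps))]),
            canopy_width=self.canopy_width,
            diastolic_level=dias,
            runoff=runoff,
        )

    def shape(self, phase: np.ndarray) -> np.ndarray:
        """Noise-free beat shape on the given phase grid (arbitrary units)."""
        v = np.zeros_like(phase, dtype=float)
        for c, a, (sl, sr) in zip(
            self.peak_positions, self.peak_amplitudes, self.peak_widths
        ):
            s = np.where(phase < c, sl, sr)
            v += a * np.exp(-((phase - c) ** 2) / (2.0 * s**2))
        c0, a0, s0 = self.runoff
        v += a0 * np.exp(-((phase - c0) ** 2) / (2.0 * s0**2))
        return v


#: Versioned flow-type templates.  Frozen: tests depend on these values.
FLOW_TYPES: dict[str, FlowTypeSpec] = {
    "I": FlowTypeSpec(
        type_id="I",
        peak_positions=(0.17, 0.36, 0.55),
        peak_amplitudes=(1.0, 0.62, 0.40),
        peak_widths=((0.065, 0.072), (0.075, 0.075), (0.08, 0.09)),
        onset_delay=0.17,
        canopy_width=0.63,
        diastolic_level=0.15,
        runoff=(0.70, 0.20, 0.29),
    ),
    "II": FlowTypeSpec(
        type_id="II",
        peak_positions=(0.15, 0.36, 0.56),
        peak_amplitudes=(0.65, 1.0, 0.45),
        peak_widths=((0.055, 0.062), (0.068, 0.075), (0.08, 0.09)),
        onset_delay=0.36,
        canopy_width=0.64,
        diastolic_level=0.18,
        runoff=(0.72, 0.20, 0.29),
    ),
    "III": FlowTypeSpec(
        type_id="III",
        peak_positions=(0.18,),
        peak_amplitudes=(1.0,),
        peak_widths=((0.065, 0.075),),
        onset_delay=0.18,
        canopy_width=0.23,
        diastolic_level=0.05,
        runoff=(0.80, 0.06, 0.45),
    ),
    "IV": FlowTypeSpec(
        type_id="IV",
        peak_positions=(0.52,),
        peak_amplitudes=(1.0,),
        peak_widths=((0.15, 0.15),),
        onset_delay=0.52,
        canopy_width=0.54,
        diastolic_level=0.25,
        runoff=(0.70, 0.12, 0.28),
    ),
}


@dataclass
class SimConfig:
    """Cohort simulation parameters.

    ``group_flowtype_mixture`` maps each subject group to a probability
    vector over flow types I-IV; defaults loosely mirror the group
    compositions reported for stroke-center cohorts (LVO hemispheres mostly
    types III/IV, controls mostly I/II).
    """

    n_subjects_per_group: int = 10
    group_flowtype_mixture: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "LVO": {"I": 0.05, "II": 0.15, "III": 0.25, "IV": 0.55},
            "IHC": {"I": 0.45, "II": 0.35, "III": 0.02, "IV": 0.18},
            "OHC": {"I": 0.70, "II": 0.25, "III": 0.01, "IV": 0.04},
        }
    )
    heart_rate_mean: float = 75.0  # bpm
    heart_rate_sd: float = 5.0  # bpm
    sampling_rate: float = 125.0  # Hz
    duration: float = 30.0  # s
    noise_sd: float = 0.03  # fraction of systolic amplitude
    artifact_beat_rate: float = 0.05  # probability per beat
    morph_jitter: float = 1.0  # inter-subject morphology variability scale
    depths_per_hemisphere: int = 2
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.sampling_rate not in VALID_FS:
            raise ConfigurationError(f"sampling_rate must be one of {VALID_FS}")
        if self.n_subjects_per_group < 1:
            raise ConfigurationError("n_subjects_per_group must be >= 1")
        if not (0 <= self.artifact_beat_rate <= 1):
            raise ConfigurationError("artifact_beat_rate must be in [0, 1]")
        if self.heart_rate_mean <= 0 or self.heart_rate_sd < 0:
            raise ConfigurationError("invalid heart-rate parameters")
        # a 30 s window must fit >= 15 beats at the mean heart rate
        if self.duration < 15 * 60.0 / self.heart_rate_mean:
            raise ConfigurationError(
                "duration too short to fit 15 beats at the mean heart rate"
            )
        for g, mix in self.group_flowtype_mixture.items():
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(f"mixture for group {g} sums to {total}")
            if any(p < 0 for p in mix.values()):
                raise ConfigurationError(f"negative mixture weight for group {g}")


def generate_beat(
    spec: FlowTypeSpec,
    beat_duration: float,
    fs: float,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    systolic_cm_s: float = DEFAULT_SYSTOLIC_CM_S,
) -> np.ndarray:
    """Generate one beat (velocity in cm/s) of the given flow type.

    The beat starts at the foot of the systolic upstroke (its minimum lies at
    sample 0 in the noise-free case) and its maximum occurs at beat phase
    ``spec.onset_delay``.  ``noise_sd`` adds white Gaussian noise as a
    fraction of the systolic amplitude; the result is clipped at zero
    (velocities are non-negative).
    """
    if fs not in VALID_FS:
        raise ConfigurationError(f"fs must be one of {VALID_FS}")
    if not (BEAT_DURATION_RANGE[0] <= beat_duration <= BEAT_DURATION_RANGE[1]):
        raise ConfigurationError(
            f"beat_duration must lie in {BEAT_DURATION_RANGE}, got {beat_duration}"
        )
    n = int(round(beat_duration * fs))
    phase = np.arange(n) / n
    shape = spec.shape(phase)
    pulse_amp = systolic_cm_s * (1.0 - spec.diastolic_level)
    v = systolic_cm_s * spec.diastolic_level + pulse_amp * shape / shape.max()
    if noise_sd > 0:
        if rng is None:
            raise ConfigurationError("rng required when noise_sd > 0")
        v = v + noise_sd * systolic_cm_s * rng.standard_normal(n)
    return np.clip(v, 0.0, None)


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float) -> float:
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(100):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def generate_recording(
    cfg: SimConfig,
    spec: FlowTypeSpec,
    rng: np.random.Generator,
    subject_id: str = "S000",
    group: str = "OHC",
    hemisphere: str = "left",
    depth_mm: float | None = None,
    systolic_cm_s: float = DEFAULT_SYSTOLIC_CM_S,
) -> RawRecording:
    """Generate one per-depth recording as a train of beats.

    Per-beat durations are drawn i.i.d. from a truncated normal implied by
    the heart-rate distribution.  With probability ``cfg.artifact_beat_rate``
    a beat is replaced by an artifact: either a flatline at the diastolic
    level (shape outlier) or a 3x amplitude spike (scale outlier).  Ground
    truth (onsets, artifact flags, flow type) is stored on the recording.
    """
    fs = cfg.sampling_rate
    total = int(round(cfg.duration * fs))
    if depth_mm is None:
        depth_mm = float(rng.uniform(45.0, 60.0))
    # one morphology draw per recording (a recording yields one average beat)
    spec = spec.jittered(rng, cfg.morph_jitter)

    samples = np.empty(0)
    onsets: list[int] = []
    artifact_flags: list[bool] = []
    while len(samples) < total:
        hr = _truncnorm(rng, cfg.heart_rate_mean, cfg.heart_rate_sd, 40.0, 140.0)
        dur = float(np.clip(60.0 / hr, *BEAT_DURATION_RANGE))
        beat = generate_beat(
            spec, dur, fs,
            noise_sd=cfg.noise_sd, rng=rng, systolic_cm_s=systolic_cm_s,
        )
        is_artifact = bool(rng.random() < cfg.artifact_beat_rate)
        if is_artifact:
            if rng.random() < 0.5:
                beat = np.full_like(
                    beat, systolic_cm_s * spec.diastolic_level
                )  # flatline
            else:
                beat = beat * 3.0  # amplitude spike
        onsets.append(len(samples))
        artifact_flags.append(is_artifact)
        samples = np.concatenate([samples, beat])
    samples = samples[:total]
    onsets = [o for o in onsets if o < total]
    artifact_flags = artifact_flags[: len(onsets)]

    return RawRecording(
        samples=samples,
        fs=fs,
        subject_id=subject_id,
        group=group,
        hemisphere=hemisphere,
        depth_mm=depth_mm,
        ground_truth={
            "onsets": onsets,
            "artifact": artifact_flags,
            "flow_type": spec.type_id,
        },
    )


def simulate_cohort(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> list[RawRecording]:
    """Simulate a three-group cohort of per-depth recordings.

    One flow type is drawn per subject hemisphere from the group's mixture;
    each hemisphere contributes ``cfg.depths_per_hemisphere`` recordings at
    depths drawn uniformly from 45-60 mm.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    type_ids = list(FLOW_TYPES)
    recordings: list[RawRecording] = []
    for group in GROUPS:
        mix = cfg.group_flowtype_mixture[group]
        probs = np.array([mix.get(t, 0.0) for t in type_ids])
        for i in range(cfg.n_subjects_per_group):
            sid = f"{group}-{i:03d}"
            for hemi in HEMISPHERES:
                ft = type_ids[rng.choice(len(type_ids), p=probs)]
                for _ in range(cfg.depths_per_hemisphere):
                    recordings.append(
                        generate_recording(
                            cfg, FLOW_TYPES[ft], rng,
                            subject_id=sid, group=group, hemisphere=hemi,
                        )
                    )
    return recordings


def generate_feature_cloud(
    k: int,
    n_per_cluster: int,
    separation: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Planted 3-D point cloud: ``k`` isotropic unit-variance groups.

    Cluster centroids are drawn with pairwise Euclidean distances of at least
    ``separation`` (in z-units); each group receives ``n_per_cluster``
    standard-normal points around its centroid.  Returns ``(X, labels)``.
    """
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    if n_per_cluster < 1:
        raise ConfigurationError("n_per_cluster must be >= 1")
    if separation <= 0:
        raise ConfigurationError("separation must be positive")

    if k <= 4:
        # randomly rotated regular simplex: every centroid pair exactly
        # `separation` apart, the canonical well-separated configuration
        E = np.eye(k) * separation / np.sqrt(2.0)
        E = E - E.mean(axis=0)
        # distance-preserving coordinates in the simplex's (k-1)-dim span
        U, s, _ = np.linalg.svd(E, full_matrices=False)
        coords = U[:, : k - 1] * s[: k - 1]
        coords = np.pad(coords, ((0, 0), (0, 3 - (k - 1))))
        rot, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        centroids = coords @ rot.T
    else:
        centroids_l = [np.zeros(3)]
        scale = float(separation)
        while len(centroids_l) < k:
            for _ in range(1000):
                c = rng.normal(scale=scale, size=3)
                if all(np.linalg.norm(c - c0) >= separation for c0 in centroids_l):
                    centroids_l.append(c)
                    break
            else:
                scale *= 1.5  # widen the proposal until placement succeeds
        centroids = np.asarray(centroids_l)

    labels = np.repeat(np.arange(k), n_per_cluster)
    X = centroids[labels] + rng.standard_normal((k * n_per_cluster, 3))
    return X, labels
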