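"""Ground-truthed synthetic recordings for every pipeline stage.

The generator produces per-frame total-blood-concentration traces composed of
a cardiac pulse train (an asymmetric two-Gaussian beat template whose beat
intervals carry LF ~0.1 Hz and HF ~0.25 Hz modulation), a vasomotion
oscillation in the 1-8 cycles/min band, and white sensor noise; a stress
condition scales the pulse and vasomotion band powers and shifts the LF/HF
balance. Recordings can be rendered to spatially uniform skin-colored RGB
video through an affine concentration-to-XYZ model and a known camera mixing
matrix, so the full imaging chain is testable against stored ground truth.

Cohort templates mirror the three stress experiments the package is designed
around: an auditory tone (n=10, 140 s conditions), a Stroop color-word task
(n=11, 360 s) and mental arithmetic (n=11, 120 s), with log-normal
between-subject variability and per-subject effect sizes drawn around mean
power scalings of 0.64 (pulse) and 0.50 (vasomotion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .color_calibration import ColorCheckerObservation
from .concentration_imaging import ConcentrationSeries, FrameSequence
from .hemodynamics import BVP_BAND, BandSpec, Waveform, periodogram_psd
from .skin_optics import ChromophoreSet, TristimulusValue

__all__ = [
    "SubjectProfile",
    "ConditionEffect",
    "RecordingSpec",
    "SyntheticRecording",
    "ForwardColorModel",
    "synthesize_concentration_series",
    "render_video",
    "colorchecker_fixture",
    "generate_cohort",
    "fit_forward_color_model",
    "nominal_forward_model",
    "EXPERIMENT_TEMPLATES",
    "DEFAULT_CAMERA_MATRIX",
    "DEFAULT_TASK_EFFECT",
]

#: Mean stress effect sizes: power scale factors for pulse and vasomotion.
DEFAULT_TASK_EFFECT = (0.64, 0.50, 1.0)

#: A gently mixing, well-conditioned camera matrix (RGB = matrix @ XYZ).
DEFAULT_CAMERA_MATRIX = np.array(
    [[0.90, 0.10, 0.00], [0.05, 0.85, 0.10], [0.00, 0.10, 0.90]]
)

#: Protocol templates: (n subjects, condition duration s, frame rate Hz).
EXPERIMENT_TEMPLATES = {
    "auditory": {"n_subjects": 10, "duration_s": 140.0, "fs": 30.0},
    "stroop": {"n_subjects": 11, "duration_s": 360.0, "fs": 30.0},
    "mat": {"n_subjects": 11, "duration_s": 120.0, "fs": 30.0},
}


@dataclass(frozen=True)
class SubjectProfile:
    """Physiological ground-truth parameters of one synthetic subject.

    Amplitudes are in vol%; the pulse amplitude is defined so that the
    rest-condition BVP band power equals ``pulse_amplitude**2 / 2``.
    """

    baseline_ctb: float = 5.0
    c_m: float = 4.0
    pulse_amplitude: float = 0.5
    hr_bpm: float = 65.0
    lf_depth: float = 0.03
    lf_freq: float = 0.1
    hf_depth: float = 0.03
    hf_freq: float = 0.25
    vaso_amplitude: float = 1.0
    vaso_freq_cpm: float = 3.0
    noise_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 40.0 <= self.hr_bpm <= 180.0:
            raise ValueError("heart rate must lie in 40-180 BPM")
        if not 1.0 <= self.vaso_freq_cpm <= 8.0:
            raise ValueError("vasomotion frequency must lie in 1-8 cycles/min")
        for name in ("pulse_amplitude", "vaso_amplitude", "lf_depth", "hf_depth",
                     "noise_sigma", "baseline_ctb", "c_m"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class ConditionEffect:
    """Multiplicative condition effects on the signal components."""

    pulse_power_scale: float = 1.0
    vaso_power_scale: float = 1.0
    lf_hf_shift: float = 1.0

    def __post_init__(self) -> None:
        for name in ("pulse_power_scale", "vaso_power_scale", "lf_hf_shift"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class RecordingSpec:
    """Recording geometry: duration (s), frame rate (Hz), ROI size (px)."""

    duration_s: float = 140.0
    fs: float = 30.0
    roi_size: tuple[int, int] = (16, 16)

    def __post_init__(self) -> None:
        if self.duration_s * self.fs < 64:
            raise ValueError("recording too short for the filter warm-up")
        if self.fs <= 7.0:
            raise ValueError("frame rate under-samples the pulse band")


@dataclass(frozen=True)
class ForwardColorModel:
    """Affine concentration -> XYZ map: XYZ = matrix @ [1, Cm, CHbO, CHbR]."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 4) or np.any(~np.isfinite(m)):
            raise ValueError("forward color model must be a finite 3x4 matrix")
        object.__setattr__(self, "matrix", m)

    def xyz(self, c_m, c_hbo, c_hbr) -> np.ndarray:
        stack = np.stack(
            [np.ones_like(np.asarray(c_m, float)),
             np.asarray(c_m, float),
             np.asarray(c_hbo, float),
             np.asarray(c_hbr, float)],
            axis=-1,
        )
        return stack @ self.matrix.T


@dataclass(frozen=True)
class SyntheticRecording:
    """A generated recording with complete component-wise ground truth."""

    series: ConcentrationSeries
    true_beat_times: np.ndarray
    pulse_component: np.ndarray
    vaso_component: np.ndarray
    profile: SubjectProfile
    effect: ConditionEffect
    spec: RecordingSpec
    frames: FrameSequence | None = None

    @property
    def fs(self) -> float:
        return self.spec.fs


def _beat_times(profile: SubjectProfile, effect: ConditionEffect,
                duration: float, rng: np.random.Generator) -> np.ndarray:
    """Beat onsets from an IBI process with LF and HF sinusoidal modulation."""
    mean_ibi = 60.0 / profile.hr_bpm
    hf_depth = profile.hf_depth / effect.lf_hf_shift
    phi_lf, phi_hf = rng.uniform(0, 2 * np.pi, size=2)
    times = [0.0]
    t = 0.0
    while t < duration + 2 * mean_ibi:
        ibi = mean_ibi * (
            1.0
            + profile.lf_depth * np.sin(2 * np.pi * profile.lf_freq * t + phi_lf)
            + hf_depth * np.sin(2 * np.pi * profile.hf_freq * t + phi_hf)
        )
        t += ibi
        times.append(t)
    return np.array(times)


def _pulse_template_trace(t: np.ndarray, beats: np.ndarray) -> np.ndarray:
    """Asymmetric per-beat waveform: systolic peak plus diastolic shoulder."""
    idx = np.clip(np.searchsorted(beats, t, side="right") - 1, 0, beats.size - 2)
    onset = beats[idx]
    period = beats[idx + 1] - beats[idx]
    tau = (t - onset) / period
    systolic = np.exp(-0.5 * ((tau - 0.30) / 0.10) ** 2)
    diastolic = 0.4 * np.exp(-0.5 * ((tau - 0.65) / 0.16) ** 2)
    return systolic + diastolic


def _band_power_of(values: np.ndarray, fs: float, band: BandSpec) -> float:
    psd = periodogram_psd(Waveform(values, fs))
    return psd.band_integral(band.low, band.high)


def synthesize_concentration_series(
    profile: SubjectProfile,
    effect: ConditionEffect = ConditionEffect(),
    spec: RecordingSpec = RecordingSpec(),
) -> SyntheticRecording:
    """Generate one ground-truthed concentration recording.

    Ctb(t) = baseline + sqrt(pulse scale) * A_p * pulsewave(t)
           + sqrt(vaso scale) * A_v * sin(2 pi f_v t + phi) + noise, where
    ``pulsewave`` is the beat-template train normalized to unit-sinusoid
    band power (0.5 in the 0.7-3 Hz band) so that the rest BVP power is
    A_p^2/2 by construction. Beat intervals carry the LF and HF modulation
    (HF depth divided by the condition's LF/HF shift). All components and
    the true beat times are stored; everything is seeded.
    """
    if spec.fs < 2.5 * profile.hr_bpm / 60.0:
        raise ValueError("frame rate aliases the cardiac pulse")
    rng = np.random.default_rng(profile.seed)
    t = np.arange(int(round(spec.duration_s * spec.fs))) / spec.fs

    beats = _beat_times(profile, effect, spec.duration_s, rng)
    raw = _pulse_template_trace(t, beats)
    raw = raw - raw.mean()
    p_band = _band_power_of(raw, spec.fs, BVP_BAND)
    unit_pulse = raw / np.sqrt(max(p_band, 1e-30) / 0.5)
    pulse = np.sqrt(effect.pulse_power_scale) * profile.pulse_amplitude * unit_pulse

    f_v = profile.vaso_freq_cpm / 60.0
    phi = rng.uniform(0, 2 * np.pi)
    vaso = (
        np.sqrt(effect.vaso_power_scale)
        * profile.vaso_amplitude
        * np.sin(2 * np.pi * f_v * t + phi)
    )

    noise = profile.noise_sigma * rng.standard_normal(t.size)
    ctb = profile.baseline_ctb + pulse + vaso + noise

    # all temporal variation is carried by the oxygenated fraction
    c_hbr = np.full_like(t, 0.4 * profile.baseline_ctb)
    c_hbo = ctb - c_hbr
    series = ConcentrationSeries(
        t, np.full_like(t, profile.c_m), c_hbo, c_hbr, spec.fs
    )
    # true systolic peak instants: the template maximum within each beat
    peak_times = beats[:-1] + 0.30 * np.diff(beats)
    peak_times = peak_times[peak_times < spec.duration_s]
    return SyntheticRecording(
        series=series,
        true_beat_times=peak_times,
        pulse_component=pulse,
        vaso_component=vaso,
        profile=profile,
        effect=effect,
        spec=spec,
    )


def fit_forward_color_model(
    reference_set: list[tuple[ChromophoreSet, TristimulusValue]],
) -> ForwardColorModel:
    """Least-squares affine XYZ ~ [1, Cm, CHbO, CHbR] over a reference set.

    The inverse-direction companion of the N2 concentration regression,
    fitted on the same simulated reference pairs.
    """
    if len(reference_set) < 4:
        raise ValueError("at least 4 reference samples are required")
    design = np.array(
        [[1.0, cs.c_m, cs.c_hbo, cs.c_hbr] for cs, _ in reference_set]
    )
    target = np.array([xyz.as_array() for _, xyz in reference_set])
    coeff, _, _, _ = np.linalg.lstsq(design, target, rcond=None)
    return ForwardColorModel(coeff.T)


def nominal_forward_model() -> ForwardColorModel:
    """A fixed synthetic concentration->XYZ affine map for camera-chain tests.

    A plausible stand-in (not fitted to any simulation): concentrations
    darken the skin color with chromophore-specific weights, keeping XYZ
    well inside the positive octant over physiologic ranges.
    """
    return ForwardColorModel(
        np.array(
            [
                [55.0, -2.0, -1.5, -1.0],
                [60.0, -2.2, -2.0, -1.4],
                [45.0, -3.0, -0.8, -0.6],
            ]
        )
    )


def render_video(
    recording: SyntheticRecording,
    camera_matrix: np.ndarray = DEFAULT_CAMERA_MATRIX,
    forward: ForwardColorModel | None = None,
    pixel_noise_sigma: float = 0.0,
    seed: int = 0,
    melanin_split: float | None = None,
) -> FrameSequence:
    """Render a recording as spatially uniform skin video plus sensor noise.

    Per frame, XYZ is the forward affine image of the ground-truth
    concentrations and RGB = camera_matrix @ XYZ (so the fitted N1 is the
    camera inverse). With ``melanin_split`` the left half of the frame
    carries that multiple of the subject's melanin (a two-region pattern for
    concentration-map tests). At zero pixel noise the ROI mean inverts
    exactly back to the ground-truth XYZ.
    """
    fwd = forward or nominal_forward_model()
    s = recording.series
    h, w = recording.spec.roi_size
    cam = np.asarray(camera_matrix, dtype=float)
    rng = np.random.default_rng(seed)
    xyz = fwd.xyz(s.c_m, s.c_hbo, s.c_hbr)  # (T, 3)
    if np.any(xyz <= 0):
        raise ValueError("concentrations fall outside the forward model's domain")
    rgb = xyz @ cam.T
    frames = np.broadcast_to(rgb[:, None, None, :], (len(s.time), h, w, 3)).copy()
    if melanin_split is not None:
        xyz2 = fwd.xyz(s.c_m * melanin_split, s.c_hbo, s.c_hbr)
        if np.any(xyz2 <= 0):
            raise ValueError("melanin pattern falls outside the forward model's domain")
        frames[:, :, : w // 2, :] = (xyz2 @ cam.T)[:, None, None, :]
    if pixel_noise_sigma > 0:
        frames = frames + rng.normal(0.0, pixel_noise_sigma, size=frames.shape)
    return FrameSequence(frames, s.fs)


# Nominal chart chromaticities (x, y, Y) of the classic 24-patch chart.
_CHART_PATCHES = [
    ("dark skin", 0.400, 0.350, 10.1),
    ("light skin", 0.377, 0.345, 35.8),
    ("blue sky", 0.247, 0.251, 19.3),
    ("foliage", 0.337, 0.422, 13.3),
    ("blue flower", 0.265, 0.240, 24.3),
    ("bluish green", 0.261, 0.343, 43.1),
    ("orange", 0.506, 0.407, 30.1),
    ("purplish blue", 0.211, 0.175, 12.0),
    ("moderate red", 0.453, 0.306, 19.8),
    ("purple", 0.285, 0.202, 6.6),
    ("yellow green", 0.380, 0.489, 44.3),
    ("orange yellow", 0.473, 0.438, 43.1),
    ("blue", 0.187, 0.129, 6.1),
    ("green", 0.305, 0.478, 23.4),
    ("red", 0.539, 0.313, 12.0),
    ("yellow", 0.448, 0.470, 59.1),
    ("magenta", 0.364, 0.233, 19.8),
    ("cyan", 0.196, 0.252, 19.8),
    ("white 9.5", 0.310, 0.316, 90.0),
    ("neutral 8", 0.310, 0.316, 59.1),
    ("neutral 6.5", 0.310, 0.316, 36.2),
    ("neutral 5", 0.310, 0.316, 19.8),
    ("neutral 3.5", 0.310, 0.316, 9.0),
    ("black 2", 0.310, 0.316, 3.1),
]


def colorchecker_fixture(
    camera_matrix: np.ndarray = DEFAULT_CAMERA_MATRIX,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> ColorCheckerObservation:
    """A 24-patch chart observation through a known camera.

    Reference XYZ comes from the chart's nominal chromaticities; camera
    RGB = camera_matrix @ XYZ plus optional Gaussian noise.
    """
    cam = np.asarray(camera_matrix, dtype=float)
    rng = np.random.default_rng(seed)
    labels, xyz = [], []
    for name, x, y, big_y in _CHART_PATCHES:
        labels.append(name)
        xyz.append([x / y * big_y, big_y, (1 - x - y) / y * big_y])
    xyz = np.array(xyz)
    rgb = xyz @ cam.T
    if noise_sigma > 0:
        rgb = np.maximum(rgb + rng.normal(0.0, noise_sigma, rgb.shape), 0.0)
    return ColorCheckerObservation(tuple(labels), rgb, xyz)


def _lognormal(rng: np.random.Generator, mean: float, sd: float, size=None):
    """Log-normal draws parameterized by arithmetic mean and SD."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=size)


def generate_cohort(
    experiment: str,
    n_subjects: int | None = None,
    seed: int = 0,
    mean_effect: tuple[float, float, float] = DEFAULT_TASK_EFFECT,
    effect_sd: tuple[float, float] = (0.29, 0.26),
) -> list[tuple[SyntheticRecording, SyntheticRecording]]:
    """Seeded rest/task recording pairs for one experiment template.

    Per-subject baselines, amplitudes and effect scales are drawn from
    log-normal population distributions; the task effect distribution has
    the given arithmetic mean and between-subject SD for the pulse and
    vasomotion power scales, producing cohort percent-change dispersion on
    the order of the stated SDs.
    """
    if experiment not in EXPERIMENT_TEMPLATES:
        raise ValueError(f"unknown experiment template {experiment!r}")
    tpl = EXPERIMENT_TEMPLATES[experiment]
    n = tpl["n_subjects"] if n_subjects is None else int(n_subjects)
    if n < 1:
        raise ValueError("cohort must have at least one subject")
    spec = RecordingSpec(duration_s=tpl["duration_s"], fs=tpl["fs"])
    rng = np.random.default_rng(seed)
    cohort = []
    for _ in range(n):
        profile_kwargs = dict(
            baseline_ctb=float(_lognormal(rng, 5.0, 1.0)),
            c_m=float(np.clip(_lognormal(rng, 4.0, 1.5), 1.0, 10.0)),
            pulse_amplitude=float(_lognormal(rng, 0.5, 0.15)),
            hr_bpm=float(np.clip(rng.normal(65.0, 8.0), 45.0, 110.0)),
            lf_depth=float(_lognormal(rng, 0.03, 0.01)),
            hf_depth=float(_lognormal(rng, 0.03, 0.01)),
            vaso_amplitude=float(_lognormal(rng, 1.0, 0.3)),
            vaso_freq_cpm=float(rng.uniform(1.5, 6.0)),
            noise_sigma=0.05,
        )
        effect = ConditionEffect(
            pulse_power_scale=float(_lognormal(rng, mean_effect[0], effect_sd[0])),
            vaso_power_scale=float(_lognormal(rng, mean_effect[1], effect_sd[1])),
            lf_hf_shift=float(_lognormal(rng, mean_effect[2], 0.3)),
        )
        seed_rest, seed_task = rng.integers(0, 2**31, size=2)
        rest = synthesize_concentration_series(
            SubjectProfile(**profile_kwargs, seed=int(seed_rest)),
            ConditionEffect(),
            spec,
        )
        task = synthesize_concentration_series(
            SubjectProfile(**profile_kwargs, seed=int(seed_task)), effect, spec
        )
        cohort.append((rest, task))
    return cohort
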