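"""Synthetic per-subject trial data for both recognition channels.

Real recordings for this task pair a single-electrode EEG trace with a
stream of webcam face images per movie-watching trial. This module emulates
that structure so the whole pipeline — feature extraction, per-subject
classifiers, both fusion rules, and the subject-level statistics — can be
trained and evaluated end to end without any acquisition hardware:

* **EEG**: each 1-s window is a sum of eight band-limited sinusoids (one
  per analysis band, at the band center) whose amplitudes follow a
  state-specific template, plus 1/f background noise. The emotion state
  sets which band carries the amplitude bump; the intensity level scales
  the bump (weak 0.5x, moderate 1.0x, strong 1.5x the moderate contrast),
  so state is encoded in *where* the spectrum deviates from the grand-mean
  profile and intensity in *how far*.
* **Faces**: a parametric 48 x 48 grayscale face (elliptical head, two
  eyes, a mouth whose curvature/openness encodes the state: upturned =
  happiness, flat = neutral, downturned = sadness, open oval = fear) plus
  Gaussian pixel noise.

Channel errors are injected as *per-trial* label corruption: a corrupted
trial draws an observed state for that channel and renders it into a
fraction of the trial's images or EEG windows (default 0.7), so the
corrupted channel's trial-level evidence tilts wrong while keeping a graded
score for the true state — the regime in which score-level fusion of two
channels that err on different trials pays off. Face corruption defaults to
the happiness/neutral confusion typical of mild expressions; EEG corruption
scatters over all states but leaves intensity almost clean, making the two
channels complementary.

All randomness derives from one integer seed through ``SeedSequence``
entropy tuples ``(seed, subject, trial, stream)``, so any trial can be
regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .eeg_features import BAND_NAMES, EEGSegment, band_edges
from .labels import (
    EmotionState,
    IntensityLevel,
    STATE_ORDER,
    INTENSITY_ORDER,
)

__all__ = [
    "SubjectConfig",
    "Trial",
    "SubjectDataset",
    "band_amplitude_template",
    "GRAND_TEMPLATE",
    "synthesize_eeg",
    "render_face",
    "place_on_canvas",
    "generate_subject",
    "complementary_config",
]

# ---------------------------------------------------------------------------
# EEG templates
# ---------------------------------------------------------------------------

#: Which analysis band carries each state's amplitude bump. Happiness sits
#: in lower alpha, neutral in theta, sadness in upper beta, fear in upper
#: gamma (arousal increasing with band frequency).
STATE_SIGNATURE_BAND: dict[EmotionState, str] = {
    EmotionState.HAPPINESS: "alpha1",
    EmotionState.NEUTRAL: "theta",
    EmotionState.SADNESS: "beta2",
    EmotionState.FEAR: "gamma2",
}

_BASELINE_AMP = 0.2  # oscillator amplitude in every band, arbitrary units
_SIGNATURE_AMP = 1.2  # added to the signature band at moderate intensity

#: Intensity scales the deviation from the grand-mean template.
INTENSITY_CONTRAST: dict[IntensityLevel, float] = {
    IntensityLevel.WEAK: 0.5,
    IntensityLevel.MODERATE: 1.0,
    IntensityLevel.STRONG: 1.5,
}

#: The state-independent amplitude profile (8,).
GRAND_TEMPLATE = np.full(len(BAND_NAMES), _BASELINE_AMP)


def band_amplitude_template(state: EmotionState, intensity: IntensityLevel) -> np.ndarray:
    """Per-band oscillator amplitudes for one (state, intensity) condition."""
    amps = GRAND_TEMPLATE.copy()
    i = BAND_NAMES.index(STATE_SIGNATURE_BAND[EmotionState(state)])
    amps[i] += INTENSITY_CONTRAST[IntensityLevel(intensity)] * _SIGNATURE_AMP
    return amps


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-SD 1/f-amplitude noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0  # avoid the DC singularity
    spec /= np.sqrt(f)
    spec[0] = 0.0
    out = np.fft.irfft(spec, n)
    sd = out.std()
    return out / sd if sd > 0 else out


def synthesize_eeg(
    state: EmotionState,
    intensity: IntensityLevel,
    duration_s: float,
    fs: int = 512,
    noise_sd: float = 0.3,
    seed: "int | np.random.Generator" = 0,
) -> EEGSegment:
    """Generate one EEG segment for a (state, intensity) condition.

    The segment is the sum of eight band-center sinusoids with amplitudes
    from :func:`band_amplitude_template` (random phases) plus 1/f noise of
    the given SD. ``seed`` may be an integer or an existing Generator.
    """
    if duration_s < 1:
        raise ValueError("duration must be at least 1 s")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    amps = band_amplitude_template(state, intensity)
    phases = rng.uniform(0, 2 * np.pi, size=len(BAND_NAMES))
    x = np.zeros(n)
    for amp, band, ph in zip(amps, band_edges(), phases):
        fc = (band.lo + band.hi) / 2.0
        x += amp * np.sin(2 * np.pi * fc * t + ph)
    if noise_sd > 0:
        x += noise_sd * _pink_noise(n, rng)
    return EEGSegment(samples=x, fs=fs)


# ---------------------------------------------------------------------------
# Face renderer
# ---------------------------------------------------------------------------

_SIZE = 48


def render_face(
    state: EmotionState,
    noise_sd: float = 0.0,
    seed: "int | np.random.Generator" = 0,
) -> np.ndarray:
    """Parametric 48 x 48 grayscale face for one emotion state.

    Bright elliptical head on a dark canvas, two dark eyes, and a mouth
    whose shape encodes the state: corners raised (happiness), flat line
    (neutral), corners lowered (sadness), open oval (fear). Gaussian pixel
    noise of SD ``noise_sd`` is added and the image clipped to [0, 1].
    Deterministic given (state, seed).
    """
    state = EmotionState(state)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    yy, xx = np.mgrid[0:_SIZE, 0:_SIZE].astype(float)
    img = np.full((_SIZE, _SIZE), 0.05)

    head = ((yy - 24) / 20.0) ** 2 + ((xx - 24) / 16.0) ** 2 <= 1.0
    img[head] = 0.85
    for cx in (16.0, 32.0):
        eye = ((yy - 17) / 2.5) ** 2 + ((xx - cx) / 3.5) ** 2 <= 1.0
        img[eye] = 0.25

    if state is EmotionState.FEAR:
        mouth = ((yy - 34) / 4.0) ** 2 + ((xx - 24) / 3.0) ** 2 <= 1.0
    else:
        curvature = {
            EmotionState.HAPPINESS: -3.0,  # corners higher than center
            EmotionState.NEUTRAL: 0.0,
            EmotionState.SADNESS: 3.0,  # corners lower than center
        }[state]
        curve = 34.0 + curvature * (1.0 - ((xx - 24.0) / 8.0) ** 2)
        mouth = (np.abs(yy - curve) <= 1.2) & (np.abs(xx - 24.0) <= 8.0)
    img[mouth] = 0.15

    if noise_sd > 0:
        img = img + noise_sd * rng.standard_normal(img.shape)
    return np.clip(img, 0.0, 1.0)


def place_on_canvas(
    face: np.ndarray, canvas_shape: tuple[int, int], top_left: tuple[int, int],
    background: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Embed a face patch in a larger frame; returns (canvas, mask).

    ``mask`` marks the face-content pixels of the placed patch (those above
    the patch's own background level) — useful for checking that a
    detector's crop covers the face.
    """
    canvas = np.full(canvas_shape, background, dtype=float)
    mask = np.zeros(canvas_shape, dtype=bool)
    r, c = top_left
    h, w = face.shape
    if r < 0 or c < 0 or r + h > canvas_shape[0] or c + w > canvas_shape[1]:
        raise ValueError("face does not fit on the canvas at that offset")
    canvas[r : r + h, c : c + w] = face
    content = face > face.min() if face.max() > face.min() else np.ones_like(face, bool)
    mask[r : r + h, c : c + w] = content
    return canvas, mask


# ---------------------------------------------------------------------------
# Subject generator
# ---------------------------------------------------------------------------

#: Default face-channel confusion: probability that a trial's facial
#: expression reads as another state. Mild expressions blur the
#: happiness/neutral boundary; sadness and fear faces stay distinctive.
DEFAULT_FACE_CONFUSION: dict[EmotionState, dict[EmotionState, float]] = {
    EmotionState.HAPPINESS: {EmotionState.NEUTRAL: 0.5},
    EmotionState.NEUTRAL: {EmotionState.HAPPINESS: 0.5},
    EmotionState.SADNESS: {},
    EmotionState.FEAR: {},
}


@dataclass
class SubjectConfig:
    """Generation parameters for one synthetic subject.

    Defaults mirror the acquisition protocol the generator emulates: 40
    trials per subject, 100 face images and 200 one-second EEG windows per
    trial. ``intensity_dist`` is either ``None`` (uniform over the three
    levels) or a mapping state -> probabilities over (weak, moderate,
    strong). ``face_confusion`` gives per-trial probabilities that the
    facial channel expresses another state; ``eeg_state_confusion`` is the
    per-trial probability that the EEG spectrum follows a uniformly chosen
    other state; ``intensity_confusion`` likewise for the intensity driving
    the EEG. A corrupted channel renders the observed label into a
    ``corruption_mixture`` fraction of its windows/images.
    """

    subject_id: int = 0
    n_trials: int = 40
    images_per_trial: int = 100
    eeg_windows_per_trial: int = 200
    fs: int = 512
    face_noise_sd: float = 0.05
    eeg_noise_sd: float = 0.3
    face_confusion: Mapping[EmotionState, Mapping[EmotionState, float]] = field(
        default_factory=lambda: {s: dict(d) for s, d in DEFAULT_FACE_CONFUSION.items()}
    )
    eeg_state_confusion: float = 0.45
    intensity_confusion: float = 0.1
    corruption_mixture: float = 0.7
    intensity_dist: "Mapping[EmotionState, Sequence[float]] | None" = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1 or self.images_per_trial < 1 or self.eeg_windows_per_trial < 1:
            raise ValueError("trial/image/window counts must be positive")
        if self.face_noise_sd < 0 or self.eeg_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if not 0.0 <= self.corruption_mixture <= 1.0:
            raise ValueError("corruption_mixture must be in [0, 1]")
        for p in (self.eeg_state_confusion, self.intensity_confusion):
            if not 0.0 <= p <= 1.0:
                raise ValueError("confusion probabilities must be in [0, 1]")
        for s, d in self.face_confusion.items():
            if sum(d.values()) > 1.0 + 1e-12:
                raise ValueError(f"face confusion weights for {s} exceed 1")


@dataclass
class Trial:
    state: EmotionState
    intensity: IntensityLevel
    eeg: EEGSegment
    faces: list[np.ndarray]
    #: what each channel actually expressed (== state unless corrupted)
    face_observed_state: EmotionState = None  # type: ignore[assignment]
    eeg_observed_state: EmotionState = None  # type: ignore[assignment]
    eeg_observed_intensity: IntensityLevel = None  # type: ignore[assignment]


@dataclass
class SubjectDataset:
    config: SubjectConfig
    trials: list[Trial]


def _trial_rng(cfg: SubjectConfig, trial: int, stream: int) -> np.random.Generator:
    # trial index is offset so the trial-order draw can use slot 0
    return np.random.default_rng(
        np.random.SeedSequence((cfg.seed, cfg.subject_id, trial + 1, stream))
    )


_STREAM_LABELS, _STREAM_EEG, _STREAM_FACE = 0, 1, 2


def _draw_confused(
    rng: np.random.Generator, state: EmotionState,
    weights: Mapping[EmotionState, float],
) -> EmotionState:
    """Draw an observed state: ``state`` or a confusion partner."""
    others = list(weights.items())
    u = rng.random()
    acc = 0.0
    for other, p in others:
        acc += p
        if u < acc:
            return other
    return state


def generate_subject(config: SubjectConfig) -> SubjectDataset:
    """Generate a full per-subject dataset.

    States are balanced across trials (each state ``n_trials // 4`` times,
    remainder filled in canonical order), shuffled; intensity is drawn per
    trial from ``intensity_dist``. Channel corruption is drawn per trial and
    per channel independently.
    """
    cfg = config
    reps = cfg.n_trials // len(STATE_ORDER)
    states = list(STATE_ORDER) * reps + list(STATE_ORDER[: cfg.n_trials % len(STATE_ORDER)])
    order_rng = _trial_rng(cfg, trial=-1, stream=_STREAM_LABELS)
    states = [states[i] for i in order_rng.permutation(len(states))]

    trials: list[Trial] = []
    for k, state in enumerate(states):
        lab = _trial_rng(cfg, k, _STREAM_LABELS)
        if cfg.intensity_dist is None:
            intensity = INTENSITY_ORDER[lab.integers(len(INTENSITY_ORDER))]
        else:
            probs = np.asarray(cfg.intensity_dist[state], dtype=float)
            probs = probs / probs.sum()
            intensity = INTENSITY_ORDER[lab.choice(len(INTENSITY_ORDER), p=probs)]

        face_obs = _draw_confused(lab, state, cfg.face_confusion.get(state, {}))
        if lab.random() < cfg.eeg_state_confusion:
            eeg_obs = [s for s in STATE_ORDER if s != state][lab.integers(3)]
        else:
            eeg_obs = state
        if lab.random() < cfg.intensity_confusion:
            eeg_obs_int = [v for v in INTENSITY_ORDER if v != intensity][lab.integers(2)]
        else:
            eeg_obs_int = intensity

        # EEG: windows generated individually so a corrupted trial can mix
        # windows of the observed and true state; concatenation is seamless
        # because the analysis windows are the same non-overlapping 1-s cuts.
        erng = _trial_rng(cfg, k, _STREAM_EEG)
        pieces = []
        for _ in range(cfg.eeg_windows_per_trial):
            ws = eeg_obs if (eeg_obs != state and erng.random() < cfg.corruption_mixture) else state
            seg = synthesize_eeg(
                ws, eeg_obs_int, duration_s=1.0, fs=cfg.fs,
                noise_sd=cfg.eeg_noise_sd, seed=erng,
            )
            pieces.append(seg.samples)
        eeg = EEGSegment(samples=np.concatenate(pieces), fs=cfg.fs)

        frng = _trial_rng(cfg, k, _STREAM_FACE)
        faces = []
        for _ in range(cfg.images_per_trial):
            fs_state = (
                face_obs
                if (face_obs != state and frng.random() < cfg.corruption_mixture)
                else state
            )
            faces.append(render_face(fs_state, noise_sd=cfg.face_noise_sd, seed=frng))

        trials.append(
            Trial(
                state=state, intensity=intensity, eeg=eeg, faces=faces,
                face_observed_state=face_obs, eeg_observed_state=eeg_obs,
                eeg_observed_intensity=eeg_obs_int,
            )
        )
    return SubjectDataset(config=cfg, trials=trials)


#: Intensity distribution aligned with the production-rule semantics: a
#: weakly felt happiness is rare (it would read as neutral), a strongly
#: felt neutral is rare, and so on — mass concentrates away from the four
#: rule-remapped (state, intensity) pairs.
ALIGNED_INTENSITY_DIST: dict[EmotionState, tuple[float, float, float]] = {
    EmotionState.HAPPINESS: (0.05, 0.25, 0.70),
    EmotionState.NEUTRAL: (0.70, 0.25, 0.05),
    EmotionState.SADNESS: (0.60, 0.35, 0.05),
    EmotionState.FEAR: (0.05, 0.35, 0.60),
}


def complementary_config(
    subject_id: int,
    seed: int = 0,
    n_trials: int = 80,
    images_per_trial: int = 6,
    eeg_windows_per_trial: int = 10,
    fs: int = 128,
) -> SubjectConfig:
    """The shipped experiment conditions: complementary channel noise.

    Face errors concentrate on the happiness/neutral confusion, EEG errors
    scatter over states but barely touch intensity, and intensity follows
    the rule-aligned distribution — the regime in which both fusion rules
    outperform either single channel. Counts default to a desk-scale
    version of the acquisition protocol (80 trials so an evaluation split
    yields 40 train / 40 test; 6 images and 10 EEG windows per trial at
    128 Hz).
    """
    return SubjectConfig(
        subject_id=subject_id,
        n_trials=n_trials,
        images_per_trial=images_per_trial,
        eeg_windows_per_trial=eeg_windows_per_trial,
        fs=fs,
        intensity_dist=dict(ALIGNED_INTENSITY_DIST),
        seed=seed,
    )
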