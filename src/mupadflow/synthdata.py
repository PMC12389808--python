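"""Synthetic capillary-flow experiments.

The study data (videos of tannic-acid/mucin mixtures wicking up paper
strips) are not publicly deposited, so this module generates seeded
stand-ins at every level of the pipeline:

* per-class draws of the square-root-of-time flow coefficients,
* noisy wetting-front height series (one value per retained frame),
* rendered grayscale frame stacks, so the video-analysis stage can be
  exercised end to end.

Heights follow the shifted Lucas-Washburn law ``l(t) = a*sqrt(t + 1) + b``
with ``t`` in seconds from the first retained frame; the ``+1`` absorbs the
discarded 1-s reference window at the start of each recording.  Higher
tannic-acid concentration produces more hydrophobic tannin-mucin
aggregates at the wetting front, lowering the local surface tension and
hence the coefficient ``a`` -- the class means therefore decrease with
concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .frontextract import HeightSeries

__all__ = [
    "ExperimentDesign",
    "ClassCoefficients",
    "ClassCoefficientModel",
    "RenderGeometry",
    "SyntheticExperiment",
    "default_design",
    "default_coefficient_model",
    "sample_class_coefficients",
    "generate_profile",
    "render_frames",
    "generate_experiment",
]


class ConfigurationError(ValueError):
    """Invalid design, model or extraction configuration."""


class GeometryError(ValueError):
    """Rendered front would leave the frame."""


@dataclass(frozen=True)
class ExperimentDesign:
    """Acquisition design: sessions x concentration classes x replicates.

    Defaults reproduce the study's design: 14 sessions of 9 cuvettes
    (3 concentrations x 3 replicates), recorded for 61 s at 30 fps and
    1920x1080, with the first 30 post-contact frames reserved as the
    height reference.
    """

    n_sessions: int = 14
    classes: tuple[float, ...] = (0.1, 0.5, 1.0)
    replicates_per_class: int = 3
    fps: float = 30.0
    duration_s: float = 61.0
    reference_frames: int = 30
    frame_height_px: int = 1080
    frame_width_px: int = 1920

    def __post_init__(self) -> None:
        if self.n_sessions < 1 or self.replicates_per_class < 1:
            raise ConfigurationError("sessions and replicates must be positive")
        if not self.classes:
            raise ConfigurationError("at least one concentration class required")
        if self.reference_frames < 1:
            raise ConfigurationError("reference_frames must be >= 1")
        if self.duration_s * self.fps <= self.reference_frames:
            raise ConfigurationError(
                "recording must be longer than the reference window"
            )

    @property
    def n_profiles(self) -> int:
        return self.n_sessions * len(self.classes) * self.replicates_per_class

    @property
    def retained_frames(self) -> int:
        """Frames kept after discarding the reference window (1800 by default)."""
        return int(round(self.duration_s * self.fps)) - self.reference_frames


@dataclass(frozen=True)
class ClassCoefficients:
    """Coefficient distribution for one concentration class.

    ``a`` is the square-root-of-time slope in px/sqrt(s); ``b`` the
    vertical offset in px.  Draws of ``a`` are truncated to stay positive.
    """

    mean_a: float
    sd_a: float = 0.0
    mean_b: float = 0.0
    sd_b: float = 0.0

    def __post_init__(self) -> None:
        if self.mean_a <= 0:
            raise ConfigurationError("mean_a must be positive")
        if self.sd_a < 0 or self.sd_b < 0:
            raise ConfigurationError("standard deviations must be non-negative")


@dataclass(frozen=True)
class ClassCoefficientModel:
    """Per-class coefficient distributions plus frame-level measurement noise.

    ``noise_sd_px`` is the s.d. of additive i.i.d. Gaussian noise on each
    frame's height; together with integer-pixel quantization it reproduces
    the non-monotone raw series that the carry-forward rule presupposes.
    """

    per_class: Mapping[float, ClassCoefficients]
    noise_sd_px: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd_px < 0:
            raise ConfigurationError("noise_sd_px must be non-negative")
        labels = sorted(self.per_class)
        means = [self.per_class[c].mean_a for c in labels]
        if any(m2 >= m1 for m1, m2 in zip(means, means[1:])):
            raise ConfigurationError(
                "mean_a must decrease with concentration (higher tannic acid "
                "slows capillary flow)"
            )

    def for_class(self, class_label: float) -> ClassCoefficients:
        try:
            return self.per_class[class_label]
        except KeyError:
            raise ConfigurationError(
                f"unknown concentration class {class_label!r}; "
                f"known: {sorted(self.per_class)}"
            ) from None


def default_design() -> ExperimentDesign:
    """The study's acquisition design (126 profiles, 1800 retained frames)."""
    return ExperimentDesign()


def default_coefficient_model(noise_sd_px: float = 2.0) -> ClassCoefficientModel:
    """Default synthetic coefficient model.

    Class means (60/45/30 px/sqrt(s) for 0.1/0.5/1.0 g/L) decrease with
    concentration and sit >= 3 within-class s.d. apart; magnitudes follow
    from the strip geometry (a ~29 mm run imaged at ~17 px/mm).  These are
    synthetic defaults, not measured values.
    """
    return ClassCoefficientModel(
        per_class={
            0.1: ClassCoefficients(mean_a=60.0, sd_a=3.0, mean_b=0.0, sd_b=2.0),
            0.5: ClassCoefficients(mean_a=45.0, sd_a=3.0, mean_b=0.0, sd_b=2.0),
            1.0: ClassCoefficients(mean_a=30.0, sd_a=3.0, mean_b=0.0, sd_b=2.0),
        },
        noise_sd_px=noise_sd_px,
    )


# ---------------------------------------------------------------------------
# coefficient sampling


def sample_class_coefficients(
    model: ClassCoefficientModel,
    class_label: float,
    n: int,
    seed: int | np.random.Generator,
) -> list[tuple[float, float]]:
    """Draw ``n`` (a, b) pairs for one concentration class.

    ``a`` is drawn from N(mean_a, sd_a) truncated to (0, inf) by rejection;
    ``b`` from N(mean_b, sd_b).  Deterministic under a fixed seed.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    params = model.for_class(class_label)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    pairs: list[tuple[float, float]] = []
    for _ in range(n):
        a = params.mean_a + params.sd_a * rng.standard_normal()
        while a <= 0:
            a = params.mean_a + params.sd_a * rng.standard_normal()
        b = params.mean_b + params.sd_b * rng.standard_normal()
        pairs.append((float(a), float(b)))
    return pairs


# ---------------------------------------------------------------------------
# profile generation


def generate_profile(
    a: float,
    b: float,
    design: ExperimentDesign,
    noise_sd_px: float = 0.0,
    seed: int | np.random.Generator | None = None,
    quantize: bool | None = None,
) -> HeightSeries:
    """Generate one wetting-front height series from ``l(t) = a*sqrt(t+1) + b``.

    One value per retained frame (``design.retained_frames``), with t = 0 at
    the first retained frame.  Gaussian measurement noise of s.d.
    ``noise_sd_px`` is added per frame, heights are clipped at zero and, by
    default, rounded to integer pixels whenever noise is present (``quantize``
    overrides).  The noiseless series is exactly non-decreasing; the noisy
    series need not be -- monotone enforcement is a downstream step.
    """
    if a <= 0:
        raise ValueError(f"coefficient a must be positive, got {a}")
    if noise_sd_px < 0:
        raise ValueError("noise_sd_px must be non-negative")
    n = design.retained_frames
    t = np.arange(n) / design.fps
    heights = a * np.sqrt(t + 1.0) + b
    if noise_sd_px > 0:
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        heights = heights + noise_sd_px * rng.standard_normal(n)
    heights = np.clip(heights, 0.0, None)
    if quantize is None:
        quantize = noise_sd_px > 0
    if quantize:
        heights = np.round(heights)
    return HeightSeries(heights=heights, fps=design.fps)


# ---------------------------------------------------------------------------
# frame rendering


@dataclass(frozen=True)
class RenderGeometry:
    """Placement of the paper strip inside the rendered frame.

    Row 0 is the top of the image; the front at height ``h`` occupies rows
    ``baseline_row - round(h) .. baseline_row`` within the strip's column
    band.  ``pre_contact_padding`` dry frames are prepended so contact
    detection is exercised.
    """

    frame_height_px: int = 200
    frame_width_px: int = 80
    strip_col_start: int = 25
    strip_col_end: int = 55
    baseline_row: int = 180
    wet_intensity: int = 80
    dry_intensity: int = 200
    texture_sd: float = 0.0
    pre_contact_padding: int = 15

    def __post_init__(self) -> None:
        if not (0 <= self.strip_col_start < self.strip_col_end <= self.frame_width_px):
            raise ConfigurationError("strip column band outside frame")
        if not (0 <= self.baseline_row < self.frame_height_px):
            raise ConfigurationError("baseline_row outside frame")
        if self.pre_contact_padding < 0:
            raise ConfigurationError("pre_contact_padding must be >= 0")


def render_frames(
    series: HeightSeries,
    geometry: RenderGeometry,
    reference_frames: int = 30,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Render a height series into a grayscale uint8 frame stack.

    Stack layout: ``pre_contact_padding`` fully dry frames, then
    ``reference_frames`` frames with the front resting at the baseline row
    (the contact/reference second), then one frame per series value with the
    front ``round(h)`` rows above the baseline.  Optional Gaussian texture
    noise of s.d. ``texture_sd`` is added to every pixel.
    """
    heights = np.asarray(series.heights, dtype=float)
    max_h = float(heights.max(initial=0.0))
    if geometry.baseline_row - round(max_h) < 0:
        raise GeometryError(
            f"front height {max_h:.1f}px exceeds baseline_row "
            f"{geometry.baseline_row} (frame top)"
        )
    n_frames = geometry.pre_contact_padding + reference_frames + len(heights)
    shape = (n_frames, geometry.frame_height_px, geometry.frame_width_px)
    frames = np.full(shape, float(geometry.dry_intensity))
    cols = slice(geometry.strip_col_start, geometry.strip_col_end)
    wet_from_height = np.concatenate(
        [np.zeros(reference_frames), np.round(heights)]
    ).astype(int)
    for k, h in enumerate(wet_from_height, start=geometry.pre_contact_padding):
        top = geometry.baseline_row - h
        frames[k, top : geometry.baseline_row + 1, cols] = geometry.wet_intensity
    if geometry.texture_sd > 0:
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        frames += geometry.texture_sd * rng.standard_normal(shape)
    return np.clip(np.round(frames), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# full experiment


@dataclass
class SyntheticExperiment:
    """Labeled synthetic profiles with full provenance.

    Arrays are aligned per profile; true coefficients are retained so that
    parameter-recovery tests can compare fitted against programmed values.
    """

    design: ExperimentDesign
    profiles: list[HeightSeries]
    labels: np.ndarray  # concentration in g/L
    sessions: np.ndarray  # session id, 0-based
    replicates: np.ndarray  # replicate id within (session, class)
    true_a: np.ndarray
    true_b: np.ndarray
    seed: int | None = None
    frames: list[np.ndarray] | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.profiles)


def generate_experiment(
    design: ExperimentDesign,
    coeff_model: ClassCoefficientModel,
    seed: int,
    render: bool = False,
    geometry: RenderGeometry | None = None,
) -> SyntheticExperiment:
    """Generate a complete seeded experiment under ``design``.

    Produces ``n_sessions * n_classes * replicates_per_class`` labeled
    profiles (126 under the default design).  Per-profile random streams are
    spawned from a single root seed, so identical inputs give bitwise
    identical output.  With ``render=True`` each profile also gets a
    rendered frame stack (use a small ``geometry`` -- full-resolution stacks
    are enormous).
    """
    root = np.random.SeedSequence(seed)
    coeff_seq, noise_seq = root.spawn(2)
    coeff_rng = np.random.default_rng(coeff_seq)
    noise_streams = noise_seq.spawn(design.n_profiles)

    profiles: list[HeightSeries] = []
    frame_stacks: list[np.ndarray] | None = [] if render else None
    labels, sessions, replicates, true_a, true_b = [], [], [], [], []
    i = 0
    for session in range(design.n_sessions):
        for class_label in design.classes:
            pairs = sample_class_coefficients(
                coeff_model, class_label, design.replicates_per_class, coeff_rng
            )
            for rep, (a, b) in enumerate(pairs):
                rng = np.random.default_rng(noise_streams[i])
                profile = generate_profile(
                    a, b, design, noise_sd_px=coeff_model.noise_sd_px, seed=rng
                )
                profiles.append(profile)
                if render:
                    geo = geometry if geometry is not None else RenderGeometry()
                    assert frame_stacks is not None
                    frame_stacks.append(
                        render_frames(
                            profile, geo, design.reference_frames, seed=rng
                        )
                    )
                labels.append(class_label)
                sessions.append(session)
                replicates.append(rep)
                true_a.append(a)
                true_b.append(b)
                i += 1
    return SyntheticExperiment(
        design=design,
        profiles=profiles,
        labels=np.array(labels),
        sessions=np.array(sessions),
        replicates=np.array(replicates),
        true_a=np.array(true_a),
        true_b=np.array(true_b),
        seed=seed,
        frames=frame_stacks,
    )
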