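"""Wetting-front extraction from video frame stacks.

Turns a stack of grayscale frames of a paper strip into a monotone
fluid-height series: detect the contact frame, find the topmost wetted
pixel row per frame inside the strip's region of interest, convert rows
to heights relative to a reference computed over the first second after
contact, and enforce the physical constraint that the wetted region never
shrinks (carry the previous value forward whenever a frame reads lower).

Wet/dry segmentation is absolute grayscale difference against the
pre-contact baseline frame with a fixed threshold -- the simplest operator
that is invariant to global intensity shifts smaller than the threshold.
Image row 0 is at the top; height is positive upward (reference_row - row).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "HeightSeries",
    "ExtractionConfig",
    "ContactNotFoundError",
    "detect_contact",
    "extract_front_rows",
    "rows_to_heights",
    "enforce_monotone",
    "extract_height_series",
    "read_frames",
]


class ContactNotFoundError(RuntimeError):
    """No frame showed enough wetted pixels to qualify as fluid contact."""


@dataclass
class HeightSeries:
    """Per-frame fluid-front height in pixels.

    ``heights[i]`` is the front height at ``t = i / fps`` seconds after the
    first retained frame.  ``contact_frame`` indexes the source video;
    ``reference_row`` is the pixel row taken as zero height.
    """

    heights: np.ndarray
    fps: float
    contact_frame: int | None = None
    reference_row: float | None = None

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 1:
            raise ValueError("heights must be one-dimensional")
        if np.any(self.heights < 0):
            raise ValueError("heights must be non-negative")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    def __len__(self) -> int:
        return len(self.heights)

    @property
    def times(self) -> np.ndarray:
        """Seconds since the first retained frame."""
        return np.arange(len(self.heights)) / self.fps

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame_index": np.arange(len(self.heights)),
                "t_s": self.times,
                "height_px": self.heights,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        """Write heights as CSV plus a JSON metadata sidecar."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        meta = {
            "fps": self.fps,
            "contact_frame": self.contact_frame,
            "reference_row": self.reference_row,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


@dataclass(frozen=True)
class ExtractionConfig:
    """Front-extraction parameters.

    roi
        ``(col_start, col_end)`` column band of the strip, in pixels.
    diff_threshold
        Grayscale difference against the pre-contact baseline above which a
        pixel counts as wet.
    min_wet_pixels_per_row
        Wet pixels a row must contain to count as wetted.
    reference_frames
        Post-contact frames (default 30 = 1 s at 30 fps) whose rows form the
        zero-height reference; ``reference_statistic`` in
        {``mean``, ``median``, ``max-extent``} selects how they are combined
        (max-extent = the highest front reached, i.e. the smallest row).
    """

    roi: tuple[int, int]
    diff_threshold: float = 30.0
    min_wet_pixels_per_row: int = 3
    reference_frames: int = 30
    reference_statistic: str = "mean"

    def __post_init__(self) -> None:
        if self.roi[1] <= self.roi[0]:
            raise ValueError("empty ROI column band")
        if self.diff_threshold <= 0:
            raise ValueError("diff_threshold must be positive")
        if self.reference_frames < 1:
            raise ValueError("reference_frames must be >= 1")
        if self.reference_statistic not in ("mean", "median", "max-extent"):
            raise ValueError(
                f"unknown reference_statistic {self.reference_statistic!r}"
            )


def _wet_mask(frame: np.ndarray, baseline: np.ndarray, config: ExtractionConfig) -> np.ndarray:
    cols = slice(*config.roi)
    diff = np.abs(
        frame[:, cols].astype(float) - baseline[:, cols].astype(float)
    )
    return diff > config.diff_threshold


def detect_contact(frames: np.ndarray, config: ExtractionConfig) -> int:
    """Index of the first frame showing fluid contact.

    The first frame is the dry baseline; contact is the first frame whose
    wetted-pixel count inside the ROI exceeds ``min_wet_pixels_per_row``.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3 or len(frames) < 1:
        raise ValueError("expected a non-empty (n_frames, H, W) stack")
    baseline = frames[0]
    for k in range(len(frames)):
        if _wet_mask(frames[k], baseline, config).sum() > config.min_wet_pixels_per_row:
            return k
    raise ContactNotFoundError(
        "no contact detected: no frame exceeded the wet-pixel threshold"
    )


def extract_front_rows(
    frames: np.ndarray, config: ExtractionConfig, contact_frame: int
) -> np.ndarray:
    """Topmost wetted pixel row per frame, from ``contact_frame`` onward.

    A row is wetted when >= ``min_wet_pixels_per_row`` of its ROI pixels
    differ from the pre-contact baseline by more than ``diff_threshold``.
    Frames where the front transiently vanishes inherit the previous
    frame's row (the bottommost image row if it vanishes immediately), so
    detector dropouts never read as spurious zero heights.
    """
    frames = np.asarray(frames)
    if not 0 <= contact_frame < len(frames):
        raise ValueError(f"contact_frame {contact_frame} outside stack")
    baseline = frames[0]
    rows = np.empty(len(frames) - contact_frame, dtype=float)
    previous = float(frames.shape[1] - 1)
    for i, k in enumerate(range(contact_frame, len(frames))):
        wet_rows = np.nonzero(
            _wet_mask(frames[k], baseline, config).sum(axis=1)
            >= config.min_wet_pixels_per_row
        )[0]
        previous = float(wet_rows[0]) if len(wet_rows) else previous
        rows[i] = previous
    return rows


def rows_to_heights(rows: np.ndarray, config: ExtractionConfig, fps: float,
                    contact_frame: int | None = None) -> HeightSeries:
    """Convert front rows to heights relative to the reference window.

    The reference row is ``reference_statistic`` over the first
    ``reference_frames`` rows; each retained frame's height is
    ``max(0, reference_row - row)``, so the series has
    ``len(rows) - reference_frames`` values.
    """
    rows = np.asarray(rows, dtype=float)
    if len(rows) <= config.reference_frames:
        raise ValueError(
            f"need more than {config.reference_frames} rows, got {len(rows)}"
        )
    window = rows[: config.reference_frames]
    if config.reference_statistic == "mean":
        reference_row = float(np.mean(window))
    elif config.reference_statistic == "median":
        reference_row = float(np.median(window))
    else:  # max-extent: the highest point reached, i.e. the smallest row
        reference_row = float(np.min(window))
    heights = np.maximum(0.0, reference_row - rows[config.reference_frames :])
    return HeightSeries(
        heights=heights,
        fps=fps,
        contact_frame=contact_frame,
        reference_row=reference_row,
    )


def enforce_monotone(series: HeightSeries) -> HeightSeries:
    """Carry the previous value forward wherever a frame reads lower.

    The wetted region cannot shrink during capillary imbibition, so the
    output is the running maximum of the input: non-decreasing, idempotent,
    pointwise >= the input, same length.
    """
    return HeightSeries(
        heights=np.maximum.accumulate(series.heights),
        fps=series.fps,
        contact_frame=series.contact_frame,
        reference_row=series.reference_row,
    )


def extract_height_series(
    frames: np.ndarray, config: ExtractionConfig, fps: float, monotone: bool = True
) -> HeightSeries:
    """Full chain: detect contact, track the front, reference, monotonize."""
    contact = detect_contact(frames, config)
    rows = extract_front_rows(frames, config, contact)
    series = rows_to_heights(rows, config, fps, contact_frame=contact)
    return enforce_monotone(series) if monotone else series


def read_frames(source: str | Path) -> np.ndarray:
    """Load a frame stack from a directory of PNGs or a video file.

    A directory is read as sorted (zero-padded) image files; anything else
    is handed to imageio's video reader (MP4/AVI support requires an ffmpeg
    plugin).  Color frames are converted to grayscale by channel averaging.
    """
    import imageio.v3 as iio

    source = Path(source)
    if source.is_dir():
        files = sorted(
            p for p in source.iterdir()
            if p.suffix.lower() in (".png", ".tif", ".tiff", ".bmp", ".jpg")
        )
        if not files:
            raise FileNotFoundError(f"no image files in {source}")
        frames = np.stack([iio.imread(f) for f in files])
    else:
        frames = np.asarray(iio.imread(source))
    if frames.ndim == 4:  # color -> grayscale
        frames = frames.mean(axis=-1)
    return frames
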