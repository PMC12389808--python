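"""Lucas-Washburn fitting: reduce each flow profile to one coefficient.

Capillary imbibition advances with the square root of time
(``l^2/t ∝ R*γ*cosθ / 2μ``, collapsing radius, interfacial tension,
contact angle and viscosity into a single rate).  Because the first second
after contact is discarded as the height reference, the retained profile
follows the shifted form

    l(t) = a * sqrt(t + 1) + b,     t seconds from the first retained frame,

where ``a`` (height units per sqrt-second) carries all the physics and
``b`` absorbs the vertical offset of the reference.  Fitting every profile
and keeping only ``a`` turns an 1800-frame time series into a single
discriminative feature.

Time is kept in seconds rather than frames so that ``a`` has stable units
across frame rates.  ``a`` is constrained non-negative (physical monotone
imbibition); the solver is bounded least squares started from the
closed-form guess ``a0 = (h_T - h_0)/(sqrt(T+1) - 1)``, ``b0 = h_0 - a0``,
which makes convergence deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .datasets import ProfileDataset
from .frontextract import HeightSeries

__all__ = [
    "WashburnFit",
    "washburn_model",
    "fit_washburn",
    "fit_profiles",
    "build_coefficient_dataset",
]


def washburn_model(t: np.ndarray, a: float, b: float) -> np.ndarray:
    """Shifted square-root-of-time imbibition law ``a*sqrt(t+1) + b``."""
    return a * np.sqrt(t + 1.0) + b


@dataclass(frozen=True)
class WashburnFit:
    """Result of fitting one profile.

    ``a >= 0`` is the square-root slope, ``b`` the vertical offset,
    ``rss`` the residual sum of squares over the ``n_points`` fitted, and
    ``window_s`` the seconds of data used.  ``converged`` is False when the
    solver failed; the reported parameters are then the analytic initial
    guess, never a silent fallback.
    """

    a: float
    b: float
    window_s: float
    rss: float
    n_points: int
    converged: bool

    def predict(self, t: np.ndarray) -> np.ndarray:
        return washburn_model(np.asarray(t, dtype=float), self.a, self.b)


def fit_washburn(
    series: HeightSeries | np.ndarray,
    fps: float | None = None,
    window_s: float | None = None,
) -> WashburnFit:
    """Fit ``l(t) = a*sqrt(t+1) + b`` to the first ``window_s`` seconds.

    Parameters
    ----------
    series
        A :class:`HeightSeries`, or a bare height array (then ``fps`` is
        required).
    window_s
        Seconds of data to fit; ``None`` uses the full series.

    Returns the least-squares ``(a, b)`` with ``a`` bounded below by zero.
    Deterministic for identical input.
    """
    if isinstance(series, HeightSeries):
        heights = series.heights
        fps = series.fps
    else:
        heights = np.asarray(series, dtype=float)
        if fps is None:
            raise ValueError("fps required when fitting a bare array")
    if not np.all(np.isfinite(heights)):
        raise ValueError("heights must be finite")
    n = len(heights)
    if window_s is not None:
        n = min(n, int(round(window_s * fps)))
    if n < 3:
        raise ValueError(f"need >= 3 points in the fit window, got {n}")
    h = heights[:n]
    t = np.arange(n) / fps

    # closed-form start: exact for noiseless data, robust otherwise
    span = np.sqrt(t[-1] + 1.0) - 1.0
    a0 = max((h[-1] - h[0]) / span, 0.0)
    b0 = h[0] - a0
    used_window = n / fps if window_s is None else float(window_s)
    try:
        popt, _ = curve_fit(
            washburn_model,
            t,
            h,
            p0=(a0, b0),
            bounds=([0.0, -np.inf], [np.inf, np.inf]),
        )
        a, b = float(popt[0]), float(popt[1])
        converged = True
    except RuntimeError:
        a, b, converged = a0, b0, False
    rss = float(np.sum((h - washburn_model(t, a, b)) ** 2))
    return WashburnFit(
        a=a, b=b, window_s=used_window, rss=rss, n_points=n, converged=converged
    )


def fit_profiles(
    dataset: ProfileDataset, fps: float, window_s: float | None = None
) -> list[WashburnFit]:
    """Fit every row of a frame-height dataset, keeping full diagnostics."""
    if dataset.feature_kind != "frame_height":
        raise ValueError("fits run on frame-height profiles")
    return [fit_washburn(row, fps=fps, window_s=window_s) for row in dataset.matrix]


def build_coefficient_dataset(
    dataset: ProfileDataset,
    fps: float,
    window_s: float | None = None,
    drop_failed: bool = False,
) -> ProfileDataset:
    """Fit every row of a frame-height dataset; keep the coefficient ``a``.

    Applied to the replicate-averaged (mean) dataset this yields the
    single-feature "fit coefficient dataset" (42 x 1 under the default
    design); ``window_s=15`` gives its 15-s variant.  Labels and session
    groups are preserved row for row.  Failed fits are recorded and, with
    ``drop_failed``, excluded.
    """
    fits = fit_profiles(dataset, fps=fps, window_s=window_s)
    keep = np.array([f.converged or not drop_failed for f in fits])
    coeffs = np.array([[f.a] for f in fits])
    return ProfileDataset(
        matrix=coeffs[keep],
        labels=dataset.labels[keep],
        groups=dataset.groups[keep],
        feature_kind="fit_coefficient",
        normalization="none",
    )
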