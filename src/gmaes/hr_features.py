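"""Section-averaged heart-rate series and the extraction features.

The algorithm consumes instantaneous heart rate already averaged over
consecutive 10-second sections (the standard export of beat-interval
analysis software). From that series it derives, per section,

* ``MovAvHR`` — the moving-average HR over the trailing 60-s window,
* ``dHR``    — current section HR minus MovAvHR (bpm), and
* ``%dHR``   — current section HR as a percentage of MovAvHR,

which are the sole quantities the downstream extraction rules look at.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["HRSeries", "SectionFeatures", "compute_section_features"]


@dataclass(frozen=True)
class HRSeries:
    """A uniform, gapless grid of section-averaged heart-rate values.

    Section ``i`` covers the half-open time span
    ``[start_time + i*section_seconds, start_time + (i+1)*section_seconds)``.

    Parameters
    ----------
    values
        Mean instantaneous HR per section, beats/min. Must be finite and
        strictly positive.
    section_seconds
        Duration of one section in seconds (default 10).
    start_time
        Recording-clock offset of section 0, seconds (default 0).
    """

    values: np.ndarray
    section_seconds: float = 10.0
    start_time: float = 0.0

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1:
            raise ValueError("HR values must be one-dimensional")
        if self.section_seconds <= 0:
            raise ValueError("section_seconds must be positive")
        if vals.size and (not np.all(np.isfinite(vals)) or np.any(vals <= 0)):
            raise ValueError("all HR values must be finite and > 0")
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)

    @property
    def n_sections(self) -> int:
        return int(self.values.size)

    @property
    def duration_seconds(self) -> float:
        return self.n_sections * self.section_seconds

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration_seconds

    def section_times(self) -> np.ndarray:
        """Start time of every section, seconds on the recording clock."""
        return self.start_time + np.arange(self.n_sections) * self.section_seconds

    def section_span(self, i: int) -> tuple[float, float]:
        """Half-open ``[start, end)`` time span of section ``i``."""
        if not 0 <= i < self.n_sections:
            raise IndexError(f"section index {i} out of range")
        t0 = self.start_time + i * self.section_seconds
        return t0, t0 + self.section_seconds


@dataclass(frozen=True)
class SectionFeatures:
    """Per-section extraction features; NaN marks undefined sections.

    Features are undefined for the leading sections that lack a full
    trailing window (index < ``window_sections`` with the default
    window-excludes-current convention).
    """

    hr: np.ndarray
    mov_av_hr: np.ndarray
    delta_hr: np.ndarray
    pct_delta_hr: np.ndarray
    window_sections: int = 6
    window_includes_current: bool = field(default=False)

    @property
    def n_sections(self) -> int:
        return int(self.hr.size)

    @property
    def first_defined(self) -> int:
        """Index of the first section with a defined feature triplet."""
        if self.window_includes_current:
            return self.window_sections - 1
        return self.window_sections

    @property
    def defined(self) -> np.ndarray:
        """Boolean mask: True where the feature triplet is defined."""
        return ~np.isnan(self.mov_av_hr)


def compute_section_features(
    series: HRSeries,
    window_sections: int = 6,
    *,
    window_includes_current: bool = False,
) -> SectionFeatures:
    """Compute MovAvHR, dHR and %dHR for every section of *series*.

    With the default convention the moving average at section ``i`` is the
    mean of the ``window_sections`` sections strictly before ``i`` — the
    "past 60 s" against which the current section is contrasted. With
    ``window_includes_current=True`` the window is the ``window_sections``
    sections ending at and including ``i``.

    Raises
    ------
    ValueError
        If the series is shorter than ``window_sections + 1`` sections.
    """
    if window_sections < 1:
        raise ValueError("window_sections must be >= 1")
    values = series.values
    n = values.size
    if n < window_sections + 1:
        raise ValueError("series too short for feature computation")

    w = window_sections
    mov = np.full(n, np.nan)
    # per-window sums (not cumsum differences): window means are then
    # independent of position, so slices reproduce full-series features
    win_means = np.lib.stride_tricks.sliding_window_view(values, w).sum(axis=-1) / w
    if window_includes_current:
        # mean of values[i-w+1 .. i], defined for i >= w-1
        mov[w - 1 :] = win_means
    else:
        # mean of values[i-w .. i-1], defined for i >= w
        mov[w:] = win_means[:-1]

    delta = values - mov
    pct = 100.0 * values / mov
    return SectionFeatures(
        hr=values,
        mov_av_hr=mov,
        delta_hr=delta,
        pct_delta_hr=pct,
        window_sections=w,
        window_includes_current=window_includes_current,
    )
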