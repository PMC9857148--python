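"""Annotated intervals, section rasterization and concordance metrics.

Video review yields general-movement (GM) intervals and artifact
intervals on the recording clock. Both are rasterized onto the same
10-s section grid as the heart-rate series, and agreement between the
automatically extracted sections (AESs) and GM sections is summarised by
four quantities:

1. percentage of AESs accompanied by a GM section, among all AESs;
2. percentage of full-course GMs among GMs accompanied by an AES, where
   a full-course GM lies beginning-to-end inside a single AES;
3. percentage of GMs accompanied by an AES, among all GMs;
4. total AES time as a percentage of evaluable recording time.

Sections contaminated by artifacts (care interventions, electrode
detachment, ...) are excluded from the evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from .extraction import AES
from .hr_features import HRSeries

__all__ = [
    "GMInterval",
    "ArtifactInterval",
    "SectionMask",
    "ConcordanceReport",
    "validate_gm_intervals",
    "rasterize",
    "build_section_mask",
    "evaluate_concordance",
    "pool_reports",
]

ArtifactPolicy = Literal["drop-events", "mask-sections"]

DEFAULT_MIN_GM_SECONDS = 20.0


@dataclass(frozen=True, order=True)
class GMInterval:
    """One general-movement episode: [start_time, end_time) seconds."""

    start_time: float
    end_time: float

    def __post_init__(self) -> None:
        if not self.end_time > self.start_time:
            raise ValueError("GM interval must have end_time > start_time")

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time


@dataclass(frozen=True, order=True)
class ArtifactInterval:
    """A time span to exclude from evaluation (care, electrode loss, ...)."""

    start_time: float
    end_time: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.end_time > self.start_time:
            raise ValueError("artifact interval must have end_time > start_time")


@dataclass(frozen=True)
class SectionMask:
    """Per-section annotation flags on the heart-rate series grid.

    ``aes_id`` is -1 outside every AES, otherwise the 0-based index of
    the covering AES.
    """

    is_gm: np.ndarray
    is_artifact: np.ndarray
    aes_id: np.ndarray


@dataclass(frozen=True)
class ConcordanceReport:
    """Counts and percentages of AES/GM agreement for one recording.

    Percentages with a zero denominator are ``None`` (undefined), never
    0 or 100, so pooled reports stay correct.
    """

    n_aes: int
    n_aes_with_gm: int
    n_gm: int
    n_gm_with_aes: int
    n_full_course_gm_in_aes: int
    total_aes_seconds: float
    evaluable_recording_seconds: float
    n_recordings: int = 1
    mean_full_course_per_recording: Optional[float] = field(default=None)

    def __post_init__(self) -> None:
        if not (
            self.n_full_course_gm_in_aes <= self.n_gm_with_aes <= self.n_gm
        ):
            raise ValueError("full-course <= GM-with-AES <= GM count violated")
        if self.n_aes_with_gm > self.n_aes:
            raise ValueError("n_aes_with_gm exceeds n_aes")
        if self.mean_full_course_per_recording is None:
            object.__setattr__(
                self,
                "mean_full_course_per_recording",
                self.n_full_course_gm_in_aes / self.n_recordings,
            )

    @staticmethod
    def _pct(num: float, den: float) -> Optional[float]:
        return 100.0 * num / den if den > 0 else None

    @property
    def pct_aes_with_gm(self) -> Optional[float]:
        return self._pct(self.n_aes_with_gm, self.n_aes)

    @property
    def pct_gm_with_aes(self) -> Optional[float]:
        return self._pct(self.n_gm_with_aes, self.n_gm)

    @property
    def pct_full_course_among_gm_with_aes(self) -> Optional[float]:
        return self._pct(self.n_full_course_gm_in_aes, self.n_gm_with_aes)

    @property
    def pct_aes_of_recording(self) -> Optional[float]:
        return self._pct(self.total_aes_seconds, self.evaluable_recording_seconds)

    def to_dict(self) -> dict:
        return {
            "n_aes": self.n_aes,
            "n_aes_with_gm": self.n_aes_with_gm,
            "pct_aes_with_gm": self.pct_aes_with_gm,
            "n_gm": self.n_gm,
            "n_gm_with_aes": self.n_gm_with_aes,
            "pct_gm_with_aes": self.pct_gm_with_aes,
            "n_full_course_gm_in_aes": self.n_full_course_gm_in_aes,
            "pct_full_course_among_gm_with_aes": self.pct_full_course_among_gm_with_aes,
            "total_aes_seconds": self.total_aes_seconds,
            "evaluable_recording_seconds": self.evaluable_recording_seconds,
            "pct_aes_of_recording": self.pct_aes_of_recording,
            "n_recordings": self.n_recordings,
            "mean_full_course_per_recording": self.mean_full_course_per_recording,
        }


def validate_gm_intervals(
    raw: Sequence[tuple[float, float]] | Sequence[GMInterval],
    min_gm_seconds: float = DEFAULT_MIN_GM_SECONDS,
) -> tuple[list[GMInterval], list[tuple[GMInterval, str]]]:
    """Split raw intervals into accepted GMs and rejected ones with reasons.

    Movements shorter than ``min_gm_seconds`` (default 20 s) are not GMs
    — they are typically isolated or reflex movements — and are rejected.
    Overlap among the survivors is an annotation defect and raises.
    """
    intervals = [
        iv if isinstance(iv, GMInterval) else GMInterval(*iv) for iv in raw
    ]
    accepted: list[GMInterval] = []
    rejected: list[tuple[GMInterval, str]] = []
    for iv in intervals:
        if iv.duration < min_gm_seconds:
            rejected.append(
                (iv, f"duration {iv.duration:g} s < minimum {min_gm_seconds:g} s")
            )
        else:
            accepted.append(iv)
    accepted.sort()
    for a, b in zip(accepted, accepted[1:]):
        if b.start_time < a.end_time:
            raise ValueError(
                f"overlapping GM intervals: ({a.start_time:g},{a.end_time:g}) "
                f"and ({b.start_time:g},{b.end_time:g})"
            )
    return accepted, rejected


def rasterize(
    intervals: Sequence[GMInterval] | Sequence[ArtifactInterval],
    series: HRSeries,
) -> np.ndarray:
    """Flag every section the intervals overlap; boolean per-section mask.

    A section is flagged when an interval covers any positive-length part
    of it (half-open sections: an interval ending exactly at a section
    boundary does not flag the following section).
    """
    mask = np.zeros(series.n_sections, dtype=bool)
    ss = series.section_seconds
    t0 = series.start_time
    for iv in intervals:
        if iv.start_time < t0 or iv.end_time > series.end_time:
            raise ValueError(
                f"interval ({iv.start_time:g},{iv.end_time:g}) outside the "
                f"recording span [{t0:g},{series.end_time:g}]"
            )
        first = int(np.floor((iv.start_time - t0) / ss))
        # last flagged section: the one containing end_time, unless the
        # interval ends exactly on its left boundary
        last = int(np.ceil((iv.end_time - t0) / ss)) - 1
        mask[first : last + 1] = True
    return mask


def build_section_mask(
    series: HRSeries,
    aes_list: Sequence[AES],
    gm_intervals: Sequence[GMInterval] = (),
    artifact_intervals: Sequence[ArtifactInterval] = (),
) -> SectionMask:
    """Combine AES membership and rasterized annotations on one grid."""
    aes_id = np.full(series.n_sections, -1, dtype=int)
    for k, aes in enumerate(aes_list):
        aes_id[aes.first_section : aes.last_section + 1] = k
    return SectionMask(
        is_gm=rasterize(gm_intervals, series),
        is_artifact=rasterize(artifact_intervals, series),
        aes_id=aes_id,
    )


def evaluate_concordance(
    aes_list: Sequence[AES],
    gm_intervals: Sequence[GMInterval],
    artifact_intervals: Sequence[ArtifactInterval],
    series: HRSeries,
    *,
    artifact_policy: ArtifactPolicy = "drop-events",
) -> ConcordanceReport:
    """Compute the four agreement metrics for one recording.

    Artifact handling (``artifact_policy``):

    * ``"drop-events"`` (default, the conservative policy): any AES or GM
      that touches an artifact section is excluded from the event counts;
    * ``"mask-sections"``: events are kept but their artifact sections are
      ignored, so a GM is judged on its clean sections only.

    Under both policies, artifact sections are removed from both the AES
    time numerator and the recording-time denominator of metric 4.
    """
    if artifact_policy not in ("drop-events", "mask-sections"):
        raise ValueError(f"unknown artifact policy: {artifact_policy!r}")
    n = series.n_sections
    artifact_mask = rasterize(artifact_intervals, series)

    aes_sections: list[set[int]] = [set(a.sections()) for a in aes_list]
    for s in aes_sections:
        if s and (min(s) < 0 or max(s) >= n):
            raise ValueError("AES extends beyond the series grid")
    gm_sections: list[set[int]] = [
        set(np.flatnonzero(rasterize([gm], series))) for gm in gm_intervals
    ]

    artifact_set = set(np.flatnonzero(artifact_mask))

    if artifact_policy == "drop-events":
        eval_aes = [s for s in aes_sections if not (s & artifact_set)]
        eval_gm = [s for s in gm_sections if not (s & artifact_set)]
    else:  # mask-sections: keep events, ignore their artifact sections
        eval_aes = [s - artifact_set for s in aes_sections]
        eval_aes = [s for s in eval_aes if s]
        eval_gm = [s - artifact_set for s in gm_sections]
        eval_gm = [s for s in eval_gm if s]

    gm_union: set[int] = set().union(*eval_gm) if eval_gm else set()
    n_aes = len(eval_aes)
    n_aes_with_gm = sum(1 for s in eval_aes if s & gm_union)

    n_gm = len(eval_gm)
    n_gm_with_aes = 0
    n_full_course = 0
    for s in eval_gm:
        covering = [a for a in eval_aes if s & a]
        if covering:
            n_gm_with_aes += 1
            # full-course: every GM section inside ONE AES
            if any(s <= a for a in covering):
                n_full_course += 1

    # metric 4 masks artifact sections out of both numerator and
    # denominator, independent of the event-drop policy
    all_aes_union: set[int] = set().union(*aes_sections) if aes_sections else set()
    aes_clean = all_aes_union - artifact_set
    ss = series.section_seconds
    total_aes_seconds = len(aes_clean) * ss
    evaluable_seconds = (n - len(artifact_set)) * ss

    return ConcordanceReport(
        n_aes=n_aes,
        n_aes_with_gm=n_aes_with_gm,
        n_gm=n_gm,
        n_gm_with_aes=n_gm_with_aes,
        n_full_course_gm_in_aes=n_full_course,
        total_aes_seconds=total_aes_seconds,
        evaluable_recording_seconds=evaluable_seconds,
    )


def pool_reports(reports: Sequence[ConcordanceReport]) -> ConcordanceReport:
    """Pool per-recording reports by summing counts, then recompute rates.

    Recordings are pooled by adding AES and GM counts and seconds across
    recordings and recomputing the percentages from the pooled totals
    (not by averaging the per-recording percentages). The mean number of
    full-course GMs per recording is reported alongside.
    """
    if not reports:
        raise ValueError("cannot pool an empty list of reports")
    n_recordings = sum(r.n_recordings for r in reports)
    n_full = sum(r.n_full_course_gm_in_aes for r in reports)
    return ConcordanceReport(
        n_aes=sum(r.n_aes for r in reports),
        n_aes_with_gm=sum(r.n_aes_with_gm for r in reports),
        n_gm=sum(r.n_gm for r in reports),
        n_gm_with_aes=sum(r.n_gm_with_aes for r in reports),
        n_full_course_gm_in_aes=n_full,
        total_aes_seconds=sum(r.total_aes_seconds for r in reports),
        evaluable_recording_seconds=sum(
            r.evaluable_recording_seconds for r in reports
        ),
        n_recordings=n_recordings,
        mean_full_course_per_recording=n_full / n_recordings,
    )
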