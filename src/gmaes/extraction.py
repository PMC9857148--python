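"""Detection of automated extraction sections (AESs) from HR features.

An AES is a contiguous span of 10-s sections in which a general movement
is expected to emerge, derived purely from heart-rate dynamics:

1. find every maximal run of consecutive sections with dHR > 0 that is at
   least ``min_run`` sections long and contains at least one section with
   %dHR strictly above the threshold (103 or 105 percent);
2. expand each run outward, backward and forward independently, until dHR
   has gone negative twice on that flank (the second negative section is
   excluded by default), the record ends, or features become undefined;
3. merge expanded spans that overlap or touch.

All comparisons are strict: dHR == 0 neither qualifies a candidate
section nor counts toward the negative-twice stop rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hr_features import HRSeries, SectionFeatures, compute_section_features

__all__ = [
    "ExtractionConfig",
    "CandidateRun",
    "AES",
    "find_candidate_runs",
    "expand_run",
    "merge_overlapping",
    "extract_aes",
]


@dataclass(frozen=True)
class ExtractionConfig:
    """Tunable parameters of the AES extraction rules.

    ``threshold_pct`` defaults to 105 (the recommended setting); 103 is
    the documented more-sensitive alternative.
    """

    threshold_pct: float = 105.0
    min_run: int = 3
    window_sections: int = 6
    section_seconds: float = 10.0
    include_second_negative: bool = False
    window_includes_current: bool = False

    def __post_init__(self) -> None:
        if self.threshold_pct <= 100:
            raise ValueError("threshold_pct must be > 100")
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")
        if self.window_sections < 1:
            raise ValueError("window_sections must be >= 1")
        if self.section_seconds <= 0:
            raise ValueError("section_seconds must be positive")


@dataclass(frozen=True)
class CandidateRun:
    """A maximal run of dHR-positive sections qualifying for extraction."""

    first_section: int
    last_section: int
    peak_pct: float

    @property
    def n_sections(self) -> int:
        return self.last_section - self.first_section + 1


@dataclass(frozen=True)
class AES:
    """An automated extraction section: an expanded, merged index range."""

    first_section: int
    last_section: int
    source_runs: tuple[CandidateRun, ...] = field(default=())
    threshold_pct: float = 105.0

    def __post_init__(self) -> None:
        if self.first_section > self.last_section:
            raise ValueError("AES first_section must be <= last_section")

    @property
    def n_sections(self) -> int:
        return self.last_section - self.first_section + 1

    def duration_seconds(self, section_seconds: float = 10.0) -> float:
        return self.n_sections * section_seconds

    def sections(self) -> range:
        return range(self.first_section, self.last_section + 1)

    def contains(self, other: "AES") -> bool:
        return (
            self.first_section <= other.first_section
            and other.last_section <= self.last_section
        )


def find_candidate_runs(
    features: SectionFeatures, config: ExtractionConfig
) -> list[CandidateRun]:
    """Return every maximal dHR-positive run meeting the extraction rule.

    A run qualifies when it spans at least ``config.min_run`` consecutive
    sections with dHR > 0 and contains at least one section whose %dHR is
    strictly above ``config.threshold_pct``. Runs are disjoint (maximality)
    and returned in section order.
    """
    delta = features.delta_hr
    pct = features.pct_delta_hr
    positive = np.zeros(features.n_sections, dtype=bool)
    defined = features.defined
    positive[defined] = delta[defined] > 0

    runs: list[CandidateRun] = []
    n = positive.size
    i = 0
    while i < n:
        if not positive[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and positive[j + 1]:
            j += 1
        if j - i + 1 >= config.min_run:
            peak = float(np.max(pct[i : j + 1]))
            if peak > config.threshold_pct:
                runs.append(CandidateRun(i, j, peak))
        i = j + 1
    return runs


def expand_run(
    features: SectionFeatures,
    run: CandidateRun,
    *,
    include_second_negative: bool = False,
    threshold_pct: float = 105.0,
) -> AES:
    """Expand a candidate run outward until dHR goes negative twice.

    Each flank is walked one section at a time, counting sections with
    dHR strictly below zero. The walk stops at the record boundary, at
    the first undefined-feature section, or when the negative count
    would reach two. By default the section carrying the second negative
    is excluded, so each flank contains at most one negative section;
    ``include_second_negative=True`` keeps it.
    """
    delta = features.delta_hr

    def walk(start: int, step: int) -> int:
        pos = start
        negatives = 0
        while True:
            nxt = pos + step
            if nxt < 0 or nxt >= features.n_sections or np.isnan(delta[nxt]):
                return pos
            if delta[nxt] < 0:
                negatives += 1
                if negatives == 2:
                    return nxt if include_second_negative else pos
            pos = nxt

    first = walk(run.first_section, -1)
    last = walk(run.last_section, +1)
    return AES(first, last, source_runs=(run,), threshold_pct=threshold_pct)


def merge_overlapping(aes_list: list[AES]) -> list[AES]:
    """Merge AESs whose section ranges overlap or touch.

    Adjacent spans (sharing a boundary, e.g. [3,6] and [7,10]) merge as
    well: the output is a sorted list of pairwise disjoint,
    non-adjacent AESs, each carrying the source runs it absorbed.
    """
    if not aes_list:
        return []
    ordered = sorted(aes_list, key=lambda a: (a.first_section, a.last_section))
    merged: list[AES] = [ordered[0]]
    for nxt in ordered[1:]:
        cur = merged[-1]
        if nxt.first_section <= cur.last_section + 1:
            merged[-1] = AES(
                cur.first_section,
                max(cur.last_section, nxt.last_section),
                source_runs=cur.source_runs + nxt.source_runs,
                threshold_pct=cur.threshold_pct,
            )
        else:
            merged.append(nxt)
    return merged


def extract_aes(series: HRSeries, config: ExtractionConfig | None = None) -> list[AES]:
    """Run the full extraction pipeline on a heart-rate series.

    Composition of feature computation, candidate-run detection,
    per-run expansion and merging. Deterministic.
    """
    if config is None:
        config = ExtractionConfig()
    features = compute_section_features(
        series,
        config.window_sections,
        window_includes_current=config.window_includes_current,
    )
    runs = find_candidate_runs(features, config)
    expanded = [
        expand_run(
            features,
            run,
            include_second_negative=config.include_second_negative,
            threshold_pct=config.threshold_pct,
        )
        for run in runs
    ]
    return merge_overlapping(expanded)
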