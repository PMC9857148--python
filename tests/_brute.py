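"""Independent brute-force oracles used only by the tests.

These follow the extraction and concordance rules literally, step by
step, with plain Python loops — deliberately sharing no code with the
package implementation they check.
"""

from __future__ import annotations

import math


def brute_features(values, window, include_current=False):
    """(mov_av, delta, pct) lists; None where undefined."""
    n = len(values)
    mov = [None] * n
    delta = [None] * n
    pct = [None] * n
    for i in range(n):
        if include_current:
            lo, hi = i - window + 1, i + 1
        else:
            lo, hi = i - window, i
        if lo < 0:
            continue
        m = math.fsum(values[lo:hi]) / window
        mov[i] = m
        delta[i] = values[i] - m
        pct[i] = 100.0 * values[i] / m
    return mov, delta, pct


def brute_positive_runs(delta):
    """Maximal runs of strictly positive, defined delta: (first, last)."""
    runs = []
    start = None
    for i, d in enumerate(delta):
        if d is not None and d > 0:
            if start is None:
                start = i
        else:
            if start is not None:
                runs.append((start, i - 1))
                start = None
    if start is not None:
        runs.append((start, len(delta) - 1))
    return runs


def brute_expand(delta, first, last, include_second_negative=False):
    """Walk each flank, literally counting strict negatives."""
    n = len(delta)

    def flank(pos, step):
        negatives = 0
        while True:
            nxt = pos + step
            if nxt < 0 or nxt >= n or delta[nxt] is None:
                return pos
            if delta[nxt] < 0:
                negatives += 1
                if negatives == 2:
                    return nxt if include_second_negative else pos
            pos = nxt

    return flank(first, -1), flank(last, +1)


def brute_extract(values, threshold=105.0, min_run=3, window=6,
                  include_second_negative=False, include_current=False):
    """Full literal pipeline: runs -> expand -> union of covered sections.

    Merging is done by marking every covered section and taking the
    connected components of the coverage (components separated by a gap
    of at least one uncovered section), which is an independent route to
    the overlap-or-adjacent merge rule.
    """
    _, delta, pct = brute_features(values, window, include_current)
    n = len(values)
    covered = [False] * n
    any_run = False
    for first, last in brute_positive_runs(delta):
        if last - first + 1 < min_run:
            continue
        if not any(pct[i] is not None and pct[i] > threshold for i in range(first, last + 1)):
            continue
        any_run = True
        lo, hi = brute_expand(delta, first, last, include_second_negative)
        for i in range(lo, hi + 1):
            covered[i] = True
    if not any_run:
        return []
    out = []
    i = 0
    while i < n:
        if covered[i]:
            j = i
            while j + 1 < n and covered[j + 1]:
                j += 1
            out.append((i, j))
            i = j + 1
        else:
            i += 1
    return out


def brute_rasterize_1s(intervals, n_sections, section_seconds=10, start_time=0):
    """Per-second membership: flag a section if any of its seconds is inside
    any half-open interval. Requires integer section_seconds and interval
    endpoints on the 1-s grid."""
    flags = [False] * n_sections
    step = int(section_seconds)
    for i in range(n_sections):
        sec_start = int(start_time) + i * step
        for s in range(sec_start, sec_start + step):
            if any(a <= s < b for a, b in intervals):
                flags[i] = True
                break
    return flags


def brute_concordance(aes_ranges, gm_intervals, artifact_intervals, n_sections,
                      section_seconds=10):
    """Four metrics from per-second rasterization and set logic.

    Uses the drop-events artifact policy. ``aes_ranges`` are inclusive
    (first, last) section pairs; intervals are (start_s, end_s) with
    integer endpoints.
    """
    art = brute_rasterize_1s(artifact_intervals, n_sections, section_seconds)
    art_set = {i for i, f in enumerate(art) if f}

    gm_secs = []
    for a, b in gm_intervals:
        flags = brute_rasterize_1s([(a, b)], n_sections, section_seconds)
        gm_secs.append({i for i, f in enumerate(flags) if f})
    aes_secs = [set(range(f, l + 1)) for f, l in aes_ranges]

    ok_aes = [s for s in aes_secs if not s & art_set]
    ok_gm = [s for s in gm_secs if not s & art_set]

    gm_union = set().union(*ok_gm) if ok_gm else set()
    n_aes_with_gm = sum(1 for s in ok_aes if s & gm_union)
    n_gm_with_aes = 0
    n_full = 0
    for g in ok_gm:
        hits = [a for a in ok_aes if g & a]
        if hits:
            n_gm_with_aes += 1
            if any(g <= a for a in hits):
                n_full += 1

    all_aes = set().union(*aes_secs) if aes_secs else set()
    return {
        "n_aes": len(ok_aes),
        "n_aes_with_gm": n_aes_with_gm,
        "n_gm": len(ok_gm),
        "n_gm_with_aes": n_gm_with_aes,
        "n_full_course_gm_in_aes": n_full,
        "total_aes_seconds": len(all_aes - art_set) * section_seconds,
        "evaluable_recording_seconds": (n_sections - len(art_set)) * section_seconds,
    }
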