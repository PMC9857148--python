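"""Trace plots: HR with its moving average, %dHR, AES boxes, GM spans.

Matplotlib is imported lazily; install the ``plot`` extra to use this
module.
"""

from __future__ import annotations

from typing import Sequence

from .concordance import GMInterval
from .extraction import AES, ExtractionConfig
from .hr_features import HRSeries, SectionFeatures


def plot_extraction(
    series: HRSeries,
    features: SectionFeatures,
    aes_list: Sequence[AES],
    gm_intervals: Sequence[GMInterval] = (),
    config: ExtractionConfig | None = None,
    axes=None,
):
    """Two-panel trace: HR + moving average on top, %dHR below.

    AESs are drawn as shaded boxes spanning both panels; GM intervals as
    horizontal bars; the extraction threshold as a dashed line.
    """
    import matplotlib.pyplot as plt

    if config is None:
        config = ExtractionConfig()
    if axes is None:
        _, axes = plt.subplots(2, 1, sharex=True, figsize=(10, 5))
    ax_hr, ax_pct = axes
    t = series.section_times()

    ax_hr.plot(t, series.values, color="goldenrod", lw=1.0, label="HR")
    ax_hr.plot(t, features.mov_av_hr, color="seagreen", lw=1.0, label="moving average")
    ax_hr.set_ylabel("HR (bpm)")
    ax_hr.legend(loc="upper right", fontsize="small")

    ax_pct.plot(t, features.pct_delta_hr, color="black", lw=1.0)
    ax_pct.axhline(config.threshold_pct, color="red", ls="--", lw=0.8)
    ax_pct.axhline(100.0, color="grey", ls=":", lw=0.8)
    ax_pct.set_ylabel("%dHR (%)")
    ax_pct.set_xlabel("time (s)")

    for aes in aes_list:
        t0, _ = series.section_span(aes.first_section)
        _, t1 = series.section_span(aes.last_section)
        for ax in (ax_hr, ax_pct):
            ax.axvspan(t0, t1, color="lightblue", alpha=0.4)
    for gm in gm_intervals:
        ax_hr.axvspan(gm.start_time, gm.end_time, ymin=0.95, color="navy", alpha=0.8)
    return axes
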