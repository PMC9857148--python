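"""Seed-reproducible synthetic neonatal heart-rate recordings.

The generator emulates the statistical structure the extraction
algorithm assumes in a preterm infant at rest:

* a baseline HR around 155 bpm with short-range variability modelled as
  an AR(1) process at the 10-s section resolution (the algorithm only
  ever sees section means, so beat-level simulation adds nothing);
* general movements (GMs) of at least 20 s, arriving as a Poisson
  process thinned to forbid overlap, each accompanied by a transient HR
  acceleration of a few percent with a trapezoidal rise-plateau-decay
  profile (GMs have a gradual beginning and end);
* brief isolated-movement "blips" (< 20 s, small amplitude);
* artifact intervals (care interventions and the like), recorded as
  ground truth but by default leaving the HR untouched — exclusion is
  the evaluator's job, not the monitor's.

The ground-truth GM, blip and artifact intervals are returned next to
the HR series so extraction output can be scored against them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .concordance import (
    ArtifactInterval,
    ConcordanceReport,
    GMInterval,
    evaluate_concordance,
    pool_reports,
)
from .extraction import ExtractionConfig, extract_aes
from .hr_features import HRSeries

__all__ = ["SimulationConfig", "SyntheticRecording", "simulate_recording", "run_scenario"]

_FINE_DT = 0.5  # s; sub-section grid on which event profiles are sampled


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic recording.

    Defaults describe a one-hour supine recording of a preterm infant:
    baseline 155 bpm, section-to-section variability of ~2 bpm with
    moderate autocorrelation, about 12 GMs per hour lasting 20-120 s
    with an 8 percent peak HR acceleration, occasional sub-20-s
    isolated movements, and roughly one artifact interval per hour.
    """

    duration_s: float = 3600.0
    section_seconds: float = 10.0
    baseline_bpm: float = 155.0
    noise_sd_bpm: float = 2.0
    ar1_coeff: float = 0.6
    gm_rate_per_hour: float = 12.0
    gm_duration_range_s: tuple[float, float] = (20.0, 120.0)
    accel_amplitude_pct: float = 8.0
    accel_rise_s: float = 10.0
    accel_decay_s: float = 10.0
    blip_rate_per_hour: float = 6.0
    blip_amplitude_pct: float = 2.0
    blip_duration_s: float = 5.0
    artifact_rate_per_hour: float = 1.0
    artifact_duration_s: float = 60.0
    artifact_mode: str = "record-only"  # or "perturb"
    fixed_gms: Optional[tuple[tuple[float, float], ...]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.gm_duration_range_s
        if lo < 20.0:
            raise ValueError("GM durations must be >= 20 s at the low end")
        if hi < lo:
            raise ValueError("gm_duration_range_s must be (low, high) with low <= high")
        if min(self.gm_rate_per_hour, self.blip_rate_per_hour, self.artifact_rate_per_hour) < 0:
            raise ValueError("event rates must be >= 0")
        if min(self.accel_amplitude_pct, self.blip_amplitude_pct) < 0:
            raise ValueError("amplitudes must be >= 0")
        if not 0 <= self.ar1_coeff < 1:
            raise ValueError("ar1_coeff must lie in [0, 1)")
        if self.noise_sd_bpm < 0:
            raise ValueError("noise_sd_bpm must be >= 0")
        if self.duration_s < self.section_seconds:
            raise ValueError("duration_s must cover at least one section")
        if self.artifact_mode not in ("record-only", "perturb"):
            raise ValueError("artifact_mode must be 'record-only' or 'perturb'")
        expected_gm_time = (
            self.gm_rate_per_hour * (self.duration_s / 3600.0) * (lo + hi) / 2.0
        )
        if self.fixed_gms is None and expected_gm_time > self.duration_s:
            raise ValueError(
                "infeasible config: expected GM time exceeds recording duration"
            )


@dataclass(frozen=True)
class SyntheticRecording:
    """A simulated recording plus its ground-truth annotations."""

    hr: HRSeries
    gms: tuple[GMInterval, ...]
    blips: tuple[tuple[float, float], ...]
    artifacts: tuple[ArtifactInterval, ...]
    config: SimulationConfig = field(repr=False, default=None)  # type: ignore[assignment]


def _draw_nonoverlapping(
    rng: np.random.Generator,
    rate_per_hour: float,
    duration_s: float,
    dur_lo: float,
    dur_hi: float,
) -> list[tuple[float, float]]:
    """Poisson onsets with uniform durations, thinned to forbid overlap."""
    n = rng.poisson(rate_per_hour * duration_s / 3600.0)
    if n == 0:
        return []
    onsets = np.sort(rng.uniform(0.0, duration_s, size=n))
    durs = rng.uniform(dur_lo, dur_hi, size=n)
    out: list[tuple[float, float]] = []
    prev_end = -np.inf
    for start, dur in zip(onsets, durs):
        end = start + dur
        if start >= prev_end and end <= duration_s:
            out.append((float(start), float(end)))
            prev_end = end
    return out


def _trapezoid(t: np.ndarray, start: float, end: float, rise: float, decay: float) -> np.ndarray:
    """Unit-height rise-plateau-decay profile on [start, end), 0 outside.

    If the event is shorter than rise + decay the ramps are shrunk
    proportionally so the profile still peaks at 1.
    """
    dur = end - start
    if rise + decay > dur:
        scale = dur / (rise + decay)
        rise, decay = rise * scale, decay * scale
    shape = np.zeros_like(t)
    inside = (t >= start) & (t < end)
    ti = t[inside]
    up = np.minimum(1.0, (ti - start) / rise) if rise > 0 else np.ones_like(ti)
    down = np.minimum(1.0, (end - ti) / decay) if decay > 0 else np.ones_like(ti)
    shape[inside] = np.minimum(up, down)
    return shape


def simulate_recording(config: SimulationConfig) -> SyntheticRecording:
    """Generate one recording; identical config + seed is bit-identical."""
    rng = np.random.default_rng(config.seed)
    ss = config.section_seconds
    n_sections = int(round(config.duration_s / ss))
    duration = n_sections * ss

    # AR(1) at section resolution, stationary sd = noise_sd_bpm
    noise = np.zeros(n_sections)
    if config.noise_sd_bpm > 0:
        a = config.ar1_coeff
        innov_sd = config.noise_sd_bpm * np.sqrt(1.0 - a * a)
        e = rng.normal(0.0, 1.0, size=n_sections)
        noise[0] = config.noise_sd_bpm * e[0]
        for t in range(1, n_sections):
            noise[t] = a * noise[t - 1] + innov_sd * e[t]
    hr = config.baseline_bpm + noise

    # GM episodes
    if config.fixed_gms is not None:
        gm_spans = [(s, s + d) for s, d in config.fixed_gms]
        gm_spans.sort()
        for (a0, b0), (a1, _) in zip(gm_spans, gm_spans[1:]):
            if a1 < b0:
                raise ValueError("fixed GMs overlap")
        for a0, b0 in gm_spans:
            if b0 - a0 < 20.0 or a0 < 0 or b0 > duration:
                raise ValueError("fixed GM outside recording or shorter than 20 s")
    else:
        lo, hi = config.gm_duration_range_s
        gm_spans = _draw_nonoverlapping(rng, config.gm_rate_per_hour, duration, lo, hi)

    # per-fine-sample multiplicative acceleration profile
    t_fine = (np.arange(int(duration / _FINE_DT)) + 0.5) * _FINE_DT
    mult = np.ones_like(t_fine)
    amp = config.accel_amplitude_pct / 100.0
    for a0, b0 in gm_spans:
        mult += amp * _trapezoid(t_fine, a0, b0, config.accel_rise_s, config.accel_decay_s)

    blips = _draw_nonoverlapping(
        rng, config.blip_rate_per_hour, duration, config.blip_duration_s, config.blip_duration_s
    )
    bamp = config.blip_amplitude_pct / 100.0
    for a0, b0 in blips:
        half = (b0 - a0) / 2.0
        mult += bamp * _trapezoid(t_fine, a0, b0, half, half)

    sect_mult = mult.reshape(n_sections, -1).mean(axis=1)
    hr = hr * sect_mult

    artifacts = [
        ArtifactInterval(a0, b0, label="synthetic")
        for a0, b0 in _draw_nonoverlapping(
            rng,
            config.artifact_rate_per_hour,
            duration,
            config.artifact_duration_s,
            config.artifact_duration_s,
        )
    ]
    if config.artifact_mode == "perturb":
        # crude electrode-trouble spikes so masking can be exercised
        times = np.arange(n_sections) * ss
        for art in artifacts:
            hit = (times + ss > art.start_time) & (times < art.end_time)
            hr[hit] += 40.0

    return SyntheticRecording(
        hr=HRSeries(hr, section_seconds=ss, start_time=0.0),
        gms=tuple(GMInterval(a0, b0) for a0, b0 in gm_spans),
        blips=tuple(blips),
        artifacts=tuple(artifacts),
        config=config,
    )


def replicate_seeds(seed: int, n: int) -> list[int]:
    """Independent per-replicate seeds derived from one master seed."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s) % (2**31) for s in state]


def run_scenario(
    config: SimulationConfig,
    extraction_configs: Sequence[ExtractionConfig],
    n_replicates: int,
    *,
    artifact_policy: str = "drop-events",
) -> dict[float, ConcordanceReport]:
    """Simulate replicates, extract at each threshold, pool concordance.

    Returns one pooled report per extraction config, keyed by its
    ``threshold_pct``. All replicates share the recording configuration;
    per-replicate seeds are derived from ``config.seed``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    thresholds = [ec.threshold_pct for ec in extraction_configs]
    if len(set(thresholds)) != len(thresholds):
        raise ValueError("extraction configs must have distinct thresholds")
    per_threshold: dict[float, list[ConcordanceReport]] = {t: [] for t in thresholds}
    for sub in replicate_seeds(config.seed, n_replicates):
        rec = simulate_recording(replace(config, seed=sub))
        for ec in extraction_configs:
            aes = extract_aes(rec.hr, ec)
            per_threshold[ec.threshold_pct].append(
                evaluate_concordance(
                    aes, rec.gms, rec.artifacts, rec.hr, artifact_policy=artifact_policy
                )
            )
    return {t: pool_reports(reps) for t, reps in per_threshold.items()}
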