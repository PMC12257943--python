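"""Maximum heart rate (fHmax) thermal-performance analysis.

Beat timestamps recorded under a 1 degC / 6 min stepped-warming protocol
are reduced to one fHmax value per temperature step, computed from the RR
intervals falling wholly inside the final 1-min analysis window of each
step.  Arrhythmia onset (T_arr) is the first step whose analysis window
contains a skipped-beat gap (RR > ``gap_factor`` x the window median RR)
or excessive RR variability (CV > ``cv_max``).  The curve summary reports
peak fHmax, its temperature (T_peak), T_arr and the absolute and fold
increase in fHmax from the 12 degC start.

The arrhythmia thresholds are operational choices (ECG studies rely on
visual inspection); both are exposed as parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_units import BeatSeries

__all__ = [
    "StepRate",
    "HeartRateCurve",
    "CardiacSummary",
    "fhmax_per_step",
    "detect_arrhythmia",
    "summarize_cardiac",
]

MIN_WINDOW_BEATS = 5


@dataclass
class StepRate:
    temp_c: float
    fhmax_bpm: float | None  # None when the window held < MIN_WINDOW_BEATS beats
    n_beats: int
    rr_cv: float | None
    max_rr_ratio: float | None  # max RR / median RR within the window


@dataclass
class HeartRateCurve:
    fish_id: str
    steps: list[StepRate]
    arrhythmic_from_step: int | None = None  # index into steps

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "temp_c": [s.temp_c for s in self.steps],
                "fhmax_bpm": [s.fhmax_bpm for s in self.steps],
                "n_beats": [s.n_beats for s in self.steps],
                "rr_cv": [s.rr_cv for s in self.steps],
                "arrhythmic": [
                    self.arrhythmic_from_step is not None
                    and i >= self.arrhythmic_from_step
                    for i in range(len(self.steps))
                ],
            }
        )


@dataclass
class CardiacSummary:
    fish_id: str
    peak_fhmax_bpm: float
    t_peak_c: float
    t_arr_c: float | None
    fh_at_start_bpm: float | None
    delta_fhmax_bpm: float | None
    fold_delta_fhmax: float | None


def _window_rr(beats: BeatSeries, step_start: float, window_s: float) -> np.ndarray:
    """RR intervals wholly inside the final ``window_s`` of one step."""
    w_lo = step_start + beats.step_duration_s - window_s
    w_hi = step_start + beats.step_duration_s
    inside = beats.beat_times_s[(beats.beat_times_s >= w_lo) & (beats.beat_times_s <= w_hi)]
    return np.diff(inside)


def fhmax_per_step(beats: BeatSeries, window_s: float = 60.0) -> HeartRateCurve:
    """fHmax per temperature step from the final 1-min analysis window.

    fHmax = 60 / mean(RR) in beats per minute.  Steps with fewer than
    5 beats in the window are flagged missing rather than fabricated.
    """
    steps: list[StepRate] = []
    for step_start, temp in beats.step_schedule:
        rr = _window_rr(beats, step_start, window_s)
        n = rr.size + 1 if rr.size else 0
        if n < MIN_WINDOW_BEATS:
            steps.append(StepRate(temp_c=temp, fhmax_bpm=None, n_beats=n, rr_cv=None, max_rr_ratio=None))
            continue
        steps.append(
            StepRate(
                temp_c=temp,
                fhmax_bpm=float(60.0 / rr.mean()),
                n_beats=n,
                rr_cv=float(rr.std() / rr.mean()),
                max_rr_ratio=float(rr.max() / np.median(rr)),
            )
        )
    return HeartRateCurve(fish_id=beats.fish_id, steps=steps)


def detect_arrhythmia(
    beats: BeatSeries,
    window_s: float = 60.0,
    gap_factor: float = 1.8,
    cv_max: float = 0.15,
) -> tuple[float | None, HeartRateCurve]:
    """Temperature of the first arrhythmic step (T_arr), or None.

    A step is arrhythmic when its analysis window contains an RR interval
    exceeding ``gap_factor`` times the window median RR, or when the RR
    coefficient of variation exceeds ``cv_max``.  Returns the annotated
    curve alongside T_arr; absence of arrhythmia is a valid outcome.
    """
    curve = fhmax_per_step(beats, window_s)
    for i, s in enumerate(curve.steps):
        if s.fhmax_bpm is None:
            continue
        if (s.max_rr_ratio is not None and s.max_rr_ratio > gap_factor) or (
            s.rr_cv is not None and s.rr_cv > cv_max
        ):
            curve.arrhythmic_from_step = i
            return s.temp_c, curve
    return None, curve


def summarize_cardiac(
    curve: HeartRateCurve, t_arr_c: float | None = None
) -> CardiacSummary:
    """Peak fHmax, T_peak and the warming scope from an annotated curve.

    The peak is searched over pre-arrhythmic steps only; ties break toward
    the lower temperature.  Delta fHmax = peak - value at the 12 degC
    start; fold = peak / start.  Both are flagged undefined (None) when the
    12 degC step is missing.
    """
    if t_arr_c is None and curve.arrhythmic_from_step is not None:
        t_arr_c = curve.steps[curve.arrhythmic_from_step].temp_c
    usable = [
        s
        for i, s in enumerate(curve.steps)
        if s.fhmax_bpm is not None
        and (curve.arrhythmic_from_step is None or i < curve.arrhythmic_from_step)
    ]
    if len(usable) < 2:
        raise ValueError("need at least 2 pre-arrhythmic steps")
    peak = max(usable, key=lambda s: (s.fhmax_bpm, -s.temp_c))
    start = next((s for s in curve.steps if s.temp_c == 12.0 and s.fhmax_bpm is not None), None)
    delta = None if start is None else peak.fhmax_bpm - start.fhmax_bpm
    fold = None if start is None else peak.fhmax_bpm / start.fhmax_bpm
    if t_arr_c is not None and peak.temp_c > t_arr_c:
        raise ValueError("peak temperature exceeds T_arr; inconsistent annotation")
    return CardiacSummary(
        fish_id=curve.fish_id,
        peak_fhmax_bpm=peak.fhmax_bpm,
        t_peak_c=peak.temp_c,
        t_arr_c=t_arr_c,
        fh_at_start_bpm=None if start is None else start.fhmax_bpm,
        delta_fhmax_bpm=delta,
        fold_delta_fhmax=fold,
    )
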