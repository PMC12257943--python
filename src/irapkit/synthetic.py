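"""Synthetic respirometry, tolerance-ramp and cardiac trials with known truth.

The simulator emulates the study design the analysis modules are built for:
a chase-to-exhaustion intermittent-flow respirometry trial (short recovery
cycles capturing MMR, longer routine cycles over two diurnal cycles for SMR
and EPOC), a terminal progressive-hypoxia phase for P_crit, free-swimming
thermal and hypoxia tolerance ramps ending in loss of equilibrium, and a
stepped-warming maximum-heart-rate trial ending in arrhythmia.

Every stochastic element draws from a single `numpy` Generator seeded from
``TrialTruth.seed``; identical truth -> identical traces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .io_units import BeatSeries, PO2Trace, RampRecord, RespirometerConfig

__all__ = [
    "TrialTruth",
    "CycleProtocol",
    "HypoxiaRampSpec",
    "default_config",
    "simulate_irap_trial",
    "simulate_hypoxia_phase",
    "simulate_tolerance_ramp",
    "simulate_cardiac_trial",
]

DIEL_PERIOD_H = 24.0


class TrialTruth(BaseModel):
    """Ground-truth parameters of one simulated fish.

    Defaults describe a ~50 g rainbow trout acclimated to 18 degC: SMR
    90 mg O2/h/kg, MMR 450, exponential post-exhaustion recovery at
    0.8 /h (excess metabolism repaid over ~5 h, typical of salmonids),
    diel elevation of routine metabolism up to 10% of SMR,
    P_crit 18% air sat, LOE_hyp 5% air sat, CT_max 29.7 degC, and a
    maximum-heart-rate curve rising with Q10 1.8 from 60 bpm at 12 degC
    to a peak at 23.9 degC with arrhythmia onset at 26.9 degC.
    """

    smr_true: float = Field(default=90.0, gt=0)
    mmr_true: float = Field(default=450.0, gt=0)
    recovery_k: float = Field(default=0.8, gt=0, description="recovery rate (1/h)")
    diel_amplitude: float = Field(default=0.10, ge=0, lt=1)
    noise_sd: float = Field(default=0.05, ge=0, description="optode noise (% air sat)")
    background_rate: float = Field(default=0.04, ge=0, lt=0.05)
    pcrit_true: float = Field(default=18.0, gt=0)
    hypoxia_routine_factor: float = Field(
        default=1.1,
        ge=1.0,
        description="routine MO2 during the hypoxia challenge, as a multiple of SMR",
    )
    loehyp_true: float = Field(default=5.0, gt=0)
    ctmax_true: float = Field(default=29.7)
    accl_temp_c: float = 18.0
    fh12_true: float = Field(default=60.0, gt=0, description="fHmax at 12 degC (bpm)")
    q10_true: float = Field(default=1.8, gt=0)
    tpeak_true: float = Field(default=23.9)
    tarr_true: float = Field(default=26.9)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "TrialTruth":
        if not self.smr_true < self.mmr_true:
            raise ValueError("smr_true must be below mmr_true")
        if not self.loehyp_true < self.pcrit_true:
            raise ValueError("loehyp_true must lie below pcrit_true")
        if self.tpeak_true > self.tarr_true:
            raise ValueError("tpeak_true must not exceed tarr_true")
        return self

    @property
    def epoc_true(self) -> float:
        """Closed-form excess integral of the recovery curve (mg O2/kg).

        The excess (mmr-smr)*exp(-k t) integrates to
        ((mmr-smr) - 0.1*smr)/k between t=0 and the crossing of
        1.1*smr, i.e. where the excess equals 0.1*smr.
        """
        return ((self.mmr_true - self.smr_true) - 0.1 * self.smr_true) / self.recovery_k


@dataclass
class CycleProtocol:
    """Flush / stabilization / measurement timing of an intermittent-flow trial.

    Durations in seconds.  The short recovery cycle runs immediately after
    the chase; the routine cycle carries the diurnal SMR record.
    """

    recovery_cycle: tuple[float, float, float] = (20.0, 40.0, 120.0)
    routine_cycle: tuple[float, float, float] = (90.0, 95.0, 360.0)
    recovery_duration_s: float = 3.0 * 3600.0
    total_duration_s: float = 48.0 * 3600.0

    def __post_init__(self) -> None:
        for cyc in (self.recovery_cycle, self.routine_cycle):
            if any(d <= 0 for d in cyc):
                raise ValueError(f"non-positive phase duration in cycle {cyc}")

    def phase_plan(self, duration_s: float | None = None) -> list[tuple[str, float]]:
        """Expanded (phase label, duration) sequence covering the trial."""
        total = self.total_duration_s if duration_s is None else duration_s
        plan: list[tuple[str, float]] = []
        t = 0.0
        while t < total:
            cyc = self.recovery_cycle if t < self.recovery_duration_s else self.routine_cycle
            for label, dur in zip(("flush", "stabilization", "measurement"), cyc):
                plan.append((label, dur))
                t += dur
            if t > 10 * 24 * 3600:  # guard against runaway protocols
                break
        return plan


@dataclass
class HypoxiaRampSpec:
    """Two-rate bath deoxygenation for the terminal P_crit / LOE_hyp phase."""

    fast_drawdown_s: float = 45.0 * 60.0
    slow_rate_sat_per_min: float = 0.15
    start_sat: float = 100.0


def default_config(
    chamber_id: str = "ch1",
    mass_kg: float = 0.05,
    temp_c: float = 18.0,
    volume_ratio: float = 50.0,
) -> RespirometerConfig:
    """Chamber sized to the default simulated fish (50:1 water:mass ratio)."""
    return RespirometerConfig.for_fish(chamber_id, mass_kg, temp_c, volume_ratio)


def _mo2_truth(truth: TrialTruth, t_s: np.ndarray) -> np.ndarray:
    """True instantaneous MO2 (mg O2/h/kg) at seconds-since-sealing ``t_s``.

    SMR is the floor of the diel cycle: routine activity elevates MO2 by a
    non-negative sinusoid (zero at trial start, peak ``diel_amplitude``),
    and the post-exhaustion excess decays exponentially on top of it.
    """
    t_h = np.asarray(t_s, dtype=float) / 3600.0
    diel = 0.5 * (1.0 + np.sin(2.0 * np.pi * t_h / DIEL_PERIOD_H - 0.5 * np.pi))
    excess = (truth.mmr_true - truth.smr_true) * np.exp(-truth.recovery_k * t_h)
    return truth.smr_true * (1.0 + truth.diel_amplitude * diel) + excess


def _sat_decline_per_s(mo2: np.ndarray, config: RespirometerConfig) -> np.ndarray:
    """% air sat lost per second in a sealed chamber at uptake ``mo2``."""
    return (
        np.asarray(mo2)
        * config.M_f
        * 100.0
        / (config.S_o * (config.V_r - config.V_f) * config.t_const)
    )


def _washout_rate(flush_s: float) -> float:
    # >= 99% bath equilibration within the flush duration
    return -math.log(0.01) / flush_s


def _simulate_chamber(
    config: RespirometerConfig,
    mo2_of_t,
    plan: list[tuple[str, float]],
    bath_of_t,
    rng: np.random.Generator,
    noise_sd: float,
    t0: float = 0.0,
    p0: float | None = None,
) -> PO2Trace:
    """Integrate chamber PO2 through a flush/stab/measurement plan.

    ``mo2_of_t(t_s, po2)`` may depend on chamber PO2 (oxyconformity);
    ``bath_of_t(t_s)`` gives the bath saturation the flush pulls toward.
    """
    dt = 1.0 / config.sampling_hz
    times: list[np.ndarray] = []
    po2s: list[np.ndarray] = []
    phases: list[np.ndarray] = []
    t = t0
    p = float(bath_of_t(t0)) if p0 is None else p0
    for label, dur in plan:
        n = max(int(round(dur * config.sampling_hz)), 1)
        tt = t + dt * np.arange(1, n + 1)
        if label == "flush":
            bath = bath_of_t(tt)
            r = _washout_rate(dur)
            pp = bath + (p - bath) * np.exp(-r * (tt - t))
        elif getattr(mo2_of_t, "state_dependent", False):
            # Euler integration when uptake depends on chamber PO2
            pp = np.empty(n)
            cur = p
            for k in range(n):
                rate = _sat_decline_per_s(mo2_of_t(tt[k], cur), config)
                cur = cur - float(rate) * dt
                pp[k] = cur
        else:
            rate = _sat_decline_per_s(mo2_of_t(tt, p), config)
            pp = p - np.cumsum(rate * dt)
        times.append(tt)
        po2s.append(np.maximum(pp, 0.0))
        phases.append(np.full(n, label, dtype=object))
        t = tt[-1]
        p = float(pp[-1])
    time_s = np.concatenate(times)
    po2 = np.concatenate(po2s)
    if noise_sd > 0:
        po2 = po2 + rng.normal(0.0, noise_sd, size=po2.size)
    po2 = np.clip(po2, 0.0, 110.0)
    return PO2Trace(
        chamber_id=config.chamber_id,
        time_s=time_s,
        po2=po2,
        temp_c=np.full(time_s.size, _bath_temp(bath_of_t)),
        phase=np.concatenate(phases),
    )


def _bath_temp(bath_of_t) -> float:
    return getattr(bath_of_t, "temp_c", 18.0)


def simulate_irap_trial(
    config: RespirometerConfig,
    truth: TrialTruth,
    protocol: CycleProtocol | None = None,
) -> tuple[PO2Trace, PO2Trace, TrialTruth]:
    """Simulate a full chase-to-exhaustion intermittent-flow trial.

    Returns the fish trace, the empty-chamber (blank) trace carrying
    ``background_rate * smr_true``, and the truth object.
    """
    protocol = protocol or CycleProtocol()
    rng = np.random.default_rng(truth.seed)
    plan = protocol.phase_plan()

    def bath(t):
        return np.full_like(np.asarray(t, dtype=float), 100.0)

    bath.temp_c = truth.accl_temp_c

    background = truth.background_rate * truth.smr_true

    def fish_mo2(t, _p):
        # the fish chamber carries the same microbial background as the blank
        return _mo2_truth(truth, t) + background

    trace = _simulate_chamber(config, fish_mo2, plan, bath, rng, truth.noise_sd)

    def blank_mo2(t, _p):
        return np.full_like(np.asarray(t, dtype=float), background)

    blank = _simulate_chamber(config, blank_mo2, plan, rng=rng, bath_of_t=bath, noise_sd=truth.noise_sd)
    blank.chamber_id = config.chamber_id + "_blank"
    blank.is_blank = True
    return trace, blank, truth


def simulate_hypoxia_phase(
    config: RespirometerConfig,
    truth: TrialTruth,
    ramp: HypoxiaRampSpec | None = None,
    protocol: CycleProtocol | None = None,
    start_time_s: float = 0.0,
) -> PO2Trace:
    """Continue a trial into the terminal progressive-hypoxia phase.

    The bath is drawn down fast to ~2x the true P_crit over
    ``fast_drawdown_s``, then slowly at ``slow_rate_sat_per_min`` until it
    reaches the true LOE_hyp, where the trial ends.  Above P_crit the fish
    oxyregulates at its routine rate (``hypoxia_routine_factor * smr_true``,
    default 10% above SMR — the progressive-hypoxia record must start above
    SMR for the onset count to be meaningful); below P_crit it suppresses
    to the standard rate and conforms along the line through the origin
    that reaches SMR at P_crit.
    """
    ramp = ramp or HypoxiaRampSpec()
    protocol = protocol or CycleProtocol()
    rng = np.random.default_rng(truth.seed + 1)
    knee = 2.0 * truth.pcrit_true
    fast_rate = (ramp.start_sat - knee) / ramp.fast_drawdown_s  # %sat per s
    slow_rate = ramp.slow_rate_sat_per_min / 60.0
    slow_dur = (knee - truth.loehyp_true) / slow_rate
    total = ramp.fast_drawdown_s + slow_dur

    def bath(t):
        tt = np.asarray(t, dtype=float) - start_time_s
        fast = ramp.start_sat - fast_rate * tt
        slow = knee - slow_rate * (tt - ramp.fast_drawdown_s)
        return np.maximum(np.where(tt <= ramp.fast_drawdown_s, fast, slow), truth.loehyp_true)

    bath.temp_c = truth.accl_temp_c

    def fish_mo2(t, p):
        if p > truth.pcrit_true:
            return truth.smr_true * truth.hypoxia_routine_factor
        return truth.smr_true * max(p, 0.0) / truth.pcrit_true

    fish_mo2.state_dependent = True

    # routine cycles until the bath reaches LOE_hyp
    plan: list[tuple[str, float]] = []
    t = 0.0
    while t < total:
        for label, dur in zip(("flush", "stabilization", "measurement"), protocol.routine_cycle):
            plan.append((label, dur))
            t += dur
        if t > total + sum(protocol.routine_cycle):
            break
    return _simulate_chamber(
        config, fish_mo2, plan, bath, rng, truth.noise_sd, t0=start_time_s
    )


def simulate_tolerance_ramp(
    mode: str,
    truth: TrialTruth,
    thermal_rate_c_per_min: float = 0.1,
    thermal_start_c: float = 18.0,
    hypoxia_fast_rate: float = 1.5,
    hypoxia_slow_rate: float = 0.1,
    hypoxia_start_sat: float = 90.0,
    hypoxia_knee_sat: float = 20.0,
    sample_dt_s: float = 1.0,
    fish_id: str = "fish1",
) -> RampRecord:
    """Generate a tolerance ramp ending at the true endpoint.

    Thermal mode warms at 0.1 degC/min until CT_max; hypoxia mode
    deoxygenates at ~1.5% air sat/min to ~20% then 0.1%/min until LOE_hyp.
    The LOE flag is raised at the first sample crossing the true endpoint.
    """
    if mode == "thermal":
        if truth.ctmax_true <= thermal_start_c:
            raise ValueError("ctmax_true below the ramp start temperature")
        dur = (truth.ctmax_true - thermal_start_c) / (thermal_rate_c_per_min / 60.0)
        t = np.arange(0.0, dur + sample_dt_s, sample_dt_s)
        driver = thermal_start_c + (thermal_rate_c_per_min / 60.0) * t
        idx = int(np.argmax(driver >= truth.ctmax_true))
    elif mode == "hypoxia":
        if not (hypoxia_knee_sat > truth.loehyp_true):
            raise ValueError("loehyp_true above the slow-phase start")
        fast_dur = (hypoxia_start_sat - hypoxia_knee_sat) / (hypoxia_fast_rate / 60.0)
        slow_dur = (hypoxia_knee_sat - truth.loehyp_true) / (hypoxia_slow_rate / 60.0)
        t = np.arange(0.0, fast_dur + slow_dur + sample_dt_s, sample_dt_s)
        driver = np.where(
            t <= fast_dur,
            hypoxia_start_sat - (hypoxia_fast_rate / 60.0) * t,
            hypoxia_knee_sat - (hypoxia_slow_rate / 60.0) * (t - fast_dur),
        )
        idx = int(np.argmax(driver <= truth.loehyp_true))
    else:
        raise ValueError(f"unknown ramp mode {mode!r}")
    t = t[: idx + 1]
    driver = driver[: idx + 1]
    return RampRecord(
        fish_id=fish_id,
        mode=mode,  # type: ignore[arg-type]
        time_s=t,
        driver=driver,
        loe_time_s=float(t[idx]),
        accl_temp_c=truth.accl_temp_c,
        test_temp_c=truth.accl_temp_c if mode == "hypoxia" else None,
    )


def default_step_schedule(
    start_temp_c: float = 12.0, end_temp_c: float = 30.0, step_s: float = 360.0
) -> list[tuple[float, float]]:
    """1 degC / 6 min stepped-warming schedule starting at 12 degC."""
    n = int(round(end_temp_c - start_temp_c)) + 1
    return [(i * step_s, start_temp_c + i) for i in range(n)]


def simulate_cardiac_trial(
    truth: TrialTruth,
    schedule: list[tuple[float, float]] | None = None,
    step_duration_s: float = 360.0,
    rr_jitter_cv: float = 0.03,
    decline_bpm_per_c: float = 8.0,
    arrhythmia_gap_every: int = 8,
    arrhythmia_gap_scale: float = 2.2,
    fish_id: str = "fish1",
) -> BeatSeries:
    """Generate heartbeat timestamps under stepped warming.

    The instantaneous rate follows f(T) = f12 * Q10^((T-12)/10) up to
    T_peak, declining linearly beyond.  RR intervals carry small
    multiplicative jitter; at and beyond the true T_arr every
    ``arrhythmia_gap_every``-th beat is dropped, stretching its RR by
    ``arrhythmia_gap_scale`` (a skipped-beat arrhythmia).
    """
    if schedule is None:
        schedule = default_step_schedule(12.0, max(30.0, math.ceil(truth.tarr_true) + 2))
    if schedule[0][1] != 12.0:
        raise ValueError("cardiac schedule must start at 12 degC")
    rng = np.random.default_rng(truth.seed + 2)
    starts = np.array([s for s, _ in schedule])
    temps = np.array([T for _, T in schedule])
    t_end = starts[-1] + step_duration_s

    def temp_at(t: float) -> float:
        return float(temps[np.searchsorted(starts, t, side="right") - 1])

    def rate_bpm(T: float) -> float:
        f = truth.fh12_true * truth.q10_true ** ((min(T, truth.tpeak_true) - 12.0) / 10.0)
        if T > truth.tpeak_true:
            f -= decline_bpm_per_c * (T - truth.tpeak_true)
        return max(f, 20.0)

    beats: list[float] = []
    t = 0.0
    n_since_gap = 0
    while t < t_end:
        T = temp_at(t)
        rr = 60.0 / rate_bpm(T)
        if rr_jitter_cv > 0:
            rr *= math.exp(rng.normal(0.0, rr_jitter_cv))
        if T >= truth.tarr_true:
            n_since_gap += 1
            if n_since_gap >= arrhythmia_gap_every:
                rr *= arrhythmia_gap_scale
                n_since_gap = 0
        t += rr
        if t < t_end:
            beats.append(t)
    return BeatSeries(
        fish_id=fish_id,
        beat_times_s=np.array(beats),
        step_schedule=[(float(s), float(T)) for s, T in schedule],
        step_duration_s=step_duration_s,
    )
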