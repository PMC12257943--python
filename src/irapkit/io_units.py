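"""Physical constants, oxygen unit conversions and typed trace I/O.

All trace files are UTF-8 CSV with a mandatory header row, long format,
times in seconds from trial start.  Oxygen is carried as % air saturation
throughout the package and converted to kPa only at reporting boundaries.

Conventions (documented here because the field has no single standard):

* Water vapour pressure ``p_H2O(T)`` uses the Arden Buck (1981) fit for
  water above 0 degC::

      p_H2O = 0.61121 * exp((18.678 - T/234.5) * (T / (257.14 + T)))   [kPa]

* Freshwater oxygen solubility at 100% air saturation uses the
  Benson-Krause empirical fit (the USGS form), valid 0-40 degC, giving
  mg O2 / L at 101.325 kPa, scaled proportionally with barometric
  pressure.  Salinity is fixed at zero.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

__all__ = [
    "STANDARD_PRESSURE_KPA",
    "O2_MOLE_FRACTION",
    "RespirometerConfig",
    "PO2Trace",
    "RampRecord",
    "BeatSeries",
    "TraceParseError",
    "water_vapour_pressure_kpa",
    "o2_solubility",
    "percent_sat_to_kpa",
    "kpa_to_percent_sat",
    "read_trace",
    "read_po2_trace",
    "read_ramp_record",
    "read_beat_series",
    "write_po2_trace",
    "write_ramp_record",
    "write_beat_series",
    "read_config",
    "write_config",
]

STANDARD_PRESSURE_KPA = 101.325
#: mole fraction of O2 in dry air
O2_MOLE_FRACTION = 0.2095

PHASES = ("flush", "stabilization", "measurement")


class TraceParseError(ValueError):
    """Raised when a trace file violates the schema or a type invariant."""


# ---------------------------------------------------------------------------
# physical conversions
# ---------------------------------------------------------------------------

def water_vapour_pressure_kpa(temp_c: float) -> float:
    """Saturation vapour pressure of water (kPa), Arden Buck (1981) fit."""
    t = np.asarray(temp_c, dtype=float)
    return 0.61121 * np.exp((18.678 - t / 234.5) * (t / (257.14 + t)))


def o2_solubility(temp_c: float, pressure_kpa: float = STANDARD_PRESSURE_KPA) -> float:
    """Freshwater O2 solubility at 100% air saturation (mg O2 / L).

    Benson-Krause fit at 101.325 kPa, scaled proportionally with
    barometric pressure.  Valid for 0 < ``temp_c`` < 40.
    """
    t = np.asarray(temp_c, dtype=float)
    if np.any(t <= 0.0) or np.any(t >= 40.0):
        raise ValueError(f"temperature {temp_c!r} degC outside the (0, 40) fit range")
    tk = t + 273.15
    ln_do = (
        -139.34411
        + 1.575701e5 / tk
        - 6.642308e7 / tk**2
        + 1.243800e10 / tk**3
        - 8.621949e11 / tk**4
    )
    do_1atm = np.exp(ln_do)
    return do_1atm * (pressure_kpa / STANDARD_PRESSURE_KPA)


def percent_sat_to_kpa(
    sat: float, temp_c: float, pressure_kpa: float = STANDARD_PRESSURE_KPA
) -> float:
    """Convert oxygen level from % air saturation to partial pressure (kPa).

    PO2 = (sat/100) * 0.2095 * (P_bar - p_H2O(T)); air saturation is defined
    against air equilibrated with water, hence the vapour-pressure correction.
    """
    s = np.asarray(sat, dtype=float)
    if np.any(s < 0):
        raise ValueError("negative % air saturation")
    return s / 100.0 * O2_MOLE_FRACTION * (pressure_kpa - water_vapour_pressure_kpa(temp_c))


def kpa_to_percent_sat(
    po2_kpa: float, temp_c: float, pressure_kpa: float = STANDARD_PRESSURE_KPA
) -> float:
    """Inverse of :func:`percent_sat_to_kpa`."""
    p = np.asarray(po2_kpa, dtype=float)
    if np.any(p < 0):
        raise ValueError("negative oxygen partial pressure")
    return p * 100.0 / (O2_MOLE_FRACTION * (pressure_kpa - water_vapour_pressure_kpa(temp_c)))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

class RespirometerConfig(BaseModel):
    """Geometry and physics of one respirometry chamber.

    ``V_f`` is estimated from body mass assuming neutral density
    (1 g = 1 mL); ``S_o`` is the O2 solubility at the trial temperature
    and pressure; ``t_const`` converts per-second slopes to per-hour rates.
    """

    chamber_id: str
    V_r: float = Field(gt=0, description="respirometer volume (L)")
    V_f: float = Field(gt=0, description="fish volume (L)")
    M_f: float = Field(gt=0, description="fish body mass (kg)")
    S_o: float = Field(gt=0, description="O2 solubility (mg O2/L at 100% air sat)")
    t_const: float = 3600.0
    pressure_kpa: float = STANDARD_PRESSURE_KPA
    sampling_hz: float = Field(default=1.0, gt=0)

    @model_validator(mode="after")
    def _check_volumes(self) -> "RespirometerConfig":
        if not self.V_r > self.V_f:
            raise ValueError(
                f"respirometer volume V_r={self.V_r} must exceed fish volume V_f={self.V_f}"
            )
        return self

    @classmethod
    def for_fish(
        cls,
        chamber_id: str,
        mass_kg: float,
        temp_c: float,
        volume_ratio: float = 50.0,
        pressure_kpa: float = STANDARD_PRESSURE_KPA,
        sampling_hz: float = 1.0,
    ) -> "RespirometerConfig":
        """Build a config from body mass using a water-volume:fish-mass ratio."""
        v_f = mass_kg  # 1 kg = 1 L at neutral density
        return cls(
            chamber_id=chamber_id,
            V_r=volume_ratio * mass_kg,
            V_f=v_f,
            M_f=mass_kg,
            S_o=float(o2_solubility(temp_c, pressure_kpa)),
            pressure_kpa=pressure_kpa,
            sampling_hz=sampling_hz,
        )


def _require_strictly_increasing(t: np.ndarray, what: str) -> None:
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        k = int(bad[0]) + 1
        raise TraceParseError(f"{what} not strictly increasing at row {k} (t={t[k]!r})")


@dataclass
class PO2Trace:
    """A timestamped per-chamber oxygen / temperature / phase series."""

    chamber_id: str
    time_s: np.ndarray
    po2: np.ndarray
    temp_c: np.ndarray
    phase: np.ndarray  # str array with values in PHASES
    is_blank: bool = False

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.po2 = np.asarray(self.po2, dtype=float)
        self.temp_c = np.asarray(self.temp_c, dtype=float)
        self.phase = np.asarray(self.phase, dtype=object)
        n = self.time_s.size
        if not (self.po2.size == self.temp_c.size == self.phase.size == n):
            raise TraceParseError("trace columns have unequal lengths")
        if n == 0:
            raise TraceParseError("empty trace")
        _require_strictly_increasing(self.time_s, "time_s")
        bad = np.nonzero((self.po2 < 0) | (self.po2 > 110))[0]
        if bad.size:
            k = int(bad[0])
            raise TraceParseError(f"po2 {self.po2[k]} out of [0, 110] at row {k}")
        unknown = set(self.phase) - set(PHASES)
        if unknown:
            k = int(np.nonzero(np.isin(self.phase, list(unknown)))[0][0])
            raise TraceParseError(f"unknown phase label {self.phase[k]!r} at row {k}")

    def __len__(self) -> int:
        return int(self.time_s.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chamber_id": self.chamber_id,
                "time_s": self.time_s,
                "po2_percent_sat": self.po2,
                "temp_c": self.temp_c,
                "phase": self.phase,
                "is_blank": int(self.is_blank),
            }
        )

    def phase_runs(self) -> list[tuple[str, int, int]]:
        """Contiguous phase runs as ``(label, start_index, stop_index)`` (half-open)."""
        runs: list[tuple[str, int, int]] = []
        start = 0
        for k in range(1, len(self) + 1):
            if k == len(self) or self.phase[k] != self.phase[start]:
                runs.append((str(self.phase[start]), start, k))
                start = k
        return runs


@dataclass
class RampRecord:
    """A temperature (thermal mode) or oxygen (hypoxia mode) ramp ending in LOE.

    ``driver`` is degC in thermal mode, % air saturation in hypoxia mode.
    """

    fish_id: str
    mode: Literal["thermal", "hypoxia"]
    time_s: np.ndarray
    driver: np.ndarray
    loe_time_s: float
    accl_temp_c: float
    test_temp_c: float | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.driver = np.asarray(self.driver, dtype=float)
        if self.mode not in ("thermal", "hypoxia"):
            raise TraceParseError(f"unknown ramp mode {self.mode!r}")
        if self.time_s.size != self.driver.size or self.time_s.size == 0:
            raise TraceParseError("ramp columns empty or of unequal length")
        _require_strictly_increasing(self.time_s, "time_s")
        if not (self.time_s[0] <= self.loe_time_s <= self.time_s[-1]):
            raise TraceParseError(
                f"loe_time_s={self.loe_time_s} outside trace span "
                f"[{self.time_s[0]}, {self.time_s[-1]}]"
            )
        # the ramp must be monotone in the intended direction up to tolerance
        d = np.diff(self.driver)
        tol = 1e-9 + 0.05 * (np.abs(d).max() if d.size else 0.0)
        if self.mode == "thermal" and np.any(d < -tol):
            raise TraceParseError("thermal ramp driver must be non-decreasing")
        if self.mode == "hypoxia" and np.any(d > tol):
            raise TraceParseError("hypoxia ramp driver must be non-increasing")


@dataclass
class BeatSeries:
    """Detected heartbeat timestamps under a stepped-warming schedule.

    ``step_schedule`` lists ``(step_start_s, step_temp_c)`` for the
    1 degC / 6 min increments, temperatures strictly increasing by 1 degC.
    """

    fish_id: str
    beat_times_s: np.ndarray
    step_schedule: list[tuple[float, float]]
    step_duration_s: float = 360.0

    def __post_init__(self) -> None:
        self.beat_times_s = np.asarray(self.beat_times_s, dtype=float)
        if self.beat_times_s.size:
            _require_strictly_increasing(self.beat_times_s, "beat_times_s")
        temps = np.array([t for _, t in self.step_schedule], dtype=float)
        if temps.size < 1:
            raise TraceParseError("empty step schedule")
        if temps.size > 1 and not np.allclose(np.diff(temps), 1.0, atol=1e-9):
            raise TraceParseError("schedule temperatures must increase by exactly 1 degC")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_TRACE_COLUMNS = ["chamber_id", "time_s", "po2_percent_sat", "temp_c", "phase", "is_blank"]
_RAMP_COLUMNS = ["fish_id", "mode", "time_s", "driver", "accl_temp_c", "test_temp_c", "loe"]
_BEAT_COLUMNS = ["fish_id", "beat_time_s"]


def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TraceParseError(f"{path.name}: missing column(s) {missing}")
    return df


def read_po2_trace(path: str | Path) -> PO2Trace:
    df = _read_csv(path, _TRACE_COLUMNS)
    chambers = df["chamber_id"].unique()
    if len(chambers) != 1:
        raise TraceParseError(
            f"expected a single chamber per trace file, found {list(chambers)}"
        )
    return PO2Trace(
        chamber_id=str(chambers[0]),
        time_s=df["time_s"].to_numpy(),
        po2=df["po2_percent_sat"].to_numpy(),
        temp_c=df["temp_c"].to_numpy(),
        phase=df["phase"].to_numpy(),
        is_blank=bool(df["is_blank"].iloc[0]),
    )


def write_po2_trace(trace: PO2Trace, path: str | Path) -> None:
    # %.17g keeps doubles bit-exact through the text round trip
    trace.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_ramp_record(path: str | Path) -> RampRecord:
    df = _read_csv(path, _RAMP_COLUMNS)
    fish = df["fish_id"].unique()
    if len(fish) != 1:
        raise TraceParseError(f"expected a single fish per ramp file, found {list(fish)}")
    loe_rows = df.index[df["loe"] == 1].tolist()
    if len(loe_rows) != 1:
        raise TraceParseError(f"expected exactly one LOE event, found {len(loe_rows)}")
    test_temp = df["test_temp_c"].iloc[0]
    return RampRecord(
        fish_id=str(fish[0]),
        mode=str(df["mode"].iloc[0]),
        time_s=df["time_s"].to_numpy(),
        driver=df["driver"].to_numpy(),
        loe_time_s=float(df.loc[loe_rows[0], "time_s"]),
        accl_temp_c=float(df["accl_temp_c"].iloc[0]),
        test_temp_c=None if pd.isna(test_temp) else float(test_temp),
    )


def write_ramp_record(ramp: RampRecord, path: str | Path) -> None:
    loe = np.zeros(len(ramp.time_s), dtype=int)
    loe[int(np.argmin(np.abs(ramp.time_s - ramp.loe_time_s)))] = 1
    pd.DataFrame(
        {
            "fish_id": ramp.fish_id,
            "mode": ramp.mode,
            "time_s": ramp.time_s,
            "driver": ramp.driver,
            "accl_temp_c": ramp.accl_temp_c,
            "test_temp_c": np.nan if ramp.test_temp_c is None else ramp.test_temp_c,
            "loe": loe,
        }
    ).to_csv(path, index=False, float_format="%.17g")


def read_beat_series(path: str | Path, schedule_path: str | Path) -> BeatSeries:
    df = _read_csv(path, _BEAT_COLUMNS)
    fish = df["fish_id"].unique()
    if len(fish) != 1:
        raise TraceParseError(f"expected a single fish per beat file, found {list(fish)}")
    with open(schedule_path) as fh:
        sched = json.load(fh)
    return BeatSeries(
        fish_id=str(fish[0]),
        beat_times_s=df["beat_time_s"].to_numpy(),
        step_schedule=[(float(s), float(t)) for s, t in sched["steps"]],
        step_duration_s=float(sched.get("step_duration_s", 360.0)),
    )


def write_beat_series(beats: BeatSeries, path: str | Path, schedule_path: str | Path) -> None:
    pd.DataFrame({"fish_id": beats.fish_id, "beat_time_s": beats.beat_times_s}).to_csv(
        path, index=False, float_format="%.17g"
    )
    with open(schedule_path, "w") as fh:
        json.dump(
            {"steps": list(beats.step_schedule), "step_duration_s": beats.step_duration_s},
            fh,
            indent=2,
        )


def read_trace(path: str | Path, schema: str, **kwargs):
    """Dispatch to the typed reader for ``schema`` in {'po2', 'ramp', 'beats'}."""
    readers = {"po2": read_po2_trace, "ramp": read_ramp_record, "beats": read_beat_series}
    if schema not in readers:
        raise ValueError(f"unknown trace schema {schema!r}; expected one of {list(readers)}")
    return readers[schema](path, **kwargs)


def read_config(path: str | Path) -> RespirometerConfig:
    with open(path) as fh:
        return RespirometerConfig.model_validate(json.load(fh))


def write_config(config: RespirometerConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(config.model_dump_json(indent=2))
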