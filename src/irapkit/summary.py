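"""SMR, AAS and EPOC from an oxygen-uptake series, and mass-centred means.

SMR is the 20% quantile (linear-interpolation convention) of MO2 values
recorded after a 12-h post-handling recovery period; AAS = MMR - SMR; EPOC
is the time-weighted integral of MO2 above SMR from chamber sealing until
MO2 first returns to within 10% of SMR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .mo2 import MO2Series, detect_mmr

__all__ = [
    "MetabolicSummary",
    "estimate_smr",
    "compute_epoc",
    "mass_adjusted_means",
    "summarize_trial",
]


@dataclass
class MetabolicSummary:
    fish_id: str
    smr: float  # mg O2 / h / kg
    mmr: float
    aas: float
    epoc: float  # mg O2 / kg
    n_smr_values: int
    epoc_end_time_s: float
    mass_kg: float

    def __post_init__(self) -> None:
        assert self.aas == self.mmr - self.smr, "AAS identity violated"


def estimate_smr(
    series: MO2Series, exclude_first_h: float = 12.0, quantile_p: float = 0.2
) -> tuple[float, int]:
    """20% quantile of post-recovery MO2 values; returns ``(smr, n_values)``.

    The first ``exclude_first_h`` hours are discarded as a handling/exercise
    recovery period.  A warning is raised when fewer than 200 values remain
    (the count below which the quantile becomes unreliable).
    """
    cutoff = exclude_first_h * 3600.0
    vals = np.array(
        [w.mo2 for w in series.windows if not w.excluded and w.mid_time_s > cutoff]
    )
    if vals.size == 0:
        raise ValueError(
            f"no usable MO2 values after excluding the first {exclude_first_h} h"
        )
    if vals.size < 200:
        warnings.warn(
            f"only {vals.size} MO2 values enter the SMR quantile (<200)", stacklevel=2
        )
    return float(np.quantile(vals, quantile_p)), int(vals.size)


def _window_dt_hours(mids: np.ndarray) -> np.ndarray:
    """Cycle period represented by each window, from midpoint boundaries.

    Boundaries are placed halfway between consecutive window midpoints
    (trapezoid-style), so skipped low-R^2 windows hand their time to their
    retained neighbours instead of being dropped from the integral.
    """
    if mids.size == 1:
        return np.array([0.0])
    bounds = np.empty(mids.size + 1)
    bounds[1:-1] = 0.5 * (mids[:-1] + mids[1:])
    bounds[0] = mids[0] - 0.5 * (mids[1] - mids[0])
    bounds[-1] = mids[-1] + 0.5 * (mids[-1] - mids[-2])
    return np.diff(bounds) / 3600.0


def compute_epoc(
    series: MO2Series,
    smr: float,
    threshold_factor: float = 1.1,
    duration_weighted: bool = True,
) -> tuple[float, float]:
    """Excess post-exercise oxygen consumption (mg O2/kg) and its end time.

    Integrates ``mo2 - smr`` over successive windows from chamber sealing
    until the first window at or below ``threshold_factor * smr`` (that
    window excluded).  With ``duration_weighted`` each window contributes
    its represented cycle period; otherwise windows count as unit hours.
    """
    wins = [w for w in series.windows if not w.excluded]
    if not wins:
        raise ValueError("no usable windows for EPOC")
    if wins[0].mo2 <= threshold_factor * smr:
        warnings.warn(
            "series starts at/below the recovery threshold; EPOC = 0", stacklevel=2
        )
        return 0.0, wins[0].mid_time_s
    mo2 = np.array([w.mo2 for w in wins])
    mids = np.array([w.mid_time_s for w in wins])
    below = np.nonzero(mo2 <= threshold_factor * smr)[0]
    stop = int(below[0]) if below.size else mo2.size
    dt_h = (
        _window_dt_hours(mids)[:stop] if duration_weighted else np.ones(stop)
    )
    epoc = float(np.sum((mo2[:stop] - smr) * dt_h))
    end_time = float(mids[stop] if stop < mids.size else mids[-1])
    return max(epoc, 0.0), end_time


def mass_adjusted_means(
    values: np.ndarray,
    masses: np.ndarray,
    groups: np.ndarray,
    common_mass_kg: float | None = None,
) -> pd.DataFrame:
    """Per-group means adjusted to a common body mass (allometric ANCOVA).

    Fits log10(value) on log10(mass) with additive group offsets (common
    allometric slope), then predicts each group at ``common_mass_kg``
    (default: geometric mean of all masses).  Returns a frame with the
    back-transformed adjusted mean, its SE on the log10 scale, and the
    fitted common slope.  With no mass variation the slope is unidentifiable
    and is dropped with a warning, reducing to group geometric means.
    """
    values = np.asarray(values, dtype=float)
    masses = np.asarray(masses, dtype=float)
    groups = np.asarray(groups)
    if np.any(masses <= 0) or np.any(values <= 0):
        raise ValueError("values and masses must be positive for log transformation")
    labels = pd.unique(groups)
    if labels.size < 2:
        raise ValueError("need at least 2 groups")
    log_v = np.log10(values)
    log_m = np.log10(masses)
    if common_mass_kg is None:
        common_mass_kg = float(10 ** log_m.mean())
    dummies = pd.get_dummies(pd.Categorical(groups, categories=labels), dtype=float)
    use_slope = not np.allclose(log_m, log_m[0])
    if not use_slope:
        warnings.warn("all masses equal; allometric slope dropped", stacklevel=2)
        X = dummies.to_numpy()
    else:
        X = np.column_stack([dummies.to_numpy(), log_m - np.log10(common_mass_kg)])
    fit = sm.OLS(log_v, X).fit()
    out = []
    for j, lab in enumerate(labels):
        x0 = np.zeros(X.shape[1])
        x0[j] = 1.0  # centred covariate -> prediction at the common mass
        pred = fit.get_prediction(x0)
        out.append(
            {
                "group": lab,
                "adjusted_mean": float(10 ** pred.predicted_mean[0]),
                "se_log10": float(pred.se_mean[0]),
                "common_mass_kg": common_mass_kg,
                "allometric_slope": float(fit.params[-1]) if use_slope else np.nan,
            }
        )
    return pd.DataFrame(out)


def summarize_trial(
    series: MO2Series,
    mass_kg: float,
    exclude_first_h: float = 12.0,
    quantile_p: float = 0.2,
    threshold_factor: float = 1.1,
    mmr_horizon_s: float = 3600.0,
) -> MetabolicSummary:
    """Full per-fish metabolic summary from a background-corrected series."""
    smr, n_smr = estimate_smr(series, exclude_first_h, quantile_p)
    mmr, _ = detect_mmr(series, mmr_horizon_s)
    epoc, epoc_end = compute_epoc(series, smr, threshold_factor)
    return MetabolicSummary(
        fish_id=series.fish_id,
        smr=smr,
        mmr=mmr,
        aas=mmr - smr,
        epoc=epoc,
        n_smr_values=n_smr,
        epoc_end_time_s=epoc_end,
        mass_kg=mass_kg,
    )
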