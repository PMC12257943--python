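"""Critical oxygen tension (P_crit) and acclimation effects on LOE_hyp.

P_crit is the minimum ambient oxygen tension at which SMR can be sustained
aerobically.  Two estimators are provided:

* ``smr_intersection`` (default): fit a line to the oxyconforming points
  (the consecutive lowest-PO2 windows whose MO2 has fallen below SMR) and
  report the PO2 where that line reaches SMR.
* ``broken_stick``: exhaustive two-segment least squares over all hypoxia
  windows; the breakpoint minimising total residual sum of squares.

Protocol validity requires at least 10 MO2 points recorded before MO2
first fell below SMR; the result carries that count and a validity flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_units import percent_sat_to_kpa
from .mo2 import MO2Series

__all__ = ["PcritResult", "estimate_pcrit", "acclimation_improvement"]


@dataclass
class PcritResult:
    pcrit: float  # % air saturation
    pcrit_kpa: float
    method: str
    n_points_below_smr_onset: int
    valid: bool  # >= 10 points before MO2 fell below SMR
    regulation_slope: float
    conformity_slope: float
    conformity_intercept: float


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept and RSS of y ~ x."""
    xc = x - x.mean()
    denom = float(xc @ xc)
    slope = float(xc @ (y - y.mean())) / denom if denom > 0 else 0.0
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (slope * x + intercept)
    return slope, intercept, float(resid @ resid)


def _broken_stick(po2: np.ndarray, mo2: np.ndarray) -> float:
    """PO2 at the RSS-optimal two-segment breakpoint (segments >= 2 points).

    The reported breakpoint is the intersection of the two fitted segment
    lines (the conventional broken-stick output); when the lines are
    parallel the boundary midpoint is used.
    """
    order = np.argsort(po2)
    x, y = po2[order], mo2[order]
    best_rss, best_bp = np.inf, None
    for k in range(2, x.size - 1):  # k points in the low segment
        s_lo, i_lo, rss_lo = _ols(x[:k], y[:k])
        s_hi, i_hi, rss_hi = _ols(x[k:], y[k:])
        if rss_lo + rss_hi < best_rss:
            best_rss = rss_lo + rss_hi
            if s_lo != s_hi:
                best_bp = (i_hi - i_lo) / (s_lo - s_hi)
            else:
                best_bp = 0.5 * (x[k - 1] + x[k])
    if best_bp is None:
        raise ValueError("too few windows for a broken-stick fit")
    return float(best_bp)


def estimate_pcrit(
    series: MO2Series,
    smr: float,
    method: str = "smr_intersection",
    temp_c: float = 18.0,
    min_conforming: int = 3,
) -> PcritResult:
    """Estimate P_crit from the progressive-hypoxia windows of ``series``.

    Windows are taken in declining-PO2 order.  ``smr`` must come from the
    normoxic portion of the same trial.
    """
    wins = [w for w in series.windows if not w.excluded]
    if len(wins) < min_conforming + 2:
        raise ValueError("too few usable hypoxia windows")
    po2 = np.array([w.mean_po2 for w in wins])
    mo2 = np.array([w.mo2 for w in wins])
    order = np.argsort(-po2)  # declining PO2 = trial time order
    po2, mo2 = po2[order], mo2[order]

    below = mo2 < smr
    onset = int(np.argmax(below)) if below.any() else mo2.size
    n_before = onset

    # conforming points: scan upward from the lowest PO2 while MO2 < smr
    conf_mask = np.zeros(mo2.size, dtype=bool)
    for k in range(mo2.size - 1, -1, -1):
        if mo2[k] < smr:
            conf_mask[k] = True
        else:
            break
    n_conf = int(conf_mask.sum())
    if n_conf < min_conforming:
        raise ValueError(
            f"only {n_conf} oxyconforming points (< {min_conforming}); "
            "cannot anchor the conformity line"
        )
    c_slope, c_int, _ = _ols(po2[conf_mask], mo2[conf_mask])
    r_slope, _, _ = _ols(po2[~conf_mask], mo2[~conf_mask]) if (~conf_mask).sum() >= 2 else (0.0, 0.0, 0.0)

    if method == "smr_intersection":
        if c_slope <= 0:
            raise ValueError("conformity fit is not increasing with PO2")
        pcrit = (smr - c_int) / c_slope
    elif method == "broken_stick":
        pcrit = _broken_stick(po2, mo2)
    else:
        raise ValueError(f"unknown P_crit method {method!r}")
    if not (po2.min() - 1e-9 <= pcrit <= po2.max() + 1e-9):
        raise ValueError(f"estimated P_crit {pcrit:.2f} outside the observed PO2 range")
    return PcritResult(
        pcrit=float(pcrit),
        pcrit_kpa=float(percent_sat_to_kpa(pcrit, temp_c)),
        method=method,
        n_points_below_smr_onset=n_before,
        valid=n_before >= 10,
        regulation_slope=float(r_slope),
        conformity_slope=float(c_slope),
        conformity_intercept=float(c_int),
    )


def acclimation_improvement(
    acute_group: np.ndarray, acclimated_group: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Improvement in LOE_hyp attributable to acclimation, per fish.

    ``improvement_i = mean(acute) - acclimated_i`` (same units as the
    inputs, typically kPa) and ``percent_i = 100 * improvement_i /
    mean(acute)``.  Positive improvement = greater hypoxia tolerance after
    acclimation (LOE_hyp is an inverse tolerance measure).
    """
    acute = np.asarray(acute_group, dtype=float)
    accl = np.asarray(acclimated_group, dtype=float)
    if acute.size == 0 or accl.size == 0:
        raise ValueError("both groups must be non-empty")
    m = float(acute.mean())
    if m <= 0:
        raise ValueError("mean of the acutely tested group must be positive")
    improvement = m - accl
    return improvement, 100.0 * improvement / m
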