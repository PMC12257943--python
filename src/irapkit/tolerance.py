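"""Tolerance-ramp endpoints and the plasticity metrics ARR and TSM.

CT_max is the temperature at loss of equilibrium (LOE) during a controlled
warming ramp; LOE_hyp is the ambient oxygen level at LOE during a
controlled deoxygenation.  Plasticity is quantified by the acclimation
response ratio ARR = (endpoint_hi - endpoint_lo) / (t_hi - t_lo) and the
thermal safety margin TSM = endpoint - acclimation temperature; the two
are linked by ARR = 1 + (TSM_hi - TSM_lo) / (t_hi - t_lo).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_units import RampRecord, percent_sat_to_kpa

__all__ = ["ToleranceSummary", "extract_loe_endpoint", "compute_arr", "compute_tsm"]


@dataclass
class ToleranceSummary:
    fish_id: str
    endpoint_kind: str  # "ctmax_c" | "loehyp"
    endpoint_value: float
    accl_temp_c: float
    test_temp_c: float | None = None
    tsm: float | None = None  # thermal endpoints only
    endpoint_kpa: float | None = None  # hypoxia endpoints only


def extract_loe_endpoint(ramp: RampRecord) -> ToleranceSummary:
    """Driver value at LOE, linearly interpolated between ramp samples.

    Thermal mode returns CT_max (degC) with its TSM; hypoxia mode returns
    LOE_hyp in % air saturation with the kPa conversion attached (at the
    test temperature).
    """
    value = float(np.interp(ramp.loe_time_s, ramp.time_s, ramp.driver))
    if ramp.mode == "thermal":
        return ToleranceSummary(
            fish_id=ramp.fish_id,
            endpoint_kind="ctmax_c",
            endpoint_value=value,
            accl_temp_c=ramp.accl_temp_c,
            tsm=compute_tsm(value, ramp.accl_temp_c),
        )
    temp = ramp.test_temp_c if ramp.test_temp_c is not None else ramp.accl_temp_c
    return ToleranceSummary(
        fish_id=ramp.fish_id,
        endpoint_kind="loehyp",
        endpoint_value=value,
        accl_temp_c=ramp.accl_temp_c,
        test_temp_c=temp,
        endpoint_kpa=float(percent_sat_to_kpa(value, temp)),
    )


def compute_arr(
    endpoint_lo: float, endpoint_hi: float, t_lo: float, t_hi: float
) -> float:
    """Acclimation response ratio: change in endpoint per degC of acclimation.

    Applies identically to CT_max and to cardiac endpoints such as T_arr;
    1 indicates complete thermal compensation.
    """
    if not t_hi > t_lo:
        raise ValueError("t_hi must exceed t_lo")
    return (endpoint_hi - endpoint_lo) / (t_hi - t_lo)


def compute_tsm(endpoint_c: float, accl_temp_c: float) -> float:
    """Thermal safety margin: tolerance endpoint minus acclimation temperature."""
    return endpoint_c - accl_temp_c
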