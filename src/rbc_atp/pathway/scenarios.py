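"""Perturbation scenarios for the ATP release pathway.

Three physiologically motivated perturbations:

* Gi deficit — type 2 diabetes reduces erythrocyte membrane Gi expression by
  ~40%; modeled by scaling the conserved G-protein pool.
* PDE3 recovery — a PDE3 inhibitor (e.g. cilostazol) lowers relative PDE3
  activity; a root search finds the activity restoring baseline release.
* Insulin — pre-diabetic insulin levels raise PDE3 activity (~87%),
  accelerating cAMP hydrolysis and suppressing release.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd
from scipy.optimize import brentq

from .calibrate import (
    ANCHOR_SO2,
    DEFAULT_PULSE_S,
    _pulse_release,
    calibrate_release,
)
from .parameters import PathwayParameters

__all__ = [
    "gi_deficit_scenario",
    "find_pde3_recovery",
    "insulin_scenario",
    "UnrecoverableDeficitError",
]


class UnrecoverableDeficitError(RuntimeError):
    """Raised when no PDE3 activity can restore baseline release."""


def gi_deficit_scenario(
    params: PathwayParameters,
    gp_fraction: float,
    sO2: float = ANCHOR_SO2,
    pulse_duration: float = DEFAULT_PULSE_S,
    **sim_kwargs,
) -> float:
    """Percent decrease in total release when GP_total is scaled by gp_fraction."""
    if not 0.0 <= gp_fraction <= 1.0:
        raise ValueError(f"gp_fraction must be in [0, 1], got {gp_fraction}")
    baseline = _pulse_release(params, sO2, pulse_duration, **sim_kwargs)
    if gp_fraction == 0.0:
        return 100.0
    perturbed = _pulse_release(
        params.replace(gp_total=params.gp_total * gp_fraction),
        sO2,
        pulse_duration,
        **sim_kwargs,
    )
    return 100.0 * (1.0 - perturbed / baseline)


def find_pde3_recovery(
    params: PathwayParameters,
    gp_fraction: float,
    bracket: tuple[float, float] = (0.05, 1.0),
    xtol: float = 1e-4,
    sO2: float = ANCHOR_SO2,
    pulse_duration: float = DEFAULT_PULSE_S,
    **sim_kwargs,
) -> float:
    """Relative PDE3 activity restoring baseline release under a Gi deficit.

    Solves release(gp_fraction, pde3_rel) = release(1, 1) for pde3_rel by
    bracketed root finding (release decreases monotonically in pde3_rel).
    """
    if gp_fraction == 1.0:
        return params.pde3_rel
    if gp_fraction <= 0.0:
        raise UnrecoverableDeficitError(
            "unrecoverable: with no G-protein the pathway releases no ATP "
            "at any PDE3 activity"
        )
    target = _pulse_release(params, sO2, pulse_duration, **sim_kwargs)
    deficient = params.replace(gp_total=params.gp_total * gp_fraction)

    def gap(pde3_rel: float) -> float:
        return (
            _pulse_release(
                deficient.replace(pde3_rel=pde3_rel), sO2, pulse_duration, **sim_kwargs
            )
            - target
        )

    lo, hi = bracket
    g_lo, g_hi = gap(lo), gap(hi)
    if g_lo * g_hi > 0:
        raise UnrecoverableDeficitError(
            f"bracket ({lo}, {hi}) does not straddle the baseline release "
            f"(gaps {g_lo:.3g}, {g_hi:.3g}); the deficit may be unrecoverable"
        )
    return float(brentq(gap, lo, hi, xtol=xtol))


def insulin_scenario(
    params: PathwayParameters,
    pde3_rel_values: Sequence[float] = (1.0, 1.8, 4.1),
    sO2: float = ANCHOR_SO2,
    pulse_duration: float = DEFAULT_PULSE_S,
    **sim_kwargs,
) -> pd.DataFrame:
    """Calibrated release and integrated cAMP versus relative PDE3 activity.

    Both quantities decrease strictly as PDE3 activity rises, which is the
    mechanism by which insulin suppresses low-O2 ATP release.  Calibration is
    anchored at the pde3_rel = 1 baseline.
    """
    from .parameters import StimulusProtocol
    from .simulate import simulate_pathway

    if any(v <= 0 for v in pde3_rel_values):
        raise ValueError("pde3_rel values must be > 0")
    calib = calibrate_release(
        params.replace(pde3_rel=1.0), pulse_duration=pulse_duration, **sim_kwargs
    )
    rows = []
    for v in pde3_rel_values:
        traj = simulate_pathway(
            params.replace(pde3_rel=v),
            StimulusProtocol.pulse(sO2, pulse_duration),
            **sim_kwargs,
        )
        rows.append(
            (v, calib.to_experimental(traj.total_release()), traj.integrated_camp())
        )
    return pd.DataFrame(rows, columns=["pde3_rel", "release", "camp_integral"])
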