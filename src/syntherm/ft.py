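"""Thermodynamic potential factor F_T: evaluation, sweeps and feasibility thresholds.

F_T multiplies a kinetic rate law (e.g. a Monod term) to make it
thermodynamically consistent.  With the energy available through a reaction
DG_A = -drG'_T and the energy conserved DG_C = ATP yield * DG_p,

    F_T = 1 - exp((DG_C - DG_A) / (chi R T)) = 1 - exp((drG'_T + DG_C) / (chi R T)).

F_T approaches 1 when the available energy far exceeds the conserved energy
(the rate is then purely kinetically controlled), passes through 0 exactly
when DG_A = DG_C, and turns negative when conserving DG_C would cost more
energy than the reaction liberates (the metabolism ceases).

Note on the sign of the exponent: writing the exponent as (DG_A + DG_C)/chiRT
with DG_A = -drG'_T would contradict the limiting behaviour above; only the
(drG'_T + DG_C) form reproduces both stated limits, so that is what is
implemented.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .library import Library, ReactionSpec
from .thermo import GAS_CONSTANT, ProcessConditions, evaluate_drG

__all__ = [
    "EnergyConservationModel",
    "FtResult",
    "DELTA_GP_RANGE",
    "potential_factor",
    "evaluate_ft",
    "sweep",
    "feasibility_threshold",
]

#: kJ/mol ATP: lower, central and upper phosphorylation energies screened
DELTA_GP_RANGE = (45.0, 57.5, 70.0)

_KINETIC_CONTROL_FT = 0.95
_EXP_CLIP = 500.0


@dataclass(frozen=True)
class EnergyConservationModel:
    """Energy conserved per reaction turnover.

    ``delta_Gp`` is the Gibbs energy of phosphorylation in kJ/mol ATP; the ATP
    yield itself is a reaction property.  ``atp_yield_override`` replaces the
    reaction's default ATP yield (used e.g. for the route whose yield is
    debated between -0.1 and 0.3).
    """

    delta_Gp: float = 57.5
    atp_yield_override: float | None = None

    def __post_init__(self) -> None:
        if self.delta_Gp <= 0:
            raise ValueError("delta_Gp must be positive")

    def conserved_energy(self, reaction: ReactionSpec) -> float:
        atp = (
            self.atp_yield_override
            if self.atp_yield_override is not None
            else reaction.atp_yield
        )
        return atp * self.delta_Gp


@dataclass(frozen=True)
class FtResult:
    reaction: str
    condition: str
    delta_GA: float
    delta_GC: float
    ft: float
    regime: str


def _classify(ft: float) -> str:
    if ft <= 0.0:
        return "infeasible"
    if ft > _KINETIC_CONTROL_FT:
        return "kinetic-control"
    return "thermodynamic-control"


def potential_factor(
    drG_prime_T: float,
    delta_GC: float,
    chi: float,
    temperature: float,
) -> float:
    """F_T = 1 - exp((drG'_T + DG_C) / (chi R T)); chi R T at the process temperature."""
    if chi < 1:
        raise ValueError("chi must be >= 1")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    exponent = (drG_prime_T + delta_GC) / (chi * GAS_CONSTANT * temperature)
    if exponent < -_EXP_CLIP:
        return 1.0
    if exponent > _EXP_CLIP:
        exponent = _EXP_CLIP
    return 1.0 - math.exp(exponent)


def evaluate_ft(
    reaction: ReactionSpec,
    conditions: ProcessConditions,
    library: Library,
    model: EnergyConservationModel = EnergyConservationModel(),
    quotient_after_gibbs_helmholtz: bool = False,
) -> FtResult:
    """Compose the Gibbs-energy correction chain with the potential factor."""
    thermo = evaluate_drG(
        reaction,
        conditions,
        library,
        quotient_after_gibbs_helmholtz=quotient_after_gibbs_helmholtz,
    )
    delta_gc = model.conserved_energy(reaction)
    ft = potential_factor(
        thermo.drG_prime_T, delta_gc, reaction.chi, conditions.temperature
    )
    condition = (
        f"T={conditions.temperature:g}K pH={conditions.pH:g} "
        f"I={conditions.ionic_strength:g}M dGp={model.delta_Gp:g}"
    )
    return FtResult(
        reaction=reaction.label,
        condition=condition,
        delta_GA=-thermo.drG_prime_T,
        delta_GC=delta_gc,
        ft=ft,
        regime=_classify(ft),
    )


def _conditions_at(
    base: ProcessConditions, variable: str, value: float
) -> ProcessConditions:
    if variable == "pH":
        return base.replace(pH=float(value))
    # any solute identifier is a valid concentration axis
    if variable in base.concentrations:
        conc = dict(base.concentrations)
        conc[variable] = float(value)
        return base.replace(concentrations=conc)
    raise ValueError(
        f"invalid sweep variable {variable!r}: must be 'pH' or a solute "
        f"present in the base conditions"
    )


def sweep(
    reactions: Iterable[ReactionSpec],
    base_conditions: ProcessConditions,
    library: Library,
    variable: str,
    grid: Sequence[float],
    delta_Gp_set: Sequence[float] = DELTA_GP_RANGE,
    quotient_after_gibbs_helmholtz: bool = False,
) -> pd.DataFrame:
    """Evaluate drG' per e-mol and F_T for each reaction over a condition grid.

    Returns one row per (reaction, delta_Gp, grid point) with the grid values
    echoed; fully deterministic.
    """
    grid = list(grid)
    if len(grid) < 2:
        raise ValueError("grid must contain at least two points")
    diffs = np.diff(grid)
    if not (np.all(diffs > 0) or np.all(diffs < 0)):
        raise ValueError("grid must be strictly monotone")
    rows = []
    for reaction in reactions:
        for value in grid:
            conditions = _conditions_at(base_conditions, variable, value)
            thermo = evaluate_drG(
                reaction,
                conditions,
                library,
                quotient_after_gibbs_helmholtz=quotient_after_gibbs_helmholtz,
            )
            for delta_gp in delta_Gp_set:
                model = EnergyConservationModel(delta_Gp=float(delta_gp))
                ft = potential_factor(
                    thermo.drG_prime_T,
                    model.conserved_energy(reaction),
                    reaction.chi,
                    conditions.temperature,
                )
                rows.append(
                    {
                        "reaction": reaction.label,
                        "delta_Gp": float(delta_gp),
                        "axis_variable": variable,
                        "axis_value": float(value),
                        "drG_prime_T": thermo.drG_prime_T,
                        "drG_per_emol": thermo.drG_per_emol,
                        "ft": ft,
                    }
                )
    return pd.DataFrame(rows)


def feasibility_threshold(
    reaction: ReactionSpec,
    base_conditions: ProcessConditions,
    library: Library,
    model: EnergyConservationModel = EnergyConservationModel(),
    variable: str = "pH",
    interval: tuple[float, float] = (2.0, 9.0),
    tolerance: float = 1e-3,
    monotonicity_grid_points: int = 25,
) -> float | str:
    """Locate the value of ``variable`` at which F_T crosses zero.

    Bisects F_T = 0 to ``tolerance`` after checking numerically on a coarse
    grid that F_T is monotone over the interval (weak-acid speciation can
    break monotonicity, in which case the search refuses with a diagnostic).
    Returns ``"always feasible"`` or ``"never feasible"`` when F_T does not
    change sign on the interval.
    """
    lo, hi = interval
    if not hi > lo:
        raise ValueError("interval must be non-degenerate and ordered")

    def ft_at(value: float) -> float:
        conditions = _conditions_at(base_conditions, variable, value)
        return evaluate_ft(reaction, conditions, library, model).ft

    probe = [ft_at(v) for v in np.linspace(lo, hi, monotonicity_grid_points)]
    deltas = np.diff(probe)
    if not (np.all(deltas <= 1e-12) or np.all(deltas >= -1e-12)):
        raise ValueError(
            f"F_T of {reaction.label!r} is not monotone in {variable} on "
            f"[{lo}, {hi}]; cannot bisect a unique feasibility threshold"
        )
    f_lo, f_hi = probe[0], probe[-1]
    if f_lo > 0 and f_hi > 0:
        return "always feasible"
    if f_lo <= 0 and f_hi <= 0:
        return "never feasible"
    a, b = lo, hi
    fa = f_lo
    while b - a > tolerance:
        mid = 0.5 * (a + b)
        fm = ft_at(mid)
        if (fa > 0) == (fm > 0):
            a, fa = mid, fm
        else:
            b = mid
    return 0.5 * (a + b)
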