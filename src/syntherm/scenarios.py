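"""Named screening scenarios over the default reaction set.

The reference screening condition set mirrors the enrichment experiments:
310.15 K, ionic strength 0.08 M, P_H2 = 1.05 atm, P_CO2 = 0.6 atm,
P_CO = 0.45 atm and 1 mM for every liquid metabolite.  The pH sweep screens
the whole network across pH 3-7; the acetate sweep varies the initial acetate
concentration from 1 to 20 mM at pH 5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ft import DELTA_GP_RANGE, sweep
from .library import Library, load_default_library
from .thermo import ProcessConditions

__all__ = [
    "ScenarioConfig",
    "reference_conditions",
    "run_ph_sweep",
    "run_acetate_sweep",
]

#: atm, the headspace partial pressures of the reference screening condition
REFERENCE_PRESSURES = {"H2": 1.05, "CO2": 0.60, "CO": 0.45}
#: mol/L for every liquid metabolite unless overridden
REFERENCE_METABOLITE_CONC = 0.001


def reference_conditions(
    pH: float = 5.0,
    acetate: float | None = None,
    temperature: float = 310.15,
    ionic_strength: float = 0.08,
    speciate_weak_acids: bool = False,
) -> ProcessConditions:
    """The reference screening conditions, optionally at another pH/acetate level."""
    concentrations = {
        name: REFERENCE_METABOLITE_CONC
        for name in ("acetate", "ethanol", "butyrate", "1-butanol")
    }
    if acetate is not None:
        concentrations["acetate"] = acetate
    return ProcessConditions(
        temperature=temperature,
        ionic_strength=ionic_strength,
        pH=pH,
        partial_pressures=dict(REFERENCE_PRESSURES),
        concentrations=concentrations,
        speciate_weak_acids=speciate_weak_acids,
    )


@dataclass
class ScenarioConfig:
    """Options shared by the packaged sweep scenarios."""

    delta_Gp_set: Sequence[float] = DELTA_GP_RANGE
    speciate_weak_acids: bool = False
    quotient_after_gibbs_helmholtz: bool = False
    ph_grid: Sequence[float] = field(
        default_factory=lambda: np.round(np.arange(3.0, 7.0 + 1e-9, 0.1), 3).tolist()
    )
    acetate_grid: Sequence[float] = field(
        default_factory=lambda: np.round(
            np.linspace(0.001, 0.020, 39), 6
        ).tolist()
    )
    fixed_ph: float = 5.0
    output: Path | None = None


def _run(
    config: ScenarioConfig,
    library: Library | None,
    variable: str,
    grid: Sequence[float],
    base: ProcessConditions,
) -> pd.DataFrame:
    library = library or load_default_library()
    table = sweep(
        library.reactions.values(),
        base,
        library,
        variable=variable,
        grid=grid,
        delta_Gp_set=config.delta_Gp_set,
        quotient_after_gibbs_helmholtz=config.quotient_after_gibbs_helmholtz,
    )
    if config.output is not None:
        table.to_csv(config.output, sep="\t", index=False)
    return table


def run_ph_sweep(
    config: ScenarioConfig | None = None, library: Library | None = None
) -> pd.DataFrame:
    """drG' per e-mol and F_T for all reactions over the pH grid."""
    config = config or ScenarioConfig()
    base = reference_conditions(
        pH=config.ph_grid[0], speciate_weak_acids=config.speciate_weak_acids
    )
    return _run(config, library, "pH", config.ph_grid, base)


def run_acetate_sweep(
    config: ScenarioConfig | None = None, library: Library | None = None
) -> pd.DataFrame:
    """drG' per e-mol and F_T for all reactions over the acetate grid at fixed pH."""
    config = config or ScenarioConfig()
    base = reference_conditions(
        pH=config.fixed_ph, speciate_weak_acids=config.speciate_weak_acids
    )
    return _run(config, library, "acetate", config.acetate_grid, base)
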