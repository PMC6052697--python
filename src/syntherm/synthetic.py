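"""Synthetic batch-fermentation endpoint records with known ground truth.

The generator charges a serum bottle exactly like the enrichment experiments
(330 ml flask, 100 ml liquid, 2.14 atm total pressure with 50/22.2/27.8%
H2/CO/CO2), advances the pools by chosen extents of the net biochemical
reactions, optionally diverts a fraction of the consumed substrate electrons
to an unmeasured sink (biomass/maintenance), partitions inorganic carbon
between headspace and the dissolved carbonate pools at the stated pH, and
finally applies multiplicative lognormal measurement noise.  The ground-truth
yield report is always computed from the noise-free pools, so every metric in
:mod:`syntherm.metrics` can be tested against a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .library import Library, load_default_library
from .metrics import (
    GASES,
    METABOLITES,
    R_ATM,
    BatchRecord,
    YieldReport,
    carbonate_speciation,
    compute_yield_report,
    headspace_moles,
)

__all__ = ["ScenarioSpec", "generate_record", "generate_enrichment_series"]


@dataclass(frozen=True)
class ScenarioSpec:
    """Everything needed to generate one bottle: setup, extents, noise, seed.

    Defaults reproduce the enrichment bottle charging; ``extents`` maps
    reaction labels to mol of turnover.  ``sink_fraction`` is the fraction of
    substrate e-mol diverted to an unmeasured sink; ``noise_sigma`` the
    lognormal sigma applied per measurement.
    """

    flask_volume: float = 0.330
    liquid_volume: float = 0.100
    temperature: float = 298.15
    pressure: float = 2.14
    gas_fractions: dict[str, float] = field(
        default_factory=lambda: {"H2": 0.500, "CO": 0.222, "CO2": 0.278}
    )
    conc_initial: dict[str, float] = field(default_factory=dict)
    ph_initial: float = 5.0
    ph_final: float | None = None
    extents: dict[str, float] = field(default_factory=dict)
    sink_fraction: float = 0.0
    noise_sigma: float = 0.0
    control_production: dict[str, float] = field(default_factory=dict)
    acetate_amended: bool = False
    ionic_strength: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.sink_fraction <= 0.5:
            raise ValueError("sink_fraction must lie in [0, 0.5]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if any(x < 0 for x in self.extents.values()):
            raise ValueError("extents must be non-negative")


def _partition_inorganic_carbon(
    total_ic: float,
    headspace_volume: float,
    liquid_volume: float,
    ph: float,
    temperature: float,
    ionic_strength: float,
    library: Library,
) -> tuple[float, float]:
    """Split inorganic carbon into (headspace CO2 mol, CO2 partial pressure).

    Gas and dissolved pools are linear in P_CO2, so the equilibrium pressure
    follows in closed form from
    N_IC = P_CO2 * (V_g/RT + V_l * KH * s(pH)) with s the speciation sum.
    """
    state = carbonate_speciation(1.0, ph, ionic_strength, temperature, library)
    dissolved_per_atm = state.total_dissolved * liquid_volume
    gas_per_atm = headspace_volume / (R_ATM * temperature)
    p_co2 = total_ic / (gas_per_atm + dissolved_per_atm)
    return p_co2 * gas_per_atm, p_co2


def _apply_noise(record: BatchRecord, sigma: float, rng: np.random.Generator) -> BatchRecord:
    if sigma == 0.0:
        return record

    def jitter(value: float) -> float:
        return value * float(np.exp(rng.normal(0.0, sigma))) if value > 0 else value

    return replace(
        record,
        pressure_initial=jitter(record.pressure_initial),
        pressure_final=jitter(record.pressure_final),
        fractions_initial={g: jitter(y) for g, y in record.fractions_initial.items()},
        fractions_final={g: jitter(y) for g, y in record.fractions_final.items()},
        conc_initial={m: jitter(c) for m, c in record.conc_initial.items()},
        conc_final={m: jitter(c) for m, c in record.conc_final.items()},
    )


def generate_record(
    spec: ScenarioSpec,
    library: Library | None = None,
    bottle_id: str = "synthetic",
) -> tuple[BatchRecord, YieldReport]:
    """Generate one endpoint record and its noise-free ground-truth report.

    Raises if any extent drives a pool negative, naming the exhausted pool.
    Identical specs (including seed) generate identical records.
    """
    library = library or load_default_library()
    rng = np.random.default_rng(spec.seed)
    ph_final = spec.ph_final if spec.ph_final is not None else spec.ph_initial

    gas0 = headspace_moles(
        spec.flask_volume,
        spec.liquid_volume,
        spec.pressure,
        spec.temperature,
        {g: spec.gas_fractions.get(g, 0.0) for g in GASES},
    )
    liquid0 = {m: spec.conc_initial.get(m, 0.0) * spec.liquid_volume for m in METABOLITES}

    delta: dict[str, float] = {}
    for label, extent in spec.extents.items():
        reaction = library.reaction(label)
        for name, coeff in reaction.stoichiometry.items():
            delta[name] = delta.get(name, 0.0) + coeff * extent

    # Divert a fraction of the substrate electrons to an unmeasured sink by
    # inflating the consumption of the electron donors (H2, CO, net-consumed
    # acetate): products stay fixed, so the e-mol recovery of the noise-free
    # record is exactly (1 - sink_fraction) * 100%.
    inflation = 1.0 / (1.0 - spec.sink_fraction)
    for donor in ("H2", "CO", "acetate"):
        change = delta.get(donor, 0.0)
        if change < 0:
            delta[donor] = change * inflation

    pools = dict(gas0)
    pools.update({m: liquid0.get(m, 0.0) for m in METABOLITES})
    for name, change in delta.items():
        if name in ("H+", "H2O", "CO2"):
            continue
        new = pools.get(name, 0.0) + change
        if new < -1e-12:
            raise ValueError(
                f"extents drive the {name} pool negative ({new:.4g} mol)"
            )
        pools[name] = max(0.0, new)

    # inorganic carbon: equilibrate headspace CO2 with the dissolved pools
    headspace = spec.flask_volume - spec.liquid_volume
    dissolved0 = (
        carbonate_speciation(
            spec.pressure * spec.gas_fractions.get("CO2", 0.0),
            spec.ph_initial,
            spec.ionic_strength,
            spec.temperature,
            library,
        ).total_dissolved
        * spec.liquid_volume
    )
    total_ic = gas0.get("CO2", 0.0) + dissolved0 + delta.get("CO2", 0.0)
    if total_ic < 0:
        raise ValueError("extents drive the CO2 pool negative")
    co2_gas_final, _ = _partition_inorganic_carbon(
        total_ic,
        headspace,
        spec.liquid_volume,
        ph_final,
        spec.temperature,
        spec.ionic_strength,
        library,
    )

    gas_final = {
        "H2": pools.get("H2", 0.0),
        "CO": pools.get("CO", 0.0),
        "CO2": co2_gas_final,
        "N2": gas0.get("N2", 0.0),
        "CH4": pools.get("CH4", gas0.get("CH4", 0.0)),
    }
    n_total_final = sum(gas_final.values())
    pressure_final = n_total_final * R_ATM * spec.temperature / headspace
    fractions_final = {
        g: (n / n_total_final if n_total_final > 0 else 0.0)
        for g, n in gas_final.items()
    }

    conc_final = {}
    for m in METABOLITES:
        amount = pools.get(m, 0.0) + spec.control_production.get(m, 0.0)
        conc_final[m] = amount / spec.liquid_volume

    record = BatchRecord(
        flask_volume=spec.flask_volume,
        liquid_volume=spec.liquid_volume,
        temperature=spec.temperature,
        pressure_initial=spec.pressure,
        pressure_final=pressure_final,
        fractions_initial={g: spec.gas_fractions.get(g, 0.0) for g in GASES},
        fractions_final=fractions_final,
        conc_initial=dict(spec.conc_initial),
        conc_final=conc_final,
        ph_initial=spec.ph_initial,
        ph_final=ph_final,
        control_production=dict(spec.control_production),
        acetate_amended=spec.acetate_amended,
        ionic_strength=spec.ionic_strength,
        bottle_id=bottle_id,
    )
    truth = compute_yield_report(record, library)
    noisy = _apply_noise(record, spec.noise_sigma, rng)
    noisy.bottle_id = bottle_id
    return noisy, truth


def generate_enrichment_series(
    spec: ScenarioSpec,
    n_transfers: int,
    extent_drift: dict[str, float] | None = None,
    library: Library | None = None,
) -> list[tuple[BatchRecord, YieldReport]]:
    """Successive-transfer series with the extent vector drifting per transfer.

    ``extent_drift`` adds the given mol of turnover to each labelled reaction
    at every transfer (negative drifts are clipped at zero extent), emulating
    a consortium whose activity shifts along an enrichment.  The seed is
    advanced per transfer so replicates are reproducible but not identical.
    """
    if n_transfers < 1:
        raise ValueError("n_transfers must be >= 1")
    library = library or load_default_library()
    drift = extent_drift or {}
    series = []
    extents = dict(spec.extents)
    for transfer in range(n_transfers):
        current = replace(
            spec, extents=dict(extents), seed=spec.seed + transfer
        )
        series.append(
            generate_record(current, library, bottle_id=f"T{transfer}")
        )
        for label, step in drift.items():
            extents[label] = max(0.0, extents.get(label, 0.0) + step)
    return series
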