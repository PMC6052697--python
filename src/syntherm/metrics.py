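"""Bottle-level fermentation bookkeeping on an electron-mol and carbon-mol basis.

A batch bottle is described by its headspace state (pressure, gas mole
fractions) and liquid metabolite concentrations at the start and end of a
fermentation.  From these this module computes:

* product yields in mol product per e-mol of substrate, where the e-mol of a
  compound is its degree of reduction times its amount (H2 and CO carry
  2 e-mol/mol; acetate, when supplied as co-substrate and net consumed,
  carries 8),
* the electron recovery (% of consumed substrate e-mol found in products,
  corrected for background production measured in gas-free control bottles),
* the carbon recovery (% of consumed CO/CO2 carbon found in products, with the
  dissolved inorganic pools CO2(aq)/HCO3-/CO3-- evaluated by Henry's law and
  ionic-strength-corrected dissociation constants at the initial and final pH),
* derived quantities: ethanol-to-acetate mass ratio, biomass yield, and the
  stoichiometric ceiling on net acetate consumption per e-mol of syngas.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .library import Library, load_default_library
from .thermo import (
    GAS_CONSTANT,
    REFERENCE_TEMPERATURE,
    corrected_dissociation_constant,
    dissociation_drG0_I,
)

__all__ = [
    "GASES",
    "METABOLITES",
    "BatchRecord",
    "YieldReport",
    "CarbonateState",
    "headspace_moles",
    "substrate_emol_consumed",
    "product_yields",
    "emol_recovery",
    "carbonate_speciation",
    "cmol_recovery",
    "ethanol_acetate_ratio",
    "theoretical_acetate_consumption_ceiling",
    "compute_yield_report",
    "read_batch_table",
    "write_batch_table",
    "records_to_frame",
]

#: L atm / (mol K)
R_ATM = 0.082057

GASES = ("H2", "CO", "CO2", "N2", "CH4")
METABOLITES = (
    "acetate",
    "propionate",
    "iso-butyrate",
    "butyrate",
    "caproate",
    "ethanol",
    "1-butanol",
)

#: Henry's law constant of CO2 in water at 298.15 K, mol/(L atm)
KH_CO2_298 = 0.0339

MOLAR_MASS = {"ethanol": 46.069, "acetate": 60.052}

_DEFAULT_LIBRARY: Library | None = None


def _default_library() -> Library:
    global _DEFAULT_LIBRARY
    if _DEFAULT_LIBRARY is None:
        _DEFAULT_LIBRARY = load_default_library()
    return _DEFAULT_LIBRARY


def headspace_moles(
    flask_volume: float,
    liquid_volume: float,
    pressure: float,
    temperature: float,
    fractions: Mapping[str, float],
) -> dict[str, float]:
    """Ideal-gas moles of each headspace gas.

    n_i = y_i * P * (V_flask - V_liquid) / (R T), with volumes in L, pressure
    in atm and temperature in K.
    """
    if flask_volume <= 0 or liquid_volume < 0:
        raise ValueError("volumes must be positive")
    if liquid_volume >= flask_volume:
        raise ValueError("liquid volume must be smaller than the flask volume")
    if pressure < 0:
        raise ValueError("pressure must be non-negative")
    headspace = flask_volume - liquid_volume
    total = pressure * headspace / (R_ATM * temperature)
    return {gas: total * float(fractions.get(gas, 0.0)) for gas in fractions}


@dataclass
class BatchRecord:
    """Endpoint measurements of one batch bottle.

    Gas mole fractions and liquid concentrations are given at the start and
    end of the fermentation; ``control_production`` holds the background
    product formation (mol) measured in gas-free control bottles, which is
    subtracted in the recovery calculations.  ``acetate_amended`` marks
    bottles that received acetate as co-substrate: only then, and only on net
    consumption, does acetate enter the substrate e-mol.
    """

    flask_volume: float
    liquid_volume: float
    temperature: float
    pressure_initial: float
    pressure_final: float
    fractions_initial: dict[str, float]
    fractions_final: dict[str, float]
    conc_initial: dict[str, float]
    conc_final: dict[str, float]
    ph_initial: float
    ph_final: float
    control_production: dict[str, float] = field(default_factory=dict)
    acetate_amended: bool = False
    vss: float | None = None
    ionic_strength: float = 0.08
    bottle_id: str = "bottle"

    def __post_init__(self) -> None:
        if self.liquid_volume >= self.flask_volume:
            raise ValueError("headspace volume must be positive")
        for tag, fractions in (
            ("initial", self.fractions_initial),
            ("final", self.fractions_final),
        ):
            for gas, y in fractions.items():
                if not 0.0 <= y <= 1.0:
                    raise ValueError(f"{tag} mole fraction of {gas} outside [0, 1]")
            if sum(fractions.values()) > 1.0 + 0.05:
                raise ValueError(f"{tag} mole fractions sum above 1")
        for name, conc in self.conc_final.items():
            if conc < 0:
                raise ValueError(f"final concentration of {name} is negative")

    @property
    def headspace_volume(self) -> float:
        return self.flask_volume - self.liquid_volume

    def gas_moles_initial(self) -> dict[str, float]:
        return headspace_moles(
            self.flask_volume,
            self.liquid_volume,
            self.pressure_initial,
            self.temperature,
            self.fractions_initial,
        )

    def gas_moles_final(self) -> dict[str, float]:
        return headspace_moles(
            self.flask_volume,
            self.liquid_volume,
            self.pressure_final,
            self.temperature,
            self.fractions_final,
        )

    def metabolite_net_mol(self, name: str) -> float:
        """Net production (positive) or consumption (negative) in mol."""
        return (
            self.conc_final.get(name, 0.0) - self.conc_initial.get(name, 0.0)
        ) * self.liquid_volume


@dataclass(frozen=True)
class CarbonateState:
    """Dissolved inorganic carbon speciation at one (P_CO2, pH) state."""

    co2_aq: float
    hco3: float
    co3: float
    KH_co2: float
    Ka1: float
    Ka2: float

    @property
    def total_dissolved(self) -> float:
        return self.co2_aq + self.hco3 + self.co3


@dataclass(frozen=True)
class YieldReport:
    """Product yields and recovery metrics for one bottle."""

    yields: dict[str, float]
    percent_of_stoichiometric_max: dict[str, float]
    emol_recovery: float
    cmol_recovery: float
    ethanol_acetate_ratio: float | None
    biomass_yield: float | None
    acetate_included_as_substrate: bool
    substrate_emol: float


def _gamma(name: str, library: Library) -> int:
    return library.compounds[name].electrons_per_mol


def _carbon(name: str, library: Library) -> int:
    return library.compounds[name].carbon_count


def substrate_emol_consumed(
    record: BatchRecord, library: Library | None = None
) -> tuple[float, dict[str, float]]:
    """Total substrate e-mol consumed, with a per-substrate breakdown.

    Counts 2 e-mol per mol of H2 and CO consumed (net-produced substrates
    contribute zero), plus 8 e-mol per mol of acetate consumed when the bottle
    was acetate-amended and showed net consumption.
    """
    library = library or _default_library()
    initial = record.gas_moles_initial()
    final = record.gas_moles_final()
    breakdown: dict[str, float] = {}
    for gas in ("H2", "CO"):
        consumed = max(0.0, initial.get(gas, 0.0) - final.get(gas, 0.0))
        breakdown[gas] = consumed * _gamma(gas, library)
    if record.acetate_amended:
        net = record.metabolite_net_mol("acetate")
        breakdown["acetate"] = -net * _gamma("acetate", library) if net < 0 else 0.0
    return sum(breakdown.values()), breakdown


def _net_products(record: BatchRecord) -> dict[str, float]:
    """Net-produced amounts (mol) of metabolites and product gases."""
    products: dict[str, float] = {}
    for name in METABOLITES:
        net = record.metabolite_net_mol(name)
        if net > 0:
            products[name] = net
    initial = record.gas_moles_initial()
    final = record.gas_moles_final()
    for gas in ("CH4", "H2", "CO"):
        net = final.get(gas, 0.0) - initial.get(gas, 0.0)
        if net > 0:
            products[gas] = net
    return products


def product_yields(
    record: BatchRecord, library: Library | None = None
) -> tuple[dict[str, float], dict[str, float]]:
    """Per-product yields (mol/e-mol) and their share of the stoichiometric maximum.

    A product's stoichiometric maximum share is yield * gamma * 100: the
    percentage of consumed substrate electrons recovered in that product
    (100% for ethanol at 1 mol per 12 e-mol).
    """
    library = library or _default_library()
    total_emol, _ = substrate_emol_consumed(record, library)
    if total_emol <= 0:
        raise ValueError("no substrate consumption: yields are undefined")
    yields: dict[str, float] = {}
    percent_max: dict[str, float] = {}
    for name in METABOLITES:
        net = max(0.0, record.metabolite_net_mol(name))
        yields[name] = net / total_emol
        percent_max[name] = yields[name] * _gamma(name, library) * 100.0
    return yields, percent_max


def emol_recovery(record: BatchRecord, library: Library | None = None) -> float:
    """Electron recovery (%) in products, corrected for control production.

    100 * sum_i (n_i produced - n_i control) * gamma_i / substrate e-mol.
    Values outside [0, 100] are reported as-is with a warning (they flag a
    control over-correction or an uncounted substrate).
    """
    library = library or _default_library()
    total_emol, breakdown = substrate_emol_consumed(record, library)
    if total_emol <= 0:
        raise ValueError("no substrate consumption: recovery is undefined")
    numerator = 0.0
    for name, net in _net_products(record).items():
        if name in breakdown and breakdown[name] > 0:
            continue
        corrected = net - record.control_production.get(name, 0.0)
        numerator += corrected * _gamma(name, library)
    recovery = 100.0 * numerator / total_emol
    if not 0.0 <= recovery <= 100.0 + 1e-9:
        warnings.warn(
            f"e-mol recovery of {recovery:.1f}% outside [0, 100]: check control "
            "correction and substrate flags",
            stacklevel=2,
        )
    return recovery


def _henry_constant_co2(temperature: float, library: Library) -> float:
    """Henry constant of CO2 (mol/(L atm)) with van 't Hoff temperature scaling."""
    dh_solution = library.compounds["CO2(aq)"].dfH0 - library.compounds["CO2"].dfH0
    exponent = -(dh_solution / GAS_CONSTANT) * (
        1.0 / temperature - 1.0 / REFERENCE_TEMPERATURE
    )
    return KH_CO2_298 * math.exp(exponent)


def carbonate_speciation(
    P_co2: float,
    pH: float,
    ionic_strength: float = 0.08,
    temperature: float = 310.15,
    library: Library | None = None,
) -> CarbonateState:
    """Dissolved CO2/HCO3-/CO3-- concentrations in equilibrium with a CO2 partial pressure.

    [CO2(aq)] = KH * P_CO2; [HCO3-] = [CO2(aq)] Ka1 / [H+];
    [CO3--] = Ka2 [CO2(aq)] Ka1 / [H+]^2, with Ka1 and Ka2 derived from the
    bundled formation energies after ionic-strength correction.
    """
    if P_co2 < 0:
        raise ValueError("P_co2 must be non-negative")
    library = library or _default_library()
    compounds = library.compounds
    kh = _henry_constant_co2(temperature, library)
    # CO2(aq) + H2O -> HCO3- + H+
    drg1 = (
        compounds["HCO3-"].dfG0
        - compounds["CO2(aq)"].dfG0
        - compounds["H2O"].dfG0
    )
    drg1_i = drg1 + _ionic_offset(
        {"HCO3-": 1, "H+": 1, "CO2(aq)": -1, "H2O": -1}, ionic_strength, library
    )
    ka1 = corrected_dissociation_constant(drg1_i)
    # HCO3- -> CO3-- + H+
    drg2 = compounds["CO3-2"].dfG0 - compounds["HCO3-"].dfG0
    drg2_i = drg2 + _ionic_offset(
        {"CO3-2": 1, "H+": 1, "HCO3-": -1}, ionic_strength, library
    )
    ka2 = corrected_dissociation_constant(drg2_i)
    proton = 10.0 ** (-pH)
    co2_aq = kh * P_co2
    hco3 = co2_aq * ka1 / proton
    co3 = ka2 * co2_aq * ka1 / proton**2
    return CarbonateState(co2_aq=co2_aq, hco3=hco3, co3=co3, KH_co2=kh, Ka1=ka1, Ka2=ka2)


def _ionic_offset(
    stoichiometry: Mapping[str, float], ionic_strength: float, library: Library
) -> float:
    """Sum of Debye-Hueckel Gibbs corrections over a stoichiometry (kJ)."""
    from .thermo import correct_formation_gibbs

    total = 0.0
    for name, coeff in stoichiometry.items():
        record = library.compounds[name]
        total += coeff * (
            correct_formation_gibbs(0.0, record.charge, ionic_strength)
        )
    return total


def _dissolved_carbon(record: BatchRecord, which: str, library: Library) -> float:
    """Dissolved inorganic carbon (mol) at the initial or final state."""
    if which == "initial":
        pressure, fractions, ph = (
            record.pressure_initial,
            record.fractions_initial,
            record.ph_initial,
        )
    else:
        pressure, fractions, ph = (
            record.pressure_final,
            record.fractions_final,
            record.ph_final,
        )
    p_co2 = pressure * fractions.get("CO2", 0.0)
    state = carbonate_speciation(
        p_co2, ph, record.ionic_strength, record.temperature, library
    )
    return state.total_dissolved * record.liquid_volume


def cmol_recovery(record: BatchRecord, library: Library | None = None) -> float:
    """Carbon recovery (%) in products, against the net inorganic carbon consumed.

    The denominator is the net consumption (initial minus final, signed) of
    headspace CO and CO2 plus the dissolved CO2(aq)/HCO3-/CO3-- pools,
    evaluated by carbonate speciation at the initial and final pH; carbon
    released back as CO2 therefore reduces the denominator.
    """
    library = library or _default_library()
    if record.ph_final is None or not math.isfinite(record.ph_final):
        raise ValueError("final pH required for carbonate speciation")
    initial = record.gas_moles_initial()
    final = record.gas_moles_final()
    denominator = (
        (initial.get("CO", 0.0) - final.get("CO", 0.0))
        + (initial.get("CO2", 0.0) - final.get("CO2", 0.0))
        + _dissolved_carbon(record, "initial", library)
        - _dissolved_carbon(record, "final", library)
    )
    if abs(denominator) < 1e-12:
        raise ValueError("no net carbon consumption: Cmol recovery is undefined")
    numerator = 0.0
    for name, net in _net_products(record).items():
        carbon = _carbon(name, library)
        if carbon == 0:
            continue
        numerator += (net - record.control_production.get(name, 0.0)) * carbon
    recovery = 100.0 * numerator / denominator
    if not 0.0 <= recovery <= 100.0 + 1e-9:
        warnings.warn(
            f"Cmol recovery of {recovery:.1f}% outside [0, 100]",
            stacklevel=2,
        )
    return recovery


def ethanol_acetate_ratio(record: BatchRecord) -> float | None:
    """Mass ratio (g/g) of net ethanol to net acetate production.

    Returns ``None`` (not applicable) when acetate was not net produced.
    """
    net_ethanol = record.metabolite_net_mol("ethanol")
    net_acetate = record.metabolite_net_mol("acetate")
    if net_acetate <= 0:
        return None
    return (net_ethanol * MOLAR_MASS["ethanol"]) / (net_acetate * MOLAR_MASS["acetate"])


def theoretical_acetate_consumption_ceiling(library: Library | None = None) -> float:
    """Maximum net acetate consumption per e-mol of syngas: 0.25 mol/e-mol.

    Both acetate-reduction routes spend exactly 2 mol of a 2-e-mol/mol donor
    (H2 or CO) per mol of acetate reduced, so whenever consumed acetate leaves
    the pool as alcohol, 4 e-mol of syngas are required per mol of acetate.
    The value is derived from the reaction set rather than hard-coded.
    """
    library = library or _default_library()
    ceilings = []
    for label in ("acetate_reduction_h2", "acetate_reduction_co"):
        reaction = library.reaction(label)
        acetate = -reaction.stoichiometry["acetate"]
        donor_emol = sum(
            -coeff * library.compounds[name].electrons_per_mol
            for name, coeff in reaction.stoichiometry.items()
            if coeff < 0 and library.compounds[name].phase == "gas"
        )
        ceilings.append(acetate / donor_emol)
    if len(set(ceilings)) != 1:
        raise AssertionError("acetate-reduction routes disagree on the ceiling")
    return ceilings[0]


def compute_yield_report(
    record: BatchRecord, library: Library | None = None
) -> YieldReport:
    """Assemble the full yield/recovery report for one bottle."""
    library = library or _default_library()
    total_emol, breakdown = substrate_emol_consumed(record, library)
    yields, percent_max = product_yields(record, library)
    biomass = None
    if record.vss is not None and math.isfinite(record.vss):
        biomass = record.vss * record.liquid_volume / total_emol
    try:
        cmol = cmol_recovery(record, library)
    except ValueError:
        # no net inorganic-carbon consumption (e.g. acetate carbon merely
        # shuttled to ethanol): the syngas-carbon recovery is undefined
        cmol = float("nan")
    return YieldReport(
        yields=yields,
        percent_of_stoichiometric_max=percent_max,
        emol_recovery=emol_recovery(record, library),
        cmol_recovery=cmol,
        ethanol_acetate_ratio=ethanol_acetate_ratio(record),
        biomass_yield=biomass,
        acetate_included_as_substrate=breakdown.get("acetate", 0.0) > 0,
        substrate_emol=total_emol,
    )


# ---------------------------------------------------------------------------
# Delimited-table I/O.  One row per bottle; the column dictionary is the
# written header itself: volumes in L, temperature in K, pressures in atm,
# x_<gas> mole fractions, c_<metabolite> concentrations in mol/L,
# control_<metabolite> in mol, vss in g/L.
# ---------------------------------------------------------------------------


def _record_to_row(record: BatchRecord) -> dict[str, object]:
    row: dict[str, object] = {
        "bottle_id": record.bottle_id,
        "flask_volume_l": record.flask_volume,
        "liquid_volume_l": record.liquid_volume,
        "temperature_k": record.temperature,
        "pressure_initial_atm": record.pressure_initial,
        "pressure_final_atm": record.pressure_final,
        "ph_initial": record.ph_initial,
        "ph_final": record.ph_final,
        "ionic_strength_m": record.ionic_strength,
        "acetate_amended": int(record.acetate_amended),
        "vss_g_per_l": record.vss if record.vss is not None else float("nan"),
    }
    for gas in GASES:
        row[f"x_{gas}_initial"] = record.fractions_initial.get(gas, 0.0)
        row[f"x_{gas}_final"] = record.fractions_final.get(gas, 0.0)
    for name in METABOLITES:
        row[f"c_{name}_initial"] = record.conc_initial.get(name, 0.0)
        row[f"c_{name}_final"] = record.conc_final.get(name, 0.0)
        row[f"control_{name}_mol"] = record.control_production.get(name, 0.0)
    return row


def records_to_frame(records: list[BatchRecord]) -> pd.DataFrame:
    return pd.DataFrame([_record_to_row(r) for r in records])


def write_batch_table(records: list[BatchRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def _row_to_record(row: pd.Series) -> BatchRecord:
    vss = float(row["vss_g_per_l"])
    return BatchRecord(
        flask_volume=float(row["flask_volume_l"]),
        liquid_volume=float(row["liquid_volume_l"]),
        temperature=float(row["temperature_k"]),
        pressure_initial=float(row["pressure_initial_atm"]),
        pressure_final=float(row["pressure_final_atm"]),
        fractions_initial={g: float(row[f"x_{g}_initial"]) for g in GASES},
        fractions_final={g: float(row[f"x_{g}_final"]) for g in GASES},
        conc_initial={m: float(row[f"c_{m}_initial"]) for m in METABOLITES},
        conc_final={m: float(row[f"c_{m}_final"]) for m in METABOLITES},
        ph_initial=float(row["ph_initial"]),
        ph_final=float(row["ph_final"]),
        control_production={
            m: float(row[f"control_{m}_mol"]) for m in METABOLITES
        },
        acetate_amended=bool(int(row["acetate_amended"])),
        vss=None if math.isnan(vss) else vss,
        ionic_strength=float(row.get("ionic_strength_m", 0.08)),
        bottle_id=str(row["bottle_id"]),
    )


def read_batch_table(path: str | Path) -> list[BatchRecord]:
    """Read a batch-record table, reporting schema violations per row."""
    frame = pd.read_csv(path, sep="\t")
    records = []
    errors = []
    for index, row in frame.iterrows():
        try:
            records.append(_row_to_record(row))
        except (KeyError, ValueError) as exc:
            errors.append(f"row {index + 2}: {exc}")  # +2: header and 1-basing
    if errors:
        raise ValueError(f"{path}: malformed batch records:\n" + "\n".join(errors))
    return records
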