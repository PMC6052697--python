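"""Bottle bookkeeping: headspace moles, e-mol/Cmol recoveries, speciation, ratios."""

import math

import numpy as np
import pytest

from syntherm.metrics import (
    GASES,
    METABOLITES,
    R_ATM,
    BatchRecord,
    carbonate_speciation,
    cmol_recovery,
    emol_recovery,
    ethanol_acetate_ratio,
    headspace_moles,
    product_yields,
    read_batch_table,
    substrate_emol_consumed,
    theoretical_acetate_consumption_ceiling,
    write_batch_table,
)
from syntherm.synthetic import ScenarioSpec, generate_record


def make_record(
    gas_initial_mol,
    gas_final_mol,
    conc_initial=None,
    conc_final=None,
    control=None,
    acetate_amended=False,
    flask=0.330,
    liquid=0.100,
    temperature=298.15,
    ph=(5.0, 5.0),
):
    """Build a record from explicit gas amounts by inverting the ideal-gas law."""
    headspace = flask - liquid

    def state(moles):
        total = sum(moles.values())
        pressure = total * R_ATM * temperature / headspace
        fractions = {g: (moles.get(g, 0.0) / total if total else 0.0) for g in GASES}
        return pressure, fractions

    p_i, x_i = state(gas_initial_mol)
    p_f, x_f = state(gas_final_mol)
    return BatchRecord(
        flask_volume=flask,
        liquid_volume=liquid,
        temperature=temperature,
        pressure_initial=p_i,
        pressure_final=p_f,
        fractions_initial=x_i,
        fractions_final=x_f,
        conc_initial={m: (conc_initial or {}).get(m, 0.0) for m in METABOLITES},
        conc_final={m: (conc_final or {}).get(m, 0.0) for m in METABOLITES},
        ph_initial=ph[0],
        ph_final=ph[1],
        control_production=control or {},
        acetate_amended=acetate_amended,
    )


class TestHeadspace:
    def test_enrichment_bottle_charging(self):
        """330 ml flask with 100 ml liquid at 2.14 atm and 25 C charged with
        50/22.2/27.8% H2/CO/CO2 holds about 10.1/4.5/5.6 mmol."""
        moles = headspace_moles(
            0.330, 0.100, 2.14, 298.15, {"H2": 0.500, "CO": 0.222, "CO2": 0.278}
        )
        assert moles["H2"] * 1e3 == pytest.approx(10.1, abs=0.2)
        assert moles["CO"] * 1e3 == pytest.approx(4.5, abs=0.2)
        assert moles["CO2"] * 1e3 == pytest.approx(5.55, abs=0.2)

    def test_pure_gas_litre_at_one_atmosphere(self):
        moles = headspace_moles(1.1, 0.1, 1.0, 298.15, {"H2": 1.0})
        assert moles["H2"] * 1e3 == pytest.approx(40.87, abs=0.01)

    def test_zero_pressure_gives_zeros(self):
        moles = headspace_moles(0.33, 0.1, 0.0, 298.15, {"H2": 0.5, "CO": 0.5})
        assert all(v == 0.0 for v in moles.values())

    def test_flooded_flask_rejected(self):
        with pytest.raises(ValueError):
            headspace_moles(0.1, 0.1, 1.0, 298.15, {"H2": 1.0})


class TestSubstrateElectrons:
    def test_h2_and_co_consumption(self):
        record = make_record(
            {"H2": 0.0101, "CO": 0.0045, "CO2": 0.0055},
            {"H2": 0.0001, "CO": 0.0005, "CO2": 0.0055},
        )
        total, breakdown = substrate_emol_consumed(record)
        assert total == pytest.approx(2 * 0.010 + 2 * 0.004)
        assert breakdown["H2"] == pytest.approx(0.020)

    def test_net_produced_acetate_is_excluded(self):
        record = make_record(
            {"H2": 0.010, "CO2": 0.005},
            {"H2": 0.002, "CO2": 0.001},
            conc_initial={"acetate": 0.020},
            conc_final={"acetate": 0.022},
            acetate_amended=True,
        )
        total, breakdown = substrate_emol_consumed(record)
        assert breakdown.get("acetate", 0.0) == 0.0

    def test_consumed_acetate_counts_eight_electrons_per_mol(self):
        record = make_record(
            {"H2": 0.010, "CO2": 0.005},
            {"H2": 0.008, "CO2": 0.005},
            conc_initial={"acetate": 0.020},
            conc_final={"acetate": 0.010},
            acetate_amended=True,
        )
        total, breakdown = substrate_emol_consumed(record)
        assert breakdown["acetate"] == pytest.approx(8 * 0.001)
        # an identical record without the amendment flag never counts acetate
        record.acetate_amended = False
        total_off, breakdown_off = substrate_emol_consumed(record)
        assert "acetate" not in breakdown_off


class TestYieldsAndRecovery:
    def test_stoichiometric_ethanol_from_h2(self):
        """6 H2 + 2 CO2 -> ethanol: 1/12 mol/e-mol, 100% of the stoichiometric max."""
        record = make_record(
            {"H2": 0.012, "CO2": 0.005},
            {"H2": 0.006, "CO2": 0.003},
            conc_final={"ethanol": 0.010},
        )
        yields, percent = product_yields(record)
        assert yields["ethanol"] == pytest.approx(1.0 / 12.0)
        assert percent["ethanol"] == pytest.approx(100.0)

    def test_no_products_means_zero_yields(self):
        record = make_record({"H2": 0.010}, {"H2": 0.005})
        yields, _ = product_yields(record)
        assert all(v == 0.0 for v in yields.values())

    def test_zero_consumption_is_an_error(self):
        record = make_record({"H2": 0.010}, {"H2": 0.010})
        with pytest.raises(ValueError, match="undefined"):
            product_yields(record)

    def test_control_equal_to_gross_production_gives_zero_recovery(self):
        record = make_record(
            {"H2": 0.012, "CO2": 0.005},
            {"H2": 0.006, "CO2": 0.003},
            conc_final={"ethanol": 0.010},
            control={"ethanol": 0.001},
        )
        assert emol_recovery(record) == pytest.approx(0.0, abs=1e-9)

    def test_yields_are_intensive(self):
        """Uniformly scaling all amounts leaves the yields unchanged."""
        base = make_record(
            {"H2": 0.012, "CO2": 0.005},
            {"H2": 0.006, "CO2": 0.003},
            conc_final={"ethanol": 0.010},
        )
        scaled = make_record(
            {"H2": 0.006, "CO2": 0.0025},
            {"H2": 0.003, "CO2": 0.0015},
            conc_final={"ethanol": 0.005},
        )
        assert product_yields(base)[0]["ethanol"] == pytest.approx(
            product_yields(scaled)[0]["ethanol"]
        )


class TestCarbonateSpeciation:
    def test_bicarbonate_equals_dissolved_co2_at_pka1(self, library):
        state = carbonate_speciation(0.6, 7.0, 0.08, 310.15, library)
        pka1 = -math.log10(state.Ka1)
        at_pka = carbonate_speciation(0.6, pka1, 0.08, 310.15, library)
        assert at_pka.hco3 == pytest.approx(at_pka.co2_aq)

    def test_zero_pressure_gives_empty_pools(self):
        state = carbonate_speciation(0.0, 6.0)
        assert state.co2_aq == state.hco3 == state.co3 == 0.0

    def test_dissolved_co2_follows_henry_and_ratios_follow_the_constants(self, library):
        state = carbonate_speciation(0.6, 5.0, 0.08, 310.15, library)
        assert state.co2_aq == pytest.approx(state.KH_co2 * 0.6)
        assert state.hco3 / state.co2_aq == pytest.approx(state.Ka1 * 1e5)

    def test_total_dissolved_carbon_increases_with_ph(self):
        totals = [
            carbonate_speciation(0.6, ph).total_dissolved for ph in (4.0, 5.0, 6.0, 7.0)
        ]
        assert np.all(np.diff(totals) > 0)

    def test_henry_constant_drops_with_temperature(self, library):
        cold = carbonate_speciation(1.0, 5.0, 0.08, 298.15, library)
        warm = carbonate_speciation(1.0, 5.0, 0.08, 310.15, library)
        assert cold.KH_co2 == pytest.approx(0.0339)
        assert warm.KH_co2 < cold.KH_co2


class TestCarbonRecovery:
    def test_ethanol_from_co_closes_the_carbon_balance(self, library):
        """6 CO -> ethanol + 4 CO2: the 2 Cmol of ethanol match the 6 CO
        consumed net of the 4 CO2 returned, giving 100% recovery."""
        record, truth = generate_record(
            ScenarioSpec(extents={"ethanol_from_co": 0.0006}), library
        )
        assert truth.cmol_recovery == pytest.approx(100.0, abs=1e-6)
        assert cmol_recovery(record, library) == pytest.approx(100.0, abs=1e-6)

    def test_no_carbon_turnover_is_an_error(self):
        record = make_record({"H2": 0.010, "CO2": 0.005}, {"H2": 0.005, "CO2": 0.005})
        with pytest.raises(ValueError, match="carbon"):
            cmol_recovery(record)


class TestEthanolAcetateRatio:
    def test_equal_molar_production(self):
        record = make_record(
            {"H2": 0.012, "CO2": 0.006},
            {"H2": 0.002, "CO2": 0.004},
            conc_final={"ethanol": 0.010, "acetate": 0.010},
        )
        assert ethanol_acetate_ratio(record) == pytest.approx(0.767, abs=0.001)

    def test_net_acetate_consumption_is_not_applicable(self):
        record = make_record(
            {"H2": 0.012},
            {"H2": 0.002},
            conc_initial={"acetate": 0.020},
            conc_final={"acetate": 0.010, "ethanol": 0.010},
        )
        assert ethanol_acetate_ratio(record) is None


class TestAcetateCeiling:
    def test_value_derived_from_both_reduction_routes(self, library):
        assert theoretical_acetate_consumption_ceiling(library) == pytest.approx(0.25)

    def test_linear_programming_enumeration_agrees(self, library):
        """Independent oracle: maximise net acetate consumption per e-mol of
        syngas over non-negative extents of the whole reaction set, requiring
        that consumed acetate leaves the pool as alcohol (no net acid
        accumulation).  The optimum equals the closed-form ceiling."""
        from scipy.optimize import linprog

        labels = sorted(library.reactions)
        species = sorted(
            {s for r in library.reactions.values() for s in r.stoichiometry}
        )
        matrix = np.zeros((len(species), len(labels)))
        for j, label in enumerate(labels):
            for name, coeff in library.reactions[label].stoichiometry.items():
                matrix[species.index(name), j] = coeff
        gamma = {s: library.compounds[s].electrons_per_mol for s in species}

        def net(name):
            return matrix[species.index(name)]

        # donor e-mol consumed (H2 + CO, signed) normalised to 1
        donor = -(net("H2") * gamma["H2"] + net("CO") * gamma["CO"])
        objective = net("acetate")  # minimise net acetate change = maximise consumption
        a_eq = [donor, net("butyrate")]
        b_eq = [1.0, 0.0]
        a_ub = [-net("ethanol"), -net("1-butanol")]  # net production >= 0
        b_ub = [0.0, 0.0]
        result = linprog(
            objective, A_ub=a_ub, b_ub=b_ub, A_eq=a_eq, b_eq=b_eq,
            bounds=[(0, None)] * len(labels), method="highs",
        )
        assert result.status == 0
        assert -result.fun == pytest.approx(
            theoretical_acetate_consumption_ceiling(library), abs=1e-9
        )


class TestTableIO:
    def test_round_trip(self, tmp_path, library):
        record, _ = generate_record(
            ScenarioSpec(extents={"ethanol_from_co": 0.0005}, noise_sigma=0.01, seed=3),
            library,
        )
        path = tmp_path / "bottles.tsv"
        write_batch_table([record], path)
        loaded = read_batch_table(path)
        assert len(loaded) == 1
        assert loaded[0].pressure_final == pytest.approx(record.pressure_final)
        assert loaded[0].conc_final["ethanol"] == pytest.approx(
            record.conc_final["ethanol"]
        )

    def test_malformed_row_reports_line_number(self, tmp_path, library):
        record, _ = generate_record(
            ScenarioSpec(extents={"ethanol_from_co": 0.0005}), library
        )
        path = tmp_path / "bottles.tsv"
        write_batch_table([record], path)
        text = path.read_text().splitlines()
        text.append(text[1].replace("\t0.33\t", "\tnot-a-number\t", 1))
        path.write_text("\n".join(text) + "\n")
        with pytest.raises(ValueError, match="row 3"):
            read_batch_table(path)
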