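# Net biochemical reactions of syngas-converting consortia with their energy
# conservation parameters: ATP formed per reaction turnover and the average
# stoichiometric number chi (ion translocations per turnover; 1 for
# substrate-level phosphorylation in chain elongation).
# Stoichiometric coefficients: reactants negative, products positive.
reactions:
  - label: acetate_from_h2_co2
    category: gas-to-acetate
    atp_yield: 0.3
    chi: 2
    stoichiometry: {H2: -4, CO2: -2, acetate: 1, H+: 1, H2O: 2}
  - label: ethanol_from_h2_co2
    category: gas-to-ethanol
    atp_yield: 0.3
    # A net ATP investment of -0.1 has also been proposed for this route;
    # both variants are selectable, the positive one is the default.
    atp_yield_alternatives: [-0.1, 0.3]
    chi: 3
    stoichiometry: {H2: -6, CO2: -2, ethanol: 1, H2O: 3}
  - label: acetate_from_co
    category: gas-to-acetate
    atp_yield: 1.5
    chi: 4
    stoichiometry: {CO: -4, H2O: -2, acetate: 1, H+: 1, CO2: 2}
  - label: ethanol_from_co
    category: gas-to-ethanol
    atp_yield: 1.7
    chi: 6
    stoichiometry: {CO: -6, H2O: -3, ethanol: 1, CO2: 4}
  - label: acetate_reduction_h2
    category: vfa-reduction-H2
    atp_yield: 0.33
    chi: 4
    stoichiometry: {acetate: -1, H+: -1, H2: -2, ethanol: 1, H2O: 1}
  - label: butyrate_reduction_h2
    category: vfa-reduction-H2
    atp_yield: 0.33
    chi: 4
    stoichiometry: {butyrate: -1, H+: -1, H2: -2, 1-butanol: 1, H2O: 1}
  - label: acetate_reduction_co
    category: vfa-reduction-CO
    atp_yield: 0.66
    chi: 5
    stoichiometry: {acetate: -1, H+: -1, CO: -2, H2O: -1, ethanol: 1, CO2: 2}
  - label: butyrate_reduction_co
    category: vfa-reduction-CO
    atp_yield: 0.66
    chi: 5
    stoichiometry: {butyrate: -1, H+: -1, CO: -2, H2O: -1, 1-butanol: 1, CO2: 2}
  - label: chain_elongation
    category: chain-elongation
    atp_yield: 1.0
    chi: 1
    stoichiometry: {ethanol: -5, acetate: -3, butyrate: 4, H+: 1, H2O: 3, H2: 2}
# Conjugate acids used when weak-acid speciation of carboxylates is enabled.
conjugate_acids:
  acetate: acetic-acid
  butyrate: butyric-acid
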