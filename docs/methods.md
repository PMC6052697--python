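# Methods

## Scope and model

`syntherm` screens the bioenergetic feasibility of the net biochemical
reactions carried out by syngas-converting mixed microbial consortia:
homoacetogenic/solventogenic conversion of H2/CO2 and CO into acetate and
ethanol, reduction of acetate and butyrate to the corresponding alcohols with
H2 or CO as electron donor, and chain elongation of ethanol and acetate to
butyrate.  Nine reactions are bundled with their energy-conservation
parameters: the ATP formed per reaction turnover and the average
stoichiometric number χ (the number of ion translocations — or, for chain
elongation, substrate-level phosphorylations — per turnover).

### Correction chain

Standard formation Gibbs energies and enthalpies (298.15 K, I = 0) are
corrected in three steps to the process condition:

1. **Ionic strength** (extended Debye–Hückel):
   Δ<sub>f</sub>G°(I) = Δ<sub>f</sub>G°(0) − RT·A·z²√I/(1 + B√I) with
   A = 1.1758 kg<sup>1/2</sup> mol<sup>−1/2</sup> (water, 25 °C) and
   B = 1.6 L<sup>1/2</sup> mol<sup>−1/2</sup>, valid for I = 0.05–0.25 M
   (conditions outside that window raise a validity warning).  Enthalpies are
   corrected additively with the analogous coefficient 1.4775 z²√I/(1 + B√I).
   The proton is charge-corrected like any monovalent ion even though its
   formation values are zero.
2. **Activities** (reaction quotient): Δ<sub>r</sub>G′ = Δ<sub>r</sub>G°(I) +
   RT ln Q, with gases as partial pressures in atm, solutes in mol/L, proton
   activity 10<sup>−pH</sup> and water activity fixed at 1.  RT is evaluated
   at 298.15 K; because the quotient is added before the temperature step it
   is scaled by T/298.15 together with the standard term, which is
   algebraically identical to adding R·T·ln Q at the process temperature.
   An option (`quotient_after_gibbs_helmholtz`) instead adds the unscaled
   298.15 K quotient after the temperature step — a third defensible reading;
   the difference is (T/298.15 − 1)·RT ln Q ≈ 4% of the quotient term at
   310.15 K and is exposed rather than silently chosen.
3. **Temperature** (Gibbs–Helmholtz): Δ<sub>r</sub>G′(T) =
   Δ<sub>r</sub>G′(298)·T/298.15 + Δ<sub>r</sub>H′(298)·(298.15 − T)/298.15,
   with Δ<sub>r</sub>H′ taken as the ionic-strength-corrected standard
   reaction enthalpy (no temperature dependence of Δ<sub>r</sub>H is
   modelled, and no fugacity corrections are applied).

R = 8.314×10⁻³ kJ/(mol·K) throughout.

### Weak-acid speciation (off by default)

Optionally the carboxylate activities in Q are multiplied by the dissociated
fraction Ka/(Ka + [H⁺]) of the conjugate acid, with Ka solved from
0 = Δ<sub>r</sub>G°(I) + RT ln Ka over the bundled formation energies
(acetic acid pKa 4.76 at I = 0, 4.66 at I = 0.08 M).  This produces the
characteristic flattening of the VFA-reduction driving force below the acid's
pKa (around pH 3.5–4).  The default is **off**: the stated metabolite
concentrations are taken as the anion activity directly, which is the reading
that reproduces the reported potential-factor spot values; both modes are
first-class because the low-pH behaviour of the published figures is only
consistent with speciation on.

### Thermodynamic potential factor

F_T = 1 − exp((Δ<sub>r</sub>G′(T) + ΔG<sub>C</sub>)/(χRT)), with
ΔG<sub>C</sub> = ATP yield × ΔG<sub>p</sub> and χRT at the process
temperature.  The commonly printed form with ΔG<sub>A</sub> = −Δ<sub>r</sub>G′
in the numerator contradicts the factor's limiting behaviour (F_T → 1 for a
strongly exergonic reaction); the implemented sign convention is the one
consistent with those limits and with the reported values.  The
phosphorylation energy ΔG<sub>p</sub> defaults to the central 57.5 kJ/mol ATP
and is screened over {45, 57.5, 70} to band the uncertainty of the assumed
energy-conservation stoichiometry.  F_T ≤ 1 always; F_T = 0 exactly when the
energy available equals the energy conserved; the regime labels are
kinetic-control (F_T > 0.95), thermodynamic-control (0 < F_T ≤ 0.95) and
infeasible (F_T ≤ 0).

Feasibility thresholds bisect F_T = 0 to 10⁻³ in the sweep variable after a
25-point monotonicity probe; non-monotone profiles (possible with speciation
on) are refused with a diagnostic rather than silently rooted.

Per-e-mol normalisation for cross-reaction plots divides Δ<sub>r</sub>G′ by
the summed degree of reduction of the consumed electron-carrying substrates
(8 for 4 H2 + 2 CO2 → acetate, 84 for chain elongation); this scales plots
only and never enters F_T.

## Yield and recovery accounting

The degree of reduction γ = 4C + H − 2O − z (N referenced to N2) puts all
substrates on a common electron basis: H2 and CO carry 2, acetate 8, ethanol
12, butyrate 20, 1-butanol 24, caproate 32 e-mol/mol; CO2, carbonates, water
and the proton carry 0.  Headspace amounts follow the ideal gas law
(R = 0.082057 L·atm/(mol·K)); dissolved H2/CO pools are neglected.

* **Yields**: mol product per e-mol of substrate consumed (H2 + CO, plus
  acetate only for acetate-amended bottles with net consumption).  The
  ethanol stoichiometric maximum is 1 mol per 12 e-mol.
* **Electron recovery**: 100 × Σ(produced − control)·γ / substrate e-mol,
  with background production from gas-free control bottles subtracted.
  Net-consumed acetate of amended bottles is counted in the denominator so
  that electron conservation yields exactly 100% on closed balances;
  recoveries outside [0, 100] are reported as-is with a warning (clamping
  would hide control over-correction).
* **Carbon recovery**: organic product carbon (net of controls) over the net
  consumption of headspace CO and CO2 plus the dissolved
  CO2(aq)/HCO3⁻/CO3²⁻ pools, evaluated at the initial and final pH.
  Dissolved pools: [CO2(aq)] = K_H·P_CO2 with K_H = 0.0339 mol/(L·atm) at
  25 °C, van 't Hoff-scaled with the dissolution enthalpy from the bundled
  constants (−20.3 kJ/mol; K_H = 0.0247 at 37 °C); Ka1/Ka2 are
  ionic-strength-corrected (pKa 6.18 and 9.93 at I = 0.08 M).  The
  denominator uses signed initial-minus-final differences, the only reading
  under which a closed synthetic carbon balance recovers exactly 100%.
  When no net inorganic carbon is consumed (acetate carbon merely shuttled to
  ethanol) the metric is undefined and reported as such.
* **Ceiling**: both acetate-reduction routes spend 2 mol of a 2-e-mol/mol
  donor per acetate, so net acetate removal into alcohols is capped at
  0.25 mol/e-mol of syngas.  The test-suite oracle recovers the same optimum
  by linear programming over non-negative extents of the full reaction set
  under the no-net-acid-accumulation constraint; without that constraint,
  reduction + elongation cycles that park acetate carbon in butyrate would
  allow 0.5 mol/e-mol, which is not the scenario the ceiling describes.
* Biomass electrons/carbon are never added to recoveries; the biomass yield
  (g VSS per e-mol) is reported separately.

## Synthetic data generator

`ScenarioSpec` defaults reproduce the enrichment bottle: 330 ml flask, 100 ml
broth, charged to 2.14 atm total pressure at 25 °C with 50/22.2/27.8%
H2/CO/CO2 (≈10.1/4.5/5.6 mmol).  Final pools are initial pools plus
stoichiometry × extents; an electron-sink fraction f (default 0, modelling
biomass/maintenance) inflates donor consumption by 1/(1−f) so the noise-free
electron recovery is exactly (1−f)·100%.  Inorganic carbon is partitioned
between headspace and the dissolved pools in closed form (both are linear in
P_CO2) at the stated pH.  Measurement noise is multiplicative lognormal
(exp(σZ), default σ = 0, 0.02 recommended as a realistic GC/HPLC error) on
pressures, mole fractions and concentrations — not on extents — and the
ground-truth report is always computed from the noise-free pools.  The pH of
a generated record is prescribed by the scenario, not simulated from
acid–base balance: the generator emulates endpoint bookkeeping, not buffer
chemistry, gas–liquid transfer kinetics, time courses, inhibition or
community dynamics, so passing round-trip tests validate the accounting, not
the biology.  A single seeded generator per call makes records reproducible;
enrichment series advance the seed per transfer and drift the extent vector.

## Numerical choices and limitations

* Reaction balance validation uses exact rational arithmetic; ATP yields are
  stored exactly as printed (0.33, 0.66), not as thirds.
* The potential-factor exponential is clipped at ±500 (F_T = 1 for very
  exergonic reactions instead of overflow).
* Formation values for species outside the reaction set (propionate,
  iso-butyrate, caproate, butyric acid) are nominal compilation values that
  feed only γ/carbon bookkeeping; where no vetted enthalpy exists the field
  is blank and any attempted use raises rather than assuming zero.
* **Known discrepancy**: the reported chain-elongation potential factors at
  ΔG<sub>p</sub> = 70 kJ/mol ATP (0.98/0.86/0.68 at pH 6/5/4) imply a
  reaction Gibbs energy ≈9.5 kJ more negative than the bundled constants
  give; reproducing them would need a butyrate formation energy near
  −355 kJ/mol, whereas the cited compilations agree on −352.63 kJ/mol (the
  value also consistent with the canonical ethanol + acetate → butyrate +
  water energy of −38.6 kJ/mol).  `syntherm` computes F_T ≈ −4.5 at pH 5 and
  deliberately does not adjust the constant.  The related reported "maximum
  F_T of −0.23 at pH 3" for H2-driven acetate reduction at
  ΔG<sub>p</sub> = 70 is likewise not reproducible under either speciation
  mode (speciation off gives +0.45, on gives −0.53).
* Test and verification problem sizes: conservation and noise round-trip
  properties run over 200 seeded replicates; sweeps use the pH 3–7 grid at
  0.1 steps and acetate 1–20 mM; all headline quantities are deterministic
  single evaluations.
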