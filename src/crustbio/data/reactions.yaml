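# Catabolic reactions for sulfate reduction with alternative electron donors,
# written per mole of sulfate (8 electrons transferred), bicarbonate as the
# carbon product and water as unit-activity solvent.
- id: sulfate_co
  donor: CO
  acceptor: SO4
  n_electrons: 8
  stoichiometry: {CO: -4, SO4: -1, H2O: -4, HCO3: 4, HS: 1, H+: 3}
- id: sulfate_h2
  donor: H2
  acceptor: SO4
  n_electrons: 8
  stoichiometry: {H2: -4, SO4: -1, H+: -1, HS: 1, H2O: 4}
- id: sulfate_ch4
  donor: CH4
  acceptor: SO4
  n_electrons: 8
  stoichiometry: {CH4: -1, SO4: -1, HCO3: 1, HS: 1, H2O: 1}
- id: sulfate_acetate
  donor: acetate
  acceptor: SO4
  n_electrons: 8
  stoichiometry: {acetate: -1, SO4: -1, HCO3: 2, HS: 1}
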