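# In situ conditions of Juan de Fuca Ridge flank crustal fluids.
# temperature and sulfate are field-constrained; the remaining analyte
# concentrations, pH and ionic strength are documented placeholders
# (the field data do not constrain them) and every value is overridable.
name: jdfr
temperature_K: 337.15        # 64 degC basement fluid
pH: 7.5                      # placeholder, circum-neutral altered seawater
ionic_strength: 0.7          # placeholder, seawater-like, mol/kg
activity_model: ideal
concentrations:              # mol/kg
  SO4: 0.018                 # ~18 mM measured in basement fluids
  HS: 1.0e-05                # placeholder
  HCO3: 2.0e-03              # placeholder
  CO: 1.0e-06                # placeholder, mid of the 10 nM-100 uM sweep
  H2: 1.0e-06                # placeholder
  CH4: 1.0e-06               # placeholder
  acetate: 1.0e-06           # placeholder
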