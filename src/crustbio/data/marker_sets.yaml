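# Pathway marker sets for the Hydrothermarchaeota metabolic reconstruction.
# Members are gene symbols as annotated by the IMG pipeline; grouped subunit
# strings (e.g. fwdABCDEFG) are expanded to one member per subunit letter at
# load time. expectation=absent marks negative assertions (genes whose
# absence is the claim).
- name: wood_ljungdahl
  rule: fraction
  threshold: 0.5
  expectation: present
  members: [fwdABCDEFG, ftr, mch, mtd, mer, mtrA, hdrBCD]
- name: sulfate_reduction
  rule: all
  expectation: present
  members: [sat, aprA, aprB, dsrA, dsrB]
- name: nitrate_reduction
  rule: any
  expectation: present
  members: [napADGH, narGHIJ]
- name: co_oxidation
  rule: any
  expectation: present
  members: [cooS, cooC]
- name: codh_acs
  rule: all
  expectation: present
  members: [cdhABCDE]
- name: nife_hydrogenase_maturation
  rule: all
  expectation: present
  members: [hypABCDEF]
- name: glycolysis
  rule: all
  expectation: present
  members: [pmm, gpi, fba, fbp, gap, pgk, pgm, eno, pk]
- name: rubisco
  rule: any
  expectation: present
  members: [rbcL]
- name: methanogenesis
  rule: any
  expectation: absent
  members: [mcrA, mcrB, mcrG]
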