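# Molecular characterization of degenerative aortic stenosis (AS):
# eight pathophysiological processes ("motives"), each with a causal level
# and the effector proteins recoverable from the published strong-relationship
# table, plus the effectors of the disease-in-general pseudo-process.
# The published study defined 168 effectors in an appendix that was not
# deposited; the sets below are the recoverable subset (see fixtures/README.md).
motives:
  - id: calcification
    name: Calcification
    level: both
    effectors: [P05231, P08253, Q00653]
  - id: lipoprotein_accumulation
    name: Lipoprotein accumulation
    level: causative
    effectors: [P02647, P04114]
  - id: inflammation
    name: Inflammation
    level: causative
    effectors: [P01042, P05231, P21810, Q00653]
  - id: oxidative_stress
    name: Oxidative stress
    level: causative
    effectors: [P00441]
  - id: endothelial_dysfunction
    name: Endothelial dysfunction
    level: causative
    effectors: [P01033, P02461, P07339, P08123, P08253, P35625]
  - id: raa_system
    name: RAA system
    level: causative
    effectors: [P01019]
  - id: hypertrophy
    name: Hypertrophy
    level: symptomatic
    effectors: [P01019]
  - id: myocardial_fibrosis
    name: Myocardial fibrosis
    level: symptomatic
    effectors: [P01019, P02461, P05231, P08123, P08253]
general_effectors: [P00441, P01019, P01033, P01042, P02461, P02647, P04114,
                    P05231, P07339, P08123, P08253, P21810, P35625, Q00653]
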