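# Acronym/abbreviation expansions: short form <TAB> expansion.
DM	diabetes mellitus
PVR	pulmonary vascular resistance
TB	tuberculosis
COPD	chronic obstructive pulmonary disease
FEV1	forced expiratory volume in one second
FVC	forced vital capacity
CT	computed tomography
CRP	C-reactive protein
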