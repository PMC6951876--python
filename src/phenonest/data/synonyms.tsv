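# Synonym substitutions: phrase <TAB> pipe-separated replacements.
worsening	deterioration of
arm	upper limb
predisposition	susceptibility to disease
dyspnea	shortness of breath|breathlessness
shortness of breath	dyspnea
sputum	phlegm
physician	doctor
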