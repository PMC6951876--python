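# Neoclassical compound/morpheme -> plain-English equivalent.
# Longer patterns listed first; each rule firing yields one variant.
blood leukocyte	white blood cell
leukocyte	white blood cell
pleuritis	pleural inflammation
hepatomegaly	liver enlargement
pulmonary	lung
cardiac	heart
hepatic	liver
renal	kidney
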