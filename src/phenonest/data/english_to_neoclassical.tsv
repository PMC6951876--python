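# Plain-English phrase -> neoclassical equivalent.
inflammation of the pleura	pleuritis
pleural inflammation	pleuritis
white blood cell	leukocyte
liver enlargement	hepatomegaly
lung	pulmonary
heart	cardiac
liver	hepatic
kidney	renal
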