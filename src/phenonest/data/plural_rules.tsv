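# Plural -> singular rules. kind=word: exact word mapping (Latin/Greek
# irregulars); kind=suffix: ordered suffix rewrite, first match wins.
word	septa	septum
word	bronchi	bronchus
word	alveoli	alveolus
word	data	datum
word	criteria	criterion
word	bacteria	bacterium
suffix	ies	y
suffix	sses	ss
suffix	s
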