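# Derivational adjective -> noun pairs used by the syntactic-variation
# technique: in-place substitution, and move-to-head for a leading
# adjective ("supplemental oxygen" -> "oxygen supplementation").
supplemental	supplementation
spirometric	spirometry
atrial	atrium
arterial	artery
elevated	elevation
obstructive	obstruction
inflammatory	inflammation
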