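# Published per-category entity-normalization counts for the COPD
# phenotype corpus (http://www.nactem.ac.uk/COPD), as printed:
# category <TAB> total entities <TAB> entities normalized.
Problem	2556	2151
Condition	5119	4969
RiskFactor	1211	942
SignOrSymptom	2065	1140
IndividualBehaviour	194	124
TestOrMesureResult	685	259
Treatment	4337	3775
TestOrMeasure	3576	2609
AnatomicalConcept	2616	2372
Drug	2593	2368
Protein	820	727
Quality	1153	1015
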