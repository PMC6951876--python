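# COPD phenotype annotation scheme: label <TAB> parent ("-" for a root).
# Four roots: Problem, Treatment, Test, ConstituentConcept.
Problem	-
Condition	Problem
RiskFactor	Problem
SignOrSymptom	Problem
IndividualBehaviour	Problem
TestResult	Problem
Treatment	-
Test	-
RadiologicalTest	Test
MicrobiologicalTest	Test
PhysiologicalTest	Test
ConstituentConcept	-
AnatomicalConcept	ConstituentConcept
Drug	ConstituentConcept
Protein	ConstituentConcept
Quality	ConstituentConcept
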