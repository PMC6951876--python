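# Synthetic mock terminology for tests and examples — a small stand-in
# dictionary in the packaged terminology format, NOT a real UMLS extract.
# Columns: identifier <TAB> preferred label <TAB> pipe-separated synonyms
# ("-" for none) <TAB> pipe-separated semantic category tags.
C1867423	Increased pulmonary vascular resistance	-	Problem
C0948755	Pulmonary failure	lung failure	Condition
C0225860	Left atrium	-	AnatomicalConcept
C0556501	Upper limb training	-	Treatment
C0037981	Spirometry test	spirometry	Test
C1455997	Genetic susceptibility to disease	-	RiskFactor
C0852710	High oxygen saturation	-	TestResult
C0013404	Dyspnea	shortness of breath	SignOrSymptom|Condition
C0034067	Pulmonary emphysema	emphysema	Condition
C0010200	Coughing	cough|chronic cough	SignOrSymptom
C9000001	Alveolar septum	-	AnatomicalConcept
C9000002	Pleuritis	-	Condition
C9000003	Oxygen supplementation	supplemental oxygen therapy	Treatment
C9000004	Deterioration of lung function	-	Problem
C9000005	Type 2 diabetes mellitus	-	Condition
C9000006	Elevated white blood cell count	-	TestResult
C9000007	Inhaled corticosteroids	-	Treatment|Drug
C9000008	Spirometry	spirometric examination	Test
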