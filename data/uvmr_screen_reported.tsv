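exposure	outcome	ivw_beta	ivw_p	ml_beta	ml_p	egger_beta	egger_p	presso_beta	presso_p	wm_beta	wm_p	judgment
Phylum Firmicutes	Insomnia	0.017	1.50e-2	0.018	5.99e-3	0.017	3.18e-1	0.017	2.71e-2	0.027	2.30e-3	probable_causality
Class Negativicutes	Insomnia	0.032	1.08e-4	0.033	1.60e-4	0.041	1.47e-1	0.032	8.80e-4	0.045	1.00e-4	causality
Order Selenomonadales	Insomnia	0.032	1.08e-4	0.033	1.60e-4	0.041	1.47e-1	0.032	8.80e-4	0.045	1.25e-4	causality
Genus Lachnoclostridium	Insomnia	0.035	8.05e-4	0.038	6.01e-5	0.011	7.70e-1	0.035	6.47e-3	0.028	3.49e-2	probable_causality
Phylum Bacteroidetes	EDS	0.013	1.51e-2	0.014	1.68e-2	0.005	6.47e-1	0.013	3.30e-2	0.017	2.97e-2	probable_causality
Genus Butyricimonas	EDS	0.014	1.20e-3	0.015	1.39e-3	0.005	7.50e-1	0.014	5.18e-3	0.016	6.93e-3	probable_causality
Genus Eubacterium eligens group	EDS	0.015	2.50e-2	0.015	2.59e-2	0.048	1.35e-1	0.015	1.92e-2	0.019	3.05e-2	probable_causality
Genus Oxalobacter	EDS	0.014	3.45e-5	0.014	5.20e-5	0.012	4.82e-1	0.014	2.52e-3	0.016	4.41e-4	causality
Genus Prevotella9	SWRD	0.631	3.05e-2	0.650	6.90e-3	1.602	6.83e-2	0.631	4.83e-2	0.742	3.43e-2	probable_causality
Genus Ruminiclostridium6	SWRD	-0.819	5.38e-3	-0.798	7.32e-3	-1.925	2.17e-2	-0.819	1.39e-2	-1.218	1.88e-3	probable_causality
Genus Allisonella	OSA	0.070	1.05e-3	0.071	1.35e-3	0.044	7.70e-1	0.070	1.46e-3	0.070	7.25e-3	probable_causality
Genus Eubacterium xylanophilum group	OSA	-0.146	1.31e-4	-0.145	2.75e-4	-0.308	3.07e-2	-0.146	1.00e-3	-0.174	5.47e-4	causality
Genus Eubacterium coprostanoligenes group	iRBD	0.681	1.42e-2	0.714	9.18e-3	-0.605	5.95e-1	0.681	3.04e-2	0.837	2.80e-2	probable_causality
Genus Oscillibacter	iRBD	0.504	7.97e-3	0.531	6.46e-3	0.584	4.91e-1	0.504	7.65e-3	0.574	2.31e-2	probable_causality
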