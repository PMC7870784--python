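pathway_id	name	p_adjust	category
hsa04066	HIF-1 signaling pathway	9.13E-05	Environmental information processing (signal transduction)
hsa04010	MAPK signaling pathway	9.13E-05	Environmental information processing (signal transduction)
hsa04211	Longevity regulating pathway	0.000235603	Organismal Systems (Aging)
hsa04014	Ras signaling pathway	0.000576013	Environmental information processing (signal transduction)
hsa04152	AMPK signaling pathway	0.000795236	Environmental information processing (signal transduction)
hsa05143	African trypanosomiasis	0.000849635	Human Diseases (Infectious disease: parasitic)
hsa04151	PI3K-Akt signaling pathway	0.001008779	Environmental information processing (signal transduction)
hsa04940	Type I diabetes mellitus	0.001165778	Human diseases (Endocrine and metabolic diseases)
hsa04750	Inflammatory mediator regulation of TRP channels	0.002276445	Organismal Systems (Sensory system)
hsa04213	Longevity regulating pathway - multiple species	0.00357561	Organismal Systems (Aging)
hsa04726	Serotonergic synapse	0.00357561	Organismal Systems (Nervous system)
hsa01200	Carbon metabolism	0.00357561	Metabolism (Global and overview maps)
hsa04920	Adipocytokine signaling pathway	0.004585583	Organismal Systems (Endocrine system)
hsa01523	Antifolate resistance	0.00558566	Human Diseases (Drug resistance: antineoplastic)
hsa04015	Rap1 signaling pathway	0.005824984	Environmental information processing (signal transduction)
hsa05418	Fluid shear stress and atherosclerosis	0.005883716	Human diseases (Cardiovascular disease)
hsa01521	EGFR tyrosine kinase inhibitor resistance	0.005883716	Human Diseases (Drug resistance: antineoplastic)
hsa04932	Non-alcoholic fatty liver disease (NAFLD)	0.006946136	Human diseases (Endocrine and metabolic diseases)
hsa04610	Complement and coagulation cascades	0.006946136	Organismal Systems (Immune system)
hsa05332	Graft-vs.-host disease	0.008810959	Human disease (Immune system)
hsa05323	Rheumatoid arthritis	0.008810959	Human disease (Immune system)
hsa05215	Prostate cancer	0.009841294	Human diseases (cancers: specific types)
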