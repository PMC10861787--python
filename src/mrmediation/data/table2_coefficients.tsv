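exposure	mediator	beta_a	s_a	beta_b	s_b	beta_c	sobel_pval_printed	proportion_printed_pct	method	mediates
broad_depression	genus_Bifidobacterium	0.287	0.544	0.164	0.052	1.368	0.603	NA	none	FALSE
broad_depression	genus_Erysipelatoclostridium	-0.285	0.664	-0.111	0.051	1.368	0.674	NA	none	FALSE
broad_depression	genus_Streptococcus	-0.313	0.546	-0.043	0.014	1.368	0.573	NA	none	FALSE
broad_depression	phylum_Actinobacteria	0.927	0.513	-0.057	0.013	1.368	0.096	NA	none	FALSE
broad_depression	acetate	-0.514	0.239	-0.330	0.167	1.162	NA	12.60	difference	TRUE
broad_depression	beta_hydroxybutyrate	-0.051	0.186	0.257	0.090	1.368	0.785	NA	none	FALSE
broad_depression	insomnia	0.304	0.095	0.719	0.190	0.787	NA	16.00	difference	TRUE
MDD	genus_Bifidobacterium	0.053	0.177	0.164	0.052	0.932	0.767	NA	none	FALSE
MDD	genus_Erysipelatoclostridium	-0.069	0.224	-0.111	0.051	0.932	0.761	NA	none	FALSE
MDD	genus_Streptococcus	0.010	0.168	-0.043	0.014	0.932	0.955	NA	none	FALSE
MDD	phylum_Actinobacteria	-0.077	0.161	-0.057	0.013	0.932	0.180	NA	none	FALSE
MDD	acetate	0.069	0.062	-0.330	0.167	0.932	0.336	NA	none	FALSE
MDD	beta_hydroxybutyrate	-0.032	0.089	0.257	0.090	0.932	0.723	NA	none	FALSE
MDD	insomnia	0.210	0.040	0.719	0.190	0.932	0.002	16.20	product	TRUE
anxiety_disorder	genus_Bifidobacterium	0.006	0.045	0.164	0.052	0.040	0.900	NA	none	FALSE
anxiety_disorder	genus_Erysipelatoclostridium	-0.039	0.055	-0.111	0.051	0.040	0.501	NA	none	FALSE
anxiety_disorder	genus_Streptococcus	-0.037	0.043	-0.043	0.014	0.040	0.404	NA	none	FALSE
anxiety_disorder	phylum_Actinobacteria	0.073	0.056	-0.057	0.013	0.040	0.210	NA	none	FALSE
anxiety_disorder	acetate	0.000	0.020	-0.330	0.167	0.040	0.997	NA	none	FALSE
anxiety_disorder	beta_hydroxybutyrate	-0.005	0.028	0.257	0.090	0.040	0.854	NA	none	FALSE
anxiety_disorder	insomnia	0.007	0.008	0.719	0.190	0.040	0.365	NA	none	FALSE
PTSD	genus_Bifidobacterium	-0.107	0.190	0.164	0.052	0.651	0.580	NA	none	FALSE
PTSD	genus_Erysipelatoclostridium	0.143	0.242	-0.111	0.051	0.651	0.567	NA	none	FALSE
PTSD	genus_Streptococcus	0.054	0.197	-0.043	0.014	0.651	0.784	NA	none	FALSE
PTSD	phylum_Actinobacteria	-0.247	0.211	-0.057	0.013	0.651	0.259	NA	none	FALSE
PTSD	acetate	-0.143	0.062	-0.330	0.167	0.651	0.134	NA	none	FALSE
PTSD	beta_hydroxybutyrate	0.094	0.064	0.257	0.090	0.651	0.191	NA	none	FALSE
PTSD	insomnia	0.246	0.039	0.719	0.190	0.651	0.001	27.14	product	TRUE
schizophrenia	genus_Bifidobacterium	-0.042	0.047	0.164	0.052	0.077	0.390	NA	none	FALSE
schizophrenia	genus_Erysipelatoclostridium	0.035	0.055	-0.111	0.051	0.077	0.542	NA	none	FALSE
schizophrenia	genus_Streptococcus	0.043	0.040	-0.043	0.014	0.077	0.310	NA	none	FALSE
schizophrenia	phylum_Actinobacteria	-0.025	0.044	-0.057	0.013	0.077	0.573	NA	none	FALSE
schizophrenia	acetate	0.030	0.016	-0.330	0.167	0.077	0.177	NA	none	FALSE
schizophrenia	beta_hydroxybutyrate	0.152	0.055	0.257	0.090	0.077	0.047	50.76	product	TRUE
schizophrenia	insomnia	-0.003	0.008	0.719	0.190	0.077	0.684	NA	none	FALSE
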