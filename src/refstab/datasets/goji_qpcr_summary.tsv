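gene	efficiency_percent	r_squared	mean_ct	sd	cv	is_candidate
LbCYP	91.3	0.9953	20.19	2.166658889	0.107307139	1
LbTBP	101.0	0.9937	24.67	2.140584019	0.086744429	1
LbGAPDH	94.8	0.9775	22.46	2.267361358	0.100925407	1
LbTUB	96.1	0.9747	23.58	2.294896689	0.097316984	1
LbEF1a	92.2	0.9973	17.43	2.401203192	0.137725035	1
LbActin7	90.6	0.9962	20.29	1.841419014	0.090747549	1
LbHSP90	97.3	0.9502	18.55	2.043184756	0.110139076	1
LbHIS3	91.9	0.9957	17.18	1.561123661	0.090835934	1
LbCYC	98.5	0.9977	21.01	1.875417615	0.089258037	1
LbEIF4A	92.2	0.9543	20.79	1.830072065	0.087990277	1
LbPP2A	105.0	0.9857	21.17	1.30967704	0.061843202	1
LbUBQ	106.1	0.9993	20.14	2.090803559	0.103768094	1
LbCML38	105.7	0.9958	21.68	1.708817146	0.078819113	1
LbLEA	92.6	0.9851	18.37	1.741954661	0.094816225	1
LbEF1b	94.9	0.9947	18.88	1.674620435	0.088683577	1
LbSKIP	102.4	0.9936	25.02	2.10058639	0.083924345	1
LbRH52	97.5	0.9972	22.02	1.636191649	0.074287127	1
LbRPL7A	110.1	0.9536	20.99	1.774507767	0.084515702	1
LbMYB1	108.2	0.9809	21.11	3.398526812	0.16096409	0
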