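transcript_id	gene	mean_fragments	sd	cv	is_candidate
CL10201.Contig1_All	LbCYP	1142.214286	718.6318388	0.62915676	1
CL1082.Contig3_All	LbTBP	138.5714286	38.5141618	0.27793725	1
Unigene36249_All	LbGAPDH	145.4285714	68.28527748	0.46954513	1
CL13903.Contig10_All	LbTUB	57.57142857	57.88412069	1.005431377	1
CL2539.Contig4_All	LbEF1a	3196.071429	823.6067456	0.257693473	1
CL4826.Contig3_All	LbActin7	626.5714286	191.7922411	0.306097968	1
Unigene44516_All	LbHSP90	126.0714286	53.97501457	0.428130427	1
CL13810.Contig1_All	LbHIS3	2307.928571	612.946536	0.265582975	1
CL10058.Contig1_All	LbCYC	1009	92.22297394	0.091400371	1
Unigene55248_All	LbEIF4A	2087.928571	165.8161467	0.07941658	1
Unigene19346_All	LbPP2A	831.8571429	99.63923937	0.119779268	1
CL11175.Contig21_All	LbUBQ	1211.428571	186.5371542	0.153981141	1
Unigene15131_All	LbCML38	695	106.1066227	0.1526714	1
CL7969.Contig1_All	LbLEA	525.7142857	113.3995174	0.215705604	1
Unigene31075_All	LbEF1b	5663	1138.411849	0.201026285	1
Unigene26461_All	LbSKIP	612.5	120.2361459	0.196303912	1
Unigene55138_All	LbRH52	950.4285714	113.8816621	0.119821379	1
Unigene59903_All	LbRPL7A	793.6428571	149.1166849	0.187888902	1
Unigene59939_All	LbMYB1	2982.571429	697.3143085	0.233796348	0
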