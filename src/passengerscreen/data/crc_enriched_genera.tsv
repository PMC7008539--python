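genus	motu	auc	adj_p
Parvimonas	Parvimonas_micra [1145]	0.71	1.8e-20
Parvimonas	Parvimonas_sp._oral_taxon_110 [4961]	0.57	3.7e-08
Dialister	Dialister mOTU [0561]	0.65	5e-20
Gemella	Gemella_morbillorum [4513]	0.7	3e-18
Fusobacterium	Fusobacterium_nucleatum_subsp._animalis [0776]	0.66	9.6e-17
Fusobacterium	Fusobacterium_nucleatum_subsp._nucleatum [0777]	0.57	4.4e-08
Fusobacterium	Fusobacterium_nucleatum_subsp._vincentii [0754]	0.57	2.1e-07
Fusobacterium	Fusobacterium_sp._oral_taxon_370 [1403]	0.56	3.7e-07
Peptostreptococcus	Peptostreptococcus_stomatis [4614]	0.67	8.4e-16
Porphyromonas	Porphyromonas mOTU [2350]	0.61	1.6e-13
Porphyromonas	Porphyromonas_somerae [2101]	0.57	5.5e-09
Porphyromonas	Porphyromonas_asaccharolytica [1517]	0.58	2.9e-08
Porphyromonas	Porphyromonas mOTU [0125]	0.57	1.1e-07
Porphyromonas	Porphyromonas mOTU [1184]	0.56	8.6e-07
Porphyromonas	Porphyromonas_uenonis [2102]	0.59	1.7e-10
Solobacterium	Solobacterium_moorei [0531]	0.64	1.7e-10
Lachnoclostridium	Clostridium_symbiosum [1475]	0.67	2.3e-10
Hungatella	Hungatella_hathewayi [0882]	0.66	3.7e-09
Prevotella	Prevotella_intermedia [0515]	0.58	2.8e-09
Prevotella	Prevotella_nigrescens [0276]	0.56	5.5e-08
Anaerococcus	Anaerococcus_sp._obesiensis/vaginalis [0429]	0.58	6.6e-07
Blautia	Ruminococcus_torques [1376]	0.64	1.5e-07
Anaerotruncus	Anaerotruncus mOTU [1529]	0.6	1e-06
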