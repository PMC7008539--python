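metabolite	study	direction
L-Valine	CR33	enriched
L-Valine	CR35	enriched
L-Valine	CR41	enriched
L-Valine	CR62	enriched
L-Valine	CR64	enriched
Stearic acid	CR31	enriched
Stearic acid	CR34	enriched
Stearic acid	CR44	enriched
Stearic acid	CR62	enriched
L-Arginine	CR33	enriched
L-Arginine	CR35	enriched
L-Arginine	CR41	enriched
Phenylalanine	CR33	enriched
Phenylalanine	CR34	enriched
Phenylalanine	CR41	enriched
Phenylalanine	CR44	enriched
Spermidine	CR35	enriched
Spermidine	CR48	enriched
Spermidine	CR55	enriched
Taurine	CR32	enriched
Taurine	CR34	enriched
Taurine	CR35	enriched
Taurine	CR40	enriched
Taurine	CR41	enriched
Taurine	CR42	enriched
Taurine	CR43	enriched
Taurine	CR48	enriched
Taurine	CR63	enriched
L-Threonine	CR33	enriched
L-Threonine	CR35	enriched
L-Threonine	CR41	enriched
L-Threonine	CR42	enriched
L-Threonine	CR62	enriched
L-Threonine	CR64	enriched
Glutathione	CR35	enriched
Glutathione	CR41	enriched
Glutathione	CR47	enriched
Glutathione	CR64	enriched
Putrescine	CR35	enriched
Putrescine	CR41	enriched
Putrescine	CR48	enriched
Palmitic acid	CR31	enriched
Palmitic acid	CR34	enriched
Palmitic acid	CR44	enriched
Proline	CR33	enriched
Proline	CR34	enriched
Proline	CR35	enriched
Proline	CR41	enriched
Proline	CR44	enriched
Proline	CR62	enriched
Asparagine	CR33	enriched
Asparagine	CR35	enriched
Asparagine	CR41	enriched
Asparagine	CR62	enriched
Hypoxanthine	CR33	enriched
Hypoxanthine	CR35	enriched
Hypoxanthine	CR44	enriched
Lactic acid	CR31	enriched
Lactic acid	CR32	enriched
Lactic acid	CR34	enriched
Lactic acid	CR35	enriched
Lactic acid	CR40	enriched
Lactic acid	CR41	enriched
Lactic acid	CR42	enriched
Lactic acid	CR62	enriched
Lactic acid	CR63	enriched
Aspartic acid	CR30	enriched
Aspartic acid	CR33	enriched
Aspartic acid	CR35	enriched
Aspartic acid	CR41	enriched
Aspartic acid	CR42	enriched
Aspartic acid	CR47	enriched
Cholesterol	CR32	enriched
Cholesterol	CR33	enriched
Cholesterol	CR34	enriched
Cholesterol	CR44	enriched
Cholesterol	CR62	enriched
Glutamic acid	CR33	enriched
Glutamic acid	CR35	enriched
Glutamic acid	CR41	enriched
Glutamic acid	CR42	enriched
Glutamic acid	CR44	enriched
Glutamic acid	CR47	enriched
Tyrosine	CR33	enriched
Tyrosine	CR35	enriched
Tyrosine	CR44	enriched
Tyrosine	CR63	enriched
Tyrosine	CR64	depleted
Choline	CR32	enriched
Choline	CR34	enriched
Choline	CR40	enriched
Choline	CR44	enriched
Choline	CR50	enriched
Choline	CR51	enriched
Choline	CR52	enriched
Choline	CR63	enriched
Uridine	CR34	enriched
Uridine	CR41	enriched
Uridine	CR44	enriched
Uridine	CR62	enriched
Serine	CR33	enriched
Serine	CR35	enriched
Serine	CR41	enriched
Serine	CR62	enriched
Serine	CR64	enriched
Vaccenic acid	CR31	enriched
Vaccenic acid	CR34	enriched
Vaccenic acid	CR44	enriched
Vaccenic acid	CR33	depleted
Lysine	CR33	enriched
Lysine	CR35	enriched
Lysine	CR41	enriched
Lysine	CR44	enriched
Glycine	CR31	enriched
Glycine	CR33	enriched
Glycine	CR34	enriched
Glycine	CR35	enriched
Glycine	CR41	enriched
Glycine	CR45	enriched
Glycine	CR62	enriched
Glycine	CR32	depleted
Methionine	CR33	enriched
Methionine	CR35	enriched
Methionine	CR44	enriched
Methionine	CR62	enriched
Isoleucine	CR33	enriched
Isoleucine	CR35	enriched
Isoleucine	CR41	enriched
Isoleucine	CR62	enriched
Isoleucine	CR64	enriched
Glucose	CR31	depleted
Glucose	CR32	depleted
Glucose	CR40	depleted
Glucose	CR41	depleted
Glucose	CR42	depleted
Glucose	CR44	depleted
Glucose	CR62	depleted
Glucose	CR64	depleted
Glutamine	CR64	enriched
Glutamine	CR33	depleted
Glutamine	CR35	depleted
Glutamine	CR38	depleted
Myoinositol	CR42	depleted
Myoinositol	CR44	depleted
Myoinositol	CR47	depleted
Myoinositol	CR50	depleted
Myoinositol	CR64	depleted
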