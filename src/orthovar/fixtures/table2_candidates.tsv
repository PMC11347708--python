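gene	variant	species	exclusivity	rnaseq_validation	genomic_validation	pcr_validation	sift	polyphen	clinvar_accession	database_flags	hallmark	retained	note
ACE	p.R508H	hatl	exclusive_a	yes	yes	yes	T (0.57)	PsD (0.757)	-	literature	altered intercellular communication	true	results text reports p.R509H; RNA-seq and genomic support at 50%
ATM	p.R184Q	hmed	exclusive_b	yes	yes	yes	APF (0.00)	PbD (0.992)	VCV000481315.7	clinvar	genomic instability	true
ATM	p.Q2177R	hmed	exclusive_b	yes	yes	yes	APF (0.00)	PbD (0.999)	VCV001810514.4	clinvar	genomic instability	true
ATM	p.L8F	hatl	exclusive_a	yes	yes	yes	APF (0.03)	PbD (1.00)	VCV000487013.7	clinvar	genomic instability	true
ATM	p.V1085I	hatl	exclusive_a	yes	yes	yes	APF (0.01)	PbD (0.995)	VCV000453455.2	clinvar	genomic instability	true
ATM	p.I2914V	hatl	exclusive_a	yes	yes	yes	APF (0.03)	B (0.208)	VCV000187320.22	clinvar	genomic instability	true
ATM	p.V2937M	hatl	exclusive_a	yes	yes	yes	APF (0.01)	PsD (0.929)	VCV000187681.3	clinvar	genomic instability	true
BLM	p.M827V	hatl	exclusive_a	yes	yes	yes	T (0.10)	PbD (1.00)	-	literature	genomic instability	true	Drosophila melanogaster numbering gives M827I
BLM	p.I1039V	hatl	exclusive_a	yes	yes	yes	T (0.11)	B (0.004)	-	literature	genomic instability	true	Drosophila melanogaster numbering gives I1039A
BRCA2	p.S2807R	hmed	exclusive_b	yes	yes	yes	APF (0.00)	PbD (0.982)	VCV000216033.5	clinvar	genomic instability	true	polar to positively charged change in OB1 fold
BRCA2	p.S2807C	hatl	exclusive_a	yes	yes	yes	APF (0.00)	PsD (0.461)	VCV000441481.16	clinvar	genomic instability	true	polar to nonpolar change in OB1 fold
CETP	p.V29A	hmed	exclusive_b	no_reads	yes	yes	APF (0.02)	B (0.001)	-	uniprot_feature	deregulated nutrient sensing	true	BPI dimerization interface; same change in Latimeria chalumnae
DOCK8	p.R398H	hmed	exclusive_b	yes	yes	yes	APF (0.00)	PbD (0.999)	VCV000235481.7	clinvar	chronic inflammation	true	results text reports p.R393H; same change in one of three Salmo salar copies (parallel evolution)
FANCA	p.M427V	hatl	exclusive_a	yes	yes	not_done	-	B (0.271)	VCV001023721.1	clinvar	genomic instability	true
FANCI	p.S979T	hmed	exclusive_b	yes	yes	yes	-	B (0.230)	VCV000408250.1	clinvar	genomic instability	true	results text reports p.R393H
NUDT1	p.G99S	hmed	exclusive_b	yes	yes	yes	APF (0.00)	PsD (0.772)	-	conserved_domain_motif	genomic instability	true	nudix motif; results text reports p.G58S
SIRT1	p.V412I	hatl	exclusive_a	yes	yes	yes	APF (0.03)	PsD (0.925)	-	uniprot_feature	disabled macroautophagy	true	substrate-binding residue
XRCC5	p.E417Q	hatl	exclusive_a	yes	yes	yes	T (0.29)	PsD (0.770)	-	literature	genomic instability	true	heterodimer interface; same change in Hippoglossus hippoglossus (parallel evolution)
XRCC5	p.M427T	hatl	exclusive_a	yes	yes	yes	APF (0.00)	B (0.128)	-	literature	genomic instability	true	heterodimer interface; other changes at this position in long- and short-lived panels
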