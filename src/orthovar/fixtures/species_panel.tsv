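species_id	display_name	group	max_lifespan_years
hsap	Homo sapiens	reference	122
hatl	Hoplostethus atlanticus	focal_a	250
hmed	Hoplostethus mediterraneus	focal_b	11
ptro	Pan troglodytes	comparison	59
mmus	Mus musculus	comparison	4
hgla	Heterocephalus glaber	comparison	37
cfam	Canis lupus familiaris	comparison	24
ggal	Gallus gallus	comparison	30
drer	Danio rerio	comparison	5.5
olat	Oryzias latipes	comparison	5
omyk	Oncorhynchus mykiss	comparison	11
ssal	Salmo salar	comparison	13
nfur	Nothobranchius furzeri	comparison	1
sale	Sebastes aleutianus	long_lived	205
afim	Anoplopoma fimbria	long_lived	94
hhip	Hippoglossus hippoglossus	long_lived	50
aang	Anguilla anguilla	long_lived	88
enew	Eucyclogobius newberryi	short_lived	3
pocc	Poeciliopsis occidentalis	short_lived	3
nkuh	Nothobranchius kuhntae	short_lived	1
hzos	Hippocampus zosterae	short_lived	1
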