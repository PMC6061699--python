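relationship_type	symbol	theme	direction	supporting_clusters
chemical-gene	A+	Agonism, activation	forward	6+
chemical-gene	A-	Antagonism, blocking	forward	6-
chemical-gene	B	Binding, ligand (esp. receptors)	forward	14,15,16
chemical-gene	E+	Increases expression/production	forward	8+,9+
chemical-gene	E-	Decreases expression/production	forward	8-,9-,10
chemical-gene	E	Affects expression/production (neutral)	forward	8,9,11a
chemical-gene	N	Inhibits	forward	3
chemical-gene	O	Transport, channels	reverse	19,21
chemical-gene	K	Metabolism, pharmacokinetics	reverse	11c
chemical-gene	Z	Enzyme activity	reverse	20
chemical-disease	T	Treatment/therapy (incl. investigatory)	forward	8g,8h,9
chemical-disease	C	Inhibits cell growth (esp. cancers)	forward	2,3
chemical-disease	Sa	Side effect/adverse event	forward	6,15,16
chemical-disease	Pr	Prevents, suppresses	forward	1,9,21,24,28
chemical-disease	Pa	Alleviates, reduces	forward	26,30
chemical-disease	J	Role in pathogenesis	forward	20
chemical-disease	Mp	Biomarkers (progression)	reverse	18,19
gene-disease	U	Causal mutations	forward	14
gene-disease	Ud	Mutations affect disease course	forward	13
gene-disease	D	Drug targets	forward	10,12
gene-disease	J	Role in pathogenesis	forward	2h,4,6,8,9
gene-disease	Te	Possible therapeutic effect	forward	2j,3
gene-disease	Y	Polymorphisms alter risk	forward	22,26,27
gene-disease	G	Promotes progression	forward	29
gene-disease	Md	Biomarkers (diagnostic)	reverse	5,7
gene-disease	X	Overexpression in disease	reverse	15,17,30
gene-disease	L	Improper regulation linked to disease	reverse	18,19,21
gene-gene	B	Binding, ligand (esp. receptors)	forward	10
gene-gene	W	Enhances response	forward	13
gene-gene	V+	Activates, stimulates	forward	14,16
gene-gene	E+	Increases expression/production	forward	21,22
gene-gene	E	Affects expression/production (neutral)	forward	7,17
gene-gene	I	Signaling pathway	forward	24
gene-gene	H	Same protein or complex	forward	25
gene-gene	Rg	Regulation	forward	28,30
gene-gene	Q	Production by cell population	forward	1,2,6
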