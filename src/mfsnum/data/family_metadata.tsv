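# MFS family metadata: the proteins whose family alignments define
# superfamily conservation. UniRef50 cluster seed = the UniProt ID.
protein	family	uniprot_id	substrate	direction	species
FucP	MFS_1	P11551	Fucose/H+ symport	Into cell	E. coli
GlpT	MFS_1	P08194	Glycerol-3P/Pi antiport	Into cell	E. coli
EmrD	DHA12	P31442	Multidrug/H+ antiport	Out of cell	E. coli
YajR	DHA12	P77726	Multidrug/H+ antiport	Out of cell	E. coli
LacY	lacy_symport	P02920	Galactose/H+ symport	Into cell	E. coli
PepT	POT	Q8EKT7	Peptide/H+ symport	Into cell	Streptococcus thermophilus
YgbH	POT	P75742	Peptide/H+ symport	Into cell	E. coli
GlcPse		Q8CQA7	Glucose/H+ symport	Into cell	Staphylococcus epidermis
gkPOT	POT	Q5KYD1	Peptide/H+ symport	Into cell	Geobacillus kaustophilus
GLUT1	SP	P11166	Glucose uniport	Into cell	Homo sapiens
PiPT	SP	A8N031	Phosphate/H+ symport	Into cell	Piriformospora indica
NRT1.1	NRT1/PTR	Q05085	Nitrite/H+ symport	Into cell	Arabidopsis thaliana
NarU	NNP	P37758	Nitrate/nitrite symport	Into cell	E. coli
XylE	SP	P0AGF4	Xylose/H+ symport	Into cell	E. coli
MelB	Glycoside-pentoside-hexuronide: cation symporter	P30878	Melibose/Na+ symport	Into cell	Salmonella typhimurium
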