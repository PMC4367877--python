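# Synthetic stand-in for the EBI generic GO slim: a hand-curated list of
# broad GO terms spanning the three namespaces. Regenerate from the EBI
# QuickGO generic slim to match a specific release.
GO:0008152	metabolic process
GO:0009058	biosynthetic process
GO:0009056	catabolic process
GO:0005975	carbohydrate metabolic process
GO:0006629	lipid metabolic process
GO:0019538	protein metabolic process
GO:0006259	DNA metabolic process
GO:0006281	DNA repair
GO:0006310	DNA recombination
GO:0032196	transposition
GO:0006412	translation
GO:0006355	regulation of DNA-templated transcription
GO:0006091	generation of precursor metabolites and energy
GO:0007049	cell cycle
GO:0006810	transport
GO:0006950	response to stress
GO:0009607	response to biotic stimulus
GO:0009628	response to abiotic stimulus
GO:0007165	signal transduction
GO:0030154	cell differentiation
GO:0048856	anatomical structure development
GO:0009790	embryo development
GO:0040007	growth
GO:0008219	cell death
GO:0005488	binding
GO:0003677	DNA binding
GO:0003723	RNA binding
GO:0001071	nucleic acid binding transcription factor activity
GO:0003700	DNA-binding transcription factor activity
GO:0003824	catalytic activity
GO:0016301	kinase activity
GO:0005215	transporter activity
GO:0005198	structural molecule activity
GO:0005634	nucleus
GO:0005737	cytoplasm
GO:0005739	mitochondrion
GO:0009536	plastid
GO:0005886	plasma membrane
GO:0016020	membrane
GO:0005618	cell wall
GO:0005576	extracellular region
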