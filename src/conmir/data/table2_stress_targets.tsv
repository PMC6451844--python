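family	mirna_name	drought	salt	target_gene_id	product
miR156	miR156-3p	1	1	EMS63385.1	Argonaute 1B
miR159	miR159-3p	1	1	EMS55264.1	IAA-amino acid hydrolase ILR1-like 5
miR159	miR159-3p	1	1	EMS66412.1	IAA-amino acid hydrolase ILR1-like 3
miR159	miR159-5p	1	1	EMS59656.1	Acetyl-CoA carboxylase
miR165	miR165	0	1	EMS60006.1	3-ketoacyl-CoA synthase 6
miR166	miR166	1	1	EMS47855.1	Putative glutathione S-transferase
miR166	miR166-5p	1	1	EMS67450.1	Zinc finger CCCH domain-containing protein 45
miR168	miR168-5p	1	1	EMS63385.1	Protein argonaute 1B
miR168	miR168	1	1	EMS63385.1	Protein argonaute 1B
miR168	miR168-5p	1	1	EMS48655.1	Proline-rich receptor-like protein kinase PERK13
miR168	miR168-5p	1	1	EMS55864.1	Mitogen-activated protein kinase 17
miR168	miR168	1	1	EMS55864.1	Mitogen-activated protein kinase 17
miR168	miR168-5p	1	1	EMS62275.1	Receptor-like protein kinase
miR169	miR169	1	1	EMS46116.1	D repeat and FYVE domain-containing protein 3
miR169	miR169	1	1	EMS61213.1	Protein TIFY 6B
miR172	miR172	1	1	EMS66886.1	Trihelix transcription factor GT-2
miR172	miR172-5p	1	1	EMS50683.1	Cell division cycle 5-like protein
miR393	miR393	1	1	EMS56796.1	Hypothetical protein
miR395	miR395-5p	1	1	EMS53304.1	Hypothetical protein
miR395	miR395-5p	1	1	EMS68547.1	Alpha-glucan water dikinase, chloroplastic
miR396	miR396-3p	1	1	EMS61897.1	ATP-dependent DNA helicase MPH1
miR398	miR398-3p	1	1	EMS67509.1	Copper chaperone for superoxide dismutase
miR398	miR398-3p	1	1	EMS45437.1	Pectinesterase
miR399	miR399	1	1	EMS47483.1	Disease resistance protein RGA2
miR399	miR399	1	1	EMS48356.1	Hypothetical protein
miR408	miR408	1	1	EMS53029.1	DNA polymerase epsilon catalytic subunit A
miR444	miR444	1	1	EMS60248.1	Hypothetical protein
miR529	miR529	1	1	EMS53316.1	Transcriptional corepressor SEUSS
miR845	miR845-5p	1	0	EMS63076.1	Hypothetical protein
miR5049	miR5049	1	1	EMS46913.1	Pyruvate decarboxylase isozyme 2
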