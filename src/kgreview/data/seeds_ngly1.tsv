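id	semantic_group	preflabel	name	synonyms	description	taxon
HGNC:17646	GENE	NGLY1	N-glycanase 1	PNGase	Human gene encoding the cytosolic peptide:N-glycanase	human
HGNC:633	GENE	AQP1	aquaporin 1		Human water channel gene	human
MGI:103201	GENE	Aqp1	aquaporin 1 (mouse)		Mouse ortholog of AQP1	mouse
HGNC:24622	GENE	ENGASE	endo-beta-N-acetylglucosaminidase		Human cytosolic ENGase gene	human
HGNC:7781	GENE	NFE2L1	NFE2 like bZIP transcription factor 1	NRF1	Transcription factor dependent on NGLY1	human
HGNC:636	GENE	AQP3	aquaporin 3		Human aquaglyceroporin gene	human
HGNC:19940	GENE	AQP11	aquaporin 11		Human aquaporin gene	human
HMDB:HMDB00215	CHEMICAL	GlcNAc	N-acetyl-D-glucosamine		Metabolite implicated in the disease mechanism
OMIM:615273	DISO	NGLY1 Deficiency	congenital disorder of deglycosylation	CDDG	Ultra-rare genetic disease caused by NGLY1 loss of function	human
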