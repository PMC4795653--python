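gene	species	variant_id	clone_ids	event_types	atg	cds	cds_key	go_terms	note
Meis2	Mouse	1a	LA0AAA56YF23.CONTIG		-	-	1a		reference (U68383.1)
Meis2	Mouse	1b	LA0AAA12YB24.CONTIG	exon_skipping	+	+	1b		lacks coding exons 8-10
Meis2	Mouse	1c	LA0AAA56YF23ALT		+	-	1c		initiation-codon variant recorded in the source catalog footnote; does not match the reference
Otx2	Rat	2a	LA0ACA23YG03.CONTIG		+	-	2a		reference (NM_001100566.1)
Otx2	Rat	2b	LA0ACA6YL17.CONTIG	alt_3ss	+	+	2b		longer exon 2
Otx2	Rat	2c	LA0ACA63YE20CM1	alt_5ss	+	+	2c		smaller exon 2
Rax	Mouse	3a	LA0AAA88YP21.CONTIG		+	-	3a		reference (BC058757.1)
Rax	Mouse	3b	LA0AAA5YJ22.CONTIG	alt_3ss	-	+	3b		shorter exon 3
Rax	Mouse	3c	LA0AAA89YO03.CONTIG	alt_5ss;alt_3ss	+	+	3c		shorter exons 2 and 3
Rax	Mouse	3d	LA0AAA80YH01.CONTIG	exon_skipping	+	+	3d		lacks exon 2
Rax	Mouse	3e	3030000051432591	exon_skipping	+	+	3e		extra exon 4
Ring1	Mouse	4a	LA0AAA124YH09.CONTIG		-	-	4a		reference (BC009070)
Ring1	Mouse	4b	LA0AAA14YL18.CONTIG	intron_retention	-	+	4b		larger exon 4
Ring1	Mouse	4c	LA0AAA34YG11.CONTIG	exon_skipping	+	+	4c		shorter exon 4
Ring1	Mouse	4d	LA0AAA95YP19.CONTIG	intron_retention	-	+	4d		larger exon 5
Rorb	Mouse	5a	3030000046806503		-	-	5a		reference (DQ779924)
Rorb	Mouse	5b	LA0AAA121YD06.CONTIG		+	+	5b		isoform DQ779923
Rorb	Mouse	5c	LA0AAA37YI10.CONTIG	exon_skipping	+	+	5c		extra exon 2 (BC024842.1)
Vax2	Mouse	6a	LA0AAA100YK05.CONTIG	exon_skipping	+	-	6a		reference (Y17792.1)
Vax2	Mouse	6b	LA0AAA124YD10.CONTIG		+	+	6b		extra exon 3
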