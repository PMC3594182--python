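# N-terminally acetylated poplar (Populus simonii x P. nigra) proteins identified
# by nanoUPLC-ESI-MS/MS after TiO2 enrichment, one row per protein.
# protein_id is the JGI Populus trichocarpa v1.1 protein identifier.
# nat_annotation is the source table's putative Nat call, kept for validation only.
# The "Vla" in the source's group (ii) residue tally is recorded here as Val
# (row 739954, Ac-Val-Ser-Arg-); presumed typographic.
protein_id	description	nterm_label	nat_annotation
644907	S-adenosylmethionine synthetase 2	Ac-Met-Glu-Thr-	NatB
834837	S-adenosylmethionine synthetase 2	Ac-Met-Glu-Thr-	NatB
729359	S-adenosylmethionine synthetase 4	Ac-Met-Glu-Thr-	NatB
727847	NAD(P)-binding Rossmann-fold-containing protein	Ac-Met-Glu-Ser-	NatB
711545	Rotamase FKBP 1	Ac-Met-Glu-Glu-	NatB
742325	Putative PR-10 type pathogenesis-related proteins	Ac-Met-Glu-Val-	NatB
552891	1-aminocyclopropane-1-carboxylate oxidase-1	Ac-Met-Glu-Val-	NatB
584641	cAMP-regulated phosphoprotein 19-related protein	Ac-Met-Glu-Asp-	NatB
657667	Auxin/aluminum-responsive protein, putative	Ac-Met-Leu-Gly-	NatC, or NatE, or NatF
814125	HSBP (heat shock factor binding protein)	Ac-Met-Asp-Gly-	NatB
794816	Polyphenol oxidase	Ac-Met-Gly-Asn-	NatF
557663	Ran-binding protein 1-c	Ac-Ala-Ser-Thr-	NatA
173568	Ran-binding protein 1-b	Ac-Ala-Ser-Thr-	NatA
568329	Adenine nucleotide alpha hydrolases-like protein	Ac-Ala-Ser-Ser-	NatA
815719	L-galactose dehydrogenase	Ac-Ala-Ser-Pro-	NatA
836295	Peroxin 19-1	Ac-Ala-Asp-Gln-	NatA
817164	Peroxin 19-1	Ac-Ala-Asp-Gln-	NatA
561044	NMT1 (protein N-myristoyltransferase 1)	Ac-Ala-Asp-Asn-	NatA
247052	Nuclear transcription factor Y subunit B-3	Ac-Ala-Asp-Ser-	NatA
832542	Heat shock protein 70	Ac-Ala-Gly-Lys-	NatA
578767	Glyceraldehyde-3-phosphate dehydrogenase	Ac-Ala-Gly-Lys-	NatA
563894	Heat shock protein 70	Ac-Ala-Gly-Lys-	NatA
280896	Heat shock protein 70	Ac-Ala-Gly-Lys-	NatA
675629	Heat shock protein 70	Ac-Ala-Gly-Lys-	NatA
822482	Heat shock protein 70	Ac-Ala-Gly-Thr-	NatA
817912	HMGA (high mobility group protein A)	Ac-Ala-Ala-Glu-	NatA
766915	HMGA (high mobility group protein A)	Ac-Ala-Ala-Thr-	NatA
724015	S-adenosylmethionine synthetase 1	Ac-Ala-Glu-Thr-	NatA
564333	S-adenosylmethionine synthetase 1	Ac-Ala-Glu-Thr-	NatA
589531	DEAD-box ATP-dependent RNA helicase 38	Ac-Ala-Glu-Val-	NatA
203151	RNA-binding protein 8A	Ac-Ala-Asn-Thr-	NatA
172155	RNA-binding protein 8A	Ac-Ala-Asn-Thr-	NatA
648073	Translation initiation factor eIF-5	Ac-Ala-Leu-Gln-	NatA
553039	Translation initiation factor eIF-5	Ac-Ala-Leu-Gln-	NatA
590689	Translation initiation factor eIF-5	Ac-Ala-Leu-Gln-	NatA
830730	Plasminogen activator inhibitor 1	Ac-Ala-Thr-Ala-	NatA
551211	40S ribosomal protein S12-2	Ac-Ser-Gly-Glu-	NatA
714910	40S ribosomal protein S12-2	Ac-Ser-Gly-Glu-	NatA
834953	SUMO2 (small ubiquitin-related modifier 2)	Ac-Ser-Gly-Val-	NatA
711526	SUMO2 (small ubiquitin-related modifier 2)	Ac-Ser-Gly-Ala-	NatA
717121	Translation initiation factor eIF-5A	Ac-Ser-Asp-Glu-	NatA
832646	Translation initiation factor eIF-5A	Ac-Ser-Asp-Glu-	NatA
835953	Translation initiation factor eIF-5A	Ac-Ser-Asp-Glu-	NatA
724093	Translation initiation factor eIF-5A	Ac-Ser-Asp-Glu-	NatA
740524	WPP domain-containing protein 2	Ac-Ser-Asp-Ser-	NatA
819223	Metallopeptidase M24 protein	Ac-Ser-Ser-Asp-	NatA
577003	Metallopeptidase M24 protein	Ac-Ser-Ser-Asp-	NatA
836390	T-complex protein 1 alpha subunit	Ac-Ser-Ile-Ala-	NatA
819264	Nucleosome assembly protein 1;2	Ac-Ser-Asn-Asp-	NatA
736146	Glucose-6-phosphate dehydrogenase	Ac-Gly-Ser-Gly-	NatA
641721	Glucose-6-phosphate dehydrogenase	Ac-Gly-Ser-Gly-	NatA
825441	Phosphoglycerate mutase	Ac-Gly-Ser-Pro-	NatA
739967	26S proteasome AAA-ATPase subunit RPT1a	Ac-Gly-Ser-Gly-	NatA
819597	DEAD-box ATP-dependent RNA helicase 56	Ac-Gly-Glu-Thr-	NatA
578196	DEAD-box ATP-dependent RNA helicase 56	Ac-Gly-Thr-Asn-	NatA
735121	Ser/thr protein phosphatase PP2A catalytic subunit	Ac-Gly-Thr-Asn-	NatA
739954	Putative trehalose-6-phosphate synthase	Ac-Val-Ser-Arg-	NatA
553698	CASC3/Barentsz eIF4AIII binding protein	Ac-Thr-Lys-Val-	NatA
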