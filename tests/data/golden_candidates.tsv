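locus_tag	fc_mutant	fc_wt	gene_name	product	position	motif	operon_structure
sg0006	-3.488080413035688	6.756238173937359	-	-	-188	TTGATTGCTCGCAA	-
sg0018	-6.419696262371664	15.380736916412946	-	-	-60	TTGAACTTTTTTAA	sg0018-sg0017-sg0016-sg0015-sg0014-sg0013-sg0012
sg0017	-14.876055364552531	20.656925317343262	-	-	-	-	sg0018-sg0017-sg0016-sg0015-sg0014-sg0013-sg0012
sg0016	-2.4857016013297093	9.345633060145868	-	-	-	-	sg0018-sg0017-sg0016-sg0015-sg0014-sg0013-sg0012
sg0015	-7.292616876795029	8.941075873274746	-	-	-	-	sg0018-sg0017-sg0016-sg0015-sg0014-sg0013-sg0012
sg0014	-5.111018981899695	9.929392621588583	-	-	-	-	sg0018-sg0017-sg0016-sg0015-sg0014-sg0013-sg0012
sg0013	-8.653266310993411	4.714596646751714	-	-	-	-	sg0018-sg0017-sg0016-sg0015-sg0014-sg0013-sg0012
sg0012	-6.544491701558048	3.9640852274779	-	-	-	-	sg0018-sg0017-sg0016-sg0015-sg0014-sg0013-sg0012
sg0024	-10.598794195176657	7.681354799072774	-	-	-235	TAGATACCTGGCAA	-
sg0032	-4.889323389486086	4.387011057377114	-	-	-80	TTGCAATCACTCAA	sg0032-sg0031-sg0030
sg0031	-9.557307475075516	24.85438821760759	-	-	-	-	sg0032-sg0031-sg0030
sg0030	-7.1162709308356655	30.048895337162318	-	-	-	-	sg0032-sg0031-sg0030
sg0038	-3.967399234000497	11.79497465757394	-	-	-90	CTGCGACAGAGCAA	sg0038-sg0039
sg0039	-12.785670184551607	3.596607618365496	-	-	-	-	sg0038-sg0039
sg0040	-9.271380522539612	4.08439523968478	-	-	-211	TTGACGATTCTCAA	-
sg0041	-5.822353169522404	8.73880646478188	-	-	-123	TTGAGAATCGTCAA	-
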