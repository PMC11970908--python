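# Default exclusion list for differential expression: immediate-early,
# heat-shock and stress-response genes induced by tissue dissociation.
# Override with a user-supplied gene set where a different list applies.
Fos
Fosb
Jun
Junb
Jund
Egr1
Egr2
Atf3
Atf4
Ier2
Ier3
Ier5
Btg1
Btg2
Dusp1
Dusp2
Dusp5
Dusp6
Klf2
Klf4
Klf6
Nr4a1
Socs3
Zfp36
Hspa1a
Hspa1b
Hspa5
Hspa8
Hspb1
Hsp90aa1
Hsp90ab1
Hspe1
Hsph1
Dnaja1
Dnajb1
Cebpb
Cebpd
Mcl1
Ppp1r15a
Sgk1
Ubc
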