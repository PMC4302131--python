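transcript_id	gene_symbol	process	heart_fc	liver_fc	kidney_fc	lung_fc
10810295	Dnajb1	PF	24.1	17.1	9.7	10.5
10756343	Hsph1	PF	14.8	12.4	11.6	15.7
10819787	Dnajb4	PF	4.5	6.3	3.5	3.7
10923050	LOC501135	PF	3.1	3.4	2.8	2.0
10939480	Morc4	PF	2.4	2.3	2.1	2.7
10869047	Hspa8	PF	2.2	3.4	2.1	2.9
10774470	Hspa8	PF	2.2	2.4	2.1	2.6
10927699	LOC363224	PF	2.1	2.9	2.7	3.1
10816048	N5	PF	2.1	2.3	2.1	2.6
10828154	Hspa1b	PF/RA	80.0	209.2	50.2	67.2
10886031	Fos	PF/RA	24.9	9.7	3.5	4.1
10827231	Cyr61	PF/RA	12.8	7.5	9.5	4.2
10806122	Hmox1	PF/RA	11.0	7.7	14.4	8.1
10878112	Jun	PF/RA	6.7	12.5	8.4	4.0
10868289	Dnaja1	PF/RA	6.7	2.6	3.6	5.5
10937318	Hsp90aa1	PF/RA	6.3	4.4	3.0	4.7
10892184	Hsp90aa1	PF/RA	6.0	6.5	5.9	5.0
10845384	Nr4a2	PF/RA	5.1	2.6	2.1	2.0
10723884	Serpinh1	PF/RA	3.4	4.3	6.0	3.4
10721865	Ppp1r15a	PF/RA	3.2	3.5	2.8	2.6
10910084	Dnaja4	PF/RA	2.9	25.2	4.7	4.7
10776667	Hspd1	PF/RA	2.6	3.1	2.3	6.1
10928154	Hspd1	PF/RA	2.3	3.6	2.4	6.9
10865855	Fkbp4	PF/RA	2.2	2.2	4.0	6.1
10895861	Ddit3	PF/RA	2.1	3.1	3.6	2.8
10770710	Atf3	RA	54.8	45.8	20.0	6.1
10868940	Nr4a3	RA	17.6	4.3	8.8	7.3
10761047	Serpine1	RA	12.3	2.4	4.8	6.0
10899387	Nr4a1	RA	10.5	6.0	4.1	2.4
10757082	Zfand2a	RA	8.1	27.8	7.7	6.9
10761128	Hspb1	RA	6.5	52.8	20.6	11.2
10711401	Bag3	RA	5.2	16.0	8.2	11.4
10931308	P4ha1	RA	5.0	7.0	5.5	4.4
10933015	MGC95208	RA	4.7	2.8	2.3	3.4
10769131	Cacybp	RA	4.6	3.6	3.1	6.7
10752650	MGC95208	RA	4.5	2.8	2.3	3.4
10940689	Ifrd1	RA	4.2	6.4	4.0	2.5
10917116	Zbtb16	RA	3.7	3.0	5.2	6.8
10749352	Jmjd6	RA	3.3	3.0	2.6	3.3
10732652	Dusp1	RA	2.9	2.1	3.5	4.2
10728361	Stip1	RA	2.9	3.7	3.7	5.7
10842469	Cebpb	RA	2.9	2.4	2.4	2.0
10940529	Cebpd	RA	2.7	2.5	2.9	3.4
10764643	Trmt1l	RA	2.5	3.2	2.2	3.1
10939516	Tsc22d3	RA	2.5	5.4	3.9	4.5
10702309	Tbpl1	RA	2.5	2.3	2.3	2.4
10758134	Ubb	RA	2.5	2.9	3.0	3.8
10794225	Nfil3	RA	2.3	2.8	4.2	2.6
10778763	Rel	RA	2.2	2.9	2.1	2.1
10861560	N5	RA	2.1	3.1	2.3	2.7
10795616	Crem	RA	2.0	2.4	2.5	2.9
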