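term	term_id	term_type	category	heart_es	liver_es	kidney_es	lung_es
Protein folding	6457	BP	Protein folding/unfolding response	23.5	10.9	13.3	39.8
Unfolded protein binding	51082	MF	Protein folding/unfolding response	14.4	12.0	16.0	32.7
Heat-shock protein binding	31072	MF	Protein folding/unfolding response	13.4	5.8	7.3	15.9
Response to heat	9408	BP	Protein folding/unfolding response	9.3	15.2	10.7	13.6
Chaperone binding	51087	MF	Protein folding/unfolding response	7.6	8.6	12.7	8.5
Response to unfolded protein	6986	BP	Protein folding/unfolding response	7.3	14.9	19.9	19.1
Positive regulation of apoptotic process	43065	BP	Response to apoptosis	11.8	12.3	9.3	12.5
Negative regulation of neuron apoptotic process	43524	BP	Response to apoptosis	7.9	8.3	7.5	7.7
Response to lipopolysaccharide	32496	BP	Response to LPS/cytokines	5.7	10.1	3.2	11.1
Response to cytokine stimulus	34097	BP	Response to LPS/cytokines	4.8	6.2	4.5	15.5
RNA polymerase II core promoter proximal region sequence-specific DNA binding transcription factor activity involved in positive regulation of transcription	1077	MF	Transcriptional Response/Other	15.4	6.6	10.5	6.1
Response to cAMP	51591	BP	Transcriptional Response/Other	10.7	3.1	5.5	4.8
Double-stranded DNA binding	3690	MF	Transcriptional Response/Other	8.4	7.0	8.5	7.8
Response to mechanical stimulus	9612	BP	Transcriptional Response/Other	8.3	5.6	5.1	4.6
Response to hydrogen peroxide	42542	BP	Transcriptional Response/Other	7.9	6.6	8.1	5.9
Transcription factor complex	5667	CC	Transcriptional Response/Other	7.5	4.8	5.6	5.0
Positive regulation of smooth muscle cell proliferation	48661	BP	Transcriptional Response/Other	6.2	3.6	6.1	4.9
Response to glucocorticoid stimulus	51384	BP	Transcriptional Response/Other	5.8	11.5	4.8	3.9
Negative regulation of transcription from RNA polymerase II promoter	122	BP	Transcriptional Response/Other	5.8	6.0	7.0	4.8
Response to hypoxia	1666	BP	Transcriptional Response/Other	5.5	8.4	7.8	12.3
Response to estrogen stimulus	43627	BP	Transcriptional Response/Other	5.5	5.9	8.1	4.7
Cell surface	9986	CC	Transcriptional Response/Other	5.1	7.0	4.8	6.7
Positive regulation of angiogenesis	45766	BP	Transcriptional Response/Other	4.8	6.6	8.7	10.8
Response to light stimulus	9416	BP	Transcriptional Response/Other	3.8	7.6	10.4	6.0
Response to drug	42493	BP	Transcriptional Response/Other	3.7	7.8	6.9	3.2
MAPK signaling pathway	rno04010	KEGG	MAPK Pathway	5.0	2.8	5.3	3.3
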