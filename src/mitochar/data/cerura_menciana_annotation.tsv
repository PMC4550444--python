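# Published annotation table of the Cerura menciana mitogenome (printed
# coordinates, sizes, anticodons, start/stop codons and intergenic column,
# kept verbatim including its internal inconsistencies).
#genome_length=15369
gene	class	direction	start	end	size	anticodon	start_codon	stop_codon	intergenic
trnM	tRNA	F	1	68	68	CAT			0
trnI	tRNA	F	69	134	66	GAT			-3
trnQ	tRNA	R	132	200	69	TTG			57
nad2	PCG	F	258	1271	1014		ATT	TAA	17
trnW	tRNA	F	1289	1361	73	TCA			-8
trnC	tRNA	R	1354	1422	69	GCA			2
trnY	tRNA	R	1425	1490	66	GTA			5
cox1	PCG	F	1496	3026	1531		CGA	T	0
trnL2	tRNA	F	3027	3093	67	TAA			0
cox2	PCG	F	3094	3775	682		ATG	T	0
trnK	tRNA	F	3776	3846	71	CTT			-1
trnD	tRNA	F	3846	3911	67	GTC			0
atp8	PCG	F	3912	4070	159		ATC	TAA	-7
atp6	PCG	F	4064	4741	678		ATG	TAA	-1
cox3	PCG	F	4741	5529	789		ATG	TAA	2
trnG	tRNA	F	5532	5597	66	TCC			0
nad3	PCG	F	5598	5951	354		ATC	TAA	53
trnA	tRNA	F	6005	6074	70	TGC			-1
trnR	tRNA	F	6074	6137	64	TCG			3
trnN	tRNA	F	6141	6205	65	GTT			1
trnS1	tRNA	F	6207	6276	70	GCT			1
trnE	tRNA	F	6278	6345	68	TTC			-2
trnF	tRNA	R	6344	6410	67	GAA			-2
nad5	PCG	R	6409	8152	1744		ATT	TAA	-2
trnH	tRNA	R	8151	8216	66	GTG			-2
nad4	PCG	R	8215	9557	1339		ATA	TA	-4
nad4L	PCG	R	9554	9841	288		ATT	TAA	14
trnT	tRNA	F	9856	9920	65	TGT			0
trnP	tRNA	R	9921	9985	65	TGG			8
nad6	PCG	F	9994	10524	531		ATT	TAA	13
cob	PCG	F	10539	11687	1149		ATG	TAA	4
trnS2	tRNA	F	11692	11758	67	TGA			18
nad1	PCG	R	11777	12716	940		ATT	TAA	7
trnL1	tRNA	R	12724	12794	71	TAG			0
rrnL	rRNA	R	12795	14152	1358				0
trnV	tRNA	R	14153	14219	67	TAC			0
rrnS	rRNA	R	14220	14998	779				0
control_region	control	F	14999	15370	372
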