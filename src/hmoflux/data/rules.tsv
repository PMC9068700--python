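id	label	donor	anomer	position	acceptor	constraint	product	candidate_genes
L1	b3GnT	GN	b	3	(A		(GNb3A	B3GNT2,B3GNT3,B3GNT4,B3GNT5,B3GNT6,B3GNT8,B3GNT9
L2	a2FucT	F	a	2	(A		(Fa2A	FUT1,FUT2
L3	a3FucT	F	a	3	G/GN	~Ab3GN	Fa3G/GN	FUT3,FUT4,FUT5,FUT6,FUT7,FUT9,FUT10,FUT11
L4	ST3GalT	NN	a	3	(A		(NNa3A	ST3GAL1,ST3GAL2,ST3GAL3,ST3GAL4,ST3GAL5,ST3GAL6
L5	ST6GalT	NN	a	6	(A		(NNa6A	ST6GAL1,ST6GAL2
L6	b3GalT	A	b	3	(GN		(Ab3GN	B3GALT1,B3GALT2,B3GALT4,B3GALT5
L7	b4GalT	A	b	4	(GN		(Ab4GN	B4GALT1,B4GALT2,B4GALT3,B4GALT4,B4GALT5,B4GALT6
L8	b6GnT	GN	b	6	GNb3Ab4G		GNb3(GNb6)Ab4G	GCNT1,GCNT2,GCNT3,GCNT4,GCNT7
L9	a4FucT	F	a	4	Ab3GNb3A	~GNb4Ab3GNb3A	Ab3(Fa4)GNb3A	FUT3,FUT5
L10	ST6GnT	NN	a	6	Ab3GNb3A		Ab3(NNa6)GNb3A	ST6GALNAC1,ST6GALNAC2,ST6GALNAC3,ST6GALNAC4,ST6GALNAC5,ST6GALNAC6
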