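name	code
2'FL	Fa2Ab4G
3FL	Ab4(Fa3)G
3'SL	NNa3Ab4G
LNT	Ab3GNb3Ab4G
LNnT	Ab4GNb3Ab4G
LNFPI	Fa2Ab3GNb3Ab4G
LNFPII	Ab3(Fa4)GNb3Ab4G
LNFPIII	Ab4(Fa3)GNb3Ab4G
LSTb	Ab3(NNa6)GNb3Ab4G
LSTc	NNa6Ab4GNb3Ab4G
DFLNT1	Ab3(Fa4)GNb3Ab4(Fa3)G
DFLNT2	Ab4(Fa3)GNb3Ab4(Fa3)G
DFLNT3	Fa2Ab3(Fa4)GNb3Ab4G
DFLNT4	Fa2Ab3GNb3Ab4(Fa3)G
DFLNT5	Fa2Ab4(Fa3)GNb3Ab4G
DFLNT6	Fa2Ab4GNb3Ab4(Fa3)G
DSLNT	NNa3Ab3(NNa6)GNb3Ab4G
FLNH1	Ab3(Fa4)GNb3(Ab4GNb6)Ab4G
FLNH2	Ab3GNb3(Ab4(Fa3)GNb6)Ab4G
FLNH3	Ab3GNb3(Ab4GNb6)Ab4(Fa3)G
FLNH4	Ab3GNb3(Fa2Ab4GNb6)Ab4G
FLNH5	Fa2Ab3GNb3(Ab4GNb6)Ab4G
DFLNH1	Ab3(Fa4)GNb3(Ab4(Fa3)GNb6)Ab4G
DFLNH2	Ab3(Fa4)GNb3(Ab4GNb6)Ab4(Fa3)G
DFLNH3	Ab3(Fa4)GNb3(Fa2Ab4GNb6)Ab4G
DFLNH4	Ab3GNb3(Ab4(Fa3)GNb6)Ab4(Fa3)G
DFLNH5	Ab3GNb3(Fa2Ab4(Fa3)GNb6)Ab4G
DFLNH6	Ab3GNb3(Fa2Ab4GNb6)Ab4(Fa3)G
DFLNH7	Fa2Ab3(Fa4)GNb3(Ab4GNb6)Ab4G
DFLNH8	Fa2Ab3GNb3(Ab4(Fa3)GNb6)Ab4G
DFLNH9	Fa2Ab3GNb3(Ab4GNb6)Ab4(Fa3)G
DFLNH10	Fa2Ab3GNb3(Fa2Ab4GNb6)Ab4G
FDSLNH1	Ab3(Fa4)(NNa6)GNb3(NNa3Ab4GNb6)Ab4G
FDSLNH2	Ab3(Fa4)(NNa6)GNb3(NNa6Ab4GNb6)Ab4G
FDSLNH3	Ab3(NNa6)GNb3(NNa3Ab4(Fa3)GNb6)Ab4G
FDSLNH4	Ab3(NNa6)GNb3(NNa3Ab4GNb6)Ab4(Fa3)G
FDSLNH5	Ab3(NNa6)GNb3(NNa6Ab4(Fa3)GNb6)Ab4G
FDSLNH6	Ab3(NNa6)GNb3(NNa6Ab4GNb6)Ab4(Fa3)G
FDSLNH7	Fa2Ab3(NNa6)GNb3(NNa3Ab4GNb6)Ab4G
FDSLNH8	Fa2Ab3(NNa6)GNb3(NNa6Ab4GNb6)Ab4G
FDSLNH9	NNa3Ab3(Fa4)(NNa6)GNb3(Ab4GNb6)Ab4G
FDSLNH10	NNa3Ab3(Fa4)GNb3(NNa3Ab4GNb6)Ab4G
FDSLNH11	NNa3Ab3(Fa4)GNb3(NNa6Ab4GNb6)Ab4G
FDSLNH12	NNa3Ab3(NNa6)GNb3(Ab4(Fa3)GNb6)Ab4G
FDSLNH13	NNa3Ab3(NNa6)GNb3(Ab4GNb6)Ab4(Fa3)G
FDSLNH14	NNa3Ab3(NNa6)GNb3(Fa2Ab4GNb6)Ab4G
FDSLNH15	NNa3Ab3GNb3(NNa3Ab4(Fa3)GNb6)Ab4G
FDSLNH16	NNa3Ab3GNb3(NNa3Ab4GNb6)Ab4(Fa3)G
FDSLNH17	NNa3Ab3GNb3(NNa6Ab4(Fa3)GNb6)Ab4G
FDSLNH18	NNa3Ab3GNb3(NNa6Ab4GNb6)Ab4(Fa3)G
FDSLNH19	NNa6Ab3(Fa4)(NNa6)GNb3(Ab4GNb6)Ab4G
FDSLNH20	NNa6Ab3(Fa4)GNb3(NNa3Ab4GNb6)Ab4G
FDSLNH21	NNa6Ab3(Fa4)GNb3(NNa6Ab4GNb6)Ab4G
FDSLNH22	NNa6Ab3(NNa6)GNb3(Ab4(Fa3)GNb6)Ab4G
FDSLNH23	NNa6Ab3(NNa6)GNb3(Ab4GNb6)Ab4(Fa3)G
FDSLNH24	NNa6Ab3(NNa6)GNb3(Fa2Ab4GNb6)Ab4G
FDSLNH25	NNa6Ab3GNb3(NNa3Ab4(Fa3)GNb6)Ab4G
FDSLNH26	NNa6Ab3GNb3(NNa3Ab4GNb6)Ab4(Fa3)G
FDSLNH27	NNa6Ab3GNb3(NNa6Ab4(Fa3)GNb6)Ab4G
FDSLNH28	NNa6Ab3GNb3(NNa6Ab4GNb6)Ab4(Fa3)G
DSLNH1	Ab3(NNa6)GNb3(NNa3Ab4GNb6)Ab4G
DSLNH2	Ab3(NNa6)GNb3(NNa6Ab4GNb6)Ab4G
DSLNH3	NNa3Ab3(NNa6)GNb3(Ab4GNb6)Ab4G
DSLNH4	NNa3Ab3GNb3(NNa3Ab4GNb6)Ab4G
DSLNH5	NNa3Ab3GNb3(NNa6Ab4GNb6)Ab4G
DSLNH6	NNa6Ab3(NNa6)GNb3(Ab4GNb6)Ab4G
DSLNH7	NNa6Ab3GNb3(NNa3Ab4GNb6)Ab4G
DSLNH8	NNa6Ab3GNb3(NNa6Ab4GNb6)Ab4G
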