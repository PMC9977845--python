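ligand_proton	dna_proton	D2L	D3L
L-H1B	T4CH3	–	+ (medium)
L-H1A	A5H8	–	+ (medium)
L-H3B	T4CH3	+ (weak)	–
L-H3B	T4H1′	+ (medium)	+ (weak)
L-H3B	T4H2′	+ (weak)	–
L-H3B	T4H2″	+ (strong)	+ (medium)
L-H3B	T4H6	+ (medium)	+ (weak)
L-H3B	A5H8	+ (strong)	+ (medium)
L-H4B	T4H2″	+ (strong)	+ (medium)
L-H4B	T4H6	+ (medium)	+ (medium)
L-H4B	A5H1′	+ (medium)	–
L-H4B	A5H2′	–	+ (strong)
L-H4B	A5H8	+ (medium)	+ (medium)
L-H7A	T4CH3	+ (medium)	+ (medium)
L-H7A	T4H1′	+ (medium)	+ (weak)
L-H7A	T4H2″	+ (medium)	+ (medium)
L-H7A	T4H6	+ (medium)	+ (medium)
L-H7A	A5H8	+ (medium)	+ (weak)
L-H9A	T4CH3	+ (strong)	+ (medium)
L-H9A	A5H8	+ (strong)	+ (medium)
L-H10A	T4CH3	+ (medium)	+ (medium)
L-H10A	T4H1′	–	+ (medium)
L-H10A	A5H8	+ (strong)	–
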