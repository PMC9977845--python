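ligand_proton	dna_proton	B2L
L-H3B	T4H1′	Weak
L-H3B	T4H2′	Medium
L-H3B	T4H6	Medium
L-H7A	T4CH3	Weak
L-H7A	T4H1′	Medium
L-H7A	T4H2″	Medium
L-H7A	T4H6	Medium
L-H9A	T4CH3	Medium
L-H9A	T4H6	Strong
L-H10A	T4CH3	Weak
L-H10A	T4H1′	Strong
L-H10A	T4H3′	Medium
L-H15A	T4H1′	Strong
L-H15B	A5H1′	Medium
L-H16A	T4H1′	Medium
L-H16A	T4H6	Weak
L-H16B	T4H1′	Weak
L-H16B	T4H6	Weak
L-H17A	T4H1′	Medium
L-H18A	T4H1′	Medium
L-H18B	T4H1′	Medium
L-H18B	T4H3′	Weak
L-H18B	A5H1′	Weak
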