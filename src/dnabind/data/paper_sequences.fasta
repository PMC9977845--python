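>D1
CCCGGG
>D2
CGATATCG
>D3
CCCTAGGG
>D4
GGGTACCC
>D5
CCCATGGG
>D6
GGGATCCC
>D7
GTACGTAC
>D8
CTAGCTAG
>D9
GAACGTTC
>B1
CGGTACCG
>B2
CGCTAGCG
>B3
CGATATCG
>B4
CGTTAACG
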