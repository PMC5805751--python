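>TVD1 class=V anchor=21
GAAACCGCCTGGGCTACAATATGTTACAAT
>TVD2 class=V anchor=21
AGACTCCATACAATACCAGGTTGTAGTTGA
>TVD3 class=V anchor=21
CTGAGAGACCTGGCCTTAACCTGTCTGCTC
>TDD1 class=D family=D1
GGGACAGGGGGC
>TDD2 class=D family=D2
GGGACTAGCGGG
>TJD1 class=J family=J1 anchor=9
TCTGTAAAGTTTATCGCG
>TJD2 class=J family=J1 anchor=9
AGTGTTGTCTTTAAGCCT
>TJD3 class=J family=J2 anchor=9
GTATGAACGTTTAATATC
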