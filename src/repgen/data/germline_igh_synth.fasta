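>IGHV1-1 class=V family=V1 anchor=90
GTCAGGACCGGAAATATTGCCGTTAGAACCGAGCACCAGTTTTGCGAGGGATGGCATGGGTTGGACCACCTGTGGGAGCGCACCGCCACTTGTTATGATC
>IGHV1-2 class=V family=V1 anchor=90
GTCAGGACCGGAAATATTGCCGTCAGAACCGAGCACCAGTTTTGCGGGGGATGTCATGGGTTGGACCACCTGTGGGAGCGCACCGCCACTTGTTATGATC
>IGHV1-3 class=V family=V1 anchor=90
GTCAGGACCCGAAATATTGCCGTTAGAACCGAGCACCAGTTTTGCGAGGGATGGCACGGGTTGGACCACCTGCGGGAGCGCACCGCCACTTGTTATGATC
>IGHV2-1 class=V family=V2 anchor=90
TGTTGGTTCTCGGCCGAGCCGGGCTTCACCCTACCCGAAGGGTCTCGGGTAGCATGGTGCTTCTGAACTACCTGGTTAATGAATTCAACATGTAATAGTA
>IGHV2-2 class=V family=V2 anchor=90
TGTTGGTTGTCGGCCGAGCTGGGCTTCACCCTACCCGAAGGGTCTCGGGTAGCATGGTGTTTCTGAACTACCTGGTTAATGAATTCAACATGTAATAGTA
>IGHV2-3 class=V family=V2 anchor=90
TGTTGGTTCTCGGCCGAGGCGGGCTGCTCCCTACCCGAAGGGTCTCGGGTAGCATGGTGCTTCTGAACTACCTGGTTAATGAATTCAACATGTAATAGTA
>IGHD1 class=D family=D1
GGTATAACTGGAACG
>IGHD2 class=D family=D2
AGGATATTGTAGTAGTAC
>IGHD3 class=D family=D2
GGGATATTGTAGTAGAAA
>IGHJ1 class=J family=J anchor=9
AGGAGATCCTTTGGCGGACTATGCGTGTCC
>IGHJ2 class=J family=J anchor=9
AGGAGATCCTTTGGCGGACCATGCGAGTCC
>IGHJ3 class=J family=J anchor=9
GACCATTCTTTTGCTTATACACTACTCGTG
>IGHJ4 class=J family=J anchor=9
GACCATTCTTTTGCTGATACACTACTCGTC
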