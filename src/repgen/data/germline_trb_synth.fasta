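>TRBV1-1 class=V family=V1 anchor=60
CTCGCGCACGGTACTAGTTGTATGGTTATTCGTACACTCCTCAGTCTATCTCGTTGGCAATGTAAGCCGG
>TRBV1-2 class=V family=V1 anchor=60
CTCGCGCACGGAAATAGTTGTATGATTATACGTACACTCCTCAGTCTATCTCTTTGGCAATGTCAGCCGG
>TRBV2-1 class=V family=V2 anchor=60
GCGTCATTCGGAAAGGTGGCACGGCATAACAGACCGTGGAGGAGAACTGTTCGCCGACCGTGTCTCTTAT
>TRBV2-2 class=V family=V2 anchor=60
CCGTCATTTGGAAAGGTGGCACGGCATAACAGACCGTGGGGGAGAACTTTTCGCCAACCGTGTTTCTTAT
>TRBV3-1 class=V family=V3 anchor=60
ATGTCATTGCGCATATGTAGGATCGTCTCCGTTAAGTCAAAACGACTGACGGCCCTTATGTGTACTTGGT
>TRBV3-2 class=V family=V3 anchor=60
ATGTCATTGCGTATATGTAGGATCGTCCCCGTTAAGTCAAAACCACTGACGGCCCTTGTGTGTACTGGAT
>TRBV4-1 class=V family=V4 anchor=60
GTGATTACGATCCAAAGTAGTTCAGCTGATAGCAGTCGCCAGCCTCAGGCAGTCTCACTATGTCCACCAA
>TRBV4-2 class=V family=V4 anchor=60
GGGATTACGATCCAAAGTGGGTCAGCCGATAGCAGTCGCGAGCCTCAGGCAGCCTCACTATGTCCACCAA
>TRBD1 class=D family=D1
GGGACAGGGGGC
>TRBD2 class=D family=D2
CCTAGTAGTTACCTCG
>TRBJ1-1 class=J family=J1 anchor=9
TGACTTACTTTTAAACCAGCCCAGG
>TRBJ1-2 class=J family=J1 anchor=9
TGACTTACTTTTAAACCAGCCCAAT
>TRBJ1-3 class=J family=J1 anchor=9
TGACTTACTTTTATACCAGCCTAGG
>TRBJ2-1 class=J family=J2 anchor=9
ACCGTTGGGTTTTAGGTTCAATACG
>TRBJ2-2 class=J family=J2 anchor=9
ATCGTTGCGTTTTAGGTTCAATACG
>TRBJ2-3 class=J family=J2 anchor=9
ACCGGTGGGTTTTAGGATCAATACG
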