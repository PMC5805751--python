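>TVA class=V anchor=6
CATGGCGTACGTTAGC
>TVB class=V anchor=6
CATGGCGGTATGCAAT
>TJA class=J family=J1 anchor=3
TGTTTTCGGAGCAT
>TJB class=J family=J2 anchor=3
ACTTTTGGCAGCAT
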