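>CSB-D synthetic teleost-style consensus (T-rich); editable default
TGCTTCGTCTTGTCCATGTTCT
>CSB-I synthetic teleost-style consensus (AT-rich); editable default
ATAAAGTGCATTAGTACTTAATGA
>CSB-II synthetic teleost-style consensus (C-rich); editable default
CCTCCCCCTTACCCCCTCC
>CSB-III synthetic teleost-style consensus; editable default
TGTCAAACCCCTAAAGCA
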