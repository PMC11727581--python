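>element_synthetic length=1024 | synthetic LINE1-like element for simulations (not a biological consensus)
TAGAAAACGCCTTAGAGGAATTTACCAGATACCGCAGCATACCCTAGTCGGATCACTTTTCCCGACCTCA
GCCACGTCACTGGTATGTTGGAGTTGTACGCAGAGGAGTGTATATATCAGAAAGTTTAATGAGTACTGGG
TAGTAAAACAAGTGACTAATACTAAGAAACATTTTGTAAATAACCGAGCAGTCCCCATTGTTATTTGGTT
CATCTACAAGAGATATCCAATATCGCAAAAAACAGGTTACCGAGGAAATAAAATGCATTTTTCCAAGTCT
TTTAGTCCGGCGCAGTTATATAGTGGAACTAGATGAAGTCGTTTCCGCATTGAAAGACGTGGAAGTGGAC
TGAAGGTTTTTTATAGGTGACCATAATCTTGACTGAACCTTTTCACGAATACAGTGTAACTAGGTTTCTA
TCGCTGCAATCCGGCCTAGTGAAATCATTATCGAAGCCCCTGGATATCTATACTAGTAAATACTGTGACA
TTACTTAATGGTGCGATAAGCCCTGCTATTCTATACATGCTACTCAATCGATCCTACAGTCCAGTAGCTA
CATGAAATAGGTCATTCTGAATGAGATACTTTGAACCTTAGATATCACTGATACATTTTGAGACGATCTC
GCCTCTATGATCCGCGGGCGCACCTCCCTAGATTCTACGTCACGCATTTCTAGTCTTGCAGTACACGCAA
TAGAGGGGCAAAATGGTTGTTCATGGTCACCTACTTTCGGTAATTCAACTAAATCTCGCACAAATGGTAG
CGTGTAACAACCGCGGTATGACTCATGCCCGTAAGATATCTCTTAGAGACGCTAGTAATGCATGCAAGAT
CGAATGTAGGAAATGACGGTACAGTTGTAAACTTCTGGTTTCACGCTGGGTAGTTGCTCTGGAATTCTAT
CTCTGAAACCTCAGAATTTGACTTTATAGATACATTCGCGCGTAATAATTCCTGAATCGGTACGAGGGCG
CCATACATCCGTCGTATGGTACGACCTAAGTCCCCGATGGCTGG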