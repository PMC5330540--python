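# STOCKHOLM 1.0
#=GF ID tRNA-Sec-eukaryota
#=GF DOMAIN eukaryota
#=GF POS 1 2 3 4 5 5a 5b 6 7 8 9 10 11 12 12a 12b 13 17 18 19 20 21 22 23 23a 24 25 26 27 28 29 30 30a 31 32 33 34 35 36 37 38 39 40 41 42 43 44 45 46 47 47a 47b 47c 47d v1 v2 v3 v4 v5 48a 48b 48c 48d 48e 48f 48g 48 49 50 51 52 55 56 57 58 59 60 61 62 63 64 65 66 67 67a 67b 68 69 70 71 72
euk1         GCCCGGGTGATGCGGATAGGAATCCGCGCCGGATCTTCAAAATCCGGGGCTGGGTTCAACCCAGCCAGGTCTTCGAATGACCCACCCGGGC
euk2         GCTCGGGTGATGCGGATAGGAATCCGCGCCGGATCTTCAGAATCCGGGCCTGGGTTCAACCCAGGCAGGTCTTCGAATGACCCACCCGAGC
euk3         GCCCGGGGGATGCGAATAGGAATTCGCGCCGGATCTTCAAAATCCGGGGCTGGGTTCAACCCAGCCAGGTCTTCTAATGACCCCCCCGGGC
euk4         CCCCGGGTGATGCGGATAGGAATCCGCGCCGGACCTTCAAAGTCCGGGGCTGGGTTCAACCCAGCCAGGTCTTCGAATGACCCACCCGGGG
euk5         GCCCGGGTGATGCGGATAGGAATCCGCGCCGGATTTTCAAAATCCGGGGCTGAATTCAATTCAGCCAGGTCTTCGAATGACCCACCCGGGC
euk6         GCTCGGGTGATGCGGATAGGAATCCGCGACGGATCTTCAAAATCCGTGGCTGGGTTGAACCCAGCCAGGTCTTCGAATGACCCACCCGAGC
euk7         GCCGGGGTGATGCGGATAGGAATCCGCGCCGGATCTTCAAAATCCGGGGCTGGGTTAAACCCAGCCAGTTCTTCGAATGAACCACCCCGGC
euk8         GCCCGGGTAATGCGGATAGGAATCCGCGCCGGATCTTCAAAATCCGGGACTGGGTTCAACCCAGTCAGGTCTTCGAATGACCTACCCGGGC
euk9         GCCCGGATGATGCGGAAAGGATTCCGCGCCGGATCTTCAAAATCCGGGGCTGGGTTGAACCCAGCCAGGTCTTCGAATGACCCATCCGGGC
euk10        GCCCGGGTGATACGGATAGGAATCCGTGCCGGCTCTTCAAAAGCCGGGGCTGGGTTCAACCCAGCCAGGTCTTCCAATGACCCACCCGGGC
euk11        GCCCGGGTGATGCGGATAGGAATCCGCGCCTGATCTTCAAAATCAGGGGCTGGCTTCAAGCCAGCCAGGTCTTCGAATGACCCACCCGGGC
euk12        GCCCGGGTGATGCGGATAGGAATCCGCGCCGGCTCTTCAAAAGCCGGGGCTGTGTTCAACACAGCCAGGTCTGCGAATGACCCACCCGGGC
euk13        GCAGGGGTGATGCGGATAGGAATCCGCGCCGGATCTTCAAAATCCGGGGCTGGGTTCAACCCAGCCAGGTCTTCCAATGACCCACCCCTGC
euk14        GGCCGGGTGATGTGGATAGGAATCCACGCCGGATCTTCACAATCCGGGGCTGGGTTCAACCCAGCCAGGTCTTCGAATGACCCACCCGGCC
euk15        GCCCGGGTGATGTGGGTAGGAACCCACACCGGATCTTCAAAATCCGGGGCTGGGTTCAACCCAGCCAGGTCTTCGAATGACCCACCCGGGC
euk16        GTCCGGGTGATGCGGATAGGAATCCGCGCCGGAACTTCAAATTCCGGGGCTGGGTTCAACCCAGCCAGGTCTTCGAAAGACCCACCCGGAC
euk17        GCCCGAGTGATGCCGATAGGAATCGGCGCCGGATCTTCAAAATCCGGGGCTGGGTTCAACCCAGCCAGGTCTTCGACTGACCCACTCGGGC
euk18        GCCCGGGTGATGCGGATAGGAATCCGCGTCGGATCTTCAAAATCCGATGCTGGGTTCAACCCAGCAAGGTCTTCGAATGACCCACCCGGGC
euk19        GCCCGGGTGATGCGGACAGGAGTCCGCGCCGGATCTTCAAAATCCGGGGCTGGGTTCAACCCAGCCAGCTCTTCGAATGAGCCACCCGGGC
euk20        GCCCGGGTGATGCGGATAGGAATCCGCGCCGGAGCTTCAAACTCCGGGGCTGTGTTCAACACAGCCTGGTCTTCGAATGACCCACCCGGGC
euk21        GCCCGGGTGATGCGGACAGGAGTCCGCGCCGGATCTTCAAAATCCGGTGCTGGGTTCAACCCAGCAAGGTCTTCGAACGACCCACCCGGGC
euk22        GCCCGGGTGATGCGGATAGGAATCCGCGCCAGATTTTCAAAATCTGGGGCGGGGTTCAACCCCGCCAGGTCTTCGAATGACCCACCCGGGC
euk23        GCCCGAGTGATGCGGATAGGAATCCGCGCCGGATCTTCAAAATCCGGGGCTGGTTTCAAACCAGCCAGGTCTCCGAATGACCCACTCGGGC
euk24        GCCCGGGTGATGCGGATAGGAATCCGCGCAGGTTCTTCAAAAACCTGGGCTGGGTTGAACCCAGCCAGGTCTTCGAATGACCCACCCGGGC
euk25        GCCCGGGTGATGCGGATAGGAATCCGCGGCGGATCTTCAATATCCGCGACTGGGTTCAACCCAGTCAGGTCTTCGAATGACCCACCCGGGC
euk26        GCCCGGGTGCTGCGGATAGGAATCCGCGCCCGAGCTTCAAACTCGGGGGCTGGGTTCAACCCAGCCAGGTCTTCGAATGACCCACCCGGGC
euk27        GCCCGGGTGATGTGGATAGGAATCCACGCCGGATCTTCAAAATCCGGGGCTGGGTTCAACCCAGCCACGTCTTCGAATGACGCACCCGGGC
euk28        GCCCGGGTCATGCGGAAAGGATTCCGCGCCGGATCTTCAAAATCCGGGGCTGGGTTCAACCCAGCCAGGTCTTCGAATGACCGACCCGGGC
euk29        GCTCGGGTGATGCGGATAGGAATCCGCGCCGGATCTTCAAAATCCGGGGCTGGGTTCAACCCAGCCACGTCTTAGAATGACGCACCCGAGC
euk30        GCCCGGGTGATGCGGATAGGAATCCGCGTCGGATCTTCAAAATCCGAGGCAGGGTTCAACCCTGCCAGGTCTTCGAATGACCCACCCGGGC
euk31        GCCCAGGTGATGCGGATAGGAATCCGCGCCTGATCTTCAAAATCAGGGGCTGGGTTCAACCCAGCCAGGTCTTCAAATGACCCACCTGGGC
euk32        GCCCGGGTGATGCGGATAGGAATCCGCGCCGGATCTTCAAAATCCGGGGCCGGCTTCAAGCCGGCCAGGTCGTCGAATGACCCACCCGGGC
#=GC SS_cons <<<<<<<<<..<<<<<<....>>>>>>.<<<<<<.......>>>>>><<<<<<<.....>>>>>>>.<<<<.......>>>>>>>>>>>>>
//
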