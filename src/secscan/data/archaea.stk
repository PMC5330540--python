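# STOCKHOLM 1.0
#=GF ID tRNA-Sec-archaea
#=GF DOMAIN archaea
#=GF POS 1 2 3 4 5 5a 5b 6 7 8 9 10 11 12 12a 12b 12c 13 17 18 19 20 21 22 23 23a 23b 24 25 26 27 28 29 30 30a 31 32 33 34 35 36 37 38 39 40 41 42 43 44 45 46 47 47a 47b 47c 47d v1 v2 v3 v4 v5 48a 48b 48c 48d 48e 48f 48g 48 49 50 51 52 55 56 57 58 59 60 61 62 63 64 65 66 67 67a 67b 68 69 70 71 72
arc1         GCGGGAGTGCACGCCGGTAGGAACCGGCGGGCCCGTCTTCAAAACGGGCGCCGGTGCTTTACACCGGCCGGGTTTCAAATACCCCACTCCCGC
arc2         GCGGGAGCGCACGCCGGCGGGAGCCGGCGGGCCCGTCTTCAAAACGGGCGCCGGTGCTTTACACCGGCCGGGTTTCAAATACCCCGCTCCCGC
arc3         GCGGGAATGCACGCGGGTAGGAACCCGCGGGCCCGTGTTCAAAACGGGCGCCGGTGCTTTACACCGGCCGGGTTTCAAATACCCCATTCCCGC
arc4         GCGGGAGTGCACGCCGGTAGGTACCGGCGGGACCGTCTTCAAAACGGTCGCCGCTGCTTTACAGCGGCCGGGTTTCAAATACCCCACTCCCGC
arc5         GCGGGACTGCACGCCGGTAGGAACCGGCGGGCCTGTCTTCAAAACAGGCGCCGGTGCTTTACACCGGCCGGGTGTCAAATACCCCAGTCCCGC
arc6         GCGGGTGTGCACGCCGGTAGGAACCGGCGGGCCCTTCTTCAAAAAGGGCGCCGGTGCTTTACACCGGCCGGGTTTCAAATACCCCACACCCGC
arc7         GCGGGAGTGCACGACGGTAGGAACCGTCGGACCCGTCTTCAAAACGGGTGCCGGTGCTTTGCACCGGCCGGGTTTCAAATACCCCACTCCCGC
arc8         GCGGGAGTGCACGCCGGTAGGAACCGGCGGGCCCGTCTTCAAAACGGGCGCAGGTGCTTTACACCTGCCGGCTTTCAAATAGCCCACTCCCGC
arc9         GCGGAAGTGCACGCCGGTAGGAACCGGCGGGCCCGTCTTCAAAACGGGCGCCGGTGCTTTACACCGGCCGTGTCTCAAATACACCACTTCCGC
arc10        GCGGGAGTGCACGCCGGTAGGAACCGGCGGGCCCGTCTTCAAAACGGGCGCAGGGGCTTTACCCCTGCCGGGTTTAAAATACCCCACTCCCGC
arc11        GCGGGAGTGCATGCCGGTAGGAACCGGCAGGCCCGTCTTCAAAACGGGCGCTGGTGCTTTACACCAGCCGGGTTTCACATACCCCACTCCCGC
arc12        GCAGGAGTGCACGCCGGTAGGTACCGGCGGGCCCGTCTTCAAAACGGGCACCGGTGCTTTACACCGGTCGGGTTTCAAATACCCCACTCCTGC
arc13        GCGGGAGTGCAAGCCGGTAGGAACCGGCTGGCCCGTCTTCAAAACGGGCGCTGGTGCTTTACACCAGCCGGGTTTCAAATACCCCACTCCCGC
arc14        GCGGGAGTGCACGCCGGTAGGAACCGGCGGGCCCGTCTTCAAAACGGGCGCCGGCGCTTTACGCCGGCCGGATTTCAAATATCCCACTCCCGC
arc15        GCTGGAGTGCAAGCCGGTAGGAACCGGCTGGCCCGTCTTCAAAACGGGCGCCGGTGCTTTACACCGGCCGGGTTTCAACTACCCCACTCCAGC
arc16        GCGGGAGTGCACGCCGGTAGGAACCGGCGGCCCCGTCTTCAAAACGGGGGCCGGCGCTTTACGCCGGCCGGGTTTCAACTACCCCACTCCCGC
arc17        GCAGGAGTGCACGCCGGTAGGAACCGGCGGGCCCGTCTTCAAAACGGGCGCCGATGCTTTACATCGGCTGGGTTTCAAATACCCCACTCCTGC
arc18        GCGGGATTGCACGCCCGTAGGAACGGGCGGGCCCGTCTTCAAAACGGGCGCCGGTGCTTTACACCGGCCGGGTTTCAAATACCCCAATCCCGC
arc19        GCGGGAGTTCACGCCGGTAGGAACCGGCGGCCCCGTCTTCAAAACGGGGGCCGGTGCTTTACACCGGCCGGGTTTCAAATACCCAACTCCCGC
arc20        GCGGGAGTGCACTCCGGTAGGAACCGGAGGGCCTGTCTTCAAAACAGGCGCCGGTGCTTTACACCGGCCGGGTTTTAAATACCCCACTCCCGC
arc21        GCGGGAGTGCACGCCGGTAGGAACCGGCGGGCTCGTCTTCAAAACGAGCGCCGGTGCTTTACACCGGCCGGCTTTCAGATAGCCCACTCCCGC
arc22        GCGGGGGTGCACGCCGGTAGGAACCGGCGGGCCCGTCTTCAAAACGGGCGCGGGTGCATTACACCCGCCGGGTTTCAAATACCCCACCCCCGC
arc23        GCGGTAGTGCGCGCCGGTAGGAACCGGCGGGCTCGTCTTCAAAACGAGCGCCGGTGCTTTACACCGGCCGGGTTTCAAATACCCCACTACCGC
arc24        CCGGGAGTGCACGCCGGTAGGAACCGGCGGGCCCGTCTTCAAAACGGGCGCCGGTGCTTTACACCGGCCCGGTTTCCAATACCGCACTCCCGG
arc25        GCGGGAGGGCACGCCGGTAGGAACCGGCGGGCCCGTCTTCAAAACGGGCGCCGGTGCTTTACACCGGCCAGGTTTCAAATACCTCCCTCCCGC
arc26        GCGGGAATGCACGCCGGAAGGATCCGGCGGGCCCGTCTTCAAAACGGGCGCCGGTGCTTTACACCGGCCGGGTTTCAGATACCCCATTCCCGC
arc27        GCGTGAGTGCAAGCCGGTAGGAACCGGCTGGCCCGTCTTCAAAACGGGCGCCGGTGCTTGACACCGGCCGGGTTTCAAATACCCCACTCACGC
arc28        GCGGGATTGCATGCCGGTAGGAACCGGCAGGCCCGTCTTCAAAACGGGCGCCGGTGCTTTACACCGGCCGGGTTTCAAATACCCCAATCCCGC
arc29        GCGGGAGTGGACGCCGGTAGGAACCGGCGGGCCCGTCTTCAAAACGGGCGCCGGTGCTTTACACCGGCCGAATTTCAAATATTCCACTCCCGC
arc30        GCGGGAGTGCACGCCGGTAGGAACCGGCGTGCCCGTCTTCAAAACGGGCGCCAGAGCTTTACTCTGGCCGGGTTTCAAATACCCCACTCCCGC
arc31        GCGAGAGTGCACGCCGGTAGGAACCGGCGGGCCCGACTTCAAATCGGGCGCCGGTGCTTTACACCGGCCGGGTTTCAAATACCCCACTCTCGC
arc32        GCGGGAGTGCACTCCGGTAGGAACCGGAGGGCACGTCTTCAAAACGTGCGCCGGTGCTTTACACCGGCCGGGTTTCTAATACCCCACTCCCGC
#=GC SS_cons <<<<<<<<<..<<<<<<<....>>>>>>>.<<<<<<.......>>>>>><<<<<<<.....>>>>>>>.<<<<.......>>>>>>>>>>>>>
//
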