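# STOCKHOLM 1.0
#=GF ID tRNA-canonical
#=GF POS 1 2 3 4 5 6 7 8 9 10 11 12 13 17 18 19 20 20a 20b 20c 20d 21 22 23 24 26 27 28 29 30 31 32 33 34 35 36 37 38 39 40 41 42 43 45 46 47 v1 v2 v3 v4 48a 48b 48c 49 50 51 52 53 55 56 57 58 59 60 61 62 63 64 65 65a 66 67 68 69 70 71 72
can1         GCAGCCAGTGCTCAGGTAAAGGAGCAGCAGGCTGCTAACCTGCGGCAGTTGCCCGGTCTTCGATTGACCGTGGCTGC
can2         GCAGCCAGTGCTCAGGTAAAGGAGCCGCTGGCTGCTAACCAGCCGCAGTTGCGCGGTCTTCGATTGACCGTGGCTGC
can3         ACAGCCAGTTCTCAGGTAAAGGAGAAGCAGGCTGCTAACCTGCGGCAGTTGCCCGGTCTCCGATTGACCGTGGCTGT
can4         GCCGCCAGTGCTCAGGTAAAGGAGCACCAGGCTGCTAACCTGGGGCAGTTGCCCGGTCTTCGATTGACCGTGGCGGC
can5         GCAGCCAGTGCTAAGGTAAAGTAGCAGCAGGCTGCTAACCTGCGGCAGTTGCCAGGTCTTCGTTTGACCTTGGCTGC
can6         GCAGCCAGTGCTCAGGTAAAGGAGCAGCAGGCTGCTAACCTGCGGCAGTTGCCGGGTGTTCGATTCACCCTGGCTGC
can7         GCAGCCAGTGCTCAGGTAAAGGAGCAGCAGGCTGCTAACCTGCGGTAGTTACCTGGTCTTCGAATGACCATGGCTGC
can8         GCAGCCAGTGCTGAGGTAAAGCAGCAGCAGGCTGCTCACCTGCGGCAGTTGCCCGGACTTCGATTGTCCGTGGCTGC
can9         GCAGCCAGTGCTCAGGTAAAGGAGCAGCAAGCTGCTAACTTGCGGCAGTTGCCTGGTCTGCGATTGACCATGGCTGC
can10        GCGGCCGATGCTCAGGTAAAGGAGCAGCAGGCTGCTAACCTGCGGCAGTTGCCCGGTCTTCGATTGACCGCGGCCGC
can11        GCAGCGAGTGCTCAGGTAAAGGAGCAGCAGTCTGCTTAACTGCGGCAGTTGCCCGGTCTTCGATTGACCGTCGCTGC
can12        GCAGCCAGTGCTCAGGTAAAGGAGCAGCACGCTGCTAACGTGCGGCAGTTGCCCCGTCTTCGATTGACGGTGGCTGC
can13        GCAGGCAGTGCTCAGGTCAAGGAGCATCAGGCTGCTAACCTGAGGCAGTTGCCCGGTCTTCGATTGACCGTGCCTGC
can14        ACAGCCAGTGCTCAGGTAAAGGAGCAGCAGGCTGCTAACCTGCGACAGTTGTCCGGTCTTCGATTGACCGTGGCTGT
can15        GCAGGCAGTGCTCAGGTAAAGGAGCAGCAGGCTGCTAACCTGCGCCAGTTGGCCGGTCTTCGATTGACCGTGCCTGC
can16        GCAGCAAGTGCTGAGGTAAAGCAGCAGCAGGCTGCTAACCTGCGGCAGTTGCCCGGTCTTCGATGGACCGTTGCTGC
can17        GCAGCCAGTGCTCAGGTAAAGGAGCAGGAGGCTGCTGACCTCCGGCAGTTGCCCGGCCTTCGATTGGCCGTGGCTGC
can18        GCAGCCAGTGCTGAGGTAAAACAGCAGCAGGCTGCTAACCTGCAGCAGTTGCTCGGTCTTCGATTGACCGTGGCTGC
can19        GCAGCCAGTGCTCAGGTAAAGGAGCTGCAGGCTGCTAACCTGCGGGAGTTCCCTGGTCTTCGATTGACCATGGCTGC
can20        CCAGCCAGTGCTCAGGTAAAGGAGCAGGAGGCTGCTCACCTCCGGCAGTTGCCCGGTCTTCGATTGACCGTGGCTGG
can21        GCATCCAGTGCTCAGGTAAAGGAGCAGCAGGCTGCTACCCTGCGGCAGTTGCCCGGACTTCGATTGTCCGTGGATGC
can22        GCAGCCAGTGCTAAGGGAAAGTAGCAGCAGGCTGCTAACCTGCGGCAGTTGCCCTGTCTTCGATTGACAGTGGCTGC
can23        GCAGTAAGTGCTCAGGTAAAGGAGCAGCAGGCTGCTAACCTGCGGCAGTTGCCCGGTCTTCGATTGACCGTTACTGC
can24        GAAGCCAGTGCTCAGGTAAAGGAGCAGCGGGCTGCTCACCCGCGGCAGTTGCCCGGTCTTCGATTGACCGTGGCTTC
can25        GCAGCCAGTGCGCAGGTAAAGGCGCAGCAGGCTGCTAACCTGCGGCAGTTGCCCGGTGTTCGATTCACCGTGGCTGC
can26        GTAGCCAGTGCTCAGGTTAAGGAGCAGGAGGCTGCTAACCTCCGGCAGTTGCCCGGTCTTCGATTGACCGTGGCTAC
can27        TCAGCGAGTGCTCAGGTAAAGGAGCAGCAGGCTGCTAACCTGCGGCAGTTGCCCGGTCTTCGATTGACCGTCGCTGA
can28        GCAGCCAGTGCTAAGGTTAAGTAGCAGCAGGCTGCTAACCTGCGGCAGTTGCCCGGTATTCGATTTACCGTGGCTGC
can29        GCAGCCAGTGCTCAGGTAAAGGAGCAAGAGGCTGCTAACCTCTGGCAGTTGCCCGGTCTTCGATTGACCGTGGCTGC
can30        GCAGCCAGTACTCAGGTAAAGGAGTAGCAGGCTGCTAACCTGCGGAAGTTTCCCGGTCTTCGATTGACCGTGGCTGC
can31        GTAGCCAGTGCTCAGGTAAAGGAGCAGTAGGCTGCTAACCTACGGCAGTTGCCCGGTCTGCGATTGACCGTGGCTAC
can32        GCAGCCAGTGTTCAGGTAAAGGAACAGCAGGCTGCTAACCTGCGGCAGTTGCCCGATCTTCGAGTGATCGTGGCTGC
#=GC SS_cons <<<<<<<..<<<<........>>>>.<<<<<.......>>>>><<<....>>><<<<<.......>>>>>>>>>>>>
//
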