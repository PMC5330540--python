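# STOCKHOLM 1.0
#=GF ID tRNA-Sec-bacteria
#=GF DOMAIN bacteria
#=GF POS 1 2 3 4 5 5a 6 7 8 9 10 11 12 12a 12b 13 17 18 19 20 21 22 23 23a 24 25 26 27 28 29 30 30a 31 32 33 34 35 36 37 38 39 40 41 42 43 44 45 46 47 47a 47b 47c 47d v1 v2 v3 v4 v5 48a 48b 48c 48d 48e 48f 48g 48 49 50 51 52 53 55 56 57 58 59 60 61 62 63 64 65 65a 66 67 67a 68 69 70 71 72
bac1         GGAAGATCGATCCGGTAGGTACCGGAAGGGCTTCTTCAAGAAGCCCCCGTGGGCGCAACCCACGGTGGTCCTTCGACTGGACCGATCTTCC
bac2         GGAAGATCGATCCGGTAGGTACCGGAAGGACTTCTTCAAGAAGTCCCCGGGGGCGCAACCCCCGGTGGTCCTTCCACTGGACCGATCTTCC
bac3         GGAAGATCGACCCGGTAGGTACCGGGAGGGATTCTTCAAGAATCCCCCGTGGGCGCAACCCACGGTGGTCCGTCGACTGGACCGATCTTCC
bac4         GGAAGATCGATCCGATAGGTATCGGAAGGGCTTCTTCAAGAAGCCCCCGCGGGCGCGACCCGCGGTGGTCCTTCGACTGGACCGATCTTCC
bac5         GGAACATCGATCCGGTAGGTACCGGAACGGCTTCTTCAAAAAGCCGCCGTGGGCGCAACCCACGGTGGTCCTTCGACTGGACCGATGTTCC
bac6         GGAAGATCGAACCGGTAGGTACCGGTGGGGCTTCTTCAAGAAGCCCCCGTGGACGCAATCCACGGTGGTCCTTCGACTGGACCGATCTTCC
bac7         GGAAGATCCATCCGGTAGGTACCGGAAGGGCTTCTTCAAGAAGCCCCCGTGGGCGCAACCCACGGTAGGCCTTCGACTGGCCTGATCTTCC
bac8         GGAAGATCGTTCCGCTAGGTAGCGGAAGGGCTTCTTCAAGAAGCCCCCGTGGCCGCAAGCCACGGTGGTCCTTCGACTGGACCGATCTTCC
bac9         GGAAGATCGATCTGGTAGGTACCAGAAGGGCTACTTCAAGTAGCCCCCGTGGGCGCAACCCACGGTGGTCCTTCGACTGGACCGATCTTCC
bac10        GGAAGATCGATCCGGTGGGTACCGGAAGGGATTCTTCAAGAATCCCCCGTGGTCGCAAACCACGGTGGTCCTTCGACTGGACCGATCTTCC
bac11        GGTAGATCGATACGGTAGGTACCGTAAGGGCTTCTTCAAGAAGCCCCCGTGGGCTCAACCCACGGTGGTCCTTCGACTGGACCGATCTACC
bac12        GGAAGCTCGATCCGGTAGGTACCGGAAGGGCTTCTTCAAGAAGCCCCCGTGGGCGCTACCCACGGTGTTCCTTCGACTGGAACGAGCTTCC
bac13        GGAAGATCAATCCGGTAGGTACCGGAAGGGCTGCTTCAAGCAGCCCCCGTGGGCGCAACCCACGGTGCTCCTTCGACTGGAGCGATCTTCC
bac14        TGGAGATCGATCCGGTAGGTACCGGAAGGGCTTCTTCAAGAAGCCCCCGTGGGCGCAACCCACGGTGGTCCTTCGACTGGACCGATCTCCA
bac15        GGAAGATTGATCGGGTAGGTACCCGAAGGGCTTCTTCAAGAAGCCCCCGTGGGCGGAACCCACGGTGGTCCTTCGACTGGACCAATCTTCC
bac16        GGAAGATCGATCCGGTAGGTACCGGAAGAGCTTCTTCAAGAAGCTCCCGTGGGCGCAACCCACGGTAGTCCTTCGACTGGACTGATCTTCC
bac17        GGAAGATCGATCCGGTAGGTACCGGAAGGGCTACTTCAAGTAGCCCCGGTGGGCGCATCCCACCGTGGTCCTTCGACTGGACCGATCTTCC
bac18        GGAAGGCCAATCCGGTAGGTACCGGAAGGGCTTCTTCAAGAAGCCCCCGTGGGCGCAACCCACGGTGGTCCTTCGACTGGACCGGCCTTCC
bac19        GGAAGATTGATCCGGTAGGTACCGGAAGGGCTTCTTCAAGAAGCCCCCGTGGGCGCAACCCACGGTGGGCCTTTGACTGGCCCAATCTTCC
bac20        GGAACATCGATCCGGTAGGTACCGGAAGAGCTTCTTCAAAAAGCTCCCGTGGGCGCAACCCACGGTGGTCCTTCGACTGGACCGATGTTCC
bac21        GGAAGATCGATCCGGGAGGTCCCGGAAGGGCTTCTTCAAGAAGCCCCCGTGGACGCAATCCACGGTGGTCCTTCGACTGGACCGATCTTCC
bac22        GGAAGATCGATCCGGTAGGTACCGGAAGGGCTTCTTCAAGAAGCCCCAATGGGCGCAACCCATTGTGGTCCGTCGACTGGACCGATCTTCC
bac23        GGAAGATCGATCCGGTAGGTACCGGAAGGGCTTCTTCAAGAAGCCCCGGTGGGCGCAACCCACCGTGCTCCATCGACTGGAGCGATCTTCC
bac24        GGAAGATCGATCCGGTAGGTACCGGAAGGGTTTCTTCAAGAAACCCCCGTGGGCGCAACCCACGGTGGTCTTTCGACTAGACCGATCTTCC
bac25        GGAAGATCGATCCGGTAGGGACCGGAAGGGCTTCTTCAAGAAGCCCCGGTGGGCGCAACCCACCGTGGTACTTCGACTGTACCGATCTTCC
bac26        GGAAGATCGATCTGGTAGGTACCAGAAGGGCGTCTTCAAGACGCCCCCGTGGGCGCAACCCACGGTGGTCCATCGACTGGACCGATCTTCC
bac27        GGAAGATTGATCCGGTAGGTACCGGAAGGGCTTCTTCAAGAAGCCCCTGTGGGCGCAACCCACAGTGGTCCTTCGACTGGACCAATCTTCC
bac28        GGAAGATCGATCCGGTAGGCACCGGAAGCGTTTCTTCAAGAAACGCCCGTGGGCGCAACCCACGGTGGTCCTTCGACTGGACCGATCTTCC
bac29        GGAAGATCGATTCGGTAGGTACCGAAAGGGGTTCTTCAAGAACCCCCCGTGGGCGCAACCCACGGTGGTCCTACGACTGGACCGATCTTCC
bac30        GGAAGATCGATCTGGTAGGTACCAGAAGGGCTTCTTCAAGAAGCCCCCGTGGGGGCAACCCACGGTTGTCCTTCGACTGGACAGATCTTCC
bac31        GGAAGATCGATCCGGTAGGTACCGGAAGGGCTTCTTCAAGAAGCCCACGTGGTCGCAAACCACGTTGGTCCTTCCACTGGACCGATCTTCC
bac32        GGAAGATCGATCCGGTAGGTACCGGAAGGGCTTCTTCAAGAAGCCCCCGTTGGCGCAACCAACGGTGGTGCTTCGACGGCACCGATCTTCC
#=GC SS_cons <<<<<<<<..<<<<<<....>>>>>>.<<<<<<.......>>>>>><<<<<<<.....>>>>>>>.<<<<<.......>>>>>>>>>>>>>
//
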