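>IGHV1-2*01 segment_class=V family=IGHV1 anchor_offset=288
AGCTACAGCGATCAGCGCACCTTAAAAAGATGTCTAAGTGCACTCGAAGACTACGTCGTA
GCTCCGGGCAGCCCAGTCCGTTTGGCTTTCAACTACCTGAAGGTTAGTGGGGCAGCTAAA
ACTGGTCGTCCCGTGAAGGGTAGCAAGATGAAAAACGGGCTGGCTGCGGGTACCATGAGC
TCTTGTGCCGGCGTAAGGCTGATTGATAAACAGTCCTTCCGAGTAATGAACGGAAGTTGC
AGATTCATTCAGGTTATTATCGAAGTACGGCGCCCAGGTTCTGAAACCTGC
>IGHV1-8*01 segment_class=V family=IGHV1 anchor_offset=288
TACCACCAAGGGCACTCGGGCCTTGGAGCAACATGGATTTACACTATAGCAAGCCGGAGA
TTTCCAGCCCGACCTGTGGGTATTTATTGCTGTCGTCCGGAGTTGGGTTCGAAGTTGCTA
GTCTTCAGGCTGGGCCTTTCTTGTCGCATTTGCATTGTTGAGGCCATCGCCAGTTTGCAC
ATGAACACTGTTACCCTACAATCAATATGTCTCATGTGGCTCCGACCCTGGAGAAAAGCC
CTGCAAGGGCGTGGACGCTCCGGATTGTTAGCTTCTTACTCATCGCCCTGC
>IGHV2-5*01 segment_class=V family=IGHV2 anchor_offset=288
CGGGCGAAAAGTCAGCCCGAATCGTTTGTAGACCTTCACTGGGGTGGCCCCCAAATCTTT
GTTGTGAGCGAGTGGGTCAAGCCGCGCAACTTGTGCGATGGTTGTGTATCGTGCAACACG
TTGGCCCCCCTACTGAATGAACCCAAACAGGAGAAATCGCTCCATATCGGCAAATCGGGA
GCTGGGCTGGGACGTATGCCTGAAACAGGGGCACATCCCGTGAAAGGCGGGTTGAATTCT
TTGCCTCTATGGATCGCCACGAGACGTCGCCTTGTTCTAAAGTGCGTGTGC
>IGHV2-26*01 segment_class=V family=IGHV2 anchor_offset=288
AGATGTGTCGGGGTCGCCCTCAGCTTTGCGAAAACCCCACGGCATATTAGAGGGCGTCGC
GGTCTTGAGTTTAGCTTGGATACCCAAGTTAGAAAAGACGTCCCTTGCCTAAGTAATCCA
GCTAACGGTACAAAAAGGCTTCATATAAATGGTGGTGGTATAACAATTCAGTACCAACCA
GCTGAGCCAAGTTCGTCTTCACACAAGGATCCCATAGTTCTACGTCACATGTCCGTCACA
GACACAACTTATCCAGTCTACACCCCTGACTCCCGTCCGGTACCTGGCTGC
>IGHV3-23*01 segment_class=V family=IGHV3 anchor_offset=288
AGAACTACAAGGATACGGGAATGTCATGCTTCCCTACGTGGAGCTAATTCGGCGATTCCC
ATAAGACCACGGTGCCTTCAGATAACTTTCGATCAACTCACGATCGGGAAGGAGTTGTTG
CATGTTGGATATGGACAGATCAAAGAGGTTACCTACGAATTGATAATTTCTATAAGCGAG
ACATGGCCTCACCGTCGCTCACTAATGGAGCATCCAGATTTGCTTAAATCCTTGTTTTGG
GAGCGCAGCCACCCGCAGAAGGTGGACACAGCCTACTTCGGATTACGCTGT
>IGHV3-7*01 segment_class=V family=IGHV3 anchor_offset=288
GCGTACAAACCTGTCATTGCAACCTTGTGGACCCGACTTGGCGATACGAACGATTCAGGG
TTATTAAATAGGTGTAGTATCGCAGCCCTTGTAATGGTGTTCCTACGTCCCTTACCACAT
CCTCAATCTTGTCGTAACTCTGCGAAGCGTATGAACCATCGTGAACAACCGGAGTCTGCT
TTACCCTTTTCCCTCAGGAGGGATGAGCCGACTTTCCATGGTCACGCGATCGGCACCCGG
TTCCGGTTATATACTTCCCAGATAGGTCCTGCTTGTCATGTCGTCACTTGC
>IGHV4-34*01 segment_class=V family=IGHV4 anchor_offset=288
AGCCGCTCCAGGGGGTCCGGCCAGGGAGCCAAATTTACAGGGTTGTCCCTTGACACGGGC
ACTGAGGAAGGGTTCTCCCGCCGCTCCCCAGCTTTAGTTAACAATGATACGAATAGGCAG
CGGAGACATTTTGCTGCAATTCTCCCACGTTTCGGTCATACGTCTCGGACAAAGGCCAGA
AGCGCTCTCAGACTATGGGAAGGTAGGATACCTATGGCAGCAGGTTTTAGCGGCGGTCGG
GACCATACGTCTGGCTGGTCCTTCGAACTTTCGAGTTGGAGCTGGTGGTGC
>IGHV4-59*01 segment_class=V family=IGHV4 anchor_offset=288
AGCACACAAATCTTGCTCCGAGGGTTAGAGGTCTATCTTTCCAGAGTTGCGATAAGTTCT
GCCTGCAGGGATAGGGCATTGTCAGTTCCCCCTTCATATCTACCGGGTCGTTGTGCTGGC
CAATACTTCCGCGGAGAGAACGTGAACACATTATGCATCGATCGCCTCGAACAGAATTTG
GGACCCCCCTTTCACACCTGTAAAAATACGGGTAAACACTTGCGGGTTAAGCTCAGGTCG
GGGGACATTTGGCTGGCCGGATGGTATTGGGAGACGATTGCCGAGTGTTGC
>IGHV5-51*01 segment_class=V family=IGHV5 anchor_offset=288
GTATTCCGCTGGCGACACTCTCGCCCCCATTCTCGGAGACACCACAAGCTATGTTCTTAC
GATGAGGCGGCACCTCAAGTGATGCACACGAGGTACGGAGGATTCGGACTACAGACAATA
AAGTGTTCGATAATCTCGATACAGTTTCGTGATTCGGAGGGGTCACTCTGTCTTAGGCGT
AGGTTGGCATTTCAGCCAAAGCAGTTCAATGTTCCAAAGGTACGTGGCCCACTTTCTAGT
GCACTCCTGACTGCAGCCTCTAACTCAGAGTCCCGGGCGACGGACATATGT
>IGHV5-10*01 segment_class=V family=IGHV5 anchor_offset=288
TCCCATATTCCCTTGTGCTATACGTTGGACCGAGATCCCTGCGGTATCTGGCAGGAGTCC
CCTAACGATCAAAAGTCCGGTCAGAGGCCGATAGGCCCGCCTCTCCGAATCGTGCCGGCG
TTAGCGCGGCGGAGCGCTGCGCTTCCCGTATTTAATGGAACACCGAGCTCCACTCACCTC
CTTCCCAGCCACTTTATCACCGCCTCCAGGCGTTGGCAGAGCGTACTCCAGCTGATCAGC
CATCGATTTGTAAATGGCCACGCAGACCGCGGGAGACTCCGACGTGTTTGC
>IGHJ2*01 segment_class=J family=IGHJ anchor_offset=0
TTCCTGTTTTCCCGTGTCCACCCGACCATAGACCACCTGCGTCATGTG
>IGHJ4*01 segment_class=J family=IGHJ anchor_offset=0
TGGCAAACGAAATTTGAAACCCGCATGTATCTCCGGTTTAACCTGGTC
>IGHJ5*01 segment_class=J family=IGHJ anchor_offset=0
TGGGGGCAGTACCCTGAAGATCGTGGGCTACTATGCAAGTTCTCGGTA
>IGHJ6*01 segment_class=J family=IGHJ anchor_offset=0
TGGCGTGTTTCTCAATCTCTATTCTGCCAAATGCAACTTCATAAACGT
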