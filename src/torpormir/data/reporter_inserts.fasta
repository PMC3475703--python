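>UBE2I_miR-200bc UBE2I 3'UTR predicted miR-200b/c target region
attttaatattgatgtcagtatttca
>UBE2I_miR-182 UBE2I 3'UTR predicted miR-182 target region
tgccgctcctctctagaacct
>UBE2I_miR-183 UBE2I 3'UTR predicted miR-183 target region
ggcatcgagaccctggcaactgcaccggtgccagct
>NEDD8_miR-200bc NEDD8 3'UTR predicted miR-200b/c target region
tgtgaggatcccaggattcagtattc
>NEDD8_miR-182 NEDD8 3'UTR predicted miR-182 target region
ttatgactgtgtccctggttgtcaat
>UFM1_miR-141 UFM1 3'UTR predicted miR-141 target region
attagccaactgttaactggaagctt
>UFM1_miR-183 UFM1 3'UTR predicted miR-183 target region
aaaagaattatggaccctggatggcaatttgc
>SUMO1_miR-141 SUMO-1 3'UTR predicted miR-141 target region
cactcctggactgtgactttcagtgggagatg
>SUMO1_miR-96 SUMO-1 3'UTR predicted miR-96 target region
ttgcataaatactggaaattgcacatggta
>SUMO3_miR-200c SUMO-3 3'UTR predicted miR-200c target region
catcctcgcattgctgttgaatggtgagcacg
>SUMO3_miR-200c_2 SUMO-3 3'UTR second predicted miR-200c target region
ttcctgtttgctgtatgggctcgggtg
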