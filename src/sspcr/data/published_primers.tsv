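gene	role	tier	name	sequence
gadA	outer	I	gadA_oSSP_I	GGATGCTGCCTTCGGTGGGTTATTT
gadA	outer	II	gadA_oSSP_II	GGTTTAGGGTGGATCGTATGGCGT
gadA	outer	III	gadA_oSSP_III	ACAACAATGCTGATACGCTGCCAGA
gadA	semi	I	gadA_semi_oSSP_I	ACTCCAACGGCATCCTGGGTTATTT
gadA	semi	II	gadA_semi_oSSP_II	TAAGGTCTTCACTGCGTATGGCGT
gadA	semi	III	gadA_semi_oSSP_III	TACTTTCCATAACACCGCTGCCAGA
gadA	inner		gadA_iSSP	ACGGTTGACTCCATTGCCATTAACT
gadR	outer	I	gadR_oSSP_I	TAGCCAACCGTAAACCTGCGTAAAA
gadR	outer	II	gadR_oSSP_II	AACTATCACCCCACAACGTCATCTC
gadR	outer	III	gadR_oSSP_III	GGATACTGGCTAAAATGAATTAACTCGGAT
gadR	semi	I	gadR_semi_oSSP_I	AGCTGCGATACTCCACTGCGTAAAA
gadR	semi	II	gadR_semi_oSSP_II	GGTCCAGCATAGGGTACGTCATCTC
gadR	semi	III	gadR_semi_oSSP_III	CATGTAATAACCTCGCTTCATAACTCGGAT
gadR	inner		gadR_iSSP	ACCGTTCATAGGCGAAATTGTTTGT
hyg	outer	I	hyg_oSSP_I	AAGACCTGCCTGAAACCGAACTGC
hyg	outer	II	hyg_oSSP_II	AGTTTAGCGAGAGCCTGACCTATTG
hyg	outer	III	hyg_oSSP_III	GGAAGTGCTTGACATTGGGGAGT
hyg	semi	I	hyg_semi_oSSP_I	TTAGAACTGACCCGACCGAACTGC
hyg	semi	II	hyg_semi_oSSP_II	CCGCCTAGCCACTGATGACCTATTG
hyg	semi	III	hyg_semi_oSSP_III	CTTCTCAGCCTGGATTGGGGAGT
hyg	inner		hyg_iSSP	CAAGGAATCGGTCAATACATACATGGC
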