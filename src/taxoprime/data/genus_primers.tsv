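name	target_genus	marker	orientation	sequence	annealing_temp	product_size
Sph-rbcLX-F	Sphaerospermopsis	rbcLX	forward	AAAATCTATGGGGCTGGGTC	59	461
Sph-rbcLX-R	Sphaerospermopsis	rbcLX	reverse	ACTATTTGGTTTTTGGCACTTA	59	461
Cus-rpoB-F	Cuspidothrix	rpoB	forward	TCGCCTATTCTCACCAATGG	58	496
Cus-rpoB-R	Cuspidothrix	rpoB	reverse	ATCAAAGGTCCACAAGTACC	58	496
Raphi-rpoC1-F	Raphidiopsis	rpoC1	forward	TACCCTCAAGCCAGAAATGG	55	353
Raphi-rpoC1-R	Raphidiopsis	rpoC1	reverse	TGGTCTTCTGTTAATAACTGC	55	353
Cyl-rpoC1-F	Cylindrospermopsis	rpoC1	forward	ATTTTGTGAGCGGATCTTTG	55	325
Cyl-rpoC1-R	Cylindrospermopsis	rpoC1	reverse	GGTCTTCTGTTAACAGTTGT	55	325
Chry-cpcBA-F	Chrysosporum	cpcBA	forward	TTGAACGGTTTGCGCGAAACC	58	449
Chry-cpcBA-R	Chrysosporum	cpcBA	reverse	ACAGCTTCGGTTGCACCATCAATT	58	449
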